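"""Map fitted pH optima onto categorical pH-response groups.

Single-optimum taxa are "acid" (optimum < 5.2), "mid" (5.2–7) or "neutral"
(> 7). Plateau fits carry two optima spanning the plateau; when these
straddle a threshold the taxon gets a range class ("acid_to_mid",
"mid_to_neutral", "acid_to_neutral"). Flat fits (type I) have no optimum and
are classed "no_preference". Optima landing exactly on a threshold belong to
the closed middle band.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "RESPONSE_CLASSES",
    "CLASS_BANDS",
    "ResponseClassification",
    "classify_response",
    "classify_fit",
    "summarize_classes",
]

T_LOW = 5.2
T_HIGH = 7.0

RESPONSE_CLASSES = (
    "acid",
    "mid",
    "neutral",
    "acid_to_mid",
    "acid_to_neutral",
    "mid_to_neutral",
    "no_preference",
)

# pH bands spanned by each class; used when range classes must agree with a band
CLASS_BANDS = {
    "acid": frozenset({"acid"}),
    "mid": frozenset({"mid"}),
    "neutral": frozenset({"neutral"}),
    "acid_to_mid": frozenset({"acid", "mid"}),
    "acid_to_neutral": frozenset({"acid", "mid", "neutral"}),
    "mid_to_neutral": frozenset({"mid", "neutral"}),
    "no_preference": frozenset(),
}


@dataclass(frozen=True)
class ResponseClassification:
    otu_id: str
    response_class: str
    optima_pH: tuple[float, ...] = ()
    thresholds: tuple[float, float] = (T_LOW, T_HIGH)


def _band(optimum: float, t_low: float, t_high: float) -> str:
    if optimum < t_low:
        return "acid"
    if optimum > t_high:
        return "neutral"
    return "mid"


def classify_response(
    optima: Sequence[float] | float | None,
    t_low: float = T_LOW,
    t_high: float = T_HIGH,
) -> str:
    """Response class for zero, one or two (sorted ascending) pH optima."""
    if not t_low < t_high:
        raise ValueError(f"t_low ({t_low}) must be below t_high ({t_high})")
    if optima is None:
        return "no_preference"
    if isinstance(optima, (int, float)):
        optima = (float(optima),)
    optima = tuple(float(o) for o in optima)
    if len(optima) == 0:
        return "no_preference"
    if len(optima) == 1:
        return _band(optima[0], t_low, t_high)
    if len(optima) == 2:
        o1, o2 = optima
        if o1 > o2:
            raise ValueError(f"optima must be sorted ascending, got {optima}")
        b1, b2 = _band(o1, t_low, t_high), _band(o2, t_low, t_high)
        if b1 == b2:
            return b1
        if (b1, b2) == ("acid", "mid"):
            return "acid_to_mid"
        if (b1, b2) == ("acid", "neutral"):
            return "acid_to_neutral"
        if (b1, b2) == ("mid", "neutral"):
            return "mid_to_neutral"
        raise AssertionError("unreachable")  # pragma: no cover
    raise ValueError(f"expected at most two optima, got {len(optima)}")


def classify_fit(fit, t_low: float = T_LOW, t_high: float = T_HIGH) -> ResponseClassification:
    """Classify a finalized :class:`~ecohof.hof_fit.HOFFit` by its optima."""
    optima = tuple(sorted(fit.optima_pH))
    return ResponseClassification(
        otu_id=fit.otu_id,
        response_class=classify_response(optima, t_low, t_high),
        optima_pH=optima,
        thresholds=(t_low, t_high),
    )


def summarize_classes(classes: Iterable[ResponseClassification | str]) -> dict[str, float]:
    """Proportion of OTUs per response class (sums to 1, no_preference included)."""
    labels = [c.response_class if isinstance(c, ResponseClassification) else str(c) for c in classes]
    if not labels:
        raise ValueError("no classifications to summarize")
    counts = Counter(labels)
    n = len(labels)
    return {lbl: counts[lbl] / n for lbl in sorted(counts)}
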