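"""Indicator species analysis (IndVal) over pH bands, with permutation tests.

Samples are grouped into acid / mid / neutral bands by the same pH 5.2 and 7
thresholds used for response classification. For OTU i and group g the
group-equalized indicator value is

    IndVal_ig = 100 * A_ig * B_ig

where A_ig (specificity) is the group-mean within-sample relative abundance
of i in g divided by the sum of those group means over all groups, and B_ig
(fidelity) is the fraction of g's samples that contain i. Significance is a
label-permutation test on the per-OTU maximum IndVal with the add-one
estimator p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu_table import OTUTable, relative_abundance
from .response_classify import CLASS_BANDS, T_HIGH, T_LOW

__all__ = [
    "IndicatorResult",
    "assign_ph_groups",
    "indval",
    "indval_permutation_test",
    "significant_indicators",
    "crosstab_indicators_vs_reference",
]

PH_BANDS = ("acid", "mid", "neutral")


@dataclass(frozen=True)
class IndicatorResult:
    otu_id: str
    group: str
    indval: float
    p_value: float
    A: float
    B: float


def assign_ph_groups(
    metadata_or_samples, t_low: float = T_LOW, t_high: float = T_HIGH
) -> pd.Series:
    """Band per sample: acid (< t_low), mid (t_low..t_high, closed), neutral (> t_high)."""
    if isinstance(metadata_or_samples, OTUTable):
        ph = metadata_or_samples.ph
    elif isinstance(metadata_or_samples, pd.DataFrame):
        ph = metadata_or_samples["pH"]
    elif isinstance(metadata_or_samples, pd.Series):
        ph = metadata_or_samples
    else:  # sequence of Sample
        ph = pd.Series({s.sample_id: s.pH for s in metadata_or_samples})
    if ph.isna().any():
        raise ValueError(f"missing pH for samples: {ph.index[ph.isna()].tolist()}")
    bands = np.where(ph < t_low, "acid", np.where(ph > t_high, "neutral", "mid"))
    return pd.Series(bands, index=ph.index, name="ph_group")


def _group_matrix(groups: pd.Series, sample_ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    groups = groups.loc[list(sample_ids)]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError(f"need at least 2 groups, got {labels}")
    G = np.stack([(groups == lbl).to_numpy(dtype=float) for lbl in labels], axis=1)
    if (G.sum(axis=0) == 0).any():
        raise ValueError("empty group")
    return G, labels


def _indval_matrix(R: np.ndarray, P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B, indval as (n_otus, n_groups) arrays from relative abundances R,
    presence P and group indicator G."""
    sizes = G.sum(axis=0)
    m = (R @ G) / sizes  # group-equalized mean relative abundance
    denom = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, m / denom, 0.0)
    B = (P @ G) / sizes
    return A, B, 100.0 * A * B


def indval(table: OTUTable, groups: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Group-equalized IndVal per OTU and group.

    Returns a long DataFrame with columns otu_id, group, A, B, indval.
    Specificity A uses within-sample relative abundances (depth robustness);
    fidelity B uses presence/absence.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    G, labels = _group_matrix(groups, table.sample_ids)
    R = relative_abundance(table).to_numpy()
    P = (table.counts.to_numpy() > 0).astype(float)
    A, B, iv = _indval_matrix(R, P, G)
    rows = []
    for i, otu in enumerate(table.otu_ids):
        for j, lbl in enumerate(labels):
            rows.append((otu, lbl, A[i, j], B[i, j], iv[i, j]))
    return pd.DataFrame(rows, columns=["otu_id", "group", "A", "B", "indval"])


def indval_permutation_test(
    table: OTUTable,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values for the per-OTU maximum IndVal.

    Group labels are permuted over samples; p = (1 + #{permuted max-IndVal >=
    observed}) / (1 + n_perm), hence p in (0, 1]. Deterministic given seed.

    Returns a DataFrame indexed by otu_id with columns group (argmax band),
    indval, A, B, p_value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    G, labels = _group_matrix(groups, table.sample_ids)
    R = relative_abundance(table).to_numpy()
    P = (table.counts.to_numpy() > 0).astype(float)
    A, B, iv = _indval_matrix(R, P, G)
    best_j = np.argmax(iv, axis=1)
    obs = iv[np.arange(iv.shape[0]), best_j]

    rng = np.random.default_rng(seed)
    n = G.shape[0]
    exceed = np.zeros(iv.shape[0], dtype=np.int64)
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        _, _, ivp = _indval_matrix(R, P, G[perm])
        exceed += ivp.max(axis=1) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "group": [labels[j] for j in best_j],
            "indval": obs,
            "A": A[np.arange(len(best_j)), best_j],
            "B": B[np.arange(len(best_j)), best_j],
            "p_value": p,
        },
        index=pd.Index(table.otu_ids, name="otu_id"),
    )


def significant_indicators(
    table: OTUTable,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Indicator OTUs at significance level alpha (default p <= 0.05)."""
    res = indval_permutation_test(table, groups, n_perm=n_perm, seed=seed)
    return res[res["p_value"] <= alpha]


def crosstab_indicators_vs_reference(
    indicators: pd.DataFrame,
    best_hits: Mapping[str, object],
    reference_classes: Mapping[str, object],
) -> dict:
    """Compare indicator bands against the pH classes of their reference matches.

    Each significant indicator with a best hit inherits the matched reference
    OTU's response class and optima. Agreement is the fraction of matched
    indicators whose inherited class covers their observed band (range
    classes such as acid_to_mid agree with any band they span). Indicators
    without a best hit are excluded from the agreement denominator and
    counted separately.

    Parameters
    ----------
    indicators
        Output of :func:`significant_indicators` (indexed by query otu_id,
        with a ``group`` column).
    best_hits
        query_id -> MatchHit, from :func:`~ecohof.sequence_match.apply_hit_criteria`.
    reference_classes
        reference otu_id -> ResponseClassification.

    Returns
    -------
    dict with keys ``table`` (per-indicator DataFrame), ``contingency``
    (observed band x inherited class counts), ``agreement`` (fraction),
    ``n_matched`` and ``n_unmatched``.
    """
    rows = []
    for otu_id, row in indicators.iterrows():
        hit = best_hits.get(otu_id)
        if hit is None:
            rows.append((otu_id, row["group"], None, None, None, None))
            continue
        ref = reference_classes.get(hit.subject_id)
        if ref is None:
            raise KeyError(f"no reference classification for {hit.subject_id!r}")
        optima = ref.optima_pH
        pred_opt = float(np.mean(optima)) if len(optima) else np.nan
        agrees = row["group"] in CLASS_BANDS[ref.response_class]
        rows.append((otu_id, row["group"], hit.subject_id, ref.response_class, pred_opt, agrees))
    out = pd.DataFrame(
        rows,
        columns=["otu_id", "observed_band", "reference_id", "predicted_class",
                 "predicted_optimum_pH", "agrees"],
    ).set_index("otu_id")
    matched = out[out["reference_id"].notna()]
    n_matched = len(matched)
    agreement = float(matched["agrees"].mean()) if n_matched else float("nan")
    contingency = (
        pd.crosstab(matched["observed_band"], matched["predicted_class"])
        if n_matched
        else pd.DataFrame()
    )
    return {
        "table": out,
        "contingency": contingency,
        "agreement": agreement,
        "n_matched": n_matched,
        "n_unmatched": len(out) - n_matched,
    }
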