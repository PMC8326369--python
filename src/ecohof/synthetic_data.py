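"""Synthetic OTU tables over a pH gradient with known HOF response shapes.

The generator emulates the structure of a large national soil survey: sample
pH drawn uniformly over the observed 3.63–8.75 range, sequencing depths with
a log-normal spread, taxa following known HOF shapes (types I–V) with
Poisson count noise, and paired reference/query studies in which rare query
taxa are least likely to be shared with the reference set.

Counts are generated directly from the response curves (count ~ Poisson(mu)
with mu = hof_response at the sample's scaled pH); realized sample depths are
therefore the column sums of the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hof_fit import MODEL_TYPES, hof_response, model_optima, scale_gradient
from .otu_table import OTUTable, Sample, table_from_arrays
from .response_classify import classify_response
from .sequence_match import MatchHit

__all__ = [
    "SyntheticTruth",
    "StudyPair",
    "generate_gradient",
    "generate_truths",
    "generate_community",
    "generate_study_pair",
    "truth_response",
]

PH_MIN = 3.63
PH_MAX = 8.75

# aggregate vegetation classes of the survey, grouped by typical pH band
_HABITATS_ACID = ("heath and bog", "moorland grass mosaics", "upland wooded")
_HABITATS_MID = ("infertile grassland", "lowland wooded")
_HABITATS_NEUTRAL = ("crops and weeds", "fertile grassland", "tall grass and herb")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating model of one synthetic OTU (the recovery target)."""

    otu_id: str
    model_type: str
    params: tuple[float, ...]
    M: float
    reversed_gradient: bool = False
    gradient_range: tuple[float, float] = (PH_MIN, PH_MAX)
    true_optima: tuple[float, ...] = ()
    response_class: str = "no_preference"


@dataclass
class StudyPair:
    """A reference study plus an independent query study.

    Query OTUs are a mix of reference-shared taxa (same generating response,
    listed in ``shared_map``) and novel taxa; sharing probability increases
    with reference abundance, so rare taxa are disproportionately unique to
    one study. ``match_hits`` are simulated alignment records placing shared
    pairs above and novel taxa below the hit criteria.
    """

    reference: OTUTable
    reference_truths: list[SyntheticTruth]
    query: OTUTable
    query_truths: list[SyntheticTruth]
    shared_map: dict[str, str]
    match_hits: list[MatchHit] = field(default_factory=list)


def truth_response(truth: SyntheticTruth, ph) -> np.ndarray:
    """Noiseless expected count of a truth at given pH value(s)."""
    x = scale_gradient(ph, *truth.gradient_range)
    if truth.reversed_gradient:
        x = 1.0 - x
    return hof_response(x, truth.model_type, truth.params, truth.M)


def generate_gradient(
    n_samples: int,
    ph_min: float = PH_MIN,
    ph_max: float = PH_MAX,
    seed: int | None = None,
    *,
    median_depth: float = 10_000.0,
    depth_sigma: float = 0.5,
    min_depth: int = 1_000,
    id_prefix: str = "S",
) -> list[Sample]:
    """Samples with pH uniform on [ph_min, ph_max] and log-normal depths.

    Depths are log-normal (median ``median_depth``, log-sd ``depth_sigma``)
    truncated below at ``min_depth``, emulating the depth spread of a real
    survey. Habitat labels are drawn from the survey's aggregate vegetation
    classes, tied loosely to the sample's pH band. Deterministic given seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not ph_min < ph_max:
        raise ValueError(f"invalid pH range [{ph_min}, {ph_max}]")
    rng = np.random.default_rng(seed)
    ph = rng.uniform(ph_min, ph_max, size=n_samples)
    depths = np.maximum(
        rng.lognormal(mean=math.log(median_depth), sigma=depth_sigma, size=n_samples),
        min_depth,
    ).astype(np.int64)
    width = max(4, len(str(n_samples)))
    samples = []
    for i in range(n_samples):
        if ph[i] < 5.2:
            pool = _HABITATS_ACID
        elif ph[i] <= 7.0:
            pool = _HABITATS_MID
        else:
            pool = _HABITATS_NEUTRAL
        samples.append(
            Sample(
                sample_id=f"{id_prefix}{i + 1:0{width}d}",
                pH=float(ph[i]),
                depth=int(depths[i]),
                habitat=str(rng.choice(pool)),
            )
        )
    return samples


def _finish_truth(
    otu_id: str,
    model_type: str,
    params: tuple[float, ...],
    M: float,
    reversed_gradient: bool,
    gradient_range: tuple[float, float],
) -> SyntheticTruth:
    optima = model_optima(model_type, params, M, gradient_range, reversed_gradient)
    optima = tuple(sorted(float(np.clip(o, *gradient_range)) for o in optima))
    return SyntheticTruth(
        otu_id=otu_id,
        model_type=model_type,
        params=params,
        M=M,
        reversed_gradient=reversed_gradient,
        gradient_range=gradient_range,
        true_optima=optima,
        response_class=classify_response(optima),
    )


def _draw_truth(
    rng: np.random.Generator,
    otu_id: str,
    model_type: str,
    *,
    strong: bool,
    gradient_range: tuple[float, float],
) -> SyntheticTruth:
    """One truth of the requested type, rejection-sampled until identifiable.

    Default priors: a, c ~ U(-10, 5); b, |d| ~ U(2, 60); M ~ log-U[5, 500].

    The ``strong`` variant raises the floors to |b| >= 10 and M >= 50 and
    additionally rejection-samples until the type's distinguishing features
    express within the gradient window, without which no fitting procedure
    could identify the generating shape from counts alone:

    * a unimodal (IV/V) truth must have an interior optimum (x in
      [0.15, 0.85]) and decline to <= 35% of its peak at *both* window ends —
      a unimodal curve whose near flank never falls is observationally a
      plateau;
    * a skewed (V) truth needs a clear rate asymmetry (2-5x) between flanks,
      since V with |d| = b is exactly IV;
    * a monotone (II) truth must not saturate within the window (top of the
      curve <= ~0.8 of the asymptote): the plateau family (III) is closed
      under rescaling while II is not, so a II curve flat-topped below the
      max-count scaling constant is indistinguishable from III;
    * a plateau (III) truth needs its rise completed inside the window with
      the plateau occupying >= 35% of it;
    * a flat (I) truth needs a mean count >= 10 to dominate Poisson noise.
    """
    b_lo = 10.0 if strong else 2.0
    m_lo = 50.0 if strong else 5.0
    rev = bool(rng.integers(0, 2))
    xs = np.linspace(0.0, 1.0, 501)
    for _ in range(1000):
        M = float(np.exp(rng.uniform(np.log(m_lo), np.log(500.0))))
        if model_type == "I":
            a = float(rng.uniform(-3.0, 3.0))
            if strong and M / (1.0 + math.exp(a)) < 10.0:
                continue
            return _finish_truth(otu_id, "I", (a,), M, rev, gradient_range)
        b = float(rng.uniform(b_lo, 60.0))
        if model_type == "II":
            if strong:
                a = float(rng.uniform(-1.5, 0.5))  # top of curve in [0.38, 0.82]
            else:
                a = float(rng.uniform(-10.0, 5.0))
            mu = hof_response(np.array([0.0, 1.0]), "II", (a, b), M)
            if strong and abs(mu[1] - mu[0]) < 0.3 * M:
                continue
            return _finish_truth(otu_id, "II", (a, b), M, rev, gradient_range)
        if model_type == "III":
            if strong:
                a = float(rng.uniform(-10.0, -4.0))
                c = float(rng.uniform(-2.0, 1.0))
                # plateau (saturated region) covers >= 35% of the window and
                # the descending limb completes within it
                if (-4.0 - a) / b < 0.35 or a + b < 4.0:
                    continue
            else:
                a = float(rng.uniform(-10.0, 5.0))
                c = float(rng.uniform(-10.0, 5.0))
            return _finish_truth(otu_id, "III", (a, b, c), M, rev, gradient_range)
        if model_type == "IV":
            a = float(rng.uniform(-10.0, 5.0))
            c = float(rng.uniform(-10.0, 5.0))
            if strong:
                x_opt = (c - a) / (2.0 * b)
                if not 0.15 <= x_opt <= 0.85:
                    continue
                peak = float(hof_response(x_opt, "IV", (a, b, c), M))
                ends = hof_response(np.array([0.0, 1.0]), "IV", (a, b, c), M)
                if peak < 15.0 or (ends > 0.35 * peak).any():
                    continue
            return _finish_truth(otu_id, "IV", (a, b, c), M, rev, gradient_range)
        if model_type == "V":
            a = float(rng.uniform(-10.0, 5.0))
            c = float(rng.uniform(-10.0, 5.0))
            if strong:
                ratio = float(rng.uniform(2.0, 5.0))
                d = -(b * ratio if rng.integers(0, 2) else b / ratio)
                if abs(d) > 200.0 or abs(d) < 4.0:
                    continue
            else:
                d = -float(rng.uniform(2.0, 60.0))
            vals = hof_response(xs, "V", (a, b, c, d), M)
            i = int(np.argmax(vals))
            if strong:
                if not 0.15 <= xs[i] <= 0.85:
                    continue
                if vals[i] < 15.0 or vals[0] > 0.35 * vals[i] or vals[-1] > 0.35 * vals[i]:
                    continue
            return _finish_truth(otu_id, "V", (a, b, c, d), M, rev, gradient_range)
        raise ValueError(f"unknown model type {model_type!r}")
    raise RuntimeError(f"could not draw an identifiable type-{model_type} truth")


def generate_truths(
    n_otus: int,
    seed: int | None = None,
    *,
    strong: bool = False,
    model_types: Sequence[str] = MODEL_TYPES,
    ph_min: float = PH_MIN,
    ph_max: float = PH_MAX,
    id_prefix: str = "OTU",
) -> list[SyntheticTruth]:
    """Truths stratified round-robin over ``model_types`` (default: all five)."""
    if n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_otus)))
    return [
        _draw_truth(
            rng,
            f"{id_prefix}{i + 1:0{width}d}",
            model_types[i % len(model_types)],
            strong=strong,
            gradient_range=(ph_min, ph_max),
        )
        for i in range(n_otus)
    ]


def generate_community(
    samples: Sequence[Sample],
    truths: Sequence[SyntheticTruth],
    seed: int | None = None,
) -> OTUTable:
    """Poisson counts from the truths' response curves: count ~ Poisson(mu).

    Zero truths yield an empty (0-OTU) table.
    """
    rng = np.random.default_rng(seed)
    ph = np.array([s.pH for s in samples])
    if len(truths) == 0:
        return table_from_arrays(
            np.zeros((0, len(samples)), dtype=np.int64), [], samples)
    mu = np.vstack([truth_response(t, ph) for t in truths])
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite expected counts")
    counts = rng.poisson(mu)
    return table_from_arrays(counts, [t.otu_id for t in truths], samples)


def _simulate_match_records(
    rng: np.random.Generator,
    query_truths: Sequence[SyntheticTruth],
    shared_map: dict[str, str],
    reference_ids: Sequence[str],
) -> list[MatchHit]:
    """Alignment records placing shared pairs above and novel taxa below the
    hit criteria: shared identity ~ U(97, 100) at e-value 1e-50, novel
    identity ~ U(80, 96.9)."""
    hits = []
    ref_ids = list(reference_ids)
    for t in query_truths:
        length = int(rng.integers(380, 430))
        if t.otu_id in shared_map:
            ident = float(rng.uniform(97.0, 100.0))
            subject = shared_map[t.otu_id]
            evalue = 1e-50
        else:
            ident = float(rng.uniform(80.0, 96.9))
            subject = ref_ids[int(rng.integers(0, len(ref_ids)))]
            evalue = 1e-20
        mism = int(round(length * (1.0 - ident / 100.0)))
        hits.append(
            MatchHit(
                query_id=t.otu_id,
                subject_id=subject,
                pct_identity=round(ident, 3),
                align_len=length,
                mismatches=mism,
                gap_opens=0,
                q_start=1,
                q_end=length,
                s_start=1,
                s_end=length,
                evalue=evalue,
                bitscore=round(2.0 * length - 4.0 * mism, 1),
            )
        )
    return hits


def generate_study_pair(
    n_ref_otus: int,
    n_query_otus: int,
    shared_fraction: float,
    n_samples_each: int,
    seed: int | None = None,
    *,
    strong: bool = True,
    ph_min: float = PH_MIN,
    ph_max: float = PH_MAX,
) -> StudyPair:
    """Paired reference/query studies with abundance-biased taxon sharing.

    ``round(shared_fraction * n_query_otus)`` query OTUs reuse reference
    truths; the reused truths are drawn without replacement with probability
    decreasing in the reference taxon's abundance rank (rarest least shared).
    Novel query OTUs get fresh truths. Deterministic given seed.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    n_shared = int(round(shared_fraction * n_query_otus))
    if n_shared > n_ref_otus:
        raise ValueError(
            f"cannot share {n_shared} OTUs from a reference of {n_ref_otus}"
        )
    ss = np.random.SeedSequence(seed)
    s_truth, s_ref, s_pick, s_novel, s_query, s_match = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    ref_truths = generate_truths(
        n_ref_otus,
        seed=s_truth,
        strong=strong,
        ph_min=ph_min,
        ph_max=ph_max,
        id_prefix="REF",
    )
    ref_samples = generate_gradient(
        n_samples_each, ph_min, ph_max, seed=s_ref, id_prefix="RS")
    reference = generate_community(ref_samples, ref_truths, seed=s_ref)

    # abundance-biased sharing: linear-in-rank weight, most abundant first
    order = np.argsort([-t.M for t in ref_truths])
    weights = np.zeros(n_ref_otus)
    weights[order] = np.arange(n_ref_otus, 0, -1, dtype=float)
    weights /= weights.sum()
    shared_ref_idx = (
        s_pick.choice(n_ref_otus, size=n_shared, replace=False, p=weights)
        if n_shared
        else np.array([], dtype=int)
    )

    novel_truths = iter(
        generate_truths(
            max(n_query_otus - n_shared, 1),
            seed=s_novel,
            strong=strong,
            ph_min=ph_min,
            ph_max=ph_max,
            id_prefix="NOV",
        )
    )
    width = max(4, len(str(n_query_otus)))
    query_truths: list[SyntheticTruth] = []
    shared_map: dict[str, str] = {}
    shared_iter = iter(shared_ref_idx)
    # interleave shared and novel deterministically over query slots
    is_shared = np.zeros(n_query_otus, dtype=bool)
    if n_shared:
        is_shared[s_pick.choice(n_query_otus, size=n_shared, replace=False)] = True
    for i in range(n_query_otus):
        qid = f"Q{i + 1:0{width}d}"
        if is_shared[i]:
            src = ref_truths[next(shared_iter)]
            query_truths.append(
                SyntheticTruth(
                    otu_id=qid,
                    model_type=src.model_type,
                    params=src.params,
                    M=src.M,
                    reversed_gradient=src.reversed_gradient,
                    gradient_range=src.gradient_range,
                    true_optima=src.true_optima,
                    response_class=src.response_class,
                )
            )
            shared_map[qid] = src.otu_id
        else:
            src = next(novel_truths)
            query_truths.append(
                SyntheticTruth(
                    otu_id=qid,
                    model_type=src.model_type,
                    params=src.params,
                    M=src.M,
                    reversed_gradient=src.reversed_gradient,
                    gradient_range=src.gradient_range,
                    true_optima=src.true_optima,
                    response_class=src.response_class,
                )
            )
    query_samples = generate_gradient(
        n_samples_each, ph_min, ph_max, seed=s_query, id_prefix="QS")
    query = generate_community(query_samples, query_truths, seed=s_query)
    match_hits = _simulate_match_records(
        s_match, query_truths, shared_map, [t.otu_id for t in ref_truths])
    return StudyPair(
        reference=reference,
        reference_truths=ref_truths,
        query=query,
        query_truths=query_truths,
        shared_map=shared_map,
        match_hits=match_hits,
    )
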