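"""Predict a query study's community matrix from reference HOF fits and pH.

Each matched query OTU's expected abundance in a query sample is the matched
reference fit's response at that sample's pH, scaled to relative abundance by
the reference study's median sample depth. The predicted matrix is compared
to the observed community by non-metric multidimensional scaling (NMDS) of
Bray–Curtis dissimilarities: agreement is the squared Pearson correlation of
first-axis scores (reflection-invariant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .hof_fit import HOFFit, response_at
from .otu_table import OTUTable, Sample

__all__ = [
    "PredictedCommunity",
    "NMDSResult",
    "predict_abundance",
    "predict_community",
    "bray_curtis",
    "nmds",
    "axis1_agreement",
    "select_dominant_matched",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictedCommunity:
    """Predicted relative-abundance matrix for the matched query OTUs."""

    predicted: pd.DataFrame  # rows: query OTU ids, columns: query sample ids

    @property
    def otu_ids(self) -> list[str]:
        return self.predicted.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.predicted.columns.tolist()


@dataclass
class NMDSResult:
    scores: np.ndarray  # (n_samples, k), centered, PCA-rotated
    stress: float


def predict_abundance(fit: HOFFit, pH, ref_median_depth: float = 1.0):
    """Expected relative abundance at given pH from a reference fit.

    The fitted response (expected raw count) is divided by the reference
    study's median sample depth to yield a relative scale. pH outside the
    fitted gradient range is evaluated by affine extension, with a warning.
    """
    ph_arr = np.atleast_1d(np.asarray(pH, dtype=float))
    lo, hi = fit.gradient_range
    if (ph_arr < lo).any() or (ph_arr > hi).any():
        warnings.warn(
            f"pH outside fitted range [{lo}, {hi}]; extrapolating affinely",
            stacklevel=2,
        )
    if ref_median_depth <= 0:
        raise ValueError("ref_median_depth must be positive")
    out = response_at(fit, pH) / ref_median_depth
    return out


def predict_community(
    fits: Mapping[str, HOFFit],
    shared_map: Mapping[str, str],
    query_samples: Sequence[Sample] | pd.DataFrame,
    ref_median_depth: float = 1.0,
) -> PredictedCommunity:
    """Predicted matrix over (matched query OTU, query sample).

    ``fits`` is keyed by reference OTU id; ``shared_map`` maps query OTU id to
    reference OTU id. Every mapped query OTU must have a finalized fit.
    """
    if isinstance(query_samples, pd.DataFrame):
        sample_ids = query_samples.index.tolist()
        ph = query_samples["pH"].to_numpy(dtype=float)
    else:
        sample_ids = [s.sample_id for s in query_samples]
        ph = np.array([s.pH for s in query_samples])
    rows = {}
    for qid, rid in shared_map.items():
        fit = fits.get(rid)
        if fit is None:
            raise KeyError(f"no fit for reference OTU {rid!r} (query {qid!r})")
        rows[qid] = np.atleast_1d(predict_abundance(fit, ph, ref_median_depth))
    pred = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    pred.columns = sample_ids
    pred = pred.sort_index()
    if (pred.to_numpy().std(axis=1) == 0).all():
        logger.warning("all predicted responses are flat; matrix is rank-deficient")
    return PredictedCommunity(predicted=pred)


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between sample columns.

    d(j, k) = sum|x_ij - x_ik| / sum(x_ij + x_ik), in [0, 1], symmetric with
    zero diagonal. Two all-zero samples are defined to have d = 0.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = matrix.columns
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        cols = pd.RangeIndex(arr.shape[1])
    if (arr < 0).any():
        raise ValueError("negative abundances")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(arr.T, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=cols, columns=cols)


def _collapse_duplicates(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union-find grouping of zero-dissimilarity samples; returns
    (representative indices, group id per sample)."""
    n = d.shape[0]
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    zi, zj = np.nonzero(d == 0)
    for i, j in zip(zi, zj):
        if i < j:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    reps, group = np.unique(roots, return_inverse=True)
    return reps, group


def nmds(
    dissimilarity: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 8,
    seed: int | None = None,
    max_iter: int = 500,
) -> NMDSResult:
    """Non-metric MDS of a dissimilarity matrix (Kruskal stress-1, SMACOF).

    Best of ``n_restarts`` seeded random initializations. Zero-dissimilarity
    (duplicate) samples are collapsed before embedding and share identical
    scores. Scores are centered and rotated to principal axes so that axis 1
    carries the dominant gradient, with a deterministic sign convention.
    """
    d = dissimilarity.to_numpy(dtype=float) if isinstance(dissimilarity, pd.DataFrame) else np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if (d < 0).any():
        raise ValueError("negative dissimilarities")
    n = d.shape[0]
    if not d.any():
        raise ValueError("all dissimilarities are zero")

    reps, group = _collapse_duplicates(d)
    dr = d[np.ix_(reps, reps)]
    m = len(reps)
    if m == 1:  # pragma: no cover - excluded by the all-zero check above
        scores_r = np.zeros((1, k))
        stress = 0.0
    elif m == 2:
        scores_r = np.zeros((2, k))
        scores_r[0, 0] = -dr[0, 1] / 2
        scores_r[1, 0] = dr[0, 1] / 2
        stress = 0.0
    else:
        mds = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=n_restarts,
            max_iter=max_iter,
            eps=1e-9,
            random_state=None if seed is None else int(seed) % (2**32),
            normalized_stress=True,
        )
        scores_r = mds.fit_transform(dr)
        stress = float(mds.stress_)
    scores = scores_r[group]
    scores = scores - scores.mean(axis=0, keepdims=True)
    # rotate to principal axes (vegan-style) with deterministic signs
    u, s, vt = np.linalg.svd(scores, full_matrices=False)
    scores = scores @ vt.T
    for j in range(scores.shape[1]):
        i_max = int(np.argmax(np.abs(scores[:, j])))
        if scores[i_max, j] < 0:
            scores[:, j] = -scores[:, j]
    return NMDSResult(scores=scores, stress=stress)


def axis1_agreement(pred_scores: np.ndarray, obs_scores: np.ndarray) -> float:
    """Squared Pearson correlation of first-axis scores (reflection-invariant)."""
    a = np.asarray(pred_scores, dtype=float)
    b = np.asarray(obs_scores, dtype=float)
    a1 = a[:, 0] if a.ndim == 2 else a
    b1 = b[:, 0] if b.ndim == 2 else b
    if a1.shape != b1.shape or a1.size < 3:
        raise ValueError("need axis-1 scores of equal length >= 3")
    r = np.corrcoef(a1, b1)[0, 1]
    return float(r * r)


def select_dominant_matched(
    query_table: OTUTable,
    best_hits: Mapping[str, object],
    top_n: int = 100,
) -> dict[str, str]:
    """Top ``top_n`` query OTUs by total count that have a best hit.

    Dominance is rank by total count across all query samples (ties broken by
    id); the returned mapping query_id -> matched reference id feeds
    :func:`predict_community`.
    """
    totals = query_table.counts.sum(axis=1)
    order = sorted(totals.index, key=lambda q: (-totals[q], q))
    picked = [q for q in order if q in best_hits][:top_n]
    if len(picked) < top_n:
        logger.warning("only %d matched OTUs available for top %d", len(picked), top_n)
    return {q: best_hits[q].subject_id for q in picked}
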