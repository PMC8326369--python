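"""Sample-based species (OTU richness) accumulation curves.

The curve gives the expected cumulative number of distinct OTUs observed
after k samples, averaged over random orderings of the samples, with the
standard deviation across orderings. Curves are computed per habitat class
and pooled over all sites. An analytic sample-based rarefaction mean is kept
as an independent cross-check of the permutation estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .otu_table import OTUTable

__all__ = [
    "AccumulationCurve",
    "accumulation_curve",
    "per_habitat_curves",
    "rarefaction_mean",
]

_EXACT_LIMIT = 8  # N! enumerations are feasible only for tiny tables


@dataclass
class AccumulationCurve:
    """Mean and SD of cumulative richness after 1..N samples for one stratum."""

    n_samples: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    stratum: str = "All sites"
    n_perm: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "n_samples": self.n_samples,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def _richness_curves(presence: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Cumulative richness after k samples for each ordering (rows of orders)."""
    n = presence.shape[1]
    any_row = presence.any(axis=1)
    pres = presence[any_row]
    curves = np.empty((orders.shape[0], n), dtype=np.int64)
    for r, order in enumerate(orders):
        first = np.argmax(pres[:, order], axis=1)
        curves[r] = np.cumsum(np.bincount(first, minlength=n))
    return curves


def accumulation_curve(
    table: OTUTable,
    n_perm: int = 100,
    seed: int | None = None,
    *,
    exact: bool = False,
    stratum: str = "All sites",
) -> AccumulationCurve:
    """Accumulation curve from random permutations of sample order.

    With ``exact=True`` all N! orderings are enumerated instead (only allowed
    for very small tables), making mean and SD exact. SD uses the population
    convention, so it is exactly 0 at full depth where every ordering reaches
    the total observed richness.
    """
    n = table.n_samples
    if n < 1:
        raise ValueError("need at least one sample")
    presence = table.counts.to_numpy() > 0
    if exact:
        if n > _EXACT_LIMIT:
            raise ValueError(f"exact enumeration limited to {_EXACT_LIMIT} samples")
        orders = np.array(list(permutations(range(n))), dtype=np.int64)
        n_used = orders.shape[0]
    else:
        rng = np.random.default_rng(seed)
        orders = np.array([rng.permutation(n) for _ in range(int(n_perm))])
        n_used = int(n_perm)
    curves = _richness_curves(presence, orders)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean_richness=curves.mean(axis=0),
        sd_richness=curves.std(axis=0, ddof=0),
        stratum=stratum,
        n_perm=n_used,
    )


def per_habitat_curves(
    table: OTUTable, n_perm: int = 100, seed: int | None = None
) -> list[AccumulationCurve]:
    """One curve per habitat class plus the pooled "All sites" curve."""
    ss = np.random.SeedSequence(seed)
    habitats = sorted(table.habitats.unique())
    children = ss.spawn(len(habitats) + 1)
    curves = [
        accumulation_curve(
            table, n_perm=n_perm, seed=np.random.default_rng(children[0]))
    ]
    for child, hab in zip(children[1:], habitats):
        cols = table.metadata.index[table.habitats == hab]
        sub = OTUTable(table.counts[list(cols)], table.metadata.loc[cols, ["pH", "habitat"]])
        curves.append(
            accumulation_curve(
                sub, n_perm=n_perm, seed=np.random.default_rng(child), stratum=str(hab))
        )
    return curves


def rarefaction_mean(table: OTUTable) -> np.ndarray:
    """Analytic expected richness after k samples (sample-based rarefaction).

    E[S_k] = sum_i [1 - C(N - n_i, k) / C(N, k)] with n_i the number of
    samples containing OTU i; an independent closed-form cross-check of the
    permutation estimator's mean.
    """
    from scipy.special import gammaln

    presence = table.counts.to_numpy() > 0
    n_i = presence.sum(axis=1)
    N = table.n_samples

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    ks = np.arange(1, N + 1)
    out = np.empty(N, dtype=float)
    for j, k in enumerate(ks):
        with np.errstate(invalid="ignore"):
            ratio = np.where(
                N - n_i >= k,
                np.exp(log_comb(N - n_i, k) - log_comb(N, k)),
                0.0,
            )
        out[j] = float(np.sum(1.0 - ratio))
    return out
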