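"""Huisman–Olff–Fresco (HOF) response curves fitted by Poisson maximum likelihood.

The HOF hierarchy describes a taxon's expected abundance mu(x) along a scaled
environmental gradient x in [0, 1] as a product of logistic terms, with
g(t) = 1 / (1 + e^t):

    I    mu = M * g(a)                    flat (no trend)
    II   mu = M * g(a + b*x)              monotone increase or decrease
    III  mu = M * g(a + b*x) * g(c)       monotone trend that plateaus
    IV   mu = M * g(a + b*x) * g(c - b*x) symmetric unimodal
    V    mu = M * g(a + b*x) * g(c + d*x) skewed unimodal

M is a fixed scaling constant — the maximum observed count of the OTU — not
a free parameter, so the free-parameter counts are I:1, II:2, III:3, IV:3,
V:4 and AIC = 2k - 2*logLik is comparable across types.

Counts are modeled with a Poisson error distribution. Model choice takes the
lowest-AIC type, then hardens it against 100 bootstrap resamples: if the
modal bootstrap choice differs from the AIC choice, the bootstrap mode wins.

The slope bound b >= 0 fixes the orientation of the first logistic term;
both gradient orientations (x and 1-x) are fitted and the better likelihood
kept. The skew parameter d of model V is sign-free (a skewed unimodal shape
needs the two logistic terms to run in opposite directions).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln

__all__ = [
    "MODEL_TYPES",
    "N_FREE_PARAMS",
    "PARAM_BOUNDS",
    "HOFFit",
    "scale_gradient",
    "unscale_gradient",
    "hof_response",
    "response_at",
    "poisson_nll",
    "fit_single_model",
    "fit_all_models",
    "select_model",
    "resolve_bootstrap_choice",
    "bootstrap_select",
    "extract_optima",
    "model_optima",
]

MODEL_TYPES = ("I", "II", "III", "IV", "V")
N_FREE_PARAMS = {"I": 1, "II": 2, "III": 3, "IV": 3, "V": 4}
PARAM_BOUNDS = {
    "I": [(-50.0, 50.0)],
    "II": [(-50.0, 50.0), (0.0, 200.0)],
    "III": [(-50.0, 50.0), (0.0, 200.0), (-50.0, 50.0)],
    "IV": [(-50.0, 50.0), (0.0, 200.0), (-50.0, 50.0)],
    "V": [(-50.0, 50.0), (0.0, 200.0), (-50.0, 50.0), (-200.0, 200.0)],
}
MU_FLOOR = 1e-10
DEFAULT_GRADIENT = (3.63, 8.75)

# parsimony order used for every tie-break (fewest free parameters first)
_PARSIMONY_ORDER = {"I": 0, "II": 1, "III": 2, "IV": 3, "V": 4}


def _g(t: np.ndarray | float) -> np.ndarray | float:
    """The HOF logistic kernel g(t) = 1/(1+e^t), computed overflow-safely."""
    return expit(-np.asarray(t, dtype=float))


def scale_gradient(pH, ph_min: float, ph_max: float):
    """Affine map of pH onto [0, 1]; values outside the range extend affinely."""
    if not ph_max > ph_min:
        raise ValueError(f"ph_max ({ph_max}) must exceed ph_min ({ph_min})")
    return (np.asarray(pH, dtype=float) - ph_min) / (ph_max - ph_min)


def unscale_gradient(x, ph_min: float, ph_max: float):
    """Inverse of :func:`scale_gradient`."""
    if not ph_max > ph_min:
        raise ValueError(f"ph_max ({ph_max}) must exceed ph_min ({ph_min})")
    return ph_min + np.asarray(x, dtype=float) * (ph_max - ph_min)


def hof_response(x, model_type: str, params: Sequence[float], M: float):
    """Expected response mu(x) for one HOF type; always 0 <= mu <= M."""
    p = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite params: {params}")
    x = np.asarray(x, dtype=float)
    if model_type == "I":
        return M * _g(p[0]) * np.ones_like(x)
    if model_type == "II":
        return M * _g(p[0] + p[1] * x)
    if model_type == "III":
        return M * _g(p[0] + p[1] * x) * _g(p[2])
    if model_type == "IV":
        return M * _g(p[0] + p[1] * x) * _g(p[2] - p[1] * x)
    if model_type == "V":
        return M * _g(p[0] + p[1] * x) * _g(p[2] + p[3] * x)
    raise ValueError(f"unknown model type {model_type!r}")


def poisson_nll(counts, mu) -> float:
    """Poisson negative log-likelihood: sum(mu - y*ln(mu) + ln(y!)).

    mu is floored at a small positive value to avoid log(0) for responses
    driven to zero by saturated logistic terms.
    """
    y = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("counts and mu must have equal length")
    if (y < 0).any():
        raise ValueError("negative counts")
    mu = np.maximum(mu, MU_FLOOR)
    return float(np.sum(mu - y * np.log(mu) + gammaln(y + 1.0)))


@dataclass
class HOFFit:
    """One OTU's fitted HOF model.

    ``params`` holds the free parameters in family order (a, b, c, d),
    truncated to the type's parameter count. ``reversed_gradient`` marks fits
    obtained on the mirrored gradient 1-x. ``bootstrap_tally`` maps model
    type to the number of bootstrap resamples on which it was AIC-best.
    """

    otu_id: str
    model_type: str
    params: tuple[float, ...]
    M: float
    logLik: float
    k: int
    AIC: float
    reversed_gradient: bool = False
    gradient_range: tuple[float, float] = DEFAULT_GRADIENT
    optima_pH: tuple[float, ...] = ()
    bootstrap_tally: dict[str, int] = field(default_factory=dict)
    initial_choice: str | None = None
    n_boot_failed: int = 0


def response_at(fit: HOFFit, pH):
    """Fitted expected count at given pH value(s), honoring fit orientation."""
    x = scale_gradient(pH, *fit.gradient_range)
    if fit.reversed_gradient:
        x = 1.0 - x
    return hof_response(x, fit.model_type, fit.params, fit.M)


# ----------------------------------------------------------------------------
# likelihood + analytic gradient, used by the bounded quasi-Newton optimizer
# ----------------------------------------------------------------------------

def _nll_and_grad(theta: np.ndarray, model_type: str, x: np.ndarray, y: np.ndarray, M: float):
    """Core NLL (without the ln(y!) constant) and its gradient in theta."""
    if model_type == "II":
        g1 = _g(theta[0] + theta[1] * x)
        g2 = 1.0
        mu_raw = M * g1
    elif model_type == "III":
        g1 = _g(theta[0] + theta[1] * x)
        g2 = _g(theta[2])
        mu_raw = M * g1 * g2
    elif model_type == "IV":
        g1 = _g(theta[0] + theta[1] * x)
        g2 = _g(theta[2] - theta[1] * x)
        mu_raw = M * g1 * g2
    elif model_type == "V":
        g1 = _g(theta[0] + theta[1] * x)
        g2 = _g(theta[2] + theta[3] * x)
        mu_raw = M * g1 * g2
    else:  # pragma: no cover - type I is solved in closed form
        raise ValueError(model_type)

    mu = np.maximum(mu_raw, MU_FLOOR)
    nll = np.sum(mu - y * np.log(mu))
    w = np.where(mu_raw > MU_FLOOR, 1.0 - y / mu, 0.0)
    wm = w * mu  # common factor of all partials
    one_m_g1 = 1.0 - g1
    grad = np.empty_like(theta)
    grad[0] = -np.sum(wm * one_m_g1)
    if model_type == "II":
        grad[1] = -np.sum(wm * one_m_g1 * x)
    elif model_type == "III":
        grad[1] = -np.sum(wm * one_m_g1 * x)
        grad[2] = -np.sum(wm * (1.0 - g2))
    elif model_type == "IV":
        one_m_g2 = 1.0 - g2
        grad[1] = -np.sum(wm * x * (one_m_g1 - one_m_g2))
        grad[2] = -np.sum(wm * one_m_g2)
    elif model_type == "V":
        one_m_g2 = 1.0 - g2
        grad[1] = -np.sum(wm * one_m_g1 * x)
        grad[2] = -np.sum(wm * one_m_g2)
        grad[3] = -np.sum(wm * one_m_g2 * x)
    return nll, grad


def _logit_linear_start(x: np.ndarray, y: np.ndarray, M: float) -> tuple[float, float]:
    """(a0, b0) from a logit-linear regression of smoothed proportions.

    mu/M = g(a+bx) implies logit(mu/M) = -(a + b*x); least squares on the
    empirically smoothed proportion (y+0.5)/(M+1) gives deterministic starts.
    """
    p = np.clip((y + 0.5) / (M + 1.0), 1e-6, 1.0 - 1e-6)
    t = -np.log(p / (1.0 - p))
    A = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(A, t, rcond=None)
    return float(beta[0]), float(beta[1])


def _clip_to_bounds(theta: Sequence[float], bounds) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(th, lo, hi)


def _default_starts(model_type: str, x: np.ndarray, y: np.ndarray, M: float, fast: bool):
    """Deterministic multi-start set for one model type and orientation."""
    a0, b0 = _logit_linear_start(x, y, M)
    b0 = max(b0, 1.0)
    starts: list[list[float]] = []
    if model_type == "II":
        if fast:
            starts = [[a0, b0]]
        else:
            for da in (-2.0, 0.0, 2.0):
                for fb in (0.5, 1.0, 2.0):
                    starts.append([a0 + da, b0 * fb])
    elif model_type == "III":
        cs = (0.0,) if fast else (-2.0, 0.0, 2.0)
        starts = [[a0, b0, c] for c in cs]
    elif model_type == "IV":
        cs = (a0 + b0,) if fast else (-2.0, 0.0, 2.0, a0 + b0)
        starts = [[a0, b0, c] for c in cs]
    elif model_type == "V":
        cs = ((0.0, -b0),) if fast else ((-2.0, -b0), (0.0, -b0), (2.0, -b0), (0.0, -2.0))
        starts = [[a0, b0, c, d] for c, d in cs]
    return starts


def fit_single_model(
    counts,
    ph,
    model_type: str,
    *,
    gradient_range: tuple[float, float] | None = None,
    M: float | None = None,
    otu_id: str = "",
    extra_starts: Iterable[tuple[bool, Sequence[float]]] = (),
    orientations: tuple[bool, ...] = (False, True),
    fast: bool = False,
) -> HOFFit:
    """Fit one HOF type by bounded Poisson ML from a deterministic multi-start set.

    ``extra_starts`` is a sequence of (reversed_gradient, params) warm starts,
    typically the fits of nested types, which also guarantees the likelihood
    nesting I <= II <= {III, IV} <= V up to optimizer tolerance.
    """
    y = np.asarray(counts, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if y.shape != ph.shape:
        raise ValueError("counts and ph must have equal length")
    if (y < 0).any():
        raise ValueError("negative counts")
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    k = N_FREE_PARAMS[model_type]
    if y.size < k + 1:
        raise ValueError(f"need at least {k + 1} samples to fit type {model_type}")
    if not y.any():
        raise ValueError(f"OTU {otu_id!r}: counts are all zero")
    if gradient_range is None:
        gradient_range = (float(ph.min()), float(ph.max()))
    if M is None:
        M = float(y.max())
    x = np.asarray(scale_gradient(ph, *gradient_range), dtype=float)
    const = float(np.sum(gammaln(y + 1.0)))

    if model_type == "I":
        # closed form: the ML constant mean is the sample mean
        p = float(np.clip(y.mean() / M, 1e-12, 1.0 - 1e-12))
        a = float(np.clip(math.log((1.0 - p) / p), *PARAM_BOUNDS["I"][0]))
        mu = hof_response(x, "I", (a,), M)
        nll = poisson_nll(y, mu)
        return HOFFit(
            otu_id=otu_id, model_type="I", params=(a,), M=M, logLik=-nll, k=1,
            AIC=2 * 1 + 2 * nll, reversed_gradient=False, gradient_range=gradient_range,
        )

    bounds = PARAM_BOUNDS[model_type]
    best: tuple[float, np.ndarray, bool] | None = None
    extra = list(extra_starts)
    # fast mode trusts warm starts (bootstrap refits) and skips fresh defaults
    use_defaults = not (fast and any(len(th) == k for _, th in extra))
    for rev in orientations:
        xo = 1.0 - x if rev else x
        starts = _default_starts(model_type, xo, y, M, fast) if use_defaults else []
        starts += [list(th) for r, th in extra if r == rev and len(th) == k]
        for th0 in starts:
            th0 = _clip_to_bounds(th0, bounds)
            res = minimize(
                _nll_and_grad, th0, args=(model_type, xo, y, M), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8},
            )
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best[0]:
                best = (float(res.fun), np.asarray(res.x), rev)
    if best is None:
        raise RuntimeError(f"OTU {otu_id!r}: optimizer failed for type {model_type} from every start")
    nll_core, theta, rev = best
    nll = nll_core + const
    return HOFFit(
        otu_id=otu_id, model_type=model_type, params=tuple(float(v) for v in theta),
        M=M, logLik=-nll, k=k, AIC=2 * k + 2 * nll,
        reversed_gradient=rev, gradient_range=gradient_range,
    )


def fit_all_models(
    counts,
    ph,
    *,
    gradient_range: tuple[float, float] | None = None,
    M: float | None = None,
    otu_id: str = "",
    warm: Mapping[str, tuple[bool, Sequence[float]]] | None = None,
    fast: bool = False,
) -> dict[str, HOFFit]:
    """Fit all five HOF types, chaining each fit as a warm start for the types
    that nest it (so measured likelihoods respect the model hierarchy)."""
    warm = dict(warm or {})
    fits: dict[str, HOFFit] = {}

    def ws(t: str) -> list[tuple[bool, Sequence[float]]]:
        return [warm[t]] if t in warm else []

    fits["I"] = fit_single_model(
        counts, ph, "I", gradient_range=gradient_range, M=M, otu_id=otu_id)
    aI = fits["I"].params[0]
    fits["II"] = fit_single_model(
        counts, ph, "II", gradient_range=gradient_range, M=M, otu_id=otu_id, fast=fast,
        extra_starts=ws("II") + [(False, (aI, 0.0)), (True, (aI, 0.0))],
    )
    aII, bII = fits["II"].params
    revII = fits["II"].reversed_gradient
    chain2 = [(revII, (aII, bII, -50.0))]
    fits["III"] = fit_single_model(
        counts, ph, "III", gradient_range=gradient_range, M=M, otu_id=otu_id, fast=fast,
        extra_starts=ws("III") + chain2,
    )
    fits["IV"] = fit_single_model(
        counts, ph, "IV", gradient_range=gradient_range, M=M, otu_id=otu_id, fast=fast,
        extra_starts=ws("IV") + chain2,
    )
    aIII, bIII, cIII = fits["III"].params
    aIV, bIV, cIV = fits["IV"].params
    chain5 = [
        (fits["IV"].reversed_gradient, (aIV, bIV, cIV, -bIV)),
        (fits["III"].reversed_gradient, (aIII, bIII, cIII, 0.0)),
        (revII, (aII, bII, -50.0, 0.0)),
    ]
    fits["V"] = fit_single_model(
        counts, ph, "V", gradient_range=gradient_range, M=M, otu_id=otu_id, fast=fast,
        extra_starts=ws("V") + chain5,
    )
    return fits


def select_model(candidates: Iterable[HOFFit] | Mapping[str, HOFFit]) -> str:
    """Lowest-AIC model type; ties go to the type with fewer free parameters."""
    if isinstance(candidates, Mapping):
        cands = list(candidates.values())
    else:
        cands = list(candidates)
    if not cands:
        raise ValueError("no candidates")
    cands.sort(key=lambda f: _PARSIMONY_ORDER[f.model_type])
    best = cands[0]
    for f in cands[1:]:
        if f.AIC < best.AIC - 1e-9:
            best = f
    return best.model_type


def resolve_bootstrap_choice(initial: str, tally: Mapping[str, int]) -> str:
    """Final model type: keep the initial AIC choice if it equals the modal
    bootstrap choice, otherwise take the bootstrap mode (parsimony on ties)."""
    if not tally or sum(tally.values()) == 0:
        return initial
    top = max(tally.values())
    modal = min(
        (t for t, n in tally.items() if n == top),
        key=lambda t: _PARSIMONY_ORDER[t],
    )
    return initial if initial == modal else modal


def bootstrap_select(
    counts,
    ph,
    n_boot: int = 100,
    seed: int | None = None,
    *,
    gradient_range: tuple[float, float] | None = None,
    otu_id: str = "",
) -> HOFFit:
    """AIC model choice hardened by bootstrap: refit all five types on
    ``n_boot`` resamples of (pH, count) pairs drawn with replacement and
    override the initial choice with the modal bootstrap choice when they
    disagree. The final parameters are the original-data fit of the final type.

    Degenerate resamples (all-zero counts, optimizer failure) are excluded
    from the tally and counted in ``n_boot_failed``.
    """
    y = np.asarray(counts, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if gradient_range is None:
        gradient_range = (float(ph.min()), float(ph.max()))
    cands = fit_all_models(y, ph, gradient_range=gradient_range, otu_id=otu_id)
    initial = select_model(cands)

    rng = np.random.default_rng(seed)
    tally: Counter[str] = Counter()
    n_failed = 0
    warm = {t: (f.reversed_gradient, f.params) for t, f in cands.items() if t != "I"}
    n = y.size
    for _ in range(int(n_boot)):
        idx = rng.integers(0, n, size=n)
        yb, phb = y[idx], ph[idx]
        if not yb.any():
            n_failed += 1
            continue
        try:
            boot = fit_all_models(
                yb, phb, gradient_range=gradient_range, otu_id=otu_id, warm=warm, fast=True)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        tally[select_model(boot)] += 1

    final_type = resolve_bootstrap_choice(initial, tally)
    fit = replace(
        cands[final_type],
        bootstrap_tally={t: tally.get(t, 0) for t in MODEL_TYPES},
        initial_choice=initial,
        n_boot_failed=n_failed,
    )
    fit.optima_pH = extract_optima(fit)
    return fit


# ----------------------------------------------------------------------------
# optima
# ----------------------------------------------------------------------------

_GRID = np.linspace(0.0, 1.0, 1001)  # step 1e-3 on the scaled gradient


def model_optima(
    model_type: str,
    params: Sequence[float],
    M: float,
    gradient_range: tuple[float, float],
    reversed_gradient: bool = False,
    plateau_frac: float = 0.95,
) -> tuple[float, ...]:
    """pH optima of a HOF response.

    I yields no optimum (flat). II yields the gradient endpoint with the
    higher response. IV and V yield the interior argmax, located on a fine
    grid (step 1e-3 in x) and polished by bounded scalar minimization. III
    yields the two pH values bounding the plateau, defined as the region
    where the response is at least ``plateau_frac`` of the fitted maximum.
    """
    if model_type == "I":
        return ()

    def resp(x):
        xo = 1.0 - np.asarray(x, dtype=float) if reversed_gradient else np.asarray(x, dtype=float)
        return hof_response(xo, model_type, params, M)

    if model_type == "II":
        lo, hi = resp(0.0), resp(1.0)
        x_opt = 0.0 if lo > hi else 1.0
        return (float(unscale_gradient(x_opt, *gradient_range)),)

    vals = resp(_GRID)
    if model_type == "III":
        mx = float(vals.max())
        region = _GRID[vals >= plateau_frac * mx]
        x1, x2 = float(region.min()), float(region.max())
        p1, p2 = sorted(
            (float(unscale_gradient(x1, *gradient_range)), float(unscale_gradient(x2, *gradient_range)))
        )
        return (p1, p2)

    # IV and V: grid argmax + local refinement
    i = int(np.argmax(vals))
    lo = _GRID[max(i - 1, 0)]
    hi = _GRID[min(i + 1, len(_GRID) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda x: -float(resp(x)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-7},
        )
        x_opt = float(np.clip(res.x, 0.0, 1.0))
        if -res.fun < vals[i]:
            x_opt = float(_GRID[i])
    else:  # pragma: no cover - degenerate single-point grid
        x_opt = float(_GRID[i])
    return (float(unscale_gradient(x_opt, *gradient_range)),)


def extract_optima(fit: HOFFit, plateau_frac: float = 0.95) -> tuple[float, ...]:
    """pH optima of a finalized fit (see :func:`model_optima`)."""
    return model_optima(
        fit.model_type, fit.params, fit.M, fit.gradient_range,
        reversed_gradient=fit.reversed_gradient, plateau_frac=plateau_frac,
    )
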