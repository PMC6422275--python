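"""The six confidence intervals for a model-averaged parameter.

Wald-type intervals (Full-Wald, MA-Wald) take estimate ± quantile × se.
Tail-area intervals (MATA-Wald z/t, MATA-SBoot) solve, for the upper limit
θ_U and lower limit θ_L,

    Σ_m w_m Pr(T_m ≤ (θ̂_m - θ_U)/se_m) = α,
    Σ_m w_m Pr(T_m ≥ (θ̂_m - θ_L)/se_m) = α,

with Pr taken from N(0,1), t_{ν_m}, or the empirical distribution of the
studentized parametric-bootstrap statistic T*_m (note the bootstrap-t
reversal: the upper limit is driven by the lower tail of T*_m).  The
percentile bootstrap interval instead takes raw percentiles of per-sample
AIC-best estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, stdtr

from .averaging import ModelEstimate, WeightVector
from .boot import MIN_B, BootstrapTails, _ecdf_eval, _sufficient_resample, tail_probability
from .lognormal import LOGNORMAL_MEAN, CellTarget
from .model_space import FactorialDesign, FittedModel, TermSet, _basis, fit_model

__all__ = [
    "Interval",
    "METHODS",
    "full_wald",
    "ma_wald",
    "mata_tail_equation",
    "mata_wald",
    "mata_sboot",
    "percentile_bootstrap",
]

#: canonical method tags
METHODS = ("full_wald", "ma_wald", "mata_wald_z", "mata_wald_t", "pb", "mata_sboot")


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence interval with per-tail level alpha."""

    lower: float
    upper: float
    alpha: float
    method: str
    scale: str = "eta"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.lower > self.upper:
            raise ValueError("interval limits out of order")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def full_wald(full_estimate: ModelEstimate, alpha: float) -> Interval:
    """t-based Wald interval from the full model: θ̂ ± t_{ν,1-α}·se."""
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    half = stats.t.ppf(1 - alpha, full_estimate.nu) * full_estimate.se
    return Interval(
        full_estimate.theta_hat - half, full_estimate.theta_hat + half, alpha, "full_wald"
    )


def ma_wald(estimates, weights: WeightVector, alpha: float) -> Interval:
    """MA-Wald interval θ̄ ± z_{1-α}·sqrt(V̂(θ̄))."""
    from .averaging import ma_wald_variance, model_averaged_estimate

    theta_bar = model_averaged_estimate(estimates, weights)
    v = ma_wald_variance(estimates, weights, theta_bar, alpha)
    half = stats.norm.ppf(1 - alpha) * math.sqrt(v)
    return Interval(theta_bar - half, theta_bar + half, alpha, "ma_wald")


def _kernel_cdfs(kernel, estimates, args: np.ndarray) -> np.ndarray:
    """Pr(T_m <= args[m]) for each model under the requested kernel."""
    if isinstance(kernel, str):
        if kernel == "z":
            return ndtr(args)
        if kernel == "t":
            nu = np.array([e.nu for e in estimates], dtype=float)
            return stdtr(nu, args)
        raise ValueError(f"unknown kernel {kernel!r}")
    # sequence of BootstrapTails aligned with estimates
    return np.array(
        [tail_probability(tl, a, "lower") for tl, a in zip(kernel, args)]
    )


def mata_tail_equation(theta: float, estimates, weights: WeightVector, side: str, kernel):
    """Weighted tail mass at candidate limit theta.

    ``side="upper"`` evaluates Σ w_m Pr(T_m ≤ (θ̂_m - θ)/se_m) — the
    upper-limit equation, strictly decreasing in θ; ``side="lower"``
    evaluates Σ w_m Pr(T_m ≥ (θ̂_m - θ)/se_m), increasing in θ.
    """
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    args = np.array([(e.theta_hat - theta) / e.se for e in estimates])
    cdf = _kernel_cdfs(kernel, estimates, args)
    w = weights.weights
    if side == "upper":
        return float(w @ cdf)
    return float(w @ (1.0 - cdf))


def _initial_bracket(estimates) -> tuple[float, float]:
    theta = np.array([e.theta_hat for e in estimates])
    se_max = max(e.se for e in estimates)
    return float(theta.min() - 20 * se_max), float(theta.max() + 20 * se_max)


def _solve_limit(estimates, weights, alpha, side, kernel) -> float:
    """Root of mata_tail_equation(·) = alpha by bracketed root finding."""

    def g(theta):
        return mata_tail_equation(theta, estimates, weights, side, kernel) - alpha

    lo, hi = _initial_bracket(estimates)
    for _ in range(10):
        if g(lo) * g(hi) < 0:
            break
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        lo, hi = mid - 2 * half, mid + 2 * half
    else:
        raise RuntimeError(
            f"could not bracket the {side} limit after 10 expansions "
            f"(g({lo})={g(lo) + alpha:.3g}, g({hi})={g(hi) + alpha:.3g}, alpha={alpha})"
        )
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


def mata_wald(estimates, weights: WeightVector, alpha: float, version: str = "t") -> Interval:
    """MATA-Wald interval (z- or t-kernel tail areas)."""
    if version not in ("z", "t"):
        raise ValueError(f"version must be 'z' or 't', got {version!r}")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if len(estimates) != len(weights):
        raise ValueError("estimates and weights must have equal length")
    upper = _solve_limit(estimates, weights, alpha, "upper", version)
    lower = _solve_limit(estimates, weights, alpha, "lower", version)
    return Interval(lower, upper, alpha, f"mata_wald_{version}")


def mata_sboot(estimates, weights: WeightVector, tails, alpha: float) -> Interval:
    """MATA-SBoot interval: tail areas from the bootstrap distributions T*_m."""
    if len(estimates) != len(weights) or len(tails) != len(estimates):
        raise ValueError("estimates, weights and tails must be aligned")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if alpha < 1.0 / (min(tl.B for tl in tails) + 1):
        need = math.ceil(1.0 / alpha - 1.0)
        raise ValueError(
            f"alpha={alpha} below ECDF resolution; need B >= {need} bootstrap samples"
        )
    upper = _solve_limit(estimates, weights, alpha, "upper", tails)
    lower = _solve_limit(estimates, weights, alpha, "lower", tails)
    return Interval(lower, upper, alpha, "mata_sboot")


def _endpoints_vectorized(
    eta: np.ndarray,
    se: np.ndarray,
    nu: np.ndarray,
    w: np.ndarray,
    alpha: float,
    kernel,
    tails: np.ndarray | None = None,
    n_iter: int = 70,
) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper tail-area limits for all C cells at once.

    ``eta`` is (M, C); ``se``, ``nu``, ``w`` are (M,); for the bootstrap
    kernel ``tails`` is (M, B, C) of per-model, per-cell sorted statistics.
    Bisection on the monotone weighted tail functions.
    """
    M, C = eta.shape

    def cdf_matrix(theta: np.ndarray) -> np.ndarray:
        args = (eta - theta[None, :]) / se[:, None]  # (M, C)
        if kernel == "z":
            return ndtr(args)
        if kernel == "t":
            return stdtr(nu[:, None], args)
        return _ecdf_eval(tails, args)

    def g_upper(theta):
        return w @ cdf_matrix(theta)

    def g_lower(theta):
        return w @ (1.0 - cdf_matrix(theta))

    lo0 = eta.min() - 20 * se.max()
    hi0 = eta.max() + 20 * se.max()
    for _ in range(10):
        ok = (
            np.all(g_upper(np.full(C, lo0)) > alpha)
            and np.all(g_upper(np.full(C, hi0)) < alpha)
            and np.all(g_lower(np.full(C, lo0)) < alpha)
            and np.all(g_lower(np.full(C, hi0)) > alpha)
        )
        if ok:
            break
        mid, half = (lo0 + hi0) / 2, (hi0 - lo0) / 2
        lo0, hi0 = mid - 2 * half, mid + 2 * half
    else:
        raise RuntimeError("could not bracket tail-area limits after 10 expansions")

    out = []
    for side in ("lower", "upper"):
        lo = np.full(C, lo0)
        hi = np.full(C, hi0)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            val = g_lower(mid) if side == "lower" else g_upper(mid)
            if side == "lower":
                # g_lower increasing: root above mid where val < alpha
                below = val < alpha
            else:
                # g_upper decreasing: root above mid where val > alpha
                below = val > alpha
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out.append(0.5 * (lo + hi))
    return out[0], out[1]


def _pb_eta_stars(
    full_fit: FittedModel,
    B: int,
    rng: np.random.Generator,
    kind: str = LOGNORMAL_MEAN,
    model_idx: np.ndarray | None = None,
) -> np.ndarray:
    """(B, C) matrix of AIC-best-model estimates from full-model resamples."""
    d = full_fit.design
    basis = _basis(d.n_factors, d.factor_names)
    H, masks, p = basis["H"], basis["masks"], basis["p"]
    if model_idx is not None:
        masks, p = masks[model_idx], p[model_idx]
    C, r, n = d.n_cells, d.r, d.n
    ybar, ssw = _sufficient_resample(full_fit, B, rng)
    b = ybar @ H / C  # (B, C)
    rss = ssw[:, None] + r * C * (b**2 @ (~masks).T)  # (B, M)
    with np.errstate(divide="ignore"):
        aic = n * np.log(rss / n) + 2 * (p + 1)[None, :]
    # canonical order is by model size, so argmin's first-minimum tie-break
    # prefers fewer parameters, then canonical label order
    best = np.argmin(aic, axis=1)
    fitted = (b * masks[best]) @ H.T  # (B, C)
    sigma2 = rss[np.arange(B), best] / (n - p[best])
    if kind == LOGNORMAL_MEAN:
        fitted = fitted + sigma2[:, None] / 2.0
    return fitted


def percentile_bootstrap(
    dataset: pd.DataFrame,
    design: FactorialDesign,
    models: list[TermSet],
    target: CellTarget,
    B: int,
    alpha: float,
    rng: np.random.Generator,
) -> Interval:
    """Percentile bootstrap interval with per-sample AIC model selection.

    Bootstrap samples come from the fitted full (saturated) model; for each
    sample the AIC-best model among ``models`` supplies θ̂*, and the interval
    is the ⌈α(B+1)⌉-th and ⌈(1-α)(B+1)⌉-th order statistics of θ̂*.
    """
    if B < MIN_B:
        raise ValueError(f"B must be >= {MIN_B} to resolve 2.5% tails")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    full = max(models, key=lambda ts: ts.n_terms)
    log_y = np.log(dataset["response"].to_numpy(dtype=float))
    full_fit = fit_model(full, design, log_y, dataset)
    if full_fit.sigma2_hat <= 0:
        raise ValueError("full model has zero residual variance; cannot bootstrap")
    basis = _basis(design.n_factors, design.factor_names)
    wanted = [frozenset(ts.terms) for ts in models]
    model_idx = np.array(
        [i for i, ts in enumerate(basis["models"]) if ts.terms in wanted]
    )
    eta_stars = _pb_eta_stars(
        full_fit, B, rng, kind=target.parameter_kind, model_idx=model_idx
    )
    idx = design.cell_index(target.cell)
    stars = np.sort(eta_stars[:, idx])
    i_lo = math.ceil(alpha * (B + 1))
    i_hi = math.ceil((1 - alpha) * (B + 1))
    i_lo = min(max(i_lo, 1), B)
    i_hi = min(max(i_hi, 1), B)
    return Interval(float(stars[i_lo - 1]), float(stars[i_hi - 1]), alpha, "pb")
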