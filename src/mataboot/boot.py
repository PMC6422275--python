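"""Parametric bootstrap engine for studentized tail statistics.

For model m fitted to the data, bootstrap samples are drawn from the fitted
Gaussian log-scale model and m is refitted to each, giving

    T*_m = (η̂*_m - η̂_m) / sqrt(V̂(η̂*_m)),

whose empirical distribution stands in for the sampling distribution of the
studentized estimate T_m when model m is true.  Under the Gaussian model the
per-cell sample means and the pooled within-cell sum of squares are jointly
sufficient and independent (means are Gaussian, the SS is σ̂²·χ²_{C(r-1)}),
so the engine samples those statistics directly instead of materializing
each bootstrap table — an exact, not approximate, shortcut.  The
table-producing :func:`parametric_resample` is the reference path and is
checked against the fast path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .lognormal import LOGNORMAL_MEAN, CellTarget
from .model_space import FactorialDesign, FittedModel, TermSet, _basis, fit_model

__all__ = ["BootstrapTails", "parametric_resample", "studentized_boot_tails", "tail_probability"]

#: minimum bootstrap size so that tail probabilities near 2.5% are resolvable
MIN_B = 39


@dataclass(frozen=True)
class BootstrapTails:
    """Sorted studentized bootstrap statistics for one model and one cell."""

    sorted_stats: np.ndarray
    B: int
    model_label: str

    def __post_init__(self) -> None:
        s = np.asarray(self.sorted_stats, dtype=float)
        object.__setattr__(self, "sorted_stats", s)
        if self.B < 1:
            raise ValueError("B must be positive")
        if s.shape != (self.B,):
            raise ValueError("sorted_stats must have length B")
        if not np.isfinite(s).all():
            raise ValueError("bootstrap statistics must be finite")
        if np.any(np.diff(s) < 0):
            raise ValueError("sorted_stats must be ascending")

    @property
    def positions(self) -> np.ndarray:
        """Plotting positions b/(B+1), b = 1..B."""
        return np.arange(1, self.B + 1) / (self.B + 1)


def parametric_resample(
    fitted: FittedModel, design: FactorialDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """One bootstrap dataset from the fitted model, in long format.

    Log-responses are the fitted cell means plus N(0, σ̂²_m) noise, laid out
    exactly like the original design.
    """
    if fitted.sigma2_hat <= 0:
        raise ValueError("cannot resample from a degenerate fit (sigma2_hat = 0)")
    eps = rng.normal(0.0, np.sqrt(fitted.sigma2_hat), (design.n_cells, design.r))
    y = np.exp(fitted.fitted_cell_means[:, None] + eps)
    cells = design.cells()
    rows = {
        name: np.repeat([c[j] for c in cells], design.r)
        for j, name in enumerate(design.factor_names)
    }
    rows["replicate"] = np.tile(np.arange(1, design.r + 1), design.n_cells)
    rows["response"] = y.ravel()
    return pd.DataFrame(rows)


def _sufficient_resample(
    fitted: FittedModel, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(cell means, within-cell SS) of B bootstrap datasets, drawn directly."""
    d = fitted.design
    s2 = fitted.sigma2_hat
    ybar = fitted.fitted_cell_means[None, :] + rng.normal(
        0.0, np.sqrt(s2 / d.r), (B, d.n_cells)
    )
    ssw = s2 * rng.chisquare(d.n_cells * (d.r - 1), B)
    return ybar, ssw


def _refit_stats(fitted: FittedModel, ybar: np.ndarray, ssw: np.ndarray):
    """Refit `fitted`'s model to B resamples given their sufficient stats."""
    d = fitted.design
    basis = _basis(d.n_factors, d.factor_names)
    m = next(
        i for i, ts in enumerate(basis["models"]) if ts.terms == fitted.term_set.terms
    )
    mask = basis["masks"][m]
    H = basis["H"]
    b = ybar @ H / d.n_cells  # (B, C) contrast coefficients
    fitted_cells = (b * mask[None, :]) @ H.T  # (B, C)
    rss = ssw + d.r * np.sum((ybar - fitted_cells) ** 2, axis=1)
    sigma2 = rss / fitted.nu
    return fitted_cells, sigma2


def _tails_all_cells(
    fitted: FittedModel,
    B: int,
    rng: np.random.Generator,
    kind: str = LOGNORMAL_MEAN,
    h_mode: str = "general",
    max_redraw_rounds: int = 100,
) -> tuple[np.ndarray, int]:
    """Sorted T* matrix (B, C) for every cell at once, plus redraw count.

    Bootstrap fits with zero residual variance (probability zero under the
    continuous model, possible only in pathological near-zero-σ̂² inputs) are
    redrawn and counted.
    """
    if B < MIN_B:
        raise ValueError(f"B must be >= {MIN_B} to resolve 2.5% tails")
    if fitted.sigma2_hat <= 0:
        raise ValueError("cannot bootstrap a degenerate fit (sigma2_hat = 0)")
    d = fitted.design
    ybar, ssw = _sufficient_resample(fitted, B, rng)
    fitted_cells, sigma2 = _refit_stats(fitted, ybar, ssw)
    n_redrawn = 0
    rounds = 0
    while np.any(sigma2 <= 0):
        bad = np.flatnonzero(sigma2 <= 0)
        rounds += 1
        if rounds > max_redraw_rounds:
            raise RuntimeError("could not obtain non-degenerate bootstrap fits")
        n_redrawn += len(bad)
        yb, sw = _sufficient_resample(fitted, len(bad), rng)
        fc, s2 = _refit_stats(fitted, yb, sw)
        ybar[bad], ssw[bad] = yb, sw
        fitted_cells[bad], sigma2[bad] = fc, s2
    if n_redrawn > 0.001 * B:
        warnings.warn(
            f"{n_redrawn} of {B} bootstrap fits were degenerate and redrawn",
            RuntimeWarning,
        )
    h = fitted.p / (d.n_cells * d.r) if h_mode == "general" else 1.0 / d.r
    var = sigma2 * h
    eta_star = fitted_cells.copy()
    if kind == LOGNORMAL_MEAN:
        eta_star += sigma2[:, None] / 2.0
        var = var + sigma2**2 / (2.0 * (fitted.nu + 2))
    eta_orig = fitted.fitted_cell_means.copy()
    if kind == LOGNORMAL_MEAN:
        eta_orig = eta_orig + fitted.sigma2_hat / 2.0
    T = (eta_star - eta_orig[None, :]) / np.sqrt(var)[:, None]
    return np.sort(T, axis=0), n_redrawn


def studentized_boot_tails(
    dataset: pd.DataFrame,
    design: FactorialDesign,
    model: TermSet,
    target: CellTarget,
    B: int,
    rng: np.random.Generator,
    h_mode: str = "general",
) -> BootstrapTails:
    """Empirical distribution of T*_m for one model and one target cell.

    Fits ``model`` to ``dataset`` (responses are logged internally), draws B
    parametric resamples from that fit, refits the same model to each, and
    returns the sorted studentized statistics.
    """
    log_y = np.log(dataset["response"].to_numpy(dtype=float))
    fit = fit_model(model, design, log_y, dataset)
    T, _ = _tails_all_cells(fit, B, rng, kind=target.parameter_kind, h_mode=h_mode)
    idx = design.cell_index(target.cell)
    return BootstrapTails(T[:, idx], B, fit.term_set.label)


def tail_probability(tails: BootstrapTails, t: float, side: str) -> float:
    """Interpolated empirical tail probability of T* at t.

    The ECDF is piecewise linear through (T*_(b), b/(B+1)) and clamped to
    [1/(B+1), B/(B+1)] outside the sample range, so it is continuous and
    nondecreasing; ``side="lower"`` returns F̂(t), ``"upper"`` returns 1-F̂(t).
    """
    lo = 1.0 / (tails.B + 1)
    hi = tails.B / (tails.B + 1)
    F = float(np.interp(t, tails.sorted_stats, tails.positions, left=lo, right=hi))
    if side == "lower":
        return F
    if side == "upper":
        return 1.0 - F
    raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")


def _ecdf_eval(sorted_stats: np.ndarray, args: np.ndarray) -> np.ndarray:
    """Batched interpolated-ECDF values, matching :func:`tail_probability`.

    ``sorted_stats`` has shape (..., B, C) (one ECDF per trailing column);
    ``args`` has shape (..., C).  Returns F̂ with the shape of ``args``.
    """
    B = sorted_stats.shape[-2]
    pos = np.arange(1, B + 1) / (B + 1)
    counts = np.sum(sorted_stats < args[..., None, :], axis=-2)  # in [0, B]
    c0 = np.clip(counts - 1, 0, B - 1)
    c1 = np.clip(counts, 0, B - 1)
    x0 = np.take_along_axis(sorted_stats, c0[..., None, :], axis=-2)[..., 0, :]
    x1 = np.take_along_axis(sorted_stats, c1[..., None, :], axis=-2)[..., 0, :]
    inside = (counts >= 1) & (counts <= B - 1)
    denom = x1 - x0
    safe = inside & (denom > 0)
    frac = np.where(safe, (args - x0) / np.where(denom > 0, denom, 1.0), 0.0)
    return pos[c0] + frac * (pos[c1] - pos[c0])
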