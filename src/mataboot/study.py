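"""Coverage simulation study for the six interval methods.

Each replicate draws a fresh random effect set for its scenario, simulates a
lognormal factorial dataset, fits every hierarchical candidate model,
computes AIC weights, and builds the requested intervals for all treatment
combinations on the η scale before back-transforming.  Performance per
method is summarized by the lower and upper error rates and the mean
relative half-widths, averaged over the cells and replicates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as _st

from .averaging import aic_weights
from .boot import _tails_all_cells
from .intervals import METHODS, Interval, _endpoints_vectorized, _pb_eta_stars
from .lognormal import (
    LOGNORMAL_MEAN,
    CellTarget,
    Scenario,
    draw_effects,
    simulate_dataset,
    true_parameter,
)
from .model_space import FactorialDesign, FittedModel, _basis, _cell_stats, _fit_from_stats

__all__ = [
    "StudyResult",
    "error_rates",
    "relative_half_widths",
    "run_scenario",
    "results_to_frame",
]


@dataclass(frozen=True)
class StudyResult:
    """Aggregated performance of one interval method in one scenario."""

    scenario_label: str
    method: str
    lower_error_rate: float
    upper_error_rate: float
    mean_lower_rhw: float
    mean_upper_rhw: float
    n_sim: int
    B: int
    r: int

    def __post_init__(self) -> None:
        if not (0 <= self.lower_error_rate <= 1 and 0 <= self.upper_error_rate <= 1):
            raise ValueError("error rates must lie in [0, 1]")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


def error_rates(intervals, truths) -> tuple[float, float]:
    """Fraction of (replicate, cell) pairs missing below / above.

    ``intervals`` is a nested sequence of :class:`Interval` (replicates by
    cells) and ``truths`` the matching true parameter values on the same
    scale.  Lower error: θ_L > θ; upper error: θ_U < θ.
    """
    lowers, uppers, theta = [], [], []
    for row_i, row_t in zip(intervals, truths, strict=True):
        for iv, t in zip(row_i, row_t, strict=True):
            lowers.append(iv.lower)
            uppers.append(iv.upper)
            theta.append(t)
    lowers, uppers, theta = map(np.asarray, (lowers, uppers, theta))
    return float(np.mean(lowers > theta)), float(np.mean(uppers < theta))


def relative_half_widths(interval: Interval, truth: float) -> tuple[float, float]:
    """((θ_L - θ)/θ, (θ_U - θ)/θ); the lower value is typically negative."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    return (interval.lower - truth) / truth, (interval.upper - truth) / truth


def _replicate(
    scenario: Scenario,
    design: FactorialDesign,
    methods: tuple[str, ...],
    B: int,
    alpha: float,
    kind: str,
    h_mode: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    basis = _basis(design.n_factors, design.factor_names)
    effects = draw_effects(scenario, rng)
    data = simulate_dataset(effects, design, rng)
    log_y = np.log(data["response"].to_numpy())
    ybar, ssw = _cell_stats(design, data, log_y)
    fstats = _fit_from_stats(ybar, ssw, design, basis)
    sigma2, nu, p, fitted = fstats["sigma2"], fstats["nu"], fstats["p"], fstats["fitted"]
    C, r = design.n_cells, design.r
    weights = aic_weights(fstats["aic"]).weights

    eta = fitted.copy()  # (M, C)
    h = p / (C * r) if h_mode == "general" else np.full(len(p), 1.0 / r)
    var = sigma2 * h
    if kind == LOGNORMAL_MEAN:
        eta += sigma2[:, None] / 2.0
        var = var + sigma2**2 / (2.0 * (nu + 2))
    se = np.sqrt(var)

    truths_eta = np.array(
        [true_parameter(effects, CellTarget(c, kind)) for c in design.cells()]
    )
    theta_true = np.exp(truths_eta)

    limits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if "full_wald" in methods:
        half = _st.t.ppf(1 - alpha, nu[-1]) * se[-1]
        limits["full_wald"] = (eta[-1] - half, eta[-1] + half)
    if "ma_wald" in methods:
        z = _st.norm.ppf(1 - alpha)
        ratio2 = (_st.t.ppf(1 - alpha, nu) / z) ** 2
        bar = weights @ eta  # (C,)
        V = weights @ (ratio2[:, None] * var[:, None] + (eta - bar[None, :]) ** 2)
        half = z * np.sqrt(V)
        limits["ma_wald"] = (bar - half, bar + half)
    for version in ("z", "t"):
        tag = f"mata_wald_{version}"
        if tag in methods:
            lo, up = _endpoints_vectorized(eta, se, nu.astype(float), weights, alpha, version)
            limits[tag] = (lo, up)
    if "mata_sboot" in methods:
        tails = np.empty((len(basis["models"]), B, C))
        for m, ts in enumerate(basis["models"]):
            fm = FittedModel(
                term_set=ts,
                design=design,
                coefficients=fstats["b_full"][basis["masks"][m]],
                fitted_cell_means=fitted[m],
                rss=float(fstats["rss"][m]),
                nu=int(nu[m]),
                sigma2_hat=float(sigma2[m]),
                aic=float(fstats["aic"][m]),
                n=design.n,
                p=int(p[m]),
            )
            tails[m], _ = _tails_all_cells(fm, B, rng, kind=kind, h_mode=h_mode)
        lo, up = _endpoints_vectorized(
            eta, se, nu.astype(float), weights, alpha, "boot", tails=tails
        )
        limits["mata_sboot"] = (lo, up)
    if "pb" in methods:
        full_fit = FittedModel(
            term_set=basis["models"][-1],
            design=design,
            coefficients=fstats["b_full"],
            fitted_cell_means=fitted[-1],
            rss=float(fstats["rss"][-1]),
            nu=int(nu[-1]),
            sigma2_hat=float(sigma2[-1]),
            aic=float(fstats["aic"][-1]),
            n=design.n,
            p=int(p[-1]),
        )
        stars = np.sort(_pb_eta_stars(full_fit, B, rng, kind=kind), axis=0)
        i_lo = int(np.ceil(alpha * (B + 1)))
        i_hi = int(np.ceil((1 - alpha) * (B + 1)))
        limits["pb"] = (stars[i_lo - 1], stars[i_hi - 1])

    out: dict[str, np.ndarray] = {}
    for tag, (lo_eta, up_eta) in limits.items():
        theta_lo, theta_up = np.exp(lo_eta), np.exp(up_eta)
        out[tag] = np.stack(
            [
                theta_lo > theta_true,
                theta_up < theta_true,
                (theta_lo - theta_true) / theta_true,
                (theta_up - theta_true) / theta_true,
            ]
        )
    return out


def run_scenario(
    scenario: Scenario,
    methods=METHODS,
    n_sim: int = 2000,
    B: int = 199,
    alpha: float = 0.025,
    parameter_kind: str = LOGNORMAL_MEAN,
    h_mode: str = "general",
    n_jobs: int = 1,
    factor_names: tuple[str, ...] = ("P", "I", "V"),
) -> list[StudyResult]:
    """Run one scenario of the simulation study.

    Every replicate draws a fresh effect set.  Replicate random streams are
    spawned deterministically from ``scenario.seed``, so results are
    reproducible and invariant to ``n_jobs``.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if {"pb", "mata_sboot"} & set(methods):
        from .boot import MIN_B

        if B < MIN_B:
            raise ValueError(f"bootstrap methods need B >= {MIN_B}")
    design = FactorialDesign(factor_names, scenario.r)
    children = np.random.SeedSequence(scenario.seed).spawn(n_sim)

    def one(child):
        return _replicate(
            scenario, design, methods, B, alpha, parameter_kind, h_mode,
            np.random.default_rng(child),
        )

    if n_jobs == 1:
        per_rep = [one(c) for c in children]
    else:
        from joblib import Parallel, delayed

        per_rep = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in children)

    results = []
    for tag in methods:
        block = np.stack([rep[tag] for rep in per_rep])  # (n_sim, 4, C)
        means = block.mean(axis=(0, 2))
        results.append(
            StudyResult(
                scenario_label=scenario.label,
                method=tag,
                lower_error_rate=float(means[0]),
                upper_error_rate=float(means[1]),
                mean_lower_rhw=float(means[2]),
                mean_upper_rhw=float(means[3]),
                n_sim=n_sim,
                B=B,
                r=scenario.r,
            )
        )
    return results


def results_to_frame(results: list[StudyResult]):
    """Tidy DataFrame of study results (one row per scenario x method)."""
    import pandas as pd

    return pd.DataFrame([asdict(x) for x in results])
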