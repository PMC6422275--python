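"""Lognormal cell-mean targets and the factorial synthetic-data generator.

The response in cell (i, j, k) is lognormal: log Y = μ_ijk + ε, ε ~ N(0, σ²),
with μ_ijk built from an overall effect, main effects, two- and three-way
interactions under ±1 (sum-to-zero) coding.  The flagship target is the cell
mean θ_ijk = E(Y) on the original scale, estimated through

    η_ijk = log θ_ijk = μ_ijk + σ²/2,
    η̂_ijk,m = μ̂_ijk,m + σ̂²_m / 2,
    V̂(η̂_ijk,m) = σ̂²_m h_m + (σ̂²_m)² / (2 (ν_m + 2)),

where h_m is the cell-mean variance factor of model m and the variance
estimator is exactly unbiased under model m (χ²_ν scaling of the residual
mean square).  The median target drops the σ²/2 terms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import ModelEstimate
from .model_space import FactorialDesign, FittedModel, cell_mean_variance_factor

__all__ = [
    "CellTarget",
    "EffectSet",
    "Scenario",
    "SCENARIO_LABELS",
    "MAGNITUDES",
    "eta_hat",
    "eta_variance",
    "back_transform",
    "draw_effects",
    "simulate_dataset",
    "true_parameter",
    "cell_estimates",
    "write_dataset",
]

#: magnitude codes for randomized effect sizes
MAGNITUDES = {"H": 2.0, "M": 1.0, "L": 0.1}

#: the ten scenario labels of the simulation study, main/two-way/three-way
SCENARIO_LABELS = ("LLL", "MLL", "HLL", "MML", "HML", "MMM", "HMM", "HHL", "HHM", "HHH")

LOGNORMAL_MEAN = "lognormal_mean"
LOG_SCALE_MEAN = "log_scale_mean"  # targets the median of Y


@dataclass(frozen=True)
class CellTarget:
    """A treatment combination plus the parameter kind targeted there."""

    cell: tuple[int, ...]
    parameter_kind: str = LOGNORMAL_MEAN

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell", tuple(self.cell))
        if self.parameter_kind not in (LOGNORMAL_MEAN, LOG_SCALE_MEAN):
            raise ValueError(f"unknown parameter_kind {self.parameter_kind!r}")


@dataclass(frozen=True)
class EffectSet:
    """Effect values for the 2^3 lognormal model, one value v per term.

    Sum-to-zero coding: level 1 of a factor contributes +v, level 2
    contributes -v (and products thereof for interactions).
    """

    mu: float
    main: tuple[float, float, float]
    two_way: tuple[float, float, float]  # order: (0,1), (0,2), (1,2)
    three_way: float
    sigma2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "main", tuple(float(v) for v in self.main))
        object.__setattr__(self, "two_way", tuple(float(v) for v in self.two_way))
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    def coefficients(self) -> np.ndarray:
        """Contrast coefficients in canonical term order (intercept first)."""
        return np.array([self.mu, *self.main, *self.two_way, self.three_way])

    def cell_mean(self, cell: tuple[int, ...]) -> float:
        """μ_ijk for one treatment combination."""
        s = [1.0 if l == 1 else -1.0 for l in cell]
        if len(s) != 3:
            raise ValueError("EffectSet is for three factors")
        a, b, g = self.main
        ab, ag, bg = self.two_way
        return (
            self.mu
            + a * s[0] + b * s[1] + g * s[2]
            + ab * s[0] * s[1] + ag * s[0] * s[2] + bg * s[1] * s[2]
            + self.three_way * s[0] * s[1] * s[2]
        )

    def cell_means(self, design: FactorialDesign) -> np.ndarray:
        return np.array([self.cell_mean(c) for c in design.cells()])


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: effect magnitudes, replication and noise."""

    magnitudes: tuple[float, float, float]  # (main, two-way, three-way) SDs
    label: str
    r: int
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "magnitudes", tuple(float(v) for v in self.magnitudes))
        if self.r < 2:
            raise ValueError("r must be >= 2")
        expected = tuple(MAGNITUDES.get(c) for c in self.label)
        if len(self.label) == 3 and all(v is not None for v in expected):
            if expected != self.magnitudes:
                raise ValueError(
                    f"label {self.label!r} inconsistent with magnitudes {self.magnitudes!r}"
                )

    @classmethod
    def from_label(cls, label: str, r: int, sigma2: float = 1.0, seed: int = 0) -> "Scenario":
        if len(label) != 3 or any(c not in MAGNITUDES for c in label):
            raise ValueError(f"scenario label must be three of H/M/L, got {label!r}")
        return cls(tuple(MAGNITUDES[c] for c in label), label, r, sigma2, seed)


def draw_effects(scenario: Scenario, rng: np.random.Generator) -> EffectSet:
    """Draw one random effect set: each term's value ~ N(0, magnitude²).

    The overall effect μ is fixed at 0 (interval performance does not depend
    on it); σ² is copied from the scenario.
    """
    m1, m2, m3 = scenario.magnitudes
    main = rng.normal(0.0, m1, 3) if m1 > 0 else np.zeros(3)
    two = rng.normal(0.0, m2, 3) if m2 > 0 else np.zeros(3)
    three = rng.normal(0.0, m3) if m3 > 0 else 0.0
    return EffectSet(0.0, tuple(main), tuple(two), float(three), scenario.sigma2)


def simulate_dataset(
    effects: EffectSet, design: FactorialDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate Y = exp(μ_ijk + ε), ε ~ N(0, σ²), in long format.

    Rows are cell-major (canonical cell order, replicates within); columns
    are the factor names (levels 1/2), ``replicate`` and ``response``.
    """
    if design.n_factors != 3:
        raise ValueError("the lognormal generator is for three-factor designs")
    mu = effects.cell_means(design)
    eps = rng.normal(0.0, np.sqrt(effects.sigma2), (design.n_cells, design.r))
    y = np.exp(mu[:, None] + eps)
    cells = design.cells()
    rows = {
        name: np.repeat([c[j] for c in cells], design.r)
        for j, name in enumerate(design.factor_names)
    }
    rows["replicate"] = np.tile(np.arange(1, design.r + 1), design.n_cells)
    rows["response"] = y.ravel()
    return pd.DataFrame(rows)


def write_dataset(data: pd.DataFrame, path) -> None:
    """Long-format CSV writer matching the interface module's reader."""
    data.to_csv(path, index=False)


def true_parameter(effects: EffectSet, target: CellTarget, scale: str = "eta") -> float:
    """Exact target value: η_ijk = μ_ijk + σ²/2 (or μ_ijk for the median kind).

    ``scale="theta"`` exponentiates, giving E(Y) (or the median of Y).
    """
    eta = effects.cell_mean(target.cell)
    if target.parameter_kind == LOGNORMAL_MEAN:
        eta += effects.sigma2 / 2.0
    if scale == "eta":
        return float(eta)
    if scale == "theta":
        return float(np.exp(eta))
    raise ValueError(f"unknown scale {scale!r}")


def eta_hat(fitted: FittedModel, target: CellTarget) -> float:
    """η̂_ijk,m = μ̂_ijk,m + σ̂²_m/2 (μ̂ alone for the median kind)."""
    idx = fitted.design.cell_index(target.cell)
    mu = float(fitted.fitted_cell_means[idx])
    if target.parameter_kind == LOGNORMAL_MEAN:
        return mu + fitted.sigma2_hat / 2.0
    return mu


def eta_variance(fitted: FittedModel, target: CellTarget, h: float) -> float:
    """Unbiased variance of η̂: σ̂²h + (σ̂²)²/(2(ν+2)); second term dropped
    for the median kind."""
    if not 0 < h <= 1:
        raise ValueError("variance factor h must be in (0, 1]")
    if fitted.nu < 1:
        raise ValueError("nu must be >= 1")
    s2 = fitted.sigma2_hat
    if s2 == 0:
        raise ValueError(
            "degenerate fit (sigma2_hat = 0): interval construction impossible"
        )
    v = s2 * h
    if target.parameter_kind == LOGNORMAL_MEAN:
        v += s2**2 / (2.0 * (fitted.nu + 2))
    return float(v)


def back_transform(interval):
    """Exponentiate an interval's limits (η scale -> θ scale)."""
    if interval.lower > interval.upper:
        raise ValueError("interval limits out of order")
    return dataclasses.replace(
        interval,
        lower=float(np.exp(interval.lower)),
        upper=float(np.exp(interval.upper)),
        scale="theta",
    )


def cell_estimates(
    fits: list[FittedModel], target: CellTarget, h_mode: str = "general"
) -> list[ModelEstimate]:
    """Per-model (η̂, V̂, ν) triples for one cell, in the fits' order.

    ``h_mode="general"`` uses the exact cell-mean variance factor of each
    model; ``"literal_r"`` forces h = 1/r for every model (sensitivity mode,
    exact only for the saturated model).
    """
    if h_mode not in ("general", "literal_r"):
        raise ValueError(f"unknown h_mode {h_mode!r}")
    out = []
    for f in fits:
        h = cell_mean_variance_factor(f, target.cell) if h_mode == "general" else 1.0 / f.design.r
        out.append(ModelEstimate(eta_hat(f, target), eta_variance(f, target, h), f.nu))
    return out
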