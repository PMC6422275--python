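"""AIC model weights, the model-averaged point estimate and its variance.

The model-averaged estimate is the weighted mean θ̄ = Σ_m w_m θ̂_m with AIC
weights w_m ∝ exp(-AIC_m / 2).  The MA-Wald variance estimator is

    V̂(θ̄) = Σ_m w_m { (t_{ν_m,1-α} / z_{1-α})² V̂(θ̂_m) + (θ̂_m - θ̄)² },

whose t/z ratio inflates each model's variance for the uncertainty in its
own error-variance estimate, and whose spread term accounts for
between-model disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WeightVector", "ModelEstimate", "aic_weights", "model_averaged_estimate", "ma_wald_variance"]


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative model weights summing to one, in canonical model order."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) == 0:
            raise ValueError("weights must be a nonempty 1-d vector")
        if np.any(w < 0) or not np.isfinite(w).all():
            raise ValueError("weights must be finite and nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, i):
        return self.weights[i]


@dataclass(frozen=True)
class ModelEstimate:
    """Per-model (estimate, variance, residual df) triple on the working scale."""

    theta_hat: float
    var_hat: float
    nu: int

    def __post_init__(self) -> None:
        if not self.var_hat > 0:
            raise ValueError("var_hat must be positive")
        if self.nu < 1:
            raise ValueError("nu must be >= 1")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_hat))


def aic_weights(aics) -> WeightVector:
    """AIC weights w_m ∝ exp(-AIC_m/2), normalized after min-subtraction.

    -inf AIC values (perfect fits) receive all the weight, split uniformly
    among them.  NaN values are rejected.
    """
    a = np.asarray(aics, dtype=float)
    if a.ndim != 1 or len(a) == 0:
        raise ValueError("need a nonempty 1-d vector of AIC values")
    if np.any(np.isnan(a)):
        raise ValueError("AIC values must not be NaN")
    if np.any(np.isneginf(a)):
        w = np.where(np.isneginf(a), 1.0, 0.0)
        return WeightVector(w / w.sum())
    rel = np.exp(-(a - a.min()) / 2.0)
    return WeightVector(rel / rel.sum())


def model_averaged_estimate(estimates, weights: WeightVector) -> float:
    """θ̄ = Σ_m w_m θ̂_m."""
    if len(estimates) != len(weights):
        raise ValueError("estimates and weights must have equal length")
    theta = np.array([e.theta_hat for e in estimates])
    return float(theta @ weights.weights)


def ma_wald_variance(
    estimates, weights: WeightVector, theta_bar: float, alpha: float
) -> float:
    """The MA-Wald variance estimator V̂(θ̄) at per-tail level alpha.

    Models with zero weight are skipped (their term vanishes), which also
    tolerates degenerate entries that carry no weight.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if len(estimates) != len(weights):
        raise ValueError("estimates and weights must have equal length")
    z = stats.norm.ppf(1 - alpha)
    total = 0.0
    for e, w in zip(estimates, weights.weights):
        if w == 0.0:
            continue
        if e.nu < 1:
            raise ValueError("model with positive weight has nu < 1")
        ratio = stats.t.ppf(1 - alpha, e.nu) / z
        total += w * (ratio**2 * e.var_hat + (e.theta_hat - theta_bar) ** 2)
    return float(total)
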