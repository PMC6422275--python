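"""File I/O, configuration and reporting for factorial interval analyses.

Reads long-format CSV data (one column per factor, one positive response
column), produces the AIC weight table over the hierarchical model set, and
the per-treatment-combination table of all requested confidence intervals on
the original (θ) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import aic_weights
from .boot import BootstrapTails, _tails_all_cells
from .intervals import (
    METHODS,
    Interval,
    _pb_eta_stars,
    full_wald,
    ma_wald,
    mata_sboot,
    mata_wald,
)
from .lognormal import LOGNORMAL_MEAN, CellTarget, back_transform, cell_estimates
from .model_space import FactorialDesign, fit_all_models

__all__ = ["AnalysisConfig", "read_dataset", "weight_table", "intervals_report", "load_config"]

#: Fig-1-style level letters for the standard factor names
_LEVEL_LETTERS = {"P": ("H", "L"), "I": ("D", "B"), "V": ("S", "F")}


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a single-dataset analysis."""

    alpha: float = 0.025
    B: int = 9999
    methods: tuple[str, ...] = METHODS
    parameter_kind: str = LOGNORMAL_MEAN
    seed: int = 0
    h_mode: str = "general"
    factor_columns: tuple[str, ...] = ("P", "I", "V")
    response_column: str = "response"

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "factor_columns", tuple(self.factor_columns))
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        needs_boot = {"pb", "mata_sboot"} & set(self.methods)
        if needs_boot and self.B < math.ceil(1.0 / self.alpha - 1.0):
            raise ValueError(
                f"bootstrap methods at alpha={self.alpha} need "
                f"B >= {math.ceil(1.0 / self.alpha - 1.0)}"
            )


def load_config(path, **overrides) -> AnalysisConfig:
    """Build a config from a flat key=value text file plus overrides."""
    values: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    parsed: dict = {}
    for key, val in values.items():
        if key in ("alpha",):
            parsed[key] = float(val)
        elif key in ("B", "seed"):
            parsed[key] = int(val)
        elif key in ("methods", "factor_columns"):
            parsed[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        else:
            parsed[key] = val
    parsed.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(**parsed)


def read_dataset(path, config: AnalysisConfig) -> tuple[pd.DataFrame, FactorialDesign]:
    """Read and validate a long-format CSV dataset.

    Requires every factor column and the response column, a strictly
    positive response, exactly two levels per factor, and a balanced full
    cross.  Factor levels are recoded to 1/2 (sorted observed order) and
    the response column is renamed ``response``.
    """
    df = pd.read_csv(path)
    missing = [c for c in (*config.factor_columns, config.response_column) if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    y = df[config.response_column].to_numpy(dtype=float)
    bad = np.flatnonzero(~(y > 0) | ~np.isfinite(y))
    if len(bad):
        raise ValueError(
            f"response must be strictly positive and finite; offending row index "
            f"{int(bad[0])} (value {y[bad[0]]!r})"
        )
    out = pd.DataFrame()
    for name in config.factor_columns:
        uniq = sorted(pd.unique(df[name]).tolist())
        if len(uniq) != 2:
            raise ValueError(f"factor {name!r} must have exactly 2 levels, got {uniq!r}")
        out[name] = np.where(df[name].to_numpy() == uniq[0], 1, 2)
    out["response"] = y
    counts = out.groupby(list(config.factor_columns)).size()
    n_cells = 2 ** len(config.factor_columns)
    if len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError(
            f"unbalanced design: per-cell counts {counts.to_dict()!r} "
            f"(need all {n_cells} cells with equal replication)"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    return out, FactorialDesign(config.factor_columns, r)


def weight_table(
    dataset: pd.DataFrame, design: FactorialDesign, config: AnalysisConfig
) -> pd.DataFrame:
    """AIC and AIC weight for every candidate model, in canonical order.

    Weights are kept at full precision; round only for display.
    """
    log_y = np.log(dataset["response"].to_numpy(dtype=float))
    fits = fit_all_models(design, log_y, dataset)
    aics = np.array([f.aic for f in fits])
    w = aic_weights(aics)
    return pd.DataFrame(
        {
            "model": [f.term_set.label for f in fits],
            "aic": aics,
            "weight": w.weights,
        }
    )


def _cell_label(design: FactorialDesign, cell: tuple[int, ...]) -> str:
    parts = []
    for name, level in zip(design.factor_names, cell):
        if name in _LEVEL_LETTERS:
            parts.append(_LEVEL_LETTERS[name][level - 1])
        else:
            parts.append(f"{name}{level}")
    return "".join(parts)


def intervals_report(
    dataset: pd.DataFrame,
    design: FactorialDesign,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """All requested intervals for every treatment combination, θ scale.

    One row per (cell, method); bootstrap randomness is controlled by
    ``config.seed`` unless an explicit generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    log_y = np.log(dataset["response"].to_numpy(dtype=float))
    fits = fit_all_models(design, log_y, dataset)
    weights = aic_weights([f.aic for f in fits])
    kind = config.parameter_kind

    tails_by_model = None
    if "mata_sboot" in config.methods:
        tails_by_model = [
            _tails_all_cells(f, config.B, rng, kind=kind, h_mode=config.h_mode)[0]
            for f in fits
        ]
    pb_stars = None
    if "pb" in config.methods:
        pb_stars = np.sort(_pb_eta_stars(fits[-1], config.B, rng, kind=kind), axis=0)

    rows = []
    for cell in design.cells():
        target = CellTarget(cell, kind)
        estimates = cell_estimates(fits, target, h_mode=config.h_mode)
        idx = design.cell_index(cell)
        built: list[Interval] = []
        for method in config.methods:
            if method == "full_wald":
                iv = full_wald(estimates[-1], config.alpha)
            elif method == "ma_wald":
                iv = ma_wald(estimates, weights, config.alpha)
            elif method in ("mata_wald_z", "mata_wald_t"):
                iv = mata_wald(estimates, weights, config.alpha, method[-1])
            elif method == "mata_sboot":
                tails = [
                    BootstrapTails(T[:, idx], config.B, f.term_set.label)
                    for T, f in zip(tails_by_model, fits)
                ]
                iv = mata_sboot(estimates, weights, tails, config.alpha)
            elif method == "pb":
                i_lo = math.ceil(config.alpha * (config.B + 1))
                i_hi = math.ceil((1 - config.alpha) * (config.B + 1))
                iv = Interval(
                    float(pb_stars[i_lo - 1, idx]),
                    float(pb_stars[i_hi - 1, idx]),
                    config.alpha,
                    "pb",
                )
            built.append(back_transform(iv))
        for iv in built:
            rows.append(
                {
                    "cell": _cell_label(design, cell),
                    "method": iv.method,
                    "lower": iv.lower,
                    "upper": iv.upper,
                }
            )
    return pd.DataFrame(rows)
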