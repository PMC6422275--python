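"""Candidate model space for balanced 2-level factorial designs.

Enumerates every hierarchical model (interactions only with all their
lower-order terms), builds ±1 effect-coded design matrices, and fits each
model by least squares on the log scale.  In a balanced full factorial the
effect-coded columns are mutually orthogonal, so every submodel fit reduces
to partial sums of the saturated model's contrast coefficients; this is used
throughout for exact, fast fitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "FactorialDesign",
    "TermSet",
    "FittedModel",
    "enumerate_hierarchical_models",
    "design_matrix",
    "fit_model",
    "fit_all_models",
    "cell_mean_variance_factor",
]

_DEFAULT_NAMES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class FactorialDesign:
    """A balanced 2^k factorial layout with ``r`` replicates per cell."""

    factor_names: tuple[str, ...]
    r: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        if self.n_factors < 1:
            raise ValueError("need at least one factor")
        if self.r < 2:
            raise ValueError("replicates per cell must satisfy r >= 2")

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def n_cells(self) -> int:
        return 2 ** self.n_factors

    @property
    def n(self) -> int:
        return self.r * self.n_cells

    def cells(self) -> list[tuple[int, ...]]:
        """All treatment combinations, levels coded 1/2, first factor slowest."""
        return list(itertools.product((1, 2), repeat=self.n_factors))

    def cell_index(self, cell: tuple[int, ...]) -> int:
        cell = tuple(cell)
        if len(cell) != self.n_factors or any(l not in (1, 2) for l in cell):
            raise ValueError(f"invalid cell {cell!r} for {self.n_factors} factors")
        idx = 0
        for level in cell:
            idx = 2 * idx + (level - 1)
        return idx


@dataclass(frozen=True)
class TermSet:
    """A set of effect terms (main effects and interactions) defining one model.

    Terms are tuples of factor indices, e.g. ``(0,)`` for the first main
    effect, ``(0, 1)`` for the two-way interaction of factors 0 and 1.  The
    empty set is the Null (intercept-only) model.
    """

    terms: frozenset[tuple[int, ...]]
    factor_names: tuple[str, ...] = _DEFAULT_NAMES[:3]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(tuple(t) for t in self.terms))
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        for t in self.terms:
            if len(t) != len(set(t)):
                raise ValueError(f"repeated factor in term {t!r}")
            if any(i < 0 or i >= len(self.factor_names) for i in t):
                raise ValueError(f"factor index out of range in term {t!r}")

    def ordered_terms(self) -> list[tuple[int, ...]]:
        return sorted(self.terms, key=lambda t: (len(t), t))

    @property
    def label(self) -> str:
        if not self.terms:
            return "Null"
        return "+".join(
            "".join(self.factor_names[i] for i in t) for t in self.ordered_terms()
        )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def is_hierarchical(self) -> bool:
        """Marginality: every lower-order term of each interaction is present."""
        for t in self.terms:
            for k in range(1, len(t)):
                for sub in itertools.combinations(t, k):
                    if sub not in self.terms:
                        return False
        return True

    def sort_key(self) -> tuple:
        return (self.n_terms, tuple((len(t),) + t for t in self.ordered_terms()))


@dataclass(frozen=True)
class FittedModel:
    """One candidate model fitted by least squares on the log scale."""

    term_set: TermSet
    design: FactorialDesign
    coefficients: np.ndarray = field(repr=False)  # intercept first, canonical term order
    fitted_cell_means: np.ndarray = field(repr=False)
    rss: float
    nu: int
    sigma2_hat: float
    aic: float
    n: int
    p: int


def _all_terms(n_factors: int) -> list[tuple[int, ...]]:
    """Every main effect and interaction, ordered by (order, factor indices)."""
    out: list[tuple[int, ...]] = []
    for k in range(1, n_factors + 1):
        out.extend(itertools.combinations(range(n_factors), k))
    return out


def enumerate_hierarchical_models(
    n_factors: int, factor_names: tuple[str, ...] | None = None
) -> list[TermSet]:
    """All term sets closed under marginality, in canonical order.

    Canonical order is by model size, then by the term-index tuples in design
    order — for three factors named P, I, V this reproduces the conventional
    table order Null, P, I, V, P+I, ..., P+I+V+PI+PV+IV+PIV (19 models).
    """
    if not isinstance(n_factors, (int, np.integer)) or not 1 <= n_factors <= 4:
        raise ValueError("n_factors must be an integer in [1, 4]")
    names = tuple(factor_names) if factor_names is not None else _DEFAULT_NAMES[:n_factors]
    if len(names) != n_factors:
        raise ValueError("factor_names length must equal n_factors")
    terms = _all_terms(n_factors)
    models = []
    for k in range(len(terms) + 1):
        for subset in itertools.combinations(terms, k):
            ts = TermSet(frozenset(subset), names)
            if ts.is_hierarchical():
                models.append(ts)
    models.sort(key=TermSet.sort_key)
    return models


def _effect_columns(cells: np.ndarray, terms: list[tuple[int, ...]]) -> np.ndarray:
    """±1 columns (intercept first) for given cells (levels 1/2) and terms."""
    signs = np.where(cells == 1, 1.0, -1.0)  # (n, k)
    cols = [np.ones(len(cells))]
    for t in terms:
        cols.append(np.prod(signs[:, list(t)], axis=1))
    return np.column_stack(cols)


@lru_cache(maxsize=8)
def _basis(n_factors: int, factor_names: tuple[str, ...]):
    """Precomputed orthogonal contrast basis and model masks for a design size."""
    terms = _all_terms(n_factors)
    cells = np.array(list(itertools.product((1, 2), repeat=n_factors)))
    H = _effect_columns(cells, terms)  # (C, C), orthogonal, col norms^2 = C
    models = enumerate_hierarchical_models(n_factors, factor_names)
    masks = np.zeros((len(models), H.shape[1]), dtype=bool)
    masks[:, 0] = True  # intercept always in
    for m, ts in enumerate(models):
        for j, t in enumerate(terms, start=1):
            masks[m, j] = t in ts.terms
    p = masks.sum(axis=1)
    return {"terms": terms, "H": H, "models": models, "masks": masks, "p": p}


def design_matrix(
    term_set: TermSet, design: FactorialDesign, data: pd.DataFrame
) -> np.ndarray:
    """Effect-coded (±1) design matrix with intercept for ``term_set``.

    ``data`` must contain one column per factor in ``design.factor_names``;
    the first of the two sorted observed levels codes as +1, the second as -1.
    """
    levels = _normalized_levels(design, data)
    cols = [np.ones(len(data))]
    signs = np.where(levels == 1, 1.0, -1.0)
    for t in term_set.ordered_terms():
        cols.append(np.prod(signs[:, list(t)], axis=1))
    return np.column_stack(cols)


def _normalized_levels(design: FactorialDesign, data: pd.DataFrame) -> np.ndarray:
    """Map each factor column onto 1/2 codes (sorted observed level order)."""
    levels = np.empty((len(data), design.n_factors), dtype=int)
    for j, name in enumerate(design.factor_names):
        if name not in data.columns:
            raise ValueError(f"missing factor column {name!r}")
        vals = data[name].to_numpy()
        uniq = sorted(pd.unique(vals).tolist())
        if len(uniq) != 2:
            raise ValueError(
                f"factor {name!r} must have exactly 2 observed levels, got {uniq!r}"
            )
        levels[:, j] = np.where(vals == uniq[0], 1, 2)
    return levels


def _cell_stats(
    design: FactorialDesign, data: pd.DataFrame, log_response: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-cell means of the log response and the pooled within-cell SS.

    Raises if the layout is not the balanced full cross with r per cell.
    """
    y = np.asarray(log_response, dtype=float)
    if y.ndim != 1 or len(y) != len(data):
        raise ValueError("log_response must be 1-d and aligned with data rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("log_response must be finite")
    levels = _normalized_levels(design, data)
    idx = np.zeros(len(data), dtype=int)
    for j in range(design.n_factors):
        idx = 2 * idx + (levels[:, j] - 1)
    C = design.n_cells
    counts = np.bincount(idx, minlength=C)
    if not np.all(counts == design.r):
        raise ValueError(
            "unbalanced design: per-cell counts "
            f"{counts.tolist()} (expected {design.r} in each of {C} cells)"
        )
    sums = np.bincount(idx, weights=y, minlength=C)
    ybar = sums / design.r
    ssw = float(np.sum((y - ybar[idx]) ** 2))
    return ybar, ssw


def _fit_from_stats(ybar: np.ndarray, ssw: float, design: FactorialDesign, basis):
    """Fit every candidate model from sufficient statistics (vectorized).

    Returns dict of arrays aligned with the canonical model order.
    """
    C, r, n = design.n_cells, design.r, design.n
    b_full = basis["H"].T @ ybar / C  # saturated contrast coefficients
    masks = basis["masks"]
    # rss_m = ssw + r*C*sum of excluded contrast coefficients squared
    excl = (~masks) * (b_full**2)[None, :]
    rss = ssw + r * C * excl.sum(axis=1)
    p = basis["p"]
    nu = n - p
    sigma2 = rss / nu
    with np.errstate(divide="ignore"):
        aic = n * np.log(rss / n) + 2 * (p + 1)
    fitted = (masks * b_full[None, :]) @ basis["H"].T  # (M, C) fitted cell means
    return {
        "b_full": b_full,
        "rss": rss,
        "nu": nu,
        "sigma2": sigma2,
        "aic": aic,
        "fitted": fitted,
        "p": p,
    }


def fit_model(
    term_set: TermSet,
    design: FactorialDesign,
    log_response: np.ndarray,
    data: pd.DataFrame,
) -> FittedModel:
    """Least-squares fit of one hierarchical model on the log scale.

    AIC convention: ``n*log(rss/n) + 2*(p+1)`` (Gaussian profile likelihood,
    σ² counted as a parameter); any additive constant cancels in the weights.
    A perfect fit (rss = 0) yields sigma2_hat = 0 and AIC = -inf.
    """
    basis = _basis(design.n_factors, design.factor_names)
    models = basis["models"]
    try:
        m = next(i for i, ts in enumerate(models) if ts.terms == frozenset(term_set.terms))
    except StopIteration:
        raise ValueError(f"term set {term_set.label!r} is not hierarchical") from None
    ybar, ssw = _cell_stats(design, data, log_response)
    stats = _fit_from_stats(ybar, ssw, design, basis)
    p = int(stats["p"][m])
    nu = design.n - p
    if nu <= 0:
        raise ValueError(
            "saturated model leaves no residual degrees of freedom; need r >= 2"
        )
    mask = basis["masks"][m]
    return FittedModel(
        term_set=models[m],
        design=design,
        coefficients=stats["b_full"][mask].copy(),
        fitted_cell_means=stats["fitted"][m].copy(),
        rss=float(stats["rss"][m]),
        nu=int(nu),
        sigma2_hat=float(stats["sigma2"][m]),
        aic=float(stats["aic"][m]),
        n=design.n,
        p=p,
    )


def fit_all_models(
    design: FactorialDesign, log_response: np.ndarray, data: pd.DataFrame
) -> list[FittedModel]:
    """Fit the full hierarchical model set in canonical order."""
    basis = _basis(design.n_factors, design.factor_names)
    ybar, ssw = _cell_stats(design, data, log_response)
    stats = _fit_from_stats(ybar, ssw, design, basis)
    out = []
    for m, ts in enumerate(basis["models"]):
        mask = basis["masks"][m]
        out.append(
            FittedModel(
                term_set=ts,
                design=design,
                coefficients=stats["b_full"][mask].copy(),
                fitted_cell_means=stats["fitted"][m].copy(),
                rss=float(stats["rss"][m]),
                nu=int(stats["nu"][m]),
                sigma2_hat=float(stats["sigma2"][m]),
                aic=float(stats["aic"][m]),
                n=design.n,
                p=int(stats["p"][m]),
            )
        )
    return out


def cell_mean_variance_factor(fitted: FittedModel, cell: tuple[int, ...]) -> float:
    """h_m = x0' (X'X)^-1 x0 for the cell's covariate row.

    In a balanced effect-coded design every column of X has squared norm
    C*r and the columns are orthogonal, so h_m = p_m / (C*r); it is 1/r for
    the saturated model and 1/(C*r) for the Null model, independent of cell.
    """
    fitted.design.cell_index(cell)  # validates the cell
    return fitted.p / (fitted.design.n_cells * fitted.design.r)
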