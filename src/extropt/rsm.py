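"""Second-order response-surface modelling: OLS fit, ANOVA, term reduction.

The model is the full quadratic in coded units,

    Y = b0 + sum_j bj Xj + sum_j bjj Xj^2 + sum_{i<j} bij Xi Xj + e,

fitted by ordinary least squares.  The ANOVA decomposes total SS into model
and residual, splits the residual into lack-of-fit and pure error using the
replicated centre runs, and tests each term by its partial (drop-one,
"Type III") sum of squares — on a near-orthogonal Box-Behnken design these
coincide with the single-degree-of-freedom rows statistical DOE software
prints.  Reduction refits the model keeping only terms with partial-F
p <= alpha; polynomial hierarchy is deliberately NOT enforced (a quadratic
or interaction term may survive while its parent linear term is dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable

__all__ = [
    "QuadraticModel",
    "AnovaRow",
    "AnovaReport",
    "term_names",
    "fit_quadratic",
    "anova",
    "reduce_model",
    "predict_rsm",
]


class SingularFitError(np.linalg.LinAlgError):
    """Active design matrix is rank deficient."""


def term_names(k: int) -> list[str]:
    """Term order used throughout: intercept, linear, quadratic, interactions."""
    names = ["Intercept"]
    names += [f"X{j+1}" for j in range(k)]
    names += [f"X{j+1}^2" for j in range(k)]
    names += [f"X{i+1}X{j+1}" for i in range(k) for j in range(i + 1, k)]
    return names


def quadratic_design_matrix(coded: np.ndarray) -> np.ndarray:
    """Full quadratic basis evaluated at coded points (n x n_terms)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, j] for j in range(k)]
    cols += [coded[:, j] ** 2 for j in range(k)]
    cols += [
        coded[:, i] * coded[:, j] for i in range(k) for j in range(i + 1, k)
    ]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted second-order polynomial in coded units.

    ``coef`` is dense over the full term basis; inactive terms (mask False)
    have coefficient exactly zero.
    """

    k: int
    coef: np.ndarray
    term_mask: np.ndarray
    basis: str = "coded"

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.term_mask = np.asarray(self.term_mask, dtype=bool)
        n_terms = len(term_names(self.k))
        if self.coef.shape != (n_terms,) or self.term_mask.shape != (n_terms,):
            raise ValueError(f"expected {n_terms} terms for k={self.k}")
        if np.any(self.coef[~self.term_mask] != 0.0):
            raise ValueError("inactive terms must have zero coefficients")

    @property
    def terms(self) -> list[str]:
        return term_names(self.k)

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def linear(self) -> np.ndarray:
        return self.coef[1 : 1 + self.k]

    @property
    def quadratic(self) -> np.ndarray:
        return self.coef[1 + self.k : 1 + 2 * self.k]

    @property
    def interactions(self) -> np.ndarray:
        return self.coef[1 + 2 * self.k :]

    @property
    def n_active(self) -> int:
        return int(self.term_mask.sum())

    def coef_dict(self) -> dict[str, float]:
        return {t: float(c) for t, c in zip(self.terms, self.coef)}

    def predict(self, coded_points: np.ndarray) -> np.ndarray:
        X = quadratic_design_matrix(coded_points)
        if X.shape[1] != len(self.coef):
            raise ValueError(
                f"points have wrong dimension for k={self.k} model"
            )
        return X @ self.coef


def predict_rsm(model: QuadraticModel, coded_points: np.ndarray) -> np.ndarray:
    """Evaluate the polynomial at coded points (vectorized)."""
    return model.predict(coded_points)


def fit_quadratic(
    design: DesignTable, term_mask: Sequence[bool] | None = None
) -> QuadraticModel:
    """OLS fit of the (optionally masked) quadratic model in coded units."""
    if not design.has_responses:
        raise ValueError("design has missing responses; cannot fit")
    X = quadratic_design_matrix(design.coded)
    y = design.response
    n_terms = X.shape[1]
    mask = (
        np.ones(n_terms, dtype=bool)
        if term_mask is None
        else np.asarray(term_mask, dtype=bool)
    )
    if mask.shape != (n_terms,):
        raise ValueError(f"term_mask must have length {n_terms}")
    Xa = X[:, mask]
    if int(mask.sum()) >= design.n_runs:
        raise ValueError("number of active terms must be < number of runs")
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise SingularFitError("active design matrix is rank deficient")
    beta_active, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    coef = np.zeros(n_terms)
    coef[mask] = beta_active
    return QuadraticModel(design.k, coef, mask)


@dataclass
class AnovaRow:
    source: str
    SS: float
    df: int
    MS: float | None
    F: float | None
    p: float | None


@dataclass
class AnovaReport:
    """Variance decomposition of a fitted quadratic model.

    ``rows`` covers model, each active term, residual, lack of fit, pure
    error, and total.  Lack-of-fit rows carry None throughout when the
    design has no replicate runs.
    """

    rows: list[AnovaRow]
    R2: float
    R2_adj: float
    CV_pct: float

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def term_p_values(self, terms: Sequence[str]) -> dict[str, float]:
        return {t: self[t].p for t in terms if t != "Intercept"}


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded settings (>= 2 members)."""
    keys: dict[tuple, list[int]] = {}
    for i, row in enumerate(np.round(coded, 9)):
        keys.setdefault(tuple(row), []).append(i)
    return [np.array(ix) for ix in keys.values() if len(ix) >= 2]


def anova(model: QuadraticModel, design: DesignTable) -> AnovaReport:
    """Full ANOVA of ``model`` on ``design``.

    Per-term SS are partial (drop-one): SS_term = SSE(without term) -
    SSE(full active set).  F ratios use the residual mean square of the
    active model; p-values come from the F distribution.  CV% is
    100 * sqrt(MS_residual) / mean(response).
    """
    y = design.response
    n = design.n_runs
    X = quadratic_design_matrix(design.coded)
    mask = model.term_mask
    resid = y - model.predict(design.coded)
    SS_res = float(resid @ resid)
    SS_tot = float(((y - y.mean()) ** 2).sum())
    SS_mod = SS_tot - SS_res
    df_mod = model.n_active - 1
    df_res = n - model.n_active
    df_tot = n - 1
    MS_res = SS_res / df_res if df_res > 0 else np.nan
    MS_mod = SS_mod / df_mod if df_mod > 0 else np.nan

    def ftest(ss: float, df1: int) -> tuple[float | None, float | None]:
        if df1 <= 0 or df_res <= 0 or not np.isfinite(MS_res):
            return None, None
        if MS_res == 0.0:
            return float("inf"), 0.0
        F = (ss / df1) / MS_res
        return float(F), float(stats.f.sf(F, df1, df_res))

    rows = []
    F_mod, p_mod = ftest(SS_mod, df_mod)
    rows.append(AnovaRow("Model", SS_mod, df_mod, MS_mod, F_mod, p_mod))

    active = [i for i in range(len(mask)) if mask[i] and i != 0]
    for i in active:
        sub = mask.copy()
        sub[i] = False
        Xs = X[:, sub]
        beta_s, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        r_s = y - Xs @ beta_s
        SS_i = float(r_s @ r_s) - SS_res
        F_i, p_i = ftest(SS_i, 1)
        rows.append(AnovaRow(model.terms[i], SS_i, 1, SS_i, F_i, p_i))

    rows.append(AnovaRow("Residual", SS_res, df_res, MS_res, None, None))

    groups = _replicate_groups(design.coded)
    if groups:
        SS_pe = float(
            sum(((y[g] - y[g].mean()) ** 2).sum() for g in groups)
        )
        df_pe = int(sum(len(g) - 1 for g in groups))
        SS_lof = SS_res - SS_pe
        df_lof = df_res - df_pe
        MS_pe = SS_pe / df_pe if df_pe > 0 else np.nan
        MS_lof = SS_lof / df_lof if df_lof > 0 else np.nan
        if df_lof > 0 and df_pe > 0 and MS_pe > 0:
            F_lof = MS_lof / MS_pe
            p_lof = float(stats.f.sf(F_lof, df_lof, df_pe))
        else:
            F_lof, p_lof = None, None
        rows.append(AnovaRow("Lack of fit", SS_lof, df_lof, MS_lof, F_lof, p_lof))
        rows.append(AnovaRow("Pure error", SS_pe, df_pe, MS_pe, None, None))
    else:
        warnings.warn(
            "no replicate runs: lack-of-fit decomposition unavailable",
            stacklevel=2,
        )
        rows.append(AnovaRow("Lack of fit", np.nan, 0, None, None, None))
        rows.append(AnovaRow("Pure error", np.nan, 0, None, None, None))

    rows.append(AnovaRow("Total", SS_tot, df_tot, None, None, None))

    R2 = 1.0 - SS_res / SS_tot if SS_tot > 0 else np.nan
    R2_adj = (
        1.0 - (SS_res / df_res) / (SS_tot / df_tot)
        if df_res > 0 and SS_tot > 0
        else np.nan
    )
    CV = 100.0 * np.sqrt(MS_res) / y.mean() if np.isfinite(MS_res) else np.nan
    return AnovaReport(rows, float(R2), float(R2_adj), float(CV))


def reduce_model(
    model: QuadraticModel, design: DesignTable, alpha: float = 0.05
) -> QuadraticModel:
    """Refit keeping only terms with partial-F p <= alpha (intercept kept).

    Ties at p == alpha are retained.  Hierarchy is not enforced: a
    significant interaction or square term survives even when its parent
    linear term is dropped.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    report = anova(model, design)
    mask = model.term_mask.copy()
    for i, term in enumerate(model.terms):
        if i == 0 or not mask[i]:
            continue
        p = report[term].p
        if p is None or p > alpha:
            mask[i] = False
    if mask.sum() == 1:
        warnings.warn(
            "all non-intercept terms removed; returning intercept-only model",
            stacklevel=2,
        )
    return fit_quadratic(design, mask)
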