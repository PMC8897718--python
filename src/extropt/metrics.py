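"""Model-comparison metrics: R2, MSE, RMSE, SSE, AIC, AAD.

Two SSE conventions are carried side by side.  The study that motivated
this package defines SSE with a 1/n^2 prefactor (so SSE = MSE/n); the
field-standard definition is the plain sum of squared errors.  Because the
published SSE values are inconsistent with the published MSE values under
either reading, both are always computed and reported; the ``aic_sse``
switch controls which one enters AIC = n ln(SSE) + 2p.

AAD (absolute average deviation) is the mean absolute relative error in
percent, with observed values in the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ModelMetrics", "compute_metrics", "compare_models"]


@dataclass(frozen=True)
class ModelMetrics:
    R2: float
    MSE: float
    RMSE: float
    SSE_paper: float  # (1/n^2) * sum of squared errors
    SSE_standard: float  # plain sum of squared errors
    AIC: float
    AAD_pct: float
    n: int
    p: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    predicted: np.ndarray,
    observed: np.ndarray,
    p: int,
    aic_sse: str = "paper",
) -> ModelMetrics:
    """Compute the six-metric comparison vector for one model.

    ``p`` is the parameter count entering AIC: the number of active
    polynomial terms (intercept included) for a response-surface model, the
    total weight-plus-bias count for a network (61 for a 4-10-1 net).
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    n = len(observed)
    if n < 2:
        raise ValueError("need at least 2 points")
    if aic_sse not in ("paper", "standard"):
        raise ValueError("aic_sse must be 'paper' or 'standard'")
    zeros = np.nonzero(observed == 0.0)[0]
    if zeros.size:
        raise ZeroDivisionError(
            f"AAD undefined: observed value is zero at run index {zeros[0]}"
        )
    err = predicted - observed
    sse_std = float(err @ err)
    mse = sse_std / n
    rmse = float(np.sqrt(mse))
    sse_paper = sse_std / n**2
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("observed values are all identical; R2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - sse_std / ss_tot
    sse_for_aic = sse_paper if aic_sse == "paper" else sse_std
    aic = n * float(np.log(sse_for_aic)) + 2 * p if sse_for_aic > 0 else -np.inf
    aad = float(np.mean(np.abs(err) / np.abs(observed))) * 100.0
    return ModelMetrics(
        R2=float(r2), MSE=float(mse), RMSE=rmse,
        SSE_paper=float(sse_paper), SSE_standard=sse_std,
        AIC=float(aic), AAD_pct=aad, n=n, p=int(p),
    )


#: metric name -> True when larger is better
_DIRECTIONS = {
    "R2": True,
    "MSE": False,
    "RMSE": False,
    "SSE_paper": False,
    "AIC": False,
    "AAD_pct": False,
}


def compare_models(
    metrics_a: ModelMetrics, metrics_b: ModelMetrics,
    label_a: str = "a", label_b: str = "b",
) -> dict:
    """Per-metric winner and an overall majority verdict.

    Higher R2 wins; lower MSE/RMSE/SSE/AIC/AAD wins.  Equal values tie.  A
    split decision is reported as such, never raised.
    """
    if metrics_a.n != metrics_b.n:
        raise ValueError("metrics computed on different numbers of points")
    winners: dict[str, str | None] = {}
    tally = {label_a: 0, label_b: 0}
    for name, higher_better in _DIRECTIONS.items():
        va, vb = getattr(metrics_a, name), getattr(metrics_b, name)
        if va == vb:
            winners[name] = None
        else:
            better_a = va > vb if higher_better else va < vb
            win = label_a if better_a else label_b
            winners[name] = win
            tally[win] += 1
    if tally[label_a] > tally[label_b]:
        verdict = label_a
    elif tally[label_b] > tally[label_a]:
        verdict = label_b
    else:
        verdict = None
    return {
        "winners": winners,
        "wins": tally,
        "verdict": verdict,
        label_a: metrics_a.to_dict(),
        label_b: metrics_b.to_dict(),
    }
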