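"""Synthetic response-surface datasets with known ground truth.

The generator emulates the data-generating assumption behind the whole
pipeline: a smooth true yield surface over the factor box, observed at
Box-Behnken design points with i.i.d. Gaussian replicate noise.  The truth
is a quadratic polynomial in coded units (optionally plus a declared
non-quadratic bump, so that a network surrogate has a genuine edge over the
quadratic fit), which makes every downstream stage testable against exact
known coefficients and a grid-verified box optimum.

Noise levels: the six replicated centre runs of the packaged study design
have a sample standard deviation of about 0.125 yield points
(``NOISE_SD_DATA``); ``NOISE_SD_LOW`` = 0.08 is a low-noise setting used
for recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .design import DesignTable, FactorSpec, PAPER_FACTORS, build_bbd, RESPONSE_COLUMN
from .rsm import QuadraticModel, term_names

__all__ = [
    "SurfaceSpec",
    "GroundTruth",
    "NOISE_SD_LOW",
    "NOISE_SD_DATA",
    "published_yield_model",
    "paper_like_spec",
    "generate",
    "tansig_bump",
]

NOISE_SD_LOW = 0.08
NOISE_SD_DATA = 0.125  # sd of the packaged design's six centre yields


def published_yield_model() -> QuadraticModel:
    """The published reduced yield polynomial in coded units.

    Y = 7.34 + 0.13 X2 + 0.078 X3 + 0.049 X4 + 0.13 X1X4 - 0.14 X2X3
        - 0.15 X1^2 - 0.084 X2^2 - 0.098 X3^2 - 0.14 X4^2
    """
    names = term_names(4)
    coef = dict.fromkeys(names, 0.0)
    coef.update(
        {
            "Intercept": 7.34,
            "X2": 0.13,
            "X3": 0.078,
            "X4": 0.049,
            "X1X4": 0.13,
            "X2X3": -0.14,
            "X1^2": -0.15,
            "X2^2": -0.084,
            "X3^2": -0.098,
            "X4^2": -0.14,
        }
    )
    vec = np.array([coef[n] for n in names])
    return QuadraticModel(4, vec, vec != 0.0)


@dataclass
class SurfaceSpec:
    """Declared truth for a synthetic response-surface experiment.

    ``bump`` (optional) is an extra non-quadratic term added to the
    polynomial, as a callable of the coded point matrix.
    """

    true_model: QuadraticModel
    factors: tuple[FactorSpec, ...] = PAPER_FACTORS
    noise_sd: float = NOISE_SD_LOW
    n_center: int = 6
    seed: int = 0
    bump: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.factors = tuple(self.factors)

    def surface(self, coded: np.ndarray) -> np.ndarray:
        """Noise-free truth at coded points."""
        y = self.true_model.predict(coded)
        if self.bump is not None:
            y = y + self.bump(np.atleast_2d(np.asarray(coded, float)))
        return y


@dataclass
class GroundTruth:
    """What the generator knows: coefficients and the box optimum."""

    coef: np.ndarray
    argmax_coded: np.ndarray
    argmax_actual: np.ndarray
    max_value: float


def tansig_bump(amplitude: float = 0.3, sharpness: float = 2.0):
    """A smooth non-quadratic ridge, amplitude * tanh(s * (x1 + x2)).

    A saturating function of the x1 + x2 diagonal takes five distinct
    levels on a Box-Behnken design and cannot be interpolated by any
    quadratic in the coded factors, so adding it to a quadratic truth
    breaks the polynomial model's correct specification and gives a
    network surrogate a measurable edge.  (A separable product of odd
    one-variable functions would NOT do: on a BBD it collapses onto the
    x1*x2 interaction column.)
    """

    def bump(coded: np.ndarray) -> np.ndarray:
        return amplitude * np.tanh(sharpness * (coded[:, 0] + coded[:, 1]))

    return bump


def paper_like_spec(
    noise_sd: float = NOISE_SD_LOW, seed: int = 0, n_center: int = 6
) -> SurfaceSpec:
    """A drop-in stand-in for the extraction study.

    Truth is the published reduced polynomial, factors and centre-replicate
    count match the 30-run design, default noise is the low-noise setting.
    """
    return SurfaceSpec(
        true_model=published_yield_model(),
        factors=PAPER_FACTORS,
        noise_sd=noise_sd,
        n_center=n_center,
        seed=seed,
    )


def _grid_argmax(spec: SurfaceSpec, points_per_axis: int = 21, refine: int = 3):
    """Box optimum of the true surface by coarse grid with local refinement."""
    k = len(spec.factors)
    lo = -np.ones(k)
    hi = np.ones(k)
    best_x, best_v = None, -np.inf
    for _ in range(refine + 1):
        axes = [np.linspace(lo[i], hi[i], points_per_axis) for i in range(k)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = spec.surface(pts)
        i = int(np.argmax(vals))
        best_x, best_v = pts[i], float(vals[i])
        halfwidth = (hi - lo) / (points_per_axis - 1) * 2
        lo = np.clip(best_x - halfwidth, -1.0, 1.0)
        hi = np.clip(best_x + halfwidth, -1.0, 1.0)
    return best_x, best_v


def generate(spec: SurfaceSpec) -> tuple[DesignTable, GroundTruth]:
    """Draw one BBD dataset from the spec's truth + Gaussian noise.

    Deterministic under ``spec.seed``.  Returns the design table (responses
    filled) and the ground-truth record, including the true box optimum
    located by grid search with refinement.
    """
    table = build_bbd(spec.factors, spec.n_center)
    rng = np.random.default_rng(spec.seed)
    clean = spec.surface(table.coded)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(clean))
    table.frame[RESPONSE_COLUMN] = noisy
    from .design import decode

    ax, av = _grid_argmax(spec)
    truth = GroundTruth(
        coef=spec.true_model.coef.copy(),
        argmax_coded=ax,
        argmax_actual=decode(ax, spec.factors),
        max_value=av,
    )
    return table, truth
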