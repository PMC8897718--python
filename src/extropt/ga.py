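"""Binary-coded genetic algorithm for box-constrained maximization.

Each factor is encoded as a fixed-length bit substring; a chromosome is the
concatenation over factors (4 factors x 5 bits = 20 bits by default).  A
substring with integer value b in 0..2^L-1 decodes linearly onto the factor
box, low + b/(2^L - 1) * (high - low), so both bounds are representable and
the decodable set is a uniform grid.  Selection is fitness-proportional
(roulette), recombination is two-point crossover, variation is independent
per-bit mutation, and elitism (default 1) carries the best chromosome
unchanged into the next generation, making the best-fitness history
non-decreasing.

Fitness here is typically the neural surrogate of the extraction yield, but
any finite function of the decoded factor vector works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAConfig",
    "GAResult",
    "decode_chromosome",
    "roulette_select",
    "two_point_crossover",
    "mutate",
    "run_ga",
    "practical_round",
    "PAPER_BOUNDS",
    "PAPER_INCREMENTS",
]

#: factor box of the extraction study: power W, temperature degC,
#: liquid-to-solid ratio mL/g, time min
PAPER_BOUNDS: tuple[tuple[float, float], ...] = (
    (200.0, 400.0), (50.0, 70.0), (15.0, 25.0), (20.0, 40.0),
)

#: equipment-achievable setting increments for the same factors
PAPER_INCREMENTS: tuple[float, ...] = (50.0, 1.0, 1.0, 1.0)


class EncodingError(ValueError):
    """Chromosome length inconsistent with the configuration."""


@dataclass(frozen=True)
class GAConfig:
    bounds: tuple[tuple[float, float], ...] = PAPER_BOUNDS
    population_size: int = 20
    bits_per_variable: int = 5
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    max_generations: int = 70
    elitism: int = 1
    seed: int = 0
    stall_generations: int = 20
    stall_tol: float = 1e-6
    use_stall: bool = True

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy low < high")

    @property
    def k(self) -> int:
        return len(self.bounds)

    @property
    def chromosome_length(self) -> int:
        return self.k * self.bits_per_variable

    @property
    def levels(self) -> int:
        return 2**self.bits_per_variable


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_actual: np.ndarray
    best_fitness: float
    history_best: list[float]
    history_mean: list[float]
    generations_run: int


def decode_chromosome(chromosome: np.ndarray, config: GAConfig) -> np.ndarray:
    """Decode a bit vector into actual factor values on the box grid."""
    bits = np.asarray(chromosome, dtype=int).ravel()
    L = config.bits_per_variable
    if bits.shape != (config.chromosome_length,):
        raise EncodingError(
            f"expected {config.chromosome_length} bits, got {bits.shape}"
        )
    if np.any((bits != 0) & (bits != 1)):
        raise EncodingError("chromosome entries must be 0/1")
    place = 2 ** np.arange(L - 1, -1, -1)
    ints = bits.reshape(config.k, L) @ place
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    return lo + ints / (config.levels - 1) * (hi - lo)


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional parent index; uniform (with warning) if all zero."""
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("roulette selection requires non-negative fitnesses")
    total = f.sum()
    if total == 0.0:
        warnings.warn("all-zero fitness: selecting uniformly", stacklevel=2)
        return int(rng.integers(len(f)))
    return int(np.searchsorted(np.cumsum(f), rng.uniform(0.0, total), side="right"))


def two_point_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
    cuts: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the segment between two cut positions (inclusive of both).

    Cut positions are distinct indices in 0..L-1; the bit multiset of the
    pair is conserved.  When ``cuts`` is omitted they are drawn from the
    generator.
    """
    a = np.asarray(a, dtype=int).copy()
    b = np.asarray(b, dtype=int).copy()
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    L = len(a)
    if cuts is None:
        c1, c2 = sorted(rng.choice(L, size=2, replace=False))
    else:
        c1, c2 = sorted(cuts)
    seg = slice(c1, c2 + 1)
    a[seg], b[seg] = b[seg].copy(), a[seg].copy()
    return a, b


def mutate(
    chromosome: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit independently with probability ``prob``."""
    bits = np.asarray(chromosome, dtype=int).copy()
    flip = rng.uniform(size=len(bits)) < prob
    bits[flip] ^= 1
    return bits


def run_ga(fitness, config: GAConfig) -> GAResult:
    """Generational GA maximizing ``fitness`` over the factor box.

    Per generation: evaluate, carry over ``elitism`` best chromosomes,
    fill the population with roulette-selected parent pairs recombined by
    two-point crossover (probability ``crossover_prob``) and per-bit
    mutation.  Stops at ``max_generations`` or when the best fitness has
    not improved by more than ``stall_tol`` for ``stall_generations``
    generations.  Roulette weights are floor-shifted (f - min + eps) when
    any fitness is non-positive.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length
    pop = rng.integers(0, 2, size=(config.population_size, L))

    def evaluate(p: np.ndarray) -> np.ndarray:
        vals = np.array([fitness(decode_chromosome(c, config)) for c in p], float)
        if not np.all(np.isfinite(vals)):
            bad = p[int(np.nonzero(~np.isfinite(vals))[0][0])]
            raise ValueError(
                f"non-finite fitness at decoded point {decode_chromosome(bad, config)}"
            )
        return vals

    history_best: list[float] = []
    history_mean: list[float] = []
    best_chrom: np.ndarray | None = None
    best_fit = -np.inf
    stall = 0
    generations_run = 0

    fit = evaluate(pop)
    for gen in range(config.max_generations + 1):
        order = np.argsort(fit)[::-1]
        if fit[order[0]] > best_fit + config.stall_tol:
            stall = 0
        else:
            stall += 1
        if fit[order[0]] > best_fit:
            best_fit = float(fit[order[0]])
            best_chrom = pop[order[0]].copy()
        history_best.append(best_fit if config.elitism >= 1 else float(fit[order[0]]))
        history_mean.append(float(fit.mean()))
        generations_run = gen
        if gen == config.max_generations:
            break
        if config.use_stall and stall >= config.stall_generations:
            break

        # roulette weights must be positive
        weights = fit.copy()
        if weights.min() <= 0.0:
            weights = weights - weights.min() + 1e-12
        children = [pop[order[i]].copy() for i in range(config.elitism)]
        while len(children) < config.population_size:
            ia = roulette_select(weights, rng)
            ib = roulette_select(weights, rng)
            ca, cb = pop[ia].copy(), pop[ib].copy()
            if rng.uniform() < config.crossover_prob:
                ca, cb = two_point_crossover(ca, cb, rng)
            children.append(mutate(ca, config.mutation_prob, rng))
            if len(children) < config.population_size:
                children.append(mutate(cb, config.mutation_prob, rng))
        pop = np.vstack(children)
        fit = evaluate(pop)

    assert best_chrom is not None
    return GAResult(
        best_chromosome=best_chrom,
        best_actual=decode_chromosome(best_chrom, config),
        best_fitness=best_fit,
        history_best=history_best,
        history_mean=history_mean,
        generations_run=generations_run,
    )


def grid_maximum(fitness, config: GAConfig) -> tuple[np.ndarray, float]:
    """Exhaustive search over the GA's decodable grid (oracle for tests).

    Enumerates all ``levels**k`` grid points; intended for small k and bit
    counts (32^4 ~ 1e6 points for the default encoding).
    """
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    axes = [lo[i] + np.arange(config.levels) / (config.levels - 1) * (hi[i] - lo[i])
            for i in range(config.k)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    vals = fitness(pts)
    vals = np.asarray(vals, dtype=float).ravel()
    i = int(np.argmax(vals))
    return pts[i], float(vals[i])


def practical_round(
    actual: np.ndarray,
    increments: np.ndarray,
    bounds: tuple[tuple[float, float], ...] | None = None,
) -> np.ndarray:
    """Snap each value to the nearest multiple of its equipment increment.

    Halfway cases round away from zero (375 with increment 50 -> 400).
    Results are clipped to ``bounds`` when given.
    """
    v = np.asarray(actual, dtype=float)
    inc = np.asarray(increments, dtype=float)
    if np.any(inc <= 0):
        raise ValueError("increments must be positive")
    out = np.sign(v) * np.floor(np.abs(v) / inc + 0.5) * inc
    if bounds is not None:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        out = np.clip(out, lo, hi)
    return out
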