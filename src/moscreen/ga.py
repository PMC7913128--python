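"""Genetic-algorithm selection of target/off-target subsets.

Each candidate screening model is a bit string over the ``T`` protein
columns of a :class:`~moscreen.desirability.ProbabilityMatrix` (1 = the
column's classifier enters the desirability aggregation). The fitness of a
mask is the BEDROC (at early-recognition weight ``alpha``) of the library
ranked by the mask's desirability scores — so evolution directly maximises
early retrieval of the known desirable compounds. Masks that select no
target or no off-target column are invalid and receive a ``-inf`` fitness
sentinel, which lets the population cross invalid regions without repair.

The evolutionary operators are standard bit-string GA machinery: tournament
selection, two-point crossover, per-individual mutation with a per-bit flip
probability of ``1/T``, and single-elite preservation (which makes the
per-generation best-fitness trace non-decreasing). Fitness is memoized by
mask, a pure function of (matrix, mask, alpha), so revisited genotypes cost
nothing.

The high-level entry point follows the model/results idiom:

>>> model = DesirabilityScreenGA(matrix, GAConfig(population_size=200,
...                                               generations=100, seed=7))
>>> res = model.fit()
>>> res.best_mask, res.best_fitness
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .desirability import (
    InvalidMaskError,
    ProbabilityMatrix,
    rank_by_desirability,
)
from .metrics import RankedScreen, auac, bedroc, enrichment_factor

__all__ = ["GAConfig", "GAResult", "DesirabilityScreenGA", "fitness", "run_ga"]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults are full screening scale (population 4000 evolving for 3000
    generations, mutation probability 0.4, BEDROC weight alpha = 160.9);
    scale ``population_size``/``generations`` down for experiments.
    ``mutation_prob`` is per individual; inside a mutated individual each
    bit flips independently with probability ``bit_flip_prob`` (default
    ``1/T``).
    """

    population_size: int = 4000
    generations: int = 3000
    mutation_prob: float = 0.4
    crossover_prob: float = 0.6
    tournament_size: int = 3
    alpha: float = 160.9
    seed: int = 0
    restarts: int = 1
    bit_flip_prob: float | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("mutation_prob", "crossover_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def fitness(
    mask,
    matrix: ProbabilityMatrix,
    alpha: float,
    _cache: dict | None = None,
) -> float:
    """BEDROC(alpha) of the desirability ranking under ``mask``.

    Invalid masks (no target or no off-target bit set) return ``-inf``.
    """
    arr = np.asarray(mask, dtype=bool)
    key = arr.tobytes()
    if _cache is not None and key in _cache:
        return _cache[key]
    try:
        screen = rank_by_desirability(matrix, arr)
        value = bedroc(screen, alpha)
    except InvalidMaskError:
        value = NEG_INF
    if _cache is not None:
        _cache[key] = value
    return value


@dataclass
class GAResult:
    """Outcome of one (possibly multi-restart) GA optimisation.

    ``population`` is the final generation of the best restart as
    ``(mask, fitness)`` pairs; ``trace`` its per-generation best fitness
    (non-decreasing, elitism); ``restart_traces`` holds every restart's
    trace.
    """

    best_mask: np.ndarray
    best_fitness: float
    population: list[tuple[np.ndarray, float]]
    trace: np.ndarray
    restart_traces: list[np.ndarray]
    config: GAConfig
    matrix: ProbabilityMatrix = field(repr=False)
    n_evaluations: int = 0

    @property
    def best_screen(self) -> RankedScreen:
        return rank_by_desirability(self.matrix, self.best_mask)

    def selected_targets(self) -> list[str]:
        return [
            t
            for t, r, b in zip(
                self.matrix.target_ids, self.matrix.roles, self.best_mask
            )
            if b and r == "target"
        ]

    def selected_off_targets(self) -> list[str]:
        return [
            t
            for t, r, b in zip(
                self.matrix.target_ids, self.matrix.roles, self.best_mask
            )
            if b and r == "off_target"
        ]

    def population_frame(self) -> pd.DataFrame:
        """Final population as a DataFrame (bit string + fitness)."""
        return pd.DataFrame(
            {
                "mask": [
                    "".join("1" if b else "0" for b in m)
                    for m, _ in self.population
                ],
                "fitness": [f for _, f in self.population],
            }
        )

    def summary(self, chi: float = 0.01) -> str:
        """Human-readable report of the best model's screening performance."""
        screen = self.best_screen
        a = self.config.alpha
        lines = [
            "Desirability screen — GA model selection",
            "=" * 46,
            f"columns (T):            {self.matrix.shape[1]}",
            f"library size (M):       {self.matrix.shape[0]}",
            f"known desirables (n):   {screen.n}",
            f"population / gens:      {self.config.population_size} / "
            f"{self.config.generations} (restarts: {self.config.restarts})",
            f"fitness evaluations:    {self.n_evaluations} (memoized)",
            "-" * 46,
            f"best BEDROC (alpha={a:g}): {self.best_fitness:.4f}",
            f"EF at chi={chi:g}:          {enrichment_factor(screen, chi):.3f}",
            f"AUAC:                   {auac(screen):.4f}",
            f"selected targets ({len(self.selected_targets())}):  "
            + ", ".join(self.selected_targets()),
            f"selected off-targets ({len(self.selected_off_targets())}): "
            + ", ".join(self.selected_off_targets()),
        ]
        return "\n".join(lines)


class DesirabilityScreenGA:
    """Model object: a probability matrix plus GA configuration.

    ``fit()`` runs the evolution (all restarts) and returns a
    :class:`GAResult`. Deterministic under a fixed ``config.seed``; restart
    ``k`` uses the derived seed ``seed + k``.
    """

    def __init__(self, matrix: ProbabilityMatrix, config: GAConfig | None = None):
        if not matrix.actives:
            raise ValueError(
                "matrix must flag at least one active compound to define fitness"
            )
        if not 1 <= len(matrix.actives) < matrix.shape[0]:
            raise ValueError("actives must be a strict non-empty subset of rows")
        self.matrix = matrix
        self.config = config or GAConfig()

    # -- evolutionary operators -------------------------------------------

    def _repair(self, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Force >= 1 bit per role on by flipping one random bit of a missing
        role; used only for the initial population."""
        for role_mask in (self.matrix.target_role_mask,
                          self.matrix.off_target_role_mask):
            if not (mask & role_mask).any():
                idx = rng.choice(np.flatnonzero(role_mask))
                mask[idx] = True
        return mask

    def _initial_population(self, rng: np.random.Generator) -> list[np.ndarray]:
        T = self.matrix.shape[1]
        return [
            self._repair(rng.random(T) < 0.5, rng)
            for _ in range(self.config.population_size)
        ]

    @staticmethod
    def _two_point_crossover(
        a: np.ndarray, b: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        T = a.size
        i, j = sorted(rng.choice(T + 1, size=2, replace=False))
        c1, c2 = a.copy(), b.copy()
        c1[i:j], c2[i:j] = b[i:j], a[i:j]
        return c1, c2

    def _mutate(self, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = self.config.bit_flip_prob
        if p is None:
            p = 1.0 / mask.size
        flips = rng.random(mask.size) < p
        return np.where(flips, ~mask, mask)

    def _tournament(
        self,
        fits: np.ndarray,
        rng: np.random.Generator,
    ) -> int:
        contenders = rng.integers(0, fits.size, size=self.config.tournament_size)
        return int(contenders[np.argmax(fits[contenders])])

    # -- main loop ---------------------------------------------------------

    def _evolve_once(
        self, seed: int, cache: dict
    ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, int]:
        cfg = self.config
        rng = np.random.default_rng(seed)
        pop = self._initial_population(rng)
        evals = 0

        def evaluate(individuals: list[np.ndarray]) -> np.ndarray:
            nonlocal evals
            out = np.empty(len(individuals))
            for i, m in enumerate(individuals):
                key = m.tobytes()
                if key not in cache:
                    evals += 1
                out[i] = fitness(m, self.matrix, cfg.alpha, cache)
            return out

        fits = evaluate(pop)
        trace = [float(fits.max())]
        for _ in range(cfg.generations):
            elite_idx = int(np.argmax(fits))
            children: list[np.ndarray] = [pop[elite_idx].copy()]
            while len(children) < cfg.population_size:
                p1 = pop[self._tournament(fits, rng)]
                p2 = pop[self._tournament(fits, rng)]
                if rng.random() < cfg.crossover_prob:
                    c1, c2 = self._two_point_crossover(p1, p2, rng)
                else:
                    c1, c2 = p1.copy(), p2.copy()
                for c in (c1, c2):
                    if len(children) < cfg.population_size:
                        if rng.random() < cfg.mutation_prob:
                            c = self._mutate(c, rng)
                        children.append(c)
            pop = children
            fits = evaluate(pop)
            trace.append(float(fits.max()))
        return pop, fits, np.asarray(trace), evals

    def fit(self) -> GAResult:
        """Run the GA (all restarts) and return the results object."""
        cfg = self.config
        cache: dict = {}
        best: tuple[float, np.ndarray] | None = None
        best_run: tuple[list[np.ndarray], np.ndarray, np.ndarray] | None = None
        traces: list[np.ndarray] = []
        total_evals = 0
        for k in range(cfg.restarts):
            pop, fits, trace, evals = self._evolve_once(cfg.seed + k, cache)
            traces.append(trace)
            total_evals += evals
            i = int(np.argmax(fits))
            if best is None or fits[i] > best[0]:
                best = (float(fits[i]), pop[i].copy())
                best_run = (pop, fits, trace)
        assert best is not None and best_run is not None
        pop, fits, trace = best_run
        return GAResult(
            best_mask=best[1],
            best_fitness=best[0],
            population=[(m.copy(), float(f)) for m, f in zip(pop, fits)],
            trace=trace,
            restart_traces=traces,
            config=cfg,
            matrix=self.matrix,
            n_evaluations=total_evals,
        )


def run_ga(matrix: ProbabilityMatrix, config: GAConfig | None = None) -> GAResult:
    """Functional wrapper: ``DesirabilityScreenGA(matrix, config).fit()``."""
    return DesirabilityScreenGA(matrix, config).fit()
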