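"""Early-recognition metrics for ranked virtual screens.

A virtual screen orders ``N`` compounds from most to least promising; ``n`` of
them are the known desirables ("actives"). Each active sits at rank ``r_i``
(1-based, best first) with relative rank ``x_i = r_i / N``. The metrics here
summarise how strongly the actives concentrate at the top of the list:

* **AUAC** — area under the accumulation curve, ``1 - mean(x_i)``. Rewards a
  good *average* position but is blind to the early part of the list.
* **EF** — enrichment factor at a fraction ``chi``: actives retrieved in the
  top ``ceil(chi * N)`` positions relative to the random expectation.
* **RIE / BEDROC** — exponentially rank-weighted retrieval. ``RIE`` averages
  ``exp(-alpha * x_i)`` over the actives (normalised by the uniform
  expectation); ``BEDROC`` min-max rescales it to [0, 1]. Large ``alpha``
  makes only the very top of the list matter.

The weight ``alpha`` is calibrated so that a fraction ``theta`` of the total
BEDROC weight falls in the top fraction ``z`` of the list, by solving

    theta * (1 - exp(-alpha)) - 1 + exp(-alpha * z) = 0

for its positive root (``solve_alpha``). The conventional screening setting
``theta = 0.8``, ``z = 0.01`` gives ``alpha ≈ 160.9``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RankedScreen",
    "auac",
    "enrichment_factor",
    "rie",
    "rie_bounds",
    "bedroc",
    "solve_alpha",
]


@dataclass(frozen=True)
class RankedScreen:
    """An ordered compound list with active flags.

    Parameters
    ----------
    ids
        Compound identifiers, best rank first (rank ``r = 1 .. N``).
    active_flags
        Boolean per position; True marks a known desirable compound.
    """

    ids: tuple[str, ...]
    active_flags: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        flags = np.asarray(self.active_flags, dtype=bool)
        object.__setattr__(self, "active_flags", flags)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) != flags.size:
            raise ValueError("ids and active_flags must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("compound ids must be unique")
        n, N = int(flags.sum()), flags.size
        if not 1 <= n < N:
            raise ValueError(
                f"need 1 <= n < N actives in the screen, got n={n}, N={N}"
            )

    @property
    def N(self) -> int:
        """Total number of compounds."""
        return self.active_flags.size

    @property
    def n(self) -> int:
        """Number of actives."""
        return int(self.active_flags.sum())

    @property
    def active_ranks(self) -> np.ndarray:
        """1-based ranks ``r_i`` of the actives."""
        return np.flatnonzero(self.active_flags) + 1

    @property
    def relative_ranks(self) -> np.ndarray:
        """Relative ranks ``x_i = r_i / N`` of the actives, in (0, 1]."""
        return self.active_ranks / self.N

    @classmethod
    def from_scores(
        cls,
        ids,
        scores,
        actives,
    ) -> "RankedScreen":
        """Rank compounds by descending score, ties broken by compound id.

        The deterministic tie policy (lexicographic id within equal scores)
        gives every score vector a unique total order, which BEDROC requires.
        """
        ids = [str(i) for i in ids]
        scores = np.asarray(scores, dtype=float)
        if scores.size != len(ids):
            raise ValueError("ids and scores must have equal length")
        order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
        ranked = [ids[i] for i in order]
        active_set = set(map(str, actives))
        flags = np.fromiter((c in active_set for c in ranked), dtype=bool)
        return cls(tuple(ranked), flags)


def auac(screen: RankedScreen) -> float:
    """Area under the accumulation curve: ``1 - (1/n) * sum(x_i)``."""
    return float(1.0 - screen.relative_ranks.mean())


def enrichment_factor(screen: RankedScreen, chi: float) -> float:
    """Enrichment factor at list fraction ``chi``.

    The top set is the first ``ceil(chi * N)`` positions; the factor is the
    active count there divided by the random expectation ``chi_eff * n``,
    where ``chi_eff = ceil(chi * N) / N`` is the effective fraction actually
    cut. Using the realised cutoff (rather than the nominal ``chi``) keeps
    the maximum exactly attainable: EF = 1/chi_eff when every top position
    can hold an active.
    """
    if not 0.0 < chi <= 1.0:
        raise ValueError(f"chi must be in (0, 1], got {chi}")
    cutoff = math.ceil(chi * screen.N)
    chi_eff = cutoff / screen.N
    hits = int(np.count_nonzero(screen.active_ranks <= cutoff))
    return hits / (chi_eff * screen.n)


def _rie_uniform_mean(alpha: float, N: int) -> float:
    # (1/N) * (1 - e^{-alpha}) / (e^{alpha/N} - 1), in overflow-safe form
    return -np.expm1(-alpha) / (N * np.expm1(alpha / N))


def rie(screen: RankedScreen, alpha: float) -> float:
    """Robust initial enhancement at exponential weight ``alpha``.

    ``RIE = mean_i exp(-alpha * x_i) / E_uniform[exp(-alpha * x)]`` — the
    rank-weighted retrieval of the actives relative to a uniformly random
    placement. RIE -> 1 as alpha -> 0+ for any screen.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    num = np.exp(-alpha * screen.relative_ranks).mean()
    return float(num / _rie_uniform_mean(alpha, screen.N))


def rie_bounds(n: int, N: int, alpha: float) -> tuple[float, float]:
    """(RIE_min, RIE_max) for a screen with ``n`` actives among ``N``.

    RIE_min = (1 - e^{alpha*Ra}) / (Ra * (1 - e^{alpha}))
    RIE_max = (1 - e^{-alpha*Ra}) / (Ra * (1 - e^{-alpha}))

    with ``Ra = n / N``, evaluated via ``expm1`` so that screening-scale
    weights (alpha ~ 161) do not overflow.
    """
    ra = n / N
    rie_min = np.expm1(alpha * ra) / (ra * np.expm1(alpha))
    rie_max = np.expm1(-alpha * ra) / (ra * np.expm1(-alpha))
    return float(rie_min), float(rie_max)


def bedroc(screen: RankedScreen, alpha: float) -> float:
    """Boltzmann-enhanced discrimination of ROC, in [0, 1].

    Min–max normalisation of RIE over all possible active placements:
    ``(RIE - RIE_min) / (RIE_max - RIE_min)``. 1 means all actives occupy
    the top ``n`` ranks, 0 the bottom ``n``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    lo, hi = rie_bounds(screen.n, screen.N, alpha)
    return float((rie(screen, alpha) - lo) / (hi - lo))


def solve_alpha(theta: float, z: float) -> float:
    """Calibrate the early-recognition weight ``alpha``.

    Returns the positive root of ``theta*(1 - e^{-alpha}) - 1 + e^{-alpha*z} = 0``,
    i.e. the weight at which the top fraction ``z`` of the ranked list carries
    a fraction ``theta`` of the total BEDROC weight. Solved by bracketed root
    search (Brent); the residual of the returned root is below 1e-10.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    if not 0.0 < z < 1.0:
        raise ValueError(f"z must be in (0, 1), got {z}")
    if theta <= z:
        raise ValueError(
            "theta must exceed z (the early segment must be over-weighted) "
            f"for a positive root to exist; got theta={theta}, z={z}"
        )

    def f(a: float) -> float:
        return theta * -math.expm1(-a) - 1.0 + math.exp(-a * z)

    lo, hi = 1e-9, 10.0
    # expand the bracket until the far end is negative
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid (theta, z)
            raise RuntimeError("no sign change found while bracketing alpha")
    root = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(f(root)) >= 1e-10:  # pragma: no cover - brentq at this tol
        raise RuntimeError(f"root residual too large: {f(root):.3e}")
    return float(root)
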