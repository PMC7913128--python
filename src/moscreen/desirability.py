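"""Desirability aggregation of per-target activity probabilities.

Given a library of ``M`` compounds scored by ``T`` per-protein activity
classifiers — each cell ``P[i, j]`` the predicted probability that compound
``i`` is active on protein ``j`` — and a partition of the proteins into
*targets* (activity wanted) and *off-targets* (activity to be avoided), a
subset of columns selected by a bit mask defines one multi-objective
screening model. The desirability of compound ``i`` under that model is

    D_i = P_i^P * P_i^O

where ``P_i^P`` is the mean predicted activity probability over the selected
target columns and ``P_i^O`` the mean predicted *inactivity* probability
(``1 - P``) over the selected off-target columns. Both factors live in
[0, 1], so D rewards compounds likely to hit the chosen targets while
missing the chosen off-targets. Ranking the library by descending D yields
the virtual screen evaluated by the early-recognition metrics.

A mask must select at least one target and at least one off-target: with an
empty role the corresponding mean is undefined, and dropping the factor
would silently abandon one of the two objectives. Such masks raise
:class:`InvalidMaskError`; the genetic algorithm maps them to a -inf fitness
sentinel instead of repairing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import RankedScreen

__all__ = [
    "ROLE_TARGET",
    "ROLE_OFF_TARGET",
    "InvalidMaskError",
    "ProbabilityMatrix",
    "compound_desirability",
    "desirability_scores",
    "rank_by_desirability",
]

ROLE_TARGET = "target"
ROLE_OFF_TARGET = "off_target"


class InvalidMaskError(ValueError):
    """Raised for masks that select no target or no off-target column."""


@dataclass
class ProbabilityMatrix:
    """Compounds x proteins activity-probability matrix with column roles.

    Attributes
    ----------
    P
        Array of shape (M, T), probabilities in [0, 1], no missing cells.
    compound_ids, target_ids
        Row and column identifiers (unique).
    roles
        Per-column role, each ``"target"`` or ``"off_target"``.
    actives
        Compound ids flagged as known desirables; used only to evaluate
        screens, never to compute scores.
    """

    P: np.ndarray
    compound_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    roles: np.ndarray
    actives: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.compound_ids = tuple(str(c) for c in self.compound_ids)
        self.target_ids = tuple(str(t) for t in self.target_ids)
        self.roles = np.asarray(self.roles, dtype=object)
        self.actives = frozenset(str(a) for a in self.actives)
        if self.P.ndim != 2:
            raise ValueError("P must be 2-dimensional")
        M, T = self.P.shape
        if len(self.compound_ids) != M or len(self.target_ids) != T:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.compound_ids)) != M:
            raise ValueError("compound ids must be unique")
        if len(set(self.target_ids)) != T:
            raise ValueError("target ids must be unique")
        if self.roles.size != T:
            raise ValueError("one role per column required")
        bad_roles = set(self.roles) - {ROLE_TARGET, ROLE_OFF_TARGET}
        if bad_roles:
            raise ValueError(f"unknown column roles: {sorted(bad_roles)}")
        if np.isnan(self.P).any():
            raise ValueError("probability matrix contains missing cells")
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        unknown = self.actives - set(self.compound_ids)
        if unknown:
            raise ValueError(f"actives not present in matrix: {sorted(unknown)[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.P.shape

    @property
    def n_targets(self) -> int:
        return int((self.roles == ROLE_TARGET).sum())

    @property
    def n_off_targets(self) -> int:
        return int((self.roles == ROLE_OFF_TARGET).sum())

    @property
    def target_role_mask(self) -> np.ndarray:
        return self.roles == ROLE_TARGET

    @property
    def off_target_role_mask(self) -> np.ndarray:
        return self.roles == ROLE_OFF_TARGET

    @property
    def active_flags(self) -> np.ndarray:
        return np.fromiter(
            (c in self.actives for c in self.compound_ids), dtype=bool
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        roles,
        actives=(),
    ) -> "ProbabilityMatrix":
        """Build from a DataFrame (index = compound ids, columns = proteins).

        ``roles`` is a mapping ``target_id -> role`` or a sequence aligned
        with ``df.columns``.
        """
        if isinstance(roles, dict):
            missing = [c for c in df.columns if str(c) not in roles]
            if missing:
                raise ValueError(f"no role given for columns: {missing[:5]}")
            role_arr = np.array([roles[str(c)] for c in df.columns], dtype=object)
        else:
            role_arr = np.asarray(list(roles), dtype=object)
        return cls(
            P=df.to_numpy(dtype=float),
            compound_ids=tuple(map(str, df.index)),
            target_ids=tuple(map(str, df.columns)),
            roles=role_arr,
            actives=frozenset(map(str, actives)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.P, index=list(self.compound_ids), columns=list(self.target_ids)
        )


def _as_bool_mask(mask, T: int) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        arr = arr.astype(int).astype(bool)
    if arr.shape != (T,):
        raise ValueError(f"mask length {arr.shape} does not match T={T}")
    return arr


def validate_mask(mask, roles: np.ndarray) -> np.ndarray:
    """Check a mask selects >= 1 target and >= 1 off-target column."""
    roles = np.asarray(roles, dtype=object)
    arr = _as_bool_mask(mask, roles.size)
    if not (arr & (roles == ROLE_TARGET)).any():
        raise InvalidMaskError("mask selects no target column")
    if not (arr & (roles == ROLE_OFF_TARGET)).any():
        raise InvalidMaskError("mask selects no off-target column")
    return arr


def compound_desirability(
    p_row, mask, roles
) -> tuple[float, float, float]:
    """Desirability of a single compound: ``(D, P^P, P^O)``.

    Scalar counterpart of :func:`desirability_scores`; ``p_row`` is one row
    of the probability matrix.
    """
    roles = np.asarray(roles, dtype=object)
    arr = validate_mask(mask, roles)
    p_row = np.asarray(p_row, dtype=float)
    sel_t = arr & (roles == ROLE_TARGET)
    sel_o = arr & (roles == ROLE_OFF_TARGET)
    p_t = float(p_row[sel_t].mean())
    p_o = float((1.0 - p_row[sel_o]).mean())
    return p_t * p_o, p_t, p_o


def desirability_scores(
    matrix: ProbabilityMatrix, mask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised desirability over the whole library: ``(D, P^P, P^O)``.

    ``D[i] = mean(P[i, selected targets]) * mean(1 - P[i, selected
    off-targets])`` for every compound at once.
    """
    arr = validate_mask(mask, matrix.roles)
    sel_t = arr & matrix.target_role_mask
    sel_o = arr & matrix.off_target_role_mask
    p_t = matrix.P[:, sel_t].mean(axis=1)
    p_o = 1.0 - matrix.P[:, sel_o].mean(axis=1)
    return p_t * p_o, p_t, p_o


def rank_by_desirability(matrix: ProbabilityMatrix, mask) -> RankedScreen:
    """Rank the library by descending desirability under ``mask``.

    Ties in D are broken by compound id, so the ranking is a deterministic
    function of (matrix, mask). Active flags come from ``matrix.actives``.
    """
    d, _, _ = desirability_scores(matrix, mask)
    return RankedScreen.from_scores(matrix.compound_ids, d, matrix.actives)
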