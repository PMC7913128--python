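"""Bioactivity curation: consensus labels, dataset filters, target roles.

Raw ChEMBL-style bioactivity tables report one row per measured
compound–protein interaction (IC50 / Ki / EC50 / GI50, concentration in
μM), frequently with several replicate reports per pair that do not always
agree. The pipeline here:

1. labels every record active (< 10 μM) or inactive (strict threshold);
2. collapses replicates to one consensus label per (compound, target) pair,
   keeping a pair only when the majority label reaches 75 % agreement among
   its reports and discarding it otherwise;
3. drops proteins without at least 100 active and 100 inactive compounds
   (too few examples to train a per-protein classifier);
4. removes blocklisted compounds (approved drugs and the seed drugs that
   defined the target sets, so the screen cannot learn them);
5. assigns each protein a role: proteins found in both the target-seeded
   and off-target-seeded sets count as targets (the seed drugs are in
   clinical use, so shared proteins are evidently tolerable).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MEASURE_TYPES",
    "ACTIVE",
    "INACTIVE",
    "ActivityRecord",
    "LabeledInteraction",
    "TargetRole",
    "to_micromolar",
    "label_activity",
    "resolve_replicates",
    "filter_targets",
    "exclude_compounds",
    "assign_roles",
]

MEASURE_TYPES = frozenset({"IC50", "Ki", "EC50", "GI50"})
ACTIVE = "active"
INACTIVE = "inactive"

#: multiplicative factors to μM
_UNIT_TO_UM = {
    "um": 1.0, "µm": 1.0, "μm": 1.0, "microm": 1.0,
    "nm": 1e-3,
    "pm": 1e-6,
    "mm": 1e3,
    "m": 1e6,
}


@dataclass(frozen=True)
class ActivityRecord:
    """One measured compound–target interaction (value in μM)."""

    compound_id: str
    target_id: str
    measure_type: str
    value_um: float
    smiles: str | None = None


@dataclass(frozen=True)
class LabeledInteraction:
    """A (compound, target) pair with an active/inactive label."""

    compound_id: str
    target_id: str
    label: str


@dataclass(frozen=True)
class TargetRole:
    """Role of a protein in the screen; ``was_common`` marks proteins that
    appeared in both seed-derived sets (kept as targets)."""

    target_id: str
    role: str
    was_common: bool = False


def to_micromolar(value: float, unit: str) -> float:
    """Convert a concentration to μM (units: pM/nM/μM/mM/M, case-insensitive)."""
    key = unit.strip().lower()
    if key not in _UNIT_TO_UM:
        raise ValueError(f"unsupported concentration unit: {unit!r}")
    return value * _UNIT_TO_UM[key]


def label_activity(
    records: Iterable[ActivityRecord],
    threshold_um: float = 10.0,
) -> tuple[list[LabeledInteraction], list[tuple[ActivityRecord, str]]]:
    """Label each record active iff its value is strictly below ``threshold_um``.

    Returns ``(labeled, rejected)``: records with non-positive values or an
    unrecognised measurement type are rejected with a reason rather than
    silently dropped.
    """
    labeled: list[LabeledInteraction] = []
    rejected: list[tuple[ActivityRecord, str]] = []
    for rec in records:
        if rec.measure_type not in MEASURE_TYPES:
            rejected.append((rec, f"unsupported measure_type {rec.measure_type!r}"))
            continue
        if not rec.value_um > 0:
            rejected.append((rec, f"non-positive value {rec.value_um!r}"))
            continue
        label = ACTIVE if rec.value_um < threshold_um else INACTIVE
        labeled.append(LabeledInteraction(rec.compound_id, rec.target_id, label))
    return labeled, rejected


def resolve_replicates(
    labeled: Iterable[LabeledInteraction],
    agreement: float = 0.75,
) -> tuple[list[LabeledInteraction], list[tuple[str, str]]]:
    """Collapse replicate reports to one consensus label per pair.

    A pair is kept iff its modal label's share of the reports reaches
    ``agreement`` (default 75 %); otherwise the pair is discarded. Single
    reports pass through unchanged. Idempotent on its own output.
    """
    if not 0.5 < agreement <= 1.0:
        raise ValueError(f"agreement must be in (0.5, 1], got {agreement}")
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    order: list[tuple[str, str]] = []
    for li in labeled:
        key = (li.compound_id, li.target_id)
        if key not in counts:
            order.append(key)
        counts[key][li.label] += 1
    consensus: list[LabeledInteraction] = []
    discarded: list[tuple[str, str]] = []
    for key in order:
        c = counts[key]
        label, top = c.most_common(1)[0]
        if top / sum(c.values()) >= agreement:
            consensus.append(LabeledInteraction(key[0], key[1], label))
        else:
            discarded.append(key)
    return consensus, discarded


def filter_targets(
    consensus: Iterable[LabeledInteraction],
    min_active: int = 100,
    min_inactive: int = 100,
) -> tuple[set[str], set[str]]:
    """Keep targets with at least ``min_active`` actives AND ``min_inactive``
    inactives (inclusive bounds); returns ``(kept, dropped)``."""
    per_target: dict[str, Counter] = defaultdict(Counter)
    for li in consensus:
        per_target[li.target_id][li.label] += 1
    kept = {
        t
        for t, c in per_target.items()
        if c[ACTIVE] >= min_active and c[INACTIVE] >= min_inactive
    }
    return kept, set(per_target) - kept


def exclude_compounds(
    consensus: Iterable[LabeledInteraction],
    blocklist: set[str],
) -> list[LabeledInteraction]:
    """Drop every interaction whose compound is blocklisted (approved drugs
    and the seed drugs must not leak into training data)."""
    return [li for li in consensus if li.compound_id not in blocklist]


def assign_roles(
    target_set: Sequence[str] | set[str],
    off_target_set: Sequence[str] | set[str],
) -> list[TargetRole]:
    """Partition the union of the two seed-derived sets into roles.

    Proteins in both sets become targets with ``was_common=True`` (drugs in
    clinical use evidently tolerate them); proteins only in the off-target
    set keep the off-target role. Output is sorted by id for determinism.
    """
    targets, off = set(target_set), set(off_target_set)
    if not targets or not off:
        raise ValueError("both seed sets must be non-empty")
    common = targets & off
    if targets == off:
        warnings.warn(
            "target and off-target seed sets are identical; the off-target "
            "objective is degenerate (no off-target columns remain)",
            stacklevel=2,
        )
    roles = [
        TargetRole(t, "target", was_common=t in common) for t in sorted(targets)
    ]
    roles += [TargetRole(t, "off_target") for t in sorted(off - targets)]
    return roles
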