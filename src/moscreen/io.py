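"""File dialects: probability matrices, roles, actives, GA output, records.

All formats are plain text. The probability-matrix reader accepts both
strict TSV and the whitespace-delimited layout of published screening
supplements (one row per compound, first column the compound id, header
row of protein/target ids). Column roles travel in a two-column TSV
(`target_id<TAB>role`), actives as one id per line, GA populations as
`mask<TAB>fitness` with the mask a 0/1 string.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import ActivityRecord, LabeledInteraction, TargetRole
from .desirability import ProbabilityMatrix

__all__ = [
    "read_probability_matrix",
    "write_probability_matrix",
    "read_roles",
    "write_roles",
    "read_actives",
    "write_actives",
    "read_ga_population",
    "write_ga_population",
    "read_cluster_file",
    "read_activity_records",
    "write_activity_records",
    "write_labeled_interactions",
    "write_discard_log",
]


# -- probability matrices --------------------------------------------------

def read_probability_matrix(
    matrix_path,
    roles_path=None,
    actives_path=None,
    roles=None,
) -> ProbabilityMatrix:
    """Load a compounds x targets probability matrix.

    ``roles`` may be given directly (mapping or sequence) instead of
    ``roles_path``. Missing cells are rejected by the matrix constructor.
    """
    df = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    if any(str(c).startswith("Unnamed") for c in df.columns):
        # runs of spaces defeat the dialect sniffer; fall back to whitespace
        df = pd.read_csv(matrix_path, sep=r"\s+", index_col=0)
    if roles is None:
        if roles_path is None:
            raise ValueError("either roles_path or roles is required")
        roles = read_roles(roles_path)
    actives = read_actives(actives_path) if actives_path else ()
    return ProbabilityMatrix.from_dataframe(df, roles=roles, actives=actives)


def write_probability_matrix(matrix: ProbabilityMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="compound_id")


def read_roles(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"target_id", "role"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns target_id, role")
    return dict(zip(df["target_id"].astype(str), df["role"].astype(str)))


def write_roles(roles, path) -> None:
    """``roles``: mapping target_id -> role, or iterable of TargetRole."""
    if isinstance(roles, dict):
        rows = [{"target_id": t, "role": r} for t, r in roles.items()]
    else:
        rows = [
            {"target_id": r.target_id, "role": r.role, "was_common": r.was_common}
            for r in roles
        ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_actives(path) -> tuple[str, ...]:
    text = Path(path).read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


def write_actives(actives, path) -> None:
    Path(path).write_text("\n".join(sorted(map(str, actives))) + "\n")


# -- GA populations --------------------------------------------------------

def read_ga_population(path) -> tuple[np.ndarray, np.ndarray]:
    """Read `mask<TAB>fitness` rows; returns (masks (m, T) bool, fitnesses)."""
    df = pd.read_csv(path, sep="\t", dtype={"mask": str})
    if not {"mask", "fitness"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mask, fitness")
    masks = np.array(
        [[c == "1" for c in m] for m in df["mask"]], dtype=bool
    )
    return masks, df["fitness"].to_numpy(dtype=float)


def write_ga_population(population, path) -> None:
    """``population``: iterable of (mask, fitness)."""
    rows = [
        {"mask": "".join("1" if b else "0" for b in np.asarray(m, bool)),
         "fitness": float(f)}
        for m, f in population
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cluster_file(path) -> pd.DataFrame:
    """Model-to-cluster table: `model_id` plus one column per cut (e.g.
    ``cluster_k4``, ``cluster_k7``)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "model_id" not in df.columns:
        raise ValueError(f"{path}: expected a model_id column")
    return df


# -- activity records ------------------------------------------------------

_RECORD_COLS = ["compound_id", "smiles", "target_id", "measure_type", "value_um"]


def read_activity_records(path) -> list[ActivityRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"compound_id", "target_id", "measure_type", "value_um"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_smiles = "smiles" in df.columns
    return [
        ActivityRecord(
            compound_id=str(r.compound_id),
            target_id=str(r.target_id),
            measure_type=str(r.measure_type),
            value_um=float(r.value_um),
            smiles=(str(r.smiles) if has_smiles and pd.notna(r.smiles) else None),
        )
        for r in df.itertuples()
    ]


def write_activity_records(records, path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles or "",
                "target_id": r.target_id,
                "measure_type": r.measure_type,
                "value_um": r.value_um,
            }
            for r in records
        ],
        columns=_RECORD_COLS,
    ).to_csv(path, sep="\t", index=False)


def write_labeled_interactions(interactions, path) -> None:
    pd.DataFrame(
        [
            {"compound_id": li.compound_id, "target_id": li.target_id,
             "label": li.label}
            for li in interactions
        ],
        columns=["compound_id", "target_id", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_labeled_interactions(path) -> list[LabeledInteraction]:
    df = pd.read_csv(path, sep="\t")
    return [
        LabeledInteraction(str(r.compound_id), str(r.target_id), str(r.label))
        for r in df.itertuples()
    ]


def write_discard_log(entries, path) -> None:
    """``entries``: iterable of (compound_id, target_id, reason)."""
    pd.DataFrame(
        [{"compound_id": c, "target_id": t, "reason": why} for c, t, why in entries],
        columns=["compound_id", "target_id", "reason"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
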