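"""Cluster-consensus target relevance and drug-repurposing rankings.

The genetic algorithm leaves a population of screening models (bit masks
over the protein columns) with BEDROC fitnesses. Rather than trusting the
single best mask, the consensus stage:

1. keeps every model at or above a BEDROC threshold (duplicates retained —
   their multiplicity reflects GA convergence and weights the relevance);
2. groups the kept masks by agglomerative hierarchical clustering on the
   bit vectors (Euclidean distance, Ward linkage by default), since models
   selecting the same proteins should be analysed together;
3. scores, per cluster, each protein's relevance ``S_i`` = fraction of the
   cluster's models that include it;
4. scores a drug library per cluster by *global desirability* ``GD_i`` =
   the mean of the drug's desirability over all of the cluster's models;
5. compares clusters: top-``n`` list overlaps (Venn counts) and pairwise
   correlation of the GD vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, spearmanr

from .desirability import (
    InvalidMaskError,
    ProbabilityMatrix,
    desirability_scores,
)

__all__ = [
    "ModelPopulation",
    "ClusterAssignment",
    "select_models",
    "cluster_models",
    "relevance_profile",
    "target_relevance",
    "global_desirability",
    "top_overlap",
    "cluster_correlation",
    "category_counts",
]


@dataclass
class ModelPopulation:
    """Masks (rows of ``masks``) with fitnesses, after threshold selection."""

    masks: np.ndarray  # (m, T) bool
    fitnesses: np.ndarray  # (m,)
    threshold: float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.fitnesses = np.asarray(self.fitnesses, dtype=float)
        if self.masks.ndim != 2 or self.masks.shape[0] != self.fitnesses.size:
            raise ValueError("masks and fitnesses must align")

    def __len__(self) -> int:
        return self.masks.shape[0]


@dataclass
class ClusterAssignment:
    """1-based cluster label per model, plus linkage metadata."""

    labels: np.ndarray
    k: int
    method: str
    linkage_matrix: np.ndarray = field(repr=False)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels.tolist()))


def select_models(
    population,
    fitnesses=None,
    threshold: float = 0.15,
) -> ModelPopulation:
    """Keep every model with fitness >= ``threshold`` (inclusive).

    Accepts either a ``GAResult``-style ``[(mask, fitness), ...]`` list or a
    (masks, fitnesses) pair. Duplicate masks are kept deliberately.
    """
    if fitnesses is None:
        masks = np.asarray([m for m, _ in population], dtype=bool)
        fits = np.asarray([f for _, f in population], dtype=float)
    else:
        masks = np.asarray(population, dtype=bool)
        fits = np.asarray(fitnesses, dtype=float)
    keep = fits >= threshold
    if not keep.any():
        raise ValueError(
            f"no model reaches fitness {threshold}; best is {fits.max():.4f} — "
            "lower the threshold"
        )
    return ModelPopulation(masks[keep], fits[keep], threshold)


def cluster_models(
    models: ModelPopulation, k: int, method: str = "ward"
) -> ClusterAssignment:
    """Agglomerative clustering of model masks, cut into ``k`` clusters.

    Euclidean distance on the raw bit vectors; Ward linkage by default
    (``method="average"`` available when matching externally produced
    partitions). Deterministic.
    """
    m = len(models)
    if not 1 <= k <= m:
        raise ValueError(f"need 1 <= k <= {m} models, got k={k}")
    if m == 1:
        return ClusterAssignment(np.array([1]), 1, method, np.empty((0, 4)))
    Z = linkage(models.masks.astype(float), method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(labels, k, method, Z)


def relevance_profile(masks: np.ndarray) -> np.ndarray:
    """Per-target relevance of one model group: ``S_i`` = fraction of the
    group's masks with bit i set (column mean of the bit matrix)."""
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 2 or masks.shape[0] == 0:
        raise ValueError("need a non-empty (m, T) mask matrix")
    return masks.mean(axis=0)


def target_relevance(
    models: ModelPopulation,
    clusters: ClusterAssignment,
    target_ids=None,
) -> pd.DataFrame:
    """Relevance ``S_i`` per target per cluster (targets x clusters frame)."""
    data = {
        f"C{c}": relevance_profile(models.masks[clusters.members(c)])
        for c in clusters.cluster_ids
    }
    index = (
        list(target_ids)
        if target_ids is not None
        else [f"t{i}" for i in range(models.masks.shape[1])]
    )
    return pd.DataFrame(data, index=index)


def global_desirability(
    library: ProbabilityMatrix,
    models: ModelPopulation,
    clusters: ClusterAssignment,
) -> pd.DataFrame:
    """Consensus repurposing score: per cluster, each library compound's
    desirability averaged over the cluster's models.

    Invalid masks inside a cluster (possible when an external GA output is
    loaded) are skipped with a warning; a cluster with no valid mask raises.
    Returns a compounds x clusters frame of GD values in [0, 1].
    """
    if models.masks.shape[1] != library.shape[1]:
        raise ValueError("library columns do not match mask length")
    out: dict[str, np.ndarray] = {}
    n_skipped = 0
    for c in clusters.cluster_ids:
        member_idx = clusters.members(c)
        acc = np.zeros(library.shape[0])
        n_valid = 0
        for i in member_idx:
            try:
                d, _, _ = desirability_scores(library, models.masks[i])
            except InvalidMaskError:
                n_skipped += 1
                continue
            acc += d
            n_valid += 1
        if n_valid == 0:
            raise ValueError(f"cluster {c} contains no valid mask")
        out[f"C{c}"] = acc / n_valid
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} invalid mask(s) during global desirability",
            stacklevel=2,
        )
    return pd.DataFrame(out, index=list(library.compound_ids))


@dataclass
class TopOverlap:
    """Per-cluster top lists and their Venn structure."""

    top_lists: dict[str, list[str]]
    union: set[str]
    intersection: set[str]
    venn_counts: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return len(self.union)

    @property
    def intersection_size(self) -> int:
        return len(self.intersection)


def top_overlap(gd: pd.DataFrame, top_n: int = 50) -> TopOverlap:
    """Top-``n`` compounds per cluster by GD (ties by compound id) and the
    overlap structure across clusters.

    ``venn_counts`` maps each non-empty cluster combination (exact
    membership pattern) to the number of compounds found in precisely those
    clusters' top lists.
    """
    if top_n > gd.shape[0]:
        raise ValueError("top_n exceeds library size")
    tops: dict[str, list[str]] = {}
    for col in gd.columns:
        ranked = sorted(gd.index, key=lambda i: (-gd.at[i, col], str(i)))
        tops[col] = ranked[:top_n]
    union: set[str] = set().union(*map(set, tops.values()))
    inter = set(tops[gd.columns[0]])
    for col in gd.columns[1:]:
        inter &= set(tops[col])
    venn: dict[tuple[str, ...], int] = {}
    for r in range(1, len(gd.columns) + 1):
        for combo in combinations(gd.columns, r):
            members = set.intersection(*(set(tops[c]) for c in combo))
            for other in gd.columns:
                if other not in combo:
                    members -= set(tops[other])
            if members:
                venn[tuple(combo)] = len(members)
    return TopOverlap(tops, union, inter, venn)


def cluster_correlation(
    gd: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, float, float, float]:
    """Pairwise correlation of the clusters' GD vectors.

    Returns ``(matrix, mean, min, max)`` with the summary taken over the
    off-diagonal entries. ``method`` is ``"pearson"`` (default) or
    ``"spearman"`` (rankings are the object of interest downstream).
    """
    if gd.shape[1] < 2:
        raise ValueError("need at least two clusters")
    if (gd.std(axis=0) == 0).any():
        raise ValueError("a GD vector has zero variance; correlation undefined")
    corr_fn = {"pearson": pearsonr, "spearman": spearmanr}[method]
    cols = list(gd.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        r = float(corr_fn(gd[a].to_numpy(), gd[b].to_numpy())[0])
        mat.at[a, b] = mat.at[b, a] = r
    off = mat.to_numpy()[~np.eye(len(cols), dtype=bool)]
    return mat, float(off.mean()), float(off.min()), float(off.max())


def category_counts(
    drugs,
    category_table: dict[str, list[str]],
) -> dict[str, int]:
    """Frequency of each category code among ``drugs``.

    A drug with several codes counts once per code; drugs absent from the
    table are tallied under ``"unannotated"``. The table (e.g. ATC level-1/2
    annotations) is supplied by the caller.
    """
    counts: dict[str, int] = {}
    for drug in drugs:
        codes = category_table.get(drug)
        if not codes:
            counts["unannotated"] = counts.get("unannotated", 0) + 1
            continue
        for code in codes:
            counts[code] = counts.get(code, 0) + 1
    return counts
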