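"""Fingerprinting and class balancing for per-protein training sets.

Per-protein activity datasets are usually imbalanced (far more inactives
than actives, or vice versa). Training a classifier on such data biases it
toward the majority class, so before modelling the majority class is
reduced to the minority count — but *structurally*, not blindly: compounds
are embedded as 1024-bit Morgan circular fingerprints (radius 4), the
fingerprint matrix is compressed by PCA to the smallest number of
components explaining > 90 % of the variance, the majority class is
clustered by k-means in that space (k chosen over 3 … nPCA+1 by maximal
silhouette), and the retained majority compounds are drawn from each
cluster in proportion to its size. This preserves the chemical diversity
of the majority class instead of thinning it uniformly at random.

A stratified 25 % external split is then held out for validation of the
downstream per-protein classifiers (which are out of this package's scope:
the interface boundary is a probability matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .curation import ACTIVE, INACTIVE

__all__ = [
    "N_BITS",
    "RADIUS",
    "SmilesParseError",
    "FingerprintTable",
    "BalanceMeta",
    "BalancedDataset",
    "featurize",
    "largest_remainder",
    "balance_dataset",
    "split_external",
]

log = logging.getLogger(__name__)

N_BITS = 1024
RADIUS = 4

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=RADIUS, fpSize=N_BITS
)


class SmilesParseError(ValueError):
    """Raised when RDKit cannot parse a SMILES string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


def featurize(smiles: str) -> np.ndarray:
    """1024-bit Morgan circular fingerprint (radius 4) of one molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    fp = _fp_generator.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


@dataclass
class FingerprintTable:
    """Compound ids, 1024-bit fingerprints, active/inactive labels."""

    ids: tuple[str, ...]
    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2 or self.X.shape[1] != N_BITS:
            raise ValueError(f"X must be (n, {N_BITS}), got {self.X.shape}")
        if len(self.ids) != self.X.shape[0] or self.labels.size != self.X.shape[0]:
            raise ValueError("ids, X and labels must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("compound ids must be unique")
        bad = set(self.labels) - {ACTIVE, INACTIVE}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_smiles(cls, ids, smiles, labels) -> "FingerprintTable":
        X = np.vstack([featurize(s) for s in smiles])
        return cls(tuple(ids), X, np.asarray(labels, dtype=object))

    def subset(self, idx: np.ndarray) -> "FingerprintTable":
        idx = np.asarray(idx)
        return FingerprintTable(
            tuple(self.ids[i] for i in idx), self.X[idx], self.labels[idx]
        )

    def class_counts(self) -> dict[str, int]:
        return {
            ACTIVE: int((self.labels == ACTIVE).sum()),
            INACTIVE: int((self.labels == INACTIVE).sum()),
        }


@dataclass(frozen=True)
class BalanceMeta:
    """Provenance of one balancing run."""

    n_components_kept: int
    k_chosen: int
    silhouette: float
    seed: int
    fallback_random: bool = False
    no_op: bool = False


@dataclass
class BalancedDataset:
    """Balanced training table, removed majority ids, and run metadata;
    ``external`` is filled by :func:`split_external`."""

    training: FingerprintTable
    removed: list[str]
    meta: BalanceMeta
    external: FingerprintTable | None = None


def largest_remainder(sizes, total: int) -> np.ndarray:
    """Apportion ``total`` into integer quotas proportional to ``sizes``.

    Hamilton / largest-remainder rounding: floor the ideal quotas, then give
    the leftover units to the largest fractional remainders (ties to the
    earlier group, deterministically). Quotas always sum to ``total`` and
    never exceed the group size when ``total <= sum(sizes)``.
    """
    sizes = np.asarray(sizes, dtype=float)
    if total > sizes.sum():
        raise ValueError("total exceeds the population being apportioned")
    ideal = sizes * (total / sizes.sum())
    quotas = np.floor(ideal).astype(int)
    remainder = total - quotas.sum()
    if remainder > 0:
        frac = ideal - quotas
        # stable argsort → ties broken toward the earlier cluster
        for i in np.argsort(-frac, kind="stable")[:remainder]:
            quotas[i] += 1
    return quotas


def balance_dataset(
    table: FingerprintTable,
    variance_goal: float = 0.90,
    seed: int = 0,
) -> BalancedDataset:
    """Reduce the majority class to the minority count, diversity-aware.

    PCA is fitted on the pooled fingerprint matrix (both classes), keeping
    the smallest number of components with cumulative explained variance
    above ``variance_goal``; k-means then clusters the majority-class rows
    in that space for every k in {3, ..., nPCA+1}, the k with maximal
    silhouette wins (ties to smaller k), and each cluster contributes a
    random sample proportional to its size. The minority class is never
    touched. When the cluster range is empty/unusable the reduction falls
    back to simple random undersampling (flagged in ``meta``).
    """
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("both classes must be non-empty")
    if counts[ACTIVE] == counts[INACTIVE]:
        return BalancedDataset(
            training=table,
            removed=[],
            meta=BalanceMeta(0, 0, float("nan"), seed, no_op=True),
        )
    majority = ACTIVE if counts[ACTIVE] > counts[INACTIVE] else INACTIVE
    minority_count = min(counts.values())
    maj_idx = np.flatnonzero(table.labels == majority)
    min_idx = np.flatnonzero(table.labels != majority)
    rng = np.random.default_rng(seed)

    X = table.X.astype(float)
    pca = PCA(random_state=seed)
    scores = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_pca = int(np.searchsorted(cumvar, variance_goal, side="right") + 1)
    n_pca = min(n_pca, cumvar.size)
    Z = scores[maj_idx, :n_pca]

    # silhouette needs 2 <= k <= n_samples - 1
    k_max = min(n_pca + 1, maj_idx.size - 1)
    ks = [k for k in range(3, k_max + 1)]
    if not ks:
        log.warning(
            "cluster range 3..nPCA+1 unusable (nPCA=%d, majority=%d); "
            "falling back to simple random undersampling",
            n_pca, maj_idx.size,
        )
        keep_maj = rng.choice(maj_idx, size=minority_count, replace=False)
        removed = sorted(set(maj_idx) - set(keep_maj))
        kept = np.sort(np.concatenate([min_idx, keep_maj]))
        return BalancedDataset(
            training=table.subset(kept),
            removed=[table.ids[i] for i in removed],
            meta=BalanceMeta(n_pca, 0, float("nan"), seed, fallback_random=True),
        )

    best: tuple[float, int, np.ndarray] | None = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assign = km.fit_predict(Z)
        sil = float(silhouette_score(Z, assign))
        if best is None or sil > best[0]:  # strict → tie keeps smaller k
            best = (sil, k, assign)
    sil, k, assign = best

    sizes = np.bincount(assign, minlength=k)
    quotas = largest_remainder(sizes, minority_count)
    keep_parts = [
        rng.choice(maj_idx[assign == c], size=quotas[c], replace=False)
        for c in range(k)
        if quotas[c] > 0
    ]
    keep_maj = np.concatenate(keep_parts)
    removed = sorted(set(maj_idx.tolist()) - set(keep_maj.tolist()))
    kept = np.sort(np.concatenate([min_idx, keep_maj]))
    return BalancedDataset(
        training=table.subset(kept),
        removed=[table.ids[i] for i in removed],
        meta=BalanceMeta(n_pca, k, sil, seed),
    )


def split_external(
    table: FingerprintTable,
    fraction: float = 0.25,
    seed: int = 0,
) -> tuple[FingerprintTable, FingerprintTable]:
    """Stratified random hold-out of ``round(fraction * N)`` compounds.

    Per-class hold-out counts are apportioned by largest remainder so the
    overall size is exact and the class ratio is preserved to within one
    compound. Returns ``(training, external)``; reproducible under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    N = len(table)
    n_external = round(fraction * N)
    classes = [ACTIVE, INACTIVE]
    class_idx = [np.flatnonzero(table.labels == c) for c in classes]
    sizes = [idx.size for idx in class_idx]
    quotas = largest_remainder(sizes, n_external)
    rng = np.random.default_rng(seed)
    ext_parts = [
        rng.choice(idx, size=q, replace=False)
        for idx, q in zip(class_idx, quotas)
        if q > 0
    ]
    ext = np.sort(np.concatenate(ext_parts)) if ext_parts else np.array([], int)
    train = np.setdiff1d(np.arange(N), ext)
    return table.subset(train), table.subset(ext)
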