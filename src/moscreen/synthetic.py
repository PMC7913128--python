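"""Synthetic benchmark generator with planted ground truth.

Every stage of the screening pipeline is testable without external
databases because this module manufactures both of its input shapes:

* a probability matrix emulating the output of per-protein classifiers —
  ``M`` compounds x ``T`` protein columns split into targets and
  off-targets, with *planted informative subsets* of each role and a small
  set of planted desirable compounds ("actives"). Active compounds draw
  high activity probabilities on the informative targets and low ones on
  the informative off-targets; everything else is background. Cells are
  Beta-distributed around their level (a hard 0/1 matrix would make the
  desirability ranking tie-ridden and BEDROC pathological, and real
  classifier outputs are noisy), with a concentration parameter
  controlling the spread. Two further features of real screening libraries
  are emulated, because without them the benchmark is degenerate (every
  mask containing the planted columns ranks perfectly and the planted
  structure is unrecoverable): (i) background cells are much noisier than
  signal cells — an uninformative classifier scores a random compound
  almost anywhere in [0, 1] — so the library contains partially desirable
  decoys whose aggregated scores overlap the weakest actives, and
  averaging over *more* informative columns genuinely suppresses the decoy
  tail; (ii) actives are sparsely polypharmacological — each active
  carries the signal on an independent random subset (density
  ``signal_density``) of the informative columns, so every informative
  column contributes signal for a different sub-group of actives and
  omitting any one of them loses part of the signal.
* replicated activity records emulating raw bioactivity tables: per
  (compound, target) truth label, ``replicate_count`` measurements on the
  correct side of the 10 μM activity threshold, each flipping to the wrong
  side independently with probability ``disagreement_rate``.

The generating parameters and planted structure come back as a
:class:`GroundTruth`, so recovery experiments (does the GA find the planted
informative mask?) have an exact reference. The default scale — 2000
compounds, 20 columns (14 targets / 6 off-targets with 12 + 4 informative),
20 actives, signal level 0.9 — keeps a full GA recovery experiment within
minutes on one CPU while preserving the actives-are-rare regime
(n/N = 1 %) that early-recognition metrics are built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .curation import ActivityRecord
from .desirability import ROLE_OFF_TARGET, ROLE_TARGET, ProbabilityMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "gen_probability_matrix",
           "gen_activity_records"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    ``p_signal`` is the mean activity probability of an active compound on
    an informative target it carries signal for (and its mean *inactivity*
    probability on an informative off-target); ``p_noise`` the mean
    background level everywhere else (0.5 = an uninformative coin-flip
    classifier). ``concentration`` is the Beta pseudo-count of signal
    cells (higher = tighter around the mean) and ``background_concentration``
    that of background cells — the default 0.5 makes background cells
    U-shaped on [0, 1], mimicking the polarised scores that hard
    classifiers emit for out-of-domain compounds; ``None`` for either
    gives degenerate (exact) levels. ``signal_density`` is the probability
    that an active carries signal on any given informative column.
    """

    m_compounds: int = 2000
    n_targets: int = 14
    n_off_targets: int = 6
    n_informative_targets: int = 12
    n_informative_off_targets: int = 4
    n_actives: int = 20
    p_signal: float = 0.9
    p_noise: float = 0.5
    concentration: float | None = 30.0
    background_concentration: float | None = 0.5
    signal_density: float = 0.95
    replicate_count: int = 3
    disagreement_rate: float = 0.1
    threshold_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_targets > self.n_targets:
            raise ValueError("informative targets exceed target count")
        if self.n_informative_off_targets > self.n_off_targets:
            raise ValueError("informative off-targets exceed off-target count")
        if self.n_informative_targets < 1 or self.n_informative_off_targets < 1:
            raise ValueError("need at least one informative column per role")
        if not 0.0 <= self.p_noise < self.p_signal <= 1.0:
            raise ValueError("need 0 <= p_noise < p_signal <= 1")
        if self.n_actives >= self.m_compounds:
            raise ValueError("n_actives must be below m_compounds")
        if self.n_actives < 1:
            raise ValueError("need at least one active")
        if not 0.0 <= self.disagreement_rate <= 1.0:
            raise ValueError("disagreement_rate must be in [0, 1]")
        if not 0.0 < self.signal_density <= 1.0:
            raise ValueError("signal_density must be in (0, 1]")

    @property
    def T(self) -> int:
        return self.n_targets + self.n_off_targets


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure accompanying every generated artifact."""

    informative_mask: tuple[int, ...]
    active_ids: tuple[str, ...]
    spec: SyntheticSpec
    truth_labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "informative_mask": list(self.informative_mask),
            "active_ids": list(self.active_ids),
            "spec": asdict(self.spec),
        }
        if self.truth_labels:
            d["truth_labels"] = {
                f"{c}\t{t}": lab for (c, t), lab in self.truth_labels.items()
            }
        return d


def _beta_around(
    rng: np.random.Generator, mean: np.ndarray, concentration: float | None
) -> np.ndarray:
    """Beta draws with the given mean and pseudo-count total; exact means
    when ``concentration`` is None; means of 0/1 are kept exact."""
    mean = np.asarray(mean, dtype=float)
    if concentration is None:
        return mean.copy()
    out = np.empty_like(mean)
    interior = (mean > 0.0) & (mean < 1.0)
    out[~interior] = mean[~interior]
    a = mean[interior] * concentration
    b = (1.0 - mean[interior]) * concentration
    out[interior] = rng.beta(a, b)
    return out


def gen_probability_matrix(
    spec: SyntheticSpec,
) -> tuple[ProbabilityMatrix, GroundTruth]:
    """Generate a probability matrix with planted desirable compounds.

    Deterministic under ``spec.seed``. The planted informative columns are
    a seeded random subset of each role; actives are the first
    ``n_actives`` compound ids (their identity carries no information — the
    matrix rows are exchangeable). Every cell starts as background centred
    at ``p_noise``; actives overwrite the informative cells they carry
    signal for (probability ``signal_density`` per cell) with ``p_signal``
    on targets and ``1 - p_signal`` on off-targets; each cell then draws a
    Beta around its mean, tight (``concentration``) for signal cells and
    broad (``background_concentration``) for background cells.
    """
    rng = np.random.default_rng(spec.seed)
    M, T = spec.m_compounds, spec.T
    compound_ids = [f"cpd{i:05d}" for i in range(M)]
    target_ids = [f"TGT{i:02d}" for i in range(spec.n_targets)] + [
        f"OFF{i:02d}" for i in range(spec.n_off_targets)
    ]
    roles = np.array(
        [ROLE_TARGET] * spec.n_targets + [ROLE_OFF_TARGET] * spec.n_off_targets,
        dtype=object,
    )
    inf_t = rng.choice(spec.n_targets, spec.n_informative_targets, replace=False)
    inf_o = spec.n_targets + rng.choice(
        spec.n_off_targets, spec.n_informative_off_targets, replace=False
    )
    informative = np.zeros(T, dtype=bool)
    informative[inf_t] = True
    informative[inf_o] = True

    actives = compound_ids[: spec.n_actives]
    active_rows = np.arange(spec.n_actives)
    mean = np.full((M, T), float(spec.p_noise))
    is_signal = np.zeros((M, T), dtype=bool)
    # sparse polypharmacology: each active carries signal on its own subset
    carries_t = rng.random((spec.n_actives, inf_t.size)) < spec.signal_density
    carries_o = rng.random((spec.n_actives, inf_o.size)) < spec.signal_density
    block = mean[np.ix_(active_rows, inf_t)]
    block[carries_t] = spec.p_signal
    mean[np.ix_(active_rows, inf_t)] = block
    # low activity probability on informative off-targets → high 1-P there
    block = mean[np.ix_(active_rows, inf_o)]
    block[carries_o] = 1.0 - spec.p_signal
    mean[np.ix_(active_rows, inf_o)] = block
    is_signal[np.ix_(active_rows, inf_t)] = carries_t
    is_signal[np.ix_(active_rows, inf_o)] = carries_o

    P = _beta_around(rng, mean, spec.background_concentration)
    P[is_signal] = _beta_around(rng, mean[is_signal], spec.concentration)
    P = np.clip(P, 0.0, 1.0)

    matrix = ProbabilityMatrix(
        P=P,
        compound_ids=tuple(compound_ids),
        target_ids=tuple(target_ids),
        roles=roles,
        actives=frozenset(actives),
    )
    truth = GroundTruth(
        informative_mask=tuple(int(b) for b in informative),
        active_ids=tuple(actives),
        spec=spec,
    )
    return matrix, truth


def gen_activity_records(
    spec: SyntheticSpec,
) -> tuple[list[ActivityRecord], GroundTruth]:
    """Generate replicated raw activity records with known truth labels.

    Each of ``m_compounds x n_targets`` pairs gets a Bernoulli(0.5) truth
    label and ``replicate_count`` measurements: log-uniform below the
    threshold for true actives (0.01–10 μM) and above it for inactives
    (10–10000 μM), each replicate landing on the wrong side independently
    with probability ``disagreement_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ActivityRecord] = []
    truth_labels: dict[tuple[str, str], str] = {}
    lo, hi = spec.threshold_um * 1e-3, spec.threshold_um * 1e3
    for i in range(spec.m_compounds):
        cid = f"cpd{i:05d}"
        for j in range(spec.n_targets):
            tid = f"TGT{j:02d}"
            truly_active = bool(rng.random() < 0.5)
            truth_labels[(cid, tid)] = "active" if truly_active else "inactive"
            for _ in range(spec.replicate_count):
                active_side = truly_active ^ (rng.random() < spec.disagreement_rate)
                if active_side:
                    value = float(
                        np.exp(rng.uniform(np.log(lo), np.log(spec.threshold_um)))
                    )
                    value = min(value, np.nextafter(spec.threshold_um, 0.0))
                else:
                    value = float(
                        np.exp(rng.uniform(np.log(spec.threshold_um), np.log(hi)))
                    )
                    value = max(value, spec.threshold_um)
                records.append(
                    ActivityRecord(cid, tid, "IC50", value)
                )
    truth = GroundTruth(
        informative_mask=(),
        active_ids=(),
        spec=spec,
        truth_labels=truth_labels,
    )
    return records, truth
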