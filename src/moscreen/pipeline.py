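"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages in screening order — curation →
balancing → (external per-protein classifier step, out of scope; the
boundary is a probability matrix) → GA model selection → threshold
selection → model clustering → target relevance → global desirability →
top-list overlaps and cluster correlations — writing every intermediate as
a documented text file so any stage can be re-entered. Stages never mutate
their inputs. A single master seed deterministically derives per-stage
seeds, making a rerun with the same config byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import balancing, consensus, curation, io
from .ga import DesirabilityScreenGA, GAConfig

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)

_STAGES = ("curate", "balance", "ga", "consensus")


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-serializable).

    File inputs: ``records`` (raw activity table) for curation/balancing;
    ``matrix``/``roles``/``actives`` (screening probability matrix) for the
    GA; ``library_matrix`` (drug-library probabilities) for consensus
    repurposing — it defaults to the screening matrix. ``stages`` selects a
    contiguous subset of curate → balance → ga → consensus.
    """

    out_dir: str = "moscreen_run"
    stages: list[str] = field(default_factory=lambda: ["ga", "consensus"])
    seed: int = 0

    records: str | None = None
    matrix: str | None = None
    roles: str | None = None
    actives: str | None = None
    library_matrix: str | None = None

    activity_threshold_um: float = 10.0
    agreement: float = 0.75
    min_active: int = 100
    min_inactive: int = 100
    blocklist: list[str] = field(default_factory=list)
    variance_goal: float = 0.90
    external_fraction: float = 0.25

    population_size: int = 4000
    generations: int = 3000
    mutation_prob: float = 0.4
    crossover_prob: float = 0.6
    tournament_size: int = 3
    alpha: float = 160.9
    restarts: int = 1

    selection_threshold: float = 0.15
    n_clusters: int = 4
    linkage: str = "ward"
    top_n: int = 50
    correlation: str = "pearson"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def stage_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable, < 2^31)."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (master * 1_000_003 + h) % (2**31 - 1)


def plan(config: RunConfig) -> list[str]:
    """The ordered list of stages a run would execute."""
    return [s for s in _STAGES if s in config.stages]


def run_pipeline(config: RunConfig, dry_run: bool = False) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Every run writes its resolved configuration (``config.resolved.yaml``)
    next to the outputs. ``dry_run`` validates inputs and prints the stage
    plan without computing.
    """
    logging.basicConfig(level=config.log_level)
    stages = plan(config)
    if dry_run:
        for s in stages:
            log.info("planned stage: %s", s)
        _validate_inputs(config, stages)
        return Path(config.out_dir)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    _validate_inputs(config, stages)

    if "curate" in stages:
        _run_curate(config, out)
    if "balance" in stages:
        _run_balance(config, out)
    if "ga" in stages:
        result = _run_ga(config, out)
    else:
        result = None
    if "consensus" in stages:
        _run_consensus(config, out, result)
    return out


def _validate_inputs(config: RunConfig, stages: list[str]) -> None:
    needed: list[str] = []
    if "curate" in stages or "balance" in stages:
        needed.append("records")
    if "ga" in stages or "consensus" in stages:
        needed += ["matrix", "roles", "actives"]
    for name in needed:
        path = getattr(config, name)
        if path is None:
            raise FileNotFoundError(f"config.{name} is required for {stages}")
        if not Path(path).exists():
            raise FileNotFoundError(f"config.{name}: no such file {path}")


def _run_curate(config: RunConfig, out: Path) -> None:
    records = io.read_activity_records(config.records)
    labeled, rejected = curation.label_activity(
        records, threshold_um=config.activity_threshold_um
    )
    consensus_labels, discarded = curation.resolve_replicates(
        labeled, agreement=config.agreement
    )
    consensus_labels = curation.exclude_compounds(
        consensus_labels, set(config.blocklist)
    )
    kept, dropped = curation.filter_targets(
        consensus_labels, config.min_active, config.min_inactive
    )
    final = [li for li in consensus_labels if li.target_id in kept]
    log.info(
        "curation funnel: %d records -> %d consensus pairs -> "
        "%d targets kept (%d dropped), %d pairs in final set",
        len(records), len(consensus_labels), len(kept), len(dropped), len(final),
    )
    io.write_labeled_interactions(final, out / "consensus.tsv")
    entries = [(c, t, "replicate disagreement") for c, t in discarded]
    entries += [(r.compound_id, r.target_id, why) for r, why in rejected]
    io.write_discard_log(entries, out / "discards.tsv")


def _run_balance(config: RunConfig, out: Path) -> None:
    records = io.read_activity_records(config.records)
    labeled, _ = curation.label_activity(
        records, threshold_um=config.activity_threshold_um
    )
    consensus_labels, _ = curation.resolve_replicates(
        labeled, agreement=config.agreement
    )
    smiles: dict[str, str] = {r.compound_id: r.smiles for r in records if r.smiles}
    seed = stage_seed(config.seed, "balance")
    per_target: dict[str, list] = {}
    for li in consensus_labels:
        per_target.setdefault(li.target_id, []).append(li)
    for target, items in sorted(per_target.items()):
        ids = [li.compound_id for li in items]
        missing = [c for c in ids if c not in smiles]
        if missing:
            log.warning(
                "balance: target %s skipped (%d compounds lack SMILES)",
                target, len(missing),
            )
            continue
        table = balancing.FingerprintTable.from_smiles(
            ids, [smiles[c] for c in ids], [li.label for li in items]
        )
        balanced = balancing.balance_dataset(
            table, variance_goal=config.variance_goal, seed=seed
        )
        training, external = balancing.split_external(
            balanced.training, fraction=config.external_fraction, seed=seed
        )
        tdir = out / f"balanced_{target}"
        tdir.mkdir(exist_ok=True)
        _write_fingerprint_table(training, tdir / "training.tsv")
        _write_fingerprint_table(external, tdir / "external.tsv")
        io.write_json(
            {
                "removed": balanced.removed,
                "meta": dataclasses.asdict(balanced.meta),
            },
            tdir / "meta.json",
        )
        log.info(
            "balance funnel %s: %d -> %d training / %d external (%d removed)",
            target, len(table), len(training), len(external),
            len(balanced.removed),
        )


def _write_fingerprint_table(table: balancing.FingerprintTable, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": list(table.ids),
            "label": list(table.labels),
            "bits": ["".join(map(str, row)) for row in table.X],
        }
    ).to_csv(path, sep="\t", index=False)


def _run_ga(config: RunConfig, out: Path):
    matrix = io.read_probability_matrix(
        config.matrix, roles_path=config.roles, actives_path=config.actives
    )
    ga_cfg = GAConfig(
        population_size=config.population_size,
        generations=config.generations,
        mutation_prob=config.mutation_prob,
        crossover_prob=config.crossover_prob,
        tournament_size=config.tournament_size,
        alpha=config.alpha,
        seed=stage_seed(config.seed, "ga"),
        restarts=config.restarts,
    )
    result = DesirabilityScreenGA(matrix, ga_cfg).fit()
    io.write_ga_population(result.population, out / "ga_population.tsv")
    (out / "ga_summary.txt").write_text(result.summary() + "\n")
    log.info("GA: best BEDROC %.4f", result.best_fitness)
    return result


def _run_consensus(config: RunConfig, out: Path, ga_result) -> None:
    import pandas as pd

    if ga_result is not None:
        pop = ga_result.population
        masks = [m for m, _ in pop]
        fits = [f for _, f in pop]
    else:
        masks, fits = io.read_ga_population(out / "ga_population.tsv")
    library = io.read_probability_matrix(
        config.library_matrix or config.matrix,
        roles_path=config.roles,
        actives_path=config.actives,
    )
    models = consensus.select_models(masks, fits, config.selection_threshold)
    log.info(
        "selection funnel: %d -> %d models at BEDROC >= %g",
        len(list(masks)), len(models), config.selection_threshold,
    )
    clusters = consensus.cluster_models(
        models, k=min(config.n_clusters, len(models)), method=config.linkage
    )
    relevance = consensus.target_relevance(
        models, clusters, target_ids=library.target_ids
    )
    relevance.insert(0, "role", list(library.roles))
    relevance.to_csv(out / "target_relevance.tsv", sep="\t",
                     index_label="target_id")
    gd = consensus.global_desirability(library, models, clusters)
    gd.to_csv(out / "global_desirability.tsv", sep="\t",
              index_label="compound_id")
    top_n = min(config.top_n, gd.shape[0])
    overlap = consensus.top_overlap(gd, top_n=top_n)
    for col, ids in overlap.top_lists.items():
        pd.DataFrame(
            {"compound_id": ids, "gd": [gd.at[i, col] for i in ids]}
        ).to_csv(out / f"top{top_n}_{col}.tsv", sep="\t", index=False)
    io.write_json(
        {
            "top_n": top_n,
            "union_size": overlap.union_size,
            "intersection_size": overlap.intersection_size,
            "venn": {"+".join(k): v for k, v in overlap.venn_counts.items()},
        },
        out / "venn.json",
    )
    if gd.shape[1] >= 2:
        corr, mean, lo, hi = consensus.cluster_correlation(
            gd, method=config.correlation
        )
        corr.to_csv(out / "cluster_correlation.tsv", sep="\t",
                    index_label="cluster")
        io.write_json(
            {"mean": mean, "min": lo, "max": hi, "method": config.correlation},
            out / "cluster_correlation_summary.json",
        )
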