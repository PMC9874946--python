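"""End-to-end orchestration: observations in, characterized communities out.

``run_pipeline`` reproduces the full workflow on any cohort table — subsume,
filter, normalize, build both phenotype graphs, partition each at its own
resolution (1.0 unipartite, 1.15 bipartite by default, the settings of the
original analysis), drop singleton communities, characterize, and cross-tab
concordance — writing every intermediate artifact plus a machine-readable run
manifest so any run is reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characterize import (
    anova_by_feature,
    community_profiles,
    concordance_table,
    feature_map_order,
    profiles_frame,
)
from .community import Partition, drop_singleton_communities, louvain
from .features import distance_matrix, normalize_minmax
from .graphs import build_bipartite, build_unipartite, write_graph
from .ontology import (
    default_superclass_map,
    filter_empty_subjects,
    load_observations,
    load_superclass_map,
    subsume,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run settings; the defaults are the original analysis settings."""

    observations: str | None = None
    superclass_map: str | None = None      # None -> packaged default
    out_dir: str = "phenet_run"
    threshold: float = 0.4
    resolution_unipartite: float = 1.0
    resolution_bipartite: float = 1.15
    seed: int = 0
    unmapped_policy: str = "error"
    second_feature_ratio: float = 0.8
    distance_metric: str = "cosine"
    run_bipartite: bool = True
    run_unipartite: bool = True
    run_anova: bool = True
    run_concordance: bool = True
    holm: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _save_partition(partition: Partition, stem: Path) -> None:
    pd.DataFrame(
        {"node_id": list(partition.assignment), "community_id": list(partition.assignment.values())}
    ).to_csv(stem.with_suffix(".csv"), index=False)
    record = {
        "gamma": partition.gamma,
        "seed": partition.seed,
        "Q": partition.q,
        "community_sizes": {str(k): v for k, v in partition.sizes().items()},
        "phases": len(partition.phase_q),
        "phase_Q": partition.phase_q,
    }
    stem.with_suffix(".json").write_text(json.dumps(record, indent=2))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured workflow; returns the run directory.

    Fails fast (before writing anything) on unreadable inputs; stage failures
    abort with the stage name.
    """
    if config.observations is None:
        raise ValueError("config.observations is required")
    obs_path = Path(config.observations)
    if not obs_path.exists():
        raise FileNotFoundError(f"observations file not found: {obs_path}")
    if config.superclass_map is not None and not Path(config.superclass_map).exists():
        raise FileNotFoundError(f"superclass map not found: {config.superclass_map}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "phenet_version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("subsume")
        obs = load_observations(obs_path)
        mapping = (
            load_superclass_map(config.superclass_map)
            if config.superclass_map
            else default_superclass_map()
        )
        counts = subsume(obs, mapping, unmapped_policy=config.unmapped_policy)
        counts, excluded = filter_empty_subjects(counts)
        counts.to_csv(out / "counts.csv")
        (out / "excluded_subjects.json").write_text(json.dumps(excluded))

        stage("normalize")
        feats = normalize_minmax(counts)
        feats.to_csv(out / "features.csv")
        row_order, col_order = feature_map_order(feats)
        (out / "feature_map_order.json").write_text(
            json.dumps({"rows": [str(r) for r in row_order],
                        "columns": [str(c) for c in col_order]})
        )

        partitions: dict[str, Partition] = {}

        if config.run_unipartite:
            stage("unipartite")
            D = distance_matrix(feats, config.distance_metric)
            D.to_csv(out / "distances.csv")
            G1 = build_unipartite(D, threshold=config.threshold)
            write_graph(G1, out / "unipartite.graphml")
            part = louvain(G1, gamma=config.resolution_unipartite, seed=config.seed)
            kept, dropped = drop_singleton_communities(part, G1)
            _save_partition(kept, out / "partition_unipartite")
            (out / "dropped_singletons_unipartite.json").write_text(json.dumps([str(d) for d in dropped]))
            partitions["unipartite"] = kept
            manifest["unipartite"] = {"Q": part.q, "gamma": part.gamma,
                                      "n_communities": kept.n_communities,
                                      "community_sizes": {str(k): v for k, v in kept.sizes().items()},
                                      "dropped_singletons": [str(d) for d in dropped]}

        if config.run_bipartite:
            stage("bipartite")
            G2 = build_bipartite(feats)
            write_graph(G2, out / "bipartite.graphml")
            part = louvain(G2, gamma=config.resolution_bipartite, seed=config.seed)
            kept, dropped = drop_singleton_communities(part, G2)
            _save_partition(kept, out / "partition_bipartite")
            partitions["bipartite"] = kept
            manifest["bipartite"] = {"Q": part.q, "gamma": part.gamma,
                                     "n_communities": kept.n_communities,
                                     "community_sizes": {str(k): v for k, v in kept.sizes().items()},
                                     "dropped_singletons": [str(d) for d in dropped]}

        stage("characterize")
        for mode, part in partitions.items():
            profiles = community_profiles(feats, part, config.second_feature_ratio)
            profiles_frame(profiles).to_csv(out / f"profiles_{mode}.csv")
            manifest.setdefault("community_names", {})[mode] = {
                str(p.community_id): p.name for p in profiles
            }
            if config.run_anova:
                anova_by_feature(feats, part, holm=config.holm).to_csv(out / f"anova_{mode}.csv")

        if config.run_concordance and len(partitions) == 2:
            stage("concordance")
            table = concordance_table(partitions["unipartite"], partitions["bipartite"])
            table.j.to_csv(out / "concordance.csv")
            manifest["concordance_best_match"] = [
                {"unipartite": r, "bipartite": c, "J": j} for r, c, j in table.best_match
            ]
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        (out / "manifest.json").write_text(json.dumps({**manifest, "failed_stage": failed}, indent=2))
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
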