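"""End-to-end orchestration: simulate -> filter/rarefy -> diversity ->
maturation -> networks -> report, with a JSON manifest of every output."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rumenage import diversity, maturation, network, synthdata, tables

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters with the study's default thresholds."""

    output_dir: str = "rumenage_out"
    input_tables: dict[str, str] = field(default_factory=dict)  # kingdom -> TSV path
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    simulate: bool = True
    seed: int = 0
    rarefaction_depths: dict[str, int] = field(
        default_factory=lambda: dict(tables.DEFAULT_RAREFACTION_DEPTHS))
    detected_min_relabund: float = 0.001
    network_min_relabund: float = 0.0001
    maturation_kingdoms: tuple[str, ...] = ("bacteria",)
    n_trees: int = 500
    n_repeats: int = 100
    cv_n_trees: int = 100
    sparse_n_trees: int = 500
    n_folds: int = 10
    step: float = 0.5
    tolerance: float = 0.05
    rel_plateau_threshold: float = 0.1
    core_rho_min: float = 0.3
    core_q_max: float = 0.05
    age_specific_rho_min: float = 0.5
    keystone_k_intra: int = 3
    keystone_k_inter: int = 5

    def validate(self) -> None:
        for name, v, lo, hi in (
            ("detected_min_relabund", self.detected_min_relabund, 0, 1),
            ("network_min_relabund", self.network_min_relabund, 0, 1),
            ("tolerance", self.tolerance, 0, 1),
            ("rel_plateau_threshold", self.rel_plateau_threshold, 0, 1),
            ("core_q_max", self.core_q_max, 0, 1),
            ("core_rho_min", self.core_rho_min, 0, 1),
            ("age_specific_rho_min", self.age_specific_rho_min, 0, 1),
        ):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not self.simulate and not self.input_tables:
            raise ValueError("either simulate=True or input tables are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.maturation_kingdoms, list):
            cfg.maturation_kingdoms = tuple(cfg.maturation_kingdoms)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, path: Path, **params) -> None:
        manifest["outputs"].append(
            {"stage": stage, "path": str(path), **params})

    rng = np.random.default_rng(config.seed)

    # --- simulate or load ---------------------------------------------------
    if config.simulate:
        sim = synthdata.simulate_community(synthdata.default_community_spec(config.seed))
        kingdom_tables, metadata, taxonomy = sim.tables, sim.metadata, sim.taxonomy
        for kd, tab in kingdom_tables.items():
            p = out / f"counts_{kd}.tsv"
            tab.write_tsv(p)
            record("simulate", p, kingdom=kd)
        metadata.write_tsv(out / "metadata.tsv")
        taxonomy.write_tsv(out / "taxonomy.tsv")
        record("simulate", out / "metadata.tsv")
        record("simulate", out / "taxonomy.tsv")
    else:
        kingdom_tables = {
            kd: tables.read_feature_table(path, kd)
            for kd, path in config.input_tables.items()
        }
        metadata = tables.SampleMetadata.read_tsv(config.metadata_path)
        taxonomy = (tables.TaxonomyMap.read_tsv(config.taxonomy_path)
                    if config.taxonomy_path else None)
    manifest["stages"]["simulate" if config.simulate else "load"] = "complete"

    # --- rarefy + filters ---------------------------------------------------
    rarefied: dict[str, tables.FeatureTable] = {}
    core: dict[str, set[str]] = {}
    for kd, tab in kingdom_tables.items():
        depth = config.rarefaction_depths.get(kd, tables.DEFAULT_RAREFACTION_DEPTHS[kd])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rar = tables.rarefy(tab, tables.RarefactionSpec(
                depth=depth, seed=int(rng.integers(2**31 - 1))))
            core[kd] = tables.core_taxa(rar, metadata, config.network_min_relabund)
        p = out / f"rarefied_{kd}.tsv"
        rar.write_tsv(p)
        record("filter", p, kingdom=kd, depth=depth)
        rarefied[kd] = rar
    with open(out / "core_taxa.json", "w") as fh:
        json.dump({kd: sorted(v) for kd, v in core.items()}, fh, indent=1)
    record("filter", out / "core_taxa.json")
    manifest["stages"]["filter"] = "complete"

    # --- diversity ----------------------------------------------------------
    alpha_rows = []
    for kd, rar in rarefied.items():
        tree = synthdata.simulate_tree(rar.feature_ids,
                                       seed=int(rng.integers(2**31 - 1)))
        for sid in rar.sample_ids:
            row = rar.counts.loc[sid]
            alpha_rows.append({
                "kingdom": kd, "sample_id": sid,
                "chao1": tables.chao1(row),
                "goods_coverage": tables.goods_coverage(row),
                "observed_features": tables.observed_features(row),
                "faith_pd": diversity.faith_pd(row, tree),
            })
    alpha = pd.DataFrame(alpha_rows)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    record("diversity", out / "alpha_diversity.tsv")
    manifest["stages"]["diversity"] = "complete"

    # --- maturation ---------------------------------------------------------
    maturation_summary = {}
    for kd in config.maturation_kingdoms:
        if kd not in rarefied:
            continue
        rar = rarefied[kd]
        rel = tables.relative_abundance(rar)
        ages = metadata.ages_for(rar.sample_ids)
        res = maturation.run_maturation_pipeline(
            rel, ages, n_trees=config.n_trees, n_repeats=config.n_repeats,
            cv_n_trees=config.cv_n_trees, sparse_n_trees=config.sparse_n_trees,
            n_folds=config.n_folds, step=config.step,
            tolerance=config.tolerance,
            rel_plateau_threshold=config.rel_plateau_threshold,
            seed=int(rng.integers(2**31 - 1)),
        )
        res.importance.to_frame().to_csv(out / f"importance_{kd}.tsv", sep="\t")
        res.curve.to_frame().to_csv(out / f"cv_curve_{kd}.tsv", sep="\t", index=False)
        res.maturation.microbiota_age.to_frame().to_csv(
            out / f"microbiota_age_{kd}.tsv", sep="\t")
        for name in ("importance", "cv_curve", "microbiota_age"):
            record("maturation", out / f"{name}_{kd}.tsv", kingdom=kd)
        maturation_summary[kd] = {
            "selected_taxa": res.model.selected_taxa,
            "oob_r2": res.model.oob_r2,
            "maturation_age_days": res.maturation.maturation_age_days,
            "rel_plateau_threshold": config.rel_plateau_threshold,
        }
    with open(out / "maturation_summary.json", "w") as fh:
        json.dump(maturation_summary, fh, indent=1)
    record("maturation", out / "maturation_summary.json")
    manifest["stages"]["maturation"] = "complete"

    # --- networks -----------------------------------------------------------
    topo_rows = []
    for kd, rar in rarefied.items():
        keep = [t for t in rar.feature_ids if t in core[kd]]
        if len(keep) < 2:
            warnings.warn(f"kingdom {kd}: fewer than 2 core taxa; network skipped")
            continue
        rel = tables.relative_abundance(rar)[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = network.spearman_matrix(rel)
        net = network.build_core_network(corr, config.core_rho_min, config.core_q_max)
        network.write_graphml(net, out / f"network_core_{kd}.graphml")
        network.write_edge_list(net, out / f"edges_core_{kd}.tsv")
        record("network", out / f"network_core_{kd}.graphml", kingdom=kd)
        summary = network.topology(net).as_dict()
        summary["kingdom"] = kd
        if net.number_of_nodes():
            ranking = network.betweenness_keystones(
                net, min(config.keystone_k_intra, net.number_of_nodes()))
            summary["keystones"] = ",".join(ranking.taxa)
        topo_rows.append(summary)
    meta_net = None
    if len(rarefied) >= 2:
        meta_net = network.meta_network(
            rarefied, metadata, regime="core",
            rho_min=config.core_rho_min, q_max=config.core_q_max,
            taxa_per_kingdom=core,
        )
        network.write_graphml(meta_net, out / "network_meta.graphml")
        record("network", out / "network_meta.graphml")
        summary = network.topology(meta_net).as_dict()
        summary["kingdom"] = "meta"
        if meta_net.number_of_nodes():
            ranking = network.betweenness_keystones(
                meta_net, min(config.keystone_k_inter, meta_net.number_of_nodes()))
            summary["keystones"] = ",".join(ranking.taxa)
        topo_rows.append(summary)
    manifest["stages"]["network"] = "complete"

    # --- report -------------------------------------------------------------
    pd.DataFrame(topo_rows).to_csv(out / "topology.tsv", sep="\t", index=False)
    record("report", out / "topology.tsv")
    manifest["stages"]["report"] = "complete"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
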