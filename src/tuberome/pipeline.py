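"""End-to-end pipeline driver.

Runs simulate/load -> rOTU filtering -> alpha diversity + permutation ANOVA
-> Bray–Curtis + PERMANOVA (+ ordination) -> stability classes -> per-
timepoint random-forest selection -> ties filter -> Spearman network ->
key-OTU intersection, writing every stage's output as TSV plus a JSON
manifest (parameters, seed, checksums).  One global seed deterministically
derives per-stage seeds by hashing the stage name, so a stage re-run in
isolation sees identical randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assay_stats import fit_and_contrast, stage_sums
from .betadiv import bray_curtis, cap, permanova, pcoa
from .corr_network import STORAGE_NODE, build_network
from .diversity import alpha_diversity, permutation_anova
from .filtering import filter_rotus, filter_ties
from .indicator_rf import assign_stability_classes, rf_select_strata
from .io_tables import (CountTable, StudyMetadata, read_count_table,
                        read_metadata, write_count_table,
                        write_key_otu_report, write_metadata)
from .key_otus import intersect_key_otus
from .synthetic_data import SimulationConfig, generate_study

log = logging.getLogger("tuberome")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters with the package defaults."""

    # inputs: either simulate, or paths to counts + metadata
    simulate: bool = True
    counts_path: str | None = None
    metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    # filtering
    min_mean_relab: float = 1e-4
    min_present: int = 2
    of_replicates: int = 3
    # diversity / beta diversity
    rarefaction_depth: int | None = None  # None = minimum sample total
    n_perm: int = 9999
    factors: tuple[str, ...] = ("cultivar", "timepoint", "soil")
    run_diversity: bool = True
    run_betadiv: bool = True
    run_ordination: bool = True
    # random forest
    rf_strata: str | None = "timepoint"
    rf_include_pooled: bool = True
    n_trees: int = 2000
    n_trees_iterat: int | None = None
    rf_importance: str = "permutation"
    drop_fraction: float = 0.2
    se_multiplier: float = 1.0
    # network
    r_threshold: float = 0.5
    p_threshold: float = 0.001
    network_mode: str = "absolute"
    storage_edge_only: bool = False
    # global
    seed: int = 0
    outdir: str = "tuberome_out"

    def validate(self) -> None:
        if not self.simulate and not (self.counts_path and
                                      self.metadata_path):
            raise ValueError("simulate=false requires counts_path and "
                             "metadata_path")
        if not 0 <= self.r_threshold <= 1 or not 0 <= self.p_threshold <= 1:
            raise ValueError("network thresholds must lie in [0, 1]")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class PipelineResult:
    table: CountTable
    meta: StudyMetadata
    rotus: "object"
    alpha: "object"
    alpha_tests: list
    permanova_results: list
    stability: "object"
    rf_selected: set
    rf_origin: dict
    rf_rank: dict
    network: "object"
    key_otus: list
    truth: "object | None"
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, write: bool = True
                 ) -> PipelineResult:
    """Execute every stage; see module docstring for the stage order."""
    config.validate()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": config.to_dict(), "stages": {}}

    def _stage(name: str) -> None:
        log.info("stage: %s", name)

    # -- input ------------------------------------------------------------
    _stage("input")
    truth = None
    if config.simulate:
        sim = config.simulation or SimulationConfig(
            seed=stage_seed(config.seed, "simulate"))
        table, meta, truth = generate_study(sim)
    else:
        table = read_count_table(config.counts_path)
        meta = read_metadata(config.metadata_path).aligned_to(table)
    meta = meta.aligned_to(table)
    if write:
        write_count_table(table, outdir / "counts.tsv")
        write_metadata(meta, outdir / "metadata.tsv")

    # -- rOTU filtering ---------------------------------------------------
    _stage("filter")
    rotus = filter_rotus(table, meta, config.min_mean_relab,
                         config.min_present, config.of_replicates)
    rtable = table.select_otus(rotus.retained_otu_ids)
    manifest["stages"]["filter"] = {"n_input_otus": len(table.otu_ids),
                                    "n_rotus": len(rotus.retained_otu_ids)}
    if write:
        rotus.rule_log_frame().to_csv(outdir / "filter_rule_log.tsv",
                                      sep="\t", index=False)

    # -- alpha diversity + permutation ANOVA ------------------------------
    alpha = None
    alpha_tests: list = []
    if config.run_diversity:
        _stage("diversity")
        alpha = alpha_diversity(rtable, config.rarefaction_depth,
                                seed=stage_seed(config.seed, "rarefy"))
        meta_alpha = meta.frame.loc[alpha.frame.index]
        for response in ("observed_richness", "simpson"):
            tests = permutation_anova(
                alpha.frame[response].to_numpy(),
                {f: meta_alpha[f] for f in config.factors},
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"permanova_alpha_{response}"))
            for t in tests:
                t.factor = f"{response}:{t.factor}"
            alpha_tests.extend(tests)
        manifest["stages"]["diversity"] = {
            "depth": alpha.rarefaction_depth,
            "dropped_samples": alpha.dropped_samples,
            "tests": [dataclasses.asdict(t) for t in alpha_tests]}
        if write:
            alpha.frame.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
            pd.DataFrame([dataclasses.asdict(t) for t in alpha_tests]).to_csv(
                outdir / "alpha_permutation_anova.tsv", sep="\t", index=False)

    # -- beta diversity ---------------------------------------------------
    permanova_results = []
    if config.run_betadiv:
        _stage("betadiv")
        dm = bray_curtis(rtable)
        for f in config.factors:
            permanova_results.append(permanova(
                dm, meta.frame[f].to_numpy(), n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"permanova_{f}"), factor=f))
        manifest["stages"]["betadiv"] = {
            "permanova": [dataclasses.asdict(r) for r in permanova_results]}
        if write:
            pd.DataFrame(dm.values, index=dm.sample_ids,
                         columns=dm.sample_ids).to_csv(
                outdir / "bray_curtis.tsv", sep="\t")
            pd.DataFrame([dataclasses.asdict(r) for r in
                          permanova_results]).to_csv(
                outdir / "permanova.tsv", sep="\t", index=False)
            if config.run_ordination:
                grouping = meta.frame["timepoint"].to_numpy()
                try:
                    ordn = cap(dm, grouping)
                except Exception:  # single timepoint level: unconstrained
                    ordn = pcoa(dm)
                coords = pd.DataFrame(
                    ordn.coordinates, index=ordn.sample_ids,
                    columns=[f"CAP{k+1}" if ordn.constrained else f"PCo{k+1}"
                             for k in range(ordn.coordinates.shape[1])])
                coords.to_csv(outdir / "ordination.tsv", sep="\t")

    # -- storage-stability classes + random forest ------------------------
    _stage("rf-select")
    stability = assign_stability_classes(meta)
    strata = (meta.frame[config.rf_strata] if config.rf_strata else None)
    rf_kwargs = dict(n_trees=config.n_trees,
                     n_trees_iterat=config.n_trees_iterat,
                     importance=config.rf_importance,
                     drop_fraction=config.drop_fraction,
                     se_multiplier=config.se_multiplier)
    rf_selected, rf_origin, rf_rank = rf_select_strata(
        rtable, meta, stability.stability_class.loc[rtable.sample_ids],
        strata=strata, seed=stage_seed(config.seed, "rf"), **rf_kwargs)
    if config.rf_include_pooled and strata is not None:
        pooled_sel, _, pooled_rank = rf_select_strata(
            rtable, meta, stability.stability_class.loc[rtable.sample_ids],
            strata=None, seed=stage_seed(config.seed, "rf_pooled"),
            **rf_kwargs)
        for otu in pooled_sel:
            rf_selected.add(otu)
            rf_origin.setdefault(otu, []).append("pooled")
            r = pooled_rank[otu]
            rf_rank[otu] = min(rf_rank.get(otu, r), r)
    manifest["stages"]["rf"] = {"n_selected": len(rf_selected),
                                "cut_points": stability.cut_points}
    if write:
        pd.DataFrame(
            {"otu_id": sorted(rf_selected),
             "strata": [";".join(rf_origin[o]) for o in sorted(rf_selected)],
             "importance_rank": [rf_rank[o] for o in sorted(rf_selected)]}
        ).to_csv(outdir / "rf_selected.tsv", sep="\t", index=False)

    # -- correlation network ----------------------------------------------
    _stage("network")
    ties = filter_ties(rtable)
    ntable = rtable.select_otus(ties.retained_otu_ids)
    network = build_network(
        ntable, meta.frame.loc[ntable.sample_ids, "storage_days"].to_numpy(),
        r_threshold=config.r_threshold, p_threshold=config.p_threshold,
        mode=config.network_mode)
    manifest["stages"]["network"] = {
        "n_ties_filtered": len(ties.retained_otu_ids),
        "n_edges": len(network.edges),
        "storage_node_degree": int(network.degree()[STORAGE_NODE])}
    if write:
        pd.DataFrame(network.edges,
                     columns=["node_i", "node_j", "r"]).assign(
            p=[network.p.loc[a, b] for a, b, _ in network.edges]).to_csv(
            outdir / "network_edges.tsv", sep="\t", index=False)

    # -- key OTUs ----------------------------------------------------------
    _stage("keyotus")
    rf_in_net = rf_selected & (set(network.node_ids) - {STORAGE_NODE})
    keys = intersect_key_otus(
        rf_in_net, network, rf_rank=rf_rank, table=rtable,
        stability_class=stability.stability_class.loc[rtable.sample_ids],
        taxonomy=table.taxonomy,
        storage_edge_only=config.storage_edge_only)
    manifest["stages"]["keyotus"] = {
        "n_key_otus": len(keys),
        "directions": {d: sum(k.direction == d for k in keys)
                       for d in ("long", "medium", "short")}}
    if truth is not None:
        planted = set(truth.planted_long_ids) | set(truth.planted_short_ids)
        found = {k.otu_id for k in keys}
        correct = sum(
            1 for k in keys
            if (k.otu_id in truth.planted_long_ids and k.direction == "long")
            or (k.otu_id in truth.planted_short_ids and
                k.direction == "short"))
        manifest["stages"]["keyotus"]["recovery"] = {
            "n_planted": len(planted),
            "n_recovered": len(planted & found),
            "n_recovered_correct_direction": correct,
            "n_unplanted_reported": len(found - planted)}
    if write:
        write_key_otu_report(keys, outdir / "key_otus.tsv")
        for name in ("counts.tsv", "metadata.tsv", "key_otus.tsv"):
            manifest.setdefault("checksums", {})[name] = _checksum(
                outdir / name)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))

    return PipelineResult(table, meta, rotus, alpha, alpha_tests,
                          permanova_results, stability, rf_selected,
                          rf_origin, rf_rank, network, keys, truth, manifest)
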