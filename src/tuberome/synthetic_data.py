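"""Synthetic tuber-microbiome studies with planted storage-associated taxa.

The generator emulates the structure the downstream analysis assumes: a
crossed cultivar x soil x timepoint design with three replicate tubers per
cell, compositional counts drawn Dirichlet-multinomially around a log-normal
rank-abundance profile, a community shift between the first and last storage
timepoints, and a minority of planted OTUs whose expected relative abundance
is log-linear in the batch's storage days (positive slope: taxa enriched in
long-storing tubers; negative slope: taxa enriched in early sprouters).

Storage days are a batch-level attribute (constant over one cultivar x soil
combination), so the planted effects are simultaneously detectable by the
two downstream selection routes: random forests on the derived
short/medium/long stability classes and Spearman correlation against the
storage-days covariate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (CULTIVARS, SOILS, TIMEPOINTS, CountTable,
                        StudyMetadata)


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclasses.dataclass
class SimulationConfig:
    """Study-design and noise parameters for :func:`generate_study`.

    Defaults give a desk-scale study (3 cultivars x 3 soils x 3 timepoints
    x 3 replicates = 81 samples) over 500 OTUs.  ``effect_size`` is the
    log-abundance slope per storage day of the planted taxa; with the default
    0.02/day over a 135–169-day sprouting spread a planted OTU changes about
    two-fold between the extreme batches.  ``dirichlet_precision`` sets the
    between-replicate compositional noise (larger = tighter replicates).
    """

    n_cultivars: int = 3
    n_soils: int = 3
    timepoints: tuple[str, ...] = ("T2", "T6", "T7")
    n_replicates: int = 3
    n_otus: int = 500
    library_size_range: tuple[int, int] = (5_000, 50_000)
    base_lognormal_sigma: float = 1.5
    dirichlet_precision: float = 5_000.0
    n_long_otus: int = 10
    n_short_otus: int = 10
    planted_base_relab: float = 0.005
    effect_size: float = 0.02
    shift_strength: float = 1.0
    n_shift_otus: int = 50
    storage_days_range: tuple[float, float] = (135.0, 169.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_long_otus + self.n_short_otus > self.n_otus:
            raise ConfigError("more planted OTUs than OTUs in total")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.library_size_range[0] < 100:
            raise ConfigError("library sizes must be >= 100")
        if self.n_cultivars > len(CULTIVARS) or self.n_soils > len(SOILS):
            raise ConfigError(
                f"at most {len(CULTIVARS)} cultivars / {len(SOILS)} soils")
        if self.n_shift_otus > self.n_otus:
            raise ConfigError("n_shift_otus exceeds n_otus")
        unknown = set(self.timepoints) - set(TIMEPOINTS)
        if unknown:
            raise ConfigError(f"unknown timepoints {sorted(unknown)}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth for recovery tests."""

    planted_long_ids: list[str]
    planted_short_ids: list[str]
    storage_days: dict[tuple[str, str], float]  # (cultivar, soil) -> days
    expected_compositions: pd.DataFrame  # samples x OTUs, rows sum to 1

    def __post_init__(self) -> None:
        if set(self.planted_long_ids) & set(self.planted_short_ids):
            raise ConfigError("planted long/short id sets overlap")


def generate_study(config: SimulationConfig
                   ) -> tuple[CountTable, StudyMetadata, SimulationTruth]:
    """Draw one synthetic study.

    Counts for each sample are multinomial(library_size, q) with q ~
    Dirichlet(precision * p_sample); p_sample is the batch/timepoint-specific
    expected composition.  Fully reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    otu_ids = [f"OTU_{k + 1}" for k in range(cfg.n_otus)]

    # baseline rank-abundance profile (log-normal spread)
    base = np.exp(rng.normal(0.0, cfg.base_lognormal_sigma, cfg.n_otus))
    planted = rng.choice(cfg.n_otus, cfg.n_long_otus + cfg.n_short_otus,
                         replace=False)
    long_idx = planted[:cfg.n_long_otus]
    short_idx = planted[cfg.n_long_otus:]
    # planted taxa sit at realistic indicator abundances: spread around
    # planted_base_relab (half to double), not one identical value
    if planted.size:
        spread = np.exp(rng.uniform(np.log(0.5), np.log(2.0), planted.size))
        target = cfg.planted_base_relab * spread
        base[planted] = target * base.sum() / max(1e-12, 1 - target.sum())
    base = base / base.sum()

    # harvest -> sprouting community succession on a random OTU subset: each
    # shift OTU follows its own temporal trajectory (log-offset 0 at the
    # first timepoint, independent draws at later ones, a few strong
    # shifters among many mild ones).  Heterogeneous trajectories move the
    # community as a whole between harvest and sprouting without locking all
    # shift OTUs into one mutually correlated block.
    shift_idx = rng.choice(cfg.n_otus, cfg.n_shift_otus, replace=False)
    n_tp = len(cfg.timepoints)
    otu_scale = np.exp(rng.normal(np.log(0.4), 0.4, cfg.n_shift_otus))
    shift_profile = np.zeros((cfg.n_shift_otus, n_tp))
    if n_tp > 1:
        shift_profile[:, 1:] = (rng.normal(0.0, 1.0,
                                           (cfg.n_shift_otus, n_tp - 1))
                                * otu_scale[:, None] * cfg.shift_strength)

    cultivars = list(CULTIVARS[:cfg.n_cultivars])
    soils = list(SOILS[:cfg.n_soils])
    lo, hi = cfg.storage_days_range
    batches = [(c, s) for c in cultivars for s in soils]
    # evenly spread batch sprouting days across the configured range, with a
    # small jitter, so the tertile classes are well defined
    days = np.linspace(lo, hi, len(batches))
    if len(batches) > 1:
        step = (hi - lo) / (len(batches) - 1)
        days = days + rng.uniform(-0.25 * step, 0.25 * step, len(batches))
        days = np.clip(days, lo, hi)
    rng.shuffle(days)
    batch_days = {b: float(d) for b, d in zip(batches, days)}
    mid_days = 0.5 * (lo + hi)

    meta_rows, sample_ids, expected, counts = [], [], [], []
    for (cultivar, soil) in batches:
        d = batch_days[(cultivar, soil)]
        for t_i, tp in enumerate(cfg.timepoints):
            log_mean = np.log(base)
            # planted storage-stability effects (log-linear in days)
            log_mean[long_idx] += cfg.effect_size * (d - mid_days)
            log_mean[short_idx] -= cfg.effect_size * (d - mid_days)
            log_mean[shift_idx] += shift_profile[:, t_i]
            p = np.exp(log_mean)
            p = p / p.sum()
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{cultivar}_{tp}_{soil}_{rep}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "cultivar": cultivar,
                                  "soil": soil, "timepoint": tp,
                                  "replicate": rep, "storage_days": d})
                expected.append(p)
                lib = int(np.exp(rng.uniform(
                    np.log(cfg.library_size_range[0]),
                    np.log(cfg.library_size_range[1]))))
                q = rng.dirichlet(np.maximum(
                    p * cfg.dirichlet_precision, 1e-9))
                counts.append(rng.multinomial(lib, q))

    table = CountTable(sample_ids, otu_ids,
                       np.array(counts, dtype=np.int64))
    meta = StudyMetadata(pd.DataFrame(meta_rows))
    truth = SimulationTruth(
        planted_long_ids=[otu_ids[k] for k in long_idx],
        planted_short_ids=[otu_ids[k] for k in short_idx],
        storage_days=batch_days,
        expected_compositions=pd.DataFrame(np.array(expected),
                                           index=sample_ids,
                                           columns=otu_ids))
    return table, meta, truth


def write_study(table: CountTable, meta: StudyMetadata,
                truth: SimulationTruth, config: SimulationConfig,
                outdir: str | Path) -> None:
    """Emit the study in the TSV formats the I/O layer reads, plus a JSON
    sidecar echoing seed and configuration."""
    from .io_tables import write_count_table, write_metadata
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(table, outdir / "counts.tsv")
    write_metadata(meta, outdir / "metadata.tsv")
    pd.DataFrame({"otu_id": truth.planted_long_ids + truth.planted_short_ids,
                  "planted_direction": (["long"] * len(truth.planted_long_ids)
                                        + ["short"] * len(
                                            truth.planted_short_ids))}
                 ).to_csv(outdir / "truth_planted.tsv", sep="\t", index=False)
    (outdir / "config.json").write_text(config.to_json())


# ---------------------------------------------------------------------------
# Sprouting assay
# ---------------------------------------------------------------------------

#: ordinal BBCH principal growth stages used in the bud-disc assay
BBCH_STAGES = (0, 1, 2, 3, 5)


def generate_assay(effect_map: dict[str, float], n_discs: int = 6,
                   n_repetitions: int = 2, n_days: int = 10,
                   variety: str = "LC", seed: int = 0) -> pd.DataFrame:
    """Simulate bud-disc BBCH trajectories for a set of treatments.

    Each treatment has a mean daily stage-progression rate (stages/day,
    ``effect_map``).  A disc's final stage index after ``n_days`` is the
    number of successful daily advances, Binomial(n_days, rate) capped at the
    top BBCH stage; sprouting inhibitors (low rates) therefore have lower
    stage sums in expectation.  Returns a disc-level table with columns
    disc_id, treatment, variety, repetition, stage.
    """
    for t, rate in effect_map.items():
        if rate < 0:
            raise ConfigError(f"negative progression rate for {t!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in effect_map:
        p = min(effect_map[treatment], 1.0)  # per-day advance probability
        for rep in range(1, n_repetitions + 1):
            for disc in range(1, n_discs + 1):
                advances = rng.binomial(n_days, p)
                stage_idx = min(advances, len(BBCH_STAGES) - 1)
                rows.append({
                    "disc_id": f"{treatment}_r{rep}_d{disc}",
                    "treatment": treatment, "variety": variety,
                    "repetition": rep,
                    "stage": BBCH_STAGES[stage_idx]})
    return pd.DataFrame(rows)
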