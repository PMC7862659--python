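"""Rarefaction, alpha diversity and permutation ANOVA.

Alpha diversity is computed on counts rarefied to a common depth (default:
the minimum sample total, consistent with the convention behind depths such
as 6785 reads/sample).  Factor effects on richness/evenness are tested with a
one-way permutation ANOVA per factor: the classic F statistic with a null
distribution obtained by randomly relabelling the response values.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_tables import CountTable, ValidationError


@dataclasses.dataclass
class AlphaResult:
    """Per-sample richness and evenness at a fixed rarefaction depth."""

    frame: pd.DataFrame  # index sample_id; columns observed_richness, simpson
    rarefaction_depth: int
    seed: int
    dropped_samples: list[str]


@dataclasses.dataclass
class PermAnovaResult:
    factor: str
    F: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        assert self.F >= 0
        assert self.p >= 1.0 / (self.n_perm + 1) - 1e-15


def rarefy(table: CountTable, depth: int, seed: int = 0,
           ) -> tuple[CountTable, list[str]]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and their ids
    returned alongside the rarefied table.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals >= depth
    dropped = [table.sample_ids[i] for i in np.flatnonzero(~keep)]
    rows = []
    for i in np.flatnonzero(keep):
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    new = np.array(rows, dtype=np.int64).reshape(int(keep.sum()),
                                                 len(table.otu_ids))
    kept_ids = [table.sample_ids[i] for i in np.flatnonzero(keep)]
    return CountTable(kept_ids, list(table.otu_ids), new,
                      table.taxonomy), dropped


def observed_richness(sample_counts: np.ndarray) -> int:
    """Number of OTUs with count > 0."""
    return int(np.count_nonzero(np.asarray(sample_counts)))


def simpson_index(sample_counts: np.ndarray, variant: str = "gini") -> float:
    """Simpson's diversity on one sample.

    ``variant="gini"`` gives the Gini–Simpson index 1 - sum(p_i^2) in [0, 1];
    ``variant="inverse"`` gives 1 / sum(p_i^2).
    """
    x = np.asarray(sample_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValidationError("Simpson index undefined for zero-total sample")
    d = float(np.sum((x / total) ** 2))
    if variant == "gini":
        return 1.0 - d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


def alpha_diversity(table: CountTable, depth: int | None = None,
                    seed: int = 0) -> AlphaResult:
    """Rarefy (depth defaults to the minimum sample total) and compute
    observed richness and Gini–Simpson per sample."""
    if depth is None:
        depth = int(table.sample_totals.min())
    rare, dropped = rarefy(table, depth, seed)
    frame = pd.DataFrame(
        {"observed_richness": [observed_richness(r) for r in rare.counts],
         "simpson": [simpson_index(r) for r in rare.counts]},
        index=pd.Index(rare.sample_ids, name="sample_id"))
    return AlphaResult(frame, depth, seed, dropped)


def _oneway_f(values: np.ndarray, codes: np.ndarray, n_groups: int
              ) -> float:
    """Textbook one-way ANOVA F = MS_between / MS_within."""
    n = values.size
    counts = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    means = sums / counts
    grand = values.mean()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[codes]) ** 2))
    df_b, df_w = n_groups - 1, n - n_groups
    if df_w <= 0:
        raise ValidationError("no within-group degrees of freedom")
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def permutation_anova(values, factors: dict[str, "pd.Series | np.ndarray"],
                      n_perm: int = 9999, seed: int = 0
                      ) -> list[PermAnovaResult]:
    """One-way permutation ANOVA of ``values`` against each factor.

    Each factor is tested marginally: the observed F is the classic one-way
    ANOVA F, and p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under
    random relabelling of the values across samples.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for name, labels in factors.items():
        codes, levels = pd.factorize(np.asarray(labels))
        if len(levels) < 2:
            raise ValidationError(f"factor {name!r} has a single level")
        f_obs = _oneway_f(values, codes, len(levels))
        hits = 0
        v = values.copy()
        for _ in range(n_perm):
            rng.shuffle(v)
            if _oneway_f(v, codes, len(levels)) >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        out.append(PermAnovaResult(name, float(f_obs), float(p), n_perm))
    return out
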