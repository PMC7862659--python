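"""OTU retention rules.

Three filters are applied before the downstream statistics:

* a relative-abundance floor (default: mean per-sample relative abundance
  >= 0.01%),
* a replicate-reproducibility rule — an OTU must be present (count > 0) in at
  least 2 of the 3 replicate tubers of at least one cultivar x soil x
  timepoint cell.  OTUs passing both rules are "reproducibly occurring OTUs"
  (rOTUs);
* a ties filter applied before correlation analysis — OTUs whose modal count
  value (usually zero) occupies strictly more than two-thirds of the samples
  carry too little rank information for Spearman correlation and are dropped.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_tables import CountTable, StudyMetadata, ValidationError

#: rule tags recorded in RotuSet.rule_log
RULE_ABUNDANCE = "abundance"
RULE_REPLICATE = "replicate"
RULE_TIES = "ties"


@dataclasses.dataclass
class RotuSet:
    """Outcome of a filtering pass.

    ``retained_otu_ids`` preserves the source table's OTU order;
    ``rule_log`` maps every *removed* OTU to the rule name(s) that removed it.
    """

    retained_otu_ids: list[str]
    rule_log: dict[str, list[str]]
    source_otu_ids: list[str]

    def __post_init__(self) -> None:
        src = set(self.source_otu_ids)
        if not set(self.retained_otu_ids) <= src:
            raise ValidationError("retained ids not a subset of source ids")
        removed = src - set(self.retained_otu_ids)
        unlogged = removed - set(self.rule_log)
        if unlogged:
            raise ValidationError(f"removed OTUs without a rule: "
                                  f"{sorted(unlogged)}")

    @property
    def removed_otu_ids(self) -> list[str]:
        kept = set(self.retained_otu_ids)
        return [o for o in self.source_otu_ids if o not in kept]

    def rule_log_frame(self) -> pd.DataFrame:
        rows = [{"otu_id": o, "removed_by": ";".join(rules)}
                for o, rules in self.rule_log.items()]
        return pd.DataFrame(rows, columns=["otu_id", "removed_by"])


def relative_abundance(table: CountTable) -> np.ndarray:
    """Per-sample proportions (rows sum to 1, zeros preserved)."""
    totals = table.sample_totals
    if (totals == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"zero-total sample(s): {bad}")
    return table.counts / totals[:, None]


def filter_rotus(table: CountTable, meta: StudyMetadata,
                 min_mean_relab: float = 1e-4, min_present: int = 2,
                 of_replicates: int = 3,
                 abundance_stat: str = "mean",
                 presence_scope: str = "any_cell") -> RotuSet:
    """Apply the abundance floor and the replicate-reproducibility rule.

    An OTU is retained iff

    (a) its relative abundance statistic (``abundance_stat`` over samples:
        ``mean`` of per-sample proportions, ``max``, or ``pooled`` read
        fraction) is >= ``min_mean_relab``, and
    (b) there is at least one replicate cell (cultivar x soil x timepoint)
        in which it has count > 0 in >= ``min_present`` of ``of_replicates``
        replicates (``presence_scope="all_cells"`` demands this in every
        cell where the OTU occurs at all).

    Cells with fewer than ``of_replicates`` samples are evaluated with a
    proportionally scaled threshold ``ceil(min_present/of_replicates * n)``
    and a warning.
    """
    meta = meta.aligned_to(table)
    if abundance_stat not in ("mean", "max", "pooled"):
        raise ValueError(f"unknown abundance_stat {abundance_stat!r}")
    if presence_scope not in ("any_cell", "all_cells"):
        raise ValueError(f"unknown presence_scope {presence_scope!r}")

    relab = relative_abundance(table)
    if abundance_stat == "mean":
        stat = relab.mean(axis=0)
    elif abundance_stat == "max":
        stat = relab.max(axis=0)
    else:
        stat = table.counts.sum(axis=0) / table.counts.sum()
    pass_a = stat >= min_mean_relab

    present = table.counts > 0
    cells = meta.frame.groupby(["cultivar", "soil", "timepoint"],
                               observed=True).indices
    pos = {s: k for k, s in enumerate(table.sample_ids)}
    n_otus = table.counts.shape[1]
    if min_present <= 0:
        pass_b = np.ones(n_otus, dtype=bool)
    else:
        hit_any = np.zeros(n_otus, dtype=bool)
        miss_any = np.zeros(n_otus, dtype=bool)
        for key, rows in cells.items():
            idx = [pos[meta.frame.index[r]] for r in np.atleast_1d(rows)]
            avail = len(idx)
            if avail < of_replicates:
                thr = math.ceil(min_present / of_replicates * avail)
                warnings.warn(
                    f"cell {key} has {avail} < {of_replicates} replicates; "
                    f"presence threshold scaled to {thr}", stacklevel=2)
            else:
                thr = min_present
            n_present = present[idx, :].sum(axis=0)
            hit = n_present >= thr
            hit_any |= hit
            miss_any |= (~hit) & (n_present > 0)
        if presence_scope == "any_cell":
            pass_b = hit_any
        else:
            pass_b = hit_any & ~miss_any

    retained, log = [], {}
    for j, otu in enumerate(table.otu_ids):
        rules = []
        if not pass_a[j]:
            rules.append(RULE_ABUNDANCE)
        if not pass_b[j]:
            rules.append(RULE_REPLICATE)
        if rules:
            log[otu] = rules
        else:
            retained.append(otu)
    return RotuSet(retained, log, list(table.otu_ids))


def filter_ties(table: CountTable,
                max_tie_fraction: Fraction | float = Fraction(2, 3)
                ) -> RotuSet:
    """Drop OTUs whose modal count occurs in > ``max_tie_fraction`` of samples.

    The comparison is strict, with the default fraction held exactly as 2/3:
    an OTU tied in exactly two-thirds of the samples is retained, one tied in
    more than two-thirds is removed.
    """
    n = table.counts.shape[0]
    if n < 3:
        raise ValidationError("ties filter needs at least 3 samples")
    frac = Fraction(max_tie_fraction).limit_denominator(10**9) \
        if not isinstance(max_tie_fraction, Fraction) else max_tie_fraction
    retained, log = [], {}
    for j, otu in enumerate(table.otu_ids):
        col = table.counts[:, j]
        mode_count = int(np.bincount(
            np.unique(col, return_inverse=True)[1]).max())
        if Fraction(mode_count, n) > frac:
            log[otu] = [RULE_TIES]
        else:
            retained.append(otu)
    return RotuSet(retained, log, list(table.otu_ids))
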