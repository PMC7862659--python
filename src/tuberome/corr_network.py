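"""Spearman co-occurrence network with a storage-time node.

The ties-filtered rOTU relative abundances are augmented with one extra
column holding each sample's batch-level days from harvest to sprouting (the
storage-stability covariate).  Pairwise Spearman rank correlations (average
ranks for ties; two-sided p from the t approximation) are thresholded to
keep only strong (|r| >= 0.5) and highly significant (p <= 0.001) edges.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import relative_abundance
from .io_tables import CountTable, ValidationError

STORAGE_NODE = "storage_days"


@dataclasses.dataclass
class CorrelationNetwork:
    node_ids: list[str]
    r: pd.DataFrame  # thresholded rho (zeros where the edge was cut)
    p: pd.DataFrame
    r_threshold: float
    p_threshold: float
    mode: str
    edges: list[tuple[str, str, float]]

    def connected_nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out

    def storage_edges(self) -> dict[str, tuple[float, float]]:
        """otu_id -> (r, p) for edges incident to the storage node."""
        out = {}
        for a, b, r in self.edges:
            if STORAGE_NODE in (a, b):
                other = b if a == STORAGE_NODE else a
                out[other] = (r, float(self.p.loc[other, STORAGE_NODE]))
        return out

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=self.node_ids, dtype=int)
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def spearman_matrix(table: CountTable, storage_days,
                    use_relative_abundance: bool = True,
                    p_method: str = "t", n_perm: int = 999, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p over all rOTU pairs plus the storage node.

    ``p_method="t"`` uses the t approximation on rho; ``"permutation"``
    estimates p by permuting ranks (seeded).  Constant columns (zero rank
    variance) yield r = 0, p = 1 with a warning.
    """
    n = len(table.sample_ids)
    if n < 4:
        raise ValidationError("need >= 4 samples for correlation analysis")
    days = np.asarray(storage_days, dtype=float)
    if days.shape != (n,):
        raise ValidationError("storage_days must align with samples")
    x = relative_abundance(table) if use_relative_abundance \
        else table.counts.astype(float)
    data = np.column_stack([x, days])
    node_ids = list(table.otu_ids) + [STORAGE_NODE]

    const = data.std(axis=0) == 0
    if const.any():
        bad = [node_ids[j] for j in np.flatnonzero(const)]
        warnings.warn(f"constant node(s) {bad}: rho set to 0, p to 1",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, pval = stats.spearmanr(data, axis=0)
    rho = np.asarray(rho, dtype=float)
    pval = np.asarray(pval, dtype=float)
    m = data.shape[1]
    if rho.shape != (m, m):
        # scipy collapses the whole matrix to a scalar NaN when any column
        # is constant; recompute as average-rank Pearson with t-approx p
        ranks = pd.DataFrame(data).rank().to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
            rho = np.asarray(np.atleast_2d(rho), dtype=float)
            tstat = rho * np.sqrt(np.maximum(n - 2, 1)
                                  / np.maximum(1 - rho ** 2, 1e-300))
            pval = 2 * stats.t.sf(np.abs(tstat), n - 2)
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        ranks = pd.DataFrame(data).rank().to_numpy()
        hits = np.zeros_like(rho)
        for _ in range(n_perm):
            perm = ranks[rng.permutation(n), :]
            # permute each column independently
            for j in range(ranks.shape[1]):
                perm[:, j] = ranks[rng.permutation(n), j]
            r_perm = np.corrcoef(perm, rowvar=False)
            hits += np.abs(r_perm) >= np.abs(rho) - 1e-12
        pval = (1 + hits) / (1 + n_perm)
    elif p_method != "t":
        raise ValueError(f"unknown p_method {p_method!r}")
    rho[np.isnan(rho)] = 0.0
    pval[np.isnan(pval)] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    r = pd.DataFrame(rho, index=node_ids, columns=node_ids)
    p = pd.DataFrame(pval, index=node_ids, columns=node_ids)
    return r, p


def threshold_network(r: pd.DataFrame, p: pd.DataFrame,
                      r_threshold: float = 0.5, p_threshold: float = 0.001,
                      mode: str = "absolute") -> CorrelationNetwork:
    """Zero out weak or non-significant correlations and list the edges.

    ``mode="absolute"`` keeps |r| >= r_threshold (so taxa *negatively*
    associated with storage time survive); ``mode="positive"`` keeps only
    r >= r_threshold, the literal reading of an unsigned cut-off.
    """
    if not (0 <= r_threshold <= 1) or not (0 <= p_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if mode not in ("absolute", "positive"):
        raise ValueError(f"unknown mode {mode!r}")
    if r.shape != p.shape or list(r.index) != list(p.index):
        raise ValidationError("r and p matrices must be aligned")
    node_ids = list(r.index)
    rv = r.to_numpy(dtype=float).copy()
    pv = p.to_numpy(dtype=float)
    strength = np.abs(rv) if mode == "absolute" else rv
    keep = (strength >= r_threshold) & (pv <= p_threshold)
    np.fill_diagonal(keep, True)  # diagonal kept in the matrix, not an edge
    rv[~keep] = 0.0
    edges = []
    iu = zip(*np.triu_indices(len(node_ids), 1))
    for i, j in iu:
        if rv[i, j] != 0.0:
            edges.append((node_ids[i], node_ids[j], float(rv[i, j])))
    return CorrelationNetwork(node_ids,
                              pd.DataFrame(rv, index=node_ids,
                                           columns=node_ids),
                              p.copy(), float(r_threshold),
                              float(p_threshold), mode, edges)


def build_network(table: CountTable, storage_days,
                  r_threshold: float = 0.5, p_threshold: float = 0.001,
                  mode: str = "absolute", **kwargs) -> CorrelationNetwork:
    """spearman_matrix followed by threshold_network."""
    r, p = spearman_matrix(table, storage_days, **kwargs)
    return threshold_network(r, p, r_threshold, p_threshold, mode)
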