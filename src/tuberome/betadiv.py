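"""Beta diversity: Bray–Curtis dissimilarity, PERMANOVA and ordination.

PERMANOVA follows Anderson's partitioning of squared inter-point distances:
``SS_total = sum_{i<j} d_ij^2 / n``, ``SS_within`` from within-group pairs,
pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)), with significance from
permutation of group labels.  Ordination is classical principal-coordinates
analysis (PCoA) of the Gower-centred matrix; the constrained step (CAP)
rotates retained PCoA axes with a linear discriminant with respect to the
grouping.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io_tables import CountTable, ValidationError


@dataclasses.dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValidationError("entries must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclasses.dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    R2: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        assert self.pseudo_F >= 0
        assert 0 <= self.R2 <= 1
        assert self.p >= 1.0 / (self.n_perm + 1) - 1e-15


@dataclasses.dataclass
class OrdinationResult:
    """Sample coordinates on ordination axes, ordered by eigenvalue.

    ``eigenvalues`` lists every eigenvalue (negative ones included for
    transparency); ``coordinates`` only spans axes with positive eigenvalues
    (PCoA) or the discriminant axes (CAP).
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    constrained: bool


def bray_curtis(data: "CountTable | np.ndarray",
                sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between all sample pairs.

    d(i,j) = 1 - 2 * sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk).
    """
    if isinstance(data, CountTable):
        mat = data.counts.astype(float)
        ids = list(data.sample_ids)
    else:
        mat = np.asarray(data, dtype=float)
        ids = sample_ids or [f"S{i}" for i in range(mat.shape[0])]
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        bad = [ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"zero-total sample(s): {bad}")
    dm = squareform(pdist(mat, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(ids, np.clip(dm, 0.0, 1.0))


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int
                     ) -> tuple[float, float]:
    """(pseudo_F, R2) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ng = idx.size
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if df_w <= 0:
        raise ValidationError("PERMANOVA needs residual degrees of freedom")
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within <= 1e-300:
        f = 0.0 if ss_between <= 1e-300 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    return max(f, 0.0), min(max(r2, 0.0), 1.0)


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 9999,
              seed: int = 0, factor: str = "group",
              strata=None) -> PermanovaResult:
    """Anderson-style PERMANOVA with label-permutation significance.

    ``strata`` optionally restricts permutations to shuffle labels only
    within blocks (e.g. cultivar or soil).
    """
    labels = np.asarray(grouping)
    codes = np.unique(labels, return_inverse=True)[1]
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValidationError("grouping must have >= 2 levels")
    if n_groups == dm.n:
        raise ValidationError("every sample its own group (no residual df)")
    d2 = dm.values ** 2
    f_obs, r2 = _permanova_stats(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        blocks = [np.flatnonzero(strata == b) for b in np.unique(strata)]
    hits = 0
    perm = codes.copy()
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(codes)
        else:
            perm = codes.copy()
            for idx in blocks:
                perm[idx] = perm[rng.permutation(idx)]
        f_perm, _ = _permanova_stats(d2, perm, n_groups)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(factor, float(f_obs), float(r2), float(p), n_perm)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of the double-centred -d^2/2 matrix.

    Negative eigenvalues are reported but excluded from the coordinates; a
    warning is issued when their mass exceeds 5% of the positive mass.
    """
    n = dm.n
    b = -0.5 * dm.values ** 2
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval[np.abs(eigval) < 1e-10 * max(1.0, np.abs(eigval).max())] = 0.0
    neg_mass = -eigval[eigval < 0].sum()
    pos_mass = eigval[eigval > 0].sum()
    if pos_mass > 0 and neg_mass > 0.05 * pos_mass:
        warnings.warn(f"negative eigenvalue mass {neg_mass:.3g} exceeds 5% "
                      f"of positive mass {pos_mass:.3g}", stacklevel=2)
    pos = eigval > 0
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(list(dm.sample_ids), coords, eigval,
                            constrained=False)


def cap(dm: DistanceMatrix, grouping, n_pcoa_axes: int | None = None,
        min_explained: float = 0.85) -> OrdinationResult:
    """Constrained analysis of principal coordinates.

    PCoA axes are retained up to ``n_pcoa_axes`` (default: the smallest
    number explaining >= ``min_explained`` of the positive eigenvalue mass)
    and rotated by a linear discriminant maximising between-group separation;
    at most ``n_groups - 1`` constrained axes result.
    """
    labels = np.asarray(grouping)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("CAP grouping must have >= 2 levels")
    ord0 = pcoa(dm)
    n_pos = ord0.coordinates.shape[1]
    if n_pcoa_axes is None:
        mass = np.cumsum(ord0.eigenvalues[:n_pos])
        n_pcoa_axes = int(np.searchsorted(mass,
                                          min_explained * mass[-1]) + 1)
    if n_pcoa_axes > n_pos:
        raise ValidationError(
            f"requested {n_pcoa_axes} axes but only {n_pos} positive "
            f"eigenvalues are available")
    if n_pcoa_axes > dm.n - 1:
        raise ValidationError("more axes requested than samples - 1")
    x = ord0.coordinates[:, :n_pcoa_axes]
    lda = LinearDiscriminantAnalysis(solver="eigen", n_components=min(
        uniq.size - 1, n_pcoa_axes))
    scores = lda.fit(x, labels).transform(x)
    scores = scores - scores.mean(axis=0)
    eig = scores.var(axis=0, ddof=0) * dm.n  # per-axis dispersion
    order = np.argsort(eig)[::-1]
    return OrdinationResult(list(dm.sample_ids), scores[:, order],
                            eig[order], constrained=True)
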