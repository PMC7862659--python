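"""Random-forest backward-elimination selection of indicator OTUs.

Follows the varSelRF recipe: fit a random-forest classifier on relative
abundances, rank OTUs once by impurity importance, then repeatedly drop the
least-important fifth of the candidates, refitting and recording the
out-of-bag (OOB) error after each drop.  The selected set is the smallest
candidate set whose OOB error is within one standard error of the minimum
along the elimination path (the "1-SE rule"), which guards against picking a
large set whose apparent advantage is within noise.

The categorical response is either the storage timepoint or the derived
storage-stability class: batches (cultivar x soil) are split into
short/medium/long storers by tertiles of their days-from-harvest-to-sprouting.
"""

from __future__ import annotations

import dataclasses
import math
import zlib

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                      _get_n_samples_bootstrap)

from .filtering import relative_abundance
from .io_tables import CountTable, StudyMetadata, ValidationError


def oob_permutation_importance(forest: RandomForestClassifier,
                               x: np.ndarray, y: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """Unscaled mean-decrease-in-accuracy importance (randomForest type=1).

    For every feature, its values are permuted within each tree's out-of-bag
    samples and the drop in that tree's OOB accuracy is averaged over trees.
    Only trees that actually split on the feature are re-evaluated, which
    makes this cheap on wide tables where each feature enters few trees.
    """
    n_samples, n_features = x.shape
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    y_codes = np.searchsorted(forest.classes_, y)
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples,
                                      sample_weight=None)

    def tree_pred_codes(tree, rows: np.ndarray) -> np.ndarray:
        # low-level predict: leaf class distributions -> argmax code
        out = tree.tree_.predict(rows)
        return out.reshape(rows.shape[0], -1).argmax(axis=1)

    importances = np.zeros(n_features)
    n_trees = len(forest.estimators_)
    for est in forest.estimators_:
        idx = _generate_unsampled_indices(est.random_state, n_samples,
                                          n_boot, sample_weight=None)
        if idx.size == 0:
            continue
        x_oob = x32[idx]
        y_oob = y_codes[idx]
        base = (tree_pred_codes(est, x_oob) == y_oob).sum()
        feats = np.unique(est.tree_.feature[est.tree_.feature >= 0])
        if feats.size == 0:
            continue
        n = idx.size
        # one batched prediction per tree: block k holds the OOB rows with
        # feature feats[k] permuted
        big = np.tile(x_oob, (feats.size, 1))
        for k, j in enumerate(feats):
            big[k * n:(k + 1) * n, j] = x_oob[rng.permutation(n), j]
        pred = tree_pred_codes(est, big).reshape(feats.size, n)
        correct = (pred == y_oob).sum(axis=1)
        importances[feats] += (base - correct) / n
    return importances / n_trees


@dataclasses.dataclass
class StabilityGrouping:
    stability_class: pd.Series  # per sample: short / medium / long
    cut_points: tuple[float, float]
    method: str = "tertiles"


@dataclasses.dataclass
class RfSelectionResult:
    """Backward-elimination trajectory and the selected OTU set."""

    elimination_path: list[tuple[int, float]]  # (n_otus, oob_error)
    selected_otu_ids: list[str]
    importance_rank: dict[str, int]  # selected otu -> rank (1 = top)
    params: dict

    def __post_init__(self) -> None:
        sizes = [s for s, _ in self.elimination_path]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("elimination path sizes must be "
                                  "strictly decreasing")
        if len(self.selected_otu_ids) not in sizes:
            raise ValidationError("selected set size absent from path")
        if any(not 0 <= e <= 1 for _, e in self.elimination_path):
            raise ValidationError("OOB errors must lie in [0, 1]")


def assign_stability_classes(meta: StudyMetadata, method: str = "tertiles",
                             cut_points: tuple[float, float] | None = None
                             ) -> StabilityGrouping:
    """Label samples short/medium/long by their batch's storage days.

    Tertile cut points are computed on the *distinct batch-level* storage-day
    values so replicates (and timepoints) of one batch always share a class.
    Ties at a cut point go to the lower class; the lowest tertile (earliest
    sprouting) is "short".
    """
    days = meta.storage_days
    if method == "tertiles":
        distinct = np.unique(meta.batches()["storage_days"].to_numpy())
        if distinct.size < 3:
            raise ValidationError(
                "need >= 3 distinct storage_days values for tertiles")
        lo, hi = np.quantile(distinct, [1 / 3, 2 / 3])
    elif method == "manual":
        if cut_points is None:
            raise ValueError("manual method requires cut_points")
        lo, hi = cut_points
        if not lo <= hi:
            raise ValueError("cut_points must be ordered")
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = pd.Series(
        np.where(days <= lo, "short",
                 np.where(days <= hi, "medium", "long")),
        index=days.index, name="stability_class")
    return StabilityGrouping(labels, (float(lo), float(hi)), method)


def rf_select(table: CountTable, response, n_trees: int = 2000,
              drop_fraction: float = 0.2, se_multiplier: float = 1.0,
              seed: int = 0, recompute_importances: bool = False,
              use_relative_abundance: bool = True,
              importance: str = "permutation",
              n_trees_iterat: int | None = None) -> RfSelectionResult:
    """varSelRF-style backward elimination on a (filtered) count table.

    Importances (``importance="permutation"``: unscaled OOB mean decrease in
    accuracy, as in randomForest/varSelRF; ``"impurity"``: Gini) are taken
    from the initial ``n_trees``-tree fit and reused while eliminating
    (avoiding selection bias), unless ``recompute_importances``.  Refits
    along the path use ``n_trees_iterat`` trees (default: same as the
    initial forest; varSelRF analogously iterates with fewer trees than it
    ranks with).  The path stops at 2 OTUs; the smallest set with
    ``OOB <= min(OOB) + se_multiplier * SE(min)`` is selected,
    ``SE = sqrt(e(1-e)/n)``.
    """
    if importance not in ("permutation", "impurity"):
        raise ValueError(f"unknown importance {importance!r}")
    if n_trees_iterat is None:
        n_trees_iterat = n_trees
    y = np.asarray(response)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("response must have >= 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValidationError(f"class(es) with < 2 samples: {small}")
    x_full = relative_abundance(table) if use_relative_abundance \
        else table.counts.astype(float)
    otu_ids = list(table.otu_ids)
    n = len(table.sample_ids)
    rng = np.random.default_rng(seed)

    def fit(x: np.ndarray, n_est: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_est, oob_score=True, bootstrap=True,
            random_state=int(rng.integers(2 ** 31)), n_jobs=1,
        ).fit(x, y)

    def importances(model: RandomForestClassifier, x: np.ndarray
                    ) -> np.ndarray:
        if importance == "impurity":
            return model.feature_importances_
        return oob_permutation_importance(model, x, y, rng)

    active = np.arange(len(otu_ids))
    model = fit(x_full, n_trees)
    order = np.argsort(importances(model, x_full))[::-1]  # best first
    rank_of = {otu_ids[j]: r + 1 for r, j in enumerate(order)}
    path: list[tuple[int, float]] = [(active.size,
                                      float(1.0 - model.oob_score_))]
    sets: list[np.ndarray] = [active.copy()]
    ranking = order.copy()  # indices into otu_ids, most important first
    while active.size > 2:
        n_drop = math.ceil(drop_fraction * active.size)
        new_size = max(active.size - n_drop, 2)
        keep = ranking[:new_size]
        active = np.sort(keep)
        model = fit(x_full[:, active], n_trees_iterat)
        if recompute_importances:
            sub_order = np.argsort(importances(model,
                                               x_full[:, active]))[::-1]
            ranking = active[sub_order]
        else:
            ranking = ranking[:new_size]
        path.append((active.size, float(1.0 - model.oob_score_)))
        sets.append(active.copy())

    errs = np.array([e for _, e in path])
    e_min = errs.min()
    se = math.sqrt(e_min * (1 - e_min) / n)
    threshold = e_min + se_multiplier * se
    admissible = np.flatnonzero(errs <= threshold + 1e-12)
    best = admissible[np.argmin([sets[k].size for k in admissible])]
    selected = [otu_ids[j] for j in sets[best]]
    return RfSelectionResult(
        elimination_path=path,
        selected_otu_ids=selected,
        importance_rank={o: rank_of[o] for o in selected},
        params={"n_trees": n_trees, "n_trees_iterat": n_trees_iterat,
                "drop_fraction": drop_fraction,
                "se_multiplier": se_multiplier, "seed": seed,
                "importance": importance,
                "recompute_importances": recompute_importances},
    )


def rf_select_strata(table: CountTable, meta: StudyMetadata, response,
                     strata: pd.Series | None = None, **kwargs
                     ) -> tuple[set[str], dict[str, list[str]],
                                dict[str, int]]:
    """Run :func:`rf_select` within each stratum and pool by union.

    Returns the pooled selected-OTU set, a per-OTU record of the strata that
    selected it, and a pooled importance rank (the best rank across strata).
    """
    response = pd.Series(np.asarray(response), index=table.sample_ids)
    if strata is None:
        groups = {"all": list(table.sample_ids)}
    else:
        strata = pd.Series(np.asarray(strata), index=table.sample_ids)
        groups = {str(k): list(v) for k, v in
                  strata.groupby(strata).groups.items()}
    pooled: set[str] = set()
    origin: dict[str, list[str]] = {}
    rank: dict[str, int] = {}
    base_seed = int(kwargs.pop("seed", 0))
    for name, sample_ids in sorted(groups.items()):
        sub = table.select_samples(sample_ids)
        # independent randomness per stratum so the pooled union is not
        # tied to one forest realisation
        stratum_seed = (base_seed ^ zlib.crc32(str(name).encode())) \
            % (2 ** 31)
        res = rf_select(sub, response.loc[sample_ids].to_numpy(),
                        seed=stratum_seed, **kwargs)
        for otu in res.selected_otu_ids:
            pooled.add(otu)
            origin.setdefault(otu, []).append(name)
            r = res.importance_rank[otu]
            rank[otu] = min(rank.get(otu, r), r)
    return pooled, origin, rank
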