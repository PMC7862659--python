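"""Key-OTU identification: intersection of the two selection routes.

An rOTU is a *key OTU* when it is selected by the random-forest
backward-elimination route AND it carries at least one surviving edge in the
thresholded Spearman network.  A key OTU with a direct edge to the
storage-days node inherits that edge's sign: positive rho means the taxon is
enriched in long-storing batches ("long"), negative rho in early sprouters
("short").  Key OTUs connected only to other taxa are labelled by the
stability class in which their mean relative abundance peaks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .corr_network import STORAGE_NODE, CorrelationNetwork
from .filtering import relative_abundance
from .io_tables import CountTable, KeyOtu, ValidationError


def class_mean_abundance(table: CountTable, stability_class: pd.Series
                         ) -> pd.DataFrame:
    """Mean relative abundance of every OTU per stability class
    (classes x OTUs)."""
    relab = pd.DataFrame(relative_abundance(table), index=table.sample_ids,
                         columns=table.otu_ids)
    cls = pd.Series(np.asarray(stability_class), index=table.sample_ids)
    return relab.groupby(cls).mean()


def assign_direction(r_storage: float, class_means: pd.Series | None = None
                     ) -> str | None:
    """Direction label for one key OTU.

    The sign of the storage-node correlation takes precedence; without a
    storage edge the class with maximal mean relative abundance decides.
    """
    if r_storage > 0:
        return "long"
    if r_storage < 0:
        return "short"
    if class_means is None or class_means.empty:
        warnings.warn("no storage edge and no class means: direction unset",
                      stacklevel=2)
        return None
    if class_means.nunique() == 1:
        warnings.warn("all class means equal: direction unset", stacklevel=2)
        return None
    return str(class_means.idxmax())


def intersect_key_otus(rf_selected: "set[str] | list[str]",
                       net: CorrelationNetwork,
                       rf_rank: dict[str, int] | None = None,
                       table: CountTable | None = None,
                       stability_class: pd.Series | None = None,
                       taxonomy: dict[str, str] | None = None,
                       storage_edge_only: bool = False) -> list[KeyOtu]:
    """Intersect the RF-selected set with the network-connected set.

    Parameters
    ----------
    rf_selected
        Pooled OTU ids from the random-forest route.
    net
        Thresholded correlation network over the same rOTU universe.
    storage_edge_only
        Restrict "connected" to OTUs directly linked to the storage node
        (default: any surviving edge counts).
    table, stability_class
        When provided, key OTUs without a storage edge are direction-labelled
        by their class of maximal mean relative abundance.

    Output is ordered by \\|r_storage\\| descending, then RF importance rank.
    """
    rf_selected = set(rf_selected)
    universe = set(net.node_ids) - {STORAGE_NODE}
    stray = rf_selected - universe
    if stray:
        raise ValidationError(
            f"RF-selected OTUs absent from the network universe: "
            f"{sorted(stray)}")
    storage = net.storage_edges()
    connected = (set(storage) if storage_edge_only
                 else net.connected_nodes() - {STORAGE_NODE})
    hits = rf_selected & connected

    means = None
    if table is not None and stability_class is not None:
        means = class_mean_abundance(table, stability_class)
    out = []
    for otu in sorted(hits):
        r_s, p_s = storage.get(otu, (0.0, 1.0))
        cm = means[otu] if means is not None and otu in means.columns else None
        direction = assign_direction(r_s, cm)
        out.append(KeyOtu(
            otu_id=otu, direction=direction or "unset",
            r_storage=float(r_s), p_storage=float(p_s),
            rf_importance_rank=int(rf_rank.get(otu, 0)) if rf_rank else 0,
            taxonomy=(taxonomy or {}).get(otu, ""),
            evidence=frozenset({"rf", "network"})))
    out.sort(key=lambda k: (-abs(k.r_storage), k.rf_importance_rank,
                            k.otu_id))
    for k in out:  # both evidence routes by construction; assert on output
        assert k.evidence == frozenset({"rf", "network"})
    return out
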