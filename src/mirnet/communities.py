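"""Louvain communities on the MI network, degree statistics, DEM integration.

Community detection greedily optimizes the weighted Newman-Girvan modularity

    Q = sum_c [ w_c / W  -  gamma * (s_c / 2W)^2 ]

where w_c is the intra-community edge weight, s_c the summed strength of the
community's nodes, W the total edge weight and gamma the resolution (default
1, the value used throughout).  The number of communities is determined by the
optimization itself.  Per-node degree statistics (weighted = summed incident
MI, unweighted = incident edge count) are placed against the quartiles of the
node's own community, and DEM lists are matched to communities by maximum
overlap with a hypergeometric enrichment p as supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import MINetwork


@dataclass
class CommunityPartition:
    """node -> community id (consecutive ints), with modularity and sizes."""

    membership: pd.Series
    modularity: float
    resolution: float = 1.0
    sizes: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def communities(self) -> dict:
        return {c: set(idx) for c, idx in self.membership.groupby(self.membership).groups.items()}


def louvain(
    network: MINetwork,
    resolution: float = 1.0,
    seed: int | None = 0,
    n_restarts: int = 8,
) -> CommunityPartition:
    """Louvain community detection on the MI-weighted graph.

    Node moves and aggregation passes stop when no reassignment improves Q;
    the seed fixes the node visiting order, making the partition reproducible.
    The greedy optimizer can stall in a merged local optimum, so the search is
    restarted ``n_restarts`` times from seed-derived visiting orders and the
    highest-modularity partition is kept.  Community ids are consecutive
    integers ordered by decreasing size.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    sub_seeds = np.random.SeedSequence(seed).generate_state(max(n_restarts, 1))
    best, best_q = None, -np.inf
    for sub in sub_seeds:
        cand = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=int(sub % (2**31))
        )
        q = nx.community.modularity(g, cand, weight="weight", resolution=resolution)
        if q > best_q:
            best, best_q = cand, q
    comms = sorted(best, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    membership = pd.Series(
        {node: cid for cid, members in enumerate(comms) for node in members},
        name="community",
    ).loc[list(network.nodes)]
    part = CommunityPartition(
        membership=membership,
        modularity=0.0,
        resolution=resolution,
        sizes=membership.value_counts().sort_index(),
    )
    part.modularity = modularity(network, part.membership, gamma=resolution)
    return part


def modularity(network: MINetwork, membership: pd.Series, gamma: float = 1.0) -> float:
    """Weighted modularity Q = sum_c [w_c/W - gamma (s_c/2W)^2].

    Edge weights are the MI values.  An edgeless graph has Q = 0 by
    convention (no weight to partition).
    """
    missing = [n for n in network.nodes if n not in membership.index]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    edges = network.edges
    w_total = edges["mi"].sum()
    if w_total == 0:
        return 0.0
    strength: dict = {n: 0.0 for n in network.nodes}
    intra: dict = {}
    for src, tgt, w in edges[["source", "target", "mi"]].itertuples(index=False):
        strength[src] += w
        strength[tgt] += w
        if membership[src] == membership[tgt]:
            intra[membership[src]] = intra.get(membership[src], 0.0) + w
    q = 0.0
    for c in membership.unique():
        s_c = sum(strength[n] for n in membership.index[membership == c] if n in strength)
        q += intra.get(c, 0.0) / w_total - gamma * (s_c / (2.0 * w_total)) ** 2
    return float(q)


QUARTILE_LABELS = ("below_median", "median_to_upper", "above_upper_quartile")


def node_degrees(network: MINetwork, partition: CommunityPartition) -> pd.DataFrame:
    """Weighted/unweighted node degrees with within-community quartile labels.

    The weighted degree of a node is the summed MI of its incident edges; the
    unweighted degree is the edge count.  Each node is placed against its own
    community's degree distribution (linear-interpolation quartiles): strictly
    above Q3 -> ``above_upper_quartile``, strictly below the median ->
    ``below_median``, otherwise ``median_to_upper``.
    """
    weighted = pd.Series(0.0, index=list(network.nodes))
    unweighted = pd.Series(0, index=list(network.nodes), dtype=int)
    for src, tgt, w in network.edges[["source", "target", "mi"]].itertuples(index=False):
        weighted[src] += w
        weighted[tgt] += w
        unweighted[src] += 1
        unweighted[tgt] += 1
    out = pd.DataFrame(
        {
            "weighted_degree": weighted,
            "unweighted_degree": unweighted,
            "community": partition.membership.loc[weighted.index],
        }
    )
    for col, label in [("weighted_degree", "weighted_quartile"),
                       ("unweighted_degree", "unweighted_quartile")]:
        labels = pd.Series(index=out.index, dtype=object)
        for _, block in out.groupby("community"):
            vals = block[col].to_numpy(dtype=float)
            med, q3 = np.quantile(vals, [0.5, 0.75])
            lab = np.where(
                block[col] > q3,
                QUARTILE_LABELS[2],
                np.where(block[col] < med, QUARTILE_LABELS[0], QUARTILE_LABELS[1]),
            )
            labels.loc[block.index] = lab
        out[label] = labels
    return out


def integrate_dems(partition: CommunityPartition, dem_sets: dict):
    """Match DEM lists against communities by maximum overlap.

    Returns ``(overlaps, summary)``: the long table of per-(DEM set,
    community) overlap counts with hypergeometric enrichment p (universe =
    network nodes), and a per-set summary naming the max-overlap community
    (ties broken by smaller community, then lower id).  Sets disjoint from the
    network are flagged.
    """
    membership = partition.membership
    nodes = set(membership.index)
    n_universe = len(nodes)
    comms = partition.communities()
    rows = []
    summary = []
    for name, dems in dem_sets.items():
        in_net = set(dems) & nodes
        best = None
        for cid, members in sorted(comms.items()):
            k = len(in_net & members)
            p = stats.hypergeom.sf(k - 1, n_universe, len(members), len(in_net)) if in_net else 1.0
            rows.append(
                {"dem_set": name, "community": cid, "overlap": k,
                 "community_size": len(members), "p": float(p)}
            )
            key = (-k, len(members), cid)
            if k > 0 and (best is None or key < best[0]):
                best = (key, cid, k)
        summary.append(
            {
                "dem_set": name,
                "n_in_network": len(in_net),
                "max_overlap_community": best[1] if best else None,
                "max_overlap": best[2] if best else 0,
                "disjoint": len(in_net) == 0,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(summary)
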