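"""Bipartite network construction, degree statistics, and herb roles.

The compound-target (C-T) network connects each candidate compound to its
accepted protein targets; compounds with no accepted target are dropped
and reported.  The target-pathway (T-P) network connects targets to the
gene sets containing them.  The only centrality used anywhere is degree.

Herb-level aggregates (active-compound count, summed compound degree,
mean targets per compound) drive a formalisation of the traditional
Jun-Chen-Zuo-Shi prescription roles: the top herb by (compound count,
total degree) is the monarch (jun), the next tier the ministers (chen),
and the remainder the merged assistant/guide tier (zuo_shi).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .core_model_io import (
    BipartiteNetwork,
    CompoundRecord,
    GeneSetCollection,
    InteractionScore,
    ValidationError,
)

__all__ = [
    "HerbAggregate",
    "RoleAssignment",
    "NetworkSummary",
    "build_ct_network",
    "node_degree",
    "herb_aggregates",
    "classify_roles",
    "build_tp_network",
    "network_summary",
]


@dataclass
class HerbAggregate:
    herb_id: str
    n_active_compounds: int
    total_degree: int

    @property
    def mean_targets_per_compound(self) -> float:
        if self.n_active_compounds == 0:
            return 0.0
        return self.total_degree / self.n_active_compounds


@dataclass
class RoleAssignment:
    herb_id: str
    role: Literal["jun", "chen", "zuo_shi"]
    rank: int
    tied: bool = False


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_left: int
    n_right: int
    mean_degree_left: float
    mean_degree_right: float


def build_ct_network(
    candidates: Sequence[CompoundRecord],
    accepted: Iterable[InteractionScore],
) -> tuple[BipartiteNetwork, list[str]]:
    """Compound-target network from accepted interactions.

    Returns the network plus the ids of candidate compounds with no
    accepted target (excluded from the node set).  Duplicate accepted
    pairs collapse to one edge with a warning; targets appear only when
    incident to at least one edge.
    """
    by_id = {c.compound_id: c for c in candidates}
    edges: set[tuple[str, str]] = set()
    n_dupes = 0
    for s in accepted:
        if s.compound_id not in by_id:
            raise ValidationError(
                f"accepted pair references unknown compound: {s.compound_id}"
            )
        e = (s.compound_id, s.target_id)
        if e in edges:
            n_dupes += 1
        edges.add(e)
    if n_dupes:
        warnings.warn(f"collapsed {n_dupes} duplicate accepted pair(s)")
    connected = {u for u, _ in edges}
    dropped = sorted(cid for cid in by_id if cid not in connected)
    net = BipartiteNetwork(
        left_kind="compound",
        right_kind="target",
        left_nodes=set(connected),
        right_nodes={v for _, v in edges},
        edges=edges,
        node_meta={
            cid: {"herb_id": by_id[cid].herb_id} for cid in connected
        },
        relation="targets",
    )
    net.validate()
    return net, dropped


def node_degree(net: BipartiteNetwork, node_id: str) -> int:
    """Number of edges incident to ``node_id`` (KeyError if unknown)."""
    return net.degree(node_id)


def herb_aggregates(
    net: BipartiteNetwork, all_herbs: Optional[Iterable[str]] = None
) -> list[HerbAggregate]:
    """Per-herb compound counts and summed compound degrees.

    Compound nodes must carry ``herb_id`` metadata.  Herbs listed in
    ``all_herbs`` but absent from the network are reported with zero
    counts.  Output is sorted by herb_id.
    """
    degs = net.degrees()
    stats: dict[str, list[int]] = {}
    for cid in net.left_nodes:
        meta = net.node_meta.get(cid, {})
        if "herb_id" not in meta:
            raise ValidationError(f"compound node {cid} missing herb_id metadata")
        h = meta["herb_id"]
        bucket = stats.setdefault(h, [0, 0])
        bucket[0] += 1
        bucket[1] += degs[cid]
    if all_herbs is not None:
        for h in all_herbs:
            stats.setdefault(h, [0, 0])
    return [
        HerbAggregate(herb_id=h, n_active_compounds=c, total_degree=d)
        for h, (c, d) in sorted(stats.items())
    ]


def classify_roles(
    aggs: Sequence[HerbAggregate], chen_fraction: float = 0.35
) -> list[RoleAssignment]:
    """Rank herbs and assign Jun-Chen-Zuo-Shi prescription roles.

    Herbs are sorted by (n_active_compounds, total_degree) descending,
    ties broken by herb_id.  Rank 1 is jun; the next
    ceil(chen_fraction * (H - 1)) herbs are chen; the rest zuo_shi
    (assistant and guide are not computationally separable and are
    merged).  With 20 herbs and the default fraction this yields the
    familiar 1 / 7 / 12 split.  Tied herbs are flagged.
    """
    if not aggs:
        raise ValueError("no herb aggregates to classify")
    if not 0.0 <= chen_fraction <= 1.0:
        raise ValueError("chen_fraction must be in [0, 1]")
    key = lambda a: (-a.n_active_compounds, -a.total_degree, a.herb_id)
    ranked = sorted(aggs, key=key)
    sort_keys = [(a.n_active_compounds, a.total_degree) for a in ranked]
    h = len(ranked)
    n_chen = math.ceil(chen_fraction * (h - 1))
    out = []
    for i, a in enumerate(ranked):
        role = "jun" if i == 0 else "chen" if i <= n_chen else "zuo_shi"
        tied = (i > 0 and sort_keys[i] == sort_keys[i - 1]) or (
            i + 1 < h and sort_keys[i] == sort_keys[i + 1]
        )
        out.append(RoleAssignment(herb_id=a.herb_id, role=role, rank=i + 1,
                                  tied=tied))
    return out


def build_tp_network(
    targets: Iterable[str], pathways: GeneSetCollection
) -> tuple[BipartiteNetwork, int]:
    """Target-pathway network: edge (t, P) iff t is annotated to P.

    Targets in no pathway are excluded from the node set.  Also returns
    the number of targets appearing in two or more pathways.
    """
    targets = set(targets)
    edges = {
        (t, term)
        for term, members in pathways.sets.items()
        for t in targets & members
    }
    per_target: dict[str, int] = {}
    for t, _ in edges:
        per_target[t] = per_target.get(t, 0) + 1
    net = BipartiteNetwork(
        left_kind="target",
        right_kind="pathway",
        left_nodes=set(per_target),
        right_nodes={p for _, p in edges},
        edges=edges,
        relation="participates_in",
    )
    net.validate()
    multi = sum(1 for c in per_target.values() if c >= 2)
    return net, multi


def network_summary(net: BipartiteNetwork) -> NetworkSummary:
    """Node/edge counts and per-part mean degrees."""
    n_l, n_r, n_e = len(net.left_nodes), len(net.right_nodes), len(net.edges)
    return NetworkSummary(
        n_nodes=n_l + n_r,
        n_edges=n_e,
        n_left=n_l,
        n_right=n_r,
        mean_degree_left=n_e / n_l if n_l else 0.0,
        mean_degree_right=n_e / n_r if n_r else 0.0,
    )
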