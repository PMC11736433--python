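"""Topology of enhancer networks: modules, hubs, and pair statistics.

Modules are Louvain communities on the weighted PEI graph. A network is
"modular" when at least two modules of size >= 2 exist; enhancer pairs of a
modular network are then Intra (same module) or Inter (different modules),
the distinction that carries the additive-versus-synergistic contrast.
Hub enhancers are those in the genome-wide top tier of degree normalized by
the size of their network (network hubs) or module (module hubs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network_construction import EnhancerNetwork

__all__ = [
    "ModulePartition",
    "HubTable",
    "detect_modules",
    "is_modular",
    "classify_pairs",
    "network_connectivity",
    "rank_hubs",
    "betweenness",
    "tf_cosine_similarity",
    "pair_mutual_information",
]


@dataclass
class ModulePartition:
    """A node -> dense-integer module assignment for one network."""

    gene_id: str
    assignment: dict[str, int]
    modularity: float = float("nan")

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module_id: int) -> set[str]:
        return {n for n, m in self.assignment.items() if m == module_id}

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class HubTable:
    """Normalized-degree table with a deterministic top-K hub flag."""

    scores: dict[str, float]
    ranks: dict[str, int]
    hubs: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peak": p,
                "normalized_degree": self.scores[p],
                "rank": self.ranks[p],
                "hub": p in self.hubs,
            }
            for p in sorted(self.scores, key=lambda q: self.ranks[q])
        ]
        return pd.DataFrame(rows)


def detect_modules(
    net: EnhancerNetwork, resolution: float = 1.0, seed: int = 7
) -> ModulePartition:
    """Louvain communities on the weighted graph.

    Node order is canonicalized by peak id and the seed fixed, so the
    partition is deterministic. Isolated nodes fall out as singleton
    modules; module ids are dense integers ordered by smallest member id.
    """
    if net.size == 0:
        raise ValueError("cannot partition an empty network")
    g = net.to_networkx()
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    assignment = {n: i for i, c in enumerate(comms) for n in c}
    mod = (
        nx.community.modularity(g, comms, weight="weight")
        if g.number_of_edges() > 0
        else float("nan")
    )
    return ModulePartition(net.gene_id, assignment, mod)


def is_modular(p: ModulePartition, min_module_size: int = 2) -> bool:
    """True iff at least two modules have size >= ``min_module_size``."""
    big = [s for s in p.module_sizes().values() if s >= min_module_size]
    return len(big) >= 2


def classify_pairs(
    p: ModulePartition, min_module_size: int = 2
) -> dict[tuple[str, str], str]:
    """Label unordered node pairs Intra/Inter within a modular network.

    Nodes in modules smaller than ``min_module_size`` are discarded before
    pairing. Raises on non-modular networks, where the contrast is undefined.
    """
    if not is_modular(p, min_module_size):
        raise ValueError("pair classification requires a modular network")
    sizes = p.module_sizes()
    kept = sorted(n for n, m in p.assignment.items() if sizes[m] >= min_module_size)
    out = {}
    for a, b in combinations(kept, 2):
        same = p.assignment[a] == p.assignment[b]
        out[(a, b)] = "Intra" if same else "Inter"
    return out


def network_connectivity(net: EnhancerNetwork, definition: str = "mean_degree") -> float:
    """The network score: mean degree 2E/N by default (``definition="edge_density"``
    gives E/N). Edgeless networks score 0; empty networks are an error."""
    if net.size == 0:
        raise ValueError("connectivity undefined for an empty network")
    if definition == "mean_degree":
        return 2.0 * net.n_edges / net.size
    if definition == "edge_density":
        return net.n_edges / net.size
    raise ValueError(f"unknown connectivity definition {definition!r}")


def _normalized_degrees(
    networks: Iterable[EnhancerNetwork],
    scope: str,
    partitions: Mapping[str, ModulePartition] | None,
) -> dict[str, float]:
    best: dict[str, float] = {}
    for net in networks:
        if scope == "network":
            groups = [set(net.nodes)]
        else:
            if partitions is None or net.gene_id not in partitions:
                raise ValueError("module scope requires a partition per network")
            part = partitions[net.gene_id]
            groups = [part.members(m) for m in set(part.assignment.values())]
        deg = net.degree()
        for group in groups:
            n = len(group)
            for node in group:
                if n <= 1:
                    score = 0.0
                else:
                    within = sum(
                        1
                        for (a, b) in net.edges
                        if (a == node and b in group) or (b == node and a in group)
                    )
                    score = within / (n - 1)
                best[node] = max(best.get(node, 0.0), score)
    return best


def rank_hubs(
    networks: Sequence[EnhancerNetwork],
    scope: str = "network",
    K: int | float = 5000,
    partitions: Mapping[str, ModulePartition] | None = None,
) -> HubTable:
    """Flag the top-K enhancers by normalized degree.

    Normalized degree is degree/(N-1) with N the node count of the
    enhancer's network (``scope="network"``) or module (``scope="module"``,
    counting only within-module edges). An enhancer appearing in several
    networks keeps its maximum. ``K`` may be a fraction in (0, 1), read as
    the top quantile — convenient for small synthetic peak universes where
    the genome-wide default of 5000 is meaningless. Ties break by
    (score desc, peak id asc).
    """
    if scope not in {"network", "module"}:
        raise ValueError("scope must be 'network' or 'module'")
    scores = _normalized_degrees(networks, scope, partitions)
    if not scores:
        return HubTable({}, {}, set())
    if 0 < K < 1:
        k = max(1, int(round(K * len(scores))))
    else:
        k = int(K)
    if k < 1:
        raise ValueError("K must be >= 1")
    ordered = sorted(scores, key=lambda p: (-scores[p], p))
    if k > len(ordered):
        warnings.warn(f"K={k} exceeds the {len(ordered)} scored enhancers; flagging all")
        k = len(ordered)
    ranks = {p: i + 1 for i, p in enumerate(ordered)}
    return HubTable(scores, ranks, set(ordered[:k]))


def betweenness(net: EnhancerNetwork) -> dict[str, float]:
    """Shortest-path betweenness centrality on the unweighted graph,
    normalized by (N-1)(N-2)/2 so values lie in [0, 1]."""
    g = net.to_networkx()
    return {
        n: float(v)
        for n, v in nx.betweenness_centrality(g, normalized=True, weight=None).items()
    }


def tf_cosine_similarity(
    tf_matrix: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Cosine similarity of binary TF-binding vectors for enhancer pairs.

    ``tf_matrix`` is enhancers x TFs with 0/1 entries. Pairs involving an
    all-zero vector score 0; enhancers missing from the matrix are an error.
    """
    vals = tf_matrix.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("TF matrix must be binary")
    norms = np.linalg.norm(vals, axis=1)
    idx = {e: i for i, e in enumerate(tf_matrix.index)}
    out = {}
    for a, b in pairs:
        if a not in idx or b not in idx:
            missing = a if a not in idx else b
            raise KeyError(f"enhancer {missing!r} missing from the TF matrix")
        na, nb = norms[idx[a]], norms[idx[b]]
        if na == 0 or nb == 0:
            out[(a, b)] = 0.0
        else:
            out[(a, b)] = float(vals[idx[a]] @ vals[idx[b]] / (na * nb))
    return out


def pair_mutual_information(
    acc, pairs: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Mutual information (bits) of binarized accessibility for peak pairs.

    The plug-in estimate from the 2x2 joint table across cells; a
    zero-variance feature yields MI 0.
    """
    B = acc.binarized()
    X = B.X.toarray()
    col = {f: i for i, f in enumerate(B.features)}
    out = {}
    for a, b in pairs:
        x, y = X[:, col[a]].astype(int), X[:, col[b]].astype(int)
        out[(a, b)] = _binary_mi(x, y)
    return out


def _binary_mi(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mi = 0.0
    for xv in (0, 1):
        px = np.mean(x == xv)
        for yv in (0, 1):
            py = np.mean(y == yv)
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0 and px > 0 and py > 0:
                mi += pxy * np.log2(pxy / (px * py))
    return float(max(mi, 0.0))
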