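"""Per-gene enhancer network construction.

A gene's enhancer network is built in two stages. First, candidate peaks
within +/-100 kb of the TSS are linked to the gene by Pearson correlation
between peak accessibility and gene expression across metacells, with an
empirical permutation p-value and BH correction within the gene. Second,
linked enhancers become nodes, and enhancer pairs whose co-accessibility
exceeds a threshold become edges (predicted enhancer interactions, PEIs).
Condition- or stage-specific networks share one node set (computed from
pooled cells) and carry condition-specific edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coaccessibility import CoaccessibilityMap, MetacellMatrix
from .io_core import GeneAnnotation, PeakSet, peaks_in_window

__all__ = [
    "EnhancerGeneLink",
    "EnhancerNetwork",
    "link_enhancers_to_gene",
    "build_network",
    "build_condition_networks",
    "write_networks",
    "read_networks",
]


@dataclass(frozen=True)
class EnhancerGeneLink:
    gene_id: str
    peak_id: str
    pearson_r: float
    fdr: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr outside [0, 1]")


@dataclass
class EnhancerNetwork:
    """A gene's enhancer graph: linked peaks as nodes, PEIs as edges."""

    gene_id: str
    nodes: set[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    condition: str | None = None
    usable: bool = True

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) endpoint outside the node set")

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), w in sorted(self.edges.items()):
            g.add_edge(a, b, weight=w)
        return g


def link_enhancers_to_gene(
    expr: MetacellMatrix,
    acc: MetacellMatrix,
    gene: GeneAnnotation,
    peaks: PeakSet,
    flank: int = 100_000,
    r_min: float = 0.1,
    fdr_max: float = 0.05,
    n_shuffle: int = 100,
    seed: int = 0,
) -> list[EnhancerGeneLink]:
    """Correlate candidate peaks with a gene's expression across metacells.

    Candidates are peaks overlapping the TSS +/- ``flank`` window. For each
    candidate, the Pearson r is tested against ``n_shuffle`` metacell
    permutations of the expression vector (one-sided, r > 0, since only
    positively correlated enhancers become network nodes); p-values are
    BH-adjusted within the gene and links with ``r > r_min`` and
    ``fdr < fdr_max`` are returned.
    """
    if expr.metacells != acc.metacells:
        raise ValueError("expression and accessibility use different metacells")
    if gene.gene_id not in expr.features:
        raise ValueError(f"gene {gene.gene_id!r} absent from the expression matrix")
    candidates = peaks_in_window(peaks, gene.tss, flank)
    candidates = [p for p in candidates if p in acc.features]
    if not candidates:
        return []
    y = expr.X[:, expr.features.index(gene.gene_id)].astype(float)
    if y.std() == 0:
        warnings.warn(f"gene {gene.gene_id} has zero expression variance; no links")
        return []
    col = {f: i for i, f in enumerate(acc.features)}
    A = acc.X[:, [col[p] for p in candidates]].astype(float)
    n = len(y)
    yz = (y - y.mean()) / y.std()
    sd = A.std(axis=0)
    ok = sd > 0
    Az = np.zeros_like(A)
    Az[:, ok] = (A[:, ok] - A.mean(axis=0)[ok]) / sd[ok]
    r_obs = Az.T @ yz / n
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(candidates))
    for _ in range(n_shuffle):
        r_perm = Az.T @ yz[rng.permutation(n)] / n
        exceed += r_perm >= r_obs
    pvals = (1.0 + exceed) / (1.0 + n_shuffle)
    pvals[~ok] = 1.0
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    links = []
    for pid, r, q, good in zip(candidates, r_obs, fdrs, ok):
        if good and r > r_min and q < fdr_max:
            links.append(
                EnhancerGeneLink(gene.gene_id, pid, float(np.clip(r, -1, 1)), float(q))
            )
    return links


def build_network(
    links: Sequence[EnhancerGeneLink],
    cmap: CoaccessibilityMap,
    pei_threshold: float = 0.2,
) -> EnhancerNetwork:
    """Nodes from gene links; edges where co-accessibility strictly exceeds
    ``pei_threshold``. Isolated nodes are retained (size-1 networks exist)."""
    if not links:
        raise ValueError("cannot build a network from an empty link list")
    gene_id = links[0].gene_id
    nodes = {lk.peak_id for lk in links}
    ordered = sorted(nodes)
    edges = {}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            c = cmap.get(a, b)
            if c > pei_threshold:
                edges[(a, b)] = c
    return EnhancerNetwork(gene_id, nodes, edges, condition=cmap.condition)


def build_condition_networks(
    links: Sequence[EnhancerGeneLink],
    condition_maps: Mapping[str, CoaccessibilityMap],
    pei_threshold: float = 0.2,
    min_metacells: int = 3,
    metacell_counts: Mapping[str, int] | None = None,
) -> dict[str, EnhancerNetwork]:
    """One network per condition with a shared node set.

    The node set comes from ``links`` (computed once from pooled cells);
    edges are condition-specific. A condition backed by fewer than
    ``min_metacells`` metacells (when counts are supplied) is flagged
    unusable rather than silently trusted.
    """
    out: dict[str, EnhancerNetwork] = {}
    for cond, cmap in condition_maps.items():
        net = build_network(links, cmap, pei_threshold=pei_threshold)
        net.condition = cond
        if metacell_counts is not None and metacell_counts.get(cond, 0) < min_metacells:
            net.usable = False
            warnings.warn(f"condition {cond!r} has <{min_metacells} metacells")
        out[cond] = net
    return out


def write_networks(networks: Iterable[EnhancerNetwork], edge_path: str | Path, node_path: str | Path) -> None:
    """Serialize networks as an edge-list TSV plus a node TSV."""
    edge_rows, node_rows = [], []
    for net in networks:
        cond = net.condition or ""
        for n in sorted(net.nodes):
            node_rows.append({"gene": net.gene_id, "peak": n, "condition": cond})
        for (a, b), w in sorted(net.edges.items()):
            edge_rows.append(
                {"gene": net.gene_id, "peak_a": a, "peak_b": b, "weight": w, "condition": cond}
            )
    pd.DataFrame(edge_rows, columns=["gene", "peak_a", "peak_b", "weight", "condition"]).to_csv(
        edge_path, sep="\t", index=False
    )
    pd.DataFrame(node_rows, columns=["gene", "peak", "condition"]).to_csv(
        node_path, sep="\t", index=False
    )


def read_networks(edge_path: str | Path, node_path: str | Path) -> list[EnhancerNetwork]:
    edges = pd.read_csv(edge_path, sep="\t", dtype={"gene": str})
    nodes = pd.read_csv(node_path, sep="\t", dtype={"gene": str})
    nets = []
    for (gene, cond), sub in nodes.fillna({"condition": ""}).groupby(["gene", "condition"]):
        esub = edges[(edges["gene"] == gene) & (edges["condition"].fillna("") == cond)]
        nets.append(
            EnhancerNetwork(
                gene,
                set(sub["peak"].astype(str)),
                {
                    (str(r.peak_a), str(r.peak_b)): float(r.weight)
                    for r in esub.itertuples(index=False)
                },
                condition=cond or None,
            )
        )
    return nets
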