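"""Differential and dynamic enhancer-network analysis.

The comparison of enhancer co-accessibility across conditions (disease vs
healthy) or stages (a developmental series) follows a DiffCoEx-style
four-step procedure:

1. build the symmetric adjacency C^[n] of co-accessibility per condition
   over one fixed enhancer ordering (pairs beyond the distance window
   read as 0);
2. collapse the conditions into a single non-negative difference matrix D —
   for two conditions d_ij = |(c_ij^[2])^2 - (c_ij^[1])^2|, for n >= 3
   d_ij = sqrt(mean_n |(c_ij^[n])^2 - (c_ij^[0])^2|) with c^[0] the
   across-condition mean;
3. convert D into a topological-overlap dissimilarity T, so that enhancers
   whose co-accessibility changes share the same neighbourhood end up
   mutually similar;
4. average-linkage hierarchical clustering of T cut at a fixed height
   (0.99 by default); clusters of >= min_size enhancers are the "altered
   components" (differential/dynamic modules).

Per-gene summary scores follow: the network change score (two conditions)
sums co-accessibility over altered in-network pairs in the disease state
minus the healthy state; the network dynamic score (stage series) is the
sample standard deviation of that sum across stages. Rank rules then label
networks Gained/Shared/Lost or Early/Middle/Late/Unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .coaccessibility import CoaccessibilityMap
from .network_construction import EnhancerNetwork

__all__ = [
    "AlteredComponentSet",
    "AlteredComponentDetector",
    "adjacency_difference_two",
    "adjacency_difference_multi",
    "tom_dissimilarity",
    "cluster_altered",
    "network_change_score",
    "classify_gained_lost",
    "network_dynamic_score",
    "assign_stage_pattern",
]


@dataclass
class AlteredComponentSet:
    """Disjoint clusters of enhancers with coordinated co-accessibility
    change, plus the enhancers left unclustered."""

    clusters: list[set[str]]
    unclustered: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("altered clusters must be disjoint")
            seen |= c

    @property
    def members(self) -> set[str]:
        return set().union(*self.clusters) if self.clusters else set()

    def __len__(self) -> int:
        return len(self.clusters)


def _check_adjacency(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(C).max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("adjacency entries must lie in [-1, 1]")
    return C


def adjacency_difference_two(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """Two-condition difference d_ij = |(c_ij^[2])^2 - (c_ij^[1])^2|.

    Squaring makes the comparison sign-blind: a correlation flipping from
    -0.4 to +0.4 counts as no change.
    """
    C1, C2 = _check_adjacency(C1), _check_adjacency(C2)
    if C1.shape != C2.shape:
        raise ValueError(f"shape mismatch: {C1.shape} vs {C2.shape}")
    D = np.abs(C2**2 - C1**2)
    np.fill_diagonal(D, 0.0)
    return D


def adjacency_difference_multi(C_list: Sequence[np.ndarray]) -> np.ndarray:
    """Multi-condition difference
    d_ij = sqrt( mean_n |(c_ij^[n])^2 - (c_ij^[0])^2| ),
    with c_ij^[0] the across-condition mean of c_ij. Symmetric in the
    condition order."""
    if len(C_list) < 3:
        raise ValueError("need >= 3 conditions; use adjacency_difference_two for 2")
    mats = [_check_adjacency(C) for C in C_list]
    shape = mats[0].shape
    if any(C.shape != shape for C in mats):
        raise ValueError("all condition adjacencies must share one shape")
    stack = np.stack(mats)
    C0 = stack.mean(axis=0)
    D = np.sqrt(np.mean(np.abs(stack**2 - C0**2), axis=0))
    np.fill_diagonal(D, 0.0)
    return D


def tom_dissimilarity(D: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity
    t_ij = 1 - (sum_k d_ik d_kj + d_ij) / (min(sum_k d_ik, sum_k d_kj) + 1 - d_ij).

    Standard topological-overlap index convention: the numerator product sum
    runs over k not in {i, j}; the row sums exclude the diagonal only.
    t_ii is 0 by convention.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if D.min(initial=0.0) < -1e-12 or D.max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("difference-matrix entries must lie in [0, 1]")
    p = D.shape[0]
    Dz = D.copy()
    np.fill_diagonal(Dz, 0.0)
    rowsum = Dz.sum(axis=1)
    # with a zero diagonal, (Dz @ Dz)_ij = sum_k d_ik d_kj already excludes
    # the k=i and k=j terms (both involve a diagonal factor)
    prod = Dz @ Dz
    numer = prod + Dz
    denom = np.minimum.outer(rowsum, rowsum) + 1.0 - Dz
    if np.any(denom <= 0):
        raise ValueError("TOM denominator <= 0: difference matrix violates d_ij <= 1")
    T = 1.0 - numer / denom
    np.fill_diagonal(T, 0.0)
    return T


def cluster_altered(
    T: np.ndarray,
    enhancer_ids: Sequence[str],
    cut_height: float = 0.99,
    min_size: int = 3,
) -> AlteredComponentSet:
    """Average-linkage hierarchical clustering of the dissimilarity T,
    cut at ``cut_height``; clusters smaller than ``min_size`` go to the
    unclustered pool."""
    T = np.asarray(T, dtype=np.float64)
    ids = list(enhancer_ids)
    if T.shape != (len(ids), len(ids)):
        raise ValueError("T and enhancer id list disagree")
    if len(ids) < 2:
        return AlteredComponentSet([], set(ids))
    Tsym = 0.5 * (T + T.T)
    np.fill_diagonal(Tsym, 0.0)
    Z = linkage(squareform(Tsym, checks=False), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for lab, pid in zip(labels, ids):
        clusters.setdefault(int(lab), set()).add(pid)
    kept, loose = [], set()
    for lab in sorted(clusters):
        if len(clusters[lab]) >= min_size:
            kept.append(clusters[lab])
        else:
            loose |= clusters[lab]
    return AlteredComponentSet(kept, loose)


class AlteredComponentDetector(BaseEstimator):
    """Steps 1-4 as one estimator: fit on per-condition adjacencies.

    Parameters
    ----------
    cut_height : float
        Dendrogram cut for the average-linkage tree of T (default 0.99).
    min_size : int
        Smallest reported altered cluster (default 3).
    tom_power : float
        Optional exponent applied to T before clustering (1.0 = off).

    Attributes (after :meth:`fit`)
    ------------------------------
    difference_ : ndarray          the Step-2 matrix D
    dissimilarity_ : ndarray       the Step-3 matrix T
    components_ : AlteredComponentSet
    labels_ : ndarray of int       cluster index per enhancer, -1 = unclustered
    """

    def __init__(self, cut_height: float = 0.99, min_size: int = 3, tom_power: float = 1.0):
        self.cut_height = cut_height
        self.min_size = min_size
        self.tom_power = tom_power

    def fit(
        self,
        C_list: Sequence[np.ndarray],
        enhancer_ids: Sequence[str],
    ) -> "AlteredComponentDetector":
        if len(C_list) < 2:
            raise ValueError("need adjacencies for at least two conditions")
        if len(C_list) == 2:
            D = adjacency_difference_two(C_list[0], C_list[1])
        else:
            D = adjacency_difference_multi(C_list)
        T = tom_dissimilarity(D)
        if self.tom_power != 1.0:
            T = T**self.tom_power
        self.enhancer_ids_ = list(enhancer_ids)
        self.difference_ = D
        self.dissimilarity_ = T
        self.components_ = cluster_altered(
            T, self.enhancer_ids_, cut_height=self.cut_height, min_size=self.min_size
        )
        lab = {e: -1 for e in self.enhancer_ids_}
        for ci, cluster in enumerate(self.components_.clusters):
            for e in cluster:
                lab[e] = ci
        self.labels_ = np.array([lab[e] for e in self.enhancer_ids_])
        return self

    def fit_from_maps(
        self,
        maps: Sequence[CoaccessibilityMap],
        enhancer_ids: Sequence[str],
    ) -> "AlteredComponentDetector":
        """Convenience: build aligned adjacencies from co-accessibility maps
        (absent pairs read as 0) and fit."""
        ids = list(enhancer_ids)
        return self.fit([m.to_adjacency(ids) for m in maps], ids)


# ---------------------------------------------------------------------------
# Scores over altered components


def _altered_network_pairs(
    net: EnhancerNetwork, altered: AlteredComponentSet
) -> list[tuple[str, str]]:
    """Unordered pairs of the network's nodes with both ends altered."""
    nodes = sorted(net.nodes & altered.members)
    return list(combinations(nodes, 2))


def network_change_score(
    net: EnhancerNetwork,
    healthy_map: CoaccessibilityMap,
    disease_map: CoaccessibilityMap,
    altered: AlteredComponentSet,
    clip_negative: bool = False,
) -> float:
    """sum over altered in-network pairs of c^[disease] - c^[healthy].

    Returns 0 when fewer than two of the network's nodes are altered.
    ``clip_negative`` floors each c at 0 before summing (off by default —
    the adjacency imposes no clipping).
    """
    pairs = _altered_network_pairs(net, altered)
    if not pairs:
        return 0.0
    total = 0.0
    for a, b in pairs:
        c1 = healthy_map.get(a, b)
        c2 = disease_map.get(a, b)
        if clip_negative:
            c1, c2 = max(c1, 0.0), max(c2, 0.0)
        total += c2 - c1
    return float(total)


def network_dynamic_score(
    net: EnhancerNetwork,
    stage_maps: Sequence[CoaccessibilityMap],
    altered: AlteredComponentSet,
    clip_negative: bool = False,
) -> float:
    """Sample standard deviation across stages of the altered-pair
    co-accessibility sum: sqrt( sum_n (S_n - mean(S))^2 / (n-1) )."""
    if len(stage_maps) < 2:
        raise ValueError("dynamic score needs >= 2 stages")
    pairs = _altered_network_pairs(net, altered)
    if not pairs:
        return 0.0
    sums = []
    for cmap in stage_maps:
        s = 0.0
        for a, b in pairs:
            c = cmap.get(a, b)
            if clip_negative:
                c = max(c, 0.0)
            s += c
        sums.append(s)
    return float(np.std(sums, ddof=1))


def classify_gained_lost(
    score_diff: Mapping[str, float], q: float = 0.10
) -> dict[str, str]:
    """Rank-based decile labels on per-gene score differences.

    The top floor(q*G) genes are Gained, the bottom floor(q*G) Lost, the
    rest Shared. Ties break by gene id so the labelling is deterministic.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    genes = list(score_diff)
    G = len(genes)
    if G == 0:
        return {}
    if G < 10:
        warnings.warn(f"only {G} genes; decile classification is coarse")
    k = int(np.floor(q * G))
    by_desc = sorted(genes, key=lambda g: (-score_diff[g], g))
    gained = set(by_desc[:k])
    by_asc = sorted(genes, key=lambda g: (score_diff[g], g))
    lost = set()
    for g in by_asc:
        if len(lost) == k:
            break
        if g not in gained:
            lost.add(g)
    out = {}
    for g in genes:
        if g in gained:
            out[g] = "Gained"
        elif g in lost:
            out[g] = "Lost"
        else:
            out[g] = "Shared"
    return out


def assign_stage_pattern(
    stage_scores: Mapping[str, Mapping[str, float]],
    grouping: Mapping[str, str],
    dynamic_flags: Mapping[str, bool],
    group_order: Sequence[str] = ("Early", "Middle", "Late"),
) -> dict[str, str]:
    """Assign each gene a temporal pattern from its per-stage network scores.

    ``grouping`` maps each stage to exactly one group (Early/Middle/Late);
    per-gene scores are averaged within groups and a dynamic network takes
    the argmax group (ties to the earliest group). Non-dynamic networks are
    Unchanged regardless of scores.
    """
    if not grouping:
        raise ValueError("empty stage grouping")
    bad = set(grouping.values()) - set(group_order)
    if bad:
        raise ValueError(f"unknown groups in stage mapping: {bad}")
    out = {}
    for gene, scores in stage_scores.items():
        if not dynamic_flags.get(gene, False):
            out[gene] = "Unchanged"
            continue
        means = {}
        for grp in group_order:
            stages = [s for s, g in grouping.items() if g == grp]
            vals = [scores[s] for s in stages if s in scores]
            if vals:
                means[grp] = float(np.mean(vals))
        best = max(means.values())
        for grp in group_order:  # earliest group wins ties
            if grp in means and means[grp] == best:
                out[gene] = grp
                break
    return out
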