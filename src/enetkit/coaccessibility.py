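"""Pairwise enhancer co-accessibility per condition.

Single cells are too sparse for stable pairwise statistics, so cells are
first aggregated into metacells (k-nearest-neighbour groups in a TF-IDF +
truncated-SVD embedding, the LSI embedding standard for scATAC-seq), and
co-accessibility c_ij in [-1, 1] is then computed between peaks over
metacells, restricted to pairs within a genomic distance window.

Two backends are provided:

``correlation``
    plain Pearson correlation across metacells (default);
``glasso``
    sparse partial correlations from a graphical lasso with a
    distance-scaled penalty matrix, run in overlapping genomic windows —
    the regularized, Cicero-style estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import TruncatedSVD

from .io_core import CellByFeatureMatrix, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "MetacellMatrix",
    "CoaccessibilityMap",
    "MetacellAggregator",
    "CoaccessibilityEstimator",
    "make_metacells",
    "coaccess_correlation",
    "coaccess_glasso",
    "graphical_lasso_matrix_penalty",
]


@dataclass
class MetacellMatrix:
    """Metacell x peak summed counts plus the cell membership map."""

    metacells: list[str]
    features: list[str]
    X: np.ndarray
    membership: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.metacells), len(self.features)):
            raise ValueError("metacell matrix shape mismatch")

    @property
    def n_metacells(self) -> int:
        return len(self.metacells)


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CoaccessibilityMap:
    """Sparse symmetric map (peak, peak) -> co-accessibility score.

    Scores are defined only for distinct peak pairs within ``max_dist`` bp
    (midpoint distance); absent pairs read as 0, the neutral element for
    every downstream sum.
    """

    condition: str | None = None
    max_dist: float = 250_000
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def set(self, a: str, b: str, value: float) -> None:
        if a == b:
            raise ValueError("self-pairs are not allowed")
        if not -1.0 - 1e-9 <= value <= 1.0 + 1e-9:
            raise ValueError(f"co-accessibility {value} outside [-1, 1]")
        self.scores[_canonical_pair(a, b)] = float(np.clip(value, -1.0, 1.0))

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        if a == b:
            return 0.0
        return self.scores.get(_canonical_pair(a, b), default)

    def __len__(self) -> int:
        return len(self.scores)

    def pairs(self) -> Iterable[tuple[str, str]]:
        return self.scores.keys()

    def to_adjacency(self, peak_ids: list[str]) -> np.ndarray:
        """Dense symmetric adjacency over ``peak_ids``; missing pairs -> 0."""
        idx = {p: i for i, p in enumerate(peak_ids)}
        C = np.zeros((len(peak_ids), len(peak_ids)))
        for (a, b), v in self.scores.items():
            if a in idx and b in idx:
                C[idx[a], idx[b]] = C[idx[b], idx[a]] = v
        return C

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"peak_a": a, "peak_b": b, "condition": self.condition or "", "score": v}
            for (a, b), v in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows, columns=["peak_a", "peak_b", "condition", "score"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, max_dist: float = 250_000) -> "CoaccessibilityMap":
        df = pd.read_csv(path, sep="\t")
        cond = str(df["condition"].iloc[0]) if len(df) and "condition" in df else None
        cmap = cls(condition=cond or None, max_dist=max_dist)
        for row in df.itertuples(index=False):
            cmap.set(str(row.peak_a), str(row.peak_b), float(row.score))
        return cmap


# ---------------------------------------------------------------------------
# Metacell aggregation


class MetacellAggregator(BaseEstimator, TransformerMixin):
    """Group cells into metacells of size ``k`` and sum their counts.

    Cells are embedded with TF-IDF + truncated SVD (``n_dims`` components),
    then greedily grouped: in a seeded random order, each unassigned cell
    claims its k-1 nearest unassigned neighbours. ``k=1`` is the identity
    aggregation. Deterministic given ``random_state``.

    Attributes
    ----------
    membership_ : dict[str, list[str]]
        metacell id -> member cell ids (set by :meth:`fit`).
    """

    def __init__(self, k: int = 50, n_dims: int = 30, random_state: int = 0):
        self.k = k
        self.n_dims = n_dims
        self.random_state = random_state

    def fit(self, m: CellByFeatureMatrix, y=None) -> "MetacellAggregator":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        n = len(m.cells)
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds the number of cells ({n})")
        if self.k == 1:
            self.membership_ = {c: [c] for c in m.cells}
            self._order_ = list(m.cells)
            return self
        emb = self._embed(m)
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(n)
        unassigned = np.ones(n, dtype=bool)
        groups: list[list[int]] = []
        for i in order:
            if not unassigned[i]:
                continue
            unassigned[i] = False
            cand = np.flatnonzero(unassigned)
            take = min(self.k - 1, cand.size)
            if take > 0:
                d = np.linalg.norm(emb[cand] - emb[i], axis=1)
                nearest = cand[np.argsort(d, kind="stable")[:take]]
                unassigned[nearest] = False
                groups.append([i, *nearest.tolist()])
            else:
                groups.append([i])
        self.membership_ = {
            f"mc{g}": [m.cells[i] for i in idx] for g, idx in enumerate(groups)
        }
        self._order_ = list(self.membership_)
        return self

    def transform(self, m: CellByFeatureMatrix) -> MetacellMatrix:
        if not hasattr(self, "membership_"):
            raise RuntimeError("MetacellAggregator must be fit before transform")
        pos = {c: i for i, c in enumerate(m.cells)}
        rows = []
        names = []
        for mc_id, members in self.membership_.items():
            idx = [pos[c] for c in members]
            rows.append(np.asarray(m.X[idx].sum(axis=0)).ravel())
            names.append(mc_id)
        return MetacellMatrix(
            names, list(m.features), np.vstack(rows), dict(self.membership_)
        )

    def _embed(self, m: CellByFeatureMatrix) -> np.ndarray:
        X = m.X.tocsc()
        n, p = X.shape
        # TF-IDF on binarized presence (LSI), as usual for scATAC.
        B = X.copy()
        B.data = np.ones_like(B.data)
        rowsum = np.maximum(np.asarray(B.sum(axis=1)).ravel(), 1.0)
        df = np.maximum(np.asarray(B.sum(axis=0)).ravel(), 1.0)
        idf = np.log1p(n / df)
        tfidf = sp.diags(1.0 / rowsum) @ B @ sp.diags(idf)
        n_comp = int(min(self.n_dims, n - 1, p - 1))
        if n_comp < 1:
            return np.asarray(tfidf.todense())
        svd = TruncatedSVD(n_components=n_comp, random_state=self.random_state)
        return svd.fit_transform(tfidf)


def make_metacells(
    m: CellByFeatureMatrix, k: int, n_dims: int = 30, seed: int = 0
) -> MetacellMatrix:
    """Functional wrapper around :class:`MetacellAggregator`."""
    agg = MetacellAggregator(k=k, n_dims=n_dims, random_state=seed)
    return agg.fit(m).transform(m)


# ---------------------------------------------------------------------------
# Pair enumeration and correlation backend


def _pairs_within(peaks: PeakSet, feature_ids: list[str], max_dist: float):
    """Index pairs (i < j) of features whose midpoint distance <= max_dist."""
    info = []
    for j, pid in enumerate(feature_ids):
        if pid in peaks:
            iv = peaks[pid]
            info.append((iv.chrom, iv.midpoint, j))
    info.sort()
    out = []
    for a in range(len(info)):
        chrom_a, mid_a, ja = info[a]
        for b in range(a + 1, len(info)):
            chrom_b, mid_b, jb = info[b]
            if chrom_b != chrom_a or mid_b - mid_a > max_dist:
                break
            out.append((ja, jb))
    return out


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


class CoaccessibilityEstimator(BaseEstimator):
    """Estimate a :class:`CoaccessibilityMap` from a metacell matrix.

    Parameters
    ----------
    backend : {"correlation", "glasso"}
        Pearson correlation (default) or windowed distance-penalized
        graphical lasso returning partial correlations.
    max_dist : float
        Only peak pairs with midpoint distance <= max_dist are scored.
    window, base_penalty : glasso backend only
        Genomic window size (tiled with half-window overlap) and the base
        of the penalty rho_ij = base_penalty * (1 + dist_ij / max_dist).
    """

    def __init__(
        self,
        backend: str = "correlation",
        max_dist: float = 250_000,
        window: float = 500_000,
        base_penalty: float = 0.1,
        condition: str | None = None,
    ):
        self.backend = backend
        self.max_dist = max_dist
        self.window = window
        self.base_penalty = base_penalty
        self.condition = condition

    def fit(self, mm: MetacellMatrix, peaks: PeakSet) -> "CoaccessibilityEstimator":
        if mm.n_metacells < 3:
            raise ValueError("need at least 3 metacells for co-accessibility")
        if self.backend == "correlation":
            self.map_ = self._fit_correlation(mm, peaks)
        elif self.backend == "glasso":
            self.map_ = self._fit_glasso(mm, peaks)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        return self

    def _fit_correlation(self, mm: MetacellMatrix, peaks: PeakSet) -> CoaccessibilityMap:
        Z, ok = _standardize_columns(mm.X)
        n = mm.n_metacells
        cmap = CoaccessibilityMap(condition=self.condition, max_dist=self.max_dist)
        pairs = _pairs_within(peaks, mm.features, self.max_dist)
        for i, j in pairs:
            if ok[i] and ok[j]:
                c = float(Z[:, i] @ Z[:, j] / n)
            else:
                c = 0.0  # zero-variance features score 0, keeping sums total
            cmap.set(mm.features[i], mm.features[j], np.clip(c, -1.0, 1.0))
        return cmap

    def _fit_glasso(self, mm: MetacellMatrix, peaks: PeakSet) -> CoaccessibilityMap:
        cmap = CoaccessibilityMap(condition=self.condition, max_dist=self.max_dist)
        acc: dict[tuple[str, str], list[float]] = {}
        Z, ok = _standardize_columns(mm.X)
        n = mm.n_metacells
        for widx in self._windows(peaks, mm.features):
            widx = [j for j in widx if ok[j]]
            if len(widx) < 2:
                continue
            sub = Z[:, widx]
            S = sub.T @ sub / n
            ids = [mm.features[j] for j in widx]
            dist = np.zeros_like(S)
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    dist[a, b] = dist[b, a] = peaks.distance(ids[a], ids[b])
            rho = self.base_penalty * (1.0 + dist / self.max_dist)
            np.fill_diagonal(rho, 0.0)
            try:
                theta = graphical_lasso_matrix_penalty(S, rho)
                dd = np.sqrt(np.diag(theta))
                P = -theta / np.outer(dd, dd)
                np.fill_diagonal(P, 0.0)
            except Exception:  # non-convergence: correlation fallback
                logger.warning(
                    "graphical lasso failed in a %d-peak window; "
                    "falling back to correlation",
                    len(ids),
                )
                P = S - np.diag(np.diag(S))
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    if dist[a, b] <= self.max_dist:
                        key = _canonical_pair(ids[a], ids[b])
                        acc.setdefault(key, []).append(float(np.clip(P[a, b], -1, 1)))
        for (a, b), vals in acc.items():
            cmap.set(a, b, float(np.mean(vals)))
        return cmap

    def _windows(self, peaks: PeakSet, feature_ids: list[str]):
        """Column-index lists for overlapping windows (half-window step)."""
        by_chrom: dict[str, list[tuple[float, int]]] = {}
        for j, pid in enumerate(feature_ids):
            if pid in peaks:
                iv = peaks[pid]
                by_chrom.setdefault(iv.chrom, []).append((iv.midpoint, j))
        step = self.window / 2.0
        for chrom, items in sorted(by_chrom.items()):
            items.sort()
            mids = np.array([m for m, _ in items])
            lo, hi = mids.min(), mids.max()
            start = lo
            seen: set[tuple[int, ...]] = set()
            while True:
                mask = (mids >= start) & (mids < start + self.window)
                idx = tuple(items[t][1] for t in np.flatnonzero(mask))
                if len(idx) >= 1 and idx not in seen:
                    seen.add(idx)
                    yield list(idx)
                start += step
                if start > hi:
                    break


def coaccess_correlation(
    mm: MetacellMatrix,
    peaks: PeakSet,
    max_dist: float = 250_000,
    condition: str | None = None,
) -> CoaccessibilityMap:
    est = CoaccessibilityEstimator(
        backend="correlation", max_dist=max_dist, condition=condition
    )
    return est.fit(mm, peaks).map_


def coaccess_glasso(
    mm: MetacellMatrix,
    peaks: PeakSet,
    max_dist: float = 250_000,
    window: float = 500_000,
    base_penalty: float = 0.1,
    condition: str | None = None,
) -> CoaccessibilityMap:
    est = CoaccessibilityEstimator(
        backend="glasso",
        max_dist=max_dist,
        window=window,
        base_penalty=base_penalty,
        condition=condition,
    )
    return est.fit(mm, peaks).map_


# ---------------------------------------------------------------------------
# Graphical lasso with an elementwise penalty matrix


def graphical_lasso_matrix_penalty(
    S: np.ndarray,
    rho: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> np.ndarray:
    """Sparse inverse covariance with per-entry L1 penalties.

    Block coordinate descent over columns (Friedman et al.'s algorithm),
    generalized to a penalty matrix ``rho`` so that distant peak pairs can
    be penalized more heavily than nearby ones. Returns the precision
    matrix.

    Each column update solves the lasso subproblem
    ``min 0.5 b' W11 b - s12' b + sum_i rho12_i |b_i|`` by cyclic
    coordinate descent.
    """
    S = np.asarray(S, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    p = S.shape[0]
    if S.shape != rho.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and rho must be square matrices of equal shape")
    if p == 1:
        return np.array([[1.0 / max(S[0, 0], 1e-12)]])
    W = S.copy()
    W[np.diag_indices_from(W)] += np.diag(rho) + 1e-4  # keep W11 well-posed
    B = np.zeros((p, p))  # column j holds beta for the j-th subproblem
    off = ~np.eye(p, dtype=bool)
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            keep = np.arange(p) != j
            W11 = W[np.ix_(keep, keep)]
            s12 = S[keep, j]
            r12 = rho[keep, j]
            beta = B[keep, j]
            for _ in range(100):
                beta_old = beta.copy()
                for i in range(p - 1):
                    resid = s12[i] - W11[i] @ beta + W11[i, i] * beta[i]
                    beta[i] = _soft_threshold(resid, r12[i]) / W11[i, i]
                if np.abs(beta - beta_old).max() < tol:
                    break
            B[keep, j] = beta
            w12 = W11 @ beta
            W[keep, j] = w12
            W[j, keep] = w12
        delta = np.abs(W - W_old)[off].mean()
        denom = max(np.abs(S)[off].mean(), 1e-12)
        if delta / denom < tol:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        keep = np.arange(p) != j
        denom_j = W[j, j] - W[keep, j] @ B[keep, j]
        theta[j, j] = 1.0 / max(denom_j, 1e-12)
        theta[keep, j] = -B[keep, j] * theta[j, j]
    theta = 0.5 * (theta + theta.T)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("graphical lasso did not converge")
    return theta


def _soft_threshold(x: float, lam: float) -> float:
    if x > lam:
        return x - lam
    if x < -lam:
        return x + lam
    return 0.0
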