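"""Synergistic effects of enhancer-pair variants on gene expression.

Variants already known to associate with a gene (eQTLs) are kept only when
they fall inside one of the gene's network enhancers. Cross-enhancer variant
pairs are then tested for epistasis with an ordinary least squares model
carrying an interaction term,

    Y ~ b0 + b1*X1*X2 + b2*X1 + b3*X2 + covariates,

against the additive model without the X1*X2 term, fit on the identical
complete-case samples so their AICs are comparable. A variant pair whose
interaction term reaches p < alpha is a synergistic variant pair (SVP); an
enhancer pair containing at least one SVP is a synergistic enhancer pair
(SEP). Inter-module pairs are the ones expected to enrich for synergy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest
from sklearn.base import BaseEstimator

from .io_core import GenomicInterval, PeakSet
from .network_construction import EnhancerNetwork

__all__ = [
    "Variant",
    "VariantSet",
    "SynergyFit",
    "SynergyInteractionModel",
    "map_eqtl_to_enhancers",
    "enumerate_variant_pairs",
    "fit_interaction_model",
    "call_svp_sep",
    "synergy_enrichment",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with per-sample dosages in {0, 1, 2} (NaN = missing)."""

    variant_id: str
    position: GenomicInterval  # width-1 interval
    gene_id: str

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("variant position must be a width-1 interval")


@dataclass
class VariantSet:
    """Variants plus a samples x variants dosage frame."""

    variants: list[Variant]
    dosages: pd.DataFrame  # index: sample ids, columns: variant ids

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        missing = set(ids) - set(self.dosages.columns)
        if missing:
            raise ValueError(f"variants without dosage columns: {sorted(missing)}")
        vals = self.dosages[ids].to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def dosage(self, variant_id: str) -> pd.Series:
        return self.dosages[variant_id]

    @classmethod
    def read_tsv(cls, path) -> "VariantSet":
        """TSV layout: variant_id, chrom, pos, gene, then one column per sample."""
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str, "gene": str})
        meta_cols = ["variant_id", "chrom", "pos", "gene"]
        samples = [c for c in df.columns if c not in meta_cols]
        variants = [
            Variant(
                r.variant_id,
                GenomicInterval(r.chrom, int(r.pos), int(r.pos) + 1, r.variant_id),
                r.gene,
            )
            for r in df.itertuples(index=False)
        ]
        dos = df[samples].T
        dos.columns = df["variant_id"]
        return cls(variants, dos.astype(float))


@dataclass
class SynergyFit:
    """Result of one interactive-vs-additive model comparison."""

    variant_pair: tuple[str, str]
    enhancer_pair: tuple[str, str]
    group: str  # Inter / Intra
    beta_interaction: float
    p_interaction: float
    aic_synergistic: float
    aic_additive: float
    n_samples: int
    params: dict[str, float] = field(default_factory=dict)
    svp: bool = False
    skipped: bool = False
    skip_reason: str = ""


def map_eqtl_to_enhancers(
    variants: VariantSet, net: EnhancerNetwork, peaks: PeakSet
) -> dict[str, str]:
    """Retain variants lying inside a network enhancer; variant id -> enhancer id.

    Variants outside every network enhancer are dropped. Should enhancers
    overlap (they usually do not), the variant goes to the first enhancer in
    genomic order, with a warning.
    """
    nodes = [peaks[p] for p in sorted(net.nodes) if p in peaks]
    nodes.sort(key=lambda iv: (iv.chrom, iv.start))
    mapping: dict[str, str] = {}
    for v in variants.variants:
        hits = [
            iv.id
            for iv in nodes
            if iv.overlaps(v.position.chrom, v.position.start, v.position.end)
        ]
        if not hits:
            continue
        if len(hits) > 1:
            warnings.warn(
                f"variant {v.variant_id} overlaps {len(hits)} enhancers; using {hits[0]}"
            )
        mapping[v.variant_id] = hits[0]
    return mapping


def enumerate_variant_pairs(
    mapped: Mapping[str, str],
    module_of: Mapping[str, int] | None = None,
) -> list[tuple[str, str, str, str, str]]:
    """All unordered cross-enhancer variant pairs.

    Pairs of variants on the same enhancer are excluded — perturbing one
    enhancer twice says nothing about enhancer-pair synergy. Each pair is
    labelled Inter/Intra from the module partition when one is supplied
    (otherwise ""). Returns (v1, v2, e1, e2, group) tuples.
    """
    out = []
    for v1, v2 in combinations(sorted(mapped), 2):
        e1, e2 = mapped[v1], mapped[v2]
        if e1 == e2:
            continue
        group = ""
        if module_of is not None:
            group = "Intra" if module_of[e1] == module_of[e2] else "Inter"
        out.append((v1, v2, e1, e2, group))
    return out


class SynergyInteractionModel(BaseEstimator):
    """OLS fit of the synergistic and additive models on shared samples.

    Attributes after :meth:`fit`: ``beta_interaction_``, ``p_interaction_``,
    ``aic_synergistic_``, ``aic_additive_``, ``n_samples_``, ``params_``.
    """

    def __init__(self, min_extra_samples: int = 5):
        self.min_extra_samples = min_extra_samples

    def fit(
        self,
        y: np.ndarray,
        x1: np.ndarray,
        x2: np.ndarray,
        covariates: np.ndarray | None = None,
    ) -> "SynergyInteractionModel":
        y = np.asarray(y, dtype=float)
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if covariates is None:
            covariates = np.empty((len(y), 0))
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        mask = (
            np.isfinite(y)
            & np.isfinite(x1)
            & np.isfinite(x2)
            & np.all(np.isfinite(covariates), axis=1)
        )
        y, x1, x2, cov = y[mask], x1[mask], x2[mask], covariates[mask]
        p = cov.shape[1]
        if len(y) < p + self.min_extra_samples:
            raise ValueError(
                f"only {len(y)} complete cases for {p} covariates; cannot fit"
            )
        if np.unique(x1).size < 2 or np.unique(x2).size < 2:
            raise ValueError("monomorphic genotype after complete-case filtering")
        inter = x1 * x2
        X_syn = np.column_stack([inter, x1, x2, cov])
        X_add = np.column_stack([x1, x2, cov])
        names = (
            ["interaction", "x1", "x2"] + [f"cov{i}" for i in range(p)]
        )
        syn = sm.OLS(y, sm.add_constant(X_syn, has_constant="add")).fit()
        add = sm.OLS(y, sm.add_constant(X_add, has_constant="add")).fit()
        if syn.df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        self.n_samples_ = int(len(y))
        self.beta_interaction_ = float(syn.params[1])
        self.p_interaction_ = float(syn.pvalues[1])
        self.aic_synergistic_ = float(syn.aic)
        self.aic_additive_ = float(add.aic)
        self.params_ = {"const": float(syn.params[0])}
        self.params_.update({n: float(b) for n, b in zip(names, syn.params[1:])})
        return self


def fit_interaction_model(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_pair: tuple[str, str] = ("v1", "v2"),
    enhancer_pair: tuple[str, str] = ("e1", "e2"),
    group: str = "",
) -> SynergyFit:
    """Fit both models for one variant pair; on an unusable design the fit
    is skipped with the reason recorded rather than raised."""
    model = SynergyInteractionModel()
    try:
        model.fit(y, x1, x2, covariates)
    except ValueError as exc:
        return SynergyFit(
            variant_pair,
            enhancer_pair,
            group,
            float("nan"),
            float("nan"),
            float("nan"),
            float("nan"),
            0,
            skipped=True,
            skip_reason=str(exc),
        )
    return SynergyFit(
        variant_pair,
        enhancer_pair,
        group,
        model.beta_interaction_,
        model.p_interaction_,
        model.aic_synergistic_,
        model.aic_additive_,
        model.n_samples_,
        params=model.params_,
    )


def call_svp_sep(
    fits: Sequence[SynergyFit], alpha: float = 0.01
) -> tuple[list[SynergyFit], dict[tuple[str, str], bool]]:
    """Flag SVPs (p_interaction < alpha) and derive per-enhancer-pair SEPs.

    alpha defaults to 0.01; 0.05 is the documented fallback for sparse
    datasets. Returns the annotated fits and enhancer pair -> SEP flag.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sep: dict[tuple[str, str], bool] = {}
    out = []
    for f in fits:
        svp = (not f.skipped) and np.isfinite(f.p_interaction) and f.p_interaction < alpha
        f.svp = bool(svp)
        key = tuple(sorted(f.enhancer_pair))
        sep[key] = sep.get(key, False) or f.svp
        out.append(f)
    return out, sep


def synergy_enrichment(
    fits: Sequence[SynergyFit],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Fold enrichment of SVPs per group (Inter, Intra, Random).

    fold_g = (svp_g / pairs_g) / (svp_all / pairs_all); p from a two-sided
    binomial test of svp_g in pairs_g at the overall rate. The Random group
    is a seeded label permutation of the Inter/Intra assignments: its
    expected per-permutation rate is the overall rate, so its fold centres
    on 1.
    """
    usable = [f for f in fits if not f.skipped]
    total = len(usable)
    svp_all = sum(f.svp for f in usable)
    if total == 0:
        raise ValueError("no usable fits")
    overall = svp_all / total
    out: dict[str, dict[str, float]] = {}
    for group in ("Inter", "Intra"):
        sub = [f for f in usable if f.group == group]
        if not sub:
            out[group] = {"fold": float("nan"), "p": float("nan"), "m": 0, "n": 0}
            continue
        m = sum(f.svp for f in sub)
        n = len(sub)
        fold = (m / n) / overall if overall > 0 else float("nan")
        p = binomtest(m, n, min(overall, 1.0), alternative="two-sided").pvalue
        out[group] = {"fold": fold, "p": float(p), "m": m, "n": n}
    rng = np.random.default_rng(seed)
    svp_flags = np.array([f.svp for f in usable])
    groups = np.array([f.group for f in usable])
    inter_n = int((groups == "Inter").sum())
    folds = []
    for _ in range(n_perm):
        perm = rng.permutation(len(usable))
        m = svp_flags[perm[:inter_n]].sum()
        if inter_n and overall > 0:
            folds.append((m / inter_n) / overall)
    out["Random"] = {
        "fold": float(np.mean(folds)) if folds else float("nan"),
        "p": float("nan"),
        "m": float(svp_all * inter_n / total) if total else 0.0,
        "n": inter_n,
    }
    return out
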