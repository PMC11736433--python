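"""Depletion and interaction scores for paired-sgRNA CRISPRi screens.

A multiplexed CRISPRi proliferation screen delivers two sgRNAs per cell and
counts sgRNA pairs at day 0 and day 30. Dropout of a pair between the two
timepoints (depletion) measures the combined fitness cost of perturbing the
two targets. The interaction score asks whether a pair drops out more than
expected from its two single perturbations: for each query sgRNA, the
double-depletion of (query, other) pairs is regressed on the single
depletion of the partners, and the negative residual — extra depletion
beyond the linear (additive) expectation — is the synergy readout,
z-normalized against the query's control pairs. Enhancer-pair scores
average over the most effective half of each enhancer's sgRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SgRNAPairCounts",
    "CrispriInteractionScorer",
    "depletion_scores",
    "single_depletion",
    "interaction_scores",
]

CONTROL = "control"


@dataclass
class SgRNAPairCounts:
    """Counts of sgRNA pairs at D0/D30 plus sgRNA -> target labels."""

    counts: pd.DataFrame  # columns: sgrna_a, sgrna_b, count_d0, count_d30
    targets: dict[str, str]  # sgRNA -> enhancer id or "control"

    def __post_init__(self) -> None:
        need = {"sgrna_a", "sgrna_b", "count_d0", "count_d30"}
        missing = need - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.counts[["count_d0", "count_d30"]] < 0).to_numpy().any():
            raise ValueError("negative counts")
        guides = set(self.counts["sgrna_a"]) | set(self.counts["sgrna_b"])
        unlabeled = guides - set(self.targets)
        if unlabeled:
            raise ValueError(f"sgRNAs without target labels: {sorted(unlabeled)[:5]}")

    def is_control(self, guide: str) -> bool:
        return self.targets[guide] == CONTROL

    @classmethod
    def read_tsv(cls, counts_path, annot_path) -> "SgRNAPairCounts":
        counts = pd.read_csv(counts_path, sep="\t")
        annot = pd.read_csv(annot_path, sep="\t")
        return cls(counts, dict(zip(annot["sgrna"], annot["target"])))


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class CrispriInteractionScorer(BaseEstimator):
    """Full screen pipeline: depletion z-scores, single/double depletion,
    per-pair interaction scores, and enhancer-pair interaction scores.

    Parameters
    ----------
    min_reads : int
        Pairs with raw D0 counts below this are dropped (default 30).
    pseudo : float
        Pseudo-count added to both timepoints before the log-ratio
        (default 10).
    normalize : bool
        Scale each library to the mean total count before the ratio
        (default True), so depletion is not confounded with depth.
    top_fraction : float
        Fraction of each enhancer's sgRNAs (the most depleting ones by
        single-depletion score) whose pairs enter the enhancer-pair average.

    Attributes after :meth:`fit`
    ----------------------------
    depletion_ : dict[(a, b), float]      pair depletion z-scores
    singles_ : dict[str, float]           per-sgRNA single depletion
    double_ : dict[(a, b), float]         orientation-averaged depletion
    interaction_ : dict[(a, b), float]    per-pair interaction z-scores
    enhancer_pair_scores_ : dict[(e1, e2), float]
    """

    def __init__(
        self,
        min_reads: int = 30,
        pseudo: float = 10.0,
        normalize: bool = True,
        top_fraction: float = 0.5,
    ):
        self.min_reads = min_reads
        self.pseudo = pseudo
        self.normalize = normalize
        self.top_fraction = top_fraction

    # -- step 0: depletion z-scores ------------------------------------
    def _depletion(self, data: SgRNAPairCounts) -> dict[tuple[str, str], float]:
        df = data.counts.copy()
        d0 = df["count_d0"].to_numpy(dtype=float)
        d30 = df["count_d30"].to_numpy(dtype=float)
        if self.normalize:
            target = 0.5 * (d0.sum() + d30.sum())
            d0n = d0 * target / d0.sum() if d0.sum() > 0 else d0
            d30n = d30 * target / d30.sum() if d30.sum() > 0 else d30
        else:
            d0n, d30n = d0, d30
        keep = d0 >= self.min_reads  # filter on raw D0 reads
        e = np.log2((d30n + self.pseudo) / (d0n + self.pseudo))
        cc = np.array(
            [
                data.is_control(a) and data.is_control(b)
                for a, b in zip(df["sgrna_a"], df["sgrna_b"])
            ]
        )
        if (cc & keep).sum() < 2:
            raise ValueError("need >= 2 surviving control-control pairs")
        mu = e[cc & keep].mean()
        sd = e[cc & keep].std(ddof=1)
        if sd == 0:
            raise ValueError("control-control depletion has zero variance")
        z = (e - mu) / sd
        out: dict[tuple[str, str], float] = {}
        for a, b, zi, k in zip(df["sgrna_a"], df["sgrna_b"], z, keep):
            if k:
                out[(a, b)] = float(zi)
        return out

    # -- helpers over orientations -------------------------------------
    @staticmethod
    def _pair_values(z: Mapping[tuple[str, str], float], a: str, b: str) -> list[float]:
        vals = []
        if (a, b) in z:
            vals.append(z[(a, b)])
        if a != b and (b, a) in z:
            vals.append(z[(b, a)])
        return vals

    def fit(self, data: SgRNAPairCounts) -> "CrispriInteractionScorer":
        z = self._depletion(data)
        guides = sorted({g for pair in z for g in pair})
        controls = [g for g in guides if data.is_control(g)]

        # step 1: single depletion = mean z over guide-control pairs
        singles: dict[str, float] = {}
        for g in guides:
            vals = []
            for c in controls:
                if c == g:
                    continue
                vals.extend(self._pair_values(z, g, c))
            if vals:
                singles[g] = float(np.mean(vals))
            else:
                warnings.warn(f"sgRNA {g} has no control partner; excluded")

        # step 2: double depletion = mean over both orientations
        double: dict[tuple[str, str], float] = {}
        for (a, b) in z:
            key = _canonical(a, b)
            if key not in double:
                vals = self._pair_values(z, a, b)
                double[key] = float(np.mean(vals))

        # step 3: per-query linear fit of double depletion on the partner's
        # single depletion; the negative, control-normalized residual is the
        # query-other interaction score. Each unordered pair collects the
        # scores from both query perspectives and averages them.
        per_pair: dict[tuple[str, str], list[float]] = {}
        for q in guides:
            if q not in singles:
                continue
            partners = []
            for key, dval in double.items():
                if q in key:
                    o = key[0] if key[1] == q else key[1]
                    if o != q and o in singles:
                        partners.append((o, dval))
            if len(partners) < 3:
                continue  # not enough partners to fit
            xs = np.array([singles[o] for o, _ in partners])
            ys = np.array([d for _, d in partners])
            slope, intercept = np.polyfit(xs, ys, 1)
            resid = {o: -(d - (intercept + slope * singles[o])) for o, d in partners}
            ctrl_resid = [r for o, r in resid.items() if data.is_control(o)]
            if len(ctrl_resid) < 2:
                continue
            mu, sd = float(np.mean(ctrl_resid)), float(np.std(ctrl_resid, ddof=1))
            if sd == 0:
                continue
            for o, r in resid.items():
                per_pair.setdefault(_canonical(q, o), []).append((r - mu) / sd)
        interaction = {key: float(np.mean(vals)) for key, vals in per_pair.items()}

        # step 4: enhancer-pair scores over the top-depleting half of sgRNAs
        by_enh: dict[str, list[str]] = {}
        for g in guides:
            t = data.targets[g]
            if t != CONTROL and g in singles:
                by_enh.setdefault(t, []).append(g)
        selected: dict[str, set[str]] = {}
        for enh, gs in by_enh.items():
            gs_sorted = sorted(gs, key=lambda g: (singles[g], g))  # most depleting first
            k = max(1, int(np.ceil(self.top_fraction * len(gs_sorted))))
            selected[enh] = set(gs_sorted[:k])
        enh_scores: dict[tuple[str, str], list[float]] = {}
        for (a, b), sc in interaction.items():
            ta, tb = data.targets[a], data.targets[b]
            if ta == CONTROL or tb == CONTROL or ta == tb:
                continue
            if a in selected.get(ta, set()) and b in selected.get(tb, set()):
                enh_scores.setdefault(_canonical(ta, tb), []).append(sc)

        self.depletion_ = z
        self.singles_ = singles
        self.double_ = double
        self.interaction_ = interaction
        self.enhancer_pair_scores_ = {
            k: float(np.mean(v)) for k, v in enh_scores.items()
        }
        return self


def depletion_scores(
    counts: SgRNAPairCounts, min_reads: int = 30, pseudo: float = 10.0
) -> dict[tuple[str, str], float]:
    scorer = CrispriInteractionScorer(min_reads=min_reads, pseudo=pseudo)
    return scorer._depletion(counts)


def single_depletion(
    z: Mapping[tuple[str, str], float], data: SgRNAPairCounts
) -> dict[str, float]:
    guides = sorted({g for pair in z for g in pair})
    controls = [g for g in guides if data.is_control(g)]
    out = {}
    for g in guides:
        vals = []
        for c in controls:
            if c == g:
                continue
            vals.extend(CrispriInteractionScorer._pair_values(z, g, c))
        if vals:
            out[g] = float(np.mean(vals))
    return out


def interaction_scores(
    counts: SgRNAPairCounts,
    min_reads: int = 30,
    pseudo: float = 10.0,
    top_fraction: float = 0.5,
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Run the full pipeline; returns (per-pair, per-enhancer-pair) scores."""
    scorer = CrispriInteractionScorer(
        min_reads=min_reads, pseudo=pseudo, top_fraction=top_fraction
    )
    scorer.fit(counts)
    return scorer.interaction_, scorer.enhancer_pair_scores_
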