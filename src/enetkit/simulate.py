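"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume rather
than read-level data:

* accessibility is binary (a peak is open or closed in a cell), driven by
  latent per-cell module activities — peaks of one module share a driver,
  which directly parameterizes within-module co-accessibility;
* gene expression is a noisy weighted sum of the gene's module activities,
  so enhancers correlate with their target gene;
* condition-specific structure is planted by coupling a designated block of
  peaks to one shared driver only in the disease condition (or in chosen
  developmental stages), producing a controlled jump in pairwise
  co-accessibility;
* eQTL genotypes are Hardy-Weinberg draws, with expression generated from
  the interactive regression model (planted interaction coefficients on
  designated inter-module variant pairs, zero on intra pairs);
* CRISPRi paired-guide counts are negative-binomial at day 0 and scaled by
  2^(combined fitness effect) at day 30, with an extra synergy term for
  planted enhancer pairs.

With activity rate 0.5 and open probabilities p1/p0, peaks sharing a
driver have pairwise correlation (p1-p0)^2 * 0.25 / (pbar(1-pbar)); a
coupling weight w scales that to w^2 times the full-coupling value, which
is how the planted disease-condition jump (default ~0.5) is dialled in.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import (
    CellByFeatureMatrix,
    ConditionLabels,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
)
from .synergy import Variant, VariantSet

__all__ = [
    "SimulationConfig",
    "SimulatedAccessibility",
    "simulate_accessibility",
    "simulate_synergy_pair",
    "simulate_genotypes",
    "simulate_crispri",
]

# correlation between two peaks fully driven by one Bernoulli(0.5) activity
# with open probabilities 0.9 / 0.1
_FULL_COUPLING_R = 0.64


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 2000 cells per condition, 30 genes with two 4-peak modules
    each, activity rate 0.5 with open probabilities 0.999/0.001 — a peak
    follows its module's activity almost deterministically, putting the
    within-module co-accessibility near 0.98. That strong coupling is a
    deliberate idealization: it represents "unchanged" structure as truly
    unchanged, so that the estimation jitter of stable pairs stays below
    the tolerance of the fixed dendrogram cut in the differential analysis
    (see the variance analysis in the methods documentation). The disease
    preset plants a 6-peak gained block in 3 genes with a co-accessibility
    jump of ~0.5; the stage preset couples each dynamic gene's block only
    in its assigned stage group.
    """

    n_cells: int = 2000  # per condition
    n_genes: int = 30
    module_layout: tuple[int, ...] = (4, 4)
    p_active: float = 0.5
    p_open_active: float = 0.999
    p_open_inactive: float = 0.001
    effect_size: float = 0.8
    expr_noise_sd: float = 1.0
    conditions: tuple[str, ...] = ("healthy", "disease")
    n_affected_genes: int = 3
    gained_block_size: int = 6
    gained_delta: float = 0.5
    stage_grouping: Mapping[str, str] | None = None
    n_tfs: int = 30
    tfs_per_module: int = 8
    tf_background_rate: float = 0.05
    tf_binding_rate: float = 0.85
    # eQTL layout
    variants_per_enhancer: tuple[int, ...] = (1, 2)
    maf: float = 0.3
    beta_main: float = 0.3
    beta_interaction: float = 0.5
    n_covariates: int = 3
    # CRISPRi layout
    guides_per_enhancer: int = 12
    n_control_guides: int = 16
    guide_effect: float = -1.2
    guide_effect_sd: float = 0.1
    crispri_delta: float = -2.0
    crispri_mean_reads: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_active", "p_open_active", "p_open_inactive", "maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        attainable = _FULL_COUPLING_R_for(self)
        if self.gained_delta > attainable + 1e-9:
            raise ValueError(
                f"requested co-accessibility jump {self.gained_delta} exceeds the "
                f"attainable bound {attainable:.3f} for the configured open "
                "probabilities"
            )


def _FULL_COUPLING_R_for(cfg: SimulationConfig) -> float:
    span = cfg.p_open_active - cfg.p_open_inactive
    var_act = cfg.p_active * (1 - cfg.p_active)
    pbar = cfg.p_open_inactive + span * cfg.p_active
    var_peak = pbar * (1 - pbar)
    if var_peak == 0:
        return 0.0
    return span**2 * var_act / var_peak


@dataclass
class SimulatedAccessibility:
    peaks: PeakSet
    accessibility: CellByFeatureMatrix
    expression: CellByFeatureMatrix
    labels: ConditionLabels
    genes: dict[str, GeneAnnotation]
    tf_matrix: pd.DataFrame
    truth: dict


def _gene_layout(cfg: SimulationConfig, g: int, affected: bool):
    """Peak intervals for one gene: contiguous module blocks (plus a gained
    block for affected genes), all within the +/-100 kb window of the TSS."""
    chrom = f"chr{g + 1}"
    tss_pos = 150_000
    intervals = []
    module_of: dict[str, int] = {}
    gained: list[str] = []
    pos = tss_pos - 80_000
    blocks = list(cfg.module_layout) + ([cfg.gained_block_size] if affected else [])
    for m, size in enumerate(blocks):
        for p in range(size):
            pid = f"g{g}_m{m}_p{p}"
            intervals.append(GenomicInterval(chrom, pos, pos + 500, pid))
            if m < len(cfg.module_layout):
                module_of[pid] = m
            else:
                gained.append(pid)
            pos += 2_000
        pos += 10_000
    tss = GenomicInterval(chrom, tss_pos, tss_pos + 1, f"tss:gene{g}")
    return chrom, tss, intervals, module_of, gained


def simulate_accessibility(cfg: SimulationConfig) -> SimulatedAccessibility:
    """Binary accessibility + expression for all conditions, with planted
    module structure and condition-specific gained blocks."""
    rng = np.random.default_rng(cfg.seed)
    span = cfg.p_open_active - cfg.p_open_inactive
    stage_grouping = cfg.stage_grouping
    conditions = list(cfg.conditions)
    affected_genes = list(range(cfg.n_affected_genes))
    pattern_names = ("Early", "Middle", "Late")

    all_intervals = []
    genes: dict[str, GeneAnnotation] = {}
    per_gene = {}
    truth_modules: dict[str, dict[str, int]] = {}
    truth_gained: dict[str, list[str]] = {}
    gene_pattern: dict[str, str] = {}
    for g in range(cfg.n_genes):
        gene_id = f"gene{g}"
        affected = g in affected_genes
        chrom, tss, intervals, module_of, gained = _gene_layout(cfg, g, affected)
        all_intervals.extend(intervals)
        genes[gene_id] = GeneAnnotation(gene_id, tss)
        per_gene[gene_id] = (intervals, module_of, gained)
        truth_modules[gene_id] = module_of
        if affected:
            truth_gained[gene_id] = gained
            if stage_grouping is not None:
                gene_pattern[gene_id] = pattern_names[g % len(pattern_names)]
    peaks = PeakSet(all_intervals)

    w_gain = float(np.sqrt(cfg.gained_delta / _FULL_COUPLING_R_for(cfg)))
    cell_ids, labels = [], {}
    acc_blocks, expr_blocks = [], []
    for ci, cond in enumerate(conditions):
        n = cfg.n_cells
        ids = [f"{cond}_c{i}" for i in range(n)]
        cell_ids.extend(ids)
        labels.update({c: cond for c in ids})
        acc_cols = {}
        expr_cols = {}
        for gene_id, (intervals, module_of, gained) in per_gene.items():
            n_mod = len(cfg.module_layout)
            act = rng.random((n, n_mod)) < cfg.p_active
            drive = np.zeros(n)
            if gained:
                if stage_grouping is None:
                    coupled = cond == conditions[-1]  # disease
                    w = w_gain if coupled else 0.0
                else:
                    coupled = stage_grouping[cond] == gene_pattern[gene_id]
                    w = w_gain if coupled else 0.0
                shared = rng.random(n) < cfg.p_active
            for iv in intervals:
                pid = iv.id
                if pid in module_of:
                    a = act[:, module_of[pid]].astype(float)
                else:
                    own = (rng.random(n) < cfg.p_active).astype(float)
                    use_shared = rng.random(n) < w
                    a = np.where(use_shared, shared.astype(float), own)
                    drive = drive + a
                p_open = cfg.p_open_inactive + span * a
                acc_cols[pid] = (rng.random(n) < p_open).astype(np.float64)
            signal = act.sum(axis=1).astype(float)
            if gained:
                signal = signal + drive / max(len(gained), 1)
            expr_cols[gene_id] = (
                cfg.effect_size * signal + rng.normal(0, cfg.expr_noise_sd, n)
            )
        acc_blocks.append(pd.DataFrame(acc_cols, index=ids))
        expr_blocks.append(pd.DataFrame(expr_cols, index=ids))
    acc_df = pd.concat(acc_blocks)
    expr_df = pd.concat(expr_blocks)
    # expression is shifted to be non-negative (counts-like), preserving corr
    expr_df = expr_df - float(expr_df.min().min())

    accessibility = CellByFeatureMatrix(
        list(acc_df.index), list(acc_df.columns), sp.csr_matrix(acc_df.to_numpy())
    )
    expression = CellByFeatureMatrix(
        list(expr_df.index), list(expr_df.columns), sp.csr_matrix(expr_df.to_numpy())
    )
    cond_labels = ConditionLabels(labels, conditions)
    tf_matrix = _tf_matrix(cfg, per_gene, rng)
    truth = {
        "modules": truth_modules,
        "gained": truth_gained,
        "affected_genes": [f"gene{g}" for g in affected_genes],
        "gene_peaks": {g: [iv.id for iv in per_gene[g][0]] for g in per_gene},
        "gene_pattern": gene_pattern,
        "within_module_r": _FULL_COUPLING_R_for(cfg),
        "gained_r": w_gain**2 * _FULL_COUPLING_R_for(cfg),
    }
    return SimulatedAccessibility(
        peaks, accessibility, expression, cond_labels, genes, tf_matrix, truth
    )


def _tf_matrix(cfg: SimulationConfig, per_gene, rng) -> pd.DataFrame:
    """Binary enhancer x TF matrix: each module owns a TF subset that its
    peaks bind with high probability, on a low background rate."""
    tf_names = [f"TF{t}" for t in range(cfg.n_tfs)]
    rows = {}
    for gene_id, (intervals, module_of, gained) in per_gene.items():
        module_tfs: dict[int, np.ndarray] = {}
        gained_tfs = rng.choice(cfg.n_tfs, size=cfg.tfs_per_module, replace=False)
        for iv in intervals:
            pid = iv.id
            m = module_of.get(pid)
            if m is not None and m not in module_tfs:
                module_tfs[m] = rng.choice(
                    cfg.n_tfs, size=cfg.tfs_per_module, replace=False
                )
            own = module_tfs[m] if m is not None else gained_tfs
            row = (rng.random(cfg.n_tfs) < cfg.tf_background_rate).astype(int)
            bind = rng.random(len(own)) < cfg.tf_binding_rate
            row[own[bind]] = 1
            rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=tf_names)


# ---------------------------------------------------------------------------
# Genotypes / synergy


def simulate_synergy_pair(
    n: int,
    beta_interaction: float,
    maf: float = 0.3,
    beta_main: float = 0.3,
    n_covariates: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """One variant pair under the interactive expression model.

    Returns (y, x1, x2, covariates); the workhorse for calibration and
    power studies of the interaction test.
    """
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(2, maf, n).astype(float)
    x2 = rng.binomial(2, maf, n).astype(float)
    cov = rng.normal(size=(n, n_covariates))
    cov_beta = rng.normal(0, 0.5, n_covariates)
    y = (
        1.0
        + beta_interaction * x1 * x2
        + beta_main * x1
        + beta_main * x2
        + cov @ cov_beta
        + rng.normal(0, noise_sd, n)
    )
    return y, x1, x2, cov


def simulate_genotypes(
    cfg: SimulationConfig,
    enhancers: Sequence[GenomicInterval],
    module_of: Mapping[str, int],
    gene_id: str = "gene0",
    n_samples: int = 500,
    seed: int | None = None,
):
    """A VariantSet over a gene's enhancers with planted inter-module synergy.

    Each enhancer hosts a cycling number of variants (``variants_per_enhancer``)
    placed inside it; dosages are Hardy-Weinberg at ``maf``. Expression is
    built from the interactive model: every variant contributes a main
    effect; the first variant of each enhancer pairs across modules carry
    interaction ``beta_interaction``, intra-module pairs carry zero.
    Returns (VariantSet, expression Series, covariates DataFrame, truth).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    samples = [f"s{i}" for i in range(n_samples)]
    variants, columns = [], {}
    by_enh: dict[str, list[str]] = {}
    for ei, iv in enumerate(enhancers):
        k = cfg.variants_per_enhancer[ei % len(cfg.variants_per_enhancer)]
        for vi in range(k):
            vid = f"{iv.id}_v{vi}"
            pos = iv.start + 1 + vi * max((iv.length - 2) // max(k, 1), 1)
            variants.append(
                Variant(vid, GenomicInterval(iv.chrom, pos, pos + 1, vid), gene_id)
            )
            columns[vid] = rng.binomial(2, cfg.maf, n_samples).astype(float)
            by_enh.setdefault(iv.id, []).append(vid)
    dosages = pd.DataFrame(columns, index=samples)
    cov = pd.DataFrame(
        rng.normal(size=(n_samples, cfg.n_covariates)),
        index=samples,
        columns=[f"cov{i}" for i in range(cfg.n_covariates)],
    )
    cov_beta = rng.normal(0, 0.5, cfg.n_covariates)
    y = 1.0 + cov.to_numpy() @ cov_beta
    for vid, x in columns.items():
        y = y + cfg.beta_main * x
    planted: list[tuple[str, str]] = []
    enh_ids = [iv.id for iv in enhancers if iv.id in by_enh]
    for i, e1 in enumerate(enh_ids):
        for e2 in enh_ids[i + 1:]:
            if module_of[e1] != module_of[e2]:
                v1, v2 = by_enh[e1][0], by_enh[e2][0]
                y = y + cfg.beta_interaction * columns[v1] * columns[v2]
                planted.append((v1, v2))
    y = y + rng.normal(0, 1.0, n_samples)
    expr = pd.Series(y, index=samples, name=gene_id)
    truth = {"planted_svp": planted, "variant_enhancer": {
        v: e for e, vs in by_enh.items() for v in vs
    }}
    return VariantSet(variants, dosages), expr, cov, truth


# ---------------------------------------------------------------------------
# CRISPRi


def simulate_crispri(
    cfg: SimulationConfig,
    module_of: Mapping[str, int],
    synergy: bool = True,
    seed: int | None = None,
):
    """Paired-guide screen counts with optional planted inter-module synergy.

    Guides per enhancer carry a shared fitness effect (``guide_effect`` log2
    units, plus per-guide variation); control guides are neutral. Day-30
    counts are day-0 counts scaled by 2^(sum of guide effects + delta) with
    Poisson resampling, delta = ``crispri_delta`` on inter-module enhancer
    pairs when ``synergy`` is on (the additive screen sets it to 0).
    """
    from .crispri import CONTROL, SgRNAPairCounts

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    targets: dict[str, str] = {}
    effects: dict[str, float] = {}
    for enh in sorted(module_of):
        for gi in range(cfg.guides_per_enhancer):
            g = f"{enh}_sg{gi}"
            targets[g] = enh
            effects[g] = cfg.guide_effect + rng.normal(0, cfg.guide_effect_sd)
    for ci in range(cfg.n_control_guides):
        g = f"ctrl_sg{ci}"
        targets[g] = CONTROL
        effects[g] = 0.0
    guides = sorted(targets)
    rows = []
    nb_r = 20.0
    p_nb = nb_r / (nb_r + cfg.crispri_mean_reads)
    for i, a in enumerate(guides):
        for b in guides[i:]:
            if a == b:
                continue
            for ga, gb in ((a, b), (b, a)):  # both orientations sequenced
                d0 = int(rng.negative_binomial(nb_r, p_nb))
                ta, tb = targets[ga], targets[gb]
                delta = 0.0
                if (
                    synergy
                    and ta != CONTROL
                    and tb != CONTROL
                    and ta != tb
                    and module_of[ta] != module_of[tb]
                ):
                    delta = cfg.crispri_delta
                log2fc = effects[ga] + effects[gb] + delta + rng.normal(0, 0.15)
                d30 = int(rng.poisson(max(d0 * 2.0**log2fc, 0.0)))
                rows.append(
                    {"sgrna_a": ga, "sgrna_b": gb, "count_d0": d0, "count_d30": d30}
                )
    counts = pd.DataFrame(rows)
    return SgRNAPairCounts(counts, targets)
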