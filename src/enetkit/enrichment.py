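"""Fold-enrichment statistics against shuffled-genome backgrounds.

The recurring statistic is (m/n)/(M/N): the rate of hits (SNPs, eRNAs,
target genes) inside a group of loci relative to the genome-wide rate, with
a two-sided binomial test of m hits in n trials at rate M/N. Backgrounds
come from replacing every open-chromatin region uniformly at random on its
own chromosome, preserving lengths.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binomtest

from .io_core import GenomicInterval, PeakSet

__all__ = [
    "fold_enrichment",
    "shuffle_background",
    "overlap_count",
    "ranked_enrichment_curve",
]


def fold_enrichment(m: int, n: int, M: int, N: int) -> tuple[float, float]:
    """(m/n)/(M/N) plus a two-sided binomial p-value.

    m may exceed n — a single locus can host several SNPs. The binomial
    success rate M/N is capped at 1 and m at n for the test only.
    """
    if n <= 0 or N <= 0:
        raise ValueError("n and N must be positive")
    if M <= 0:
        raise ValueError("fold enrichment undefined for M = 0")
    rate = min(M / N, 1.0)
    fold = (m / n) / (M / N)
    p = binomtest(min(m, n), n, rate, alternative="two-sided").pvalue
    return float(fold), float(p)


def shuffle_background(
    peaks: PeakSet,
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
    n_shuffles: int = 1,
    exclude: PeakSet | None = None,
) -> PeakSet:
    """Uniformly re-place every interval on its own chromosome.

    Lengths are preserved and placements stay in bounds; shuffled intervals
    may overlap one another. ``n_shuffles > 1`` concatenates independent
    replicates (ids suffixed ``__s<r>``); divide overlap counts by
    ``n_shuffles`` for the per-shuffle expectation. ``exclude`` intervals
    (assembly gaps, blacklist) are avoided by rejection sampling.
    """
    rng = np.random.default_rng(seed)
    excl_trees: dict[str, IntervalTree] = {}
    if exclude is not None:
        for iv in exclude:
            excl_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for r in range(n_shuffles):
        for iv in peaks:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"no size for chromosome {iv.chrom!r}")
            L = chrom_sizes[iv.chrom]
            if iv.length > L:
                raise ValueError(
                    f"interval {iv.id} ({iv.length} bp) longer than {iv.chrom} ({L} bp)"
                )
            tree = excl_trees.get(iv.chrom)
            for _ in range(1000):
                start = int(rng.integers(0, L - iv.length + 1))
                if tree is None or not tree.overlap(start, start + iv.length):
                    break
            else:
                raise RuntimeError(f"cannot place {iv.id} outside excluded regions")
            suffix = f"__s{r}" if n_shuffles > 1 else ""
            out.append(
                GenomicInterval(iv.chrom, start, start + iv.length, f"{iv.id}{suffix}")
            )
    return PeakSet(out)


def overlap_count(
    a: PeakSet, b: PeakSet | Sequence[tuple[str, int]]
) -> int:
    """Number of b-records overlapping at least one interval of ``a``.

    ``b`` is a PeakSet or a sequence of (chrom, position) SNP records; a
    SNP at position p is treated as [p, p+1), so a peak's start is included
    and its end coordinate excluded (half-open semantics).
    """
    trees: dict[str, IntervalTree] = {}
    for iv in a:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    count = 0
    if isinstance(b, PeakSet):
        records = [(iv.chrom, iv.start, iv.end) for iv in b]
    else:
        records = [(chrom, pos, pos + 1) for chrom, pos in b]
    for chrom, start, end in records:
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            count += 1
    return count


def ranked_enrichment_curve(
    ranked_genes: Sequence[str],
    target_set: set[str],
    window: int = 100,
    genome_size: int | None = None,
) -> list[tuple[int, float]]:
    """Sliding-window fold enrichment of target genes along a ranking.

    For every window end r (windows of ``window`` genes sliding by 1), the
    fold is (hits_in_window/window)/(|target|/genome_size), the genome-wide
    target rate serving as background. ``genome_size`` defaults to the
    ranking length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    genes = list(ranked_genes)
    if genome_size is None:
        genome_size = len(genes)
    base = len(target_set) / genome_size
    if base == 0:
        raise ValueError("empty target set")
    if window > len(genes):
        warnings.warn("window longer than the ranking; using one truncated window")
        hits = sum(g in target_set for g in genes)
        return [(len(genes), (hits / len(genes)) / base)]
    hit = np.array([g in target_set for g in genes], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(hit)])
    out = []
    for end in range(window, len(genes) + 1):
        in_win = csum[end] - csum[end - window]
        out.append((end, (in_win / window) / base))
    return out
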