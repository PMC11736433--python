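"""Genomic data model and format IO.

The whole toolkit operates on four kinds of objects: genomic intervals
(enhancers/peaks), sparse cell-by-feature matrices (accessibility and
expression), gene TSS annotations, and per-cell condition labels. Peaks use
BED conventions throughout: 0-based, half-open intervals, sorted by
(chrom, start). Matrices are stored cells-as-rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "CellByFeatureMatrix",
    "GeneAnnotation",
    "ConditionLabels",
    "read_peaks",
    "write_peaks",
    "read_matrix",
    "write_matrix",
    "read_gene_annotation",
    "read_condition_labels",
    "peaks_in_window",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with a stable id."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def distance_to(self, other: "GenomicInterval") -> float:
        """Midpoint distance; infinite across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        return abs(self.midpoint - other.midpoint)


class PeakSet:
    """Ordered, id-indexed universe of enhancers (peaks).

    Intervals are kept sorted by (chrom, start, end); ids must be unique.
    Overlapping intervals are allowed — no merging is ever performed.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id)
        )
        self.index: dict[str, int] = {}
        for pos, iv in enumerate(self.intervals):
            if iv.id in self.index:
                raise ValueError(f"duplicate peak id {iv.id!r}")
            self.index[iv.id] = pos

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self.index

    def __getitem__(self, peak_id: str) -> GenomicInterval:
        return self.intervals[self.index[peak_id]]

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def distance(self, id_a: str, id_b: str) -> float:
        return self[id_a].distance_to(self[id_b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": [iv.id for iv in self.intervals],
            }
        )


@dataclass
class CellByFeatureMatrix:
    """Sparse non-negative cells x features matrix (peaks or genes)."""

    cells: list[str]
    features: list[str]
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X, dtype=np.float64)
        if self.X.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("negative entries are not allowed")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def binarized(self) -> "CellByFeatureMatrix":
        B = self.X.copy()
        B.data = (B.data > 0).astype(np.float64)
        B.eliminate_zeros()
        return CellByFeatureMatrix(list(self.cells), list(self.features), B)

    def subset_cells(self, cell_ids: Sequence[str]) -> "CellByFeatureMatrix":
        pos = {c: i for i, c in enumerate(self.cells)}
        idx = [pos[c] for c in cell_ids]
        return CellByFeatureMatrix(list(cell_ids), list(self.features), self.X[idx])

    def feature_vector(self, feature_id: str) -> np.ndarray:
        j = self.features.index(feature_id)
        return np.asarray(self.X[:, j].todense()).ravel()


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene anchored at its TSS (width-1 interval) with a strand."""

    gene_id: str
    tss: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss.end != self.tss.start + 1:
            raise ValueError("TSS must be a width-1 interval")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class ConditionLabels:
    """Cell -> condition label plus the ordered condition list.

    For time series the order of ``conditions`` is the developmental order.
    """

    labels: dict[str, str]
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.labels.values()))
        if not self.conditions:
            self.conditions = seen
        missing = set(seen) - set(self.conditions)
        if missing:
            raise ValueError(f"labels use conditions not in the ordered list: {missing}")
        for cond in self.conditions:
            if cond not in seen:
                raise ValueError(f"condition {cond!r} has no cells")

    def cells_for(self, condition: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == condition]

    def validate_against(self, m: CellByFeatureMatrix) -> None:
        missing = set(self.labels) - set(m.cells)
        if missing:
            raise ValueError(f"labeled cells absent from matrix: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_peaks(path: str | Path) -> PeakSet:
    """Read a BED file (3+ columns) into a :class:`PeakSet`.

    Ids come from column 4 when present, otherwise synthesized as
    ``chrom:start-end``.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            peak_id = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                intervals.append(GenomicInterval(chrom, start, end, peak_id))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def _read_ids(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def read_matrix(
    path_matrix: str | Path,
    path_rows: str | Path | None = None,
    path_cols: str | Path | None = None,
) -> CellByFeatureMatrix:
    """Read a cells x features matrix.

    Either a MatrixMarket ``.mtx`` file plus row/col id files, or a dense TSV
    whose header row carries feature ids and whose first column carries cell
    ids (row/col files then ignored).
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_rows is None or path_cols is None:
            raise ValueError("MTX input requires row and column id files")
        X = sp.csr_matrix(scipy.io.mmread(path_matrix))
        rows, cols = _read_ids(path_rows), _read_ids(path_cols)
        if X.shape != (len(rows), len(cols)):
            raise ValueError(
                f"dimension mismatch: matrix is {X.shape}, expected "
                f"({len(rows)}, {len(cols)}) from id files"
            )
        return CellByFeatureMatrix(rows, cols, X)
    df = pd.read_csv(path_matrix, sep="\t", index_col=0)
    return CellByFeatureMatrix(
        [str(c) for c in df.index],
        [str(f) for f in df.columns],
        sp.csr_matrix(df.to_numpy(dtype=np.float64)),
    )


def write_matrix(
    m: CellByFeatureMatrix,
    path_matrix: str | Path,
    path_rows: str | Path | None = None,
    path_cols: str | Path | None = None,
) -> None:
    """Write MTX + id files (``.mtx`` suffix) or a dense TSV otherwise."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_rows is None or path_cols is None:
            raise ValueError("MTX output requires row and column id paths")
        scipy.io.mmwrite(path_matrix, sp.coo_matrix(m.X))
        Path(path_rows).write_text("".join(f"{c}\n" for c in m.cells))
        Path(path_cols).write_text("".join(f"{f}\n" for f in m.features))
    else:
        pd.DataFrame(
            m.X.toarray(), index=m.cells, columns=m.features
        ).to_csv(path_matrix, sep="\t")


def read_gene_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a TSS TSV/BED: chrom, start, end, gene_id[, strand]; width-1 rows."""
    genes: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected chrom,start,end,gene")
            chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[4] if len(fields) >= 5 and fields[4] in {"+", "-"} else "+"
            genes[gene_id] = GeneAnnotation(
                gene_id, GenomicInterval(chrom, start, end, f"tss:{gene_id}"), strand
            )
    return genes


def read_condition_labels(path: str | Path) -> ConditionLabels:
    """Read a two-column TSV (cell, condition); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("condition labels need two columns: cell, condition")
    if df.iloc[0, 0].lower() in {"cell", "cell_id", "barcode"}:
        df = df.iloc[1:]
    return ConditionLabels(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def peaks_in_window(
    peaks: PeakSet, anchor: GenomicInterval, flank: int
) -> list[str]:
    """Ids of peaks overlapping ``[anchor.start - flank, anchor.end + flank)``.

    Overlap uses half-open semantics on the anchor's chromosome; the result
    preserves genomic order. An empty list is a valid outcome.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo = anchor.start - flank
    hi = anchor.end + flank
    return [
        iv.id
        for iv in peaks
        if iv.overlaps(anchor.chrom, lo, hi)
    ]
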