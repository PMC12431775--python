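"""Coordinate conventions, interval algebra, annotation and standard-format I/O.

All genomic coordinates are 0-based half-open (BED convention). Every other
module exchanges intervals, gene models, TADs, conservation tracks and
cell-group maps through the types defined here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Merged cell groups used for footprinting and all per-group statistics,
#: ordered along the differentiation axis: proliferative progenitors (PRO),
#: common precursors (CO), GABAergic branch (GA) and glutamatergic branch (GL).
DEFAULT_GROUPS = (
    "PRO1_2", "CO1_2", "GA1_2", "GA3_4", "GA5_6", "GL1_2", "GL3_4", "GL5",
)


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph content; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


class TadSet:
    """Topologically associating domains, queryable by point containment.

    Used to bound the search space when linking accessibility features to a
    gene: only features inside the TAD containing the gene's TSS are tested.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def containing(self, chrom: str, pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.at(pos)),
                      key=lambda iv: (iv.width, iv.start))


class ConservationTrack:
    """Per-base conservation scores in [0, 1], dense per chromosome.

    Positions absent from the source track score 0, matching the sparse
    bedGraph convention where unscored bases are simply not listed.
    """

    def __init__(self, scores: Mapping[str, np.ndarray]):
        self._scores: dict[str, np.ndarray] = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"conservation scores outside [0,1] on {chrom}")
            self._scores[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self._scores)

    def chrom_length(self, chrom: str) -> int:
        return int(self._scores[chrom].size)

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); positions beyond the stored array are 0."""
        if start < 0 or end <= start:
            raise ValueError("invalid range")
        arr = self._scores.get(chrom)
        out = np.zeros(end - start, dtype=float)
        if arr is None:
            return out
        lo, hi = min(start, arr.size), min(end, arr.size)
        out[: hi - lo] = arr[lo:hi]
        return out

    def chrom_scores(self, chrom: str) -> np.ndarray:
        return self._scores[chrom]


@dataclass
class CellGroupMap:
    """cell_id -> group label, plus the ordered list of group labels."""

    assignments: pd.Series
    group_order: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        self.assignments = self.assignments.astype(str)
        unknown = set(self.assignments.unique()) - set(self.group_order)
        if unknown:
            raise ValueError(f"cells assigned to unknown groups: {sorted(unknown)}")

    def cells_in(self, group: str) -> pd.Index:
        if group not in self.group_order:
            raise ValueError(f"unknown group {group!r}")
        return self.assignments.index[self.assignments == group]

    def group_means(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Per-group column means of a cells x columns matrix."""
        shared = matrix.index.intersection(self.assignments.index)
        grouped = matrix.loc[shared].groupby(self.assignments.loc[shared])
        means = grouped.mean()
        return means.reindex([g for g in self.group_order if g in means.index])


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def interval_overlap(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share at least ``min_bp`` bases (half-open)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    shared = min(a.end, b.end) - max(a.start, b.start)
    return shared >= min_bp


def tss_feature_distance(gene: GeneModel, feature: GenomicInterval) -> int:
    """Distance in bp from the TSS to the nearest base of the feature (0 if inside)."""
    if gene.chrom != feature.chrom:
        raise ValueError(
            f"gene {gene.gene_id} on {gene.chrom} vs feature on {feature.chrom}"
        )
    if feature.contains(gene.tss):
        return 0
    return min(abs(gene.tss - feature.start), abs(gene.tss - (feature.end - 1)))


def assign_tad(gene: GeneModel, tads: TadSet) -> GenomicInterval | None:
    """The TAD containing the gene's TSS; smallest-width one if several overlap."""
    hits = tads.containing(gene.chrom, gene.tss)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def parse_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals (coordinates taken verbatim)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
                )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Tab-separated gene table with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path,
                  chrom_lengths: Mapping[str, int] | None = None) -> ConservationTrack:
    """Read a bedGraph into a dense per-chromosome conservation track."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str, "start": int, "end": int, "score": float},
    )
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for chrom, sub in df.groupby("chrom"):
        lengths.setdefault(str(chrom), int(sub["end"].max()))
        lengths[str(chrom)] = max(lengths[str(chrom)], int(sub["end"].max()))
    arrays = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    for chrom, sub in df.groupby("chrom"):
        arr = arrays[str(chrom)]
        for start, end, score in zip(sub["start"], sub["end"], sub["score"]):
            arr[start:end] = score
    return ConservationTrack(arrays)


def write_bedgraph(track: ConservationTrack, path: str | Path,
                   decimals: int = 6) -> None:
    """Write a track as run-length merged bedGraph, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = np.round(track.chrom_scores(chrom), decimals)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.{decimals}g}\n")


def read_cell_groups(path: str | Path,
                     group_order: Sequence[str] = DEFAULT_GROUPS) -> CellGroupMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "group"} <= set(df.columns):
        raise ValueError("cell group table needs columns cell_id, group")
    series = pd.Series(df["group"].values, index=df["cell_id"].values, name="group")
    return CellGroupMap(series, tuple(group_order))


def write_cell_groups(groups: CellGroupMap, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": groups.assignments.index, "group": groups.assignments.values}
    ).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Dense matrix TSV: first column holds row ids, header holds column ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.name, iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals],
        columns=["name", "chrom", "start", "end", "strand"],
    )
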