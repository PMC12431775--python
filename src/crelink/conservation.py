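"""Conserved-nucleotide classification and PWM-weighted motif-site scoring.

A base is "conserved" when its phastCons-style score is at least a threshold
(default 0.5). Per-chromosome enrichment of conserved bases inside a region
class (exons, introns, accessibility features) is tested with Fisher's exact
test on the full 2x2 base-count table. A motif site's conservation is the
weighted mean of per-base scores, weighted by the maximum nucleotide
probability of each PWM column, so that information-rich positions dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome_core import ConservationTrack, GenomicInterval

ALPHABET = "ACGT"

#: Default conserved-base threshold (score "at least 0.5").
CONSERVED_THRESHOLD = 0.5


@dataclass(frozen=True)
class MotifModel:
    """A position probability matrix for one TF motif (positions x ACGT)."""

    tf_name: str
    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM must be a width x 4 matrix with width >= 1")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.motif_id}: rows must each sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    def position_weights(self, strand: str = "+") -> np.ndarray:
        """Per-position weights = column maxima; order reversed on the - strand.

        Complementing the matrix is unnecessary: the maximum probability of a
        column equals that of its reverse complement column.
        """
        w = self.matrix.max(axis=1)
        return w[::-1] if strand == "-" else w


@dataclass(frozen=True)
class MotifSite:
    """A genomic instance of a motif inside an accessibility feature."""

    site_id: str
    motif_id: str
    tf_name: str
    interval: GenomicInterval
    strand: str
    feature_id: str | None = None
    weighted_conservation: float = float("nan")


@dataclass(frozen=True)
class ConservationEnrichment:
    """2x2 base-count table and Fisher's exact result for one chromosome."""

    chrom: str
    conserved_in: int
    nonconserved_in: int
    conserved_out: int
    nonconserved_out: int
    odds_ratio: float  # nan when a zero cell makes it undefined
    p_value: float

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.conserved_in, self.nonconserved_in],
             [self.conserved_out, self.nonconserved_out]]
        )


def weighted_motif_conservation(
    pwm: MotifModel,
    site: GenomicInterval,
    track: ConservationTrack,
    strand: str = "+",
) -> float:
    """PWM-weighted mean conservation over the bases of a motif site.

    With w_j the maximum nucleotide probability of PWM column j (columns
    reversed for - strand sites) and c_j the conservation score of site base
    j, returns sum(w_j c_j) / sum(w_j), a value in [0, 1].
    """
    if site.width != pwm.width:
        raise ValueError(
            f"site width {site.width} != motif {pwm.motif_id} width {pwm.width}"
        )
    w = pwm.position_weights(strand)
    c = track.scores(site.chrom, site.start, site.end)
    return float(np.dot(w, c) / w.sum())


def annotate_sites(
    sites: Iterable[MotifSite],
    motifs: dict[str, MotifModel],
    track: ConservationTrack,
) -> list[MotifSite]:
    """Return sites with ``weighted_conservation`` filled in from the track."""
    out = []
    for s in sites:
        score = weighted_motif_conservation(
            motifs[s.motif_id], s.interval, track, s.strand
        )
        out.append(
            MotifSite(s.site_id, s.motif_id, s.tf_name, s.interval, s.strand,
                      s.feature_id, score)
        )
    return out


def flatten_regions(regions: Sequence[GenomicInterval]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent intervals into a disjoint union of ranges."""
    spans = sorted((iv.start, iv.end) for iv in regions)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def conservation_enrichment(
    regions: Sequence[GenomicInterval],
    track: ConservationTrack,
    chrom: str,
    conserved_threshold: float = CONSERVED_THRESHOLD,
    alternative: str = "two-sided",
) -> ConservationEnrichment:
    """Fisher's exact enrichment of conserved bases inside a region class.

    Every base of the chromosome is classified as conserved (score >=
    threshold) or not, and as inside the flattened region union or not;
    regions are flattened so no base is double-counted. The four counts sum
    to the chromosome length.
    """
    if not 0 < conserved_threshold <= 1:
        raise ValueError("conserved_threshold must be in (0, 1]")
    off = [iv for iv in regions if iv.chrom != chrom]
    if off:
        raise ValueError(f"{len(off)} region(s) not on {chrom}")
    scores = track.chrom_scores(chrom)
    conserved = scores >= conserved_threshold
    in_region = np.zeros(scores.size, dtype=bool)
    for s, e in flatten_regions(regions):
        in_region[s: min(e, scores.size)] = True
    a = int(np.sum(conserved & in_region))
    b = int(np.sum(~conserved & in_region))
    c = int(np.sum(conserved & ~in_region))
    d = int(np.sum(~conserved & ~in_region))
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return ConservationEnrichment(chrom, a, b, c, d, odds, float(p))


# ---------------------------------------------------------------------------
# MEME-like motif text format
# ---------------------------------------------------------------------------

def read_motifs(path: str | Path) -> list[MotifModel]:
    """Read motifs from a minimal MEME-style probability-matrix text file.

    Expected blocks::

        MOTIF <motif_id> <tf_name>
        letter-probability matrix: alength= 4 w= <width>
        <pA> <pC> <pG> <pT>
        ...
    """
    motifs: list[MotifModel] = []
    motif_id = tf_name = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows
        if motif_id is not None and rows:
            m = np.array(rows)
            sums = m.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                raise ValueError(f"motif {motif_id}: rows do not sum to 1")
            m = m / sums[:, None]  # absorb text round-off
            motifs.append(MotifModel(tf_name or motif_id, motif_id, m))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                motif_id = parts[1]
                tf_name = parts[2] if len(parts) > 2 else parts[1]
            elif line.startswith("letter-probability") or not line:
                continue
            elif line[0].isdigit() or line[0] in ".-0":
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def write_motifs(motifs: Iterable[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
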