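"""Agreement statistics between CUT&Tag peaks and footprint-bound motif sites.

For each TF with CUT&Tag data four quantities are reported: the number of
consensus peaks, the number of bound motif sites (positive footprint in at
least one cell group), the percentage of peaks overlapping a bound site, and
the percentage of bound sites overlapping a peak. Overlap requires at least
one shared base. A second analysis places each bound site within its
containing peaks on a 0-1 normalized peak axis to show where footprints fall
relative to peak boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_core import GenomicInterval, interval_overlap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorroborationStats:
    tf_name: str
    n_peaks: int
    n_bound_sites: int
    pct_peaks_with_site: float
    pct_sites_in_peak: float


@dataclass(frozen=True)
class PositionDensity:
    positions: np.ndarray  # normalized site midpoints in [0, 1]
    bin_edges: np.ndarray
    counts: np.ndarray


def _trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def corroboration_stats(
    tf_name: str,
    peaks: Sequence[GenomicInterval],
    bound_sites: Sequence[GenomicInterval],
) -> CorroborationStats:
    """The four corroboration quantities for one TF (min 1 bp overlap).

    A site bound in several cell groups appears once in ``bound_sites``; a
    site inside several peaks still counts once in the site percentage.
    """
    if not peaks or not bound_sites:
        log.warning("TF %s: zero peaks or zero bound sites", tf_name)
        return CorroborationStats(tf_name, len(peaks), len(bound_sites), 0.0, 0.0)
    site_trees = _trees(bound_sites)
    peaks_hit = sum(
        1 for pk in peaks
        if site_trees.get(pk.chrom) and site_trees[pk.chrom].overlap(pk.start, pk.end)
    )
    peak_trees = _trees(peaks)
    sites_hit = sum(
        1 for s in bound_sites
        if peak_trees.get(s.chrom) and peak_trees[s.chrom].overlap(s.start, s.end)
    )
    return CorroborationStats(
        tf_name, len(peaks), len(bound_sites),
        100.0 * peaks_hit / len(peaks), 100.0 * sites_hit / len(bound_sites))


def footprint_positions_in_peaks(
    peaks: Sequence[GenomicInterval],
    bound_sites: Sequence[GenomicInterval],
    n_bins: int = 20,
) -> PositionDensity:
    """Normalized positions of bound-site midpoints along containing peaks.

    For each (peak, contained site) pair the position is
    (site midpoint - peak start) / peak width, clipped to [0, 1]. A site in
    two overlapping peaks contributes one position per peak.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    site_trees = _trees(bound_sites)
    positions: list[float] = []
    for pk in peaks:
        if pk.end - pk.start <= 0:  # defensive: GenomicInterval forbids this
            log.warning("zero-width peak skipped: %s", pk)
            continue
        tree = site_trees.get(pk.chrom)
        if not tree:
            continue
        for hit in tree.overlap(pk.start, pk.end):
            site = bound_sites[hit.data]
            mid = 0.5 * (site.start + site.end - 1)
            positions.append(
                float(np.clip((mid - pk.start) / (pk.end - pk.start), 0.0, 1.0)))
    pos = np.array(sorted(positions))
    counts, edges = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    return PositionDensity(pos, edges, counts)
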