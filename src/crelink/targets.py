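"""Selector-TF target-gene inference, classification and characterization.

A gene is a target of a selector TF when some accessibility feature in the
gene's TAD satisfies four conditions simultaneously:

1. the TF's motif in the feature carries a bound footprint in the early
   GABAergic (GA1_2) or early glutamatergic (GL1_2) precursor group;
2. the feature is linked to the gene with |z| > 2 and p < 0.01;
3. the weighted mean conservation of the motif site is > 0.5;
4. a CUT&Tag consensus peak of the TF overlaps the feature (>= 1 bp).

Downstream characterization covers positive/negative link counts, nearest
TSS-feature distance bins (0-5, 5-50, > 50 kb), per-bin expression
variability, GA/GL-specific classification of targets, a two-edge GSEA over
the GA1_2 vs GL1_2 log2 fold-change axis, and hypergeometric marker-overlap
similarity between cluster sets from two modalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import MotifSite
from .genome_core import (GeneModel, GenomicInterval, TadSet, assign_tad,
                          interval_overlap, tss_feature_distance)
from .linkage import LinkRecord
from .regulators import CONSERVATION_THRESHOLD

DISTANCE_BINS = ((0, 5_000), (5_000, 50_000), (50_000, None))
BIN_LABELS = ("0-5", "5-50", ">50")

TARGET_GROUPS = ("GA1_2", "GL1_2")
EXPRESSION_SUBSET_THRESHOLD = 0.5
LOG2FC_THRESHOLD = 0.5


@dataclass(frozen=True)
class TargetFeature:
    """One feature supporting a target call, with its full evidence."""

    feature_id: str
    gene_id: str
    z: float
    p: float
    sign: str
    peak_id: str | None
    site_ids: tuple[str, ...]
    site_conservation: tuple[float, ...]


@dataclass(frozen=True)
class TargetCall:
    tf_name: str
    gene_id: str
    features: tuple[TargetFeature, ...]
    nearest_distance: int
    distance_bin: str
    label: str = "unclassified"


@dataclass(frozen=True)
class DeRecord:
    gene_id: str
    log2fc: float
    p: float
    p_adj: float
    frac_a: float
    frac_b: float


@dataclass(frozen=True)
class EnrichmentResult:
    ranked: tuple[str, ...]
    running: np.ndarray
    argmax: int
    argmin: int
    leading_edge_a: tuple[str, ...]
    leading_edge_b: tuple[str, ...]


def distance_bin(distance: int) -> str:
    """Half-open distance bins [0,5kb), [5kb,50kb), [50kb,inf)."""
    for (lo, hi), label in zip(DISTANCE_BINS, BIN_LABELS):
        if hi is None or lo <= distance < hi:
            if distance >= lo:
                return label
    raise ValueError(f"negative distance {distance}")


def identify_targets(
    tf_name: str,
    genes: Sequence[GeneModel],
    tads: TadSet,
    links: Mapping[str, Sequence[LinkRecord]],
    features: Mapping[str, GenomicInterval],
    sites: Sequence[MotifSite],
    footprints: pd.DataFrame,
    peaks: Mapping[str, Sequence[GenomicInterval]],
    groups: Sequence[str] = TARGET_GROUPS,
    *,
    z_min: float | None = 2.0,
    p_max: float | None = 0.01,
    conservation_min: float | None = CONSERVATION_THRESHOLD,
    require_footprint: bool = True,
    require_peak: bool = True,
) -> list[TargetCall]:
    """Four-condition target-gene inference for one selector TF.

    ``links`` maps gene_id to the LinkRecords of all features in that gene's
    TAD. Any condition can be disabled (``None`` threshold / ``require_*``
    flag), which can only grow the returned set. Raises if the TF has no
    CUT&Tag peak set while the peak condition is active.
    """
    if require_peak and tf_name not in peaks:
        raise KeyError(f"no CUT&Tag peak set for TF {tf_name!r}")
    tf_peaks = list(peaks.get(tf_name, []))

    if require_footprint:
        from .regulators import bound_in_any_group
        bound = bound_in_any_group(footprints, list(groups))
    else:
        bound = None

    # features containing a qualifying site of this TF
    feat_sites: dict[str, list[MotifSite]] = {}
    for s in sites:
        if s.tf_name != tf_name or s.feature_id is None:
            continue
        if bound is not None and s.site_id not in bound:
            continue
        if conservation_min is not None and not (
                s.weighted_conservation > conservation_min):
            continue
        feat_sites.setdefault(s.feature_id, []).append(s)

    def overlapping_peak(iv: GenomicInterval) -> str | None:
        for i, pk in enumerate(tf_peaks):
            if interval_overlap(iv, pk, 1):
                return pk.name or f"{tf_name}_peak_{i}"
        return None

    calls: list[TargetCall] = []
    for gene in genes:
        supports: list[TargetFeature] = []
        for link in links.get(gene.gene_id, []):
            if z_min is not None and not abs(link.z) > z_min:
                continue
            if p_max is not None and not link.p < p_max:
                continue
            if link.feature_id not in feat_sites:
                continue
            iv = features[link.feature_id]
            peak_id = overlapping_peak(iv)
            if require_peak and peak_id is None:
                continue
            ss = feat_sites[link.feature_id]
            supports.append(TargetFeature(
                link.feature_id, gene.gene_id, link.z, link.p, link.sign,
                peak_id, tuple(s.site_id for s in ss),
                tuple(s.weighted_conservation for s in ss)))
        if supports:
            dists = [tss_feature_distance(gene, features[tfeat.feature_id])
                     for tfeat in supports]
            nearest = min(dists)
            calls.append(TargetCall(
                tf_name, gene.gene_id, tuple(supports), nearest,
                distance_bin(nearest)))
    return calls


# ---------------------------------------------------------------------------
# differential expression and classification
# ---------------------------------------------------------------------------

def de_wilcoxon(
    expression: pd.DataFrame,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    adjust: str = "bonferroni",
) -> list[DeRecord]:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    log2FC = log2((mean(expm1 A) + 1) / (mean(expm1 B) + 1)) on the de-logged
    scale; the expressing fraction is the proportion of cells with value > 0.
    Exact p (full enumeration) for small tie-free groups, normal approximation
    with tie correction otherwise.
    """
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("need >= 3 cells in each group")
    a_mat = expression.loc[list(cells_a)]
    b_mat = expression.loc[list(cells_b)]
    records = []
    n_genes = expression.shape[1]
    for gene in expression.columns:
        a = a_mat[gene].to_numpy()
        b = b_mat[gene].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
            method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) \
                else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method=method).pvalue)
        log2fc = float(np.log2((np.expm1(a).mean() + 1.0)
                               / (np.expm1(b).mean() + 1.0)))
        if adjust == "bonferroni":
            p_adj = min(1.0, p * n_genes)
        elif adjust == "bh":
            p_adj = p  # filled after the loop
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        records.append(DeRecord(gene, log2fc, p, p_adj,
                                float((a > 0).mean()), float((b > 0).mean())))
    if adjust == "bh":
        ps = np.array([r.p for r in records])
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = ps.size - rank_i
            prev = min(prev, ps[idx] * ps.size / i)
            adj[idx] = prev
        records = [DeRecord(r.gene_id, r.log2fc, r.p, float(adj[i]),
                            r.frac_a, r.frac_b)
                   for i, r in enumerate(records)]
    return records


def classify_targets(
    targets: Sequence[TargetCall],
    de: Mapping[str, DeRecord],
    ga_means: Mapping[str, float],
    gl_means: Mapping[str, float],
    log2fc_min: float = LOG2FC_THRESHOLD,
    expr_threshold: float = EXPRESSION_SUBSET_THRESHOLD,
) -> list[TargetCall]:
    """GABA-/glutamatergic-specific labels from fold change and group means.

    GABA-specific: log2FC > 0.5, GA mean > 0.5, GL mean < 0.5 (log1p);
    glut-specific mirrors with the signs reversed; otherwise unclassified.
    """
    out = []
    for t in targets:
        rec = de.get(t.gene_id)
        ga = ga_means.get(t.gene_id, 0.0)
        gl = gl_means.get(t.gene_id, 0.0)
        label = "unclassified"
        if rec is not None:
            if rec.log2fc > log2fc_min and ga > expr_threshold and gl < expr_threshold:
                label = "GABA-specific"
            elif rec.log2fc < -log2fc_min and gl > expr_threshold and ga < expr_threshold:
                label = "glut-specific"
        out.append(TargetCall(t.tf_name, t.gene_id, t.features,
                              t.nearest_distance, t.distance_bin, label))
    return out


def characterize_targets(
    targets: Sequence[TargetCall],
    group_means: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Sign counts, distance-bin counts and per-bin expression variability.

    ``group_means`` is a groups x genes matrix of mean log1p expression;
    variability of a gene is the standard deviation of its per-group means.
    """
    if not targets:
        raise ValueError("no targets to characterize")
    sign_counts = pd.Series(
        [f.sign for t in targets for f in t.features]).value_counts()
    signs = pd.DataFrame({
        "sign": ["+", "-"],
        "n_features": [int(sign_counts.get("+", 0)),
                       int(sign_counts.get("-", 0))]})
    bins = pd.DataFrame({
        "bin": list(BIN_LABELS),
        "n_genes": [sum(t.distance_bin == b for t in targets)
                    for b in BIN_LABELS]})
    out = {"sign_counts": signs, "distance_bins": bins}
    if group_means is not None:
        rows = []
        for t in targets:
            if t.gene_id in group_means.columns:
                sd = float(group_means[t.gene_id].std(ddof=1))
                rows.append({"gene_id": t.gene_id, "bin": t.distance_bin,
                             "variability": sd})
        out["variability"] = pd.DataFrame(
            rows, columns=["gene_id", "bin", "variability"])
    return out


def target_expression_subset(
    targets: Sequence[TargetCall],
    ga_means: Mapping[str, float],
    gl_means: Mapping[str, float],
    threshold: float = EXPRESSION_SUBSET_THRESHOLD,
) -> list[str]:
    """Target genes with GA1_2 mean > threshold OR GL1_2 mean > threshold."""
    return sorted({
        t.gene_id for t in targets
        if ga_means.get(t.gene_id, 0.0) > threshold
        or gl_means.get(t.gene_id, 0.0) > threshold})


# ---------------------------------------------------------------------------
# two-edge GSEA
# ---------------------------------------------------------------------------

def gsea_two_edge(ranked: Sequence[str], gene_set: Iterable[str]
                  ) -> EnrichmentResult:
    """Classic (unweighted) running-sum enrichment with two leading edges.

    ``ranked`` is ordered by descending score (e.g. GA1_2-vs-GL1_2 log2FC).
    Hits increment by 1/|set ∩ ranked|, misses decrement by 1/(n - |hits|).
    Leading edge A = set members at or before the running-sum maximum (genes
    enriched toward the top); leading edge B = set members at or after the
    minimum (enriched toward the bottom).
    """
    ranked = list(ranked)
    in_set = set(gene_set) & set(ranked)
    if not in_set:
        raise ValueError("gene set is disjoint from the ranking")
    if len(in_set) == len(ranked):
        raise ValueError("gene set covers the entire ranking")
    n = len(ranked)
    n_hit = len(in_set)
    hit_inc = 1.0 / n_hit
    miss_dec = 1.0 / (n - n_hit)
    steps = np.array([hit_inc if g in in_set else -miss_dec for g in ranked])
    running = np.cumsum(steps)
    argmax = int(np.argmax(running))
    argmin = int(np.argmin(running))
    edge_a = tuple(g for g in ranked[: argmax + 1] if g in in_set)
    edge_b = tuple(g for g in ranked[argmin:] if g in in_set)
    return EnrichmentResult(tuple(ranked), running, argmax, argmin,
                            edge_a, edge_b)


def rank_genes_for_gsea(
    de: Sequence[DeRecord],
    p_adj_max: float = 0.01,
    min_expressing_fraction: float = 0.1,
) -> list[str]:
    """Ranking axis for GSEA: significant genes by descending log2FC.

    Keeps genes with adjusted p below ``p_adj_max`` and an expressing
    fraction of at least ``min_expressing_fraction`` in either group.
    """
    kept = [r for r in de
            if r.p_adj < p_adj_max
            and max(r.frac_a, r.frac_b) >= min_expressing_fraction]
    kept.sort(key=lambda r: (-r.log2fc, r.gene_id))
    return [r.gene_id for r in kept]


# ---------------------------------------------------------------------------
# cross-modality marker similarity
# ---------------------------------------------------------------------------

def filter_markers(de: Sequence[DeRecord], p_adj_max: float = 0.05,
                   top_k: int = 25) -> list[str]:
    """Cluster marker filter: adjusted p < 0.05, top 25 by log2FC."""
    kept = [r for r in de if r.p_adj < p_adj_max]
    kept.sort(key=lambda r: (-r.log2fc, r.gene_id))
    return [r.gene_id for r in kept[:top_k]]


def marker_similarity(
    markers_a: Mapping[str, Sequence[str]],
    markers_b: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail p for marker overlap of every cluster pair.

    The universe is the shared gene-name pool of the two modalities; marker
    genes outside it are dropped with a warning. Entry (i, j) is
    P[X >= k] for k the observed overlap, drawing |A_i| from a universe of N
    containing |B_j| successes.
    """
    import logging
    uni = set(universe)
    n_universe = len(uni)

    def clean(markers: Mapping[str, Sequence[str]]) -> dict[str, set[str]]:
        out = {}
        for cl, genes in markers.items():
            inside = set(genes) & uni
            dropped = set(genes) - uni
            if dropped:
                logging.getLogger(__name__).warning(
                    "cluster %s: %d marker(s) outside universe dropped",
                    cl, len(dropped))
            out[cl] = inside
        return out

    a_sets, b_sets = clean(markers_a), clean(markers_b)
    mat = pd.DataFrame(index=list(a_sets), columns=list(b_sets), dtype=float)
    for ca, a in a_sets.items():
        for cb, b in b_sets.items():
            k = len(a & b)
            # P[X >= k]; sf(k-1) so that k = 0 gives exactly 1
            mat.loc[ca, cb] = float(
                stats.hypergeom.sf(k - 1, n_universe, len(b), len(a)))
    return mat


def targets_to_frame(targets: Sequence[TargetCall]) -> pd.DataFrame:
    rows = []
    for t in targets:
        n_pos = sum(f.sign == "+" for f in t.features)
        n_neg = sum(f.sign == "-" for f in t.features)
        rows.append({
            "tf_name": t.tf_name, "gene_id": t.gene_id,
            "n_features": len(t.features), "n_pos_links": n_pos,
            "n_neg_links": n_neg, "nearest_distance": t.nearest_distance,
            "bin": t.distance_bin, "class": t.label,
            "feature_ids": ",".join(f.feature_id for f in t.features)})
    return pd.DataFrame(rows, columns=[
        "tf_name", "gene_id", "n_features", "n_pos_links", "n_neg_links",
        "nearest_distance", "bin", "class", "feature_ids"])
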