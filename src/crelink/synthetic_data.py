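"""Synthetic single-cell multiome bundles with planted regulatory structure.

The generator emulates the statistical shape of the inputs the downstream
analyses consume: TADs tiling synthetic chromosomes, accessibility features
placed inside them, per-cell accessibility and log1p expression matrices over
eight merged cell groups along a bifurcating lineage (PRO -> CO -> GA / GL
branches), a per-base conservation track, motif models with placed sites,
per-group footprint scores, and CUT&Tag peak sets for a subset of TFs.

Planted structure and the generative model:

* planted cCRE links: a linked gene's features receive a group-specific
  activation increment on top of a gamma per-cell baseline; the gene's
  expression is a saturating (logistic) transform of the signed mean of its
  linked features' accessibility plus gaussian noise. Negative-effect
  features activate in the complementary lineage branch, so accessibility
  and expression move in opposite directions.
* planted regulator sets: motif sites of chosen TFs are placed inside the
  selector genes' linked features, marked bound in chosen groups, and given
  elevated per-base conservation; the TFs' expression is raised above the
  expression threshold in those groups.
* planted targets: selector-TF sites bound in GA1_2 or GL1_2 inside linked
  features of other genes, with CUT&Tag peaks covering each truly bound site
  with probability ``cuttag_sensitivity`` plus Poisson false peaks.
* decoy sites exercise every filter: they are unbound, or bound with
  deliberately non-conserved bases (below the 0.5 threshold).

``GroundTruth`` is derived by applying the printed evidence rules to the
realized (planted) evidence with plain loops — never by calling the analysis
modules — so recovery tests compare two independent routes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genome_core as gc
from .conservation import MotifModel, MotifSite, annotate_sites, read_motifs, write_motifs
from .genome_core import (CellGroupMap, ConservationTrack, GeneModel,
                          GenomicInterval, TadSet, interval_overlap)

GA_PATTERN = ("GA1_2", "GA3_4", "GA5_6")
GL_PATTERN = ("GL1_2", "GL3_4", "GL5")
REGULATOR_GROUPS = ("CO1_2", "GA1_2")


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study conditions for one synthetic bundle (defaults are the defaults)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_tads_per_chrom: int = 12
    n_genes: int = 60
    n_features: int = 600
    feature_width: tuple[int, int] = (200, 800)
    group_labels: tuple[str, ...] = gc.DEFAULT_GROUPS
    cells_per_group: int = 40

    n_tfs: int = 8
    n_selectors: int = 3
    motif_width: tuple[int, int] = (8, 12)

    n_linked_genes: int = 20
    links_per_selector: int = 4
    negative_link_fraction: float = 0.25
    effect_size: float = 1.0
    link_patterns: str = "mixed"  # or "ga_only"

    regulators_per_group: int = 3
    targets_per_tf: int = 8
    decoys_per_tf: int = 12

    baseline_shape: float = 2.0
    baseline_scale: float = 0.15
    activation_increment: float = 1.5
    expression_noise_sd: float = 0.25
    expression_max: float = 4.0
    drive_center: float = 0.9
    drive_scale: float = 0.4
    tf_expr_high: float = 2.0
    tf_expr_low: float = 0.3
    tf_expression_threshold: float = 1.2

    cons_tile: int = 25
    cons_bg_beta: tuple[float, float] = (1.0, 8.0)
    cons_site_beta: tuple[float, float] = (24.0, 6.0)  # mean 0.8
    decoy_cons_max: float = 0.45

    cuttag_sensitivity: float = 0.9
    cuttag_fpr_per_mb: float = 5.0
    peak_halfwidth: int = 150

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_tads_per_chrom", "n_genes",
                     "n_features", "cells_per_group", "n_tfs", "n_selectors"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("cuttag_sensitivity", "negative_link_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_selectors > self.n_tfs:
            raise ConfigError("n_selectors cannot exceed n_tfs")

    @classmethod
    def noiseless(cls, seed: int = 0, **kw) -> "SynthConfig":
        """Zero evidence noise: exact-recovery study conditions."""
        kw.setdefault("expression_noise_sd", 0.0)
        kw.setdefault("cuttag_sensitivity", 1.0)
        kw.setdefault("cuttag_fpr_per_mb", 0.0)
        return cls(seed=seed, **kw)

    @classmethod
    def mini(cls, seed: int = 0, **kw) -> "SynthConfig":
        """Small bundle for smoke/determinism tests."""
        kw.setdefault("chrom_length", 120_000)
        kw.setdefault("n_tads_per_chrom", 5)
        kw.setdefault("n_genes", 24)
        kw.setdefault("n_features", 150)
        kw.setdefault("n_linked_genes", 8)
        kw.setdefault("cells_per_group", 35)
        kw.setdefault("targets_per_tf", 4)
        return cls(seed=seed, **kw)


@dataclass(frozen=True)
class PlantedLink:
    feature_id: str
    gene_id: str
    sign: str
    effect: float
    active_groups: tuple[str, ...]


@dataclass
class GroundTruth:
    links: list[PlantedLink]
    regulator_sets: dict[tuple[str, str], set[str]]  # (gene_id, group) -> TFs
    target_sets: dict[str, set[str]]                 # tf -> gene ids
    bound_sites: dict[str, set[str]]                 # group -> site ids


@dataclass
class SyntheticBundle:
    config: SynthConfig
    genes: list[GeneModel]
    tads: TadSet
    features: dict[str, GenomicInterval]
    conservation: ConservationTrack
    motifs: dict[str, MotifModel]
    sites: list[MotifSite]
    footprints: pd.DataFrame
    peaks: dict[str, list[GenomicInterval]]
    accessibility: pd.DataFrame
    expression: pd.DataFrame
    groups: CellGroupMap
    truth: GroundTruth

    @property
    def selector_tfs(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.config.n_selectors)]

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.config.n_tfs)]

    def feature_meta(self) -> pd.DataFrame:
        """Per-feature chrom/width/mean accessibility, for background matching."""
        rows = {fid: (iv.chrom, iv.width) for fid, iv in self.features.items()}
        meta = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["chrom", "width"])
        meta["mean_accessibility"] = self.accessibility.mean(axis=0).reindex(meta.index)
        return meta

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_features(cfg: SynthConfig, tads: list[GenomicInterval],
                    rng: np.random.Generator) -> dict[str, GenomicInterval]:
    per_tad = cfg.n_features // len(tads)
    if per_tad < 1:
        raise ConfigError("fewer features than TADs")
    slot = tads[0].width // per_tad
    if slot <= cfg.feature_width[1] + 2:
        raise ConfigError("features exceed TAD capacity")
    features: dict[str, GenomicInterval] = {}
    i = 0
    for tad in tads:
        for j in range(per_tad):
            width = int(rng.integers(cfg.feature_width[0], cfg.feature_width[1] + 1))
            lo = tad.start + j * slot
            start = int(rng.integers(lo, lo + slot - width))
            fid = f"feat_{i:04d}"
            features[fid] = GenomicInterval(tad.chrom, start, start + width, fid)
            i += 1
    return features


def _place_site(rng: np.random.Generator, feature: GenomicInterval, width: int,
                occupied: list[tuple[int, int]]) -> tuple[int, int] | None:
    if feature.width < width:
        return None
    for _ in range(30):
        start = int(rng.integers(feature.start, feature.end - width + 1))
        end = start + width
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start, end
    return None


def simulate_bundle(cfg: SynthConfig) -> SyntheticBundle:
    """Generate a complete input bundle; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    # --- TADs tile each chromosome -------------------------------------
    tad_width = cfg.chrom_length // cfg.n_tads_per_chrom
    tad_list = [
        GenomicInterval(c, k * tad_width, (k + 1) * tad_width, f"tad_{c}_{k}")
        for c in chroms for k in range(cfg.n_tads_per_chrom)
    ]
    tads = TadSet(tad_list)

    # --- features -------------------------------------------------------
    features = _place_features(cfg, tad_list, rng)
    feature_ids = list(features)

    # --- genes (first n_tfs double as TF genes; first n_selectors of
    #     those are selector TFs with CUT&Tag data). Genes carrying
    #     planted links live in dedicated TADs so the planted regulatory
    #     structure is identifiable from the TAD-constrained search.
    tf_names = [f"TF{i + 1}" for i in range(cfg.n_tfs)]
    gene_ids = tf_names + [f"G{i + 1:03d}" for i in range(cfg.n_genes - cfg.n_tfs)]
    selectors = tf_names[: cfg.n_selectors]
    other_gene_ids = [g for g in gene_ids if g not in tf_names]
    n_other = max(0, cfg.n_linked_genes - cfg.n_selectors)
    linked_others = [str(g) for g in rng.choice(
        other_gene_ids, size=min(n_other, len(other_gene_ids)), replace=False)]
    linked_genes = selectors + linked_others
    if len(linked_genes) >= len(tad_list):
        raise ConfigError(
            "need more TADs than linked genes (each linked gene gets its own)")

    dedicated = [str(t) for t in rng.choice(
        [t.name for t in tad_list], size=len(linked_genes), replace=False)]
    tad_by_name = {t.name: t for t in tad_list}
    shared_tads = [t for t in tad_list if t.name not in dedicated]
    gene_tad: dict[str, GenomicInterval] = {}
    for gid, tname in zip(linked_genes, dedicated):
        gene_tad[gid] = tad_by_name[tname]
    k = 0
    for gid in gene_ids:
        if gid in gene_tad:
            continue
        gene_tad[gid] = shared_tads[k % len(shared_tads)]
        k += 1
    genes: list[GeneModel] = []
    for gid in gene_ids:
        tad = gene_tad[gid]
        tss = int(rng.integers(tad.start + 1_000, tad.end - 1_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gid, tad.chrom, tss, strand))

    # --- motifs ---------------------------------------------------------
    motifs: dict[str, MotifModel] = {}
    for tf in tf_names:
        width = int(rng.integers(cfg.motif_width[0], cfg.motif_width[1] + 1))
        mat = rng.dirichlet([0.3, 0.3, 0.3, 0.3], size=width)
        motifs[f"{tf}.M1"] = MotifModel(tf, f"{tf}.M1", mat)

    # --- planted links --------------------------------------------------
    tad_features: dict[str, list[str]] = {}
    for fid, iv in features.items():
        for tad in tad_list:
            if iv.chrom == tad.chrom and iv.start >= tad.start and iv.end <= tad.end:
                tad_features.setdefault(tad.name, []).append(fid)
                break

    used_features: set[str] = set()
    links: list[PlantedLink] = []
    gene_pattern: dict[str, tuple[str, ...]] = {}
    for gid in linked_genes:
        if gid in selectors or cfg.link_patterns == "ga_only":
            pattern = GA_PATTERN
        else:
            pattern = GA_PATTERN if rng.random() < 0.5 else GL_PATTERN
        gene_pattern[gid] = pattern
        pool = [f for f in tad_features.get(gene_tad[gid].name, [])
                if f not in used_features]
        n_links = cfg.links_per_selector if gid in selectors \
            else int(rng.integers(1, 3))
        chosen = [str(f) for f in rng.choice(pool, size=min(n_links, len(pool)),
                                             replace=False)]
        complement = GL_PATTERN if pattern == GA_PATTERN else GA_PATTERN
        for j, fid in enumerate(chosen):
            used_features.add(fid)
            negative = (gid not in selectors
                        and rng.random() < cfg.negative_link_fraction)
            links.append(PlantedLink(
                fid, gid, "-" if negative else "+", cfg.effect_size,
                complement if negative else pattern))

    gene_links: dict[str, list[PlantedLink]] = {}
    for ln in links:
        gene_links.setdefault(ln.gene_id, []).append(ln)
    feature_active: dict[str, tuple[str, ...]] = {
        ln.feature_id: ln.active_groups for ln in links}

    # --- cells and accessibility ---------------------------------------
    cells = []
    cell_group = []
    for g in cfg.group_labels:
        for i in range(cfg.cells_per_group):
            cells.append(f"{g}_c{i:03d}")
            cell_group.append(g)
    groups = CellGroupMap(pd.Series(cell_group, index=cells, name="group"),
                          cfg.group_labels)
    n_cells = len(cells)
    group_arr = np.array(cell_group)

    acc = rng.gamma(cfg.baseline_shape, cfg.baseline_scale,
                    size=(n_cells, len(feature_ids)))
    col_of = {fid: i for i, fid in enumerate(feature_ids)}
    for fid, active in feature_active.items():
        mask = np.isin(group_arr, active)
        acc[mask, col_of[fid]] += cfg.activation_increment
    accessibility = pd.DataFrame(acc, index=cells, columns=feature_ids)

    # --- planted regulator / target site placement ----------------------
    sites_raw: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {f: [] for f in feature_ids}
    planted_bound: dict[str, set[str]] = {}  # site_id -> groups
    site_counter = 0

    def add_site(tf: str, fid: str, bound_groups: Sequence[str],
                 conserved: bool) -> str | None:
        nonlocal site_counter
        motif = motifs[f"{tf}.M1"]
        placed = _place_site(rng, features[fid], motif.width, occupied[fid])
        if placed is None:
            return None
        sid = f"site_{site_counter:04d}"
        site_counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        sites_raw.append({
            "site_id": sid, "tf": tf, "motif_id": motif.motif_id,
            "feature_id": fid, "start": placed[0], "end": placed[1],
            "chrom": features[fid].chrom, "strand": strand,
            "conserved": conserved})
        planted_bound[sid] = set(bound_groups)
        return sid

    tf_active_groups: dict[str, set[str]] = {tf: set() for tf in tf_names}
    non_selector_tfs = tf_names[cfg.n_selectors:]
    for gid in selectors:
        feats = [ln.feature_id for ln in gene_links.get(gid, [])]
        if not feats:
            continue
        for grp in REGULATOR_GROUPS:
            pool = non_selector_tfs if grp == "CO1_2" else tf_names
            n = min(cfg.regulators_per_group, len(pool))
            for tf in rng.choice(pool, size=n, replace=False):
                fid = str(rng.choice(feats))
                if add_site(str(tf), fid, [grp], conserved=True):
                    tf_active_groups[str(tf)].add(grp)

    for tf in selectors:
        pool = [g for g in linked_genes if gene_links.get(g)]
        n = min(cfg.targets_per_tf, len(pool))
        for gid in rng.choice(pool, size=n, replace=False):
            gid = str(gid)
            grp = "GA1_2" if gene_pattern[gid] == GA_PATTERN else "GL1_2"
            positive = [ln.feature_id for ln in gene_links[gid]]
            fid = str(rng.choice(positive))
            if add_site(tf, fid, [grp], conserved=True):
                tf_active_groups[tf].add(grp)

    # decoys: unbound, or bound but deliberately non-conserved
    for tf in tf_names:
        for _ in range(cfg.decoys_per_tf):
            fid = str(rng.choice(feature_ids))
            bound = rng.random() < 0.5
            grp = [str(rng.choice(cfg.group_labels))] if bound else []
            add_site(tf, fid, grp, conserved=False)

    # --- expression ------------------------------------------------------
    def sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(x - cfg.drive_center) / cfg.drive_scale))

    expr = np.zeros((n_cells, len(gene_ids)))
    gcol = {gid: i for i, gid in enumerate(gene_ids)}
    for gid in gene_ids:
        if gid in gene_links:  # saturating transform of the signed link drive
            contrib = np.zeros(n_cells)
            for ln in gene_links[gid]:
                sgn = 1.0 if ln.sign == "+" else -1.0
                contrib += sgn * ln.effect * acc[:, col_of[ln.feature_id]]
            drive = contrib / len(gene_links[gid])
            base = cfg.expression_max * sigmoid(drive)
        elif gid in tf_names:
            # TF expression planted above threshold in active groups, and a
            # random sub-threshold profile elsewhere (capped so the planted
            # expression condition stays crisp)
            active = tf_active_groups[gid]
            lookup = {
                g: cfg.tf_expr_high if g in active
                else min(float(rng.gamma(2.0, 0.25)) + cfg.tf_expr_low, 1.0)
                for g in cfg.group_labels}
            base = np.array([lookup[g] for g in group_arr])
        else:  # unlinked gene: random per-group mean profile
            means = rng.gamma(2.0, 0.25, size=len(cfg.group_labels))
            lookup = dict(zip(cfg.group_labels, means))
            base = np.array([lookup[g] for g in group_arr])
        noise = rng.normal(0.0, cfg.expression_noise_sd, size=n_cells) \
            if cfg.expression_noise_sd > 0 else 0.0
        expr[:, gcol[gid]] = np.clip(base + noise, 0.0, None)
    expression = pd.DataFrame(expr, index=cells, columns=gene_ids)

    # --- conservation track ---------------------------------------------
    cons: dict[str, np.ndarray] = {}
    for c in chroms:
        n_tiles = int(np.ceil(cfg.chrom_length / cfg.cons_tile))
        tiles = rng.beta(*cfg.cons_bg_beta, size=n_tiles)
        arr = np.repeat(tiles, cfg.cons_tile)[: cfg.chrom_length]
        cons[c] = arr
    for s in sites_raw:
        arr = cons[s["chrom"]]
        width = s["end"] - s["start"]
        if s["conserved"]:
            arr[s["start"]: s["end"]] = rng.beta(*cfg.cons_site_beta, size=width)
        else:
            arr[s["start"]: s["end"]] = rng.uniform(0.0, cfg.decoy_cons_max,
                                                    size=width)
    track = ConservationTrack(cons)

    # --- footprint scores ------------------------------------------------
    tf_group_expr = groups.group_means(expression[tf_names])
    fp_rows = []
    for s in sites_raw:
        tf = s["tf"]
        for grp in cfg.group_labels:
            expressed = tf_group_expr.loc[grp, tf] > cfg.tf_expression_threshold
            if grp in planted_bound[s["site_id"]] and expressed:
                score = float(0.05 + rng.gamma(2.0, 0.4))
            else:
                score = 0.0 if rng.random() < 0.3 else float(-rng.gamma(2.0, 0.3))
            fp_rows.append((s["site_id"], grp, score))
    footprints = pd.DataFrame(
        fp_rows, columns=["site_id", "cell_group", "footprint_score"])

    # --- motif sites with annotated conservation ------------------------
    sites = [
        MotifSite(s["site_id"], s["motif_id"], s["tf"],
                  GenomicInterval(s["chrom"], s["start"], s["end"], s["site_id"]),
                  s["strand"], s["feature_id"])
        for s in sites_raw
    ]
    sites = annotate_sites(sites, motifs, track)
    site_by_id = {s.site_id: s for s in sites}

    # --- CUT&Tag peaks ----------------------------------------------------
    bound_any = {
        sid for sid, grp in _realized_bound(footprints).items() if grp}
    peaked_tfs = selectors + non_selector_tfs[:2]
    peaks: dict[str, list[GenomicInterval]] = {}
    chrom_of_site = {s["site_id"]: s["chrom"] for s in sites_raw}
    for tf in peaked_tfs:
        plist: list[GenomicInterval] = []
        k = 0
        for s in sites_raw:
            if s["tf"] != tf or s["site_id"] not in bound_any:
                continue
            if rng.random() < cfg.cuttag_sensitivity:
                mid = (s["start"] + s["end"]) // 2
                start = max(0, mid - cfg.peak_halfwidth)
                end = min(cfg.chrom_length, mid + cfg.peak_halfwidth)
                plist.append(GenomicInterval(s["chrom"], start, end,
                                             f"{tf}_peak_{k}"))
                k += 1
        n_false = rng.poisson(
            cfg.cuttag_fpr_per_mb * cfg.n_chroms * cfg.chrom_length / 1e6)
        for _ in range(n_false):
            c = str(rng.choice(chroms))
            start = int(rng.integers(0, cfg.chrom_length - 300))
            plist.append(GenomicInterval(c, start, start + 300,
                                         f"{tf}_peak_{k}"))
            k += 1
        peaks[tf] = plist

    truth = _derive_truth(cfg, links, gene_links, site_by_id, footprints,
                          peaks, tf_group_expr, features)
    return SyntheticBundle(cfg, genes, tads, features, track, motifs, sites,
                           footprints, peaks, accessibility, expression,
                           groups, truth)


def _realized_bound(footprints: pd.DataFrame) -> dict[str, set[str]]:
    """site_id -> set of groups with a strictly positive footprint score."""
    pos = footprints[footprints["footprint_score"] > 0]
    out: dict[str, set[str]] = {sid: set() for sid in footprints["site_id"].unique()}
    for sid, grp in zip(pos["site_id"], pos["cell_group"]):
        out[sid].add(grp)
    return out


def _derive_truth(cfg: SynthConfig, links: list[PlantedLink],
                  gene_links: Mapping[str, list[PlantedLink]],
                  site_by_id: Mapping[str, MotifSite],
                  footprints: pd.DataFrame,
                  peaks: Mapping[str, list[GenomicInterval]],
                  tf_group_expr: pd.DataFrame,
                  features: Mapping[str, GenomicInterval]) -> GroundTruth:
    """Apply the printed evidence rules to the realized planted evidence.

    Plain-loop enumeration, independent of the analysis modules. Planted
    links are taken to pass the linkage thresholds (they do by construction
    under the study conditions).
    """
    bound = _realized_bound(footprints)
    bound_per_group: dict[str, set[str]] = {g: set() for g in cfg.group_labels}
    for sid, grps in bound.items():
        for g in grps:
            bound_per_group[g].add(sid)

    feature_sites: dict[str, list[MotifSite]] = {}
    for s in site_by_id.values():
        feature_sites.setdefault(s.feature_id, []).append(s)

    selectors = [f"TF{i + 1}" for i in range(cfg.n_selectors)]

    regulator_sets: dict[tuple[str, str], set[str]] = {}
    for gid in selectors:
        feats = [ln.feature_id for ln in gene_links.get(gid, [])]
        for grp in REGULATOR_GROUPS:
            tfs: set[str] = set()
            for fid in feats:
                for s in feature_sites.get(fid, []):
                    if (s.site_id in bound_per_group[grp]
                            and s.weighted_conservation > 0.5
                            and s.tf_name in tf_group_expr.columns
                            and tf_group_expr.loc[grp, s.tf_name] > cfg.tf_expression_threshold):
                        tfs.add(s.tf_name)
            regulator_sets[(gid, grp)] = tfs

    target_sets: dict[str, set[str]] = {}
    for tf in peaks:
        if tf not in selectors:
            continue
        hit: set[str] = set()
        ga_gl = bound_per_group["GA1_2"] | bound_per_group["GL1_2"]
        for gid, lns in gene_links.items():
            for ln in lns:
                feat = features[ln.feature_id]
                for s in feature_sites.get(ln.feature_id, []):
                    if s.tf_name != tf or s.site_id not in ga_gl:
                        continue
                    if not s.weighted_conservation > 0.5:
                        continue
                    if any(interval_overlap(feat, pk, 1) for pk in peaks[tf]):
                        hit.add(gid)
        target_sets[tf] = hit

    return GroundTruth(links, regulator_sets, target_sets, bound_per_group)


# ---------------------------------------------------------------------------
# bundle I/O: the exact standard formats genome_core reads
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, str]:
    """Emit the bundle as standard-format text files; returns the manifest.

    The manifest (also written as ``manifest.json``) maps each emitted file
    name to its sha256 checksum.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    gc.write_gene_table(bundle.genes, d / "genes.tsv")
    gc.write_bed(bundle.tads.intervals, d / "tads.bed")
    gc.write_bed(bundle.features.values(), d / "features.bed")
    gc.write_bedgraph(bundle.conservation, d / "conservation.bedgraph",
                      decimals=8)
    write_motifs(bundle.motifs.values(), d / "motifs.meme")

    pd.DataFrame([{
        "site_id": s.site_id, "motif_id": s.motif_id, "tf": s.tf_name,
        "chrom": s.interval.chrom, "start": s.interval.start,
        "end": s.interval.end, "strand": s.strand,
        "feature_id": s.feature_id,
        "weighted_conservation": s.weighted_conservation,
    } for s in bundle.sites]).to_csv(d / "sites.tsv", sep="\t", index=False,
                                     float_format="%.10g")

    bundle.footprints.to_csv(d / "footprints.tsv", sep="\t", index=False,
                             float_format="%.10g")
    pd.DataFrame([{
        "tf": tf, "chrom": pk.chrom, "start": pk.start, "end": pk.end,
        "name": pk.name,
    } for tf, plist in bundle.peaks.items() for pk in plist]).to_csv(
        d / "peaks.tsv", sep="\t", index=False)

    gc.write_matrix_tsv(bundle.accessibility, d / "accessibility.tsv")
    gc.write_matrix_tsv(bundle.expression, d / "expression.tsv")
    gc.write_cell_groups(bundle.groups, d / "cell_groups.tsv")

    truth = bundle.truth
    truth_json = {
        "links": [dataclasses.asdict(ln) for ln in truth.links],
        "regulator_sets": {f"{g}|{grp}": sorted(tfs)
                           for (g, grp), tfs in truth.regulator_sets.items()},
        "target_sets": {tf: sorted(gs) for tf, gs in truth.target_sets.items()},
        "bound_sites": {g: sorted(s) for g, s in truth.bound_sites.items()},
    }
    (d / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    (d / "config.json").write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=1))

    manifest = {}
    for f in sorted(d.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest[f.name] = _sha256(f)
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Reload a bundle written by :func:`write_bundle`."""
    d = Path(directory)
    cfg_dict = json.loads((d / "config.json").read_text())
    for key in ("feature_width", "motif_width", "group_labels",
                "cons_bg_beta", "cons_site_beta"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = SynthConfig(**cfg_dict)

    genes = gc.read_gene_table(d / "genes.tsv")
    tads = TadSet(gc.parse_bed(d / "tads.bed"))
    features = {iv.name: iv for iv in gc.parse_bed(d / "features.bed")}
    lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    track = gc.read_bedgraph(d / "conservation.bedgraph", lengths)
    motifs = {m.motif_id: m for m in read_motifs(d / "motifs.meme")}

    sites_df = pd.read_csv(d / "sites.tsv", sep="\t")
    sites = [
        MotifSite(r.site_id, r.motif_id, r.tf,
                  GenomicInterval(r.chrom, int(r.start), int(r.end), r.site_id),
                  r.strand, r.feature_id, float(r.weighted_conservation))
        for r in sites_df.itertuples(index=False)
    ]
    footprints = pd.read_csv(d / "footprints.tsv", sep="\t")
    peaks_df = pd.read_csv(d / "peaks.tsv", sep="\t")
    peaks: dict[str, list[GenomicInterval]] = {}
    for r in peaks_df.itertuples(index=False):
        peaks.setdefault(r.tf, []).append(
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.name))

    accessibility = gc.read_matrix_tsv(d / "accessibility.tsv")
    expression = gc.read_matrix_tsv(d / "expression.tsv")
    groups = gc.read_cell_groups(d / "cell_groups.tsv", cfg.group_labels)

    tj = json.loads((d / "ground_truth.json").read_text())
    truth = GroundTruth(
        links=[PlantedLink(ln["feature_id"], ln["gene_id"], ln["sign"],
                           ln["effect"], tuple(ln["active_groups"]))
               for ln in tj["links"]],
        regulator_sets={(k.split("|")[0], k.split("|")[1]): set(v)
                        for k, v in tj["regulator_sets"].items()},
        target_sets={tf: set(v) for tf, v in tj["target_sets"].items()},
        bound_sites={g: set(v) for g, v in tj["bound_sites"].items()},
    )
    return SyntheticBundle(cfg, genes, tads, features, track, motifs, sites,
                           footprints, peaks, accessibility, expression,
                           groups, truth)
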