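"""Configuration and orchestration of the full analysis pipeline.

Stage order: load -> conservation annotation/enrichment -> linkage and cCRE
calling -> regulator identification + permutation overlap test -> target
identification, characterization and GSEA -> footprint/CUT&Tag corroboration
-> optional laminar quantification. Every stage writes TSV/JSON into the
output directory and the run ends with a checksummed manifest. All
randomness flows through the single configured seed, so a re-run with
unchanged inputs reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corroboration as corro
from . import laminar_quant as lam
from . import linkage as lk
from . import regulators as reg
from . import synthetic_data as synth
from . import targets as tg
from .conservation import conservation_enrichment
from .genome_core import assign_tad

log = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds for one pipeline run."""

    input_dir: str
    seed: int = 0
    selectors: list[str] | None = None  # default: peaked selector TFs
    regulator_groups: list[str] = field(
        default_factory=lambda: list(synth.REGULATOR_GROUPS))

    z_threshold: float = 2.0
    p_threshold_ccre: float = 0.05
    p_threshold_target: float = 0.01
    conservation_threshold: float = 0.5
    tf_expression_threshold: float = 1.2
    accessibility_threshold: float = 0.06
    use_accessibility_filter: bool = False
    target_expression_threshold: float = 0.5
    log2fc_threshold: float = 0.5
    marker_adj_p: float = 0.05
    top_k_markers: int = 25
    permutation_n: int = 1_000_000
    n_background: int = 200
    smoothing_window: int = 12
    background_quantile: float = 0.25

    roi_table: str | None = None
    vs_points: list[list[float]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        d = Path(self.input_dir)
        if not d.is_dir():
            raise ConfigValidationError(f"input_dir does not exist: {d}")
        required = ["genes.tsv", "tads.bed", "features.bed",
                    "conservation.bedgraph", "motifs.meme", "sites.tsv",
                    "footprints.tsv", "peaks.tsv", "accessibility.tsv",
                    "expression.tsv", "cell_groups.tsv"]
        missing = [f for f in required if not (d / f).is_file()]
        if missing:
            raise ConfigValidationError(f"missing input files: {missing}")
        if self.roi_table is not None:
            if not Path(self.roi_table).is_file():
                raise ConfigValidationError(
                    f"roi_table does not exist: {self.roi_table}")
            if not self.vs_points or len(self.vs_points) != 3:
                raise ConfigValidationError(
                    "laminar stage needs exactly 3 vs_points")
        if not (0 < self.p_threshold_ccre <= 1 and 0 < self.p_threshold_target <= 1):
            raise ConfigValidationError("p thresholds must be in (0, 1]")
        if self.permutation_n < 1 or self.n_background < 50:
            raise ConfigValidationError(
                "permutation_n >= 1 and n_background >= 50 required")


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def link_all(
    bundle: synth.SyntheticBundle,
    seed: int,
    n_background: int = lk.DEFAULT_N_BACKGROUND,
) -> tuple[dict[str, list[lk.LinkRecord]], dict[str, object]]:
    """Link every gene in a bundle against its TAD's features.

    Returns (gene_id -> LinkRecords, gene_id -> containing TAD). Genes with
    constant expression are skipped.
    """
    meta = lk.add_decile_columns(bundle.feature_meta())
    rng = np.random.default_rng(seed)
    backgrounds = lk.background_map(meta, n_background, rng)
    all_links: dict[str, list[lk.LinkRecord]] = {}
    tad_of: dict[str, object] = {}
    for gene in bundle.genes:
        tad = assign_tad(gene, bundle.tads)
        tad_of[gene.gene_id] = tad
        if tad is None:
            continue
        fids = [fid for fid, iv in bundle.features.items()
                if iv.chrom == tad.chrom and iv.start >= tad.start
                and iv.end <= tad.end]
        try:
            all_links[gene.gene_id] = lk.link_gene_tad(
                gene, fids, bundle.accessibility, bundle.expression, meta,
                rng, n_background, backgrounds)
        except lk.DegenerateVectorError:
            log.warning("gene %s constant across cells; not linked",
                        gene.gene_id)
    return all_links, tad_of


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, str]:
    """Execute all stages; returns the manifest (file name -> sha256)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []  # run log (thresholds only: stable across reruns)

    bundle = synth.read_bundle(config.input_dir)
    thresholds = {k: v for k, v in dataclasses.asdict(config).items()
                  if k not in {"input_dir", "roi_table", "vs_points"}}
    for k, v in sorted(thresholds.items()):
        lines.append(f"threshold {k} = {v}")

    # --- stage: conservation enrichment of features per chromosome -------
    enr_rows = []
    for chrom in bundle.conservation.chroms:
        regions = [iv for iv in bundle.features.values() if iv.chrom == chrom]
        e = conservation_enrichment(regions, bundle.conservation, chrom,
                                    config.conservation_threshold)
        enr_rows.append({
            "chrom": chrom, "region_class": "features",
            "conserved_in": e.conserved_in, "nonconserved_in": e.nonconserved_in,
            "conserved_out": e.conserved_out,
            "nonconserved_out": e.nonconserved_out,
            "odds_ratio": e.odds_ratio, "p_value": e.p_value})
    _tsv(pd.DataFrame(enr_rows), out / "conservation_enrichment.tsv")
    lines.append("stage conservation_enrichment done")

    # --- stage: linkage for every gene, cCREs for selectors --------------
    all_links, gene_tad = link_all(bundle, config.seed, config.n_background)
    flat = [ln for lns in all_links.values() for ln in lns]
    _tsv(lk.links_to_frame(flat, bundle.features), out / "links.tsv")

    selectors = config.selectors or [
        tf for tf in bundle.selector_tfs if tf in bundle.peaks]
    ccres: dict[str, list[lk.LinkRecord]] = {}
    for gid in selectors:
        gene = bundle.gene(gid)
        ccres[gid] = lk.call_ccres(
            gene, gene_tad[gid], bundle.features, all_links.get(gid, []),
            config.z_threshold, config.p_threshold_ccre)
    _tsv(lk.links_to_frame([c for cs in ccres.values() for c in cs],
                           bundle.features), out / "ccres.tsv")
    lines.append("stage linkage done")

    # --- stage: regulators + permutation overlap test --------------------
    all_calls = []
    per_gene_group: dict[str, dict[str, dict[str, reg.RegulatorCall]]] = {}
    for grp in config.regulator_groups:
        per_gene_group[grp] = {}
        for gid in selectors:
            calls = reg.identify_regulators(
                gid, grp, ccres[gid], bundle.sites, bundle.footprints,
                bundle.expression, bundle.groups,
                conservation_min=config.conservation_threshold,
                expression_min=config.tf_expression_threshold,
                accessibility_min=(config.accessibility_threshold
                                   if config.use_accessibility_filter else None),
                accessibility=bundle.accessibility,
            )
            per_gene_group[grp][gid] = calls
            all_calls.extend(calls.values())
    _tsv(reg.calls_to_frame(all_calls), out / "regulators.tsv")

    overlap_results = {}
    universe = bundle.tf_names
    for grp, per_gene in per_gene_group.items():
        if len(per_gene) < 2:
            continue
        partition, summary = reg.summarize_common_regulators(per_gene)
        _tsv(summary, out / f"common_regulators_{grp}.tsv")
        sizes = [len(per_gene[g]) for g in per_gene]
        observed = len(set.intersection(*(set(per_gene[g]) for g in per_gene)))
        if observed <= min(sizes) and min(sizes) > 0:
            res = reg.permutation_overlap_test(
                universe, sizes, observed, config.permutation_n,
                seed=config.seed)
            overlap_results[grp] = {
                "observed": res.observed, "n_iterations": res.n_iterations,
                "exceedances": res.exceedances, "p_value": res.p_value,
                "upper_bound": res.upper_bound, "seed": res.seed}
    (out / "overlap_test.json").write_text(json.dumps(overlap_results, indent=1))
    lines.append("stage regulators done")

    # --- stage: targets, DE, classification, GSEA ------------------------
    cells_ga = list(bundle.groups.cells_in("GA1_2"))
    cells_gl = list(bundle.groups.cells_in("GL1_2"))
    de = tg.de_wilcoxon(bundle.expression, cells_ga, cells_gl)
    de_map = {r.gene_id: r for r in de}
    _tsv(pd.DataFrame([dataclasses.asdict(r) for r in de]), out / "de_ga_vs_gl.tsv")
    group_means = bundle.groups.group_means(bundle.expression)
    ga_means = group_means.loc["GA1_2"].to_dict()
    gl_means = group_means.loc["GL1_2"].to_dict()

    all_targets = []
    gsea_out = {}
    for tf in selectors:
        calls = tg.identify_targets(
            tf, bundle.genes, bundle.tads, all_links, bundle.features,
            bundle.sites, bundle.footprints, bundle.peaks,
            z_min=config.z_threshold, p_max=config.p_threshold_target,
            conservation_min=config.conservation_threshold)
        calls = tg.classify_targets(calls, de_map, ga_means, gl_means,
                                    config.log2fc_threshold,
                                    config.target_expression_threshold)
        all_targets.extend(calls)
        if calls:
            tables = tg.characterize_targets(calls, group_means)
            for name, df in tables.items():
                _tsv(df, out / f"targets_{tf}_{name}.tsv")
            ranking = tg.rank_genes_for_gsea(de)
            gene_set = {t.gene_id for t in calls} & set(ranking)
            if gene_set and len(gene_set) < len(ranking):
                res = tg.gsea_two_edge(ranking, gene_set)
                gsea_out[tf] = {
                    "n_ranked": len(res.ranked), "argmax": res.argmax,
                    "argmin": res.argmin,
                    "leading_edge_a": list(res.leading_edge_a),
                    "leading_edge_b": list(res.leading_edge_b)}
        subset = tg.target_expression_subset(
            calls, ga_means, gl_means, config.target_expression_threshold)
        (out / f"targets_{tf}_expressed.txt").write_text(
            "\n".join(subset) + ("\n" if subset else ""))
    _tsv(tg.targets_to_frame(all_targets), out / "targets.tsv")
    (out / "gsea.json").write_text(json.dumps(gsea_out, indent=1))
    lines.append("stage targets done")

    # --- stage: corroboration --------------------------------------------
    site_iv = {s.site_id: s.interval for s in bundle.sites}
    bound_any = reg.bound_in_any_group(bundle.footprints)
    stats_rows = []
    pos_rows = []
    for tf, plist in bundle.peaks.items():
        tf_bound = [site_iv[s.site_id] for s in bundle.sites
                    if s.tf_name == tf and s.site_id in bound_any]
        st = corro.corroboration_stats(tf, plist, tf_bound)
        stats_rows.append(dataclasses.asdict(st))
        dens = corro.footprint_positions_in_peaks(plist, tf_bound)
        for p in dens.positions:
            pos_rows.append({"tf_name": tf, "position": p})
    _tsv(pd.DataFrame(stats_rows), out / "corroboration.tsv")
    _tsv(pd.DataFrame(pos_rows, columns=["tf_name", "position"]),
         out / "footprint_positions.tsv")
    lines.append("stage corroboration done")

    # --- optional stage: laminar quantification ---------------------------
    if config.roi_table is not None:
        rois = lam.read_roi_table(config.roi_table)
        circle = lam.fit_vs_circle(*config.vs_points)
        profile = lam.quantify_profile(rois, circle, config.background_quantile)
        profile = lam.normalize_replicates(profile)
        channels = [c for c in profile.columns if c.startswith("ch")]
        for ch in channels:
            profile[f"{ch}_smooth"] = lam.smooth_profile(
                profile[ch], config.smoothing_window)
        _tsv(profile, out / "laminar_profile.tsv")
        lines.append("stage laminar done")

    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            h = hashlib.sha256(f.read_bytes()).hexdigest()
            manifest[f.name] = h
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
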