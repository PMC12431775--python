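"""Feature-to-gene linkage statistics within TADs and cCRE calling.

The linking statistic follows the LinkPeaks idea: for a candidate feature,
the Spearman correlation between its per-cell accessibility and the gene's
per-cell expression is standardized against the correlations of a matched
background feature set, giving a z-score and a two-sided normal p-value.
Features inside the gene's TAD that pass |z| > 2 and p < 0.05 are the gene's
candidate cis-regulatory elements (cCREs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_core import GeneModel, GenomicInterval

#: cCRE thresholds: |z| > 2 and p < 0.05 (strict inequalities).
Z_THRESHOLD = 2.0
P_THRESHOLD_CCRE = 0.05
#: Stricter link p cutoff used for target-gene calling.
P_THRESHOLD_TARGET = 0.01

DEFAULT_N_BACKGROUND = 200


class DegenerateVectorError(ValueError):
    """Raised when a correlation is undefined (constant input vector)."""


@dataclass(frozen=True)
class LinkRecord:
    feature_id: str
    gene_id: str
    rho: float
    z: float
    p: float

    @property
    def sign(self) -> str:
        return "+" if self.z >= 0 else "-"


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateVectorError("constant vector: correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def _rank_columns(matrix: np.ndarray) -> np.ndarray:
    """Average-rank transform of each column of a cells x columns matrix."""
    return stats.rankdata(matrix, axis=0)


def _pearson_vec(ranked_cols: np.ndarray, ranked_y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``ranked_cols`` against ``ranked_y``.

    Columns with zero variance yield nan.
    """
    xc = ranked_cols - ranked_cols.mean(axis=0)
    yc = ranked_y - ranked_y.mean()
    num = xc.T @ yc
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def add_decile_columns(feature_meta: pd.DataFrame) -> pd.DataFrame:
    """Attach mean-accessibility and width decile columns (idempotent)."""
    if "acc_decile" in feature_meta.columns:
        return feature_meta
    meta = feature_meta.copy()
    meta["acc_decile"] = pd.qcut(
        meta["mean_accessibility"].rank(method="first"), 10, labels=False)
    meta["width_decile"] = pd.qcut(
        meta["width"].rank(method="first"), 10, labels=False)
    return meta


def select_background(
    feature_id: str,
    feature_meta: pd.DataFrame,
    n_background: int,
    rng: np.random.Generator,
) -> list[str]:
    """Matched background features for z-score standardization.

    Candidates come from the query feature's chromosome and are ranked by
    decile distance in mean accessibility and in width; the ``n_background``
    closest are taken, with a seeded random shuffle breaking ties. Falls back
    to other chromosomes only when the chromosome has too few features.
    ``feature_meta`` is indexed by feature id with columns chrom, width,
    mean_accessibility.
    """
    if feature_id not in feature_meta.index:
        raise KeyError(f"unknown feature {feature_id}")
    meta = add_decile_columns(feature_meta)
    q = meta.loc[feature_id]
    pool = meta.drop(index=feature_id)
    same = pool[pool["chrom"] == q["chrom"]]
    if len(same) >= n_background:
        pool = same
    dist = (pool["acc_decile"] - q["acc_decile"]).abs() + \
           (pool["width_decile"] - q["width_decile"]).abs()
    order = pool.index.to_numpy()[rng.permutation(len(pool))]
    order = order[np.argsort(dist.loc[order].to_numpy(), kind="stable")]
    chosen = order[: n_background]
    if chosen.size < 50:
        raise ValueError(
            f"only {chosen.size} background features available (need >= 50)"
        )
    return list(chosen)


def background_map(
    feature_meta: pd.DataFrame,
    n_background: int,
    rng: np.random.Generator,
    feature_ids: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """Matched background sets for many features at once (cheaper than
    calling :func:`select_background` per gene: backgrounds depend only on
    the feature)."""
    meta = add_decile_columns(feature_meta)
    fids = list(feature_ids) if feature_ids is not None else list(meta.index)
    return {fid: select_background(fid, meta, n_background, rng)
            for fid in fids}


def link_feature_gene(
    feature_id: str,
    gene_id: str,
    accessibility: pd.DataFrame,
    expression: pd.DataFrame,
    background_ids: Sequence[str],
    *,
    precomputed_ranks: tuple[pd.Index, np.ndarray, dict[str, int]] | None = None,
) -> LinkRecord:
    """Background-standardized Spearman link between one feature and one gene.

    rho_obs is computed over the cells shared by both matrices; each
    background feature is correlated with the same gene, and
    z = (rho_obs - mean(rho_bg)) / sd(rho_bg) with a two-sided normal p.
    """
    if len(background_ids) < 50:
        raise ValueError("need >= 50 background features")
    if precomputed_ranks is not None:
        cells, ranked, col_of = precomputed_ranks
    else:
        cells = accessibility.index.intersection(expression.index)
        if len(cells) < 30:
            raise ValueError(f"only {len(cells)} shared cells (need >= 30)")
        ranked = _rank_columns(accessibility.loc[cells].to_numpy())
        col_of = {f: i for i, f in enumerate(accessibility.columns)}

    y = expression.loc[cells, gene_id].to_numpy()
    if np.unique(y).size < 2:
        raise DegenerateVectorError(f"gene {gene_id} constant across cells")
    ranked_y = stats.rankdata(y)

    cols = [col_of[feature_id]] + [col_of[b] for b in background_ids]
    rhos = _pearson_vec(ranked[:, cols], ranked_y)
    rho_obs = rhos[0]
    if np.isnan(rho_obs):
        raise DegenerateVectorError(f"feature {feature_id} constant across cells")
    rho_bg = rhos[1:]
    rho_bg = rho_bg[~np.isnan(rho_bg)]
    sd = rho_bg.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate background: sd of background rhos is 0")
    z = (rho_obs - rho_bg.mean()) / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return LinkRecord(feature_id, gene_id, float(rho_obs), float(z), float(p))


def link_gene_tad(
    gene: GeneModel,
    tad_feature_ids: Sequence[str],
    accessibility: pd.DataFrame,
    expression: pd.DataFrame,
    feature_meta: pd.DataFrame,
    rng: np.random.Generator,
    n_background: int = DEFAULT_N_BACKGROUND,
    backgrounds: Mapping[str, Sequence[str]] | None = None,
) -> list[LinkRecord]:
    """Link every feature in a gene's TAD to the gene (shared rank transform).

    Pass a precomputed ``backgrounds`` map (see :func:`background_map`) when
    linking many genes over the same feature space.
    """
    cells = accessibility.index.intersection(expression.index)
    if len(cells) < 30:
        raise ValueError(f"only {len(cells)} shared cells (need >= 30)")
    if len(cells) < 0.5 * max(len(accessibility.index), len(expression.index)):
        import logging
        logging.getLogger(__name__).warning(
            "cell sets overlap by less than 50%% (%d shared)", len(cells)
        )
    ranked = _rank_columns(accessibility.loc[cells].to_numpy())
    col_of = {f: i for i, f in enumerate(accessibility.columns)}
    meta = add_decile_columns(feature_meta)

    y = expression.loc[cells, gene.gene_id].to_numpy()
    if np.unique(y).size < 2:
        raise DegenerateVectorError(f"gene {gene.gene_id} constant across cells")
    ranked_y = stats.rankdata(y)

    if backgrounds is None:
        backgrounds = {fid: select_background(fid, meta, n_background, rng)
                       for fid in tad_feature_ids}
    needed = sorted({f for fid in tad_feature_ids
                     for f in [fid, *backgrounds[fid]]})
    pos = {f: i for i, f in enumerate(needed)}
    rhos = _pearson_vec(ranked[:, [col_of[f] for f in needed]], ranked_y)

    links = []
    for fid in tad_feature_ids:
        rho_obs = rhos[pos[fid]]
        if np.isnan(rho_obs):
            continue  # constant feature vector
        rho_bg = rhos[[pos[b] for b in backgrounds[fid]]]
        rho_bg = rho_bg[~np.isnan(rho_bg)]
        sd = rho_bg.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate background: sd of background rhos is 0")
        z = (rho_obs - rho_bg.mean()) / sd
        p = 2.0 * stats.norm.sf(abs(z))
        links.append(LinkRecord(fid, gene.gene_id, float(rho_obs), float(z),
                                float(p)))
    return links


def call_ccres(
    gene: GeneModel,
    tad: GenomicInterval | None,
    features: Mapping[str, GenomicInterval],
    links: Iterable[LinkRecord],
    z_threshold: float = Z_THRESHOLD,
    p_threshold: float = P_THRESHOLD_CCRE,
) -> list[LinkRecord]:
    """Retain links with |z| > z_threshold, p < p_threshold, feature in the TAD."""
    if tad is None:
        import logging
        logging.getLogger(__name__).warning(
            "gene %s has no containing TAD; no cCREs called", gene.gene_id
        )
        return []
    out = []
    for link in links:
        iv = features.get(link.feature_id)
        if iv is None:
            continue
        in_tad = (iv.chrom == tad.chrom and iv.start >= tad.start
                  and iv.end <= tad.end)
        if abs(link.z) > z_threshold and link.p < p_threshold and in_tad:
            out.append(link)
    return out


def links_to_frame(links: Iterable[LinkRecord],
                   features: Mapping[str, GenomicInterval] | None = None
                   ) -> pd.DataFrame:
    rows = []
    for ln in links:
        iv = features.get(ln.feature_id) if features else None
        rows.append({
            "feature_id": ln.feature_id, "gene_id": ln.gene_id,
            "chrom": iv.chrom if iv else "", "start": iv.start if iv else -1,
            "end": iv.end if iv else -1, "rho": ln.rho, "z": ln.z,
            "p": ln.p, "sign": ln.sign,
        })
    return pd.DataFrame(
        rows, columns=["feature_id", "gene_id", "chrom", "start", "end",
                       "rho", "z", "p", "sign"])


def write_links(links: Iterable[LinkRecord], path: str | Path,
                features: Mapping[str, GenomicInterval] | None = None) -> None:
    links_to_frame(links, features).to_csv(path, sep="\t", index=False,
                                           float_format="%.10g")
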