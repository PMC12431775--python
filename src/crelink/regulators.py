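"""Regulator identification from footprint, conservation and expression evidence.

A TF is called a regulator of a selector gene in a cell group when three
conditions hold simultaneously:

1. the TF has a bound footprint (score > 0) at a motif site inside one of
   the gene's cCREs (features linked at |z| > 2, p < 0.05);
2. the weighted mean conservation of that motif site is > 0.5;
3. the TF gene's mean log1p expression in the cell group is > 1.2.

Regulator sets of several selector genes are compared by their intersection
partition, and the significance of the observed multi-set overlap is assessed
with a permutation test drawing same-sized random sets from the candidate
universe (1,000,000 iterations by default, reporting the 1/(N+1) upper bound
when no permutation reaches the observed intersection).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import MotifSite
from .genome_core import CellGroupMap, GenomicInterval, interval_overlap
from .linkage import LinkRecord

#: Printed thresholds for the three regulator conditions.
CONSERVATION_THRESHOLD = 0.5
EXPRESSION_THRESHOLD = 1.2
#: Optional extra filter used for footprint dot plots (off by default).
ACCESSIBILITY_THRESHOLD = 0.06

PERMUTATION_ITERATIONS = 1_000_000


@dataclass(frozen=True)
class RegulatorCall:
    """One TF called as regulator of one selector gene in one cell group."""

    gene_id: str
    cell_group: str
    tf_name: str
    ccre_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    conservation: tuple[float, ...]
    tf_mean_expression: float
    min_link_p: float


@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    n_iterations: int
    exceedances: int
    p_value: float
    upper_bound: bool
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"observed": self.observed, "n_iterations": self.n_iterations,
                 "exceedances": self.exceedances, "p_value": self.p_value,
                 "upper_bound": self.upper_bound, "seed": self.seed},
                fh, indent=2)


def bound_site_set(footprints: pd.DataFrame, group: str) -> set[str]:
    """Site ids with a strictly positive footprint score in ``group``.

    ``footprints`` has columns site_id, cell_group, footprint_score.
    """
    if group not in set(footprints["cell_group"]):
        raise ValueError(f"unknown cell group {group!r}")
    sub = footprints[footprints["cell_group"] == group]
    return set(sub.loc[sub["footprint_score"] > 0, "site_id"])


def bound_in_any_group(footprints: pd.DataFrame,
                       groups: Sequence[str] | None = None) -> set[str]:
    """Site ids bound (score > 0) in at least one of the given groups (all by default)."""
    sub = footprints
    if groups is not None:
        sub = footprints[footprints["cell_group"].isin(groups)]
    return set(sub.loc[sub["footprint_score"] > 0, "site_id"])


def identify_regulators(
    gene_id: str,
    group: str,
    ccres: Sequence[LinkRecord],
    sites: Sequence[MotifSite],
    footprints: pd.DataFrame,
    expression: pd.DataFrame,
    groups: CellGroupMap,
    *,
    conservation_min: float | None = CONSERVATION_THRESHOLD,
    expression_min: float | None = EXPRESSION_THRESHOLD,
    require_footprint: bool = True,
    accessibility_min: float | None = None,
    accessibility: pd.DataFrame | None = None,
) -> dict[str, RegulatorCall]:
    """Three-condition regulator identification for one selector gene and group.

    Threshold arguments may be set to ``None`` (or ``require_footprint=False``)
    to disable a condition; every relaxation can only grow the returned set.
    Returns tf_name -> RegulatorCall with full evidence.
    """
    ccre_ids = {c.feature_id for c in ccres}
    link_p = {c.feature_id: c.p for c in ccres}
    bound = bound_site_set(footprints, group) if require_footprint else None

    if accessibility_min is not None:
        if accessibility is None:
            raise ValueError("accessibility matrix required for the accessibility filter")
        acc_means = groups.group_means(accessibility)
        accessible = set(
            acc_means.columns[acc_means.loc[group] > accessibility_min])
    else:
        accessible = None

    # group means always computed: they are recorded as call evidence
    cells = expression.index.intersection(groups.cells_in(group))
    expr_mean_in_group = expression.loc[cells].mean(axis=0).to_dict()

    evidence: dict[str, list[MotifSite]] = {}
    for site in sites:
        if site.feature_id not in ccre_ids:
            continue
        if accessible is not None and site.feature_id not in accessible:
            continue
        if bound is not None and site.site_id not in bound:
            continue
        if conservation_min is not None and not (
                site.weighted_conservation > conservation_min):
            continue
        evidence.setdefault(site.tf_name, []).append(site)

    calls: dict[str, RegulatorCall] = {}
    import logging
    for tf, tf_sites in sorted(evidence.items()):
        if tf not in expression.columns:
            logging.getLogger(__name__).warning(
                "TF %s absent from expression matrix; skipped", tf)
            continue
        mean_expr = float(expr_mean_in_group[tf])
        if expression_min is not None and not mean_expr > expression_min:
            continue
        feats = tuple(sorted({s.feature_id for s in tf_sites}))
        calls[tf] = RegulatorCall(
            gene_id=gene_id, cell_group=group, tf_name=tf,
            ccre_ids=feats,
            site_ids=tuple(s.site_id for s in tf_sites),
            conservation=tuple(s.weighted_conservation for s in tf_sites),
            tf_mean_expression=mean_expr,
            min_link_p=min(link_p[f] for f in feats),
        )
    return calls


def summarize_common_regulators(
    per_gene_calls: Mapping[str, Mapping[str, RegulatorCall]],
) -> tuple[dict[frozenset[str], set[str]], pd.DataFrame]:
    """Intersection partition of per-gene regulator sets + per-TF significance.

    Returns the full Venn partition (each region keyed by the frozenset of
    gene ids whose sets contain its members) and, for TFs in the full
    intersection, a significance summary: per gene the minimum link p over
    the TF's supporting cCREs, and overall the maximum of those minima.
    """
    genes = list(per_gene_calls)
    if len(genes) < 2:
        raise ValueError("need regulator sets for at least 2 genes")
    sets = {g: set(per_gene_calls[g]) for g in genes}
    partition: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(set(), *(sets[g] for g in genes
                                         if g not in combo))
            partition[frozenset(combo)] = inside - outside

    common = set.intersection(*sets.values())
    rows = []
    for tf in sorted(common):
        per_gene_min = {g: per_gene_calls[g][tf].min_link_p for g in genes}
        rows.append({"tf_name": tf,
                     **{f"min_p_{g}": per_gene_min[g] for g in genes},
                     "max_min_p": max(per_gene_min.values())})
    summary = pd.DataFrame(
        rows, columns=["tf_name", *(f"min_p_{g}" for g in genes), "max_min_p"])
    return partition, summary


def permutation_overlap_test(
    universe: Sequence[str] | int,
    set_sizes: Sequence[int],
    observed: int,
    n_iterations: int = PERMUTATION_ITERATIONS,
    seed: int = 0,
    chunk: int = 20_000,
) -> OverlapTestResult:
    """Permutation null for the overlap of several same-universe sets.

    Each iteration draws one uniform without-replacement set per requested
    size and records the size of their common intersection. The empirical p
    is the proportion of iterations with intersection >= observed; when no
    iteration reaches it, the upper bound 1/(N+1) is reported instead.
    """
    n_universe = universe if isinstance(universe, int) else len(universe)
    sizes = list(set_sizes)
    if any(s > n_universe for s in sizes):
        raise ValueError("set size exceeds universe size")
    if observed > min(sizes):
        raise ValueError("observed intersection exceeds the smallest set size")
    if n_iterations < 1:
        raise ValueError("need at least one iteration")

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        inter = np.ones((m, n_universe), dtype=bool)
        for k in sizes:
            r = rng.random((m, n_universe))
            idx = np.argpartition(r, k - 1, axis=1)[:, :k]
            mask = np.zeros((m, n_universe), dtype=bool)
            np.put_along_axis(mask, idx, True, axis=1)
            inter &= mask
        exceed += int(np.sum(inter.sum(axis=1) >= observed))
        done += m

    if exceed == 0:
        return OverlapTestResult(observed, n_iterations, 0,
                                 1.0 / (n_iterations + 1), True, seed)
    return OverlapTestResult(observed, n_iterations, exceed,
                             exceed / n_iterations, False, seed)


def calls_to_frame(calls: Iterable[RegulatorCall]) -> pd.DataFrame:
    rows = [{
        "gene_id": c.gene_id, "cell_group": c.cell_group, "tf_name": c.tf_name,
        "ccre_ids": ",".join(c.ccre_ids), "site_ids": ",".join(c.site_ids),
        "conservation": ",".join(f"{x:.6g}" for x in c.conservation),
        "tf_mean_expression": c.tf_mean_expression, "min_link_p": c.min_link_p,
    } for c in calls]
    return pd.DataFrame(rows, columns=[
        "gene_id", "cell_group", "tf_name", "ccre_ids", "site_ids",
        "conservation", "tf_mean_expression", "min_link_p"])
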