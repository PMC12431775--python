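#!/usr/bin/env python
"""Identify the selector genes' regulators and test their overlap.

Applies the three evidence conditions (bound footprint in a cCRE, motif
conservation > 0.5, TF expression > 1.2) per selector gene and cell group,
summarizes the regulators common to all selectors, and asks whether the
observed three-way overlap could arise by drawing same-sized random sets
from the TF universe (permutation null; the full analysis uses 1,000,000
iterations, here 100,000 keeps the driver snappy with the same estimator).
"""

from pathlib import Path

from crelink import linkage as lk
from crelink import regulators as reg
from crelink.pipeline import link_all
from crelink.synthetic_data import REGULATOR_GROUPS, read_bundle

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 11, n_iterations: int = 100_000) -> None:
    bundle = read_bundle(ROOT / "data" / "noiseless")
    all_links, tad_of = link_all(bundle, seed=seed)

    all_calls = []
    for grp in REGULATOR_GROUPS:
        per_gene = {}
        for gid in bundle.selector_tfs:
            ccres = lk.call_ccres(bundle.gene(gid), tad_of[gid],
                                  bundle.features, all_links[gid])
            calls = reg.identify_regulators(
                gid, grp, ccres, bundle.sites, bundle.footprints,
                bundle.expression, bundle.groups)
            per_gene[gid] = calls
            all_calls.extend(calls.values())
            truth = bundle.truth.regulator_sets[(gid, grp)]
            match = "exact match" if set(calls) == truth else "MISMATCH"
            print(f"{gid} {grp}: {sorted(calls)}  [planted: {match}]")

        partition, summary = reg.summarize_common_regulators(per_gene)
        common = partition[frozenset(per_gene)]
        print(f"{grp}: common regulators of all selectors: {sorted(common)}")
        if not summary.empty:
            summary.to_csv(ROOT / f"common_regulators_{grp}.tsv", sep="\t",
                           index=False)
        sizes = [len(v) for v in per_gene.values()]
        if min(sizes) > 0:
            res = reg.permutation_overlap_test(
                bundle.tf_names, sizes, len(common), n_iterations, seed=seed)
            bound = "<" if res.upper_bound else "="
            print(f"{grp}: overlap {len(common)} vs sizes {sizes}: "
                  f"p {bound} {res.p_value:.3g} "
                  f"({res.exceedances}/{res.n_iterations} exceedances)")
            res.to_json(ROOT / f"overlap_test_{grp}.json")

    reg.calls_to_frame(all_calls).to_csv(ROOT / "regulators.tsv", sep="\t",
                                         index=False)
    print(f"wrote {ROOT / 'regulators.tsv'}")


if __name__ == "__main__":
    main()
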