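#!/usr/bin/env python
"""Quantify how CUT&Tag peaks and footprint-bound motif sites corroborate.

Per TF with CUT&Tag data: peak/site counts, the percentage of peaks with a
bound site and of bound sites inside a peak, and the density of bound-site
positions along the normalized peak axis.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from crelink import corroboration as corro
from crelink.regulators import bound_in_any_group
from crelink.synthetic_data import read_bundle

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = read_bundle(ROOT / "data" / "default")
    bound = bound_in_any_group(bundle.footprints)
    rows, pos_rows = [], []
    for tf, peaks in bundle.peaks.items():
        sites = [s.interval for s in bundle.sites
                 if s.tf_name == tf and s.site_id in bound]
        st = corro.corroboration_stats(tf, peaks, sites)
        rows.append(dataclasses.asdict(st))
        print(f"{tf}: {st.n_peaks} peaks, {st.n_bound_sites} bound sites; "
              f"{st.pct_peaks_with_site:.1f}% of peaks contain a site, "
              f"{st.pct_sites_in_peak:.1f}% of sites fall in a peak")
        dens = corro.footprint_positions_in_peaks(peaks, sites)
        pos_rows.extend({"tf_name": tf, "position": p}
                        for p in dens.positions)

    pd.DataFrame(rows).to_csv(ROOT / "corroboration.tsv", sep="\t",
                              index=False)
    pd.DataFrame(pos_rows).to_csv(ROOT / "footprint_positions.tsv", sep="\t",
                                  index=False)
    print(f"wrote {ROOT / 'corroboration.tsv'}")


if __name__ == "__main__":
    main()
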