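#!/usr/bin/env python
"""Scan for bins fixed for the reference allelic state in domesticated lines.

Aggregates the window profile into wild-vs-domesticated bin statistics
(mean domesticated heterozygosity; wild/domesticated non-reference
homozygosity ratio; normalised difference), derives 5% genome-wide quantile
thresholds, calls fixed regions under the dual criterion (het <= 0.0002 and
ratio >= 1.73 by default) and checks them against the planted sweeps.
"""

import argparse
from pathlib import Path

from divscan import fixation_scan as fx
from divscan import io_formats as io
from divscan import synthetic_data as sd
from divscan import windowed_diversity as wd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/bundle"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--het-thresh", type=float,
                    default=fx.DEFAULT_HET_THRESHOLD)
    ap.add_argument("--ratio-thresh", type=float,
                    default=fx.DEFAULT_RATIO_THRESHOLD)
    args = ap.parse_args()
    args.results.mkdir(exist_ok=True)

    pm = io.read_population_map(args.bundle / "popmap.tsv")
    table = io.VariantTable.from_vcf(args.bundle / "sim.vcf", pm)
    tracks = {s: io.read_depth_track(args.bundle / "depth" / f"{s}.bed", s)
              for s in table.samples}
    truth = sd.SimulationTruth.from_json(args.bundle / "truth.json")

    profile = wd.window_profile(table, tracks)
    bins = fx.bin_stats(profile, pm)
    bins.to_frame().to_csv(args.results / "bin_stats.tsv", sep="\t",
                           index=False)

    het_q, ratio_q = fx.derive_thresholds(bins)
    print(f"data-derived 5% quantile thresholds: het <= {het_q:.3g}, "
          f"ratio >= {ratio_q:.3g} "
          f"(fixed defaults: {args.het_thresh}, {args.ratio_thresh})")

    calls = fx.call_fixed_regions(bins, args.het_thresh, args.ratio_thresh)
    io.write_bed(args.results / "fixed_regions.bed",
                 fx.calls_to_bed(calls),
                 extra_header="contig\tstart\tend\tn_bins\tmean_het_dom\t"
                              "min_ratio")

    def overlaps(call, region):
        c, s, e = region
        return call.contig == c and call.start < e and call.end > s

    recovered = sum(any(overlaps(c, r) for c in calls)
                    for r in truth.sweep_regions)
    false = [c for c in calls
             if not any(overlaps(c, r) for r in truth.sweep_regions)]
    print(f"{len(calls)} fixed regions called; {recovered}/"
          f"{len(truth.sweep_regions)} planted sweeps recovered; "
          f"{len(false)} calls outside any planted sweep")
    for c in calls:
        print(f"  {c.contig}:{c.start}-{c.end} ({c.n_bins} bins, "
              f"het_dom {c.mean_het_dom:.2g}, min ratio {c.min_ratio:.3g})")


if __name__ == "__main__":
    main()
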