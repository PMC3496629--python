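#!/usr/bin/env python
"""Nei genetic distances and the neighbor-joining relatedness tree.

Selects SNPs called in at least 9 of the 11 populations, computes pairwise
Nei standard distances among all individuals (pairwise-complete loci), runs
neighbor-joining and roots the tree on the wild population.  Writes the
distance matrix (TSV + PHYLIP) and the rooted newick tree to results/.
"""

import argparse
from pathlib import Path

import numpy as np

from divscan import genetic_distance as gd
from divscan import io_formats as io
from divscan import variant_filtering as vf


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/bundle"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-pops", type=int, default=9)
    ap.add_argument("--thin", type=int, default=5,
                    help="use every n-th shared site (distances are means "
                         "over loci, so thinning only adds noise)")
    args = ap.parse_args()
    args.results.mkdir(exist_ok=True)

    pm = io.read_population_map(args.bundle / "popmap.tsv")
    table = io.VariantTable.from_vcf(args.bundle / "sim.vcf", pm)
    cls = vf.classify_sites(table, pm)
    mask = gd.select_shared_sites(cls, k=args.min_pops)
    idx = np.where(mask)[0][::args.thin]
    sub = io.VariantTable(table.samples, table.contigs[idx], table.pos[idx],
                          table.ref[idx], table.alt[idx], table.gt[idx],
                          table.gq[idx], table.dp[idx], table.contig_lengths)
    dm = gd.nei_distance_matrix(sub, pm)
    dm.write_tsv(args.results / "nei_distances.tsv")
    dm.write_phylip(args.results / "nei_distances.phy")

    tree = gd.neighbor_joining(dm)
    rooted = gd.root_at_outgroup(tree, pm.samples_in(pm.wild_population))
    io.write_newick(args.results / "nj_tree.nwk", rooted)

    sides = [set(lf.taxon.label for lf in k.leaf_iter())
             for k in rooted.seed_node.child_nodes()]
    basal = set(pm.samples_in(pm.wild_population)) in sides
    print(f"{int(mask.sum())} SNPs called in >= {args.min_pops} populations "
          f"({len(idx)} used after thinning)")
    print(f"wild population forms the basal clade: {basal}")
    print(f"tree written to {args.results / 'nj_tree.nwk'}")


if __name__ == "__main__":
    main()
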