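#!/usr/bin/env python
"""Functional annotation of the simulated SNPs against the bundle's genes.

Places every putative SNP relative to the bundle's gene models (exonic,
splice site, UTR, intronic, upstream/downstream, ncRNA, intergenic) and
derives codon-level effects from the reference FASTA for CDS hits.  Writes
the per-site table and the category summary (total and segregating) under
results/.
"""

import argparse
from pathlib import Path

import numpy as np

from divscan import annotation as ann
from divscan import io_formats as io
from divscan import variant_filtering as vf


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/bundle"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(exist_ok=True)

    pm = io.read_population_map(args.bundle / "popmap.tsv")
    table = io.VariantTable.from_vcf(args.bundle / "sim.vcf", pm)
    putative = vf.putative_snps(table)
    models = ann.load_gene_models(args.bundle / "genes.gff3")
    fasta = io.read_fasta(args.bundle / "reference.fa")

    cls = vf.classify_sites(putative, pm)
    segregating = np.any(cls.status == vf.SEGREGATING, axis=1)

    # the toy gene set spans ~100 kb of chr1; annotate that neighbourhood
    near = (putative.contigs == "chr1") & (putative.pos <= 200_000)
    sites = list(zip(putative.contigs[near], putative.pos[near],
                     putative.ref[near], putative.alt[near]))
    results, summary = ann.annotate_all(sites, models, fasta,
                                        segregating=segregating[near])
    results.to_csv(args.results / "annotation_sites.tsv", sep="\t",
                   index=False)
    summary.to_csv(args.results / "annotation_summary.tsv", sep="\t",
                   index=False)
    print(f"{len(sites)} SNPs annotated against {len(models)} transcripts")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
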