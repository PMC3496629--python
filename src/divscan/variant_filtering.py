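"""Putative-SNP filtering and per-population fixed/segregating classification.

A genotype call passes the discovery filter when its quality is at least 20
and its depth lies in the closed range 1-25.  A site is a putative SNP when at
least one passing genotype in any population is variant with respect to the
reference (heterozygous or homozygous non-reference).  Within a population a
putative SNP is *fixed* when every passing genotype is homozygous
non-reference, and *segregating* when the passing genotypes include a
heterozygote or a mix of the two homozygous classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (HET, HOM_NONREF, HOM_REF, MISSING, GenotypeCall,
                         PopulationMap, VariantSite, VariantTable)

# per-population site statuses
ABSENT = 0          # no passing genotype in the population
MONOMORPHIC_REF = 1  # called but every passing genotype is hom_ref
SEGREGATING = 2
FIXED = 3

STATUS_NAMES = {ABSENT: "absent", MONOMORPHIC_REF: "monomorphic_ref",
                SEGREGATING: "segregating", FIXED: "fixed"}

DEFAULT_MIN_GQ = 20
DEFAULT_DP_LO = 1
DEFAULT_DP_HI = 25


def passing_call(call: GenotypeCall, min_gq: int = DEFAULT_MIN_GQ,
                 dp_lo: int = DEFAULT_DP_LO, dp_hi: int = DEFAULT_DP_HI) -> bool:
    """True iff the genotype is present, GQ >= min_gq and dp_lo <= DP <= dp_hi.

    Both depth bounds are inclusive.
    """
    if call.gt_class == MISSING:
        return False
    return call.gq >= min_gq and dp_lo <= call.dp <= dp_hi


def passing_mask(table: VariantTable, min_gq: int = DEFAULT_MIN_GQ,
                 dp_lo: int = DEFAULT_DP_LO,
                 dp_hi: int = DEFAULT_DP_HI) -> np.ndarray:
    """Boolean (n_sites, n_samples) matrix of genotypes passing the filter."""
    return ((table.gt != MISSING) & (table.gq >= min_gq)
            & (table.dp >= dp_lo) & (table.dp <= dp_hi))


def putative_mask(table: VariantTable, min_gq: int = DEFAULT_MIN_GQ,
                  dp_lo: int = DEFAULT_DP_LO,
                  dp_hi: int = DEFAULT_DP_HI) -> np.ndarray:
    """Per-site boolean: at least one passing, non-hom_ref genotype."""
    passing = passing_mask(table, min_gq, dp_lo, dp_hi)
    variant = (table.gt == HET) | (table.gt == HOM_NONREF)
    return np.any(passing & variant, axis=1)


def putative_snps(table: VariantTable, min_gq: int = DEFAULT_MIN_GQ,
                  dp_lo: int = DEFAULT_DP_LO,
                  dp_hi: int = DEFAULT_DP_HI) -> VariantTable:
    """Subset the table to putative SNPs."""
    keep = putative_mask(table, min_gq, dp_lo, dp_hi)
    return VariantTable(
        samples=table.samples,
        contigs=table.contigs[keep], pos=table.pos[keep],
        ref=table.ref[keep], alt=table.alt[keep],
        gt=table.gt[keep], gq=table.gq[keep], dp=table.dp[keep],
        contig_lengths=table.contig_lengths,
    )


def classify_population(site: VariantSite, population: str,
                        population_map: PopulationMap,
                        min_gq: int = DEFAULT_MIN_GQ,
                        dp_lo: int = DEFAULT_DP_LO,
                        dp_hi: int = DEFAULT_DP_HI) -> int:
    """Classify one population at one site from its passing genotype calls."""
    members = set(population_map.samples_in(population))
    classes = [c.gt_class for c in site.calls
               if c.sample in members and passing_call(c, min_gq, dp_lo, dp_hi)]
    return _classify(classes)


def _classify(classes) -> int:
    if not classes:
        return ABSENT
    has_het = any(c == HET for c in classes)
    has_ref = any(c == HOM_REF for c in classes)
    has_nonref = any(c == HOM_NONREF for c in classes)
    if has_het or (has_ref and has_nonref):
        return SEGREGATING
    if has_nonref:
        return FIXED
    return MONOMORPHIC_REF


@dataclass
class SiteClassifications:
    """Per-site per-population statuses over a variant table.

    ``status`` is an (n_sites, n_populations) int8 matrix of the module's
    status codes; ``n_populations_called`` counts non-absent populations.
    """

    populations: list[str]
    contigs: np.ndarray
    pos: np.ndarray
    status: np.ndarray
    n_populations_called: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"contig": self.contigs, "pos": self.pos})
        for k, p in enumerate(self.populations):
            df[p] = [STATUS_NAMES[s] for s in self.status[:, k]]
        df["n_populations_called"] = self.n_populations_called
        return df


def classify_sites(table: VariantTable, population_map: PopulationMap,
                   min_gq: int = DEFAULT_MIN_GQ, dp_lo: int = DEFAULT_DP_LO,
                   dp_hi: int = DEFAULT_DP_HI) -> SiteClassifications:
    """Vectorised fixed/segregating/monomorphic/absent classification."""
    passing = passing_mask(table, min_gq, dp_lo, dp_hi)
    pops = population_map.populations
    status = np.zeros((table.n_sites, len(pops)), dtype=np.int8)
    for k, pop in enumerate(pops):
        cols = [table.sample_index(s) for s in population_map.samples_in(pop)
                if s in table.samples]
        sub_gt = table.gt[:, cols]
        sub_ok = passing[:, cols]
        has_het = np.any(sub_ok & (sub_gt == HET), axis=1)
        has_ref = np.any(sub_ok & (sub_gt == HOM_REF), axis=1)
        has_nonref = np.any(sub_ok & (sub_gt == HOM_NONREF), axis=1)
        any_call = np.any(sub_ok, axis=1)
        st = np.full(table.n_sites, ABSENT, dtype=np.int8)
        st[any_call] = MONOMORPHIC_REF
        st[any_call & has_nonref & ~has_ref & ~has_het] = FIXED
        st[has_het | (has_ref & has_nonref)] = SEGREGATING
        status[:, k] = st
    n_called = np.sum(status != ABSENT, axis=1)
    return SiteClassifications(list(pops), table.contigs, table.pos,
                               status, n_called)


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ti_tv(ref, alt) -> float:
    """Transition / transversion ratio over a set of substitutions.

    Accepts parallel sequences of single-base reference and alternate
    alleles.  Returns 0.0 when there are no transitions and +inf when there
    are transitions but no transversions.
    """
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    if len(ref) != len(alt):
        raise ValueError("ref and alt must be parallel")
    ti = sum((r, a) in _TRANSITIONS for r, a in zip(ref, alt))
    tv = len(ref) - ti
    if tv == 0:
        return float("inf") if ti else 0.0
    return ti / tv
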