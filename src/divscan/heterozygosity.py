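"""Coverage-restricted heterozygosity (heterozygous SNPs per kb).

Low sequence coverage depresses heterozygous genotype discovery, so the
estimate is restricted to reference positions covered 5-10 fold: the
numerator counts passing heterozygous genotypes at such positions and the
denominator is the number of bases so covered.  Population heterozygosity is
the unweighted mean of its members' per-individual estimates (each member has
its own denominator), which is what reproduces the published per-population
values from the per-individual ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import HET, DepthTrack, VariantTable, covered_bases, depth_at
from .variant_filtering import (DEFAULT_DP_HI, DEFAULT_DP_LO, DEFAULT_MIN_GQ,
                                passing_mask)

logger = logging.getLogger(__name__)

DEFAULT_COV_LO = 5
DEFAULT_COV_HI = 10


@dataclass(frozen=True)
class HetEstimate:
    """Per-individual heterozygosity restricted to a coverage band.

    ``het_per_kb`` is ``None`` (undefined, not zero) when no bases fall in
    the coverage band.
    """

    sample: str
    n_het_in_range: int
    denom_bases: int

    @property
    def het_per_kb(self) -> float | None:
        if self.denom_bases == 0:
            return None
        return 1000.0 * self.n_het_in_range / self.denom_bases


def het_per_kb(n_het: int, denom_bases: int) -> float:
    """1000 * n_het / denom_bases — the published ratio on printed counts."""
    if denom_bases <= 0:
        raise ValueError("denominator must be positive")
    return 1000.0 * n_het / denom_bases


def individual_het(sample: str, table: VariantTable, track: DepthTrack,
                   lo: int = DEFAULT_COV_LO, hi: int = DEFAULT_COV_HI,
                   min_gq: int = DEFAULT_MIN_GQ, dp_lo: int = DEFAULT_DP_LO,
                   dp_hi: int = DEFAULT_DP_HI) -> HetEstimate:
    """Count passing heterozygous genotypes at positions covered lo-hi fold.

    Position depth is taken from the sample's own depth track; the closed
    coverage band applies to both the numerator positions and the
    covered-base denominator.
    """
    j = table.sample_index(sample)
    ok = passing_mask(table, min_gq, dp_lo, dp_hi)[:, j]
    is_het = table.gt[:, j] == HET
    n_het = 0
    for contig in dict.fromkeys(table.contigs):  # preserves order
        at = table.contigs == contig
        cand = at & ok & is_het
        if not np.any(cand):
            continue
        depths = depth_at(track, contig, table.pos[cand] - 1)
        n_het += int(np.sum((depths >= lo) & (depths <= hi)))
    denom = covered_bases(track, lo, hi)
    return HetEstimate(sample, n_het, denom)


def population_het(estimates) -> float | None:
    """Unweighted mean of the members' het/kb; undefined members excluded."""
    vals = []
    for est in estimates:
        v = est.het_per_kb if isinstance(est, HetEstimate) else est
        if v is None:
            name = est.sample if isinstance(est, HetEstimate) else "?"
            logger.warning("excluding undefined heterozygosity for %s", name)
            continue
        vals.append(v)
    if not vals:
        return None
    return float(np.mean(vals))


def het_table(table: VariantTable, population_map, tracks: dict[str, DepthTrack],
              lo: int = DEFAULT_COV_LO, hi: int = DEFAULT_COV_HI) -> pd.DataFrame:
    """Per-individual estimates for every mapped sample, as a tidy frame."""
    rows = []
    for sample in table.samples:
        est = individual_het(sample, table, tracks[sample], lo, hi)
        rows.append({
            "sample": sample,
            "population": population_map.sample_to_population[sample],
            "n_het_in_range": est.n_het_in_range,
            "denom_bases": est.denom_bases,
            "het_per_kb": est.het_per_kb,
        })
    return pd.DataFrame(rows)


def population_het_table(individual_table: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean of individual het/kb values."""
    grouped = (individual_table.dropna(subset=["het_per_kb"])
               .groupby("population", sort=False)["het_per_kb"]
               .mean().reset_index())
    return grouped
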