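"""Scan for genomic bins fixed for the reference allelic state in
domesticated populations.

During domestication, selection (aided by low recombination near
centromeres) can drive the reference-genome allele to fixation in all
domesticated lines while the wild population retains the alternative.  Such
regions show (a) near-zero heterozygosity averaged across domesticated
populations and (b) an excess of homozygous non-reference calls in the wild
relative to the domesticated mean.  Both statistics are computed per 300 kb
bin; a bin is called fixed when its domesticated heterozygosity is at or
below a low-tail threshold AND its wild/domesticated non-reference
homozygosity ratio is at or above an upper-tail threshold.  Thresholds are
the empirical 5% genome-wide quantiles (or fixed published overrides
0.0002 and 1.73).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PopulationMap
from .windowed_diversity import WindowProfile

DEFAULT_HET_THRESHOLD = 0.0002
DEFAULT_RATIO_THRESHOLD = 1.73


@dataclass
class BinStats:
    """Per-bin wild/domesticated diversity contrasts.

    All densities are counts per covered base.  ``ratio`` is +inf where the
    wild population shows non-reference homozygosity but the domesticated
    mean is zero, and NaN where undefined; ``diff_norm`` is NaN where the
    all-population mean density (its normaliser) is zero or undefined.
    """

    contigs: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    het_dom: np.ndarray      # mean het density across domesticated populations
    homnr_dom: np.ndarray    # mean hom-non-ref density across domesticated pops
    homnr_wild: np.ndarray
    diff_norm: np.ndarray
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contig": self.contigs, "start": self.starts, "end": self.ends,
            "het_dom": self.het_dom, "homnr_dom": self.homnr_dom,
            "homnr_wild": self.homnr_wild, "diff_norm": self.diff_norm,
            "ratio": self.ratio,
        })


def _population_mean_density(profile: WindowProfile, density: np.ndarray,
                             population_map: PopulationMap,
                             population: str) -> np.ndarray:
    cols = [profile.samples.index(s)
            for s in population_map.samples_in(population)
            if s in profile.samples]
    with np.errstate(invalid="ignore"):
        return np.nanmean(density[:, cols], axis=1)


def bin_stats(profile: WindowProfile,
              population_map: PopulationMap) -> BinStats:
    """Aggregate a window profile into wild-vs-domesticated bin statistics.

    Each population's density is the mean of its members' densities; the
    domesticated aggregate weights populations equally regardless of member
    count.
    """
    wild = population_map.wild_population
    dom = population_map.domesticated_populations
    het_d = profile.density("het")
    homnr_d = profile.density("homnr")

    het_pop = {p: _population_mean_density(profile, het_d, population_map, p)
               for p in population_map.populations}
    homnr_pop = {p: _population_mean_density(profile, homnr_d, population_map, p)
                 for p in population_map.populations}

    with np.errstate(invalid="ignore"):
        het_dom = np.nanmean(np.vstack([het_pop[p] for p in dom]), axis=0)
        homnr_dom = np.nanmean(np.vstack([homnr_pop[p] for p in dom]), axis=0)
        homnr_all = np.nanmean(
            np.vstack([homnr_pop[p] for p in population_map.populations]),
            axis=0)
    homnr_wild = homnr_pop[wild]

    n = profile.n_windows
    ratio = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_dom = homnr_dom > 0
        ratio[pos_dom] = homnr_wild[pos_dom] / homnr_dom[pos_dom]
    zero_dom = (homnr_dom == 0) & (homnr_wild > 0)
    ratio[zero_dom] = np.inf

    diff_norm = np.full(n, np.nan)
    ok = np.isfinite(homnr_all) & (homnr_all > 0) \
        & np.isfinite(homnr_wild) & np.isfinite(homnr_dom)
    diff_norm[ok] = (homnr_wild[ok] - homnr_dom[ok]) / homnr_all[ok]

    return BinStats(profile.contigs, profile.starts, profile.ends,
                    het_dom, homnr_dom, homnr_wild, diff_norm, ratio)


def _tail_order_statistic(values: np.ndarray, frac: float, side: str) -> float:
    """Inclusive empirical quantile: the order statistic v such that the
    fraction of values <= v (side='lower') or >= v (side='upper') is at
    least ``frac`` with the smallest such tail."""
    v = values[~np.isnan(values)]
    if v.size == 0:
        raise ValueError("no defined values to take a quantile of")
    k = max(1, math.ceil(frac * v.size - 1e-9))
    v = np.sort(v)
    if side == "lower":
        return float(v[k - 1])
    return float(v[v.size - k])


def derive_thresholds(bins: BinStats, het_quantile: float = 0.05,
                      ratio_quantile: float = 0.95) -> tuple[float, float]:
    """Empirical thresholds: the het value with 5% of bins at or below it,
    and the ratio value with 5% of bins at or above it."""
    het_threshold = _tail_order_statistic(bins.het_dom, het_quantile, "lower")
    finite_ratio = bins.ratio.copy()
    ratio_threshold = _tail_order_statistic(finite_ratio, 1 - ratio_quantile,
                                            "upper")
    return het_threshold, ratio_threshold


@dataclass(frozen=True)
class FixedRegionCall:
    """A maximal run of adjacent bins passing both fixation criteria."""

    contig: str
    start: int
    end: int
    n_bins: int
    mean_het_dom: float
    min_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


def call_fixed_regions(bins: BinStats,
                       het_threshold: float = DEFAULT_HET_THRESHOLD,
                       ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                       merge: bool = True) -> list[FixedRegionCall]:
    """Bins with het_dom <= het_threshold and ratio >= ratio_threshold.

    Both bounds are inclusive; an infinite ratio (wild signal over a zero
    domesticated mean) passes the ratio criterion.  Adjacent qualifying bins
    on the same contig are merged when ``merge`` is true.
    """
    with np.errstate(invalid="ignore"):
        qual = ((~np.isnan(bins.het_dom)) & (bins.het_dom <= het_threshold)
                & (~np.isnan(bins.ratio)) & (bins.ratio >= ratio_threshold))
    calls: list[FixedRegionCall] = []
    i = 0
    n = len(qual)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        k = i
        while (merge and k + 1 < n and qual[k + 1]
               and bins.contigs[k + 1] == bins.contigs[i]
               and bins.starts[k + 1] == bins.ends[k]):
            k += 1
        sl = slice(i, k + 1)
        calls.append(FixedRegionCall(
            contig=bins.contigs[i], start=int(bins.starts[i]),
            end=int(bins.ends[k]), n_bins=k - i + 1,
            mean_het_dom=float(np.mean(bins.het_dom[sl])),
            min_ratio=float(np.min(bins.ratio[sl])),
        ))
        i = k + 1
    return calls


def calls_to_bed(calls: list[FixedRegionCall]) -> list[tuple]:
    """BED rows (contig, start, end, n_bins, mean_het_dom, min_ratio)."""
    return [(c.contig, c.start, c.end, c.n_bins,
             f"{c.mean_het_dom:.3g}",
             "inf" if math.isinf(c.min_ratio) else f"{c.min_ratio:.3g}")
            for c in calls]
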