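"""Windowed nucleotide diversity profiles, homozygous-run detection, and
false-discovery-rate estimation from identical-by-descent regions.

Diversity is profiled in 300 kb windows: per sample, the number of
heterozygous and homozygous non-reference genotype calls (GQ >= 20, depth
3-15) in the window, normalised by that sample's own bases covered 3-15 fold
within the window.  Long runs of near-zero heterozygosity mark regions where
an individual carries two copies of one haplotype; heterozygous calls inside
such runs are genotyping errors, and the false discovery rate per nucleotide
is their count divided by the bases covered 1-25 fold in the runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HET, HOM_NONREF, DepthTrack, VariantTable, covered_bases
from .variant_filtering import DEFAULT_MIN_GQ, passing_mask

DEFAULT_WIDTH = 300_000
DIVERSITY_DP_LO = 3
DIVERSITY_DP_HI = 15
FDR_DENOM_LO = 1
FDR_DENOM_HI = 25
# automated stand-ins for the visual identification of homozygous regions
DEFAULT_MAX_RUN_DENSITY = 2e-5      # het calls per covered base
DEFAULT_MIN_RUN_LENGTH = 2_700_000  # smallest region used for FDR estimation


@dataclass
class WindowProfile:
    """Per-window, per-sample counts and covered-base denominators.

    Windows tile each contig without overlap (the last window of a contig may
    be short).  Densities are count / covered_bases and are undefined (NaN)
    where a sample has no covered bases in the window.
    """

    samples: list[str]
    contigs: np.ndarray            # per window
    starts: np.ndarray             # 0-based
    ends: np.ndarray               # half-open
    het: np.ndarray                # (n_windows, n_samples) int64
    homnr: np.ndarray
    covered: np.ndarray            # bases in the diversity depth band
    width: int = DEFAULT_WIDTH

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def density(self, kind: str = "het") -> np.ndarray:
        """(n_windows, n_samples) density matrix; NaN where undefined."""
        counts = self.het if kind == "het" else self.homnr
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.covered > 0, counts / self.covered, np.nan)

    def to_frame(self) -> pd.DataFrame:
        cols = {"contig": self.contigs, "start": self.starts,
                "end": self.ends}
        het_d = self.density("het")
        homnr_d = self.density("homnr")
        for j, s in enumerate(self.samples):
            cols[f"{s}.het"] = self.het[:, j]
            cols[f"{s}.homnr"] = self.homnr[:, j]
            cols[f"{s}.covered"] = self.covered[:, j]
            cols[f"{s}.het_density"] = het_d[:, j]
            cols[f"{s}.homnr_density"] = homnr_d[:, j]
        return pd.DataFrame(cols)


def _tile(contig_lengths: dict[str, int], width: int):
    contigs, starts, ends = [], [], []
    for name, length in contig_lengths.items():
        edges = np.arange(0, length, width, dtype=np.int64)
        contigs.extend([name] * len(edges))
        starts.append(edges)
        ends.append(np.minimum(edges + width, length))
    return (np.array(contigs, dtype=object), np.concatenate(starts),
            np.concatenate(ends))


def window_profile(table: VariantTable, tracks: dict[str, DepthTrack],
                   width: int = DEFAULT_WIDTH,
                   dp_lo: int = DIVERSITY_DP_LO, dp_hi: int = DIVERSITY_DP_HI,
                   min_gq: int = DEFAULT_MIN_GQ,
                   contig_lengths: dict[str, int] | None = None) -> WindowProfile:
    """Count het / hom-non-ref calls and covered bases per window per sample."""
    if contig_lengths is None:
        contig_lengths = dict(table.contig_lengths)
        if not contig_lengths:
            raise ValueError("contig lengths unavailable; pass contig_lengths")
    w_contigs, w_starts, w_ends = _tile(contig_lengths, width)
    n_windows = len(w_starts)
    window_base = {}
    for i, c in enumerate(w_contigs):
        window_base.setdefault(c, i)

    n_samples = table.n_samples
    het = np.zeros((n_windows, n_samples), dtype=np.int64)
    homnr = np.zeros((n_windows, n_samples), dtype=np.int64)
    covered = np.zeros((n_windows, n_samples), dtype=np.int64)

    ok = passing_mask(table, min_gq, dp_lo, dp_hi)
    for contig in contig_lengths:
        at = table.contigs == contig
        if np.any(at):
            widx = window_base[contig] + (table.pos[at] - 1) // width
            sub_ok = ok[at]
            sub_gt = table.gt[at]
            for j in range(n_samples):
                np.add.at(het[:, j], widx[sub_ok[:, j] & (sub_gt[:, j] == HET)], 1)
                np.add.at(homnr[:, j],
                          widx[sub_ok[:, j] & (sub_gt[:, j] == HOM_NONREF)], 1)
        for j, sample in enumerate(table.samples):
            track = tracks[sample]
            if contig not in track.intervals:
                continue
            s, e, d = track.intervals[contig]
            band = (d >= dp_lo) & (d <= dp_hi)
            s, e = s[band], e[band]
            ws = s // width
            we = (e - 1) // width
            simple = ws == we
            np.add.at(covered[:, j], window_base[contig] + ws[simple],
                      (e - s)[simple])
            for si, ei, wsi, wei in zip(s[~simple], e[~simple],
                                        ws[~simple], we[~simple]):
                for wi in range(wsi, wei + 1):
                    lo_b = max(si, wi * width)
                    hi_b = min(ei, (wi + 1) * width)
                    covered[window_base[contig] + wi, j] += hi_b - lo_b
    return WindowProfile(list(table.samples), w_contigs, w_starts, w_ends,
                         het, homnr, covered, width)


@dataclass(frozen=True)
class HomozygousRegion:
    """A run of consecutive low-heterozygosity windows in one sample."""

    contig: str
    start: int
    end: int
    sample: str
    mean_het_density: float

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_homozygous_runs(profile: WindowProfile, sample: str,
                           max_density: float = DEFAULT_MAX_RUN_DENSITY,
                           min_run_length: int = DEFAULT_MIN_RUN_LENGTH
                           ) -> list[HomozygousRegion]:
    """Maximal runs of consecutive windows with het density <= max_density.

    Windows with no covered bases carry no evidence and do not interrupt a
    run, but a reported run must contain at least one defined window.  Runs
    shorter than ``min_run_length`` are discarded.
    """
    j = profile.samples.index(sample)
    dens = profile.density("het")[:, j]
    qualifies = np.isnan(dens) | (dens <= max_density)
    regions: list[HomozygousRegion] = []
    i = 0
    n = profile.n_windows
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        k = i
        while (k + 1 < n and qualifies[k + 1]
               and profile.contigs[k + 1] == profile.contigs[i]):
            k += 1
        start, end = int(profile.starts[i]), int(profile.ends[k])
        run_dens = dens[i:k + 1]
        defined = run_dens[~np.isnan(run_dens)]
        if end - start >= min_run_length and defined.size:
            regions.append(HomozygousRegion(profile.contigs[i], start, end,
                                            sample, float(np.mean(defined))))
        i = k + 1
    return regions


@dataclass
class FdrResult:
    """Per-sample and mean false-het rate per covered nucleotide."""

    per_sample: dict[str, float] = field(default_factory=dict)
    per_sample_het: dict[str, int] = field(default_factory=dict)
    per_sample_denom: dict[str, int] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        vals = list(self.per_sample.values())
        return float(np.mean(vals)) if vals else float("nan")


def estimate_fdr(regions, table: VariantTable, tracks: dict[str, DepthTrack],
                 samples: list[str] | None = None,
                 min_gq: int = DEFAULT_MIN_GQ,
                 dp_lo: int = DIVERSITY_DP_LO, dp_hi: int = DIVERSITY_DP_HI,
                 denom_lo: int = FDR_DENOM_LO,
                 denom_hi: int = FDR_DENOM_HI) -> FdrResult:
    """False-discovery rate from regions believed IBD-homozygous.

    ``regions`` is a list of (contig, start, end) 0-based half-open tuples or
    :class:`HomozygousRegion` objects.  For each sample, every passing
    heterozygous call inside the regions is counted as a false positive and
    divided by the sample's bases covered ``denom_lo``-``denom_hi`` fold in
    the same regions.  The result is invariant to how the region set is
    partitioned.
    """
    tuples = [(r.contig, r.start, r.end) if isinstance(r, HomozygousRegion)
              else (r[0], int(r[1]), int(r[2])) for r in regions]
    if samples is None:
        samples = list(table.samples)
    ok = passing_mask(table, min_gq, dp_lo, dp_hi)
    in_regions = np.zeros(table.n_sites, dtype=bool)
    for contig, start, end in tuples:
        pos0 = table.pos - 1
        in_regions |= (table.contigs == contig) & (pos0 >= start) & (pos0 < end)
    result = FdrResult()
    for sample in samples:
        j = table.sample_index(sample)
        n_het = int(np.sum(in_regions & ok[:, j] & (table.gt[:, j] == HET)))
        denom = sum(covered_bases(tracks[sample], denom_lo, denom_hi, region=r)
                    for r in tuples)
        if denom > 0:
            result.per_sample[sample] = n_het / denom
            result.per_sample_het[sample] = n_het
            result.per_sample_denom[sample] = denom
    return result
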