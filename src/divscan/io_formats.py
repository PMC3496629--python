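"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Coordinate conventions: VCF positions are 1-based; every interval (BED depth
tracks, windows, bins, sweep regions) is 0-based half-open.  Conversion happens
only at the I/O boundary.

The streaming view of a VCF is a sequence of :class:`VariantSite` records; the
in-memory form used by the analysis modules is :class:`VariantTable`, a set of
aligned numpy matrices (one row per site, one column per sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

# genotype classes (values used in VariantTable.gt matrices)
HOM_REF = 0
HET = 1
HOM_NONREF = 2
MISSING = -1

GT_CLASS_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_NONREF: "hom_nonref",
                  MISSING: "missing"}


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site, with its quality and depth.

    ``gq`` and ``dp`` are ``None`` exactly when ``gt_class`` is missing.
    """

    sample: str
    contig: str
    pos: int              # 1-based
    ref_allele: str
    alt_allele: str
    gt_class: int         # HOM_REF | HET | HOM_NONREF | MISSING
    gq: int | None
    dp: int | None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if (self.gt_class == MISSING) != (self.gq is None and self.dp is None):
            raise ValueError("gq/dp must be absent iff the genotype is missing")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic site with at most one :class:`GenotypeCall` per sample."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    calls: tuple[GenotypeCall, ...]

    def __post_init__(self) -> None:
        seen = set()
        for c in self.calls:
            if (c.contig, c.pos) != (self.contig, self.pos):
                raise ValueError("call coordinates disagree with site")
            if c.sample in seen:
                raise ValueError(f"duplicate call for sample {c.sample}")
            seen.add(c.sample)


@dataclass(frozen=True)
class Read:
    """A sequencing read: bases with per-base phred qualities."""

    identifier: str
    bases: str
    quals: tuple[int, ...]
    mate: int = 0  # 1, 2, or 0 for unpaired

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class PopulationMap:
    """sample -> population mapping with a wild/domesticated flag per population."""

    sample_to_population: dict[str, str]
    wild_populations: frozenset[str]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_population)

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for p in self.sample_to_population.values():
            if p not in out:
                out.append(p)
        return out

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_population.items() if p == population]

    def is_wild(self, population: str) -> bool:
        return population in self.wild_populations

    @property
    def domesticated_populations(self) -> list[str]:
        return [p for p in self.populations if p not in self.wild_populations]

    @property
    def wild_population(self) -> str:
        """The unique wild population (required by the fixation scan)."""
        wild = [p for p in self.populations if p in self.wild_populations]
        if len(wild) != 1:
            raise ValueError(f"exactly one wild population required, got {wild}")
        return wild[0]


def read_population_map(path) -> PopulationMap:
    """Read a 3-column TSV: sample, population, wild flag (1/0/true/false)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["sample", "population", "wild"], dtype=str,
                     comment="#")
    truthy = {"1", "true", "wild", "yes"}
    wild = frozenset(df.loc[df["wild"].str.lower().isin(truthy), "population"])
    return PopulationMap(dict(zip(df["sample"], df["population"])), wild)


def write_population_map(path, popmap: PopulationMap) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.sample_to_population.items():
            fh.write(f"{s}\t{p}\t{1 if popmap.is_wild(p) else 0}\n")


# ---------------------------------------------------------------------------
# read trimming
# ---------------------------------------------------------------------------

def trim_read(read: Read, window: int = 3, min_mean_q: float = 13) -> Read:
    """Quality-trim a read at the first low-quality window.

    The retained part is the longest prefix that ends before the first
    position at which ``window`` consecutive bases have a mean phred quality
    below ``min_mean_q``.  Trimming is 3'-only: quality decays toward the read
    end on short-read platforms, so the 5' prefix is kept.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n < window:
        return read
    q = np.asarray(read.quals, dtype=float)
    # compare window sums against window * threshold: exact for integer quals
    sums = np.convolve(q, np.ones(window), mode="valid")
    below = np.nonzero(sums < min_mean_q * window)[0]
    if below.size == 0:
        return read
    cut = int(below[0])
    return Read(read.identifier, read.bases[:cut], read.quals[:cut], read.mate)


def trim_pair(r1: Read, r2: Read, window: int = 3, min_mean_q: float = 13,
              min_len: int = 40) -> tuple[Read, Read] | None:
    """Trim both mates; keep the pair only if both exceed ``min_len`` bases.

    Returns the trimmed pair, or ``None`` when the pair is rejected.
    """
    t1 = trim_read(r1, window, min_mean_q)
    t2 = trim_read(r2, window, min_mean_q)
    if len(t1) > min_len and len(t2) > min_len:
        return t1, t2
    return None


def read_fastq(path) -> Iterator[Read]:
    """Parse a phred+33 FASTQ file into :class:`Read` records."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        mate = 0
        name = rec.id
        if name.endswith("/1"):
            mate, name = 1, name[:-2]
        elif name.endswith("/2"):
            mate, name = 2, name[:-2]
        yield Read(name, str(rec.seq),
                   tuple(rec.letter_annotations["phred_quality"]), mate)


def write_fastq(path, reads: Iterable[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if r.mate else ""
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.identifier}{suffix}\n{r.bases}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# VariantTable: matrix view of a multi-sample VCF
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Aligned per-site arrays and per-site-per-sample genotype matrices.

    ``gt`` holds genotype classes (HOM_REF/HET/HOM_NONREF/MISSING); ``gq`` and
    ``dp`` hold -1 where the genotype is missing.
    """

    samples: list[str]
    contigs: np.ndarray          # object array of contig names, per site
    pos: np.ndarray              # int64, 1-based
    ref: np.ndarray              # single-base strings
    alt: np.ndarray
    gt: np.ndarray               # (n_sites, n_samples) int8
    gq: np.ndarray               # (n_sites, n_samples) int32
    dp: np.ndarray               # (n_sites, n_samples) int32
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sites(self) -> Iterator[VariantSite]:
        """Yield the streaming-record view of the table."""
        for i in range(self.n_sites):
            calls = []
            for j, s in enumerate(self.samples):
                cls = int(self.gt[i, j])
                if cls == MISSING:
                    calls.append(GenotypeCall(s, self.contigs[i], int(self.pos[i]),
                                              self.ref[i], self.alt[i], MISSING,
                                              None, None))
                else:
                    calls.append(GenotypeCall(s, self.contigs[i], int(self.pos[i]),
                                              self.ref[i], self.alt[i], cls,
                                              int(self.gq[i, j]), int(self.dp[i, j])))
            yield VariantSite(self.contigs[i], int(self.pos[i]), self.ref[i],
                              self.alt[i], tuple(calls))

    @classmethod
    def from_vcf(cls, path, population_map: PopulationMap | None = None,
                 multiallelic: str = "drop") -> "VariantTable":
        """Load a VCF 4.x file with GT/GQ/DP per genotype.

        ``multiallelic`` is ``"drop"`` (default; dropped records are counted in
        the log) or ``"split"`` (one biallelic row per alternate allele).
        """
        if multiallelic not in ("drop", "split"):
            raise ValueError("multiallelic must be 'drop' or 'split'")
        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        if population_map is not None:
            unmapped = [s for s in samples
                        if s not in population_map.sample_to_population]
            if unmapped:
                raise ValueError(f"samples not in population map: {unmapped}")
        try:
            contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
        except AttributeError:  # no contig lines in the header
            contig_lengths = {}

        contigs: list[str] = []
        pos: list[int] = []
        ref: list[str] = []
        alt: list[str] = []
        gts: list[np.ndarray] = []
        gqs: list[np.ndarray] = []
        dps: list[np.ndarray] = []
        n_multi = 0
        for v in vcf:
            alts = v.ALT
            if len(alts) != 1 or len(v.REF) != 1 or any(len(a) != 1 for a in alts):
                if multiallelic == "drop" or len(v.REF) != 1:
                    n_multi += 1
                    continue
                use_alts = [a for a in alts if len(a) == 1]
            else:
                use_alts = alts
            # gts012: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
            g = v.gt_types.astype(np.int8)
            g[g == 3] = MISSING
            g[g == 2] = HOM_NONREF
            q = v.gt_quals
            q = np.full(len(samples), -1, np.int32) if q is None \
                else np.where(np.isnan(q), -1, q).astype(np.int32)
            d = v.format("DP")
            if d is None:
                d = np.full(len(samples), -1, np.int32)
            else:
                d = d[:, 0].astype(np.int32)
                d[d < 0] = -1  # htslib missing-int sentinel
            q[g == MISSING] = -1
            d[g == MISSING] = -1
            for a in use_alts:
                contigs.append(v.CHROM)
                pos.append(v.POS)
                ref.append(v.REF)
                alt.append(a)
                gts.append(g)
                gqs.append(q)
                dps.append(d)
        if n_multi:
            logger.info("dropped %d multi-allelic / non-SNP records", n_multi)
        n = len(pos)
        return cls(
            samples=samples,
            contigs=np.array(contigs, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            ref=np.array(ref, dtype=object),
            alt=np.array(alt, dtype=object),
            gt=np.vstack(gts) if n else np.empty((0, len(samples)), np.int8),
            gq=np.vstack(gqs) if n else np.empty((0, len(samples)), np.int32),
            dp=np.vstack(dps) if n else np.empty((0, len(samples)), np.int32),
            contig_lengths=contig_lengths,
        )


_GT_FIELD = {HOM_REF: "0/0", HET: "0/1", HOM_NONREF: "1/1", MISSING: "./."}


def write_vcf(path, table: VariantTable) -> None:
    """Write a VariantTable as an uncompressed VCF 4.2 file.

    Emission is assembled as text for throughput on large simulated tables;
    round-trip identity against the cyvcf2 reader is covered by tests.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">']
    for name, length in table.contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples))
    gt, gq, dp = table.gt, table.gq, table.dp
    for i in range(table.n_sites):
        fields = [table.contigs[i], str(table.pos[i]), ".", table.ref[i],
                  table.alt[i], ".", "PASS", ".", "GT:GQ:DP"]
        row = gt[i]
        for j in range(table.n_samples):
            if row[j] == MISSING:
                fields.append("./.:.:.")
            else:
                fields.append(f"{_GT_FIELD[row[j]]}:{gq[i, j]}:{dp[i, j]}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, population_map: PopulationMap | None = None,
             multiallelic: str = "drop") -> Iterator[VariantSite]:
    """Stream a VCF as :class:`VariantSite` records in file order."""
    table = VariantTable.from_vcf(path, population_map, multiallelic)
    yield from table.sites()


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Per-sample piecewise-constant coverage: sorted, non-overlapping
    0-based half-open intervals with an integer depth each."""

    sample: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # contig -> (starts, ends, depths)

    def validate(self) -> None:
        for contig, (s, e, d) in self.intervals.items():
            if np.any(e <= s):
                raise ValueError(f"{contig}: empty or inverted interval")
            if np.any(d < 0):
                raise ValueError(f"{contig}: negative depth")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{contig}: overlapping intervals")


def read_depth_track(path, sample: str) -> DepthTrack:
    """Read a BED4 file (contig, start, end, depth) into a DepthTrack."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "depth"],
                     dtype={"contig": str}, comment="#")
    intervals = {}
    for contig, sub in df.groupby("contig", sort=False):
        sub = sub.sort_values("start")
        intervals[contig] = (sub["start"].to_numpy(np.int64),
                             sub["end"].to_numpy(np.int64),
                             sub["depth"].to_numpy(np.int64))
    track = DepthTrack(sample, intervals)
    track.validate()
    return track


def write_depth_track(path, track: DepthTrack) -> None:
    with open(path, "w") as fh:
        for contig, (s, e, d) in track.intervals.items():
            for i in range(len(s)):
                fh.write(f"{contig}\t{s[i]}\t{e[i]}\t{d[i]}\n")


def covered_bases(track: DepthTrack, lo: int, hi: int,
                  region: tuple[str, int, int] | None = None) -> int:
    """Number of reference positions with depth in the closed range [lo, hi].

    ``region`` restricts the count to (contig, start, end), 0-based half-open.
    """
    if lo > hi:
        raise ValueError("lo must be <= hi")
    total = 0
    for contig, (s, e, d) in track.intervals.items():
        if region is not None:
            rc, rs, re_ = region
            if contig != rc:
                continue
            s = np.maximum(s, rs)
            e = np.minimum(e, re_)
        mask = (d >= lo) & (d <= hi) & (e > s)
        total += int(np.sum(e[mask] - s[mask]))
    return total


def depth_at(track: DepthTrack, contig: str, positions: np.ndarray) -> np.ndarray:
    """Depth of ``track`` at 0-based ``positions`` (0 where uncovered)."""
    out = np.zeros(len(positions), dtype=np.int64)
    if contig not in track.intervals:
        return out
    s, e, d = track.intervals[contig]
    idx = np.searchsorted(s, positions, side="right") - 1
    valid = idx >= 0
    inside = np.zeros(len(positions), dtype=bool)
    inside[valid] = positions[valid] < e[idx[valid]]
    out[inside] = d[idx[inside]]
    return out


# ---------------------------------------------------------------------------
# FASTA / GFF / BED / newick
# ---------------------------------------------------------------------------

def read_fasta(path) -> Fasta:
    """Open a FASTA file for random access (pyfaidx-backed)."""
    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gene_models(path):
    """Load gene models from a GFF3/GTF file (see :mod:`divscan.annotation`)."""
    from .annotation import load_gene_models

    return load_gene_models(path)


def write_bed(path, intervals: Iterable[tuple], extra_header: str | None = None):
    """Write (contig, start, end, *extra) rows as 0-based half-open BED."""
    with open(path, "w") as fh:
        if extra_header:
            fh.write(f"#{extra_header}\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns as (contig, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_newick(path, tree) -> None:
    """Write a dendropy tree (or newick string) to ``path``."""
    if hasattr(tree, "as_string"):
        text = tree.as_string(schema="newick", suppress_rooting=True)
    else:
        text = str(tree)
        if not text.endswith(";"):
            text += ";"
    with open(path, "w") as fh:
        fh.write(text.strip() + "\n")
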