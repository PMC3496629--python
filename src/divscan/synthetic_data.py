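"""Synthetic genotype, depth, reference and gene-model fixtures.

The generator emulates the study design the analysis modules assume: eleven
populations — seven commercial lines (3 birds each), three heritage
varieties (3/3/2) and one wild population (3) — descended from a shared
ancestral gene pool.  Ancestral alternate-allele frequencies are drawn from
a U-shaped Beta(0.5, 0.5); each population then drifts by Wright-Fisher
binomial resampling for a configurable number of generations at its own
effective size (domesticated lines: many generations at small size; the
wild population: mild drift).  The reference genome plays the role of one
commercial haplotype, so domesticated populations are relatively close to
it.  Inside planted sweep regions every domesticated population is forced to
alternate-allele frequency zero (fixed for the reference allele) while the
wild population keeps its ancestral frequency — the signature the fixation
scan is designed to recover.

Observation model: per-sample coverage is piecewise-constant Poisson per
1 kb chunk; a genotype's DP equals the track depth at its position (no call
where depth is zero).  With probability ``genotype_error_rate`` the emitted
genotype class is flipped to an adjacent class (hom <-> het).  Correct calls
get GQ = min(99, 20 + 3*DP); erroneous calls get GQ ~ round(Exp(scale=15)),
so errors concentrate at low GQ while a known fraction exp(-(gq-0.5)/scale)
survives a GQ cutoff — which keeps the GQ filter meaningful and makes the
expected false-heterozygote rate closed-form (see ``expected_fdr``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (HET, HOM_NONREF, HOM_REF, MISSING, DepthTrack,
                         PopulationMap, VariantTable, depth_at, write_depth_track,
                         write_fasta, write_population_map, write_vcf)

DEFAULT_SNP_DENSITY = 0.0065      # SNP sites per bp
DEFAULT_MEAN_DEPTH = 5.0
DEFAULT_ERROR_RATE = 1e-3
DEFAULT_TI_FRACTION = 0.71        # P(alternate allele is a transition)


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n_individuals: int
    wild: bool
    drift_generations: int
    effective_size: int


_SUFFIX = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    seed: int
    contigs: list[tuple[str, int]]
    populations: list[PopulationSpec]
    sweep_regions: list[tuple[str, int, int]] = field(default_factory=list)
    snp_density: float = DEFAULT_SNP_DENSITY
    mean_depth: float = DEFAULT_MEAN_DEPTH
    genotype_error_rate: float = DEFAULT_ERROR_RATE
    gq_correct_base: int = 20
    gq_correct_slope: int = 3
    gq_error_scale: float = 15.0
    depth_chunk: int = 1000
    beta_a: float = 0.5
    beta_b: float = 0.5
    ti_fraction: float = DEFAULT_TI_FRACTION

    def __post_init__(self) -> None:
        lengths = dict(self.contigs)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("contig lengths must be positive")
        if any(p.n_individuals <= 0 or p.effective_size <= 0
               for p in self.populations):
            raise ValueError("population sizes must be positive")
        wild = [p for p in self.populations if p.wild]
        if len(wild) != 1:
            raise ValueError("exactly one wild population required")
        for contig, start, end in self.sweep_regions:
            if contig not in lengths or not (0 <= start < end <= lengths[contig]):
                raise ValueError(f"sweep region {(contig, start, end)} outside "
                                 "contigs")

    @property
    def samples(self) -> list[str]:
        return [f"{p.label}{_SUFFIX[i]}" for p in self.populations
                for i in range(p.n_individuals)]

    @property
    def sample_population(self) -> dict[str, str]:
        return {f"{p.label}{_SUFFIX[i]}": p.label for p in self.populations
                for i in range(p.n_individuals)}

    def population_map(self) -> PopulationMap:
        wild = frozenset(p.label for p in self.populations if p.wild)
        return PopulationMap(dict(self.sample_population), wild)

    def _rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        return np.random.default_rng(ss)


def default_populations() -> list[PopulationSpec]:
    """Seven commercial lines, three heritage varieties, one wild population.

    Drift settings are calibrated analytically: heterozygosity decays by
    (1 - 1/(2Ne))^g, so 40 generations at Ne=40 keep ~60% of ancestral
    diversity in the domesticated lines while Ne=500 leaves the wild
    population nearly intact — yielding roughly 1 vs 1.6 het/kb at the
    default SNP density.
    """
    pops = [PopulationSpec(f"L{i}", 3, False, 40, 40) for i in range(1, 8)]
    pops += [PopulationSpec("BvSW", 3, False, 40, 40),
             PopulationSpec("Nset", 3, False, 40, 40),
             PopulationSpec("RP", 2, False, 40, 40),
             PopulationSpec("SM", 3, True, 40, 500)]
    return pops


def default_config(seed: int,
                   contigs: list[tuple[str, int]] | None = None,
                   sweep_regions: list[tuple[str, int, int]] | None = None,
                   **overrides) -> SimulationConfig:
    """The study-condition configuration at a reduced genome scale."""
    if contigs is None:
        contigs = [("chr1", 15_000_000), ("chr2", 15_000_000)]
    if sweep_regions is None:
        sweep_regions = [("chr1", 3_000_000, 4_000_000),
                         ("chr1", 9_600_000, 10_600_000),
                         ("chr2", 6_000_000, 7_000_000)]
    return SimulationConfig(seed=seed, contigs=contigs,
                            populations=default_populations(),
                            sweep_regions=sweep_regions, **overrides)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Per-site ancestral and per-population alternate-allele frequencies."""

    contigs: np.ndarray
    pos: np.ndarray                 # 1-based
    ancestral: np.ndarray           # alternate-allele frequency
    populations: dict[str, np.ndarray]
    in_sweep: np.ndarray            # bool

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def _site_positions(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    contigs, pos = [], []
    for name, length in config.contigs:
        n = int(round(config.snp_density * length))
        draw = np.unique(rng.integers(0, length, size=int(n * 1.05) + 8))
        if len(draw) > n:
            keep = rng.choice(len(draw), size=n, replace=False)
            draw = np.sort(draw[keep])
        contigs.extend([name] * len(draw))
        pos.append(draw + 1)
    return np.array(contigs, dtype=object), np.concatenate(pos)


def _sweep_mask(config: SimulationConfig, contigs: np.ndarray,
                pos: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    pos0 = pos - 1
    for contig, start, end in config.sweep_regions:
        mask |= (contigs == contig) & (pos0 >= start) & (pos0 < end)
    return mask


def simulate_frequencies(config: SimulationConfig) -> FrequencyTable:
    """Ancestral Beta frequencies drifted per population by Wright-Fisher.

    Inside sweep regions the domesticated populations' alternate-allele
    frequency is forced to 0 (fixed for the reference allele); the wild
    population keeps its ancestral frequency there.
    """
    rng = config._rng(0)
    contigs, pos = _site_positions(config, rng)
    n = len(pos)
    anc = rng.beta(config.beta_a, config.beta_b, size=n)
    anc = np.clip(anc, 1e-9, 1 - 1e-9)  # condition on polymorphism
    in_sweep = _sweep_mask(config, contigs, pos)
    pops: dict[str, np.ndarray] = {}
    for spec in config.populations:
        q = anc.copy()
        two_n = 2 * spec.effective_size
        for _ in range(spec.drift_generations):
            q = rng.binomial(two_n, q) / two_n
        if not spec.wild:
            q[in_sweep] = 0.0
        else:
            q[in_sweep] = anc[in_sweep]
        pops[spec.label] = q
    return FrequencyTable(contigs, pos, anc, pops, in_sweep)


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

def simulate_depth_tracks(config: SimulationConfig) -> dict[str, DepthTrack]:
    """Piecewise-constant Poisson coverage per sample (one value per chunk)."""
    rng = config._rng(1)
    tracks: dict[str, DepthTrack] = {}
    for sample in config.samples:
        intervals = {}
        for name, length in config.contigs:
            starts = np.arange(0, length, config.depth_chunk, dtype=np.int64)
            ends = np.minimum(starts + config.depth_chunk, length)
            depths = rng.poisson(config.mean_depth, size=len(starts))
            intervals[name] = (starts, ends, depths.astype(np.int64))
        tracks[sample] = DepthTrack(sample, intervals)
    return tracks


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth for recovery tests: frequencies, genotypes, sweeps."""

    samples: list[str]
    sample_population: dict[str, str]
    contigs: np.ndarray
    pos: np.ndarray
    ancestral: np.ndarray
    population_frequencies: dict[str, np.ndarray]
    true_gt: np.ndarray            # (n_sites, n_samples) int8, no errors
    sweep_regions: list[tuple[str, int, int]]

    def frequencies_for_sample(self, sample: str) -> np.ndarray:
        return self.population_frequencies[self.sample_population[sample]]

    def to_json(self, path) -> None:
        payload = {
            "samples": self.samples,
            "sample_population": self.sample_population,
            "contigs": [str(c) for c in self.contigs],
            "pos": self.pos.tolist(),
            "ancestral": np.round(self.ancestral, 6).tolist(),
            "population_frequencies": {
                k: np.round(v, 6).tolist()
                for k, v in self.population_frequencies.items()},
            "true_gt": self.true_gt.tolist(),
            "sweep_regions": [list(r) for r in self.sweep_regions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["samples"], d["sample_population"],
                   np.array(d["contigs"], dtype=object),
                   np.array(d["pos"], dtype=np.int64),
                   np.array(d["ancestral"]),
                   {k: np.array(v) for k, v in
                    d["population_frequencies"].items()},
                   np.array(d["true_gt"], dtype=np.int8),
                   [tuple(r) for r in d["sweep_regions"]])


_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ["C", "T"], "G": ["C", "T"],
                  "C": ["A", "G"], "T": ["A", "G"]}


def _alleles(n: int, config: SimulationConfig, rng):
    ref = rng.choice(_BASES, size=n)
    is_ti = rng.random(n) < config.ti_fraction
    pick = rng.integers(0, 2, size=n)
    alt = np.empty(n, dtype=object)
    for i in range(n):
        alt[i] = _TRANSITION[ref[i]] if is_ti[i] \
            else _TRANSVERSIONS[ref[i]][pick[i]]
    return ref, alt


def simulate_genotypes(freqs: FrequencyTable, config: SimulationConfig,
                       tracks: dict[str, DepthTrack] | None = None
                       ) -> tuple[VariantTable, SimulationTruth]:
    """Hardy-Weinberg genotypes with depth, quality and error noise.

    Sites where no emitted genotype is variant are dropped from the VCF table
    (as a variant caller would); the returned truth covers exactly the
    emitted sites.
    """
    rng = config._rng(2)
    if tracks is None:
        tracks = simulate_depth_tracks(config)
    samples = config.samples
    sample_pop = config.sample_population
    n_sites = freqs.n_sites
    n_samples = len(samples)

    true_gt = np.empty((n_sites, n_samples), dtype=np.int8)
    for j, sample in enumerate(samples):
        q = freqs.populations[sample_pop[sample]]
        true_gt[:, j] = rng.binomial(2, q).astype(np.int8)

    # observation: depth, errors, genotype quality
    dp = np.empty((n_sites, n_samples), dtype=np.int32)
    for j, sample in enumerate(samples):
        track = tracks[sample]
        col = np.empty(n_sites, dtype=np.int64)
        for contig in dict.fromkeys(freqs.contigs):
            at = freqs.contigs == contig
            col[at] = depth_at(track, contig, freqs.pos[at] - 1)
        dp[:, j] = col

    obs_gt = true_gt.copy()
    err = rng.random((n_sites, n_samples)) < config.genotype_error_rate
    coin = rng.integers(0, 2, size=(n_sites, n_samples)).astype(np.int8)
    flipped = np.where(obs_gt == HET, np.where(coin == 0, HOM_REF, HOM_NONREF),
                       HET).astype(np.int8)
    obs_gt[err] = flipped[err]

    gq = np.minimum(99, config.gq_correct_base
                    + config.gq_correct_slope * dp).astype(np.int32)
    err_gq = np.rint(rng.exponential(config.gq_error_scale,
                                     size=(n_sites, n_samples)))
    gq[err] = np.minimum(99, err_gq[err]).astype(np.int32)

    missing = dp == 0
    obs_gt[missing] = MISSING
    gq[missing] = -1
    dp_obs = dp.copy()
    dp_obs[missing] = -1

    emitted = np.any((obs_gt == HET) | (obs_gt == HOM_NONREF), axis=1)
    ref, alt = _alleles(int(np.sum(emitted)), config, rng)
    table = VariantTable(
        samples=list(samples),
        contigs=freqs.contigs[emitted], pos=freqs.pos[emitted],
        ref=ref, alt=alt,
        gt=obs_gt[emitted], gq=gq[emitted], dp=dp_obs[emitted],
        contig_lengths=dict(config.contigs),
    )
    truth = SimulationTruth(
        samples=list(samples), sample_population=dict(sample_pop),
        contigs=freqs.contigs[emitted], pos=freqs.pos[emitted],
        ancestral=freqs.ancestral[emitted],
        population_frequencies={k: v[emitted]
                                for k, v in freqs.populations.items()},
        true_gt=true_gt[emitted], sweep_regions=list(config.sweep_regions),
    )
    return table, truth


# ---------------------------------------------------------------------------
# analytic expectations under the observation model
# ---------------------------------------------------------------------------

def gq_error_pass_probability(config: SimulationConfig,
                              min_gq: int = 20) -> float:
    """P(an erroneous call's rounded exponential GQ >= min_gq)."""
    return math.exp(-(min_gq - 0.5) / config.gq_error_scale)


def _observed_het_probability(q: np.ndarray,
                              config: SimulationConfig) -> np.ndarray:
    """P(emitted genotype is a GQ-passing het) per site, given alt freq q."""
    h = 2 * q * (1 - q)
    e = config.genotype_error_rate
    return h * (1 - e) + (1 - h) * e * gq_error_pass_probability(config)


def _emission_probability(truth: SimulationTruth,
                          config: SimulationConfig) -> np.ndarray:
    """P(a site enters the VCF) — some individual shows a non-missing
    variant genotype.  Sites are emitted conditionally, so expectations for
    one individual at emitted sites must be divided by this probability."""
    p0 = math.exp(-config.mean_depth)  # P(zero depth -> no call)
    e = config.genotype_error_rate
    counts: dict[str, int] = {}
    for pop in truth.sample_population.values():
        counts[pop] = counts.get(pop, 0) + 1
    none_variant = np.ones(len(truth.pos))
    for pop, n in counts.items():
        q = truth.population_frequencies[pop]
        # hom_ref stays non-variant unless flipped to het (prob e); a true
        # het flipped to hom_ref (prob e/2) becomes non-variant
        not_var = (1 - q) ** 2 * (1 - e) + 2 * q * (1 - q) * (e / 2)
        none_variant *= (p0 + (1 - p0) * not_var) ** n
    return 1.0 - none_variant


def expected_het_estimate(truth: SimulationTruth, sample: str,
                          track: DepthTrack, config: SimulationConfig,
                          lo: int = 5, hi: int = 10) -> tuple[float, float]:
    """Analytic (expected het/kb, standard error) for one individual.

    The expectation conditions on the realised depth track and on site
    emission: it sums, over truth sites whose position depth is in
    [lo, hi], the per-site probability of observing a passing heterozygote
    given that the site entered the VCF, divided by the realised covered
    bases.  The SE is the binomial sum sqrt(sum p(1-p)) on the same scale.
    """
    from .io_formats import covered_bases

    q = truth.frequencies_for_sample(sample)
    in_band = np.zeros(len(truth.pos), dtype=bool)
    for contig in dict.fromkeys(truth.contigs):
        at = truth.contigs == contig
        d = depth_at(track, contig, truth.pos[at] - 1)
        in_band[at] = (d >= lo) & (d <= hi)
    p = _observed_het_probability(q[in_band], config)
    p = np.minimum(1.0, p / _emission_probability(truth, config)[in_band])
    denom = covered_bases(track, lo, hi)
    expected = 1000.0 * float(np.sum(p)) / denom
    se = 1000.0 * math.sqrt(float(np.sum(p * (1 - p)))) / denom
    return expected, se


def expected_fdr(truth: SimulationTruth, sample: str, track: DepthTrack,
                 regions, config: SimulationConfig,
                 dp_lo: int = 3, dp_hi: int = 15, denom_lo: int = 1,
                 denom_hi: int = 25) -> tuple[float, float]:
    """Analytic (expected false-het rate, SE) over IBD-homozygous regions.

    Uses the sample's true population frequencies inside the regions (zero
    for domesticated samples in sweep regions, so every observed het there
    is an error), the error rate, the erroneous-GQ survival probability and
    the realised depth track.
    """
    from .io_formats import covered_bases

    pos0 = truth.pos - 1
    in_regions = np.zeros(len(truth.pos), dtype=bool)
    for contig, start, end in regions:
        in_regions |= (truth.contigs == contig) & (pos0 >= start) \
            & (pos0 < end)
    q = truth.frequencies_for_sample(sample)
    in_band = np.zeros(len(truth.pos), dtype=bool)
    for contig in dict.fromkeys(truth.contigs):
        at = truth.contigs == contig
        d = depth_at(track, contig, truth.pos[at] - 1)
        in_band[at] = (d >= dp_lo) & (d <= dp_hi)
    use = in_regions & in_band
    p = _observed_het_probability(q[use], config)
    p = np.minimum(1.0, p / _emission_probability(truth, config)[use])
    denom = sum(covered_bases(track, denom_lo, denom_hi, region=(c, s, e))
                for c, s, e in regions)
    if denom == 0:
        return float("nan"), float("nan")
    lam = float(np.sum(p))
    return lam / denom, math.sqrt(lam) / denom


# ---------------------------------------------------------------------------
# reference sequence, gene models, bundle
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig, table: VariantTable
                       ) -> dict[str, str]:
    """Random reference sequences carrying the reference allele at each site."""
    rng = config._rng(3)
    seqs: dict[str, str] = {}
    for name, length in config.contigs:
        arr = rng.choice(_BASES, size=length)
        at = table.contigs == name
        arr[table.pos[at] - 1] = table.ref[at]
        seqs[name] = "".join(arr.tolist())
    return seqs


def toy_gff_lines(contig: str, n_genes: int = 4,
                  gene_start: int = 10_000, spacing: int = 20_000) -> list[str]:
    """A small deterministic gene set: coding genes on both strands plus one
    non-coding RNA gene, with UTRs and two exons each."""
    lines = ["##gff-version 3"]
    start = gene_start
    for g in range(n_genes):
        gid = f"gene{g + 1}"
        tid = f"tx{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        # exon1: [start, start+400); exon2: [start+1000, start+1400)
        e1s, e1e = start, start + 400
        e2s, e2e = start + 1000, start + 1400
        # CDS: last 300 of exon1 + first 300 of exon2 (600 bp, divisible by 3)
        c1s, c1e = e1s + 100, e1e
        c2s, c2e = e2s, e2s + 300
        lines.append(f"{contig}\tsim\tgene\t{e1s + 1}\t{e2e}\t.\t{strand}\t.\t"
                     f"ID={gid}")
        lines.append(f"{contig}\tsim\tmRNA\t{e1s + 1}\t{e2e}\t.\t{strand}\t.\t"
                     f"ID={tid};Parent={gid}")
        for s, e in ((e1s, e1e), (e2s, e2e)):
            lines.append(f"{contig}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                         f"Parent={tid}")
        # both CDS segments are 300 bp, so every phase is 0 on either strand
        lines.append(f"{contig}\tsim\tCDS\t{c1s + 1}\t{c1e}\t.\t{strand}\t0\t"
                     f"Parent={tid}")
        lines.append(f"{contig}\tsim\tCDS\t{c2s + 1}\t{c2e}\t.\t{strand}\t0\t"
                     f"Parent={tid}")
        start += spacing
    # one non-coding gene
    s = start
    lines.append(f"{contig}\tsim\tgene\t{s + 1}\t{s + 800}\t.\t+\t.\tID=ncgene")
    lines.append(f"{contig}\tsim\tncRNA\t{s + 1}\t{s + 800}\t.\t+\t.\t"
                 f"ID=nctx;Parent=ncgene")
    lines.append(f"{contig}\tsim\texon\t{s + 1}\t{s + 800}\t.\t+\t.\tParent=nctx")
    return lines


def emit_fixture_bundle(config: SimulationConfig, outdir,
                        include_fasta: bool = True) -> dict[str, object]:
    """Simulate and write a complete on-disk fixture bundle.

    Writes the multi-sample VCF, per-sample depth BEDs, the population map,
    the ground-truth JSON and (optionally) the reference FASTA and a small
    GFF3 gene set.  Returns the paths plus the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freqs = simulate_frequencies(config)
    tracks = simulate_depth_tracks(config)
    table, truth = simulate_genotypes(freqs, config, tracks)

    paths: dict[str, object] = {}
    vcf_path = outdir / "sim.vcf"
    write_vcf(vcf_path, table)
    paths["vcf"] = vcf_path

    depth_dir = outdir / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sample, track in tracks.items():
        write_depth_track(depth_dir / f"{sample}.bed", track)
    paths["depth_dir"] = depth_dir

    popmap_path = outdir / "popmap.tsv"
    write_population_map(popmap_path, config.population_map())
    paths["popmap"] = popmap_path

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path

    if include_fasta:
        fasta_path = outdir / "reference.fa"
        write_fasta(fasta_path, simulate_reference(config, table))
        paths["fasta"] = fasta_path
        gff_path = outdir / "genes.gff3"
        with open(gff_path, "w") as fh:
            fh.write("\n".join(toy_gff_lines(config.contigs[0][0])) + "\n")
        paths["gff"] = gff_path

    paths["table"] = table
    paths["truth_obj"] = truth
    paths["tracks"] = tracks
    return paths
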