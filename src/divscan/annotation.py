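"""Gene-model-based functional annotation of SNPs.

Each SNP is placed relative to the gene models (exonic, splice site, 5'/3'
UTR, intronic, upstream/downstream within a flank, ncRNA, intergenic) and,
when it falls in protein-coding sequence, its codon-level effect is derived
by mutating the codon in the reference CDS and translating with the standard
genetic code (synonymous, nonsynonymous, stop gain, stop loss, with the
amino-acid change).

When a site touches several transcripts the reported category is the highest
by precedence (exonic > splice_site > UTR > ncRNA > intronic >
upstream/downstream > intergenic); a multi-label mode emits every
per-transcript category instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1000   # upstream/downstream window, bp
DEFAULT_SPLICE = 2     # splice donor/acceptor window into the intron, bp

LOCATION_PRECEDENCE = ["exonic", "splice_site", "5'UTR", "3'UTR", "ncRNA",
                       "intronic", "upstream", "downstream", "intergenic"]
_RANK = {loc: i for i, loc in enumerate(LOCATION_PRECEDENCE)}


@dataclass
class GeneModel:
    """One transcript's structure: sorted 0-based half-open interval lists."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str                       # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.transcript_id}: overlapping {name}")
            setattr(self, name, ivs)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def annotatable(self) -> bool:
        """Coding transcripts must have a CDS length divisible by 3."""
        return self.is_coding and self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def derive_utrs(self) -> None:
        """Fill UTRs as exon minus CDS, split 5'/3' by strand."""
        if not self.is_coding or self.utr5 or self.utr3:
            return
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        before, after = [], []
        for s, e in self.exons:
            if s < cds_lo:
                before.append((s, min(e, cds_lo)))
            if e > cds_hi:
                after.append((max(s, cds_hi), e))
        if self.strand == "+":
            self.utr5, self.utr3 = before, after
        else:
            self.utr5, self.utr3 = after, before


def load_gene_models(path) -> list[GeneModel]:
    """Parse a GFF3/GTF file into transcript-level :class:`GeneModel` records."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    transcript_types = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "miRNA",
                        "rRNA", "tRNA", "snoRNA", "snRNA"}
    models: list[GeneModel] = []
    seen_transcripts = set()
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        transcripts = [f for f in db.children(gene, level=1)
                       if f.featuretype in transcript_types]
        if not transcripts:
            transcripts = [gene]  # exons annotated directly on the gene
        for tr in transcripts:
            seen_transcripts.add(tr.id)
            exons = [(f.start - 1, f.end) for f in db.children(tr, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
            utr5 = [(f.start - 1, f.end)
                    for f in db.children(tr, featuretype="five_prime_UTR")]
            utr3 = [(f.start - 1, f.end)
                    for f in db.children(tr, featuretype="three_prime_UTR")]
            if not exons:
                exons = cds or [(tr.start - 1, tr.end)]
            model = GeneModel(gene_id, tr.id, tr.seqid, tr.strand,
                              exons, cds, utr5, utr3)
            model.derive_utrs()
            if model.is_coding and not model.annotatable:
                logger.warning("transcript %s: CDS length %d not divisible "
                               "by 3; coding effects skipped",
                               tr.id, model.cds_length)
            models.append(model)
    return models


def _in_any(pos0: int, intervals) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def _transcript_location(pos0: int, m: GeneModel, flank: int,
                         splice: int) -> str | None:
    """Category of a 0-based position relative to one transcript, or None."""
    lo, hi = m.span
    if lo <= pos0 < hi:
        if not m.is_coding:
            return "ncRNA"
        if _in_any(pos0, m.cds):
            return "exonic"
        # splice window: within `splice` bp inside an intron, next to an exon
        for (s1, e1), (s2, _) in zip(m.exons, m.exons[1:]):
            if e1 <= pos0 < min(e1 + splice, s2) or \
               max(s2 - splice, e1) <= pos0 < s2:
                return "splice_site"
        if _in_any(pos0, m.utr5):
            return "5'UTR"
        if _in_any(pos0, m.utr3):
            return "3'UTR"
        if _in_any(pos0, m.exons):
            # exon base outside CDS/UTR bookkeeping (non-coding exon of a
            # coding transcript) -- treat as exonic
            return "exonic"
        return "intronic"
    if lo - flank <= pos0 < lo:
        return "upstream" if m.strand == "+" else "downstream"
    if hi <= pos0 < hi + flank:
        return "downstream" if m.strand == "+" else "upstream"
    return None


def classify_location(contig: str, pos: int, gene_models: list[GeneModel],
                      flank: int = DEFAULT_FLANK,
                      splice: int = DEFAULT_SPLICE) -> str:
    """Highest-precedence location of a 1-based position across transcripts."""
    labels = transcript_locations(contig, pos, gene_models, flank, splice)
    if not labels:
        return "intergenic"
    return min((lab for lab, _ in labels), key=_RANK.__getitem__)


def transcript_locations(contig: str, pos: int, gene_models: list[GeneModel],
                         flank: int = DEFAULT_FLANK,
                         splice: int = DEFAULT_SPLICE
                         ) -> list[tuple[str, GeneModel]]:
    """All (location, transcript) labels of a 1-based position."""
    pos0 = pos - 1
    out = []
    for m in gene_models:
        if m.contig != contig:
            continue
        loc = _transcript_location(pos0, m, flank, splice)
        if loc is not None:
            out.append((loc, m))
    return out


def cds_offset(pos0: int, m: GeneModel) -> int | None:
    """Offset of a genomic position within the transcript's spliced CDS
    (5'->3' in coding orientation), or None if outside the CDS."""
    total = 0
    plus_offset = None
    for s, e in m.cds:
        if s <= pos0 < e:
            plus_offset = total + (pos0 - s)
        total += e - s
    if plus_offset is None:
        return None
    return plus_offset if m.strand == "+" else total - 1 - plus_offset


def coding_effect(contig: str, pos: int, ref_allele: str, alt_allele: str,
                  transcript: GeneModel, fasta) -> tuple[str, str]:
    """Codon-level effect of a SNP inside a transcript's CDS.

    Returns ``(effect, aa_change)`` where effect is one of nonsynonymous /
    synonymous / stopgain / stoploss and aa_change is like ``"K12*"``
    (reference amino acid, 1-based codon index, alternate amino acid).
    """
    if not transcript.annotatable:
        raise ValueError(f"transcript {transcript.transcript_id} has CDS "
                         "length not divisible by 3")
    pos0 = pos - 1
    off = cds_offset(pos0, transcript)
    if off is None:
        raise ValueError("position is not inside the transcript CDS")
    cds_seq = "".join(str(fasta[contig][s:e]) for s, e in transcript.cds)
    genome_base = str(fasta[contig][pos0]).upper()
    if genome_base != ref_allele.upper():
        logger.warning("%s:%d reference base %s differs from site ref %s",
                       contig, pos, genome_base, ref_allele)
    if transcript.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        base_ref = str(Seq(ref_allele).reverse_complement())
        base_alt = str(Seq(alt_allele).reverse_complement())
    else:
        base_ref, base_alt = ref_allele.upper(), alt_allele.upper()
    codon_idx = off // 3
    within = off % 3
    codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
    mutated = codon[:within] + base_alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_ref != "*" and aa_alt == "*":
        effect = "stopgain"
    elif aa_ref == "*" and aa_alt != "*":
        effect = "stoploss"
    else:
        effect = "nonsynonymous"
    return effect, f"{aa_ref}{codon_idx + 1}{aa_alt}"


@dataclass(frozen=True)
class AnnotationResult:
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    location: str
    effect: str = "none"          # != "none" only for exonic CDS sites
    aa_change: str | None = None
    gene_id: str | None = None
    transcript_id: str | None = None


def annotate_site(contig: str, pos: int, ref_allele: str, alt_allele: str,
                  gene_models: list[GeneModel], fasta,
                  flank: int = DEFAULT_FLANK,
                  splice: int = DEFAULT_SPLICE) -> AnnotationResult:
    """Single-category annotation of one SNP (highest precedence wins)."""
    labels = transcript_locations(contig, pos, gene_models, flank, splice)
    if not labels:
        return AnnotationResult(contig, pos, ref_allele, alt_allele,
                                "intergenic")
    loc, model = min(labels, key=lambda lm: _RANK[lm[0]])
    effect, aa = "none", None
    if loc == "exonic" and model.annotatable \
            and cds_offset(pos - 1, model) is not None:
        effect, aa = coding_effect(contig, pos, ref_allele, alt_allele,
                                   model, fasta)
    return AnnotationResult(contig, pos, ref_allele, alt_allele, loc,
                            effect, aa, model.gene_id, model.transcript_id)


def annotate_all(sites, gene_models: list[GeneModel], fasta,
                 segregating: np.ndarray | None = None,
                 flank: int = DEFAULT_FLANK, splice: int = DEFAULT_SPLICE,
                 multi_label: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate (contig, pos, ref, alt) records; tally category counts.

    ``sites`` is an iterable of (contig, pos, ref, alt) tuples or a
    :class:`~divscan.io_formats.VariantTable`.  ``segregating`` is an optional
    boolean vector marking sites segregating in at least one population; the
    summary then reports both total and segregating tallies.  In multi-label
    mode every per-transcript (location, effect) pair is tallied, so one site
    may contribute to several rows.
    """
    from .io_formats import VariantTable

    if isinstance(sites, VariantTable):
        records = list(zip(sites.contigs, sites.pos, sites.ref, sites.alt))
    else:
        records = [(c, int(p), r, a) for c, p, r, a in sites]
    seg = (np.zeros(len(records), dtype=bool) if segregating is None
           else np.asarray(segregating, dtype=bool))

    rows = []
    for i, (contig, pos, ref, alt) in enumerate(records):
        if multi_label:
            labels = transcript_locations(contig, pos, gene_models,
                                          flank, splice)
            if not labels:
                labels = [("intergenic", None)]
            for loc, model in labels:
                effect, aa = "none", None
                if (loc == "exonic" and model is not None and model.annotatable
                        and cds_offset(pos - 1, model) is not None):
                    effect, aa = coding_effect(contig, pos, ref, alt, model,
                                               fasta)
                rows.append({"contig": contig, "pos": pos, "ref": ref,
                             "alt": alt, "location": loc, "effect": effect,
                             "aa_change": aa, "segregating": bool(seg[i]),
                             "gene_id": getattr(model, "gene_id", None),
                             "transcript_id": getattr(model, "transcript_id",
                                                      None)})
        else:
            r = annotate_site(contig, pos, ref, alt, gene_models, fasta,
                              flank, splice)
            rows.append({"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                         "location": r.location, "effect": r.effect,
                         "aa_change": r.aa_change, "segregating": bool(seg[i]),
                         "gene_id": r.gene_id,
                         "transcript_id": r.transcript_id})
    results = pd.DataFrame(rows)
    summary = summarize_categories(results)
    return results, summary


def summarize_categories(results: pd.DataFrame) -> pd.DataFrame:
    """Tally locations and coding effects for all and segregating sites."""
    rows = []
    for name, sub in (("location", results.groupby("location")),
                      ("effect", results[results["effect"] != "none"]
                       .groupby("effect"))):
        for cat, grp in sub:
            rows.append({"kind": name, "category": cat,
                         "total": len(grp),
                         "segregating": int(grp["segregating"].sum())})
    return pd.DataFrame(rows)
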