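"""Gene-based SNP annotation: placement precedence and codon effects."""

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from divscan import annotation as ann

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _aa(codon: str) -> str:
    return "*" if codon in standard_dna_table.stop_codons \
        else standard_dna_table.forward_table[codon]


@pytest.fixture(scope="module")
def toy_models():
    """Hand-placed transcripts on a 20 kb contig (0-based half-open)."""
    gene_p = ann.GeneModel("gP", "txP", "c", "+",
                           exons=[(1100, 1200), (1300, 1420)],
                           cds=[(1130, 1200), (1300, 1362)])
    gene_p.derive_utrs()
    gene_m = ann.GeneModel("gM", "txM", "c", "-",
                           exons=[(5000, 5100), (5200, 5300)],
                           cds=[(5030, 5100), (5200, 5262)])
    gene_m.derive_utrs()
    nc = ann.GeneModel("gN", "txN", "c", "+", exons=[(9000, 9400)])
    return [gene_p, gene_m, nc]


@pytest.fixture(scope="module")
def toy_fasta(rng_module):
    seq = "".join(rng_module.choice(list("ACGT"), size=20_000))
    return {"c": seq}


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(20260925)


class TestLocationPrecedence:
    # positions are 1-based; the toy intervals above are 0-based half-open
    @pytest.mark.parametrize("pos0,expected", [
        (1150, "exonic"),          # inside CDS of exon 1
        (1200, "splice_site"),     # first intron base after the donor
        (1201, "splice_site"),     # second intron base (window = 2)
        (1202, "intronic"),
        (1298, "splice_site"),     # acceptor side
        (1250, "intronic"),
        (1110, "5'UTR"),
        (1400, "3'UTR"),
        (101, "upstream"),         # 999 bp 5' of the + strand gene start
        (1425, "downstream"),
        (5305, "upstream"),        # 3' in genome = 5' of the - strand gene
        (4995, "downstream"),
        (5270, "5'UTR"),           # high-coordinate UTR of a - strand gene
        (5010, "3'UTR"),           # low-coordinate UTR of a - strand gene
        (9100, "ncRNA"),
        (7000, "intergenic"),
    ])
    def test_category(self, toy_models, pos0, expected):
        assert ann.classify_location("c", pos0 + 1, toy_models) == expected

    def test_other_contig_is_intergenic(self, toy_models):
        assert ann.classify_location("other", 1150, toy_models) == "intergenic"

    def test_flank_boundary(self, toy_models):
        # exactly 1000 bp away falls outside the default flank
        assert ann.classify_location("c", 100 + 1, toy_models) == "upstream"
        assert ann.classify_location("c", 99 + 1, toy_models) == "intergenic"


class TestCodingEffect:
    @pytest.mark.parametrize("codon,alt_base,within,expected", [
        ("GGA", "G", 2, "synonymous"),     # GGA->GGG, Gly->Gly wobble
        ("TAC", "A", 2, "stopgain"),       # TAC->TAA
        ("TGA", "C", 2, "stoploss"),       # TGA->TGC
        ("AAA", "G", 0, "nonsynonymous"),  # AAA->GAA, Lys->Glu
    ])
    def test_known_codon_changes(self, codon, alt_base, within, expected):
        model = ann.GeneModel("g", "t", "c", "+", exons=[(0, 3)],
                              cds=[(0, 3)])
        fasta = {"c": codon}
        pos = within + 1
        effect, aa = ann.coding_effect("c", pos, codon[within], alt_base,
                                       model, fasta)
        assert effect == expected
        assert aa[0] == _aa(codon)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_possible_snp_matches_codon_table_oracle(
            self, strand, toy_fasta):
        """Exhaustive enumeration over a 30-codon single-exon gene."""
        start, end = (12_000, 12_090)
        model = ann.GeneModel("g", "t", "c", strand,
                              exons=[(start, end)], cds=[(start, end)])
        genome = toy_fasta["c"]
        cds = genome[start:end] if strand == "+" \
            else _revcomp(genome[start:end])
        for pos0 in range(start, end):
            ref = genome[pos0]
            off = (pos0 - start) if strand == "+" else (end - 1 - pos0)
            for alt in "ACGT":
                if alt == ref:
                    continue
                effect, aa_change = ann.coding_effect(
                    "c", pos0 + 1, ref, alt, model, toy_fasta)
                # independent oracle: substitute in the coding-strand CDS
                alt_c = alt if strand == "+" else alt.translate(_COMP)
                codon_i = off // 3
                codon = cds[codon_i * 3: codon_i * 3 + 3]
                mutated = (codon[:off % 3] + alt_c + codon[off % 3 + 1:])
                ref_aa, alt_aa = _aa(codon), _aa(mutated)
                if ref_aa == alt_aa:
                    expected = "synonymous"
                elif ref_aa != "*" and alt_aa == "*":
                    expected = "stopgain"
                elif ref_aa == "*" and alt_aa != "*":
                    expected = "stoploss"
                else:
                    expected = "nonsynonymous"
                assert effect == expected, (strand, pos0, alt)
                assert aa_change == f"{ref_aa}{codon_i + 1}{alt_aa}"

    def test_strand_mirror_symmetry(self, toy_fasta):
        """A gene and its reverse-complement mirror give mirrored effects."""
        genome = toy_fasta["c"]
        L = len(genome)
        mirror = {"c": _revcomp(genome)}
        fwd = ann.GeneModel("g", "t", "c", "+", exons=[(12_000, 12_090)],
                            cds=[(12_000, 12_090)])
        rev = ann.GeneModel("g", "t", "c", "-",
                            exons=[(L - 12_090, L - 12_000)],
                            cds=[(L - 12_090, L - 12_000)])
        for pos0 in (12_000, 12_043, 12_089):
            ref = genome[pos0]
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
            e1 = ann.coding_effect("c", pos0 + 1, ref, alt, fwd, toy_fasta)
            m0 = L - 1 - pos0
            e2 = ann.coding_effect("c", m0 + 1, ref.translate(_COMP),
                                   alt.translate(_COMP), rev, mirror)
            assert e1 == e2

    def test_non_triplet_cds_is_rejected(self):
        model = ann.GeneModel("g", "t", "c", "+", exons=[(0, 4)],
                              cds=[(0, 4)])
        assert not model.annotatable
        with pytest.raises(ValueError, match="divisible"):
            ann.coding_effect("c", 1, "A", "G", model, {"c": "ACGTA"})


class TestAnnotateAll:
    def test_empty_gene_set_all_intergenic(self, toy_fasta):
        sites = [("c", 100, "A", "G"), ("c", 5000, "C", "T")]
        results, summary = ann.annotate_all(sites, [], toy_fasta)
        assert set(results["location"]) == {"intergenic"}

    def test_category_tallies_sum_to_site_count(self, toy_models, toy_fasta):
        positions = [1151, 1201, 1111, 1401, 102, 9101, 7001, 5050, 5271,
                     1251]
        sites = [("c", p, toy_fasta["c"][p - 1],
                  "A" if toy_fasta["c"][p - 1] != "A" else "G")
                 for p in positions]
        results, summary = ann.annotate_all(sites, toy_models, toy_fasta)
        loc = summary[summary["kind"] == "location"]
        assert loc["total"].sum() == len(sites)

    def test_segregating_subset_never_exceeds_total(self, toy_models,
                                                    toy_fasta, rng_module):
        positions = list(range(1000, 10_000, 250))
        sites = [("c", p, toy_fasta["c"][p - 1],
                  "A" if toy_fasta["c"][p - 1] != "A" else "G")
                 for p in positions]
        seg = rng_module.random(len(sites)) < 0.5
        _, summary = ann.annotate_all(sites, toy_models, toy_fasta,
                                      segregating=seg)
        assert (summary["segregating"] <= summary["total"]).all()

    def test_multi_label_emits_per_transcript_rows(self, toy_fasta):
        # two overlapping transcripts: one coding, one non-coding
        coding = ann.GeneModel("g1", "t1", "c", "+", exons=[(1000, 1090)],
                               cds=[(1000, 1090)])
        nc = ann.GeneModel("g2", "t2", "c", "+", exons=[(900, 1200)])
        site = [("c", 1001, toy_fasta["c"][1000],
                 "A" if toy_fasta["c"][1000] != "A" else "G")]
        single, _ = ann.annotate_all(site, [coding, nc], toy_fasta)
        multi, _ = ann.annotate_all(site, [coding, nc], toy_fasta,
                                    multi_label=True)
        assert list(single["location"]) == ["exonic"]
        assert sorted(multi["location"]) == ["exonic", "ncRNA"]

    def test_gff_loading_round_trip(self, tmp_path, toy_fasta):
        from divscan.synthetic_data import toy_gff_lines

        gff = tmp_path / "g.gff3"
        gff.write_text("\n".join(toy_gff_lines("c")) + "\n")
        models = ann.load_gene_models(gff)
        coding = [m for m in models if m.is_coding]
        assert len(coding) == 4
        assert all(m.annotatable for m in coding)
        assert any(not m.is_coding for m in models)
        m = coding[0]
        assert m.utr5 and m.utr3 and m.cds_length == 600
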