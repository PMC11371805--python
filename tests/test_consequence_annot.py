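"""Consequence classification, aberrant isoform enumeration, translation,
and domain-loss reporting on hand-built and generated fixture genes."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cosegmap.consequence_annot import (
    Domain,
    DomainTable,
    GeneModel,
    classify_coding_variant,
    enumerate_aberrant_isoforms,
    load_domain_table,
    report_truncation,
    translate_isoform,
)
from cosegmap.coseg_classifier import VariantSite
from cosegmap.errors import ValidationError
from cosegmap.synthetic_genes import build_pmel_like_gene, reverse_complement_fixture


def snv(scaffold, pos, ref, alt):
    return VariantSite(scaffold, pos, ref, alt, None, [], None, None)


# ---------------------------------------------------------------------------
# hand-built mini gene: 2 exons + intron, fully explicit sequences
# ---------------------------------------------------------------------------
# exon1 CDS: ATG AAA CCC  | intron: GT AAAC AG | exon2 CDS: GGG TTT TAA
MINI_SEQ = "TTTT" + "ATGAAACCC" + "GTAAACAG" + "GGGTTTTAA" + "TTTT"
MINI = GeneModel(
    gene_id="mini",
    transcript_id="mini_t",
    scaffold="m",
    strand="+",
    exons=[(4, 13), (21, 30)],
    cds=[(4, 13), (21, 30)],
)
MINI_GENOME = {"m": MINI_SEQ}


class TestMiniGene:
    def test_reference_round_trip(self):
        assert MINI.cds_seq(MINI_GENOME) == "ATGAAACCCGGGTTTTAA"
        assert MINI.reference_protein(MINI_GENOME) == "MKPGF"

    def test_synonymous_third_position(self):
        # AAA -> AAG, both lysine
        call = classify_coding_variant(MINI, snv("m", 9, "A", "G"), MINI_GENOME)
        assert call.category == "synonymous"

    def test_missense(self):
        # CCC -> CAC : P3H
        call = classify_coding_variant(MINI, snv("m", 11, "C", "A"), MINI_GENOME)
        assert call.category == "missense"
        assert call.aa_change == "P3H"

    def test_nonsense(self):
        # GGG -> TGA-making change? exon2 GGG TTT: G->T at first base of GGG
        # gives TGG (Trp), so mutate TTT -> TAA-like: TTT at codon5, T->A mid
        call = classify_coding_variant(MINI, snv("m", 25, "T", "A"), MINI_GENOME)
        # TTT -> TAT is missense; build a true stop: GGG -> TAG needs MNP
        assert call.category == "missense"
        call2 = classify_coding_variant(MINI, snv("m", 21, "GGG", "TAG"), MINI_GENOME)
        assert call2.category == "nonsense"
        assert call2.aa_change == "G4*"

    def test_intronic_and_intergenic_and_utr(self):
        assert classify_coding_variant(MINI, snv("m", 16, "A", "C"), MINI_GENOME).category == "intronic"
        assert (
            classify_coding_variant(MINI, snv("m", 1, "T", "C"), MINI_GENOME, flank=0).category
            == "intergenic"
        )

    def test_donor_disruption(self):
        call = classify_coding_variant(MINI, snv("m", 13, "G", "C"), MINI_GENOME)
        assert call.category == "splice_donor"

    def test_acceptor_disruption(self):
        call = classify_coding_variant(MINI, snv("m", 20, "G", "T"), MINI_GENOME)
        assert call.category == "splice_acceptor"

    def test_donor_overlap_without_change_is_not_splice(self):
        # MNP spanning exon end + donor GT but leaving the GT intact: the
        # only real change is exonic (CCC->CCA, synonymous)
        call = classify_coding_variant(MINI, snv("m", 12, "CGT", "AGT"), MINI_GENOME)
        assert call.category == "synonymous"

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValidationError, match="mismatch"):
            classify_coding_variant(MINI, snv("m", 9, "C", "G"), MINI_GENOME)

    def test_frameshift_and_inframe_indels(self):
        ins1 = VariantSite("m", 9, "A", "AT", None, [], None, None)
        assert classify_coding_variant(MINI, ins1, MINI_GENOME).category == "frameshift_indel"
        del3 = VariantSite("m", 8, "AACC", "A", None, [], None, None)
        assert classify_coding_variant(MINI, del3, MINI_GENOME).category == "inframe_indel"


def test_random_snvs_agree_with_naive_retranslation_oracle(pmel_gene, rng):
    """500 random coding SNVs: category matches a from-scratch oracle that
    rebuilds the mutant CDS by string surgery and translates it."""
    gene = pmel_gene
    model, genome = gene.model, gene.genome
    seq = genome[model.scaffold]
    cds_positions = np.concatenate([np.arange(s, e) for s, e in model.cds])
    # avoid the two splice-site bases flanking each intron
    splice = set()
    for i in range(model.n_exons - 1):
        for r in (model.donor_region(i), model.acceptor_region(i)):
            splice.update(range(*r))
    candidates = np.array([p for p in cds_positions if p not in splice])
    picks = rng.choice(candidates, size=500, replace=True)
    for pos in picks:
        pos = int(pos)
        ref = seq[pos]
        alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        call = classify_coding_variant(model, snv(model.scaffold, pos, ref, alt), genome)
        # oracle: splice mutant genome string, slice CDS, translate with Bio
        mutant = seq[:pos] + alt + seq[pos + 1 :]
        ref_cds = "".join(seq[s:e] for s, e in model.cds)
        alt_cds = "".join(mutant[s:e] for s, e in model.cds)
        ref_prot = str(Seq(ref_cds).translate()).split("*")[0]
        alt_prot = str(Seq(alt_cds).translate()).split("*")[0]
        if alt_prot == ref_prot:
            expected = "synonymous"
        elif len(alt_prot) < len(ref_prot):
            expected = "nonsense"
        else:
            expected = "missense"
        assert call.category == expected, (pos, ref, alt)


class TestAberrantIsoforms:
    def test_no_cryptic_gt_gives_only_exon_skip(self):
        seq = "TTTT" + "ATGAAACCC" + "GT" + "A" * 40 + "AG" + "GGGTTTTAA" + "TTTT"
        model = GeneModel("g", "t", "m", "+", [(4, 13), (57, 66)], [(4, 13), (57, 66)])
        isoforms = enumerate_aberrant_isoforms(model, 0, {"m": seq})
        assert [iso.kind for iso in isoforms] == ["exon_skip"]

    def test_cryptic_gt_offsets_match_retained_lengths(self, pmel_gene):
        isoforms = enumerate_aberrant_isoforms(
            pmel_gene.model, pmel_gene.disrupted_intron, pmel_gene.genome
        )
        retained = sorted(
            iso.retained_length for iso in isoforms if iso.kind == "intron_retention"
        )
        assert retained == [20, 233]

    def test_retained_blocks_end_immediately_before_a_gt(self, rng):
        """Exhaustive check over random introns."""
        for _ in range(20):
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=100)) + "AG"
            seq = "TT" + "ATGAAACCC" + intron + "GGGTTTTAA" + "TT"
            e2 = 11 + len(intron)
            model = GeneModel("g", "t", "m", "+", [(2, 11), (e2, e2 + 9)], [(2, 11), (e2, e2 + 9)])
            genome = {"m": seq}
            for iso in enumerate_aberrant_isoforms(model, 0, genome):
                if iso.kind != "intron_retention":
                    continue
                k = iso.retained_length
                assert intron[k : k + 2] == "GT"
                assert k >= 1

    def test_intron_index_out_of_range(self, pmel_gene):
        with pytest.raises(ValidationError):
            enumerate_aberrant_isoforms(pmel_gene.model, 99, pmel_gene.genome)


class TestTranslation:
    def test_reference_protein_length(self, pmel_gene):
        protein = pmel_gene.model.reference_protein(pmel_gene.genome)
        assert len(protein) == pmel_gene.model.cds_seq(pmel_gene.genome).__len__() // 3 - 1
        assert len(protein) == 713

    def test_exon_skip_frameshifts_to_478(self, pmel_gene):
        isoforms = enumerate_aberrant_isoforms(
            pmel_gene.model, pmel_gene.disrupted_intron, pmel_gene.genome
        )
        (skip,) = [i for i in isoforms if i.kind == "exon_skip"]
        tr = translate_isoform(skip, pmel_gene.model, pmel_gene.genome)
        assert len(tr.protein) == 478
        assert tr.truncated and not tr.runoff

    def test_retention_isoforms_share_the_in_frame_stop(self, pmel_gene):
        """Two retention isoforms with different retained lengths translate to
        the identical protein when the stop sits in the shared prefix."""
        isoforms = enumerate_aberrant_isoforms(
            pmel_gene.model, pmel_gene.disrupted_intron, pmel_gene.genome
        )
        retentions = [i for i in isoforms if i.kind == "intron_retention"]
        proteins = {
            iso.retained_length: translate_isoform(iso, pmel_gene.model, pmel_gene.genome).protein
            for iso in retentions
        }
        assert len(proteins[20]) == len(proteins[233]) == 532
        assert proteins[20] == proteins[233]

    def test_in_frame_exon_skip_is_internal_deletion_not_truncation(self):
        # exon2 is 6 nt (2 codons): skipping preserves frame and the C-terminus
        seq = "TT" + "ATGAAACCC" + "GTAAAAAG" + "AAATTT" + "GTCCCCAG" + "GGGTGA" + "TT"
        exons = [(2, 11), (19, 25), (33, 39)]
        model = GeneModel("g", "t", "m", "+", exons, exons)
        genome = {"m": seq}
        assert model.reference_protein(genome) == "MKPKFG"
        (skip, *_) = enumerate_aberrant_isoforms(model, 1, genome)
        assert skip.kind == "exon_skip" and skip.skipped_exon == 1
        tr = translate_isoform(skip, model, genome)
        assert tr.protein == "MKPG"
        assert not tr.truncated  # C-terminus intact: internal in-frame deletion

    def test_frame_arithmetic_of_retention_lengths(self):
        """Retained lengths congruent mod 3 with no stop in the differing
        region give proteins differing by exactly delta/3 residues."""
        # cryptic GTs at offsets 3 and 9 (delta 6, divisible by 3)
        intron = "GTA" + "GT" + "AACA" + "GT" + "A" * 20 + "AG"
        assert intron[3:5] == "GT" and intron[9:11] == "GT"
        seq = "TT" + "ATGAAACCC" + intron + "GGGTTTTAA" + "TT"
        e2 = 11 + len(intron)
        model = GeneModel("g", "t", "m", "+", [(2, 11), (e2, e2 + 9)], [(2, 11), (e2, e2 + 9)])
        genome = {"m": seq}
        retentions = {
            iso.retained_length: iso
            for iso in enumerate_aberrant_isoforms(model, 0, genome)
            if iso.kind == "intron_retention"
        }
        p3 = translate_isoform(retentions[3], model, genome).protein
        p9 = translate_isoform(retentions[9], model, genome).protein
        assert len(p9) - len(p3) == (9 - 3) // 3

    def test_start_lost_when_start_exon_is_skipped(self):
        seq = "TT" + "ATGAAA" + "GTAAAAAG" + "CCCGGGTAA" + "TT"
        exons = [(2, 8), (16, 25)]
        model = GeneModel("g", "t", "m", "+", exons, exons)
        (skip, *_) = enumerate_aberrant_isoforms(model, 0, {"m": seq})
        tr = translate_isoform(skip, model, {"m": seq})
        assert tr.start_lost and tr.protein == ""


def test_minus_strand_twin_produces_identical_proteins(pmel_gene):
    rc = reverse_complement_fixture(pmel_gene)
    ref_plus = pmel_gene.model.reference_protein(pmel_gene.genome)
    ref_minus = rc.model.reference_protein(rc.genome)
    assert ref_plus == ref_minus
    call = classify_coding_variant(rc.model, rc.variant, rc.genome)
    assert call.category == "splice_donor"
    for iso_p, iso_m in zip(
        enumerate_aberrant_isoforms(pmel_gene.model, 7, pmel_gene.genome),
        enumerate_aberrant_isoforms(rc.model, 7, rc.genome),
    ):
        assert iso_p.kind == iso_m.kind
        assert iso_p.retained_length == iso_m.retained_length
        assert (
            translate_isoform(iso_p, pmel_gene.model, pmel_gene.genome).protein
            == translate_isoform(iso_m, rc.model, rc.genome).protein
        )


class TestTruncationReport:
    def test_bundled_domain_table_and_532_aa_truncation(self):
        domains = load_domain_table()
        report = report_truncation("A" * 532, "A" * 713, domains)
        assert set(report.lost) == {"KLD", "TM", "cyto"}
        assert report.partial == ()
        assert {"IP", "CAF", "PKD", "RPT", "CS"} <= set(report.retained)

    def test_478_aa_truncation_cuts_through_rpt(self):
        report = report_truncation("A" * 478, "A" * 713, load_domain_table())
        assert set(report.lost) == {"CS", "KLD", "TM", "cyto"}
        assert report.partial == ("RPT",)

    def test_full_length_protein_loses_nothing(self):
        report = report_truncation("A" * 713, "A" * 713, load_domain_table())
        assert report.lost == () and report.partial == ()

    def test_random_truncations_match_brute_force(self, rng):
        domains = DomainTable([Domain(f"d{i}", int(s), int(s) + int(w))
                               for i, (s, w) in enumerate(zip(rng.integers(1, 700, 30),
                                                              rng.integers(0, 100, 30)))])
        for L in rng.integers(0, 800, 50):
            report = report_truncation("A" * int(L), "A" * 800, domains)
            for d in domains:
                if d.aa_start > L:
                    assert d.name in report.lost
                elif d.aa_end > L:
                    assert d.name in report.partial
                else:
                    assert d.name in report.retained


def test_annotated_isoform_lengths_differ_by_three(pmel_gene):
    long_len = pmel_gene.model.spliced_length()
    short_len = pmel_gene.model_short.spliced_length()
    assert (long_len, short_len) == (3135, 3132)
    assert long_len - short_len == 3
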