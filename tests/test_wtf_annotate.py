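"""Motif scanning, ATG-subtype calls, pseudogene lesions, identity and
LTR-deletion reconstruction on constructed sequences."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sporekit import synthetic_data as sd
from sporekit import wtf_annotate as wa


def _family(plans, seed=0, **kw):
    fam = sd.generate_wtf_family(plans, seed=seed, **kw)
    motifs = {
        "intron1_150bp": wa.MotifDefinition("intron1_150bp", fam.intron1_motif),
        "conserved_up": wa.MotifDefinition("conserved_up", fam.conserved_up,
                                           expected_context="upstream"),
    }
    structures = {n: wa.FamilyStructure(exon_lengths=s["exon_lengths"],
                                        cds_length=s["cds_length"])
                  for n, s in fam.consensus_structures.items()}
    return fam, motifs, structures


def _classify(fam, motifs, structures, gene):
    gm = wa.GeneModel(gene_id=gene.gene_id, exons=gene.exons,
                      cds_start=gene.cds_start)
    return wa.classify_gene(gm, gene.sequence, motifs,
                            wa.pick_consensus(structures, gm))


class TestScanMotif:
    def test_planted_exact_motif(self, rng):
        motif = "".join(rng.choice(list("ACGT"), 150))
        seq = ("".join(rng.choice(list("ACGT"), 400)) + motif +
               "".join(rng.choice(list("ACGT"), 300)))
        hits = wa.scan_motif(seq, wa.MotifDefinition("intron1_150bp", motif))
        assert len(hits) == 1
        assert hits[0].position == 401
        assert hits[0].identity == 1.0

    def test_mutated_motif_identity(self, rng):
        motif = "".join(rng.choice(list("ACGT"), 150))
        mutated = list(motif)
        for i in rng.choice(150, 15, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        seq = "X" * 0 + "".join(rng.choice(list("ACGT"), 200)) + \
            "".join(mutated) + "".join(rng.choice(list("ACGT"), 200))
        hits = wa.scan_motif(seq, wa.MotifDefinition("intron1_150bp", motif))
        assert hits and hits[0].identity == pytest.approx(0.9)

    def test_random_sequence_false_positive_rate(self):
        """Unrelated sequence of equal length never reaches 80% identity
        to a 150-bp consensus (identity concentrates near 25%)."""
        rng = np.random.default_rng(99)
        motif = "".join(rng.choice(list("ACGT"), 150))
        mdef = wa.MotifDefinition("intron1_150bp", motif)
        hits = 0
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 600))
            hits += bool(wa.scan_motif(seq, mdef))
        assert hits == 0


class TestLocateFirstInframeAtg:
    def _gene(self, planted, seed=1):
        fam, _, _ = _family([sd.SyntheticGenePlan(
            "g", has_intron1_motif=True, planted_atg=planted)], seed=seed)
        g = fam.genes[0]
        gm = wa.GeneModel(gene_id="g", exons=g.exons, cds_start=g.cds_start)
        return g, gm

    def test_intron1_atg_seven_bp_before_exon2(self):
        g, gm = self._gene(("intron1", 7))
        res = wa.locate_first_inframe_atg(gm, g.sequence,
                                          from_position=g.exons[0][1] + 1)
        assert res.location == "intron1"
        assert res.distance_to_exon2 == 7

    def test_exon2_atg(self):
        g, gm = self._gene(("exon2", 30))
        res = wa.locate_first_inframe_atg(gm, g.sequence,
                                          from_position=g.exons[0][1] + 1)
        assert res.location == "exon2"
        assert res.offset == 30

    def test_out_of_frame_atg_skipped(self):
        """An ATG planted out of frame upstream of the in-frame one must
        be passed over."""
        g, gm = self._gene(("exon2", 30), seed=2)
        seq = list(g.sequence)
        e2 = gm.exon2_start
        l1 = gm.exon1_cds_length()
        # place an out-of-frame ATG 20 bp before exon 2
        p0 = e2 - 20
        assert (e2 - p0) % 3 != l1 % 3
        seq[p0 - 1:p0 + 2] = list("ATG")
        res = wa.locate_first_inframe_atg(gm, "".join(seq),
                                          from_position=g.exons[0][1] + 1)
        assert res.location == "exon2" and res.offset == 30

    def test_beyond_exon2_rejected(self):
        g, gm = self._gene(("intron1", 7))
        with pytest.raises(ValueError, match="beyond"):
            wa.locate_first_inframe_atg(gm, g.sequence,
                                        from_position=gm.exon2_start + 10)

    def test_depth_limit_bounds_search(self):
        g, gm = self._gene(("exon2", 30))
        res = wa.locate_first_inframe_atg(gm, g.sequence,
                                          from_position=g.exons[0][1] + 1,
                                          exon2_depth_limit=10)
        assert res.location == "none"


class TestPseudogeneCalls:
    @pytest.mark.parametrize("lesion", ["lost_start", "premature_stop",
                                        "frameshift_indel",
                                        "segmental_deletion"])
    def test_planted_lesions_detected(self, lesion):
        fam, motifs, structures = _family(
            [sd.SyntheticGenePlan("g", planted_lesion=lesion)], seed=13)
        g = fam.genes[0]
        gm = wa.GeneModel(gene_id="g", exons=g.exons, cds_start=g.cds_start)
        lesions = wa.call_pseudogene(gm, g.sequence,
                                     wa.pick_consensus(structures, gm))
        assert lesion in {l.kind for l in lesions}

    def test_intact_gene_no_lesions(self):
        fam, _, structures = _family([sd.SyntheticGenePlan("g")], seed=14)
        g = fam.genes[0]
        gm = wa.GeneModel(gene_id="g", exons=g.exons, cds_start=g.cds_start)
        assert wa.call_pseudogene(gm, g.sequence, structures[5]) == []

    def test_single_base_deletion_frameshift_oracle(self):
        """Deleting one base from an intact gene's exon 3 must register as
        a frameshift (translate-and-check)."""
        fam, _, structures = _family([sd.SyntheticGenePlan("g")], seed=15)
        g = fam.genes[0]
        s3, e3 = g.exons[2]
        seq = g.sequence[:s3 + 10] + g.sequence[s3 + 11:]
        exons = [(s, e) if e <= s3 + 10 else
                 ((s, e - 1) if s <= s3 + 10 else (s - 1, e - 1))
                 for s, e in g.exons]
        gm = wa.GeneModel(gene_id="g", exons=exons, cds_start=g.cds_start)
        lesions = wa.call_pseudogene(gm, seq, structures[5])
        assert "frameshift_indel" in {l.kind for l in lesions}


class TestClassification:
    def test_full_category_panel(self):
        plans = [
            sd.SyntheticGenePlan("intron1", has_intron1_motif=True,
                                 planted_atg=("intron1", 7)),
            sd.SyntheticGenePlan("exon2", has_intron1_motif=True,
                                 planted_atg=("exon2", 45)),
            sd.SyntheticGenePlan("antidote", has_intron1_motif=False),
            sd.SyntheticGenePlan("pseudo", planted_lesion="premature_stop"),
        ]
        fam, motifs, structures = _family(plans, seed=16)
        expected = {
            "intron1": "poison_and_antidote_intron1_atg",
            "exon2": "poison_and_antidote_exon2_atg",
            "antidote": "antidote_only",
            "pseudo": "pseudogene",
        }
        for g in fam.genes:
            res = _classify(fam, motifs, structures, g)
            assert res.category == expected[g.gene_id], g.gene_id

    def test_divergent_list_precedence(self):
        fam, motifs, structures = _family(
            [sd.SyntheticGenePlan("g", has_intron1_motif=True,
                                  planted_atg=("intron1", 7))], seed=17)
        g = fam.genes[0]
        gm = wa.GeneModel(gene_id="g", exons=g.exons, cds_start=g.cds_start)
        res = wa.classify_gene(gm, g.sequence, motifs, structures[5],
                               divergent_list={"g"})
        assert res.category == "divergent_unclassified"

    def test_pseudogene_requires_lesion_reason(self):
        fam, motifs, structures = _family(
            [sd.SyntheticGenePlan("g", planted_lesion="lost_start")], seed=18)
        res = _classify(fam, motifs, structures, fam.genes[0])
        assert res.category == "pseudogene"
        assert any("lost_start" in r for r in res.reasons)


class TestPairwiseIdentity:
    def test_identical(self):
        assert wa.pairwise_identity("ACGT" * 25, "ACGT" * 25) == 1.0

    def test_hand_counted_alignment(self):
        assert wa.pairwise_identity("ACGT-A", "ACGTTA") == pytest.approx(5 / 6)

    def test_both_gap_columns_removed(self):
        # both-gap columns drop out: 4 informative columns, 3 identical
        assert wa.pairwise_identity("AC--GT", "AC--GA") == pytest.approx(0.75)

    @given(st.text(alphabet="ACGT-", min_size=1, max_size=60),
           st.text(alphabet="ACGT-", min_size=1, max_size=60))
    def test_symmetry_and_range(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            x = wa.pairwise_identity(a, b)
        except ValueError:
            return
        assert 0.0 <= x <= 1.0
        assert x == wa.pairwise_identity(b, a)
        if x == 1.0:
            stripped = [(p, q) for p, q in zip(a, b)
                        if not (p == "-" and q == "-")]
            assert all(p == q and p != "-" for p, q in stripped)


class TestLtrDeletion:
    def _pair_gene(self, seed=20):
        fam, _, _ = _family([sd.SyntheticGenePlan(
            "g", ltr_flanks="directly_oriented_pair")], seed=seed)
        return fam.genes[0]

    def test_recovers_exact_deleted_interval(self):
        g = self._pair_gene()
        gd = sd.diverge_ltr_pair(g, rate=0.08, identical_window=(100, 20),
                                 seed=1)
        prod = sd.apply_ltr_recombination(gd)
        event, reason = wa.detect_ltr_deletion(
            wa.LtrRegion(gd.sequence, gd.ltrs),
            wa.LtrRegion(prod["sequence"], [prod["solo_ltr"]]))
        assert reason == "ok"
        assert (event.deleted_start, event.deleted_end) == \
            prod["deleted_interval"]

    def test_seven_nt_breakpoint_homology(self):
        g = self._pair_gene(seed=21)
        gd = sd.diverge_ltr_pair(g, rate=0.12, identical_window=(140, 7),
                                 seed=2)
        prod = sd.apply_ltr_recombination(gd)
        event, _ = wa.detect_ltr_deletion(
            wa.LtrRegion(gd.sequence, gd.ltrs),
            wa.LtrRegion(prod["sequence"], [prod["solo_ltr"]]))
        assert event.homology_length == 7

    def test_inverted_pair_rejected(self):
        g = self._pair_gene(seed=22)
        (s1, e1, _), (s2, e2, _) = g.ltrs
        donor = wa.LtrRegion(g.sequence, [(s1, e1, "+"), (s2, e2, "-")])
        prod = sd.apply_ltr_recombination(g)
        event, reason = wa.detect_ltr_deletion(
            donor, wa.LtrRegion(prod["sequence"], [prod["solo_ltr"]]))
        assert event is None
        assert "inverted" in reason

    def test_unrelated_recipient_rejected(self):
        g = self._pair_gene(seed=23)
        rng = np.random.default_rng(3)
        fake = "".join(rng.choice(list("ACGT"), len(g.sequence)))
        event, reason = wa.detect_ltr_deletion(
            wa.LtrRegion(g.sequence, g.ltrs),
            wa.LtrRegion(fake, [(g.ltrs[0][0], g.ltrs[0][1], "+")]))
        assert event is None


class TestFamilyConsensus:
    def test_inferred_consensus_matches_generator_layout(self):
        plans = [sd.SyntheticGenePlan(f"g{i}") for i in range(6)]
        fam, _, structures = _family(plans, seed=24)
        genes = [wa.GeneModel(gene_id=g.gene_id, exons=g.exons,
                              cds_start=g.cds_start) for g in fam.genes]
        inferred = wa.infer_family_consensus(genes)
        assert inferred[5].exon_lengths == structures[5].exon_lengths
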