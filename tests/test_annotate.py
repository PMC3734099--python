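"""Nearest-gene annotation, mechanism bins, and trio inheritance."""

import random

import pytest

from cnvscan import annotate as ann
from cnvscan import regions as rg
from cnvscan.model import (
    CNVCall,
    CNVType,
    Cohort,
    EvidenceTrack,
    GeneModel,
    Pedigree,
    TrackName,
)


def region_from(*calls):
    (region,) = rg.merge_loci(rg.overlap_clusters(list(calls)), 10_000_000)
    return region


def gene(chrom="1", start=10_000, end=20_000, gene_id="g1", strand="+"):
    return GeneModel(chrom, start, end, gene_id, strand)


class TestNearestGeneDistance:
    def test_abutting_gene_gives_zero_distance(self, call_factory):
        region = region_from(
            call_factory(start=9_000, end=9_999),
            call_factory(start=9_100, end=9_999, sample_id="s2"),
        )
        gid, nearest, furthest = ann.nearest_gene_distance(region, [gene()])
        assert (gid, nearest) == ("g1", 0)

    def test_single_member_nearest_equals_furthest(self, call_factory):
        region = region_from(call_factory(start=5_000, end=6_000))
        _gid, nearest, furthest = ann.nearest_gene_distance(region, [gene()])
        assert nearest == furthest == 10_000 - 6_000 - 1

    def test_planted_distance_is_recovered_exactly(self, call_factory):
        # region ending 5,000 intervening bases upstream of the gene span
        region = region_from(call_factory(start=2_000, end=10_000 - 5_001))
        _gid, nearest, _f = ann.nearest_gene_distance(region, [gene()])
        assert nearest == 5_000

    def test_furthest_is_max_member_gap_to_chosen_gene(self, call_factory):
        near = call_factory(start=8_000, end=9_500, sample_id="s1")
        far = call_factory(start=2_000, end=8_100, sample_id="s2")
        region = region_from(near, far)
        _gid, nearest, furthest = ann.nearest_gene_distance(region, [gene()])
        assert nearest == 10_000 - 9_500 - 1
        assert furthest == 10_000 - 8_100 - 1

    def test_no_gene_on_chromosome(self, call_factory):
        region = region_from(call_factory())
        assert ann.nearest_gene_distance(region, [gene(chrom="9")]) == (
            None, None, None,
        )

    def test_tie_broken_by_smaller_gene_start(self, call_factory):
        region = region_from(call_factory(start=10_000, end=11_000))
        left = gene(start=8_999, end=9_500, gene_id="left")
        right = gene(start=11_501, end=12_000, gene_id="right")
        gid, dist, _ = ann.nearest_gene_distance(region, [right, left])
        assert (gid, dist) == ("left", 499)

    def test_agrees_with_exhaustive_scan(self, call_factory):
        rng = random.Random(9)
        genes = []
        for i in range(200):
            s = rng.randint(1, 5_000_000)
            genes.append(gene(start=s, end=s + rng.randint(100, 20_000),
                              gene_id=f"g{i}"))
        for _ in range(50):
            s = rng.randint(1, 5_000_000)
            region = region_from(call_factory(start=s, end=s + 5_000))
            gid, nearest, _ = ann.nearest_gene_distance(region, genes)
            gaps = []
            for g in genes:
                if g.end < region.start:
                    gaps.append((region.start - g.end - 1, g.start, g.gene_id))
                elif g.start > region.end:
                    gaps.append((g.start - region.end - 1, g.start, g.gene_id))
                else:
                    gaps.append((0, g.start, g.gene_id))
            best = min(gaps)
            assert (nearest, gid) == (best[0], best[2])


class TestCandidateGenesAndEvidence:
    def test_nearest_gene_on_list_flags_region(self, call_factory):
        region = region_from(call_factory(start=5_000, end=6_000))
        a = ann.annotate_region(region, [gene()], [], {"g1"})
        assert a.is_candidate_gene

    def test_empty_candidate_list_flags_nothing(self, call_factory):
        region = region_from(call_factory(start=5_000, end=6_000))
        a = ann.annotate_region(region, [gene()], [], set())
        assert not a.is_candidate_gene

    def test_non_nearest_gene_within_window_still_flags(self, call_factory):
        region = region_from(call_factory(start=5_000, end=6_000))
        genes = [gene(), gene(start=500_000, end=510_000, gene_id="risk")]
        a = ann.annotate_region(region, genes, [], {"risk"}, window_bp=1_000_000)
        assert a.nearest_gene == "g1"
        assert a.is_candidate_gene

    def test_evidence_labels_any_overlapping_track(self, call_factory):
        region = region_from(call_factory(start=5_000, end=6_000))
        est = EvidenceTrack(TrackName.EXPRESSED_SEQUENCE, [("1", 5_500, 5_800, "e")])
        cons = EvidenceTrack(TrackName.CONSERVED_ELEMENT, [("1", 9_000, 9_100, "c")])
        assert ann.evidence_overlap(region, []) == set()
        assert ann.evidence_overlap(region, [est]) == {"expressed_sequence"}
        assert ann.evidence_overlap(region, [est, cons]) == {"expressed_sequence"}
        cons2 = EvidenceTrack(TrackName.CONSERVED_ELEMENT, [("1", 5_900, 6_100, "c")])
        assert ann.evidence_overlap(region, [est, cons2]) == {
            "expressed_sequence", "conserved_element",
        }


class TestAssignBin:
    def make(self, call_factory, tracks):
        region = region_from(call_factory(start=5_000, end=6_000))
        genes = [gene()]  # 3,999 intervening bases downstream of region
        a = ann.annotate_region(region, genes, tracks, set(), window_bp=10_000)
        return a.bin

    def test_no_evidence_near_gene_gives_bin_i(self, call_factory):
        assert self.make(call_factory, []) == {"i"}

    def test_unlinked_expressed_sequence_gives_compound_i_ii(self, call_factory):
        # ES interval inside the region, ending > window away from the gene
        est = EvidenceTrack(
            TrackName.EXPRESSED_SEQUENCE, [("1", 5_100, 5_200, "e")]
        )
        region = region_from(call_factory(start=5_000, end=6_000))
        genes = [gene(start=500_000, end=510_000)]
        a = ann.annotate_region(region, genes, [est], set(), window_bp=10_000)
        assert a.bin == {"i", "ii"}

    def test_gene_linked_expressed_sequence_includes_iii(self, call_factory):
        est = EvidenceTrack(
            TrackName.EXPRESSED_SEQUENCE, [("1", 5_500, 9_900, "mRNA")]
        )
        assert "iii" in self.make(call_factory, [est])

    def test_conserved_element_contributes_ii(self, call_factory):
        cons = EvidenceTrack(TrackName.CONSERVED_ELEMENT, [("1", 5_500, 5_600, "c")])
        assert self.make(call_factory, [cons]) == {"i", "ii"}

    def test_assignment_is_pure(self, call_factory):
        est = EvidenceTrack(TrackName.EXPRESSED_SEQUENCE, [("1", 5_500, 9_900, "e")])
        assert self.make(call_factory, [est]) == self.make(call_factory, [est])


class TestDetermineInheritance:
    def setup_method(self):
        self.ped = Pedigree(trios={"kid": ("dad", "mum")})
        self.call = CNVCall("1", 10_000, 20_000, CNVType.LOSS, "kid", Cohort.CASE)

    def parent(self, sample_id, start=10_500, end=19_500, cnv_type=CNVType.LOSS):
        return CNVCall("1", start, end, cnv_type, sample_id, Cohort.PARENT)

    def test_maternal_copy_detected(self):
        res = ann.determine_inheritance(self.call, [self.parent("mum")], self.ped)
        assert res.status == ann.INHERITED_MATERNAL

    def test_paternal_copy_detected(self):
        res = ann.determine_inheritance(self.call, [self.parent("dad")], self.ped)
        assert res.status == ann.INHERITED_PATERNAL

    def test_match_in_both_parents_reports_maternal_and_logs_both(self):
        res = ann.determine_inheritance(
            self.call, [self.parent("mum"), self.parent("dad")], self.ped
        )
        assert res.status == ann.INHERITED_MATERNAL
        assert res.matched_parents == ("mum", "dad")

    def test_no_parental_match_is_de_novo(self):
        far = self.parent("mum", start=90_000, end=95_000)
        res = ann.determine_inheritance(self.call, [far], self.ped)
        assert res.status == ann.DE_NOVO

    def test_type_mismatch_is_not_a_match(self):
        gain = self.parent("mum", cnv_type=CNVType.GAIN)
        res = ann.determine_inheritance(self.call, [gain], self.ped)
        assert res.status == ann.DE_NOVO

    def test_missing_parent_without_match_is_unknown(self):
        ped = Pedigree(trios={"kid": (None, "mum")})
        res = ann.determine_inheritance(self.call, [], ped)
        assert res.status == ann.UNKNOWN

    def test_sample_absent_from_pedigree_is_unknown(self):
        res = ann.determine_inheritance(self.call, [], Pedigree())
        assert res.status == ann.UNKNOWN

    def test_ro_threshold_governs_parent_matching(self):
        # parent call with RO ~0.45 against the proband call
        weak = self.parent("mum", start=15_500, end=25_500)
        res = ann.determine_inheritance(self.call, [weak], self.ped, ro_threshold=0.5)
        assert res.status == ann.DE_NOVO
        res = ann.determine_inheritance(self.call, [weak], self.ped, ro_threshold=0.4)
        assert res.status == ann.INHERITED_MATERNAL


def test_simulation_inheritance_labels_recovered_exactly(default_cohort):
    """Trio probands' planted CNVs classify to their ground-truth labels."""
    from cnvscan import simulate as sm

    truth = default_cohort.ground_truth
    assert truth.inheritance_labels, "default simulation produces labelled trios"
    by_key = {
        sm.GroundTruth.label_key(c): c
        for c in default_cohort.case_calls
    }
    for key, expected in truth.inheritance_labels.items():
        call = by_key[key]
        got = ann.determine_inheritance(
            call, default_cohort.parent_calls, default_cohort.pedigree
        ).status
        if expected == "de_novo":
            assert got == ann.DE_NOVO
        else:
            assert got == expected
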