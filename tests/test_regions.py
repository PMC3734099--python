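"""Overlap clustering, locus merging, and the region-level filters."""

import pytest

from cnvscan import regions as rg
from cnvscan import table1
from cnvscan.model import (
    CNVCall,
    CNVType,
    Cohort,
    EvidenceTrack,
    Pedigree,
    TrackName,
)

from conftest import random_calls


def brute_clusters(calls):
    """Union-find over all O(n^2) pairs (the clustering oracle)."""
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(calls[i])
    return groups.values()


def as_key(cluster):
    return frozenset((c.sample_id, c.chrom, c.start, c.end) for c in cluster)


class TestOverlapClusters:
    def test_disjoint_calls_form_singletons(self, call_factory):
        a = call_factory(start=100, end=200)
        b = call_factory(start=300, end=400, sample_id="s2")
        assert [len(cl) for cl in rg.overlap_clusters([a, b])] == [1, 1]

    def test_single_linkage_transitivity(self, call_factory):
        a = call_factory(start=100, end=200)
        b = call_factory(start=150, end=320, sample_id="s2")
        c = call_factory(start=300, end=400, sample_id="s3")
        # a and c do not overlap but are linked through b
        (cluster,) = rg.overlap_clusters([a, b, c])
        assert len(cluster) == 3

    def test_types_mixed_within_a_cluster(self, call_factory):
        a = call_factory(cnv_type=CNVType.LOSS)
        b = call_factory(cnv_type=CNVType.GAIN, sample_id="s2")
        assert len(rg.overlap_clusters([a, b])) == 1

    def test_reference_2p16_rows_form_three_clusters(self):
        calls = [r.call for r in table1.load_table1_fixture() if r.locus == "2p16.3"]
        clusters = rg.overlap_clusters(calls)
        spans = sorted(
            (min(c.start for c in cl), max(c.end for c in cl)) for cl in clusters
        )
        assert spans == [
            (51157414, 51225851),
            (51405882, 51524684),
            (52220120, 52253660),
        ]

    def test_matches_brute_force_union_find(self):
        calls = random_calls(500, seed=21, span=3_000_000)
        got = {as_key(cl) for cl in rg.overlap_clusters(calls)}
        expected = {as_key(cl) for cl in brute_clusters(calls)}
        assert got == expected

    def test_deterministic_ordering(self):
        calls = random_calls(200, seed=5)
        a = rg.overlap_clusters(calls)
        b = rg.overlap_clusters(list(reversed(calls)))
        assert [as_key(cl) for cl in a] == [as_key(cl) for cl in b]


class TestMergeLoci:
    def fixture_regions(self, gap=1_000_000):
        return rg.merge_loci(rg.overlap_clusters(table1.table1_calls()), gap)

    def test_4q13_clusters_merge_into_one_locus(self):
        regions = [r for r in self.fixture_regions() if r.chrom == "4"]
        assert len(regions) == 1
        assert len(regions[0].clusters) == 2  # 412 kb apart, within 1 Mb

    def test_11p12_groups_1_29_mb_apart_stay_separate(self):
        regions = [
            r for r in self.fixture_regions()
            if r.chrom == "11" and r.start >= 40_000_000 and r.end <= 43_000_000
        ]
        assert len(regions) == 2
        assert regions[0].end == 40703298 and regions[1].start == 41990280

    def test_zero_gap_merging_is_noop_beyond_clustering(self):
        clusters = rg.overlap_clusters(table1.table1_calls())
        assert len(rg.merge_loci(clusters, 0)) == len(clusters)

    def test_region_span_is_member_envelope(self, call_factory):
        a = call_factory(start=100, end=300)
        b = call_factory(start=250, end=900, sample_id="s2")
        (region,) = rg.merge_loci(rg.overlap_clusters([a, b]))
        assert region.span == (100, 900)
        assert region.n_distinct_cases == 2


class TestRecurrenceFilter:
    def region_of(self, *calls):
        return rg.merge_loci(rg.overlap_clusters(list(calls)))

    def test_two_samples_sharing_family_removed(self, call_factory):
        a = call_factory(sample_id="s1", family_id="famA")
        b = call_factory(sample_id="s2", family_id="famA", start=120, end=220)
        assert rg.recurrence_filter(self.region_of(a, b), 2) == []

    def test_two_unrelated_samples_retained(self, call_factory):
        a = call_factory(sample_id="s1")
        b = call_factory(sample_id="s2", start=120, end=220)
        assert len(rg.recurrence_filter(self.region_of(a, b), 2)) == 1

    def test_siblings_inferred_from_pedigree_are_related(self, call_factory):
        ped = Pedigree(trios={"s1": ("f", "m"), "s2": ("f", "m")})
        a = call_factory(sample_id="s1")
        b = call_factory(sample_id="s2", start=120, end=220)
        assert rg.recurrence_filter(self.region_of(a, b), 2, ped) == []

    def test_recurrence_requires_overlap_not_just_proximity(self, call_factory):
        # two disjoint singletons joined only by the gap rule: no recurrence
        a = call_factory(sample_id="s1", start=100, end=200)
        b = call_factory(sample_id="s2", start=5_000, end=6_000)
        (region,) = rg.merge_loci(rg.overlap_clusters([a, b]), 1_000_000)
        assert len(region.clusters) == 2
        assert rg.recurrence_filter([region], 2) == []

    def test_singleton_subcluster_tags_along_with_recurrent_one(self, call_factory):
        lone = call_factory(sample_id="s1", start=100, end=200)
        a = call_factory(sample_id="s2", start=5_000, end=6_000)
        b = call_factory(sample_id="s3", start=5_500, end=6_400)
        (region,) = rg.merge_loci(rg.overlap_clusters([lone, a, b]), 1_000_000)
        kept = rg.recurrence_filter([region], 2)
        assert len(kept) == 1
        assert kept[0].sample_ids == {"s1", "s2", "s3"}

    def test_one_sample_with_two_cnvs_counts_once(self, call_factory):
        a = call_factory(sample_id="s1", start=100, end=200)
        b = call_factory(sample_id="s1", start=150, end=260)
        assert rg.recurrence_filter(self.region_of(a, b), 2) == []

    def test_reference_7q21_locus_retained(self):
        regions = rg.merge_loci(rg.overlap_clusters(table1.table1_calls()))
        kept = rg.recurrence_filter(regions, 2)
        assert any(
            r.chrom == "7" and "8-6258-03" in r.sample_ids for r in kept
        )


class TestControlAbsenceFilter:
    def make_region(self, call_factory):
        a = call_factory(sample_id="s1", start=1000, end=2000)
        b = call_factory(sample_id="s2", start=1500, end=2500)
        return rg.merge_loci(rg.overlap_clusters([a, b]))

    def control(self, call_factory, **kw):
        kw.setdefault("cohort", Cohort.CONTROL)
        kw.setdefault("sample_id", "c1")
        return call_factory(**kw)

    def test_control_carrier_removes_region(self, call_factory):
        regions = self.make_region(call_factory)
        ctrl = self.control(call_factory, start=1800, end=1900)
        assert rg.control_absence_filter(regions, [ctrl], 0) == []

    def test_no_control_overlap_retains_region(self, call_factory):
        regions = self.make_region(call_factory)
        ctrl = self.control(call_factory, start=9000, end=9500)
        assert len(rg.control_absence_filter(regions, [ctrl], 0)) == 1

    def test_opposite_type_control_does_not_count(self, call_factory):
        regions = self.make_region(call_factory)
        ctrl = self.control(call_factory, start=1800, end=1900, cnv_type=CNVType.GAIN)
        assert len(rg.control_absence_filter(regions, [ctrl], 0, same_type=True)) == 1
        regions = self.make_region(call_factory)
        assert rg.control_absence_filter(regions, [ctrl], 0, same_type=False) == []

    def test_carrier_cap_counts_distinct_samples(self, call_factory):
        regions = self.make_region(call_factory)
        ctrls = [
            self.control(call_factory, start=1800, end=1900, sample_id="c1"),
            self.control(call_factory, start=1850, end=1950, sample_id="c1"),
        ]
        # one distinct control sample: retained at cap 1, removed at cap 0
        assert len(rg.control_absence_filter(regions, ctrls, 1)) == 1
        regions = self.make_region(call_factory)
        assert rg.control_absence_filter(regions, ctrls, 0) == []


def span_region(call_factory, start, end):
    a = call_factory(sample_id="s1", start=start, end=end)
    b = call_factory(sample_id="s2", start=start, end=end)
    return rg.merge_loci(rg.overlap_clusters([a, b]))


def track(name, *ivs):
    return EvidenceTrack(TrackName(name), [("1", s, e, "x") for s, e in ivs])


class TestCoverageFilters:
    def test_region_inside_common_variant_interval_removed(self, call_factory):
        regions = span_region(call_factory, 1000, 2000)
        t = track("common_variant", (500, 3000))
        assert rg.dgv_filter(regions, t, 0.5) == []

    def test_zero_overlap_retained_and_trail_records_coverage(self, call_factory):
        regions = span_region(call_factory, 1000, 2000)
        t = track("common_variant", (5000, 6000))
        kept = rg.dgv_filter(regions, t, 0.5)
        assert len(kept) == 1
        assert kept[0].filter_trail[-1] == {
            "filter": "common_variant",
            "statistic": {"coverage": 0.0},
            "passed": True,
        }

    def test_half_covered_region_removed_at_inclusive_boundary(self, call_factory):
        regions = span_region(call_factory, 1, 100)  # closed span of 100 bases
        t = track("common_variant", (1, 50))
        assert rg.dgv_filter(regions, t, 0.5) == []

    def test_union_coverage_does_not_double_count(self, call_factory):
        regions = span_region(call_factory, 1, 100)
        # two overlapping intervals covering bases 1..49 only (49%)
        t = track("common_variant", (1, 40), (20, 49))
        assert len(rg.dgv_filter(regions, t, 0.5)) == 1

    def test_repeat_81_percent_removed_80_retained(self, call_factory):
        regions = span_region(call_factory, 1, 100)
        assert rg.repeat_filter(regions, track("repeat", (1, 81)), 0.8) == []
        regions = span_region(call_factory, 1, 100)
        assert len(rg.repeat_filter(regions, track("repeat", (1, 80)), 0.8)) == 1

    def test_repeat_decoy_region_removed_in_simulation(self, default_cohort):
        truth = default_cohort.ground_truth
        decoy = truth.repeat_decoys[0]
        calls = [
            c
            for c in default_cohort.case_calls
            if c.sample_id in decoy.sample_ids
            and c.chrom == decoy.chrom
            and decoy.start <= c.start
            and c.end <= decoy.end
        ]
        regions = rg.merge_loci(rg.overlap_clusters(calls))
        assert rg.repeat_filter(regions, default_cohort.tracks["repeat"], 0.8) == []

    def test_dgv_and_repeat_filters_commute(self, default_cohort):
        calls = [c for c in default_cohort.case_calls]
        dgv = default_cohort.tracks["common_variant"]
        rep = default_cohort.tracks["repeat"]

        def ids(regions):
            return [r.region_id for r in regions]

        base = rg.merge_loci(rg.overlap_clusters(calls))
        ab = rg.repeat_filter(rg.dgv_filter(base, dgv, 0.5), rep, 0.8)
        base2 = rg.merge_loci(rg.overlap_clusters(calls))
        ba = rg.dgv_filter(rg.repeat_filter(base2, rep, 0.8), dgv, 0.5)
        assert ids(ab) == ids(ba)


def test_filters_only_remove(default_cohort):
    """Every filter's output region set is a subset of its input."""
    calls = list(default_cohort.case_calls)
    regions = rg.merge_loci(rg.overlap_clusters(calls))
    stages = [regions]
    stages.append(rg.recurrence_filter(stages[-1], 2))
    stages.append(
        rg.control_absence_filter(stages[-1], default_cohort.control_calls, 0)
    )
    stages.append(
        rg.dgv_filter(stages[-1], default_cohort.tracks["common_variant"], 0.5)
    )
    stages.append(rg.repeat_filter(stages[-1], default_cohort.tracks["repeat"], 0.8))
    for before, after in zip(stages, stages[1:]):
        assert set(map(id, after)) <= set(map(id, before))
        assert len(after) <= len(before)
    for region in stages[0]:
        assert region.filter_trail, "every region carries an audit trail"
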