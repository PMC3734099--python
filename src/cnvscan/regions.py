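"""Candidate-region construction: overlap clustering, locus merging, filters.

Case CNVs are clustered per chromosome by single-linkage any-overlap
(>=1 shared base, type-agnostic — one locus can mix losses and gains);
clusters separated by at most ``locus_merge_gap`` intervening bases are
merged into one candidate locus.  Region-level filters then enforce
recurrence in unrelated cases, absence from controls, absence from the
common-variant (DGV-style) catalogue, and a cap on repeat-masked
fraction.  Filters only remove regions, and every decision is recorded
on the region's ``filter_trail``.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from intervaltree import IntervalTree

from . import intervals as iv
from .model import (
    CandidateRegion,
    CNVCall,
    EvidenceTrack,
    FilterThresholds,
    Pedigree,
)


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def overlap_clusters(case_calls: Sequence[CNVCall]) -> list[list[CNVCall]]:
    """Single-linkage connected components under >=1 bp overlap, per chromosome.

    Type-agnostic; transitive (a~b, b~c puts a and c in one cluster even if
    disjoint).  Clusters are ordered by (chromosome, min start); members
    within a cluster by (start, end, sample_id).
    """
    by_chrom: dict[str, list[CNVCall]] = defaultdict(list)
    for c in case_calls:
        by_chrom[c.chrom].append(c)
    clusters: list[list[CNVCall]] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.sample_id))
        current: list[CNVCall] = []
        reach = -1  # max end of current cluster
        for call in calls:
            if current and call.start <= reach:  # closed intervals share a base
                current.append(call)
                reach = max(reach, call.end)
            else:
                if current:
                    clusters.append(current)
                current = [call]
                reach = call.end
        if current:
            clusters.append(current)
    return clusters


def merge_loci(
    clusters: Sequence[list[CNVCall]], locus_merge_gap: int = 1_000_000
) -> list[CandidateRegion]:
    """Merge same-chromosome clusters separated by <= ``locus_merge_gap`` bases.

    Single-linkage on cluster spans: a chain of clusters each within the gap
    of the next forms one candidate locus.  The resulting region records the
    sub-cluster partition.  Region ids are ``locus_001`` ... in (chromosome,
    start) order.
    """
    by_chrom: dict[str, list[list[CNVCall]]] = defaultdict(list)
    for cl in clusters:
        if not cl:
            continue
        chroms = {c.chrom for c in cl}
        if len(chroms) != 1:
            raise ValueError("cluster spans multiple chromosomes")
        by_chrom[chroms.pop()].append(cl)
    regions: list[CandidateRegion] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        chrom_clusters = sorted(by_chrom[chrom], key=lambda cl: min(c.start for c in cl))
        group: list[list[CNVCall]] = []
        group_end = -1
        for cl in chrom_clusters:
            cl_start = min(c.start for c in cl)
            cl_end = max(c.end for c in cl)
            # intervening bases between closed spans; negative when overlapping
            if group and cl_start - group_end - 1 <= locus_merge_gap:
                group.append(cl)
                group_end = max(group_end, cl_end)
            else:
                if group:
                    regions.append(_make_region(chrom, group))
                group = [cl]
                group_end = cl_end
        if group:
            regions.append(_make_region(chrom, group))
    regions.sort(key=lambda r: (_chrom_key(r.chrom), r.start))
    for i, region in enumerate(regions, start=1):
        region.region_id = f"locus_{i:03d}"
    return regions


def _make_region(chrom: str, group: list[list[CNVCall]]) -> CandidateRegion:
    members = [c for cl in group for c in cl]
    return CandidateRegion(
        region_id="", chrom=chrom, members=members,
        clusters=[list(cl) for cl in group],
    )


def recurrence_filter(
    regions: Sequence[CandidateRegion],
    min_cases: int = 2,
    pedigree: Pedigree | None = None,
) -> list[CandidateRegion]:
    """Retain regions with >= ``min_cases`` unrelated cases in one sub-cluster.

    Recurrence means *overlapping* CNVs in two or more unrelated cases, so
    the requirement is evaluated per overlap sub-cluster: a locus survives
    when at least one of its sub-clusters reaches ``min_cases`` distinct
    unrelated carriers.  Singleton sub-clusters attached to a surviving
    locus by the gap rule are reported with it (published loci include such
    tag-along events) but cannot establish recurrence on their own.
    Unrelatedness keys on family_id when present, else on parental IDs from
    the pedigree (siblings share parents), else on sample_id.  A sample with
    several CNVs in one sub-cluster contributes once.
    """

    def n_families(calls: list[CNVCall]) -> int:
        families = set()
        for call in calls:
            if call.family_id:
                families.add(call.family_id)
            elif pedigree is not None:
                families.add(pedigree.siblings_key(call.sample_id))
            else:
                families.add(call.sample_id)
        return len(families)

    out = []
    for region in regions:
        best = max(n_families(cl) for cl in region.clusters)
        passed = best >= min_cases
        region.record("recurrence", {"max_unrelated_cases_in_cluster": best}, passed)
        if passed:
            out.append(region)
    return out


def control_absence_filter(
    regions: Sequence[CandidateRegion],
    control_calls: Sequence[CNVCall],
    max_control_carriers: int = 0,
    *,
    same_type: bool = True,
    ro_threshold: float | None = None,
) -> list[CandidateRegion]:
    """Remove regions seen in more than ``max_control_carriers`` control samples.

    A control sample counts as a carrier when one of its calls overlaps
    (>=1 bp) any member CNV with matching type; pass ``ro_threshold`` to
    require reciprocal overlap instead of any-overlap.  The default cap of
    0 implements strict absence from controls.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for c in control_calls:
        trees[c.chrom].addi(c.start, c.end + 1, c)
    out = []
    for region in regions:
        carriers: set[str] = set()
        tree = trees.get(region.chrom)
        if tree is not None:
            for m in region.members:
                for hit in tree.overlap(m.start, m.end + 1):
                    ctrl: CNVCall = hit.data
                    if same_type and ctrl.cnv_type != m.cnv_type:
                        continue
                    if ro_threshold is not None and (
                        iv.reciprocal_overlap(m.interval, ctrl.interval) < ro_threshold
                    ):
                        continue
                    carriers.add(ctrl.sample_id)
        passed = len(carriers) <= max_control_carriers
        region.record("control_absence", {"control_carriers": len(carriers)}, passed)
        if passed:
            out.append(region)
    return out


def _coverage_filter(
    regions: Sequence[CandidateRegion],
    track: EvidenceTrack | None,
    name: str,
    remove_when,
) -> list[CandidateRegion]:
    out = []
    for region in regions:
        ivs = (
            [(s, e) for s, e, _ in track.on_chrom(region.chrom)] if track else []
        )
        frac = iv.union_coverage(region.span, ivs)
        removed = remove_when(frac)
        region.record(name, {"coverage": frac}, not removed)
        if not removed:
            out.append(region)
    return out


def dgv_filter(
    regions: Sequence[CandidateRegion],
    common_variant_track: EvidenceTrack | None,
    dgv_max_overlap: float = 0.5,
) -> list[CandidateRegion]:
    """Remove regions covered by the common-variant catalogue at >= the cutoff.

    Coverage is the fraction of the merged span under the union of track
    intervals (no double counting).  Inclusive at the boundary: a region
    exactly half-covered at the default 0.5 is removed.
    """
    return _coverage_filter(
        regions, common_variant_track, "common_variant",
        lambda frac: frac >= dgv_max_overlap,
    )


def repeat_filter(
    regions: Sequence[CandidateRegion],
    repeat_track: EvidenceTrack | None,
    repeat_max_fraction: float = 0.8,
) -> list[CandidateRegion]:
    """Remove regions whose repeat-masked fraction is strictly > the cutoff.

    Strict at the boundary: a region exactly 80% masked is retained.
    """
    return _coverage_filter(
        regions, repeat_track, "repeat",
        lambda frac: frac > repeat_max_fraction,
    )


def discover_regions(
    case_calls: Sequence[CNVCall],
    thresholds: FilterThresholds | None = None,
    *,
    control_calls: Sequence[CNVCall] = (),
    common_variant_track: EvidenceTrack | None = None,
    repeat_track: EvidenceTrack | None = None,
    pedigree: Pedigree | None = None,
    same_type_controls: bool = True,
    skip_filters: frozenset[str] | set[str] = frozenset(),
) -> list[CandidateRegion]:
    """Full region stage: cluster, enforce recurrence/absence filters, merge loci.

    Filter names accepted in ``skip_filters``: recurrence, control_absence,
    common_variant, repeat.
    """
    th = thresholds or FilterThresholds()
    regions = merge_loci(overlap_clusters(case_calls), th.locus_merge_gap)
    if "recurrence" not in skip_filters:
        regions = recurrence_filter(regions, th.min_cases, pedigree)
    if "control_absence" not in skip_filters:
        regions = control_absence_filter(
            regions, control_calls, th.max_control_carriers,
            same_type=same_type_controls,
        )
    if "common_variant" not in skip_filters:
        regions = dgv_filter(regions, common_variant_track, th.dgv_max_overlap)
    if "repeat" not in skip_filters:
        regions = repeat_filter(regions, repeat_track, th.repeat_max_fraction)
    return regions
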