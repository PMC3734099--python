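"""Locus annotation: nearest gene, candidate-gene status, evidence overlap,
mechanism bin, and trio-based inheritance of member CNVs.

Mechanism bins encode three hypothesized modes of action of an intergenic
CNV: (i) perturbing regulatory elements of a nearby gene, (ii) hitting an
undiscovered gene or non-coding RNA inside the region, (iii) disrupting an
uncharacterized extended isoform of a neighbouring gene.  Assignment is a
transparent rule set over the evidence-track overlaps and nearest-gene
geometry; ambiguous evidence yields compound bins such as {i, ii}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import intervals as iv
from .model import (
    CandidateRegion,
    CNVCall,
    EvidenceTrack,
    GeneModel,
    Pedigree,
    TrackName,
)

INHERITED_MATERNAL = "inherited_maternal"
INHERITED_PATERNAL = "inherited_paternal"
DE_NOVO = "de_novo"
UNKNOWN = "unknown"


@dataclass(slots=True)
class LocusAnnotation:
    region_id: str
    nearest_gene: str | None = None
    nearest_distance_bp: int | None = None
    furthest_distance_bp: int | None = None
    direction: str | None = None  # upstream / downstream / flanking_both
    is_candidate_gene: bool = False
    evidence: set[str] = field(default_factory=set)
    bin: set[str] = field(default_factory=set)


@dataclass(frozen=True, slots=True)
class InheritanceCall:
    sample_id: str
    cnv: CNVCall
    status: str  # inherited_maternal | inherited_paternal | de_novo | unknown
    matched_parents: tuple[str, ...] = ()


def _gene_gap(span: tuple[int, int], gene: GeneModel) -> int:
    return iv.gap_between(span, (gene.start, gene.end))


def nearest_gene_distance(
    region: CandidateRegion, genes: list[GeneModel]
) -> tuple[str | None, int | None, int | None]:
    """Nearest gene to the merged span, with nearest and furthest member gaps.

    The nearest gene minimizes the gap to the merged span (0 when abutting);
    ties break to the smaller gene start.  The furthest distance is the
    largest, over member CNVs, of that member's own gap to the chosen gene —
    for a single-member region it equals the nearest distance.  Returns
    (None, None, None) when the chromosome has no gene.
    """
    on_chrom = [g for g in genes if g.chrom == region.chrom]
    if not on_chrom:
        return (None, None, None)
    best = min(on_chrom, key=lambda g: (_gene_gap(region.span, g), g.start))
    nearest = _gene_gap(region.span, best)
    furthest = max(_gene_gap(m.interval, best) for m in region.members)
    return (best.gene_id, nearest, max(nearest, furthest))


def gene_direction(region: CandidateRegion, gene: GeneModel) -> str:
    """Position of the region relative to the gene on the forward strand.

    A region left of the gene start is 'upstream' for a + strand gene and
    'downstream' for a - strand gene; unknown strand falls back to + .
    """
    if region.end < gene.start:
        left = True
    elif region.start > gene.end:
        left = False
    else:
        return "flanking_both"
    plus = gene.strand != "-"
    return "upstream" if left == plus else "downstream"


def flag_candidate_genes(
    annotation: LocusAnnotation,
    region: CandidateRegion,
    genes: list[GeneModel],
    candidate_list: set[str],
    window_bp: int = 1_000_000,
) -> LocusAnnotation:
    """Set is_candidate_gene when the nearest gene, or any gene within
    ``window_bp`` of the merged span, is on the candidate list."""
    hit = annotation.nearest_gene in candidate_list if annotation.nearest_gene else False
    if not hit:
        for g in genes:
            if g.chrom == region.chrom and g.gene_id in candidate_list:
                if _gene_gap(region.span, g) <= window_bp:
                    hit = True
                    break
    annotation.is_candidate_gene = hit
    return annotation


def evidence_overlap(
    region: CandidateRegion, tracks: list[EvidenceTrack]
) -> set[str]:
    """Labels of every track with >=1 bp overlap with the merged span."""
    labels = set()
    for track in tracks:
        for s, e, _lab in track.on_chrom(region.chrom):
            if iv.overlaps(region.span, (s, e)):
                labels.add(track.name.value)
                break
    return labels


def assign_bin(
    region: CandidateRegion,
    annotation: LocusAnnotation,
    tracks: list[EvidenceTrack],
    genes: list[GeneModel],
    gene_link_gap: int = 1_000_000,
) -> set[str]:
    """Rule-based mechanism bin assignment (pure in its inputs).

    - i   whenever a nearest gene exists (regulatory perturbation is always
          on the table for an intergenic CNV near a gene);
    - ii  when expressed-sequence or conserved-element evidence overlaps the
          region without being linked to the nearest gene;
    - iii when an overlapping expressed-sequence interval extends to within
          ``gene_link_gap`` of the nearest gene's span (the signature of an
          unannotated extended isoform).
    """
    bins: set[str] = set()
    if annotation.nearest_distance_bp is not None:
        bins.add("i")
    nearest = None
    if annotation.nearest_gene is not None:
        nearest = next(
            (g for g in genes if g.gene_id == annotation.nearest_gene), None
        )
    es_linked = False
    es_unlinked = False
    for track in tracks:
        if track.name is not TrackName.EXPRESSED_SEQUENCE:
            continue
        for s, e, _lab in track.on_chrom(region.chrom):
            if not iv.overlaps(region.span, (s, e)):
                continue
            if nearest is not None and (
                iv.gap_between((s, e), (nearest.start, nearest.end)) <= gene_link_gap
            ):
                es_linked = True
            else:
                es_unlinked = True
    conserved = any(
        t.name is TrackName.CONSERVED_ELEMENT
        and any(iv.overlaps(region.span, (s, e)) for s, e, _ in t.on_chrom(region.chrom))
        for t in tracks
    )
    if es_linked:
        bins.add("iii")
    if es_unlinked or conserved:
        bins.add("ii")
    annotation.bin = bins
    return bins


def annotate_region(
    region: CandidateRegion,
    genes: list[GeneModel],
    tracks: list[EvidenceTrack],
    candidate_list: set[str] | None = None,
    *,
    window_bp: int = 1_000_000,
) -> LocusAnnotation:
    """Full annotation of one region (nearest gene, evidence, bin, flags)."""
    gene_id, nearest, furthest = nearest_gene_distance(region, genes)
    ann = LocusAnnotation(
        region_id=region.region_id,
        nearest_gene=gene_id,
        nearest_distance_bp=nearest,
        furthest_distance_bp=furthest,
    )
    if gene_id is not None:
        gene = next(g for g in genes if g.gene_id == gene_id)
        ann.direction = gene_direction(region, gene)
    ann.evidence = evidence_overlap(region, tracks)
    assign_bin(region, ann, tracks, genes, gene_link_gap=window_bp)
    if candidate_list:
        flag_candidate_genes(ann, region, genes, candidate_list, window_bp)
    return ann


def determine_inheritance(
    proband_call: CNVCall,
    parent_calls: list[CNVCall],
    pedigree: Pedigree,
    ro_threshold: float = 0.5,
) -> InheritanceCall:
    """Classify a proband CNV as inherited, de novo, or unknown.

    Inherited when a same-type parental call with reciprocal overlap >=
    ``ro_threshold`` exists (maternal checked first; a match in both
    parents reports maternal and lists both in ``matched_parents``);
    de novo when both parents are present and neither matches; unknown
    when either parent's data is absent.
    """
    father, mother = pedigree.parents_of(proband_call.sample_id)

    def matches(parent_id: str | None) -> bool:
        if parent_id is None:
            return False
        for pc in parent_calls:
            if pc.sample_id != parent_id or pc.chrom != proband_call.chrom:
                continue
            if pc.cnv_type != proband_call.cnv_type:
                continue
            if iv.reciprocal_overlap(proband_call.interval, pc.interval) >= ro_threshold:
                return True
        return False

    hit_mother = matches(mother)
    hit_father = matches(father)
    if hit_mother:
        matched = (mother, father) if hit_father else (mother,)
        return InheritanceCall(
            proband_call.sample_id, proband_call, INHERITED_MATERNAL, matched
        )
    if hit_father:
        return InheritanceCall(
            proband_call.sample_id, proband_call, INHERITED_PATERNAL, (father,)
        )
    if father is None or mother is None:
        # a negative result is inconclusive without both parents
        return InheritanceCall(proband_call.sample_id, proband_call, UNKNOWN)
    return InheritanceCall(proband_call.sample_id, proband_call, DE_NOVO)
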