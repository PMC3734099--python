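"""Core domain types for the intergenic CNV screen.

All genomic intervals in this package use **1-based, fully-closed**
coordinates: a call spanning bases 10..20 contains both endpoints.  The
reported ``size`` of a CNV is ``end - start`` (the convention of the source
call sets this package mirrors), while overlap arithmetic uses the true
closed-interval base count ``end - start + 1``.  BED inputs are converted on
read (start + 1) and converted back on write.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; chromosome names are bare ('2', 'X')."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


class CNVType(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"

    @classmethod
    def parse(cls, token: str) -> "CNVType":
        t = token.strip().lower()
        if t in {"loss", "del", "deletion", "cn=1", "cn=0"}:
            return cls.LOSS
        if t in {"gain", "dup", "duplication", "amplification"}:
            return cls.GAIN
        raise ValueError(f"unknown CNV type token: {token!r}")


class Cohort(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    PARENT = "parent"


@dataclass(frozen=True, slots=True)
class CNVCall:
    """One copy-number event in one sample (1-based closed interval)."""

    chrom: str
    start: int
    end: int
    cnv_type: CNVType
    sample_id: str
    cohort: Cohort = Cohort.CASE
    platform: str | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid CNV interval {self.chrom}:{self.start}-{self.end} "
                f"({self.sample_id}): start must be < end"
            )

    @property
    def size(self) -> int:
        """Reported size, ``end - start`` (matches published call tables)."""
        return self.end - self.start

    @property
    def length(self) -> int:
        """True base count of the closed interval."""
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def family_key(self) -> str:
        """Key defining unrelatedness: family_id when known, else sample_id."""
        return self.family_id if self.family_id else self.sample_id


@dataclass(frozen=True, slots=True)
class GeneModel:
    """Full transcript span of an annotated gene."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "?"  # '+', '-', or '?'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


class TrackName(str, enum.Enum):
    COMMON_VARIANT = "common_variant"
    REPEAT = "repeat"
    EXPRESSED_SEQUENCE = "expressed_sequence"
    CONSERVED_ELEMENT = "conserved_element"


@dataclass(slots=True)
class EvidenceTrack:
    """A named set of genomic intervals used for overlap filters/annotation."""

    name: TrackName
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, _label in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.name.value}: bad interval {chrom}:{start}-{end}"
                )

    def on_chrom(self, chrom: str) -> list[tuple[int, int, str]]:
        return [(s, e, lab) for c, s, e, lab in self.intervals if c == chrom]


@dataclass(slots=True)
class Pedigree:
    """Maps proband sample_id to (father, mother); None marks a missing parent."""

    trios: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for proband, (father, mother) in self.trios.items():
            if proband in (father, mother):
                raise ValueError(f"proband {proband} listed as its own parent")

    def parents_of(self, sample_id: str) -> tuple[str | None, str | None]:
        return self.trios.get(sample_id, (None, None))

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.trios

    def siblings_key(self, sample_id: str) -> str:
        """A family key derived from parental IDs (siblings share it)."""
        father, mother = self.parents_of(sample_id)
        if father is None and mother is None:
            return sample_id
        return f"{father or '.'}|{mother or '.'}"


@dataclass(slots=True)
class CandidateRegion:
    """A merged cluster of case CNVs surviving the screen's filters.

    ``clusters`` partitions ``members`` into overlap-connected sub-clusters;
    a region holds >1 sub-cluster only after gap-based locus merging.
    ``filter_trail`` records, in order, each filter applied to the region with
    the measured statistic and the pass/fail outcome.
    """

    region_id: str
    chrom: str
    members: list[CNVCall]
    clusters: list[list[CNVCall]]
    filter_trail: list[dict] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_distinct_cases(self) -> int:
        return len({m.sample_id for m in self.members})

    @property
    def sample_ids(self) -> set[str]:
        return {m.sample_id for m in self.members}

    def record(self, filter_name: str, statistic, passed: bool) -> None:
        self.filter_trail.append(
            {"filter": filter_name, "statistic": statistic, "passed": passed}
        )


@dataclass(slots=True)
class FilterThresholds:
    """Thresholds of the region-level screen."""

    min_cases: int = 2
    max_control_carriers: int = 0
    dgv_max_overlap: float = 0.5  # remove when coverage >= this fraction
    repeat_max_fraction: float = 0.8  # remove when coverage strictly > this
    locus_merge_gap: int = 1_000_000  # bp

    def __post_init__(self) -> None:
        if self.min_cases < 2:
            raise ValueError("min_cases must be >= 2 (recurrence requires it)")
        for name in ("dgv_max_overlap", "repeat_max_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.locus_merge_gap < 0:
            raise ValueError("locus_merge_gap must be >= 0")


@dataclass(slots=True)
class CohortConfig:
    """All knobs of the screen, mirrored by the YAML config blocks."""

    # rarity
    max_freq: float = 0.01
    ro_threshold: float = 0.5
    same_type: bool = True
    stratify_by_platform: bool = False
    # genic classification
    genic_mode: str = "span"  # or "exon"
    # region filters
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    # genome build is opaque: asserted only as a declared string
    build: str = "unspecified"


def distinct_samples(calls: Iterable[CNVCall]) -> set[str]:
    return {c.sample_id for c in calls}
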