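"""Carrier-frequency estimation and the rare-variant filter.

Two calls from different samples are the *same* CNV when they lie on the
same chromosome, have reciprocal overlap at or above a threshold (default
0.5, the field-standard criterion) and — by default — the same type.  A
call is *rare* when the fraction of distinct samples in the overall
dataset (cases + controls pooled) carrying the same CNV is strictly below
``max_freq`` (default 1%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .model import CNVCall
from . import intervals as iv


def reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    """Reciprocal overlap of two calls; 0.0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    return iv.reciprocal_overlap(a.interval, b.interval)


@dataclass(frozen=True, slots=True)
class FrequencyResult:
    call: CNVCall
    carrier_count: int  # distinct samples carrying an equivalent call, incl. self
    dataset_size: int
    @property
    def frequency(self) -> float:
        return self.carrier_count / self.dataset_size


class CallIndex:
    """Per-chromosome interval index over a call set for RO queries."""

    def __init__(self, calls: list[CNVCall]):
        self.calls = calls
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for c in calls:
            # closed interval -> half-open tree coordinates
            self._trees[c.chrom].addi(c.start, c.end + 1, c)
        self.samples = {c.sample_id for c in calls}
        self.platform_samples: dict[str | None, set[str]] = defaultdict(set)
        for c in calls:
            self.platform_samples[c.platform].add(c.sample_id)

    def overlapping(self, call: CNVCall) -> list[CNVCall]:
        tree = self._trees.get(call.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(call.start, call.end + 1)]

    def carriers(
        self, call: CNVCall, ro_threshold: float, same_type: bool
    ) -> set[str]:
        """Distinct sample_ids owning >=1 equivalent call (always incl. self)."""
        out = {call.sample_id}
        for other in self.overlapping(call):
            if same_type and other.cnv_type != call.cnv_type:
                continue
            if reciprocal_overlap(call, other) >= ro_threshold:
                out.add(other.sample_id)
        return out


def carrier_count(
    call: CNVCall,
    all_calls: list[CNVCall] | CallIndex,
    ro_threshold: float = 0.5,
    same_type: bool = True,
    *,
    dataset_size: int | None = None,
    stratify_by_platform: bool = False,
) -> FrequencyResult:
    """Count distinct samples in the overall dataset carrying this CNV.

    ``dataset_size`` defaults to the number of distinct samples present in
    ``all_calls``; pass the genotyped cohort size explicitly when samples
    without calls exist.  With ``stratify_by_platform`` both the carriers
    and the denominator are restricted to the call's platform.
    """
    if not 0.0 < ro_threshold <= 1.0:
        raise ValueError("ro_threshold must lie in (0, 1]")
    index = all_calls if isinstance(all_calls, CallIndex) else CallIndex(all_calls)
    if not index.calls:
        raise ValueError("overall dataset is empty: dataset_size must be > 0")
    carriers = index.carriers(call, ro_threshold, same_type)
    if stratify_by_platform:
        stratum = index.platform_samples.get(call.platform, set())
        carriers = {s for s in carriers if s in stratum} | {call.sample_id}
        n = dataset_size if dataset_size is not None else max(len(stratum), 1)
    else:
        n = dataset_size if dataset_size is not None else len(index.samples)
    if n <= 0:
        raise ValueError("dataset_size must be > 0")
    return FrequencyResult(call=call, carrier_count=len(carriers), dataset_size=n)


def filter_rare(
    calls: list[CNVCall],
    all_calls: list[CNVCall] | CallIndex,
    max_freq: float = 0.01,
    ro_threshold: float = 0.5,
    same_type: bool = True,
    *,
    dataset_size: int | None = None,
    stratify_by_platform: bool = False,
) -> list[CNVCall]:
    """Retain exactly the calls with carrier frequency strictly < ``max_freq``.

    Input order is preserved.  The strict inequality means a call at
    exactly the threshold (e.g. 2 carriers in 200 at 1%) is removed.
    """
    if not 0.0 < max_freq <= 1.0:
        raise ValueError("max_freq must lie in (0, 1]")
    index = all_calls if isinstance(all_calls, CallIndex) else CallIndex(all_calls)
    out = []
    for call in calls:
        freq = carrier_count(
            call,
            index,
            ro_threshold,
            same_type,
            dataset_size=dataset_size,
            stratify_by_platform=stratify_by_platform,
        ).frequency
        if freq < max_freq:
            out.append(call)
    return out
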