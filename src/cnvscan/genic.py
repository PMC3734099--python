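"""Genic/intergenic classification against the gene annotation.

A call is *genic* when its interval shares at least one base with any
gene span (full transcript span, strand-agnostic); otherwise it is
*intergenic*.  No minimum overlap fraction applies: touching a gene's
first or last base is enough.  An exon-level mode restricts the mask to
exon intervals supplied by the caller.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from intervaltree import IntervalTree

from .model import CNVCall, GeneModel

logger = logging.getLogger(__name__)

GENIC = "genic"
INTERGENIC = "intergenic"


class GeneIndex:
    """Per-chromosome interval index over gene (or exon) spans."""

    def __init__(self, genes: list[GeneModel], mode: str = "span",
                 exons: list[tuple[str, int, int]] | None = None):
        if mode not in ("span", "exon"):
            raise ValueError(f"genic mode must be 'span' or 'exon', got {mode!r}")
        self.mode = mode
        self.genes = genes
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        if mode == "span":
            for g in genes:
                self._trees[g.chrom].addi(g.start, g.end + 1, g)
        else:
            if exons is None:
                raise ValueError("exon mode requires an exon interval list")
            for chrom, start, end in exons:
                self._trees[chrom].addi(start, end + 1, None)

    def hits(self, call: CNVCall) -> list:
        tree = self._trees.get(call.chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(call.start, call.end + 1))


def classify_genic(call: CNVCall, genes: list[GeneModel] | GeneIndex) -> str:
    """Return 'genic' if the call intersects any gene span, else 'intergenic'."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return GENIC if index.hits(call) else INTERGENIC


def filter_intergenic(
    calls: list[CNVCall],
    genes: list[GeneModel] | GeneIndex,
    *,
    log: list[tuple[CNVCall, str]] | None = None,
) -> list[CNVCall]:
    """Retain exactly the intergenic calls, preserving order.

    When ``log`` is supplied every per-call classification is appended to
    it, so genic and intergenic calls together partition the input.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    out = []
    for call in calls:
        status = classify_genic(call, index)
        if log is not None:
            log.append((call, status))
        logger.debug(
            "%s:%d-%d %s -> %s", call.chrom, call.start, call.end,
            call.sample_id, status,
        )
        if status == INTERGENIC:
            out.append(call)
    return out
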