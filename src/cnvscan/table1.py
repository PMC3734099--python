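"""Packaged reference call set: the 45 published intergenic ASD CNVs.

The fixture transcribes the published locus table verbatim — 15 locus
entries, 45 CNV rows across 41 unrelated cohort cases plus one
literature-reported case (SK0167-003).  Coordinates are 1-based closed on
an hg18-era build and every row satisfies size = end - start.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .model import CNVCall, CNVType, Cohort

LITERATURE_SAMPLES = frozenset({"SK0167-003"})

#: Size of the screened case cohort the published fraction refers to.
PUBLISHED_COHORT_SIZE = 1491


@dataclass(frozen=True, slots=True)
class Table1Row:
    """One fixture CNV with its published locus-level labels."""

    entry: int  # 1..15, ordinal of the locus entry in the table
    locus: str  # cytoband label (not unique: two 11p12 entries)
    gene: str  # flanking gene symbol(s), ';'-separated
    furthest_distance: str  # printed distance(s), ';'-separated, units kb-scale
    bin: str  # published mechanism bin ('i', 'ii', 'iii', 'i or ii')
    call: CNVCall


def load_table1_fixture() -> list[Table1Row]:
    """Load the packaged 45-row reference call set.

    Raises RuntimeError if the fixture is missing or fails its internal
    size identity (size = end - start on every row).
    """
    try:
        text = (
            resources.files("cnvscan.data").joinpath("table1_cnvs.tsv").read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RuntimeError(f"packaged reference fixture missing: {exc}") from exc
    rows: list[Table1Row] = []
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    expected = [
        "entry", "locus", "chrom", "gene", "sample_id", "cnv_type",
        "start", "end", "size", "furthest_distance", "bin",
    ]
    if header != expected:
        raise RuntimeError(f"reference fixture corrupt: header {header}")
    for line_no, line in enumerate(lines[1:], start=2):
        f = dict(zip(header, line.split("\t")))
        call = CNVCall(
            chrom=f["chrom"],
            start=int(f["start"]),
            end=int(f["end"]),
            cnv_type=CNVType.parse(f["cnv_type"]),
            sample_id=f["sample_id"],
            cohort=Cohort.CASE,
        )
        if call.size != int(f["size"]):
            raise RuntimeError(
                f"reference fixture corrupt at line {line_no}: "
                f"end - start = {call.size} != printed size {f['size']}"
            )
        rows.append(
            Table1Row(
                entry=int(f["entry"]),
                locus=f["locus"],
                gene=f["gene"],
                furthest_distance=f["furthest_distance"],
                bin=f["bin"],
                call=call,
            )
        )
    if len(rows) != 45:
        raise RuntimeError(f"reference fixture corrupt: {len(rows)} rows, expected 45")
    return rows


def table1_calls() -> list[CNVCall]:
    return [row.call for row in load_table1_fixture()]


def default_candidate_genes() -> set[str]:
    """The packaged ASD candidate-gene list (the fixture's gene column)."""
    text = (
        resources.files("cnvscan.data").joinpath("candidate_genes.txt").read_text()
    )
    return {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
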