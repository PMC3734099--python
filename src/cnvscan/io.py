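"""Readers and writers for the screen's standard-format inputs and outputs.

CNV call sets are BED-like tab-separated files whose coordinates are taken
verbatim (1-based closed, the convention of published CNV call tables);
pass ``coords="bed"`` for true 0-based half-open BED.  Gene annotation is
GFF3 (via gffutils) or BED; auxiliary tracks are BED; pedigrees are
3-column TSV.  BED coordinates are shifted to the internal 1-based closed
convention on read and shifted back on write.
"""

from __future__ import annotations

import logging
import sys
import warnings
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import gffutils

from .model import (
    CandidateRegion,
    CNVCall,
    CNVType,
    Cohort,
    EvidenceTrack,
    GeneModel,
    Pedigree,
    TrackName,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

CNV_BED_COLUMNS = ("chrom", "start", "end", "cnv_type", "sample_id", "platform", "family_id")

REPORT_COLUMNS = (
    "locus_id",
    "chrom",
    "region_start",
    "region_end",
    "gene",
    "distance_bp",
    "sample",
    "cnv_type",
    "start",
    "end",
    "size",
    "inheritance",
    "bin",
)

_SEX_CHROMS = {"X", "Y"}


class ParseError(ValueError):
    """Fatal parse failure, carrying path and line context."""


def _warn_sex_chrom(chrom: str, path) -> None:
    warnings.warn(
        f"{path}: sex chromosome {chrom!r} accepted, but carrier-frequency "
        "handling is naive (no copy-number ploidy adjustment)",
        stacklevel=3,
    )


def read_cnv_bed(
    path: str | Path,
    cohort: Cohort | str,
    *,
    coords: str = "1-closed",
    rejected: list[tuple[int, str, str]] | None = None,
) -> list[CNVCall]:
    """Read a CNV call set: chrom, start, end, type, sample[, platform[, family]].

    Comment (#) and header lines are skipped; type tokens are normalized
    case-insensitively (DEL/deletion -> loss, DUP/duplication -> gain).
    Malformed records are rejected individually: each is logged and, when a
    ``rejected`` list is supplied, appended as (line_no, line, reason).
    """
    cohort = Cohort(cohort)
    shift = 1 if coords == "bed" else 0
    if coords not in ("1-closed", "bed"):
        raise ValueError(f"coords must be '1-closed' or 'bed', got {coords!r}")
    calls: list[CNVCall] = []
    seen_sex: set[str] = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chr", "chromosome", "track"):
                continue  # header
            try:
                if len(fields) < 5:
                    raise ValueError(f"expected >=5 columns, got {len(fields)}")
                chrom = normalize_chrom(fields[0])
                start = int(fields[1]) + shift
                end = int(fields[2])
                if start < 0 or end < 0:
                    raise ValueError("negative coordinate")
                cnv_type = CNVType.parse(fields[3])
                sample_id = fields[4].strip()
                if not sample_id:
                    raise ValueError("empty sample id")
                platform = fields[5].strip() or None if len(fields) > 5 else None
                if platform == ".":
                    platform = None
                family = fields[6].strip() or None if len(fields) > 6 else None
                if family == ".":
                    family = None
                call = CNVCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    sample_id=sample_id,
                    cohort=cohort,
                    platform=platform,
                    family_id=family,
                )
            except ValueError as exc:
                logger.warning("%s:%d: rejected record: %s", path, line_no, exc)
                if rejected is not None:
                    rejected.append((line_no, line, str(exc)))
                continue
            if call.chrom in _SEX_CHROMS and call.chrom not in seen_sex:
                seen_sex.add(call.chrom)
                _warn_sex_chrom(call.chrom, path)
            calls.append(call)
    return calls


def write_cnv_bed(calls: Iterable[CNVCall], path: str | Path) -> None:
    """Write calls in the 7-column TSV this package reads ('.' for missing)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CNV_BED_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    (
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        c.cnv_type.value,
                        c.sample_id,
                        c.platform or ".",
                        c.family_id or ".",
                    )
                )
                + "\n"
            )


def read_gene_annotation(path: str | Path, fmt: str = "gff3") -> list[GeneModel]:
    """Read gene spans from GFF3 (features of type 'gene') or BED.

    BED intervals (0-based half-open) are converted to the internal 1-based
    closed convention; GFF3 is already 1-based closed.
    """
    if fmt == "gff3":
        return _read_genes_gff3(path)
    if fmt == "bed":
        return _read_genes_bed(path)
    raise ValueError(f"fmt must be 'gff3' or 'bed', got {fmt!r}")


def _read_genes_gff3(path: str | Path) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a zoo of types
        raise ParseError(f"{path}: cannot parse GFF3: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gene_id = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
            or f"{feat.seqid}:{feat.start}-{feat.end}"
        )
        strand = feat.strand if feat.strand in ("+", "-") else "?"
        genes.append(
            GeneModel(
                chrom=normalize_chrom(feat.seqid),
                start=feat.start,
                end=feat.end,
                gene_id=gene_id,
                strand=strand,
            )
        )
    return genes


def _read_genes_bed(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom = normalize_chrom(fields[0])
                start = int(fields[1]) + 1  # BED -> 1-based closed
                end = int(fields[2])
                gene_id = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "?"
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{line_no}: bad BED gene record: {exc}") from exc
            genes.append(GeneModel(chrom, start, end, gene_id, strand))
    return genes


def read_track(path: str | Path, name: TrackName | str) -> EvidenceTrack:
    """Read a BED interval track (common-variant, repeat, EST/mRNA, conserved)."""
    name = TrackName(name)
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom = normalize_chrom(fields[0])
                start = int(fields[1]) + 1
                end = int(fields[2])
                label = fields[3] if len(fields) > 3 else name.value
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{line_no}: bad BED record: {exc}") from exc
            intervals.append((chrom, start, end, label))
    return EvidenceTrack(name=name, intervals=intervals)


def write_track(track: EvidenceTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in track.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{label}\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column TSV (proband, father, mother); 'NA' or '.' = missing."""
    trios: dict[str, tuple[str | None, str | None]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("proband", "sample", "child"):
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{line_no}: expected 3 columns")
            proband = fields[0].strip()
            father = None if fields[1].strip() in ("NA", ".", "") else fields[1].strip()
            mother = None if fields[2].strip() in ("NA", ".", "") else fields[2].strip()
            trios[proband] = (father, mother)
    return Pedigree(trios=trios)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#proband\tfather\tmother\n")
        for proband in sorted(pedigree.trios):
            father, mother = pedigree.trios[proband]
            fh.write(f"{proband}\t{father or 'NA'}\t{mother or 'NA'}\n")


def read_candidate_genes(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_region_report(
    regions: Sequence[CandidateRegion],
    path: str | Path | TextIO,
    *,
    annotations: dict[str, object] | None = None,
    inheritance: dict[tuple[str, str, int, int], str] | None = None,
) -> None:
    """Write the per-CNV region report (one line per member, grouped by region).

    Ordering is deterministic: regions by (chrom-sortable, start), members by
    (start, end, sample_id).  ``annotations`` maps region_id to a
    LocusAnnotation; ``inheritance`` maps (sample, chrom, start, end) to a
    status string; missing annotation fields are emitted as '.'.
    """
    annotations = annotations or {}
    inheritance = inheritance or {}

    def chrom_key(chrom: str):
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom)

    close = False
    if isinstance(path, (str, Path)):
        fh: TextIO = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for region in sorted(regions, key=lambda r: (chrom_key(r.chrom), r.start)):
            ann = annotations.get(region.region_id)
            gene = getattr(ann, "nearest_gene", None) or "."
            dist = getattr(ann, "nearest_distance_bp", None)
            dist_s = str(dist) if dist is not None else "."
            bins = getattr(ann, "bin", None)
            bin_s = ",".join(sorted(bins)) if bins else "."
            for m in sorted(region.members, key=lambda c: (c.start, c.end, c.sample_id)):
                status = inheritance.get((m.sample_id, m.chrom, m.start, m.end), ".")
                fh.write(
                    "\t".join(
                        (
                            region.region_id,
                            region.chrom,
                            str(region.start),
                            str(region.end),
                            gene,
                            dist_s,
                            m.sample_id,
                            m.cnv_type.value,
                            str(m.start),
                            str(m.end),
                            str(m.size),
                            status,
                            bin_s,
                        )
                    )
                    + "\n"
                )
    finally:
        if close:
            fh.close()
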