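"""End-to-end orchestration of the intergenic CNV screen.

Stage order is fixed: load -> rarity -> intergenic -> overlap clustering ->
locus merge -> recurrence -> control absence -> common-variant -> repeat ->
annotate -> report.  Locus merging precedes the region-level filters so
that recurrence counts unrelated carriers per locus, not per sub-cluster.
All outputs (region report TSV, filter-trail JSON lines, summary) are
deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import genic, rarity, regions as rg
from . import io as cio
from . import table1
from .model import (
    CandidateRegion,
    CNVCall,
    CohortConfig,
    Cohort,
    EvidenceTrack,
    FilterThresholds,
    Pedigree,
    TrackName,
)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class ScreenInputs:
    case_calls: list[CNVCall]
    control_calls: list[CNVCall]
    parent_calls: list[CNVCall] = field(default_factory=list)
    genes: list = field(default_factory=list)
    tracks: dict[str, EvidenceTrack] = field(default_factory=dict)
    pedigree: Pedigree | None = None
    candidate_genes: set[str] = field(default_factory=set)
    dataset_size: int | None = None  # genotyped samples; default: observed


@dataclass(slots=True)
class ScreenResult:
    regions: list[CandidateRegion]
    annotations: dict[str, ann.LocusAnnotation]
    inheritance: dict[tuple[str, str, int, int], str]
    summary: dict[str, int]

    def summary_json(self) -> str:
        return json.dumps(self.summary, indent=1, sort_keys=False) + "\n"


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "inputs" not in cfg:
        raise ValueError(f"{path}: config must define an 'inputs' block")
    return cfg


def load_inputs(cfg: dict, base_dir: Path | None = None) -> ScreenInputs:
    """Resolve and read every input file named by the config's inputs block."""
    inp = cfg["inputs"]
    base = base_dir or Path(".")

    def path_of(value) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    def read_calls(key: str, cohort: Cohort) -> list[CNVCall]:
        value = inp.get(key)
        if value is None:
            return []
        paths = value if isinstance(value, list) else [value]
        calls: list[CNVCall] = []
        for p in paths:
            calls.extend(cio.read_cnv_bed(path_of(p), cohort))
        return calls

    # fail fast on missing files, before any stage runs
    for key in ("cases", "controls", "parents", "genes", "pedigree"):
        value = inp.get(key)
        if value is None:
            continue
        for p in value if isinstance(value, list) else [value]:
            if not path_of(p).exists():
                raise FileNotFoundError(f"input '{key}': {path_of(p)} does not exist")
    for name, p in (inp.get("tracks") or {}).items():
        if not path_of(p).exists():
            raise FileNotFoundError(f"track '{name}': {path_of(p)} does not exist")

    genes = []
    if inp.get("genes"):
        genes = cio.read_gene_annotation(
            path_of(inp["genes"]), fmt=inp.get("genes_format", "gff3")
        )
    tracks = {
        name: cio.read_track(path_of(p), TrackName(name))
        for name, p in (inp.get("tracks") or {}).items()
    }
    pedigree = cio.read_pedigree(path_of(inp["pedigree"])) if inp.get("pedigree") else None
    if inp.get("candidate_genes"):
        candidates = cio.read_candidate_genes(path_of(inp["candidate_genes"]))
    else:
        candidates = table1.default_candidate_genes()
    return ScreenInputs(
        case_calls=read_calls("cases", Cohort.CASE),
        control_calls=read_calls("controls", Cohort.CONTROL),
        parent_calls=read_calls("parents", Cohort.PARENT),
        genes=genes,
        tracks=tracks,
        pedigree=pedigree,
        candidate_genes=candidates,
        dataset_size=inp.get("dataset_size"),
    )


def inputs_from_cohort(cohort) -> ScreenInputs:
    """Screen inputs for an in-memory simulated cohort.

    The rarity denominator is the genotyped cohort size (cases + controls),
    not just the samples that happen to carry calls.
    """
    return ScreenInputs(
        case_calls=list(cohort.case_calls),
        control_calls=list(cohort.control_calls),
        parent_calls=list(cohort.parent_calls),
        genes=list(cohort.genes),
        tracks=dict(cohort.tracks),
        pedigree=cohort.pedigree,
        candidate_genes=set(),
        dataset_size=cohort.config.n_cases + cohort.config.n_controls,
    )


def cohort_config_from(cfg: dict) -> CohortConfig:
    r = cfg.get("rarity", {})
    g = cfg.get("genic", {})
    f = cfg.get("filters", {})
    return CohortConfig(
        max_freq=r.get("max_freq", 0.01),
        ro_threshold=r.get("ro_threshold", 0.5),
        same_type=r.get("same_type", True),
        stratify_by_platform=r.get("stratify_by_platform", False),
        genic_mode=g.get("mode", "span"),
        thresholds=FilterThresholds(
            min_cases=f.get("min_cases", 2),
            max_control_carriers=f.get("max_control_carriers", 0),
            dgv_max_overlap=f.get("dgv_max_overlap", 0.5),
            repeat_max_fraction=f.get("repeat_max_fraction", 0.8),
            locus_merge_gap=f.get("locus_merge_gap", 1_000_000),
        ),
        build=cfg.get("build", "unspecified"),
    )


def run_screen(
    inputs: ScreenInputs,
    config: CohortConfig | None = None,
    *,
    skip_filters: frozenset[str] | set[str] = frozenset(),
    annotate_window_bp: int | None = None,
) -> ScreenResult:
    """Execute the full screen on loaded inputs.

    ``skip_filters`` may name any of: rarity, intergenic, recurrence,
    control_absence, common_variant, repeat (for ablation runs).
    """
    cc = config or CohortConfig()
    th = cc.thresholds
    window = annotate_window_bp if annotate_window_bp is not None else th.locus_merge_gap
    summary: dict[str, int] = {}
    summary["case_calls_loaded"] = len(inputs.case_calls)
    summary["control_calls_loaded"] = len(inputs.control_calls)

    calls = list(inputs.case_calls)
    if "rarity" not in skip_filters and calls:
        pooled = rarity.CallIndex(inputs.case_calls + inputs.control_calls)
        calls = rarity.filter_rare(
            calls,
            pooled,
            max_freq=cc.max_freq,
            ro_threshold=cc.ro_threshold,
            same_type=cc.same_type,
            dataset_size=inputs.dataset_size,
            stratify_by_platform=cc.stratify_by_platform,
        )
    summary["after_rarity"] = len(calls)

    if "intergenic" not in skip_filters and inputs.genes:
        calls = genic.filter_intergenic(calls, inputs.genes)
    summary["after_intergenic"] = len(calls)

    clusters = rg.overlap_clusters(calls)
    summary["overlap_clusters"] = len(clusters)
    region_list = rg.merge_loci(clusters, th.locus_merge_gap)
    summary["merged_loci"] = len(region_list)

    if "recurrence" not in skip_filters:
        region_list = rg.recurrence_filter(region_list, th.min_cases, inputs.pedigree)
    summary["after_recurrence"] = len(region_list)
    if "control_absence" not in skip_filters:
        region_list = rg.control_absence_filter(
            region_list, inputs.control_calls, th.max_control_carriers,
            same_type=cc.same_type,
        )
    summary["after_control_absence"] = len(region_list)
    if "common_variant" not in skip_filters:
        region_list = rg.dgv_filter(
            region_list, inputs.tracks.get("common_variant"), th.dgv_max_overlap
        )
    summary["after_common_variant"] = len(region_list)
    if "repeat" not in skip_filters:
        region_list = rg.repeat_filter(
            region_list, inputs.tracks.get("repeat"), th.repeat_max_fraction
        )
    summary["after_repeat"] = len(region_list)

    annotations = {
        region.region_id: ann.annotate_region(
            region,
            inputs.genes,
            list(inputs.tracks.values()),
            inputs.candidate_genes,
            window_bp=window,
        )
        for region in region_list
    }
    inheritance: dict[tuple[str, str, int, int], str] = {}
    if inputs.pedigree is not None:
        for region in region_list:
            for m in region.members:
                call = ann.determine_inheritance(
                    m, inputs.parent_calls, inputs.pedigree, cc.ro_threshold
                )
                inheritance[(m.sample_id, m.chrom, m.start, m.end)] = call.status
    summary["reported_regions"] = len(region_list)
    summary["reported_samples"] = len(
        {s for region in region_list for s in region.sample_ids}
    )
    return ScreenResult(
        regions=region_list,
        annotations=annotations,
        inheritance=inheritance,
        summary=summary,
    )


def write_outputs(result: ScreenResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "regions.tsv",
        "filter_trail": outdir / "filter_trail.jsonl",
        "summary": outdir / "summary.json",
    }
    cio.write_region_report(
        result.regions,
        paths["report"],
        annotations=result.annotations,
        inheritance=result.inheritance,
    )
    with open(paths["filter_trail"], "w") as fh:
        for region in result.regions:
            for entry in region.filter_trail:
                fh.write(
                    json.dumps(
                        {
                            "region_id": region.region_id,
                            "chrom": region.chrom,
                            "start": region.start,
                            "end": region.end,
                            **entry,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
    with open(paths["summary"], "w") as fh:
        fh.write(result.summary_json())
    return paths


def run_screen_from_config(
    config_path: str | Path,
    outdir: str | Path | None = None,
    *,
    skip_filters: frozenset[str] | set[str] = frozenset(),
) -> ScreenResult:
    cfg = load_config(config_path)
    inputs = load_inputs(cfg, base_dir=Path(config_path).parent)
    result = run_screen(
        inputs,
        cohort_config_from(cfg),
        skip_filters=skip_filters,
        annotate_window_bp=(cfg.get("annotate") or {}).get("window_bp"),
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


# ---------------------------------------------------------------------------
# Reference-table regression
# ---------------------------------------------------------------------------

def regression_table1(locus_merge_gap: int = 1_000_000) -> list[str]:
    """Re-derive the published loci from the packaged 45-CNV reference set
    and diff the result against the transcription.

    Clustering and 1 Mb locus merging are run on the raw fixture calls
    (the published table reports the post-filter screen, so the remaining
    filters are vacuous here); the discovered loci are compared against
    the table's own entry labels: locus count, per-locus member samples,
    the size identity of every row, and the samples hitting several loci.
    Returns a list of human-readable diff strings (empty = exact match).
    """
    rows = table1.load_table1_fixture()
    diffs: list[str] = []
    # frozen summary expectations of the published table, independent of the
    # fixture contents, so a corrupted transcription cannot self-validate
    if len(rows) != 45:
        diffs.append(f"row count: fixture has {len(rows)}, table prints 45")
    all_samples = {r.call.sample_id for r in rows}
    if len(all_samples) != 42:
        diffs.append(f"distinct samples: {len(all_samples)}, table prints 42")
    for row in rows:
        if row.call.size != row.call.end - row.call.start:
            diffs.append(f"size mismatch in row {row.call.sample_id}@{row.locus}")

    expected_by_entry: dict[int, set[str]] = {}
    entry_label: dict[int, str] = {}
    for row in rows:
        expected_by_entry.setdefault(row.entry, set()).add(row.call.sample_id)
        entry_label[row.entry] = row.locus

    discovered = rg.merge_loci(rg.overlap_clusters([r.call for r in rows]), locus_merge_gap)
    if locus_merge_gap == 1_000_000 and len(discovered) != 15:
        diffs.append(f"locus count: discovered {len(discovered)}, table lists 15")
    elif len(discovered) != len(expected_by_entry):
        diffs.append(
            f"locus count: discovered {len(discovered)}, "
            f"table lists {len(expected_by_entry)}"
        )

    # map each discovered region to the fixture entries of its members
    call_entry = {
        (r.call.sample_id, r.call.chrom, r.call.start, r.call.end): r.entry
        for r in rows
    }
    region_entries: dict[int, set[str]] = {}
    for region in discovered:
        entries = {
            call_entry[(m.sample_id, m.chrom, m.start, m.end)]
            for m in region.members
        }
        if len(entries) != 1:
            diffs.append(
                f"{region.region_id} ({region.chrom}:{region.start}-{region.end}) "
                f"mixes table entries {sorted(entries)}"
            )
            continue
        entry = entries.pop()
        if entry in region_entries:
            diffs.append(f"table entry {entry_label[entry]} split across loci")
        region_entries[entry] = region.sample_ids
    for entry, expected_samples in sorted(expected_by_entry.items()):
        got = region_entries.get(entry)
        if got is None:
            diffs.append(f"table entry {entry_label[entry]} not recovered")
        elif got != expected_samples:
            diffs.append(
                f"{entry_label[entry]}: samples {sorted(got)} != "
                f"table {sorted(expected_samples)}"
            )

    # samples hitting several distinct loci
    hits = Counter()
    for entry, samples in expected_by_entry.items():
        for s in samples:
            hits[s] += 1
    expected_multi = {s for s, n in hits.items() if n >= 2}
    got_hits = Counter()
    for region in discovered:
        for s in region.sample_ids:
            got_hits[s] += 1
    got_multi = {s for s, n in got_hits.items() if n >= 2}
    if expected_multi != got_multi:
        diffs.append(
            f"multi-locus samples {sorted(got_multi)} != table {sorted(expected_multi)}"
        )
    return diffs
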