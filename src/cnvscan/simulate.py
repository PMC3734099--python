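"""Seeded synthetic cohort generator with exact ground truth.

Generates case/control/parent CNV call sets, a gene annotation and the four
evidence tracks with the statistical structure the screen assumes: planted
rare intergenic recurrent clusters (the true positives), common copy-number
polymorphisms shared by cases and controls (removed by the rarity filter),
genic decoy clusters (removed by the intergenic filter), a repeat decoy
cluster in >80%-masked sequence (removed by the repeat filter), per-sample
rare background calls, and trio structure with known inheritance.

Ground truth is exact by construction: planted loci are separated by more
than the locus-merge gap, and background calls are rejection-sampled so
that no two case samples share a background interval — hence no spurious
recurrent cluster can arise and the screen's expected output is exactly
the planted regions.
"""

from __future__ import annotations

import json
import math
import random
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

from intervaltree import IntervalTree

from . import io as cio
from .model import (
    CNVCall,
    CNVType,
    Cohort,
    EvidenceTrack,
    GeneModel,
    Pedigree,
    TrackName,
)

_PLACEMENT_TRIES = 2000


@dataclass(slots=True)
class SimulationConfig:
    """Desk-scale defaults: 2 chromosomes x 50 Mb, 150 cases, 150 controls.

    ``paper_scale()`` returns the full-cohort preset (1491 cases, 3644
    controls) for benchmarking; the desk scale is the test default.
    ``planted_cases_per_region`` defaults to 2 — the screen's recurrence
    minimum — which keeps planted clusters strictly below the 1% rarity
    cutoff in the 300-sample default cohort.
    """

    n_cases: int = 150
    n_controls: int = 150
    genome: tuple[tuple[str, int], ...] = (("1", 50_000_000), ("2", 50_000_000))
    n_genes: int = 40
    n_planted_regions: int = 5
    planted_cases_per_region: int = 2
    common_cnp_freq: float = 0.05
    n_common_cnp_loci: int = 3
    background_rate: float = 0.5
    repeat_fraction_target: float = 0.45
    trio_fraction: float = 0.5
    inherited_fraction: float = 1.0
    seed: int = 0
    n_genic_decoys: int | None = None  # default: 2 when planting, else 0
    n_repeat_decoys: int | None = None  # default: 1 when planting, else 0
    locus_separation: int = 1_200_000  # min distance between planted loci

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_planted_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_planted_regions and self.planted_cases_per_region < 2:
            raise ValueError("planted_cases_per_region must be >= 2")
        for name in (
            "common_cnp_freq", "repeat_fraction_target",
            "trio_fraction", "inherited_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if any(length <= 0 for _c, length in self.genome):
            raise ValueError("genome lengths must be > 0")
        if self.n_genic_decoys is None:
            self.n_genic_decoys = 2 if self.n_planted_regions else 0
        if self.n_repeat_decoys is None:
            self.n_repeat_decoys = 1 if self.n_planted_regions else 0

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SimulationConfig":
        return cls(
            n_cases=1491,
            n_controls=3644,
            genome=tuple((str(i), 100_000_000) for i in range(1, 11)),
            n_genes=400,
            n_planted_regions=15,
            planted_cases_per_region=3,
            seed=seed,
        )


@dataclass(slots=True)
class PlantedCluster:
    chrom: str
    start: int  # union span of member calls
    end: int
    sample_ids: list[str]
    kind: str  # planted | repeat_decoy | genic_decoy


@dataclass(slots=True)
class GroundTruth:
    planted_regions: list[PlantedCluster] = field(default_factory=list)
    repeat_decoys: list[PlantedCluster] = field(default_factory=list)
    genic_decoys: list[PlantedCluster] = field(default_factory=list)
    common_cnp_loci: list[tuple[str, int, int]] = field(default_factory=list)
    inheritance_labels: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def label_key(call: CNVCall) -> str:
        return f"{call.sample_id}|{call.chrom}|{call.start}|{call.end}"


@dataclass(slots=True)
class SimulatedCohort:
    config: SimulationConfig
    case_calls: list[CNVCall]
    control_calls: list[CNVCall]
    parent_calls: list[CNVCall]
    genes: list[GeneModel]
    tracks: dict[str, EvidenceTrack]
    pedigree: Pedigree
    ground_truth: GroundTruth


class _Placer:
    """Rejection-sampling placement of disjoint intervals on the genome."""

    def __init__(self, rng: random.Random, genome):
        self.rng = rng
        self.genome = list(genome)
        self.total = sum(length for _c, length in self.genome)
        self.trees: dict[str, dict[str, IntervalTree]] = defaultdict(
            lambda: defaultdict(IntervalTree)
        )

    def occupy(self, layer: str, chrom: str, start: int, end: int, pad: int = 0) -> None:
        self.trees[layer][chrom].addi(max(1, start - pad), end + pad + 1)

    def clear_of(self, layers, chrom: str, start: int, end: int) -> bool:
        return all(
            not self.trees[layer][chrom].overlap(start, end + 1) for layer in layers
        )

    def place(self, length: int, avoid_layers, pad: int = 0) -> tuple[str, int, int]:
        """Place a closed interval of size ``length`` (end - start) clear of
        the given layers (candidate expanded by ``pad`` for the check)."""
        for _ in range(_PLACEMENT_TRIES):
            r = self.rng.random() * self.total
            acc = 0
            chrom, clen = self.genome[-1]
            for c, ln in self.genome:
                acc += ln
                if r < acc:
                    chrom, clen = c, ln
                    break
            if clen <= length + 2 * pad + 2:
                continue
            start = self.rng.randint(1 + pad, clen - length - pad)
            end = start + length
            if self.clear_of(avoid_layers, chrom, start - pad, end + pad):
                return chrom, start, end
        raise RuntimeError(
            f"genome too small: failed to place an interval of {length} bp "
            f"clear of {sorted(avoid_layers)} after {_PLACEMENT_TRIES} tries"
        )


def _poisson(rng: random.Random, rate: float) -> int:
    if rate <= 0:
        return 0
    limit = math.exp(-rate)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _jitter(rng: random.Random, start: int, end: int, frac: float = 0.1) -> tuple[int, int]:
    """Perturb both ends by up to ``frac`` of the length, keeping start < end."""
    length = end - start
    d = max(1, int(length * frac))
    s = start + rng.randint(-d, d)
    e = end + rng.randint(-d, d)
    if s < 1:
        s = 1
    if e <= s:
        e = s + max(1, length // 2)
    return s, e


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate the full synthetic cohort; deterministic given config.seed."""
    cfg = config or SimulationConfig()
    rng = random.Random(cfg.seed)
    placer = _Placer(rng, cfg.genome)
    truth = GroundTruth()

    case_ids = [f"case_{i:04d}" for i in range(1, cfg.n_cases + 1)]
    control_ids = [f"control_{i:04d}" for i in range(1, cfg.n_controls + 1)]
    case_calls: list[CNVCall] = []
    control_calls: list[CNVCall] = []

    # ---- genes: non-overlapping spans --------------------------------------
    genes: list[GeneModel] = []
    for i in range(1, cfg.n_genes + 1):
        length = rng.randint(10_000, 200_000)
        chrom, start, end = placer.place(length, avoid_layers=("gene",), pad=1_000)
        placer.occupy("gene", chrom, start, end)
        genes.append(
            GeneModel(chrom, start, end, f"gene_{i:04d}", rng.choice("+-"))
        )
    genes.sort(key=lambda g: (g.chrom, g.start))

    # ---- planted rare intergenic recurrent clusters ------------------------
    def plant_cluster(kind: str, n_members: int, avoid, pad: int) -> PlantedCluster:
        length = rng.randint(20_000, 150_000)
        chrom, start, end = placer.place(length, avoid_layers=avoid, pad=pad)
        # wide padding keeps distinct planted loci outside each other's
        # locus-merge window and keeps jittered members intergenic
        placer.occupy("locus", chrom, start, end, pad=cfg.locus_separation)
        placer.occupy("locus_core", chrom, start, end, pad=int(0.2 * length) + 1_000)
        cnv_type = rng.choice((CNVType.LOSS, CNVType.GAIN))
        samples = rng.sample(case_ids, n_members)
        members = []
        for sid in samples:
            s, e = _jitter(rng, start, end)
            members.append(
                CNVCall(chrom, s, e, cnv_type, sid, Cohort.CASE, family_id=f"fam_{sid}")
            )
        case_calls.extend(members)
        return PlantedCluster(
            chrom=chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            sample_ids=sorted(samples),
            kind=kind,
        )

    planted_pad = int(0.2 * 150_000) + 2_000
    for _ in range(cfg.n_planted_regions):
        truth.planted_regions.append(
            plant_cluster(
                "planted",
                cfg.planted_cases_per_region,
                avoid=("gene", "locus", "locus_core", "cnp"),
                pad=planted_pad,
            )
        )
    for _ in range(cfg.n_repeat_decoys or 0):
        truth.repeat_decoys.append(
            plant_cluster(
                "repeat_decoy",
                max(2, cfg.planted_cases_per_region),
                avoid=("gene", "locus", "locus_core", "cnp"),
                pad=planted_pad,
            )
        )

    # ---- genic decoy clusters: recurrent case CNVs inside genes ------------
    for _ in range(cfg.n_genic_decoys or 0):
        if not genes:
            break
        gene = rng.choice(genes)
        length = max(2_000, (gene.end - gene.start) // 2)
        mid = (gene.start + gene.end) // 2
        start, end = mid - length // 2, mid - length // 2 + length
        cnv_type = rng.choice((CNVType.LOSS, CNVType.GAIN))
        samples = rng.sample(case_ids, max(2, cfg.planted_cases_per_region))
        members = []
        for sid in samples:
            s, e = _jitter(rng, start, end)
            members.append(
                CNVCall(gene.chrom, s, e, cnv_type, sid, Cohort.CASE,
                        family_id=f"fam_{sid}")
            )
        case_calls.extend(members)
        truth.genic_decoys.append(
            PlantedCluster(
                chrom=gene.chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                sample_ids=sorted(samples),
                kind="genic_decoy",
            )
        )

    # ---- common copy-number polymorphisms ----------------------------------
    n_cnp = cfg.n_common_cnp_loci if cfg.common_cnp_freq > 0 else 0
    for _ in range(n_cnp):
        length = rng.randint(10_000, 100_000)
        chrom, start, end = placer.place(
            length, avoid_layers=("locus", "locus_core", "cnp"), pad=20_000
        )
        placer.occupy("cnp", chrom, start, end, pad=int(0.2 * length) + 1_000)
        cnv_type = rng.choice((CNVType.LOSS, CNVType.GAIN))
        n_case_carriers = max(1, math.ceil(cfg.common_cnp_freq * cfg.n_cases))
        n_ctrl_carriers = max(1, math.ceil(cfg.common_cnp_freq * cfg.n_controls))
        for sid in rng.sample(case_ids, min(n_case_carriers, cfg.n_cases)):
            s, e = _jitter(rng, start, end, frac=0.05)
            case_calls.append(
                CNVCall(chrom, s, e, cnv_type, sid, Cohort.CASE, family_id=f"fam_{sid}")
            )
        for sid in rng.sample(control_ids, min(n_ctrl_carriers, cfg.n_controls)):
            s, e = _jitter(rng, start, end, frac=0.05)
            control_calls.append(
                CNVCall(chrom, s, e, cnv_type, sid, Cohort.CONTROL)
            )
        truth.common_cnp_loci.append((chrom, start, end))

    # ---- rare background calls ---------------------------------------------
    # case backgrounds are mutually disjoint across samples (layer case_bg),
    # so no spurious recurrent cluster can form
    for sid in case_ids:
        for _ in range(_poisson(rng, cfg.background_rate)):
            length = rng.randint(5_000, 50_000)
            chrom, start, end = placer.place(
                length, avoid_layers=("locus", "cnp", "case_bg"), pad=500
            )
            placer.occupy("case_bg", chrom, start, end)
            case_calls.append(
                CNVCall(chrom, start, end, rng.choice((CNVType.LOSS, CNVType.GAIN)),
                        sid, Cohort.CASE, family_id=f"fam_{sid}")
            )
    for sid in control_ids:
        for _ in range(_poisson(rng, cfg.background_rate)):
            length = rng.randint(5_000, 50_000)
            chrom, start, end = placer.place(
                length, avoid_layers=("locus", "cnp"), pad=500
            )
            control_calls.append(
                CNVCall(chrom, start, end, rng.choice((CNVType.LOSS, CNVType.GAIN)),
                        sid, Cohort.CONTROL)
            )

    # ---- trios and inheritance ----------------------------------------------
    n_trios = round(cfg.trio_fraction * cfg.n_cases)
    trio_ids = set(rng.sample(case_ids, n_trios)) if n_trios else set()
    pedigree = Pedigree(
        trios={sid: (f"{sid}_fa", f"{sid}_mo") for sid in sorted(trio_ids)}
    )
    parent_calls: list[CNVCall] = []
    labelled = [
        m
        for cluster in truth.planted_regions + truth.repeat_decoys
        for m in case_calls
        if m.sample_id in cluster.sample_ids
        and m.chrom == cluster.chrom
        and m.start >= cluster.start
        and m.end <= cluster.end
    ]
    seen: set[str] = set()
    for call in labelled:
        key = GroundTruth.label_key(call)
        if key in seen:
            continue
        seen.add(key)
        if call.sample_id not in trio_ids:
            continue
        father, mother = pedigree.parents_of(call.sample_id)
        if rng.random() < cfg.inherited_fraction:
            parent_id, status = rng.choice(
                ((mother, "inherited_maternal"), (father, "inherited_paternal"))
            )
            s, e = _jitter(rng, call.start, call.end)
            parent_calls.append(
                CNVCall(call.chrom, s, e, call.cnv_type, parent_id, Cohort.PARENT)
            )
            truth.inheritance_labels[key] = status
        else:
            truth.inheritance_labels[key] = "de_novo"

    # ---- evidence tracks -----------------------------------------------------
    tracks = {
        "repeat": _build_repeat_track(cfg, rng, placer, truth),
        "common_variant": EvidenceTrack(
            TrackName.COMMON_VARIANT,
            [(c, s, e, f"cnp_{i:03d}") for i, (c, s, e) in
             enumerate(truth.common_cnp_loci, start=1)],
        ),
        "expressed_sequence": _build_est_track(rng, truth, genes),
        "conserved_element": _build_conserved_track(rng, placer, truth),
    }

    case_calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    control_calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    parent_calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    return SimulatedCohort(
        config=cfg,
        case_calls=case_calls,
        control_calls=control_calls,
        parent_calls=parent_calls,
        genes=genes,
        tracks=tracks,
        pedigree=pedigree,
        ground_truth=truth,
    )


def _build_repeat_track(
    cfg: SimulationConfig,
    rng: random.Random,
    placer: _Placer,
    truth: GroundTruth,
) -> EvidenceTrack:
    """Repeat-mask track: background coverage toward the target fraction,
    plus near-complete masking (~96%) over each repeat-decoy cluster."""
    intervals: list[tuple[str, int, int, str]] = []
    for i, decoy in enumerate(truth.repeat_decoys, start=1):
        span = decoy.end - decoy.start
        gap = max(1, span // 50)  # two small unmasked gaps -> ~96% coverage
        cut1 = decoy.start + span // 3
        cut2 = decoy.start + 2 * span // 3
        intervals.extend(
            [
                (decoy.chrom, decoy.start, cut1, f"decoy_{i}a"),
                (decoy.chrom, cut1 + gap, cut2, f"decoy_{i}b"),
                (decoy.chrom, cut2 + gap, decoy.end, f"decoy_{i}c"),
            ]
        )
    target = cfg.repeat_fraction_target * placer.total
    placed = sum(e - s + 1 for _c, s, e, _l in intervals)
    i = 0
    while placed < target:
        length = rng.randint(50_000, 500_000)
        try:
            chrom, start, end = placer.place(
                length, avoid_layers=("locus", "locus_core", "repeat"), pad=1_000
            )
        except RuntimeError:
            break  # best effort: genome saturated
        placer.occupy("repeat", chrom, start, end)
        i += 1
        intervals.append((chrom, start, end, f"rep_{i:05d}"))
        placed += length + 1
    intervals.sort()
    return EvidenceTrack(TrackName.REPEAT, intervals)


def _build_est_track(
    rng: random.Random, truth: GroundTruth, genes: list[GeneModel]
) -> EvidenceTrack:
    """EST/mRNA evidence over alternating planted regions; odd regions get a
    gene-linked interval stretching from the region toward its nearest gene."""
    intervals: list[tuple[str, int, int, str]] = []
    for idx, region in enumerate(truth.planted_regions):
        mid = (region.start + region.end) // 2
        if idx % 2 == 0:
            quarter = max(1_000, (region.end - region.start) // 4)
            intervals.append(
                (region.chrom, mid - quarter, mid + quarter, f"est_{idx:03d}")
            )
        else:
            on_chrom = [g for g in genes if g.chrom == region.chrom]
            if not on_chrom:
                continue
            gene = min(
                on_chrom,
                key=lambda g: min(abs(g.start - region.end), abs(region.start - g.end)),
            )
            anchor = gene.start if gene.start > region.end else gene.end
            s, e = sorted((mid, anchor))
            intervals.append((region.chrom, s, max(e, s + 1), f"mrna_{idx:03d}"))
    intervals.sort()
    return EvidenceTrack(TrackName.EXPRESSED_SEQUENCE, intervals)


def _build_conserved_track(
    rng: random.Random, placer: _Placer, truth: GroundTruth
) -> EvidenceTrack:
    intervals: list[tuple[str, int, int, str]] = []
    for idx, region in enumerate(truth.planted_regions):
        if idx % 3 == 0:
            mid = (region.start + region.end) // 2
            intervals.append((region.chrom, mid - 500, mid + 500, f"cons_{idx:03d}"))
    for j in range(5):
        try:
            chrom, s, e = placer.place(rng.randint(500, 3_000), ("locus",), pad=100)
        except RuntimeError:
            break
        intervals.append((chrom, s, e, f"cons_bg_{j}"))
    intervals.sort()
    return EvidenceTrack(TrackName.CONSERVED_ELEMENT, intervals)


def make_repeat_track(config: SimulationConfig | None = None) -> EvidenceTrack:
    """The repeat track of a simulated cohort (includes the >80% decoy)."""
    return simulate_cohort(config).tracks["repeat"]


def write_cohort(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the formats the readers consume, plus ground truth.

    Emits cases.tsv / controls.tsv / parents.tsv (CNV TSV), genes.gff3,
    one BED per evidence track, pedigree.tsv and ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, calls in (
        ("cases", sim.case_calls),
        ("controls", sim.control_calls),
        ("parents", sim.parent_calls),
    ):
        paths[name] = outdir / f"{name}.tsv"
        cio.write_cnv_bed(calls, paths[name])
    paths["genes"] = outdir / "genes.gff3"
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sim.genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand if g.strand in '+-' else '.'}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
    for name, track in sorted(sim.tracks.items()):
        paths[name] = outdir / f"{name}.bed"
        cio.write_track(track, paths[name])
    paths["pedigree"] = outdir / "pedigree.tsv"
    cio.write_pedigree(sim.pedigree, paths["pedigree"])
    paths["screen_config"] = outdir / "screen_config.yaml"
    with open(paths["screen_config"], "w") as fh:
        fh.write(
            "# ready-to-run screen config for this simulated cohort\n"
            "build: simulated\n"
            "inputs:\n"
            "  cases: cases.tsv\n"
            "  controls: controls.tsv\n"
            "  parents: parents.tsv\n"
            "  genes: genes.gff3\n"
            "  genes_format: gff3\n"
            "  pedigree: pedigree.tsv\n"
            f"  dataset_size: {sim.config.n_cases + sim.config.n_controls}\n"
            "  tracks:\n"
            + "".join(
                f"    {name}: {name}.bed\n" for name in sorted(sim.tracks)
            )
        )
    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = sim.ground_truth
    payload = {
        "planted_regions": [asdict(p) for p in truth.planted_regions],
        "repeat_decoys": [asdict(p) for p in truth.repeat_decoys],
        "genic_decoys": [asdict(p) for p in truth.genic_decoys],
        "common_cnp_loci": [list(t) for t in truth.common_cnp_loci],
        "inheritance_labels": truth.inheritance_labels,
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
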