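# Methods

## Coordinate conventions

All intervals are 1-based and fully closed, matching published CNV call
tables. The *reported* size of a call is `end − start` (the convention of
those tables), while all overlap arithmetic — reciprocal overlap,
coverage fractions, gap distances — uses the true closed-interval base
count `end − start + 1`. BED inputs are shifted (+1 on start) on read and
shifted back on write; CNV call TSVs are read verbatim by default because
the call sets this package mirrors are published 1-based
(`coords="bed"` opts into the shift). Chromosome names are normalized by
stripping a leading `chr`. Sex chromosomes are accepted with a warning:
carrier counting does not model hemizygosity, and no ploidy adjustment is
attempted. The genome build is opaque — declared as a config string,
asserted nowhere; all inputs must share one build.

## The screen

1. **Rarity.** A call's carriers are the distinct samples in the pooled
   case + control dataset owning a call on the same chromosome with
   reciprocal overlap ≥ `rarity.ro_threshold` (default 0.5, the field's
   standard CNV-equivalence criterion) and, by default, the same type
   (`rarity.same_type`). A call is kept when carriers / dataset size is
   **strictly** below `rarity.max_freq` (default 0.01): a call carried by
   exactly 1% of samples is common. The denominator is the number of
   genotyped samples, supplied explicitly (`inputs.dataset_size`);
   defaulting to the samples observed in the call files undercounts the
   cohort whenever some samples carry no calls, which at desk scale is
   enough to misclassify a 2-carrier cluster — hence the explicit knob.
   Per-platform stratified counting is available (`stratify_by_platform`)
   for cohorts genotyped on heterogeneous arrays, default off.
2. **Intergenic mask.** A call intersecting ≥ 1 base of any gene's full
   transcript span is genic and removed. Span-level masking (rather than
   exon-level) is the default because intergenic risk loci are expected to
   act through flanking sequence of intact genes; an exon-level mode
   exists for annotations that provide exon intervals.
3. **Clustering and locus merging.** Surviving case calls are clustered
   per chromosome by single-linkage any-overlap, type-agnostic (published
   loci mix losses and gains). Clusters whose spans are separated by at
   most `filters.locus_merge_gap` intervening bases (default 1 Mb) merge
   into one candidate locus; the sub-cluster partition is retained. The
   1 Mb default is the value consistent with the packaged reference loci:
   it joins sub-clusters ~400–700 kb apart at one cytoband while keeping
   the two groups ~1.29 Mb apart at 11p12 distinct.
4. **Recurrence.** A locus survives when at least one of its overlap
   sub-clusters contains ≥ `filters.min_cases` (default 2) distinct
   *unrelated* carriers — relatedness keys on `family_id`, else on shared
   parental IDs in the pedigree (siblings), else on `sample_id`.
   Recurrence is deliberately evaluated per sub-cluster, not per merged
   locus: proximity alone (two disjoint singletons within 1 Mb) is not
   evidence of a shared variant, and treating it as such floods the
   output with false loci at realistic background rates. Singleton
   sub-clusters attached to a surviving locus by the gap rule are
   reported with it, mirroring how published locus tables list tag-along
   events.
5. **Control absence.** A region is removed when more than
   `filters.max_control_carriers` (default 0 — strict absence) distinct
   control samples carry a call overlapping any member CNV with matching
   type. Any-overlap is used rather than reciprocal overlap because
   absence from controls is read conservatively; RO-based matching is
   available via `ro_threshold`.
6. **Common-variant catalogue.** Regions whose merged span is covered by
   the union of catalogue intervals at a fraction ≥
   `filters.dgv_max_overlap` (default 0.5, inclusive) are removed as
   known polymorphic. The source gives no numeric criterion for this
   step; 0.5 is this package's documented default and is excluded from
   the regression targets.
7. **Repeat content.** Regions whose repeat-masked fraction is strictly
   greater than `filters.repeat_max_fraction` (default 0.8) are removed —
   strict, so an exactly-80%-masked region is retained. Coverage is a
   union sweep, never double-counted.
8. **Annotation.** The nearest gene minimizes the gap (intervening bases;
   0 when abutting) to the merged span, ties to the smaller gene start.
   The *furthest distance* is the largest member-CNV gap to that chosen
   gene, so single-member loci have nearest = furthest; the alternative
   "span gap" reading is noted but not the default, since the reference
   table prints one distance per locus consistent with the member-wise
   reading. Candidate-gene status is set when the nearest gene, or any
   gene within the merge-gap window, is on the supplied list (a default
   list of ASD risk genes flanking the reference loci is packaged).
   Mechanism bins are a transparent rule set, not a reproduction of
   manual curation: bin i whenever a nearest gene exists; bin ii when
   expressed-sequence or conserved-element evidence overlaps the region
   without reaching the nearest gene; bin iii when an overlapping
   expressed-sequence interval extends to within the gene-link window of
   the nearest gene's span (the extended-isoform signature). Ambiguity
   yields compound bins ({i, ii}), never a forced choice.
9. **Inheritance.** A member CNV of a proband with pedigree data is
   inherited when a same-type parental call reaches RO ≥ 0.5 (the same
   threshold as rarity; maternal checked first, a double match reported
   as maternal with both parents logged), de novo when both parents are
   present and neither matches, and unknown when a parent is missing and
   no present parent matches — a negative result without both parents is
   inconclusive.

Filters only remove: every stage's region set is a subset of its input,
and each decision is appended to the region's `filter_trail` with the
measured statistic, emitted as JSON lines (the audit/provenance log).
Merging precedes the region-level filters; the common-variant and repeat
filters are pure region predicates and commute (asserted in tests).

## Synthetic cohorts

The generator emulates the data regime of a two-platform case-control
CNV screen at desk scale: 150 cases, 150 controls, two 50 Mb
chromosomes, 40 non-overlapping genes. Full-cohort sizes (1491 cases /
3644 controls) are available as a `paper_scale()` preset; the desk scale
is the test default so the whole suite runs in seconds on one CPU. It
plants, with known ground truth:

- **5 rare intergenic recurrent regions** of 20–150 kb, each carried by
  2 distinct case samples (the recurrence minimum; in a 300-sample pooled
  cohort 2 carriers = 0.67% stays strictly under the 1% rarity cutoff,
  whereas 3 would sit exactly at the boundary and be removed). Member
  boundaries are jittered uniformly within ±10% of the length —
  published carriers of one locus have non-identical boundaries — which
  bounds pairwise RO below 1 but above ~0.67, safely over the 0.5
  equivalence threshold.
- **Common copy-number polymorphisms** (3 loci) carried by ≥ 5% of cases
  and of controls (tight boundary jitter, 5%), which the rarity filter
  must remove; the same loci constitute the common-variant catalogue
  track.
- **Genic decoys**: recurrent case clusters centered inside genes, for
  the intergenic filter to remove.
- **One repeat decoy**: a recurrent intergenic case cluster whose span
  the emitted repeat track masks at ~96% (three pieces with two small
  gaps), for the repeat filter to remove.
- **Background calls** per sample, Poisson with mean 0.5, 5–50 kb.
- **Trios** for 50% of cases; every planted or repeat-decoy CNV of a
  trio proband is copied (with ±10% jitter, keeping RO ≥ 0.5) into one
  parent with probability `inherited_fraction` (default 1.0 — the
  reference screen found all its defining events inherited) or withheld
  from both parents (de novo) otherwise.

Two guarantees are engineered rather than probabilistic, because the
generator's purpose is exact ground truth: planted loci are placed with
≥ 1.2 Mb clearance from each other (so the 1 Mb gap rule cannot merge two
truths), and background placement rejects any candidate overlapping a
planted/CNP locus or another case sample's background call — so no
spurious recurrent intergenic cluster can arise and the screen's correct
output is *exactly* the planted regions. Consequences for
interpretation: passing recovery tests demonstrates the pipeline's
filters implement their definitions, not that the screen is robust to
coincidental background overlap in real cohorts, where two unrelated rare
background CNVs can and do overlap. The generator also does not model
array-probe density, platform-specific breakpoint error, sex chromosomes,
or allele frequencies (carriers are counted, not alleles). Placement is
rejection sampling with a bounded retry budget; a genome too small for
the requested structure fails fast with a diagnostic rather than looping.

All randomness flows from one `random.Random(seed)` stream; identical
configs produce byte-identical output files.

## Numerical and degenerate-input choices

- Strict vs inclusive boundaries follow the stated definitions: rarity
  `< 1%` strict, repeat `> 80%` strict, catalogue coverage `≥ 50%`
  inclusive, recurrence `≥ 2` inclusive.
- Empty gene lists retain all calls; empty tracks remove nothing; an
  empty case file yields an empty, header-only report and zero counts.
- An empty pooled dataset is an error (the frequency denominator must be
  positive), as is an RO threshold outside (0, 1].
- Region ordering, report lines and JSON key order are fully
  deterministic; two runs on identical inputs are byte-identical.
- Malformed call records are rejected individually with line numbers
  (collected via the `rejected` hook and logged); malformed gene/track
  files are fatal with path and line context.

## Known limitations

- No burden statistic or case/control enrichment p-value is computed: the
  method is a deterministic screen, and no multiple-testing machinery
  applies.
- The published pre-annotation count of 212 candidate regions and the
  printed per-locus gene distances depend on the original full cohort
  call set and annotation freeze and are not reproducible from the
  packaged reference rows; the regression targets are the locus
  structure, sample counts and size identities, which are.
- Carrier frequency treats platform heterogeneity only through optional
  stratification; no cross-platform sensitivity modelling.
- The mechanism-bin rules are intentionally coarse; they encode the three
  hypotheses transparently rather than recovering curated labels.
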