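# cnvscan

Discovery and annotation of rare, recurrent, control-absent **intergenic**
copy-number-variant (CNV) regions in case-control cohorts.

Most disease-focused CNV analyses stop at the gene boundary: a call that
does not touch an annotated transcript is discarded. `cnvscan` implements
the complementary screen for neurodevelopmental case-control studies (its
reference application is autism spectrum disorder): starting from
per-sample CNV call sets for cases and controls, it isolates CNVs that are
**rare** (carrier frequency < 1% of the overall genotyped dataset, calls
matched across samples at ≥ 50% reciprocal overlap with the same type),
**intergenic** (sharing no base with any gene span), **recurrent**
(overlapping CNVs in ≥ 2 unrelated cases) and **absent from controls**,
then removes regions explained by known common structural variation
(DGV-style catalogue coverage ≥ 50% of the span) or by repeat content
(> 80% repeat-masked), merges nearby CNV clusters (≤ 1 Mb apart) into
candidate loci, and annotates each locus with its nearest gene and
distance, candidate-gene status, expressed-sequence/conservation evidence,
a mechanism bin, and — where trio data exist — the mode of inheritance of
every member CNV.

## Core definitions

For two calls $a, b$ on one chromosome, the reciprocal overlap is

$$\mathrm{RO}(a,b) = \min\!\left(\frac{|a \cap b|}{|a|}, \frac{|a \cap b|}{|b|}\right)$$

on closed-interval base counts; two calls are the *same* CNV when
$\mathrm{RO} \ge 0.5$ and the types match. A call is *rare* when the
number of distinct carriers of that CNV among all genotyped samples
(cases + controls pooled) is strictly below 1%. Candidate regions are
single-linkage connected components of surviving case calls under
any-overlap (≥ 1 bp, type-agnostic), and clusters whose spans lie within
1 Mb of each other are merged into one locus; recurrence requires ≥ 2
unrelated carriers *within one overlap cluster* (nearby singletons are
reported with the locus but cannot establish it). Mechanism bins encode
three hypotheses for an intergenic risk CNV: (i) perturbed regulatory
elements of a nearby gene, (ii) an undiscovered gene or non-coding RNA
inside the region, (iii) disruption of an unannotated extended isoform of
a neighbouring gene.

A machine-readable transcription of the 45 published reference CNVs
(15 loci, 41 cohort cases plus one literature case) is packaged and serves
as a regression anchor: clustering + merging must re-derive the published
loci exactly.

## Worked example

Generate a desk-scale synthetic cohort (150 cases / 150 controls, 5
planted intergenic recurrent regions, common polymorphisms, genic and
repeat decoys, trio structure) and run the screen:

```sh
cnvscan simulate --out sim --seed 7
cnvscan run --config sim/screen_config.yaml --out out
```

which prints the per-stage summary:

```json
{
 "case_calls_loaded": 108,
 "control_calls_loaded": 88,
 "after_rarity": 84,
 "after_intergenic": 76,
 "overlap_clusters": 70,
 "merged_loci": 40,
 "after_recurrence": 6,
 "after_control_absence": 6,
 "after_common_variant": 6,
 "after_repeat": 5,
 "reported_regions": 5,
 "reported_samples": 10
}
```

Reading the counts: 108 case calls load; the rarity filter removes the 24
common-polymorphism calls (84 left); the gene mask removes genic calls
(76); clustering and 1 Mb merging give 40 candidate loci, of which 6
contain a genuinely recurrent overlap cluster; the repeat filter removes
the one decoy cluster sitting in > 80% masked sequence, leaving exactly
the 5 planted regions carried by 10 case samples. `out/regions.tsv` lists
one line per member CNV:

```
locus_id  chrom  region_start  region_end  gene       distance_bp  sample     cnv_type ...
locus_005  1      8276127       8380704     gene_0009  250348       case_0120  loss
locus_005  1      8276127       8380704     gene_0009  250348       case_0125  loss
```

`out/filter_trail.jsonl` records every filter decision per region with the
measured statistic (the audit trail), and `sim/ground_truth.json` holds the
planted truth for comparison. The packaged reference regression runs with

```sh
cnvscan regression-table1
# reference call set reproduced: 0 diffs
```

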