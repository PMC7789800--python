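# Methods

## Problem and model

Optical genome mapping (OGM) calls structural variants (SVs) from de novo
assemblies of long, labeled DNA molecules. Because the technique is not
sequence-based, breakpoints carry an average uncertainty of roughly 3.3 kb,
so two observations of the same variant rarely agree exactly on
coordinates. `svannotate` annotates OGM SV call sets (single-enzyme SMAP or
dual-enzyme SVmerge TXT files) with the evidence an analyst needs to judge
pathogenicity: population frequency in external and internal databases,
overlapping and nearby genes, expression of those genes, phenotype-driven
gene lists, and inheritance classification, partitioned into a multi-sheet
workbook.

### Variant identity under breakpoint uncertainty

Two SVs are considered the same variant when they

1. share a type class (insertion / deletion / duplication / inversion /
   translocation, after collapsing caller subtypes),
2. lie on the same chromosome (both breakpoint chromosomes for
   translocations),
3. have both breakpoints within a window *W* of each other
   (|Δstart| ≤ W and |Δend| ≤ W), with W = `win_indel` = 10 kb for
   insertions/deletions/duplications and `win_inv_trans` = 50 kb for
   inversions/translocations, and
4. for the indel classes, have a size-similarity ratio
   min(s₁,s₂)/max(s₁,s₂) ≥ `perc_similarity` = 0.50.

The size rule is off by default for inversions and translocations, whose
sizes are frequently absent from caller output; `apply_size_to_inv_trans`
turns it on. The min/max ratio was chosen because it is symmetric and
bounded in (0, 1]; the upstream description does not write the formula
explicitly. When the size rule applies but a candidate's size is absent,
the candidate is rejected in strict (filtered) matching and admitted in
unfiltered matching.

For matching a proband call against its parents, `perc_similarity` rises
to 0.90: an inherited variant should be virtually identical to the
parental one.

### Frequency formulas

All cohorts are diploid, so a database of *N* samples holds 2*N* alleles.

* **Public databases (DGV, DECIPHER)** report no zygosity; the frequency
  is `matched records / (2N) × 100`. A DGV record listing several
  supporting samples counts once in the numerator; the `DGV_Count` column
  separately reports the number of distinct supporting samples.
* **Control database (BNDB)** reports zygosity. Matches are collapsed to
  one per database sample; each sample contributes 2 alleles if any of its
  matched records is homozygous or of unknown zygosity, else 1. Counting
  unknowns as 2 deliberately overestimates frequency (a conservative choice
  when screening for rare variants). Two figures are reported:
  *unfiltered* (matching only) and *filtered*, which additionally requires
  candidate confidence ≥ 0.5 (indels), 0.01 (inversions) or 0.1
  (translocations) and candidate size ≥ 1 kb. Duplications carry no
  confidence score and are exempt; an absent confidence or size is likewise
  exempt rather than treated as zero — a hard gate on absent
  inversion/translocation sizes would empty their filtered frequencies in
  older database releases.
* **Internal cohort**: per-sample call files are concatenated under
  `NR<family>.<relation>` identifiers (1 = proband, 2 = mother,
  3 = father; optional project prefix). For a query from family *f*, all
  records of family *f* are excluded from the numerator and the denominator
  becomes `2 × (N − members of f)`, so inherited variants are not counted
  as common merely because relatives carry them. Exact within-sample
  duplicate records (same coordinates, class, size and zygosity — an
  occasional caller artifact) are counted once. The filtered figure
  additionally drops assembly-gap (`*_nbase`) candidates, candidates not
  supported by the sample's own molecules, and
  duplications/inversions/translocations failing the assembly
  chimeric-score check; the unfiltered figure applies matching, family
  exclusion and deduplication only (the split parallels the control-database
  filtered/unfiltered pair; the upstream description names both columns
  without defining the internal split).
  When the whole cohort belongs to the query's family the frequency is
  reported as not computable (`-`), not as a division error.

Percentages are stored at full precision and displayed truncated (not
rounded) to two decimals, matching the convention of the published worked
example (43/468 × 100 = 9.188 → 9.18).

### Gene overlap and nearest genes

Gene coordinates come from BED (0-based half-open, converted on read) or
the numeric-chromosome BNBED dialect (X = 23, Y = 24, 1-based inclusive);
all annotation is done in 1-based inclusive coordinates with an
interval-tree index per chromosome. The search interval is the SV expanded
by a breakpoint-uncertainty window (3 kb for indel classes, 10 kb for
inversions/translocations), but the reported percentage is always computed
on the unexpanded SV: overlap length / gene length × 100, capped at 100.
Consequences of the convention, fixed here because the upstream prose
covers only the partial-overlap and whole-gene-deletion cases:

* a gene wholly inside the SV reports 100;
* an SV wholly inside a gene reports SV span / gene length × 100;
* a gene reached only through the uncertainty window (raw overlap zero)
  reports a 0.01 display floor, so it is never confused with no overlap;
* translocation breakpoints are treated as points, each searched ±10 kb on
  its own chromosome, the percentage being the window's coverage of the
  gene.

The k = 3 nearest non-overlapping genes per side are reported with
distances in kb ((SV start − gene end)/1000 upstream, analogously
downstream, on the second chromosome for translocations); ties break by
gene start then symbol for determinism.

### Quality filtration and sheet taxonomy

Default filtration keeps a call iff it is supported by the sample's own
molecules and, for duplications/inversions/translocations, passes the
assembly chimeric-score check. For dual-enzyme input, per-enzyme evidence
columns are harmonized disjunctively (support from either enzyme counts;
parental evidence is unioned across enzymes, and `-` means none). The
workbook tabs are:

| design | single-enzyme (count) | SVmerge adds |
|---|---|---|
| solo | all_PG_OV, indel_dup, inv, trans, all (5) | Mismatch (6) |
| duo | all_PG_OV, indel_dup_notShared, indel_dup_Shared, inv, trans, all (6) | Mismatch (7) |
| trio | all_PG_OV, indel_dup_denovo, \_both, \_mother, \_father, \_cmpdHET, inv, trans, all (9) | Mismatch (10) |

`all` holds every input variant (no silent drops) with every annotation
column; `all_PG_OV` holds rows intersecting the primary gene list without
default filtration; category sheets hold default-filtered calls only.
Trio indels route by parental molecule support (none → denovo, both,
mother, father); `indel_dup_cmpdHET` is exactly mother-sheet ∪
father-sheet, a candidate compound-heterozygote list for manual review.
Translocation calls flagged common/segdup by the upstream annotation are
likely false and excluded from `trans`; assembly-gap (`nbase`) calls
appear only in `all`. `all` is the last tab; category order is fixed for
determinism. An optional rarity filter (`max_freq_perc`, off by default)
additionally requires every computed frequency below a threshold and the
query confidence above its class threshold — this mirrors a manual
post-hoc analysis step, hence not a default.

## Synthetic data generator

`svannotate.simulate` writes complete, deterministic bundles: per-sample
SMAP/SVmerge files, cohort relation key, BED genes, miniature
DGV/DECIPHER/BNDB tables, expression tables, gene-list snapshots and a
manifest of analytically computed expectations for every planted variant.
The default trio spec mirrors the conditions the method was evaluated
under: an 8-sample internal cohort containing one 3-member family
(yielding the 2 × (8 − 3) = 10 allele denominator and a 30% worked
frequency for a deletion carried by one heterozygous and one homozygous
unrelated sample) and a 234-sample control database (468 alleles). A toy
genome of a few 5 Mb chromosomes keeps files readable; background variants
are rejection-sampled at least 120 kb away from planted variants so no
background record can satisfy the 50 kb window, making the manifest
arithmetic exact.

What the generator does **not** emulate: molecule-level OGM data, real
breakpoint-error distributions (planted carriers share exact coordinates
except where a test shifts them deliberately), reference-genome gap
structure behind `nbase` calls, linked inheritance patterns, or the scale
of real call sets (~10⁴ variants). Passing tests therefore demonstrate the
correctness of the arithmetic, matching and partitioning logic under
controlled conditions, not calling performance on real genomes.

## Numerical and degenerate-input choices

* Truncation (floor), never rounding, for displayed percentages; full
  precision internally.
* The conventional −1 sentinel for confidence/size parses to "absent",
  which is distinct from 0 and exempt from thresholds.
* Unsupported contigs (chrM, alts) are skipped with a logged count on
  read rather than aborting a run.
* Empty databases or zero matches yield 0% (not errors); a zero-sample
  database is a configuration error.
* Discordant parental zygosities are joined in the fixed order
  homozygous < heterozygous < unknown.
* Re-running on identical inputs is byte-identical; there is no hidden
  randomness anywhere in the pipeline.
* Problem sizes in the test suite and acceptance script are desk-scale
  (hundreds of records, thousands of queries), chosen because the checked
  quantities are exact arithmetic identities that do not gain information
  from scale.

## Known limitations

* Only trio relation codes are supported; larger pedigrees are rejected
  with a clear error.
* Hemizygous X calls in XY individuals arrive mislabeled homozygous from
  upstream callers; internal frequency on chromosome X is therefore
  overestimated, as in the original method. Y-chromosome frequencies are
  unaffected.
* The published example-I allele count (12 hom + 21 het stated as 43
  alleles) is internally inconsistent with the stated counting rule
  (which yields 45); the rule is implemented as documented.
* Gene lists are built from local snapshot tables by case-insensitive
  substring matching; parity with any live database release is not
  guaranteed (live results are version-dependent by nature).
* No VCF input/output, gnomAD adapter, automated ACMG classification or
  somatic mode.
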