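# svannotate

Structural-variant annotation for optical genome mapping (OGM).

OGM calls structural variants (SVs) from de novo assemblies of long,
fluorescently labeled DNA molecules. It detects large and balanced events
that short reads miss, but its breakpoints carry kilobase-scale
uncertainty, and the raw call sets (~10⁴ variants per genome) arrive with
almost no interpretation support. `svannotate` is for analysts triaging
such call sets — clinical or research — and appends to each call the
evidence needed to judge it: population frequency, gene context, gene
expression, phenotype relevance and inheritance, partitioned into a
reviewable multi-sheet workbook.

## What it computes

**Variant identity.** Two SVs are the same variant when they share a type
class and chromosome, both breakpoints lie within a window *W* of each
other (*W* = 10 kb for insertions/deletions/duplications, 50 kb for
inversions/translocations), and — for the indel classes — their sizes
satisfy min(s₁,s₂)/max(s₁,s₂) ≥ 0.5. Parental matching uses a 0.90 ratio,
since inherited variants should be nearly identical.

**Frequency.** For a database of *N* diploid samples,

```
frequency (%) = matched variant alleles / 2N × 100
```

Public databases (DGV, DECIPHER) carry no zygosity, so matched records are
counted directly. The Bionano control database (BNDB, *N* = 234) and the
user's internal cohort carry zygosity: matches collapse to one per sample,
contributing 2 alleles if homozygous or unknown and 1 if heterozygous, and
both a filtered figure (confidence ≥ 0.5/0.01/0.1 per class, size ≥ 1 kb)
and an unfiltered one are reported. For the internal cohort, every sample
of the query's own family is removed from numerator and denominator
(`2 × (N − family members)`), and parental zygosity is extracted for
duo/trio analyses.

**Gene context.** Overlapping genes (±3 kb search window for indels,
±10 kb for inversions/translocations) with strand and percent of the gene
covered; the 3 nearest non-overlapping genes per side with distances in
kb; per-role expression values of those genes; and intersection with a
phenotype-driven primary gene list built from Gene/OMIM/GTR/ClinVar
snapshot tables.

**Filtration and inheritance.** Calls supported by the sample's own
molecules (and passing the assembly chimeric-score check for
duplications/inversions/translocations) are routed into sheets by type and
inheritance: de novo, inherited from both/mother/father, candidate
compound heterozygotes (mother-only ∪ father-only), inversions,
translocations, discordant dual-enzyme calls, plus an `all` sheet holding
every input row. Solo/duo/trio × single-enzyme/SVmerge give workbooks of
5/6/6/7/9/10 tabs respectively.

## Worked example

The package ships a deterministic synthetic-data generator whose default
trio bundle mirrors a classic evaluation scenario: an 8-sample internal
cohort containing one trio family, where the proband's deletion is carried
by his mother and by two unrelated cohort samples (one heterozygous, one
homozygous).

```python
import pandas as pd
from svannotate import SVCall, build_internal_db, internal_frequency, bndb_frequency
from svannotate.frequency import truncate_percent
from svannotate.io import aggregate_bndb
from svannotate.simulate import default_trio_spec, generate_fixture

spec = default_trio_spec(seed=1)
bundle = generate_fixture(spec, "bundle")
db = build_internal_db(bundle.cohort_files, pd.read_csv(bundle.key_file, sep="\t"))

pv = spec.planted[0]
query = SVCall(call_id="q", chrom=pv.chrom, ref_start=pv.start, ref_end=pv.end,
               sv_type=pv.sv_type, size_bp=pv.size, zygosity="heterozygous")

fr = internal_frequency(query, db, query_family=spec.family_id)
print(f"internal: filtered={truncate_percent(fr.freq_perc_filtered)}% "
      f"unfiltered={truncate_percent(fr.freq_perc_unfiltered)}% "
      f"denominator={fr.denominator} homozygotes={fr.homozygotes}")

bndb = aggregate_bndb(bundle.bndb_dir, "hg19", n_samples=spec.bndb_n_samples)
res = bndb_frequency(query, bndb)
print(f"control DB: filtered={truncate_percent(res.freq_perc_filtered)}% "
      f"unfiltered={truncate_percent(res.freq_perc_unfiltered)}% "
      f"homozygotes={res.homozygotes}")
```

prints

```
internal: filtered=30.0% unfiltered=30.0% denominator=10 homozygotes=1
control DB: filtered=9.61% unfiltered=9.61% homozygotes=12
```

The internal figure is 3 alleles (1 het + 1 hom unrelated carrier) over
2 × (8 − 3) = 10 alleles after excluding the three family members — 30%.
The control-database figure is 45 alleles (12 homozygous + 21 heterozygous
carriers) over 2 × 234 = 468 — 9.61%, truncated for display. The full
pipeline (`svannotate.report.run_pipeline` or the CLI below) appends these
as `Internal_Freq_Perc_*`, `BNG_Freq_Perc_*` and the other annotation
columns, and writes the sheet-partitioned workbook.

## Command line

One subcommand per entry mode:

```sh
svannotate trio-se --smap proband.smap --bed genes.bed \
    --dgv dgv.tsv --decipher decipher.tsv --bndb-dir bndb/ --bndb-n-samples 234 \
    --internal-db cohort.tsv --query-nanoid NR23.1 \
    --genelist primary_genes.csv --out proband_trio.xlsx
```

plus `solo-se`, `solo-svmerge`, `duo-se`, `duo-svmerge`, `trio-svmerge`,
`build-internal-db`, `gene-list` and `run-config` (YAML). `--tsv-dir`
additionally emits one TSV per sheet.

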