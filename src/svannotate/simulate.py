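"""Deterministic synthetic-data generator with analytic ground truth.

Every stage of the annotation pipeline is testable offline against bundles
produced here: per-sample SV call files (single-enzyme SMAP or dual-enzyme
SVmerge TXT), a gene BED file, miniature DGV/DECIPHER/BNDB tables,
expression tables and gene-list snapshots, together with a manifest stating
the expected annotation of every planted variant (sheet assignment,
internal and external frequencies, gene-overlap percentages, nearest-gene
distances) computed analytically from the specification.

The default cohort emulates the evaluation conditions of the method: an
internal database of 8 optically mapped genomes of which 3 form one trio
family, and an external control database representing 234 diploid samples.
A toy genome (a few chromosomes of 5 Mb) keeps fixtures readable; planted
variants and random background variants are kept mutually unmatchable by
rejection sampling, so the manifest arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import (
    CHIMERIC_CHECK_CLASSES,
    CLASS_INVERSION,
    CLASS_TRANSLOCATION,
    HETEROZYGOUS,
    HOMOZYGOUS,
    INDEL_CLASSES,
    RELATION_FATHER,
    RELATION_MOTHER,
    RELATION_PROBAND,
    is_common_translocation,
    is_nbase_type,
    type_class,
)

#: Toy genome used by all fixtures (chromosome code -> length in bp).
DEFAULT_CHROM_LENGTHS: Dict[int, int] = {1: 5_000_000, 2: 5_000_000, 3: 5_000_000, 23: 5_000_000}

#: Control-database cohort size emulated by default (diploid samples).
BNDB_DEFAULT_SAMPLES = 234

_ZYG_ALLELES = {HOMOZYGOUS: 2, HETEROZYGOUS: 1, "unknown": 2}


@dataclass
class PlantedVariant:
    """One ground-truth variant with known carriers and database presence."""

    name: str
    sv_type: str
    chrom: int
    start: int
    end: int
    size: Optional[int] = None          # defaults to span for non-insertions
    confidence: float = 0.9
    zygosity: str = HETEROZYGOUS        # zygosity of the proband call
    #: cohort carriers besides the proband: label -> zygosity.  Labels are
    #: "mother", "father" or "U<i>" for the i-th unrelated sample.
    carriers: Dict[str, str] = field(default_factory=dict)
    found_in_self: str = "yes"
    chimeric: str = "pass"
    parental_support: str = "none"      # trio proband file column
    control_support: str = "no"         # duo proband file column
    #: zygosities of the distinct control-database (BNDB) samples carrying it
    bndb_carriers: Sequence[str] = ()
    #: matching record counts planted in the public databases
    dgv_records: int = 0
    decipher_records: int = 0

    def __post_init__(self) -> None:
        if self.size is None:
            self.size = self.end - self.start + 1
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")

    @property
    def klass(self) -> str:
        return type_class(self.sv_type)


@dataclass
class FixtureSpec:
    """Full description of one synthetic bundle; same seed, same bytes."""

    seed: int = 0
    n_cohort_samples: int = 8
    family_size: int = 3                # focal-family members within the cohort
    family_design: str = "trio"         # design of the proband analysis file
    dialect: str = "single_enzyme"      # or "svmerge"
    family_id: int = 23
    n_background: int = 25              # random background SVs per sample
    planted: List[PlantedVariant] = field(default_factory=list)
    #: gene layout: (chrom, start, end, strand, symbol), 1-based inclusive
    genes: List[Tuple[int, int, int, str, str]] = field(default_factory=list)
    chrom_lengths: Dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    bndb_n_samples: int = BNDB_DEFAULT_SAMPLES
    dgv_n_samples: int = 100
    decipher_n_samples: int = 100
    n_db_background: int = 40           # background records per external DB
    #: expression TPM per (gene symbol, role); unmentioned genes drawn randomly
    expression: Dict[Tuple[str, str], float] = field(default_factory=dict)
    #: gene-list snapshots: (source, gene, condition, clinical_significance)
    genelist_rows: List[Tuple[str, str, str, str]] = field(default_factory=list)
    include_malformed_rows: bool = False

    def validate(self) -> None:
        labels = self.cohort_labels()
        for pv in self.planted:
            if pv.chrom not in self.chrom_lengths:
                raise ValueError(f"{pv.name}: chromosome {pv.chrom} not in toy genome")
            if pv.end > self.chrom_lengths[pv.chrom]:
                raise ValueError(f"{pv.name}: end beyond chromosome length")
            unknown = set(pv.carriers) - set(labels)
            if unknown:
                raise ValueError(f"{pv.name}: carriers {sorted(unknown)} not in cohort")
        if self.family_size > self.n_cohort_samples:
            raise ValueError("family larger than cohort")
        if self.family_size > 3:
            raise ValueError("only trio families (<= 3 members) are supported")

    def cohort_labels(self) -> List[str]:
        """Semantic labels of cohort members: proband/mother/father + U<i>."""
        fam = ["proband", "mother", "father"][: self.family_size]
        unrelated = [f"U{i + 1}" for i in range(self.n_cohort_samples - self.family_size)]
        return fam + unrelated


@dataclass
class FixtureBundle:
    """Paths of everything written plus the ground-truth manifest."""

    outdir: Path
    proband_sv: Path
    cohort_files: List[Path]
    key_file: Path
    bed_file: Path
    dgv_file: Path
    decipher_file: Path
    bndb_dir: Path
    expression_files: List[Path]
    snapshot_files: Dict[str, Path]
    manifest: pd.DataFrame


# --------------------------------------------------------------------------
# expected-annotation arithmetic (independent of the pipeline implementation)
# --------------------------------------------------------------------------


def _expected_internal(spec: FixtureSpec, pv: PlantedVariant) -> Optional[float]:
    """Family-excluded internal frequency the pipeline must reproduce."""
    denom = 2 * (spec.n_cohort_samples - spec.family_size)
    if denom <= 0:
        return None
    family = {"proband", "mother", "father"}
    alleles = sum(
        _ZYG_ALLELES[z] for label, z in pv.carriers.items() if label not in family
    )
    return alleles / denom * 100.0


def _expected_bndb(spec: FixtureSpec, pv: PlantedVariant) -> float:
    alleles = sum(_ZYG_ALLELES[z] for z in pv.bndb_carriers)
    return alleles / (2 * spec.bndb_n_samples) * 100.0


def _expected_sheet(spec: FixtureSpec, pv: PlantedVariant) -> str:
    """Category sheet the proband call must land in ('' = none)."""
    if is_nbase_type(pv.sv_type) or pv.found_in_self != "yes":
        return ""
    klass = pv.klass
    if klass in CHIMERIC_CHECK_CLASSES and pv.chimeric != "pass":
        return ""
    if klass in INDEL_CLASSES:
        if spec.family_design == "solo":
            return "indel_dup"
        if spec.family_design == "duo":
            return (
                "indel_dup_Shared"
                if pv.control_support == "yes"
                else "indel_dup_notShared"
            )
        return {
            "both": "indel_dup_both",
            "mother": "indel_dup_mother",
            "father": "indel_dup_father",
        }.get(pv.parental_support, "indel_dup_denovo")
    if klass == CLASS_INVERSION:
        return "inv"
    if klass == CLASS_TRANSLOCATION and not is_common_translocation(pv.sv_type):
        return "trans"
    return ""


def _expected_overlaps(
    spec: FixtureSpec, pv: PlantedVariant
) -> List[Tuple[str, float]]:
    win = 10_000 if pv.klass in (CLASS_INVERSION, CLASS_TRANSLOCATION) else 3_000
    out = []
    for chrom, gstart, gend, _strand, symbol in spec.genes:
        if chrom != pv.chrom:
            continue
        if gend < pv.start - win or gstart > pv.end + win:
            continue
        raw = max(0, min(pv.end, gend) - max(pv.start, gstart) + 1)
        length = gend - gstart + 1
        pct = max(0.01, min(100.0, raw / length * 100.0))
        out.append((symbol, round(pct, 2)))
    return out


def _expected_nearest(
    spec: FixtureSpec, pv: PlantedVariant, k: int = 3
) -> Tuple[List[Tuple[str, float]], List[Tuple[str, float]]]:
    overlap_syms = {s for s, _ in _expected_overlaps(spec, pv)}
    up, down = [], []
    for chrom, gstart, gend, _strand, symbol in spec.genes:
        if chrom != pv.chrom or symbol in overlap_syms:
            continue
        if gend < pv.start:
            up.append(((pv.start - gend) / 1000.0, gstart, symbol))
        elif gstart > pv.end:
            down.append(((gstart - pv.end) / 1000.0, gstart, symbol))
    up.sort()
    down.sort()
    return (
        [(s, d) for d, _, s in up[:k]],
        [(s, d) for d, _, s in down[:k]],
    )


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

_SE_COLUMNS = [
    "SmapEntryID",
    "RefcontigID1",
    "RefcontigID2",
    "RefStartPos",
    "RefEndPos",
    "Confidence",
    "Type",
    "Zygosity",
    "Size",
    "Found_in_self_molecules",
    "Fail_assembly_chimeric_score",
]
_SVMERGE_COLUMNS = [
    "SVIndex",
    "RefcontigID1",
    "RefcontigID2",
    "RefStartPos",
    "RefEndPos",
    "Confidence",
    "Type",
    "Zygosity",
    "Size",
    "Found_in_self_BSPQI_molecules",
    "Found_in_self_BSSSI_molecule",
    "Fail_BSPQI_assembly_chimeric_score",
    "Fail_BSSSI_assembly_chimeric_score",
]


def _sv_row(dialect: str, idx: int, rec: dict, design: str) -> List[str]:
    common = [
        str(idx),
        str(rec["chrom"]),
        str(rec.get("chrom2", rec["chrom"])),
        f"{rec['start']:.1f}",
        f"{rec['end']:.1f}",
        str(rec.get("confidence", 0.9)),
        rec["sv_type"],
        rec.get("zygosity", HETEROZYGOUS),
        str(rec.get("size", "")),
    ]
    self_v = rec.get("found_in_self", "yes")
    chim_v = rec.get("chimeric", "pass")
    if dialect == "single_enzyme":
        row = common + [self_v, chim_v]
        if design == "trio":
            row.append(rec.get("parental_support", "none"))
        elif design == "duo":
            row.append(rec.get("control_support", "no"))
    else:
        row = common + [self_v, self_v, chim_v, chim_v]
        if design == "trio":
            ps = rec.get("parental_support", "none")
            row += [ps, ps]
        elif design == "duo":
            cs = rec.get("control_support", "no")
            row += [cs, cs]
    return row


def write_sv_file(
    path: Path,
    records: Sequence[dict],
    dialect: str = "single_enzyme",
    design: str = "solo",
    malformed: bool = False,
) -> None:
    """Write a synthetic SMAP (single-enzyme) or SVmerge TXT call file."""
    columns = list(_SE_COLUMNS if dialect == "single_enzyme" else _SVMERGE_COLUMNS)
    if design == "trio":
        columns += (
            ["Found_in_parents_molecules"]
            if dialect == "single_enzyme"
            else ["Found_in_parents_BSPQI_molecules", "Found_in_parents_BSSSI_molecules"]
        )
    elif design == "duo":
        columns += (
            ["Found_in_control_molecules"]
            if dialect == "single_enzyme"
            else [
                "Found_in_control_sample_BSPQI_molecules",
                "Found_in_control_sample_BSSSI_molecules",
            ]
        )
    lines = [
        "# synthetic OGM SV call file",
        "# Reference: toy genome",
        "#h " + "\t".join(columns),
    ]
    for i, rec in enumerate(records, start=1):
        lines.append("\t".join(_sv_row(dialect, i, rec, design)))
    if malformed:
        lines.append("not\ta\tvalid\trow")
    path.write_text("\n".join(lines) + "\n")


def _write_bed(path: Path, genes) -> None:
    name = {23: "chrX", 24: "chrY"}
    with open(path, "w") as fh:
        for chrom, start, end, strand, symbol in genes:
            label = name.get(chrom, f"chr{chrom}")
            fh.write(f"{label}\t{start - 1}\t{end}\t{symbol}\t0\t{strand}\n")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _collides(start: float, end: float, chrom: int, planted, margin: float = 120_000) -> bool:
    for pv in planted:
        if pv.chrom == chrom and not (end < pv.start - margin or start > pv.end + margin):
            return True
    return False


def _background_records(
    rng: np.random.Generator, spec: FixtureSpec, n: int
) -> List[dict]:
    """Random background SVs guaranteed not to match any planted variant."""
    chroms = sorted(spec.chrom_lengths)
    types = ["insertion", "deletion", "duplication", "inversion"]
    out: List[dict] = []
    while len(out) < n:
        chrom = int(rng.choice(chroms))
        length = int(rng.integers(2_000, 60_000))
        start = int(rng.integers(1, spec.chrom_lengths[chrom] - length - 1))
        end = start + length
        if _collides(start, end, chrom, spec.planted):
            continue
        sv_type = str(rng.choice(types))
        out.append(
            {
                "chrom": chrom,
                "start": float(start),
                "end": float(end),
                "sv_type": sv_type,
                "size": length,
                "confidence": round(float(rng.uniform(0.3, 1.0)), 2),
                "zygosity": str(rng.choice([HOMOZYGOUS, HETEROZYGOUS])),
                "found_in_self": "yes",
                "chimeric": "pass",
                "parental_support": str(rng.choice(["none", "both", "mother", "father"])),
                "control_support": str(rng.choice(["yes", "no"])),
            }
        )
    return out


def _planted_record(pv: PlantedVariant, zygosity: Optional[str] = None) -> dict:
    return {
        "chrom": pv.chrom,
        "start": float(pv.start),
        "end": float(pv.end),
        "sv_type": pv.sv_type,
        "size": pv.size,
        "confidence": pv.confidence,
        "zygosity": zygosity or pv.zygosity,
        "found_in_self": pv.found_in_self,
        "chimeric": pv.chimeric,
        "parental_support": pv.parental_support,
        "control_support": pv.control_support,
    }


def _external_db_rows(rng, spec: FixtureSpec):
    """Background + planted rows for the three external databases."""
    dgv_rows, decipher_rows, bndb_rows = [], [], []
    for _ in range(spec.n_db_background):
        rec = _background_records(rng, spec, 1)[0]
        subtype = {"deletion": "loss", "duplication": "gain"}.get(
            rec["sv_type"], rec["sv_type"]
        )
        dgv_rows.append(
            (f"dgv_{len(dgv_rows)}", rec["chrom"], int(rec["start"]), int(rec["end"]),
             subtype, f"DGVS{rng.integers(1, spec.dgv_n_samples + 1)}")
        )
        rec2 = _background_records(rng, spec, 1)[0]
        if rec2["sv_type"] in ("deletion", "duplication"):
            decipher_rows.append(
                (rec2["chrom"], int(rec2["start"]), int(rec2["end"]),
                 "-1" if rec2["sv_type"] == "deletion" else "1",
                 spec.decipher_n_samples)
            )
        rec3 = _background_records(rng, spec, 1)[0]
        bndb_rows.append(
            (f"BN{rng.integers(1, spec.bndb_n_samples + 1)}", rec3["chrom"],
             rec3["chrom"], int(rec3["start"]), int(rec3["end"]), rec3["sv_type"],
             rec3["size"], rec3["zygosity"], rec3["confidence"])
        )
    bn_next = 10_000  # distinct planted BNDB carrier labels
    for pv in spec.planted:
        for i in range(pv.dgv_records):
            dgv_rows.append(
                (f"dgv_{pv.name}_{i}", pv.chrom, pv.start, pv.end,
                 {"deletion": "loss", "duplication": "gain"}.get(pv.klass, pv.klass),
                 f"DGVS_{pv.name}")
            )
        for i in range(pv.decipher_records):
            code = {"deletion": "-1", "duplication": "1"}.get(pv.klass)
            if code is None:
                raise ValueError(
                    f"{pv.name}: DECIPHER holds copy-number classes only"
                )
            decipher_rows.append((pv.chrom, pv.start, pv.end, code, spec.decipher_n_samples))
        for zyg in pv.bndb_carriers:
            bn_next += 1
            bndb_rows.append(
                (f"BN{bn_next}", pv.chrom, pv.chrom, pv.start, pv.end,
                 pv.klass, pv.size, zyg, pv.confidence)
            )
    return dgv_rows, decipher_rows, bndb_rows


def _manifest_row(spec: FixtureSpec, pv: PlantedVariant) -> dict:
    overlaps = _expected_overlaps(spec, pv)
    up, down = _expected_nearest(spec, pv)
    internal = _expected_internal(spec, pv)
    return {
        "name": pv.name,
        "sv_type": pv.sv_type,
        "chrom": pv.chrom,
        "start": pv.start,
        "end": pv.end,
        "expected_sheet": _expected_sheet(spec, pv),
        "internal_freq_perc": "" if internal is None else internal,
        "bndb_freq_perc": _expected_bndb(spec, pv),
        "dgv_freq_perc": pv.dgv_records / (2 * spec.dgv_n_samples) * 100.0,
        "decipher_freq_perc": pv.decipher_records / (2 * spec.decipher_n_samples) * 100.0,
        "overlap_genes": ";".join(f"{s}:{p}" for s, p in overlaps),
        "upstream_genes": ";".join(f"{s}:{d}" for s, d in up),
        "downstream_genes": ";".join(f"{s}:{d}" for s, d in down),
    }


def generate_fixture(spec: FixtureSpec, outdir: Union[str, Path]) -> FixtureBundle:
    """Write the full synthetic bundle for ``spec`` under ``outdir``.

    Raises a validation error before writing anything when the spec is
    inconsistent (carriers outside the cohort, coordinates off-chromosome).
    Identical specs (including seed) produce byte-identical bundles.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    labels = spec.cohort_labels()
    relation_of = {
        "proband": RELATION_PROBAND,
        "mother": RELATION_MOTHER,
        "father": RELATION_FATHER,
    }
    key_rows, cohort_files = [], []
    for i, label in enumerate(labels):
        if label in relation_of:
            family, relation = spec.family_id, relation_of[label]
        else:
            family, relation = spec.family_id + 1 + i, RELATION_PROBAND
        stem = f"cohort_{label}"
        key_rows.append({"SampleID": stem, "FamilyID": family, "Relation": relation})
        records = _background_records(rng, spec, spec.n_background)
        for pv in spec.planted:
            zyg = pv.carriers.get(label)
            if label == "proband":
                zyg = pv.zygosity
            if zyg is not None:
                records.append(_planted_record(pv, zygosity=zyg))
        path = outdir / f"{stem}.smap"
        write_sv_file(path, records, dialect="single_enzyme", design="solo")
        cohort_files.append(path)

    key_file = outdir / "cohort_key.tsv"
    pd.DataFrame(key_rows).to_csv(key_file, sep="\t", index=False)

    # the proband analysis file carries the design-specific evidence columns
    proband_records = _background_records(rng, spec, spec.n_background)
    proband_records += [_planted_record(pv) for pv in spec.planted]
    proband_sv = outdir / ("proband." + ("txt" if spec.dialect == "svmerge" else "smap"))
    write_sv_file(
        proband_sv,
        proband_records,
        dialect=spec.dialect,
        design=spec.family_design,
        malformed=spec.include_malformed_rows,
    )

    bed_file = outdir / "genes.bed"
    if spec.genes:
        _write_bed(bed_file, spec.genes)

    dgv_rows, decipher_rows, bndb_rows = _external_db_rows(rng, spec)
    dgv_file = outdir / "dgv.tsv"
    pd.DataFrame(
        dgv_rows,
        columns=["variantaccession", "chr", "start", "end", "variantsubtype", "samples"],
    ).to_csv(dgv_file, sep="\t", index=False)
    decipher_file = outdir / "decipher.tsv"
    pd.DataFrame(
        decipher_rows, columns=["chr", "start", "end", "type", "sample_size"]
    ).to_csv(decipher_file, sep="\t", index=False)

    bndb_dir = outdir / "bndb"
    bndb_dir.mkdir(exist_ok=True)
    bndb_cols = [
        "Sample", "RefcontigID1", "RefcontigID2", "RefStartPos", "RefEndPos",
        "Type", "Size", "Zygosity", "Confidence",
    ]
    by_token = {"indel": [], "duplication": [], "inversion": [], "translocation": []}
    for row in bndb_rows:
        klass = row[5]
        token = {
            "insertion": "indel",
            "deletion": "indel",
            "duplication": "duplication",
            "inversion": "inversion",
            "translocation": "translocation",
        }.get(klass, "indel")
        by_token[token].append(row)
    for token, rows in by_token.items():
        pd.DataFrame(rows, columns=bndb_cols).to_csv(
            bndb_dir / f"BNDB_hg19_{token}.txt", sep="\t", index=False
        )

    expression_files: List[Path] = []
    if spec.expression:
        gene_symbols = sorted({s for (s, _r) in spec.expression})
        for code, role in (("P", "proband"), ("UM", "mother"), ("UF", "father")):
            rows = []
            for symbol in gene_symbols:
                if (symbol, role) in spec.expression:
                    rows.append((symbol, spec.expression[(symbol, role)]))
            if not rows:
                continue
            path = outdir / f"Sample{spec.family_id}_{code}_expression.txt"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
            expression_files.append(path)

    snapshot_files: Dict[str, Path] = {}
    if spec.genelist_rows:
        by_source: Dict[str, List[Tuple[str, str, str]]] = {}
        for source, gene, condition, signif in spec.genelist_rows:
            by_source.setdefault(source, []).append((gene, condition, signif))
        for source, rows in by_source.items():
            path = outdir / f"snapshot_{source}.csv"
            pd.DataFrame(
                rows, columns=["Gene", "Condition", "ClinicalSignificance"]
            ).to_csv(path, index=False)
            snapshot_files[source] = path

    manifest = pd.DataFrame([_manifest_row(spec, pv) for pv in spec.planted])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(spec.chrom_lengths.items()), columns=["chrom", "length"]
    ).to_csv(outdir / "genome.tsv", sep="\t", index=False)

    return FixtureBundle(
        outdir=outdir,
        proband_sv=proband_sv,
        cohort_files=cohort_files,
        key_file=key_file,
        bed_file=bed_file,
        dgv_file=dgv_file,
        decipher_file=decipher_file,
        bndb_dir=bndb_dir,
        expression_files=expression_files,
        snapshot_files=snapshot_files,
        manifest=manifest,
    )


def default_trio_spec(seed: int = 0) -> FixtureSpec:
    """A ready-made trio bundle mirroring the evaluation-cohort conditions.

    8-sample internal cohort with one 3-member family; a deletion spanning a
    whole gene, carried by the mother and by two unrelated samples (one
    heterozygous, one homozygous) so its family-excluded internal frequency
    is 3/10 x 100 = 30%; a de novo insertion; an inherited inversion; plus a
    gene layout giving known overlap percentages and nearest-gene distances.
    """
    genes = [
        (1, 1_000_000, 1_030_000, "+", "GENEA"),      # fully inside the deletion
        (1, 1_060_000, 1_070_000, "-", "GENEB"),      # partial 3' overlap
        (1, 900_000, 940_000, "+", "GENEUP1"),        # upstream, 55 kb away
        (1, 700_000, 720_000, "-", "GENEUP2"),        # upstream, 275 kb away
        (1, 1_200_000, 1_210_000, "+", "GENEDN1"),    # downstream, 135 kb away
        (2, 2_000_000, 2_040_000, "+", "GENEC"),      # spans the insertion site
        (3, 3_000_000, 3_050_000, "-", "GENED"),      # inside the inversion
    ]
    planted = [
        PlantedVariant(
            name="del_family",
            sv_type="deletion",
            chrom=1,
            start=995_000,
            end=1_065_000,
            zygosity=HETEROZYGOUS,
            carriers={
                "mother": HETEROZYGOUS,
                "U1": HETEROZYGOUS,
                "U2": HOMOZYGOUS,
            },
            parental_support="mother",
            bndb_carriers=[HOMOZYGOUS] * 12 + [HETEROZYGOUS] * 21,
            dgv_records=4,
            decipher_records=2,
        ),
        PlantedVariant(
            name="ins_denovo",
            sv_type="insertion",
            chrom=2,
            start=2_010_000,
            end=2_010_500,
            size=8_000,
            zygosity=HETEROZYGOUS,
            parental_support="none",
        ),
        PlantedVariant(
            name="inv_inherited",
            sv_type="inversion",
            chrom=3,
            start=2_990_000,
            end=3_100_000,
            zygosity=HETEROZYGOUS,
            carriers={"father": HETEROZYGOUS},
            parental_support="father",
        ),
    ]
    expression = {
        ("GENEA", "proband"): 10.0,
        ("GENEA", "mother"): 12.5,
        ("GENEA", "father"): 11.0,
        ("GENEB", "proband"): 3.25,
        ("GENEB", "mother"): 2.0,
        ("GENEB", "father"): 4.0,
        ("GENEUP1", "proband"): 7.0,
        ("GENEC", "proband"): 5.5,
    }
    genelist_rows = [
        ("OMIM", "GENEA", "osteoporosis", ""),
        ("Gene", "GENEA", "osteoporosis susceptibility", ""),
        ("ClinVar", "GENED", "osteoporosis", "Pathogenic"),
        ("GTR", "GENEC", "unrelated condition", ""),
    ]
    return FixtureSpec(
        seed=seed,
        n_cohort_samples=8,
        family_size=3,
        family_design="trio",
        planted=planted,
        genes=genes,
        expression=expression,
        genelist_rows=genelist_rows,
    )
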