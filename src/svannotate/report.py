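"""Quality filtration, sheet taxonomy and end-to-end pipeline orchestration.

The annotated calls of one sample are partitioned into a workbook whose tab
set depends on the analysis design (solo/duo/trio) and labeling dialect
(single-enzyme vs SVmerge):

=========  =============  ======================================================
design     sheets (SE)    sheets (SVmerge adds ``Mismatch``)
=========  =============  ======================================================
solo       5              all_PG_OV, indel_dup, inv, trans, [Mismatch], all
duo        6              all_PG_OV, indel_dup_notShared, indel_dup_Shared,
                          inv, trans, [Mismatch], all
trio       9              all_PG_OV, indel_dup_denovo, indel_dup_both,
                          indel_dup_mother, indel_dup_father, indel_dup_cmpdHET,
                          inv, trans, [Mismatch], all
=========  =============  ======================================================

``all`` holds every input variant with every annotation column; all other
sheets (except ``all_PG_OV`` and ``Mismatch``) contain only calls passing
the default quality filtration: supported by the sample's own molecules,
and passing the assembly chimeric-score check for duplications, inversions
and translocations.  For trios the four inheritance sheets partition the
filtered indel/duplication set and ``indel_dup_cmpdHET`` is exactly the
union of the mother-only and father-only sheets (candidate compound
heterozygotes for manual inspection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .cohort import InternalDB, internal_frequency, parental_zygosity
from .datamodel import (
    CHIMERIC_CHECK_CLASSES,
    CLASS_INVERSION,
    CLASS_MISMATCH,
    CLASS_TRANSLOCATION,
    DBVariantSet,
    INDEL_CLASSES,
    MatchCriteria,
    SVCall,
    is_common_translocation,
    parse_nanoid,
)
from .expression import ExpressionMatrix, attach_expression, combine_expression
from .frequency import bndb_frequency, public_db_frequency, truncate_percent
from .gene_overlap import (
    annotate_sv_genes,
    format_nearest_cell,
    format_overlap_cell,
)
from .genelist import PrimaryGeneList, build_gene_list, intersect_primary_genes
from .io import (
    GeneIntervalSet,
    SVCallSet,
    aggregate_bndb,
    read_bed,
    read_external_db,
    read_sv_file,
    write_report,
)

logger = logging.getLogger(__name__)

SHEET_ALL = "all"
SHEET_PG = "all_PG_OV"
SHEET_MISMATCH = "Mismatch"

_CATEGORY_SHEETS = {
    "solo": ["indel_dup", "inv", "trans"],
    "duo": ["indel_dup_notShared", "indel_dup_Shared", "inv", "trans"],
    "trio": [
        "indel_dup_denovo",
        "indel_dup_both",
        "indel_dup_mother",
        "indel_dup_father",
        "indel_dup_cmpdHET",
        "inv",
        "trans",
    ],
}


@dataclass
class SheetPlan:
    """Ordered tab list for one design x dialect entry mode."""

    design: str
    dialect: str
    sheets: List[str]


def build_sheet_plan(design: str, dialect: str) -> SheetPlan:
    if design not in _CATEGORY_SHEETS:
        raise ValueError(f"unknown design {design!r}")
    names = [SHEET_PG] + list(_CATEGORY_SHEETS[design])
    if dialect == "svmerge":
        names.append(SHEET_MISMATCH)
    names.append(SHEET_ALL)
    return SheetPlan(design=design, dialect=dialect, sheets=names)


def default_filter(calls: Sequence[SVCall]) -> List[SVCall]:
    """Default quality filtration applied to every category sheet.

    Keep a call iff it is supported by the sample's own molecules
    (found_in_self = yes) and, for duplication/inversion/translocation
    classes, its assembly chimeric score passes.
    """
    kept = []
    for call in calls:
        if call.flags.found_in_self != "yes":
            continue
        if call.klass in CHIMERIC_CHECK_CLASSES and call.flags.chimeric_pass != "pass":
            continue
        kept.append(call)
    return kept


def categorize(
    calls: Sequence[SVCall], design: str
) -> Dict[str, List[SVCall]]:
    """Assign default-filtered calls to category sheets.

    Indel classes route by inheritance evidence (trio) or control-sample
    presence (duo); inversions to ``inv``; translocations to ``trans``
    except the common/segdup-flagged types, which the upstream annotation
    classifies as likely false.  Assembly-gap (nbase) calls appear in no
    category sheet.  ``indel_dup_cmpdHET`` is mother-sheet union
    father-sheet.
    """
    sheets: Dict[str, List[SVCall]] = {name: [] for name in _CATEGORY_SHEETS[design]}
    for call in default_filter(calls):
        if call.is_nbase:
            continue
        klass = call.klass
        if klass in INDEL_CLASSES:
            if design == "solo":
                sheets["indel_dup"].append(call)
            elif design == "duo":
                name = (
                    "indel_dup_Shared"
                    if call.flags.control_support == "yes"
                    else "indel_dup_notShared"
                )
                sheets[name].append(call)
            else:  # trio
                support = call.flags.parental_support
                if support == "both":
                    sheets["indel_dup_both"].append(call)
                elif support == "mother":
                    sheets["indel_dup_mother"].append(call)
                elif support == "father":
                    sheets["indel_dup_father"].append(call)
                else:  # none / '-' / not_applicable -> de novo candidate
                    sheets["indel_dup_denovo"].append(call)
        elif klass == CLASS_INVERSION:
            sheets["inv"].append(call)
        elif klass == CLASS_TRANSLOCATION and not is_common_translocation(call.sv_type):
            sheets["trans"].append(call)
        # mismatch and unclassed types appear only in 'all' (and 'Mismatch')
    if design == "trio":
        sheets["indel_dup_cmpdHET"] = (
            sheets["indel_dup_mother"] + sheets["indel_dup_father"]
        )
    return sheets


@dataclass
class AnnotatedReport:
    """Sheet-partitioned annotated output for one sample."""

    sample: str
    plan: SheetPlan
    sheets: Dict[str, pd.DataFrame]

    def sheet(self, name: str) -> pd.DataFrame:
        return self.sheets[name]


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All inputs and options of one annotation run.

    Only the SV file is mandatory; every annotation stage whose inputs are
    absent is skipped with a logged notice and its columns are not appended.
    """

    sv_path: Union[str, Path]
    design: Optional[str] = None       # solo/duo/trio; default: inferred from file
    dialect: str = "auto"
    out_path: Optional[Union[str, Path]] = None
    tsv_dir: Optional[Union[str, Path]] = None

    bed_path: Optional[Union[str, Path]] = None
    bed_format: str = "BED"
    dgv_path: Optional[Union[str, Path]] = None
    dgv_n_samples: Optional[int] = None
    decipher_path: Optional[Union[str, Path]] = None
    decipher_n_samples: Optional[int] = None
    bndb_dir: Optional[Union[str, Path]] = None
    bndb_pattern: str = "hg19"
    bndb_n_samples: Optional[int] = None

    internal_db_path: Optional[Union[str, Path]] = None
    query_nanoid: Optional[str] = None  # nanoID of the query sample, for family exclusion

    expression_files: Sequence[Union[str, Path]] = field(default_factory=tuple)
    genelist_csv: Optional[Union[str, Path]] = None
    terms: Optional[Sequence[str]] = None
    snapshots: Optional[Dict[str, Union[str, Path]]] = None

    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    nearest_k: int = 3
    win_indel_gene: int = 3_000
    win_invtrans_gene: int = 10_000

    # optional manual rarity filtration (off by default): keep category-sheet
    # rows only when every computed frequency is below this percentage
    max_freq_perc: Optional[float] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if crit:
            cfg.criteria = MatchCriteria(**crit)
        return cfg


_FREQ_COLUMNS = [
    "DGV_Count",
    "DGV_Freq_Perc",
    "DECIPHER_Freq_Perc",
    "BNG_Freq_Perc_Filtered",
    "BNG_Freq_Perc_UnFiltered",
    "BNG_Homozygotes",
]
_INTERNAL_COLUMNS = [
    "MotherZygosity",
    "FatherZygosity",
    "Internal_Freq_Perc_Filtered",
    "Internal_Freq_Perc_Unfiltered",
    "Internal_Homozygotes",
]
_GENE_COLUMNS = [
    "OverlapGenes_strand_perc",
    "Upstream_nonOverlapGenes_dist_kb",
    "Downstream_nonOverlapGenes_dist_kb",
]


def _trunc(value: Optional[float]):
    return "-" if value is None else truncate_percent(value)


def annotate_calls(
    svset: SVCallSet,
    config: PipelineConfig,
    genes: Optional[GeneIntervalSet] = None,
    dgv: Optional[DBVariantSet] = None,
    decipher: Optional[DBVariantSet] = None,
    bndb: Optional[DBVariantSet] = None,
    internal: Optional[InternalDB] = None,
    expression: Optional[ExpressionMatrix] = None,
    genelist: Optional[PrimaryGeneList] = None,
) -> Dict[str, Dict[str, object]]:
    """Compute every annotation column for every call.

    Returns a per-call ordered mapping of appended column name -> cell
    value; column presence is uniform across calls (absent stages contribute
    no columns at all).
    """
    design = config.design or svset.analysis_design
    criteria = config.criteria
    query_identity = None
    if internal is not None:
        if config.query_nanoid:
            query_identity = parse_nanoid(config.query_nanoid)
        else:
            try:
                query_identity = parse_nanoid(svset.sample)
            except Exception:
                logger.warning(
                    "no query nanoID given and sample %r is not one; "
                    "internal frequency computed without family exclusion",
                    svset.sample,
                )

    annotations: Dict[str, Dict[str, object]] = {}
    for call in svset.calls:
        row: Dict[str, object] = {}
        if dgv is not None:
            count, perc = public_db_frequency(call, dgv, criteria)
            row["DGV_Count"] = count
            row["DGV_Freq_Perc"] = truncate_percent(perc)
        if decipher is not None:
            _, perc = public_db_frequency(call, decipher, criteria)
            row["DECIPHER_Freq_Perc"] = truncate_percent(perc)
        if bndb is not None:
            fr = bndb_frequency(call, bndb, criteria)
            row["BNG_Freq_Perc_Filtered"] = truncate_percent(fr.freq_perc_filtered)
            row["BNG_Freq_Perc_UnFiltered"] = truncate_percent(fr.freq_perc_unfiltered)
            row["BNG_Homozygotes"] = fr.homozygotes
        if internal is not None:
            if query_identity is not None and design in ("duo", "trio"):
                zyg = parental_zygosity(
                    call,
                    internal,
                    query_identity.family_id,
                    criteria,
                    project=query_identity.project,
                )
                row["MotherZygosity"] = zyg.mother_zygosity
                row["FatherZygosity"] = zyg.father_zygosity
            else:
                row["MotherZygosity"] = "-"
                row["FatherZygosity"] = "-"
            family = query_identity.family_id if query_identity else -1
            project = query_identity.project if query_identity else None
            freq = internal_frequency(call, internal, family, criteria, project=project)
            row["Internal_Freq_Perc_Filtered"] = _trunc(freq.freq_perc_filtered)
            row["Internal_Freq_Perc_Unfiltered"] = _trunc(freq.freq_perc_unfiltered)
            row["Internal_Homozygotes"] = freq.homozygotes
        if genes is not None:
            ann = annotate_sv_genes(
                call,
                genes,
                k=config.nearest_k,
                win_indel_gene=config.win_indel_gene,
                win_invtrans_gene=config.win_invtrans_gene,
            )
            row["OverlapGenes_strand_perc"] = format_overlap_cell(ann.overlaps)
            row["Upstream_nonOverlapGenes_dist_kb"] = format_nearest_cell(ann.upstream)
            row["Downstream_nonOverlapGenes_dist_kb"] = format_nearest_cell(
                ann.downstream
            )
            if expression is not None:
                row.update(
                    attach_expression(
                        ann.overlap_symbols,
                        ann.upstream_symbols,
                        ann.downstream_symbols,
                        expression,
                        design,
                    )
                )
            if genelist is not None:
                row.update(
                    intersect_primary_genes(
                        ann.overlap_symbols,
                        ann.upstream_symbols,
                        ann.downstream_symbols,
                        genelist,
                    )
                )
        annotations[call.call_id] = row
    return annotations


def _rows_to_frame(
    calls: Sequence[SVCall],
    annotations: Dict[str, Dict[str, object]],
    columns: List[str],
) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = dict(call.extras)
        row.update(annotations.get(call.call_id, {}))
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def _passes_manual_filter(
    call: SVCall, ann: Dict[str, object], max_freq: float, criteria: MatchCriteria
) -> bool:
    for col in (
        "DGV_Freq_Perc",
        "DECIPHER_Freq_Perc",
        "BNG_Freq_Perc_Filtered",
        "Internal_Freq_Perc_Filtered",
    ):
        v = ann.get(col)
        if isinstance(v, (int, float)) and v >= max_freq:
            return False
    threshold = criteria.confidence_threshold(call.klass)
    if threshold is not None and call.confidence is not None:
        if call.confidence < threshold:
            return False
    return True


def assemble_report(
    svset: SVCallSet,
    annotations: Dict[str, Dict[str, object]],
    config: PipelineConfig,
) -> AnnotatedReport:
    """Partition annotated calls into the design- and dialect-specific sheets."""
    design = config.design or svset.analysis_design
    dialect = svset.dialect
    plan = build_sheet_plan(design, dialect)

    appended: List[str] = []
    for row in annotations.values():
        for col in row:
            if col not in appended:
                appended.append(col)
        break  # column set is uniform across calls
    columns = list(svset.columns) + appended

    calls = list(svset.calls)
    category = categorize(calls, design)
    if config.max_freq_perc is not None:
        category = {
            name: [
                c
                for c in members
                if _passes_manual_filter(
                    c, annotations.get(c.call_id, {}), config.max_freq_perc, config.criteria
                )
            ]
            for name, members in category.items()
        }
        if design == "trio":
            category["indel_dup_cmpdHET"] = (
                category["indel_dup_mother"] + category["indel_dup_father"]
            )

    pg_rows = [
        c
        for c in calls
        if not c.is_nbase
        and any(
            annotations.get(c.call_id, {}).get(col, "-") != "-"
            for col in ("Overlap_PG", "Non_Overlap_UP_PG", "Non_Overlap_DN_PG")
        )
    ]
    sheets: Dict[str, pd.DataFrame] = {}
    for name in plan.sheets:
        if name == SHEET_ALL:
            members = calls
        elif name == SHEET_PG:
            members = pg_rows
        elif name == SHEET_MISMATCH:
            members = [c for c in calls if c.klass == CLASS_MISMATCH]
        else:
            members = category[name]
        sheets[name] = _rows_to_frame(members, annotations, columns)
        logger.info("sheet %-22s %6d rows", name, len(members))
    return AnnotatedReport(sample=svset.sample, plan=plan, sheets=sheets)


def run_pipeline(config: PipelineConfig) -> AnnotatedReport:
    """Execute the full annotation pipeline for one sample and write output.

    Stages: read SV file -> external frequencies (DGV, DECIPHER, BNDB) ->
    internal cohort frequency and parental zygosity -> gene overlap ->
    expression -> primary-gene-list intersection -> quality filtration and
    sheet partitioning -> workbook write.  Missing optional inputs skip
    their stage; a failure in any stage aborts with a stage-named error.
    """

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    svset = stage("read_sv", lambda: read_sv_file(config.sv_path, dialect=config.dialect))
    logger.info("read %d calls (%s, %s)", len(svset), svset.dialect, svset.analysis_design)
    if config.design and config.design != svset.analysis_design:
        logger.info(
            "design override: file suggests %s, config says %s",
            svset.analysis_design,
            config.design,
        )

    genes = dgv = decipher = bndb = internal = expression = genelist = None
    if config.bed_path:
        genes = stage("read_bed", lambda: read_bed(config.bed_path, fmt=config.bed_format))
    if config.dgv_path:
        dgv = stage(
            "read_dgv",
            lambda: read_external_db(
                "DGV", config.dgv_path, n_samples_override=config.dgv_n_samples
            ),
        )
    if config.decipher_path:
        decipher = stage(
            "read_decipher",
            lambda: read_external_db(
                "DECIPHER",
                config.decipher_path,
                n_samples_override=config.decipher_n_samples,
            ),
        )
    if config.bndb_dir:
        bndb = stage(
            "aggregate_bndb",
            lambda: aggregate_bndb(
                config.bndb_dir,
                reference_pattern=config.bndb_pattern,
                n_samples=config.bndb_n_samples,
            ),
        )
    if config.internal_db_path:
        internal = stage(
            "load_internal_db", lambda: InternalDB.from_tsv(config.internal_db_path)
        )
    if config.expression_files:
        expression = stage(
            "combine_expression", lambda: combine_expression(config.expression_files)
        )
    else:
        logger.info("no expression input; expression columns skipped")
    if config.genelist_csv:
        genelist = stage(
            "load_gene_list", lambda: PrimaryGeneList.from_csv(config.genelist_csv)
        )
    elif config.terms and config.snapshots:
        genelist = stage(
            "build_gene_list", lambda: build_gene_list(config.terms, config.snapshots)
        )
    else:
        logger.info("no gene-list input; PG columns skipped")

    design = config.design or svset.analysis_design
    if design in ("duo", "trio") and not any(
        c.flags.parental_support != "not_applicable"
        or c.flags.control_support != "not_applicable"
        for c in svset.calls
    ) and svset.calls:
        raise RuntimeError(
            f"pipeline stage 'categorize' failed: {design} design requires "
            "parental/control evidence columns, none found in input"
        )

    annotations = stage(
        "annotate",
        lambda: annotate_calls(
            svset,
            config,
            genes=genes,
            dgv=dgv,
            decipher=decipher,
            bndb=bndb,
            internal=internal,
            expression=expression,
            genelist=genelist,
        ),
    )
    report = stage("assemble", lambda: assemble_report(svset, annotations, config))
    out_path = config.out_path or f"{svset.sample}_{design}.xlsx"
    stage("write", lambda: write_report(report.sheets, out_path, tsv_dir=config.tsv_dir))
    logger.info("report written to %s (%d sheets)", out_path, len(report.sheets))
    return report
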