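"""Internal cohort database: frequency with family exclusion, parental zygosity.

Laboratories accumulate per-sample SV call files over time; concatenating
them with a family-aware sample identifier (``NR<family>.<relation>``) gives
an internal frequency resource that is far better matched to the platform's
error profile than public databases.  Frequency for a query variant excludes
every sample of the query's own family from both numerator and denominator,
so that an inherited variant is not counted as "common" merely because the
proband's relatives carry it.  For duos/trios the same matching kernel, at a
raised 90% size-similarity threshold, retrieves the parental records for a
proband call and reports each parent's zygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .datamodel import (
    CHIMERIC_CHECK_CLASSES,
    DBRecord,
    DBVariantSet,
    HETEROZYGOUS,
    HOMOZYGOUS,
    MatchCriteria,
    NanoIDError,
    RELATION_FATHER,
    RELATION_MOTHER,
    SampleIdentity,
    SVCall,
    UNKNOWN,
    parse_nanoid,
)
from .frequency import allele_denominator, count_alleles
from .matching import Match, find_matches

logger = logging.getLogger(__name__)

_ZYGOSITY_ORDER = {HOMOZYGOUS: 0, HETEROZYGOUS: 1, UNKNOWN: 2}

#: Columns of the persisted internal-database text table.
_DB_COLUMNS = [
    "nanoID",
    "Chromosome",
    "Chromosome2",
    "RefStartPos",
    "RefEndPos",
    "TypeClass",
    "Size",
    "Zygosity",
    "Confidence",
    "Found_in_self",
    "Chimeric",
    "Nbase",
]


@dataclass
class InternalDB:
    """Concatenated cohort SV records keyed by nanoID."""

    variants: DBVariantSet
    identities: List[SampleIdentity] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.variants.n_samples

    def family_members(
        self, family_id: int, project: Optional[str] = None
    ) -> List[SampleIdentity]:
        return [
            ident
            for ident in self.identities
            if ident.family_id == family_id and ident.project == project
        ]

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Persist as a tab-delimited table reloadable without the sample key."""
        rows = []
        for rec in self.variants.records:
            f = rec.flags
            rows.append(
                {
                    "nanoID": rec.sample_label,
                    "Chromosome": rec.chrom,
                    "Chromosome2": rec.chrom2,
                    "RefStartPos": rec.ref_start,
                    "RefEndPos": rec.ref_end,
                    "TypeClass": rec.sv_type_class,
                    "Size": "-" if rec.size_bp is None else rec.size_bp,
                    "Zygosity": rec.zygosity,
                    "Confidence": "-" if rec.confidence is None else rec.confidence,
                    "Found_in_self": f.found_in_self if f else "unknown",
                    "Chimeric": f.chimeric_pass if f else "unknown",
                    "Nbase": "yes" if rec.is_nbase else "no",
                }
            )
        pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "InternalDB":
        from .datamodel import QualityFlags

        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(_DB_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"internal DB {path}: missing columns {sorted(missing)}")
        records = []
        identities: Dict[str, SampleIdentity] = {}
        for _, row in df.iterrows():
            label = row["nanoID"]
            if label not in identities:
                identities[label] = parse_nanoid(label)
            flags = QualityFlags(
                found_in_self=row["Found_in_self"],
                chimeric_pass=row["Chimeric"],
                is_nbase=row["Nbase"] == "yes",
            )
            records.append(
                DBRecord(
                    sample_label=label,
                    chrom=int(row["Chromosome"]),
                    chrom2=int(row["Chromosome2"]),
                    ref_start=float(row["RefStartPos"]),
                    ref_end=float(row["RefEndPos"]),
                    sv_type_class=row["TypeClass"],
                    size_bp=None if row["Size"] == "-" else float(row["Size"]),
                    zygosity=row["Zygosity"],
                    confidence=None
                    if row["Confidence"] == "-"
                    else float(row["Confidence"]),
                    flags=flags,
                    is_nbase=row["Nbase"] == "yes",
                )
            )
        variants = DBVariantSet(
            source="INTERNAL", n_samples=len(identities), records=records
        )
        return cls(variants=variants, identities=list(identities.values()))


def build_internal_db(
    files: Sequence[Union[str, Path]],
    key: Union[Dict[str, Tuple[int, int]], pd.DataFrame],
    project: Optional[str] = None,
    dialect: str = "auto",
) -> InternalDB:
    """Concatenate per-sample SV files into an internal cohort database.

    ``key`` maps each file's sample label (its basename stem by default) to a
    ``(family_id, relation)`` pair, either as a dict or as a table with
    columns ``SampleID``/``FamilyID``/``Relation``.  Every file must map to a
    key row, and no two files may claim the same (family, relation) slot.
    """
    from .io import read_sv_file

    if isinstance(key, pd.DataFrame):
        key = {
            str(r["SampleID"]): (int(r["FamilyID"]), int(r["Relation"]))
            for _, r in key.iterrows()
        }
    if not files:
        raise ValueError("no input files: an internal database needs >= 1 sample")

    records: List[DBRecord] = []
    identities: List[SampleIdentity] = []
    seen_slots: Dict[Tuple[Optional[str], int, int], str] = {}
    for path in files:
        stem = Path(path).stem
        if stem not in key:
            raise KeyError(f"sample file {path} has no row in the relation key")
        family_id, relation = key[stem]
        try:
            ident = SampleIdentity(
                family_id=family_id, relation=relation, project=project, raw_label=stem
            )
        except NanoIDError as exc:
            raise NanoIDError(f"sample {stem}: {exc}") from exc
        slot = (project, family_id, relation)
        if slot in seen_slots:
            raise ValueError(
                f"duplicate (family, relation) = ({family_id}, {relation}) "
                f"for files {seen_slots[slot]!r} and {stem!r}"
            )
        seen_slots[slot] = stem
        identities.append(ident)
        label = ident.serialize()
        callset = read_sv_file(path, dialect=dialect)
        for call in callset.calls:
            records.append(
                DBRecord(
                    sample_label=label,
                    chrom=call.chrom,
                    chrom2=call.chrom2,
                    ref_start=call.ref_start,
                    ref_end=call.ref_end,
                    sv_type_class=call.klass,
                    size_bp=call.size_bp,
                    zygosity=call.zygosity,
                    confidence=call.confidence,
                    flags=call.flags,
                    is_nbase=call.is_nbase,
                    record_id=call.call_id,
                )
            )
    variants = DBVariantSet(
        source="INTERNAL", n_samples=len(identities), records=records
    )
    logger.info(
        "internal DB built: %d samples, %d records", len(identities), len(records)
    )
    return InternalDB(variants=variants, identities=identities)


@dataclass
class InternalFrequency:
    """Internal-cohort frequency figures; None when not computable."""

    freq_perc_filtered: Optional[float]
    freq_perc_unfiltered: Optional[float]
    homozygotes: int
    denominator: int


def _dedup(matches: Iterable[Match]) -> List[Match]:
    """Drop exact within-sample duplicate records (caller artifacts).

    SV callers occasionally emit the same variant twice under distinct call
    indices; such records are identical in every characteristic and must be
    counted once.  The key includes zygosity so a genuine hom+het pair in one
    sample survives (the per-sample max rule applies afterwards).
    """
    seen = set()
    kept = []
    for m in matches:
        r = m.record
        k = (
            r.sample_label,
            r.chrom,
            r.ref_start,
            r.ref_end,
            r.sv_type_class,
            r.size_bp,
            r.zygosity,
        )
        if k not in seen:
            seen.add(k)
            kept.append(m)
    return kept


def _passes_internal_quality(rec: DBRecord) -> bool:
    """Quality gate for the filtered internal figure.

    Candidates must not be assembly-gap (nbase) calls, must be supported by
    the sample's own molecules, and — for duplications, inversions and
    translocations — must pass the assembly chimeric-score check.
    """
    if rec.is_nbase:
        return False
    flags = rec.flags
    if flags is None or flags.found_in_self != "yes":
        return False
    if rec.sv_type_class in CHIMERIC_CHECK_CLASSES:
        if flags.chimeric_pass != "pass":
            return False
    return True


def _family_labels(db: InternalDB, family: int, project: Optional[str]) -> set:
    return {i.serialize() for i in db.family_members(family, project)}


def internal_frequency(
    query: SVCall,
    db: InternalDB,
    query_family: int,
    criteria: Optional[MatchCriteria] = None,
    project: Optional[str] = None,
) -> InternalFrequency:
    """Family-excluded internal cohort frequency of ``query``.

    Records from the query's family never enter the numerator, and the
    denominator is ``2 * (cohort size - family members)``.  The unfiltered
    figure applies matching, family exclusion and duplicate removal only; the
    filtered figure additionally applies the nbase/self-molecule/chimeric
    gates.  When the whole cohort belongs to the family the frequency is not
    computable and both figures are None.
    """
    criteria = criteria or MatchCriteria()
    fam_labels = _family_labels(db, query_family, project)
    denom = allele_denominator(db.n_samples, len(fam_labels))
    if denom <= 0:
        return InternalFrequency(None, None, 0, denom)
    unfiltered = [
        m
        for m in find_matches(query, db.variants, criteria, missing_size_ok=True)
        if m.sample_label not in fam_labels
    ]
    strict = [
        m
        for m in find_matches(query, db.variants, criteria, missing_size_ok=False)
        if m.sample_label not in fam_labels
    ]
    unfiltered = _dedup(unfiltered)
    filtered = [m for m in _dedup(strict) if _passes_internal_quality(m.record)]
    return InternalFrequency(
        freq_perc_filtered=count_alleles(filtered) / denom * 100.0,
        freq_perc_unfiltered=count_alleles(unfiltered) / denom * 100.0,
        homozygotes=sum(1 for m in filtered if m.record.zygosity == HOMOZYGOUS),
        denominator=denom,
    )


@dataclass
class ZygosityAnnotation:
    """Parental zygosity for one proband call; '-' when no parental match."""

    mother_zygosity: str = "-"
    father_zygosity: str = "-"


def _parent_zygosity(matches: List[Match]) -> str:
    zygs = sorted(
        {m.record.zygosity for m in matches},
        key=lambda z: _ZYGOSITY_ORDER.get(z, 99),
    )
    return ";".join(zygs) if zygs else "-"


def parental_zygosity(
    query: SVCall,
    db: InternalDB,
    family: int,
    criteria: Optional[MatchCriteria] = None,
    project: Optional[str] = None,
) -> ZygosityAnnotation:
    """Zygosity of the query variant in each parent of the given family.

    Matching uses the standard breakpoint windows but a 90% size-similarity
    threshold, since an inherited variant should be virtually identical to
    the parental one.  Multiple concordant parental matches collapse to a
    single value; discordant ones are joined in the fixed order homozygous <
    heterozygous < unknown.
    """
    criteria = (criteria or MatchCriteria()).replace(
        perc_similarity=MatchCriteria.PARENTAL_SIMILARITY
    )
    by_relation: Dict[int, List[Match]] = {RELATION_MOTHER: [], RELATION_FATHER: []}
    labels = {
        i.serialize(): i.relation
        for i in db.family_members(family, project)
        if i.relation in by_relation
    }
    if labels:
        for m in find_matches(query, db.variants, criteria, missing_size_ok=True):
            rel = labels.get(m.sample_label)
            if rel is not None:
                by_relation[rel].append(m)
    return ZygosityAnnotation(
        mother_zygosity=_parent_zygosity(by_relation[RELATION_MOTHER]),
        father_zygosity=_parent_zygosity(by_relation[RELATION_FATHER]),
    )
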