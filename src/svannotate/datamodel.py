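"""Shared domain types for optical-genome-mapping structural-variant annotation.

Optical genome mapping (OGM) calls structural variants (SVs) from de novo
assemblies of long, fluorescently labeled DNA molecules.  Breakpoints carry an
uncertainty of a few kilobases, so "the same" variant observed in two samples
or two databases rarely has identical coordinates.  Everything downstream —
population-frequency estimation, inheritance classification, report
partitioning — is built on the small vocabulary defined here: chromosome
codes, SV type classes, zygosity states, quality flags, cohort sample
identifiers, and the breakpoint-window match criteria.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

# --------------------------------------------------------------------------
# Chromosome codes
# --------------------------------------------------------------------------

#: Number of supported chromosome codes: autosomes 1-22, X=23, Y=24.
MAX_CHROM_CODE = 24


class UnsupportedContigError(ValueError):
    """Raised for contigs outside the 1-24 chromosome code space (chrM, alts)."""


def normalize_chromosome(label: Union[str, int]) -> int:
    """Map a chromosome token to its integer code.

    Autosomes map to 1-22, X to 23 and Y to 24 (the numeric-chromosome
    convention of the BNBED gene-file dialect and SMAP reference contig IDs).
    Case-insensitive; a leading ``chr`` prefix is stripped.

    Raises
    ------
    UnsupportedContigError
        For mitochondrial, alt or otherwise unmapped contigs, so callers can
        skip such rows with a warning instead of aborting.
    """
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    upper = text.upper()
    if upper == "X":
        return 23
    if upper == "Y":
        return 24
    try:
        code = int(float(text))
    except ValueError:
        raise UnsupportedContigError(f"unsupported contig: {label!r}") from None
    if not 1 <= code <= MAX_CHROM_CODE:
        raise UnsupportedContigError(f"unsupported contig: {label!r}")
    return code


# --------------------------------------------------------------------------
# Zygosity
# --------------------------------------------------------------------------

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
UNKNOWN = "unknown"

_ZYGOSITY_ALIASES = {
    "homozygous": HOMOZYGOUS,
    "hom": HOMOZYGOUS,
    "heterozygous": HETEROZYGOUS,
    "het": HETEROZYGOUS,
    "unknown": UNKNOWN,
}


def normalize_zygosity(value: Optional[str]) -> str:
    """Harmonize a source zygosity string; anything unrecognized is unknown."""
    if value is None:
        return UNKNOWN
    return _ZYGOSITY_ALIASES.get(str(value).strip().lower(), UNKNOWN)


# --------------------------------------------------------------------------
# SV type vocabulary
# --------------------------------------------------------------------------

#: The five coarse classes shared by all reference databases.
CLASS_INSERTION = "insertion"
CLASS_DELETION = "deletion"
CLASS_DUPLICATION = "duplication"
CLASS_INVERSION = "inversion"
CLASS_TRANSLOCATION = "translocation"
CLASS_MISMATCH = "mismatch"
CLASS_OTHER = "other"

INDEL_CLASSES = frozenset({CLASS_INSERTION, CLASS_DELETION, CLASS_DUPLICATION})
#: Classes for which the assembly chimeric-score check applies.
CHIMERIC_CHECK_CLASSES = frozenset(
    {CLASS_DUPLICATION, CLASS_INVERSION, CLASS_TRANSLOCATION}
)

_TYPE_CLASS = {
    "insertion": CLASS_INSERTION,
    "deletion": CLASS_DELETION,
    "duplication": CLASS_DUPLICATION,
    "duplication_split": CLASS_DUPLICATION,
    "duplication_inverted": CLASS_DUPLICATION,
    "inversion": CLASS_INVERSION,
    "inversion_paired": CLASS_INVERSION,
    "inversion_partial": CLASS_INVERSION,
    "inversion_repeat": CLASS_INVERSION,
    "translocation": CLASS_TRANSLOCATION,
    "translocation_intrachr": CLASS_TRANSLOCATION,
    "translocation_interchr": CLASS_TRANSLOCATION,
    "trans_intrachr_common": CLASS_TRANSLOCATION,
    "trans_interchr_common": CLASS_TRANSLOCATION,
    "trans_intrachr_segdupe": CLASS_TRANSLOCATION,
    "trans_interchr_segdupe": CLASS_TRANSLOCATION,
    "mismatch": CLASS_MISMATCH,
    "loss": CLASS_DELETION,
    "gain": CLASS_DUPLICATION,
}


def is_nbase_type(sv_type: str) -> bool:
    """True for ``*_nbase`` calls, which overlap reference assembly gaps."""
    return str(sv_type).strip().lower().endswith("_nbase")


def type_class(sv_type: str) -> str:
    """Collapse a source SV type string to one of the five coarse classes.

    ``_nbase`` suffixes are stripped before lookup (an ``insertion_nbase`` is
    still an insertion for matching purposes); unrecognized types map to
    ``other`` and are retained verbatim by readers.
    """
    key = str(sv_type).strip().lower()
    if key.endswith("_nbase"):
        key = key[: -len("_nbase")]
    return _TYPE_CLASS.get(key, CLASS_OTHER)


def is_common_translocation(sv_type: str) -> bool:
    """Translocation calls flagged common/segdup by the upstream annotation.

    These are classified as likely false and are excluded from the ``trans``
    report sheet (they remain visible in the ``all`` sheet).
    """
    key = str(sv_type).strip().lower()
    return key.startswith("trans_") and (
        key.endswith("_common") or key.endswith("_segdupe")
    )


# --------------------------------------------------------------------------
# Quality flags
# --------------------------------------------------------------------------

PARENT_NONE = "none"
PARENT_MOTHER = "mother"
PARENT_FATHER = "father"
PARENT_BOTH = "both"
NOT_APPLICABLE = "not_applicable"


@dataclass
class QualityFlags:
    """Molecule- and assembly-level quality evidence attached to one SV call.

    For dual-enzyme (SVmerge) inputs the per-enzyme columns are harmonized
    disjunctively: ``found_in_self`` is ``yes`` if either enzyme's
    self-molecule column says yes, and ``chimeric_pass`` is ``pass`` if either
    enzyme's chimeric-score column passes.
    """

    found_in_self: str = "unknown"          # yes / no / unknown
    chimeric_pass: str = "unknown"          # pass / fail / unknown
    parental_support: str = NOT_APPLICABLE  # none / mother / father / both / n.a.
    control_support: str = NOT_APPLICABLE   # yes / no / n.a.
    is_nbase: bool = False


# --------------------------------------------------------------------------
# Cohort sample identity (nanoID)
# --------------------------------------------------------------------------

RELATION_PROBAND = 1
RELATION_MOTHER = 2
RELATION_FATHER = 3

RELATION_NAMES = {
    RELATION_PROBAND: "proband",
    RELATION_MOTHER: "mother",
    RELATION_FATHER: "father",
}

_NANOID_RE = re.compile(r"^(?:(?P<project>.+)_)?NR(?P<family>\d+)\.(?P<relation>\d+)$")


class NanoIDError(ValueError):
    """Raised for malformed or unsupported cohort sample identifiers."""


@dataclass(frozen=True)
class SampleIdentity:
    """Cohort sample identifier encoding family membership and relation.

    Serialized as ``NR<family>.<relation>`` with relation 1 = proband,
    2 = mother, 3 = father, optionally prefixed ``<project>_`` when several
    projects share one institutional cohort.  Only trio relations are
    supported.
    """

    family_id: int
    relation: int
    project: Optional[str] = None
    raw_label: str = ""

    def __post_init__(self) -> None:
        if self.family_id <= 0:
            raise NanoIDError(f"family id must be positive, got {self.family_id}")
        if self.relation not in RELATION_NAMES:
            raise NanoIDError(
                f"relation code {self.relation} unsupported; only trio codes "
                f"{sorted(RELATION_NAMES)} (proband/mother/father) are allowed"
            )

    @property
    def relation_name(self) -> str:
        return RELATION_NAMES[self.relation]

    def serialize(self) -> str:
        core = f"NR{self.family_id}.{self.relation}"
        return f"{self.project}_{core}" if self.project else core

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def parse_nanoid(text: str) -> SampleIdentity:
    """Parse ``[<project>_]NR<family>.<relation>`` into a :class:`SampleIdentity`."""
    m = _NANOID_RE.match(str(text).strip())
    if m is None:
        raise NanoIDError(f"malformed nanoID: {text!r}")
    relation = int(m.group("relation"))
    if relation not in RELATION_NAMES:
        raise NanoIDError(
            f"malformed nanoID {text!r}: relation code {relation} is not a trio code"
        )
    return SampleIdentity(
        family_id=int(m.group("family")),
        relation=relation,
        project=m.group("project"),
        raw_label=str(text).strip(),
    )


# --------------------------------------------------------------------------
# Match criteria
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchCriteria:
    """Thresholds governing when two SVs count as the same variant.

    Defaults follow the OGM breakpoint-uncertainty model: +/-10 kb windows for
    insertions/deletions/duplications, +/-50 kb for inversions/translocations,
    and >=50% size similarity (raised to 90% when matching a proband call
    against its parents, since inherited variants are expected to be nearly
    identical).  The confidence thresholds and the 1 kb minimum size apply
    only to filtered reference-database frequency; duplications carry no
    confidence score and are exempt.
    """

    win_indel: int = 10_000
    win_inv_trans: int = 50_000
    perc_similarity: float = 0.50
    apply_size_to_inv_trans: bool = False
    min_db_size_bp: int = 1_000
    conf_indel: float = 0.5
    conf_inv: float = 0.01
    conf_trans: float = 0.1

    #: Size-similarity threshold used for parental (inherited-variant) matching.
    PARENTAL_SIMILARITY = 0.90

    def __post_init__(self) -> None:
        if self.win_indel < 0 or self.win_inv_trans < 0:
            raise ValueError("breakpoint windows must be non-negative")
        if not 0.0 <= self.perc_similarity <= 1.0:
            raise ValueError("perc_similarity must lie in [0, 1]")
        for name in ("conf_indel", "conf_inv", "conf_trans"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def window_for(self, klass: str) -> int:
        """Breakpoint window (bp) appropriate for an SV class."""
        if klass in (CLASS_INVERSION, CLASS_TRANSLOCATION):
            return self.win_inv_trans
        return self.win_indel

    def confidence_threshold(self, klass: str) -> Optional[float]:
        """Per-class confidence threshold, or None where no score is defined."""
        if klass in (CLASS_INSERTION, CLASS_DELETION):
            return self.conf_indel
        if klass == CLASS_INVERSION:
            return self.conf_inv
        if klass == CLASS_TRANSLOCATION:
            return self.conf_trans
        return None

    def replace(self, **kwargs) -> "MatchCriteria":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# SV call and database records
# --------------------------------------------------------------------------


@dataclass
class SVCall:
    """One structural-variant call from an SMAP or SVmerge file.

    Coordinates are 1-based inclusive reference positions.  ``chrom2`` equals
    ``chrom`` for all non-translocation types.  ``confidence`` is None when
    the caller reports no score (the conventional -1 sentinel); this is
    distinct from a score of 0 and exempt from confidence thresholds.
    ``extras`` holds every source column verbatim, in file order, so that
    report output reproduces the input row exactly plus appended annotations.
    """

    call_id: str
    chrom: int
    ref_start: float
    ref_end: float
    sv_type: str
    chrom2: Optional[int] = None
    size_bp: Optional[float] = None
    confidence: Optional[float] = None
    zygosity: str = UNKNOWN
    sample: Union[SampleIdentity, str, None] = None
    flags: QualityFlags = field(default_factory=QualityFlags)
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom2 is None:
            self.chrom2 = self.chrom
        if not 1 <= self.chrom <= MAX_CHROM_CODE:
            raise ValueError(f"chrom code {self.chrom} outside 1-{MAX_CHROM_CODE}")
        if not 1 <= self.chrom2 <= MAX_CHROM_CODE:
            raise ValueError(f"chrom2 code {self.chrom2} outside 1-{MAX_CHROM_CODE}")
        if self.klass != CLASS_TRANSLOCATION and self.ref_start > self.ref_end:
            raise ValueError(
                f"ref_start {self.ref_start} > ref_end {self.ref_end} "
                f"for non-translocation call {self.call_id}"
            )
        if self.size_bp is not None and self.size_bp < 0:
            self.size_bp = None

    @property
    def klass(self) -> str:
        return type_class(self.sv_type)

    @property
    def is_nbase(self) -> bool:
        return is_nbase_type(self.sv_type)


@dataclass
class DBRecord:
    """One record of a reference SV collection (DGV/DECIPHER/BNDB/internal).

    ``sv_type_class`` is always one of the five coarse classes; the original
    vocabulary is mapped by the reader.  Zygosity, confidence, size and
    quality flags are optional because not every source provides them.
    """

    sample_label: str
    chrom: int
    ref_start: float
    ref_end: float
    sv_type_class: str
    chrom2: Optional[int] = None
    size_bp: Optional[float] = None
    zygosity: str = UNKNOWN
    confidence: Optional[float] = None
    flags: Optional[QualityFlags] = None
    is_nbase: bool = False
    record_id: Optional[str] = None
    #: All supporting sample labels when the source lists several per record
    #: (DGV does); ``sample_label`` is then the first of them.
    samples: tuple = ()

    def __post_init__(self) -> None:
        if self.chrom2 is None:
            self.chrom2 = self.chrom

    @property
    def klass(self) -> str:
        return self.sv_type_class


@dataclass
class DBVariantSet:
    """A reference collection of SV records with a diploid sample count.

    ``n_samples`` is the number of distinct diploid individuals the
    collection represents; the allele denominator of every frequency formula
    is ``2 * n_samples``.
    """

    source: str  # DGV / DECIPHER / BNDB / INTERNAL
    n_samples: int
    records: list

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"{self.source}: n_samples must be positive")
        self._index = None

    def distinct_samples(self) -> int:
        return len({r.sample_label for r in self.records})
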