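"""Reader for Bionano SV call files: single-enzyme SMAP and dual-enzyme SVmerge.

A single-enzyme SMAP is the SVcaller output: comment lines starting ``#``, a
``#h``-prefixed column-declaration line, then tab-separated records.  The
dual-enzyme workflow merges the call sets of two nicking enzymes
(Nt.BspQI + Nb.BssSI) into one TXT file of the same shape whose
molecule-support and chimeric-score columns are duplicated per enzyme with
``BSPQI``/``BSSSI`` infixes.  The reader harmonizes the per-enzyme columns
disjunctively (support from either enzyme counts) and infers the analysis
design (solo/duo/trio) from which evidence columns are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from ..datamodel import (
    QualityFlags,
    SVCall,
    UnsupportedContigError,
    is_nbase_type,
    normalize_chromosome,
    normalize_zygosity,
)

logger = logging.getLogger(__name__)

SINGLE_ENZYME = "single_enzyme"
SVMERGE = "svmerge"

SOLO = "solo"
DUO = "duo"
TRIO = "trio"


class FormatError(ValueError):
    """Raised when a file lacks mandatory columns or a parseable header."""


#: Candidate source-column names for each consumed field, first match wins.
#: Overridable per call for schema drift across Solve releases.
DEFAULT_COLUMN_MAP: Dict[str, List[str]] = {
    "call_id": ["SmapEntryID", "SVIndex", "SmapID"],
    "chrom": ["RefcontigID1", "RefContigID1"],
    "chrom2": ["RefcontigID2", "RefContigID2"],
    "ref_start": ["RefStartPos"],
    "ref_end": ["RefEndPos"],
    "sv_type": ["Type", "SVType"],
    "size_bp": ["Size", "SVsize", "SVSize"],
    "confidence": ["Confidence"],
    "zygosity": ["Zygosity"],
}

_SELF_COLS = {
    SINGLE_ENZYME: ["Found_in_self_molecules"],
    SVMERGE: [
        "Found_in_self_BSPQI_molecules",
        "Found_in_self_BSSSI_molecule",
        "Found_in_self_BSSSI_molecules",
    ],
}
_CHIMERIC_COLS = {
    SINGLE_ENZYME: ["Fail_assembly_chimeric_score"],
    SVMERGE: [
        "Fail_BSPQI_assembly_chimeric_score",
        "Fail_BSSSI_assembly_chimeric_score",
    ],
}
_PARENT_COLS = {
    SINGLE_ENZYME: ["Found_in_parents_molecules"],
    SVMERGE: [
        "Found_in_parents_BSPQI_molecules",
        "Found_in_parents_BSSSI_molecules",
    ],
}
_CONTROL_COLS = {
    SINGLE_ENZYME: ["Found_in_control_molecules"],
    SVMERGE: [
        "Found_in_control_sample_BSPQI_molecules",
        "Found_in_control_sample_BSSSI_molecules",
        "Found_in_control_BSPQI_molecules",
        "Found_in_control_BSSSI_molecules",
    ],
}

_MANDATORY = ["chrom", "ref_start", "ref_end", "sv_type"]


@dataclass
class SVCallSet:
    """All calls of one sample file plus enough context to reproduce it."""

    sample: str
    dialect: str
    analysis_design: str
    calls: List[SVCall] = field(default_factory=list)
    source_header: List[str] = field(default_factory=list)
    columns: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)


def _split_header(lines: List[str]):
    """Separate comment lines, the column line and data lines."""
    header_lines: List[str] = []
    columns: Optional[List[str]] = None
    data: List[str] = []
    for line in lines:
        stripped = line.rstrip("\n")
        if not stripped.strip():
            continue
        if stripped.startswith("#"):
            header_lines.append(stripped)
            if stripped.startswith("#h"):
                columns = stripped[2:].strip().split("\t")
                if len(columns) == 1:
                    columns = stripped[2:].split()
        elif columns is None:
            columns = stripped.split("\t")
            if len(columns) == 1:
                columns = stripped.split()
        else:
            data.append(stripped)
    if columns is None:
        raise FormatError("no header line found (neither '#h' nor a column row)")
    return header_lines, columns, data


def _first_present(columns: List[str], names: List[str]) -> Optional[str]:
    for name in names:
        if name in columns:
            return name
    return None


def _numeric(value: str) -> Optional[float]:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if v < 0 else v  # -1 is the conventional absent sentinel


def _merge_parental(values: List[str]) -> str:
    """Disjunctive merge of per-enzyme parental-support values.

    ``-`` (no evidence, used by SVmerge) is treated as none.  Evidence from
    different enzymes is unioned: mother from one enzyme plus father from the
    other means both parents carry the variant.
    """
    parents = set()
    for v in values:
        v = str(v).strip().lower()
        if v in ("mother", "father"):
            parents.add(v)
        elif v == "both":
            parents.update(("mother", "father"))
    if parents == {"mother", "father"}:
        return "both"
    if parents:
        return next(iter(parents))
    return "none"


def read_sv_file(
    path: Union[str, Path],
    dialect: str = "auto",
    column_map: Optional[Dict[str, List[str]]] = None,
    sample: Optional[str] = None,
) -> SVCallSet:
    """Parse an SMAP or SVmerge TXT file into an :class:`SVCallSet`.

    ``dialect="auto"`` sniffs for enzyme-suffixed (BSPQI/BSSSI) quality
    columns.  Every source column is kept verbatim, in order, in each call's
    ``extras`` so downstream report output reproduces the input row exactly.
    Rows on unsupported contigs are skipped with a logged count.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    lines = path.read_text().splitlines()
    header_lines, columns, data = _split_header(lines)

    if dialect == "auto":
        dialect = SVMERGE if any("BSPQI" in c or "BSSSI" in c for c in columns) else SINGLE_ENZYME
    if dialect not in (SINGLE_ENZYME, SVMERGE):
        raise ValueError(f"unknown dialect {dialect!r}")

    resolved = {f: _first_present(columns, names) for f, names in cmap.items()}
    missing = [f for f in _MANDATORY if resolved[f] is None]
    if missing:
        raise FormatError(
            f"{path.name}: mandatory columns absent for fields {missing}; "
            f"file columns are {columns}"
        )

    self_cols = [c for c in _SELF_COLS[dialect] if c in columns]
    chim_cols = [c for c in _CHIMERIC_COLS[dialect] if c in columns]
    parent_cols = [c for c in _PARENT_COLS[dialect] if c in columns]
    control_cols = [c for c in _CONTROL_COLS[dialect] if c in columns]

    if parent_cols:
        design = TRIO
    elif control_cols:
        design = DUO
    else:
        design = SOLO

    calls: List[SVCall] = []
    skipped = 0
    for i, line in enumerate(data):
        values = line.split("\t")
        if len(values) < len(columns):
            values += [""] * (len(columns) - len(values))
        row = dict(zip(columns, values))

        def get(fieldname: str, default: str = "") -> str:
            col = resolved.get(fieldname)
            return row.get(col, default) if col else default

        try:
            chrom = normalize_chromosome(row[resolved["chrom"]])
            chrom2 = (
                normalize_chromosome(get("chrom2"))
                if resolved.get("chrom2")
                else chrom
            )
        except UnsupportedContigError:
            skipped += 1
            continue

        flags = QualityFlags(is_nbase=is_nbase_type(get("sv_type")))
        if self_cols:
            vals = [str(row.get(c, "")).strip().lower() for c in self_cols]
            flags.found_in_self = "yes" if "yes" in vals else "no"
        if chim_cols:
            vals = [str(row.get(c, "")).strip().lower() for c in chim_cols]
            flags.chimeric_pass = "pass" if "pass" in vals else "fail"
        if parent_cols:
            flags.parental_support = _merge_parental([row.get(c, "") for c in parent_cols])
        if control_cols:
            vals = [str(row.get(c, "")).strip().lower() for c in control_cols]
            flags.control_support = "yes" if "yes" in vals else "no"

        calls.append(
            SVCall(
                call_id=get("call_id") or str(i + 1),
                chrom=chrom,
                chrom2=chrom2,
                ref_start=float(row[resolved["ref_start"]]),
                ref_end=float(row[resolved["ref_end"]]),
                sv_type=get("sv_type"),
                size_bp=_numeric(get("size_bp")),
                confidence=_numeric(get("confidence")),
                zygosity=normalize_zygosity(get("zygosity")),
                flags=flags,
                extras=row,
            )
        )
    if skipped:
        logger.warning("%s: skipped %d rows on unsupported contigs", path.name, skipped)
    return SVCallSet(
        sample=sample or path.stem,
        dialect=dialect,
        analysis_design=design,
        calls=calls,
        source_header=header_lines,
        columns=columns,
    )
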