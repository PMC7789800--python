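"""Gene-expression integration.

Per-sample transcript-quantification outputs (any tool's gene-level table
reduced to symbol + TPM) are merged into a gene-by-sample matrix; sample
roles (proband / mother / father, affected or unaffected) are read from a
``_<CODE>_`` token in each file name, e.g. ``Sample23_P_expression.txt``.
Expression values of a variant's overlapping and nearest genes are then
rendered into per-role report columns as ``SYMBOL(value)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

ROLE_PROBAND = "proband"
ROLE_MOTHER = "mother"
ROLE_FATHER = "father"

#: File-name codes: P = proband, UM/AM = unaffected/affected mother,
#: UF/AF = unaffected/affected father.
ROLE_CODES: Dict[str, str] = {
    "P": ROLE_PROBAND,
    "UM": ROLE_MOTHER,
    "AM": ROLE_MOTHER,
    "UF": ROLE_FATHER,
    "AF": ROLE_FATHER,
}

_CODE_RE = re.compile(r"_({})(?=_)".format("|".join(ROLE_CODES)))


class RoleParseError(ValueError):
    """Raised when a file name carries no, or several, role codes."""


def parse_role(filename: Union[str, Path]) -> str:
    """Extract the sample role from a ``_<CODE>_`` file-name token."""
    name = Path(filename).name
    codes = _CODE_RE.findall(name)
    if not codes:
        raise RoleParseError(f"no role code (_P_/_UM_/_AM_/_UF_/_AF_) in {name!r}")
    roles = {ROLE_CODES[c] for c in codes}
    if len(roles) > 1:
        raise RoleParseError(f"ambiguous role codes {codes} in {name!r}")
    return roles.pop()


@dataclass
class ExpressionMatrix:
    """Gene-by-sample TPM matrix with role-tagged columns.

    Missing values are absent (NaN), not zero: a gene unmeasured in one
    sample is distinct from a silent gene.
    """

    data: pd.DataFrame  # index: gene symbol; columns: sample labels
    roles: Dict[str, str] = field(default_factory=dict)  # sample -> role

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    def value(self, gene: str, role: str) -> Optional[float]:
        """TPM of ``gene`` in the first sample with the given role, else None."""
        for sample, r in self.roles.items():
            if r == role:
                if gene in self.data.index:
                    v = self.data.at[gene, sample]
                    if pd.notna(v):
                        return float(v)
                return None
        return None

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.data.copy()
        out.columns = [f"{s} [{self.roles.get(s, '?')}]" for s in out.columns]
        out.to_csv(path, sep="\t", index_label="Gene")


def _read_quant_table(path: Union[str, Path]) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, value)")
    # tolerate a header row
    if not _is_number(df.iloc[0, 1]):
        df = df.iloc[1:]
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = int(values.isna().sum())
    if bad:
        raise ValueError(f"{path}: {bad} rows with non-numeric expression values")
    series = pd.Series(values.to_numpy(), index=df.iloc[:, 0].to_numpy())
    # duplicate symbols (transcript-level rows) aggregate by sum of TPM
    return series.groupby(level=0).sum()


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def combine_expression(files: Sequence[Union[str, Path]]) -> ExpressionMatrix:
    """Outer-join per-sample quantification tables into one matrix.

    Genes absent from a sample are NaN.  Each file's role is parsed from its
    name; two files may share a role only across projects, so duplicate roles
    get numbered sample labels.
    """
    if not files:
        raise ValueError("no expression files given")
    columns: Dict[str, pd.Series] = {}
    roles: Dict[str, str] = {}
    for path in files:
        role = parse_role(path)  # raises with the offending file name
        label = Path(path).stem
        if label in columns:
            label = f"{label}_{len(columns)}"
        columns[label] = _read_quant_table(path)
        roles[label] = role
    data = pd.DataFrame(columns).sort_index()
    return ExpressionMatrix(data=data, roles=roles)


def _fmt_value(v: Optional[float]) -> str:
    if v is None:
        return "-"
    text = f"{v:.2f}".rstrip("0").rstrip(".")
    return text if text else "0"


def _render(symbols: List[str], matrix: ExpressionMatrix, role: str) -> str:
    if not symbols:
        return "-"
    return ";".join(f"{s}({_fmt_value(matrix.value(s, role))})" for s in symbols)


#: Report column layout per analysis design.  Duo columns use whichever
#: parent role is present in the matrix.
def expression_columns(design: str, matrix: Optional[ExpressionMatrix] = None) -> List[str]:
    roles = _design_roles(design, matrix)
    cols = []
    for prefix, cap in (("Overlap", True), ("NonOverlapUP", False), ("NonOverlapDN", False)):
        for role in roles:
            name = role.capitalize() if cap else role
            cols.append(f"{prefix}{name}EXP")
    return cols


def _design_roles(design: str, matrix: Optional[ExpressionMatrix]) -> List[str]:
    if design == "solo":
        return [ROLE_PROBAND]
    if design == "duo":
        parent = ROLE_MOTHER
        if matrix is not None and ROLE_FATHER in matrix.roles.values() and (
            ROLE_MOTHER not in matrix.roles.values()
        ):
            parent = ROLE_FATHER
        return [ROLE_PROBAND, parent]
    if design == "trio":
        return [ROLE_PROBAND, ROLE_MOTHER, ROLE_FATHER]
    raise ValueError(f"unknown design {design!r}")


def attach_expression(
    overlap_symbols: List[str],
    upstream_symbols: List[str],
    downstream_symbols: List[str],
    matrix: ExpressionMatrix,
    design: str,
) -> Dict[str, str]:
    """Render per-role expression cells for one annotated SV row.

    Returns exactly 3 columns for solo, 6 for duo and 9 for trio designs,
    e.g. ``OverlapProbandEXP = "GENEX(10)"`` for a proband TPM of 10; genes
    absent from the matrix render as ``SYMBOL(-)`` and empty gene lists as
    ``-``.
    """
    roles = _design_roles(design, matrix)
    cells: Dict[str, str] = {}
    for prefix, symbols, cap in (
        ("Overlap", overlap_symbols, True),
        ("NonOverlapUP", upstream_symbols, False),
        ("NonOverlapDN", downstream_symbols, False),
    ):
        for role in roles:
            name = role.capitalize() if cap else role
            cells[f"{prefix}{name}EXP"] = _render(symbols, matrix, role)
    return cells
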