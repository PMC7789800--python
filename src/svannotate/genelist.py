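"""Phenotype-driven primary gene list and its intersection with SV genes.

A primary gene list maps the patient's phenotype (one or more query terms)
to candidate genes via local snapshot tables of the public term-to-gene
association resources (NCBI Gene, OMIM, GTR, ClinVar).  Matching is
case-insensitive substring over each snapshot's condition field.  Genes with
Pathogenic/Likely Pathogenic ClinVar records for a query term are flagged in
a separate clinical-significance column.  Snapshot files are the tested
core; live database queries are version-dependent and deliberately out of
the offline path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

SOURCES = ("Gene", "OMIM", "GTR", "ClinVar")

PATHOGENIC_FLAG = "Pathogenic/Likely Pathogenic"
_PATHOGENIC_VALUES = {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}


@dataclass
class GeneListEntry:
    symbol: str
    #: (term, source) provenance pairs, insertion-ordered, unique.
    terms: List[Tuple[str, str]] = field(default_factory=list)
    clinical: bool = False

    @property
    def terms_cell(self) -> str:
        return ";".join(f"{t}({s})" for t, s in self.terms)


@dataclass
class PrimaryGeneList:
    entries: List[GeneListEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_symbol = {e.symbol: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def get(self, symbol: str) -> Optional[GeneListEntry]:
        return self._by_symbol.get(symbol)

    @property
    def symbols(self) -> List[str]:
        return [e.symbol for e in self.entries]

    @property
    def flagged(self) -> List[str]:
        return [e.symbol for e in self.entries if e.clinical]

    def to_csv(self, path: Union[str, Path]) -> None:
        rows = [
            {
                "Genes": e.symbol,
                "Terms": e.terms_cell,
                "ClinicalSignificance": PATHOGENIC_FLAG if e.clinical else "-",
            }
            for e in self.entries
        ]
        pd.DataFrame(rows, columns=["Genes", "Terms", "ClinicalSignificance"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PrimaryGeneList":
        """Load a user-supplied gene list, bypassing snapshot matching."""
        df = pd.read_csv(path, dtype=str).fillna("-")
        if "Genes" not in df.columns:
            raise ValueError(f"{path}: gene list needs a 'Genes' column")
        entries = []
        for _, row in df.iterrows():
            terms: List[Tuple[str, str]] = []
            cell = row.get("Terms", "-")
            if cell and cell != "-":
                for item in str(cell).split(";"):
                    if "(" in item and item.endswith(")"):
                        term, source = item[:-1].rsplit("(", 1)
                        terms.append((term, source))
            clinical = str(row.get("ClinicalSignificance", "-")).strip() not in ("-", "")
            entries.append(GeneListEntry(row["Genes"], terms, clinical))
        return cls(entries=entries)


def _load_snapshot(source: str, table: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        path = Path(table)
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"Gene", "Condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source} snapshot: missing columns {sorted(missing)}")
    return df.fillna("")


def _as_terms(terms: Union[str, Sequence[str], Path]) -> List[str]:
    if isinstance(terms, Path) or (
        isinstance(terms, str) and Path(str(terms)).suffix.lower() in (".txt", ".lst")
        and Path(str(terms)).exists()
    ):
        lines = Path(terms).read_text().splitlines()
        out = [ln.strip() for ln in lines if ln.strip()]
    elif isinstance(terms, str):
        out = [terms]
    else:
        out = [str(t) for t in terms]
    if not out:
        raise ValueError("empty term set")
    return out


def build_gene_list(
    terms: Union[str, Sequence[str], Path],
    snapshots: Dict[str, Union[str, Path, pd.DataFrame]],
) -> PrimaryGeneList:
    """Assemble the primary gene list for one or more phenotype terms.

    ``snapshots`` maps source name (Gene/OMIM/GTR/ClinVar) to a table with
    columns ``Gene`` and ``Condition`` (ClinVar additionally
    ``ClinicalSignificance``).  Every gene whose condition field contains a
    query term, in any source and irrespective of clinical significance, is
    included; ClinVar pathogenic/likely-pathogenic genes are flagged.
    """
    term_list = _as_terms(terms)
    entries: Dict[str, GeneListEntry] = {}
    for source in SOURCES:
        if source not in snapshots:
            continue
        df = _load_snapshot(source, snapshots[source])
        conditions = df["Condition"].str.lower()
        for term in term_list:
            hits = df[conditions.str.contains(term.lower(), regex=False)]
            for _, row in hits.iterrows():
                symbol = str(row["Gene"]).strip()
                if not symbol:
                    continue
                entry = entries.setdefault(symbol, GeneListEntry(symbol))
                if (term, source) not in entry.terms:
                    entry.terms.append((term, source))
                if source == "ClinVar":
                    signif = str(row.get("ClinicalSignificance", "")).strip().lower()
                    if signif in _PATHOGENIC_VALUES:
                        entry.clinical = True
    return PrimaryGeneList(entries=list(entries.values()))


#: Report columns appended by the primary-gene-list intersection.
PG_COLUMNS = [
    "Overlap_PG",
    "Overlap_PG_Terms",
    "Non_Overlap_UP_PG",
    "Non_Overlap_UP_Terms",
    "Non_Overlap_DN_PG",
    "Non_Overlap_DN_Terms",
]


def _intersect(symbols: Iterable[str], pg: PrimaryGeneList) -> Tuple[str, str]:
    hits = [s for s in symbols if s in pg]
    if not hits:
        return "-", "-"
    genes = ";".join(hits)
    terms = ";".join(f"{s}({pg.get(s).terms_cell})" for s in hits)
    return genes, terms


def intersect_primary_genes(
    overlap_symbols: List[str],
    upstream_symbols: List[str],
    downstream_symbols: List[str],
    pg: PrimaryGeneList,
) -> Dict[str, str]:
    """Fill the six PG columns for one SV row; dashes when nothing intersects."""
    ov_g, ov_t = _intersect(overlap_symbols, pg)
    up_g, up_t = _intersect(upstream_symbols, pg)
    dn_g, dn_t = _intersect(downstream_symbols, pg)
    return {
        "Overlap_PG": ov_g,
        "Overlap_PG_Terms": ov_t,
        "Non_Overlap_UP_PG": up_g,
        "Non_Overlap_UP_Terms": up_t,
        "Non_Overlap_DN_PG": dn_g,
        "Non_Overlap_DN_Terms": dn_t,
    }
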