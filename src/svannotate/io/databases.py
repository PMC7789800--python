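"""Readers for external SV reference databases: DGV, DECIPHER and BNDB.

Each public project publishes a tab-delimited download table in its own
schema; column names and variant-class vocabulary are mapped through
per-source configuration with defaults targeting the public download
formats.  The Bionano control database (BNDB) ships as one file per SV type
per reference build and is aggregated into a single variant set.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from ..datamodel import (
    CLASS_DELETION,
    CLASS_DUPLICATION,
    CLASS_INSERTION,
    CLASS_INVERSION,
    CLASS_TRANSLOCATION,
    DBRecord,
    DBVariantSet,
    UnsupportedContigError,
    normalize_chromosome,
    normalize_zygosity,
)

logger = logging.getLogger(__name__)

#: Source vocabulary -> coarse class, covering DGV subtype strings and the
#: signed type codes of the DECIPHER population-CNV table.
VARIANT_CLASS_MAP: Dict[str, str] = {
    "loss": CLASS_DELETION,
    "deletion": CLASS_DELETION,
    "-1": CLASS_DELETION,
    "gain": CLASS_DUPLICATION,
    "duplication": CLASS_DUPLICATION,
    "1": CLASS_DUPLICATION,
    "tandem duplication": CLASS_DUPLICATION,
    "insertion": CLASS_INSERTION,
    "novel sequence insertion": CLASS_INSERTION,
    "mobile element insertion": CLASS_INSERTION,
    "inversion": CLASS_INVERSION,
    "translocation": CLASS_TRANSLOCATION,
}

#: Default column mapping per source schema; each entry may be overridden.
DEFAULT_DB_COLUMNS: Dict[str, Dict[str, Optional[str]]] = {
    "DGV": {
        "chrom": "chr",
        "start": "start",
        "end": "end",
        "type": "variantsubtype",
        "samples": "samples",       # comma-separated per-record sample list
        "sample_size": None,
        "zygosity": None,
        "confidence": None,
        "size": None,
    },
    "DECIPHER": {
        "chrom": "chr",
        "start": "start",
        "end": "end",
        "type": "type",
        "samples": None,
        "sample_size": "sample_size",
        "zygosity": None,
        "confidence": None,
        "size": None,
    },
    "BNDB": {
        "chrom": "RefcontigID1",
        "chrom2": "RefcontigID2",
        "start": "RefStartPos",
        "end": "RefEndPos",
        "type": "Type",
        "samples": "Sample",
        "sample_size": None,
        "zygosity": "Zygosity",
        "confidence": "Confidence",
        "size": "Size",
    },
}


def _map_class(value) -> Optional[str]:
    key = str(value).strip().lower()
    if key.endswith("_nbase"):
        key = key[: -len("_nbase")]
    if key in VARIANT_CLASS_MAP:
        return VARIANT_CLASS_MAP[key]
    from ..datamodel import type_class, CLASS_OTHER

    klass = type_class(key)
    return None if klass == CLASS_OTHER else klass


def _optional_float(value) -> Optional[float]:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if v < 0 else v


def _records_from_table(
    df: pd.DataFrame, colmap: Dict[str, Optional[str]], source: str
) -> List[DBRecord]:
    records: List[DBRecord] = []
    skipped = 0
    for idx, row in df.iterrows():
        klass = _map_class(row[colmap["type"]]) if colmap.get("type") else None
        if klass is None:
            skipped += 1
            continue
        try:
            chrom = normalize_chromosome(row[colmap["chrom"]])
            chrom2 = (
                normalize_chromosome(row[colmap["chrom2"]])
                if colmap.get("chrom2") and colmap["chrom2"] in df.columns
                else chrom
            )
        except UnsupportedContigError:
            skipped += 1
            continue
        start = float(row[colmap["start"]])
        end = float(row[colmap["end"]])
        size = None
        if colmap.get("size") and colmap["size"] in df.columns:
            size = _optional_float(row[colmap["size"]])
        if size is None and klass != CLASS_TRANSLOCATION:
            span = end - start + 1
            size = span if span > 0 else None
        sample_field = colmap.get("samples")
        raw_samples = (
            str(row[sample_field]) if sample_field and sample_field in df.columns else ""
        )
        labels = [s.strip() for s in raw_samples.split(",") if s.strip()] or [
            f"{source}_record_{idx}"
        ]
        zyg = (
            normalize_zygosity(row[colmap["zygosity"]])
            if colmap.get("zygosity") and colmap["zygosity"] in df.columns
            else "unknown"
        )
        conf = (
            _optional_float(row[colmap["confidence"]])
            if colmap.get("confidence") and colmap["confidence"] in df.columns
            else None
        )
        records.append(
            DBRecord(
                sample_label=labels[0],
                chrom=chrom,
                chrom2=chrom2,
                ref_start=start,
                ref_end=end,
                sv_type_class=klass,
                size_bp=size,
                zygosity=zyg,
                confidence=conf,
                record_id=str(idx),
                samples=tuple(labels),
            )
        )
    if skipped:
        logger.warning("%s: skipped %d rows with unmappable class/contig", source, skipped)
    return records


def _infer_n_samples(
    df: pd.DataFrame,
    colmap: Dict[str, Optional[str]],
    records: List[DBRecord],
) -> int:
    if colmap.get("sample_size") and colmap["sample_size"] in df.columns:
        return int(pd.to_numeric(df[colmap["sample_size"]], errors="coerce").max())
    labels: set = set()
    for r in records:
        labels.update(r.samples or (r.sample_label,))
    return len(labels)


def read_external_db(
    source: str,
    path: Union[str, Path],
    column_map: Optional[Dict[str, Optional[str]]] = None,
    n_samples_override: Optional[int] = None,
) -> DBVariantSet:
    """Load a DGV or DECIPHER download table into a :class:`DBVariantSet`.

    The cohort size defaults to the number of distinct sample identifiers in
    the file (or the maximum declared sample_size column for DECIPHER); for
    multi-study tables pass ``n_samples_override`` with the documented cohort
    size.
    """
    source = source.upper()
    if source not in ("DGV", "DECIPHER"):
        raise ValueError(f"unknown external database {source!r}")
    colmap = dict(DEFAULT_DB_COLUMNS[source])
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    records = _records_from_table(df, colmap, source)
    if not records:
        raise ValueError(f"{source} file {path}: no rows with a mappable variant class")
    n_samples = n_samples_override or _infer_n_samples(df, colmap, records)
    return DBVariantSet(source=source, n_samples=n_samples, records=records)


#: SV-type tokens expected in BNDB per-type file names.
BNDB_TYPE_TOKENS = ("indel", "duplication", "inversion", "translocation")


def aggregate_bndb(
    directory: Union[str, Path],
    reference_pattern: str = "hg19",
    n_samples: Optional[int] = None,
    column_map: Optional[Dict[str, Optional[str]]] = None,
) -> DBVariantSet:
    """Merge the per-type BNDB files of one reference build into one set.

    Files are selected by substring match of ``reference_pattern`` in the
    file name; a warning names any of the four expected SV-type files
    (indel/duplication/inversion/translocation) that are absent.  The control
    cohort size is file-external knowledge and should be passed as
    ``n_samples`` (the published database covers 234 diploid samples);
    otherwise the distinct sample labels in the files are counted.
    """
    directory = Path(directory)
    colmap = dict(DEFAULT_DB_COLUMNS["BNDB"])
    if column_map:
        colmap.update(column_map)
    files = sorted(
        p
        for p in directory.iterdir()
        if p.is_file() and reference_pattern in p.name
    )
    if not files:
        raise FileNotFoundError(
            f"no BNDB files matching {reference_pattern!r} in {directory}"
        )
    found_tokens = {
        tok for tok in BNDB_TYPE_TOKENS if any(tok in p.name.lower() for p in files)
    }
    missing = set(BNDB_TYPE_TOKENS) - found_tokens
    if missing:
        logger.warning("BNDB: no file found for SV types %s", sorted(missing))
    records: List[DBRecord] = []
    for p in files:
        df = pd.read_csv(p, sep="\t", dtype=str, comment="#")
        records.extend(_records_from_table(df, colmap, "BNDB"))
    if not records:
        raise ValueError(f"BNDB directory {directory}: no mappable records")
    if n_samples is None:
        n_samples = len({r.sample_label for r in records})
    return DBVariantSet(source="BNDB", n_samples=n_samples, records=records)
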