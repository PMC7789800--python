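"""Gene coordinate files: standard BED and the numeric-chromosome BNBED dialect.

Standard BED is 0-based half-open with ``chr``-prefixed names; the BNBED
dialect used by the OGM toolchain numbers X and Y as chromosomes 23 and 24
and stores 1-based inclusive coordinates.  Both are loaded into a single
strand-aware :class:`GeneIntervalSet` holding 1-based inclusive intervals,
with an interval-tree index per chromosome for overlap queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from intervaltree import IntervalTree

from ..datamodel import UnsupportedContigError, normalize_chromosome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    """One gene: chromosome code, 1-based inclusive span, strand, symbol."""

    chrom: int
    start: int
    end: int
    strand: str
    symbol: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneIntervalSet:
    """Strand-aware gene coordinate index keyed by chromosome."""

    entries: List[GeneInterval] = field(default_factory=list)
    _trees: Optional[Dict[int, IntervalTree]] = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.entries)

    def _index(self) -> Dict[int, IntervalTree]:
        if self._trees is None:
            trees: Dict[int, IntervalTree] = {}
            for i, g in enumerate(self.entries):
                trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, i)
            self._trees = trees
        return self._trees

    def query(self, chrom: int, start: float, end: float) -> List[GeneInterval]:
        """Genes whose 1-based inclusive span intersects [start, end]."""
        tree = self._index().get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end + 1), key=lambda iv: iv.data)
        return [self.entries[iv.data] for iv in hits]

    def on_chromosome(self, chrom: int) -> List[GeneInterval]:
        return [g for g in self.entries if g.chrom == chrom]


def _parse_row(fields: List[str], fmt: str):
    chrom = normalize_chromosome(fields[0])
    if fmt == "BED":
        start, end = int(fields[1]) + 1, int(fields[2])  # 0-based half-open -> 1-based
    else:  # BNBED: already 1-based inclusive
        start, end = int(fields[1]), int(fields[2])
    symbol = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
    strand = fields[5] if len(fields) > 5 else "+"
    if strand not in ("+", "-"):
        strand = "+"
    return GeneInterval(chrom=chrom, start=start, end=end, strand=strand, symbol=symbol)


def read_bed(path: Union[str, Path], fmt: str = "BED") -> GeneIntervalSet:
    """Load a BED/BNBED gene file into a unified :class:`GeneIntervalSet`.

    Rows on unsupported contigs (chrM, alt scaffolds) and degenerate
    zero-length intervals are skipped with a logged count.
    """
    if fmt not in ("BED", "BNBED"):
        raise ValueError(f"unknown gene-file format {fmt!r}")
    path = Path(path)
    entries: List[GeneInterval] = []
    skipped = 0
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 3:
            skipped += 1
            continue
        try:
            entry = _parse_row(fields, fmt)
        except (UnsupportedContigError, ValueError):
            skipped += 1
            continue
        if entry.start > entry.end:
            skipped += 1
            continue
        entries.append(entry)
    if skipped:
        logger.warning("%s: skipped %d unparseable/unsupported rows", path.name, skipped)
    if not entries:
        raise ValueError(f"{path}: no parseable gene rows")
    return GeneIntervalSet(entries=entries)


def convert_bed_to_bnbed(src: Union[str, Path], dst: Union[str, Path]) -> int:
    """Rewrite a standard BED file in the BNBED dialect; returns rows written.

    Chromosome names become numeric codes (X=23, Y=24) and coordinates become
    1-based inclusive.  Reading the converted file with ``fmt="BNBED"``
    yields the same :class:`GeneIntervalSet` as reading the original with
    ``fmt="BED"``.
    """
    genes = read_bed(src, fmt="BED")
    with open(dst, "w") as fh:
        for g in genes.entries:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")
    return len(genes)
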