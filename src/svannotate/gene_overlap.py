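"""Gene overlap and nearest-gene annotation for structural variants.

Each SV is annotated with the genes its interval touches — expanded by a
breakpoint-uncertainty window of 3 kb for insertions/deletions/duplications
and 10 kb for inversions/translocations — reporting each gene's strand and
the percentage of the gene covered by the (unexpanded) SV, plus the k
nearest non-overlapping genes up- and downstream with distances in kb.
Translocations are treated per breakpoint: genes within the window of either
breakpoint are reported on that breakpoint's chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .datamodel import CLASS_INVERSION, CLASS_TRANSLOCATION, SVCall
from .io.bed import GeneInterval, GeneIntervalSet

#: Default breakpoint-uncertainty windows for gene search (bp).
WIN_INDEL_GENE = 3_000
WIN_INVTRANS_GENE = 10_000

#: Display floor for a positive-but-tiny overlap percentage, so that a gene
#: found only via the uncertainty window is never confused with no overlap.
MIN_PERCENT = 0.01


@dataclass(frozen=True)
class OverlapHit:
    symbol: str
    strand: str
    percent: float


@dataclass(frozen=True)
class NearestHit:
    symbol: str
    strand: str
    distance_kb: float


@dataclass
class OverlapAnnotation:
    """Per-SV gene annotation: overlapping plus k nearest genes per side."""

    overlaps: List[OverlapHit] = field(default_factory=list)
    upstream: List[NearestHit] = field(default_factory=list)
    downstream: List[NearestHit] = field(default_factory=list)

    @property
    def overlap_symbols(self) -> List[str]:
        return [h.symbol for h in self.overlaps]

    @property
    def upstream_symbols(self) -> List[str]:
        return [h.symbol for h in self.upstream]

    @property
    def downstream_symbols(self) -> List[str]:
        return [h.symbol for h in self.downstream]


def _gene_window(sv: SVCall, win_indel_gene: int, win_invtrans_gene: int) -> int:
    if sv.klass in (CLASS_INVERSION, CLASS_TRANSLOCATION):
        return win_invtrans_gene
    return win_indel_gene


def _overlap_length(a_start: float, a_end: float, g: GeneInterval) -> float:
    return max(0.0, min(a_end, g.end) - max(a_start, g.start) + 1)


def _percent(sv_start: float, sv_end: float, g: GeneInterval) -> float:
    """Percent of the gene covered by the unexpanded SV interval.

    The search window models breakpoint uncertainty only; the reported
    percentage is always computed on the SV interval itself, capped at 100,
    and floored at a small positive display value when the gene was reached
    only through the window (raw overlap zero).
    """
    raw = _overlap_length(sv_start, sv_end, g)
    pct = min(100.0, raw / g.length * 100.0)
    return max(MIN_PERCENT, pct)


def overlap_genes(
    sv: SVCall,
    genes: GeneIntervalSet,
    win_indel_gene: int = WIN_INDEL_GENE,
    win_invtrans_gene: int = WIN_INVTRANS_GENE,
) -> List[OverlapHit]:
    """Genes intersecting the SV interval expanded by the class window.

    For translocations each breakpoint is a point: genes within the window
    of breakpoint 1 (on ``chrom``) or breakpoint 2 (on ``chrom2``) are
    reported with the percentage of the gene covered by that window.
    """
    win = _gene_window(sv, win_indel_gene, win_invtrans_gene)
    hits: List[OverlapHit] = []
    seen = set()
    if sv.klass == CLASS_TRANSLOCATION:
        breakpoints = [(sv.chrom, sv.ref_start), (sv.chrom2, sv.ref_end)]
        for chrom, pos in breakpoints:
            for g in genes.query(chrom, pos - win, pos + win):
                key = (g.chrom, g.start, g.end, g.symbol)
                if key in seen:
                    continue
                seen.add(key)
                raw = _overlap_length(pos - win, pos + win, g)
                pct = max(MIN_PERCENT, min(100.0, raw / g.length * 100.0))
                hits.append(OverlapHit(g.symbol, g.strand, pct))
        return hits
    for g in genes.query(sv.chrom, sv.ref_start - win, sv.ref_end + win):
        key = (g.chrom, g.start, g.end, g.symbol)
        if key in seen:
            continue
        seen.add(key)
        hits.append(OverlapHit(g.symbol, g.strand, _percent(sv.ref_start, sv.ref_end, g)))
    return hits


def nearest_genes(
    sv: SVCall,
    genes: GeneIntervalSet,
    k: int = 3,
    exclude: Optional[List[str]] = None,
) -> Tuple[List[NearestHit], List[NearestHit]]:
    """The k nearest non-overlapping genes on each side of the SV.

    Upstream genes lie wholly before the start breakpoint (distance =
    (start - gene end)/1000 kb); downstream genes wholly after the end
    breakpoint (on ``chrom2`` for translocations).  Genes already reported
    as overlapping are excluded; ties at equal distance break by gene start
    coordinate then symbol.
    """
    excluded = set(exclude or [])
    up: List[Tuple[float, int, str, NearestHit]] = []
    for g in genes.on_chromosome(sv.chrom):
        if g.symbol in excluded or g.end >= sv.ref_start:
            continue
        d = (sv.ref_start - g.end) / 1000.0
        up.append((d, g.start, g.symbol, NearestHit(g.symbol, g.strand, d)))
    down: List[Tuple[float, int, str, NearestHit]] = []
    down_chrom = sv.chrom2 if sv.klass == CLASS_TRANSLOCATION else sv.chrom
    for g in genes.on_chromosome(down_chrom):
        if g.symbol in excluded or g.start <= sv.ref_end:
            continue
        d = (g.start - sv.ref_end) / 1000.0
        down.append((d, g.start, g.symbol, NearestHit(g.symbol, g.strand, d)))
    up.sort(key=lambda t: t[:3])
    down.sort(key=lambda t: t[:3])
    return [t[3] for t in up[:k]], [t[3] for t in down[:k]]


def annotate_sv_genes(
    sv: SVCall,
    genes: GeneIntervalSet,
    k: int = 3,
    win_indel_gene: int = WIN_INDEL_GENE,
    win_invtrans_gene: int = WIN_INVTRANS_GENE,
) -> OverlapAnnotation:
    overlaps = overlap_genes(sv, genes, win_indel_gene, win_invtrans_gene)
    upstream, downstream = nearest_genes(
        sv, genes, k=k, exclude=[h.symbol for h in overlaps]
    )
    return OverlapAnnotation(overlaps=overlaps, upstream=upstream, downstream=downstream)


def format_overlap_cell(hits: List[OverlapHit]) -> str:
    """Render ``SYMBOL(strand:percent)`` entries joined by ';', or '-'."""
    if not hits:
        return "-"
    return ";".join(f"{h.symbol}({h.strand}:{round(h.percent, 2)})" for h in hits)


def format_nearest_cell(hits: List[NearestHit]) -> str:
    """Render ``SYMBOL(strand:distance_kb)`` entries joined by ';', or '-'."""
    if not hits:
        return "-"
    return ";".join(f"{h.symbol}({h.strand}:{h.distance_kb:.2f})" for h in hits)
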