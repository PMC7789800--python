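"""The variant-to-variant identity kernel.

Because OGM breakpoints carry kilobase-scale uncertainty, two calls of the
same variant rarely agree exactly on coordinates.  Two SVs are considered the
same when they (i) share a type class, (ii) lie on the same chromosome (both
breakpoint chromosomes for translocations), (iii) have both breakpoints
within a class-specific window of each other, and (iv), for
insertion/deletion/duplication classes, have sizes within a similarity ratio
(min/max >= threshold).  The size rule is off by default for inversions and
translocations, whose sizes are frequently absent from caller output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

from .datamodel import (
    CLASS_INVERSION,
    CLASS_TRANSLOCATION,
    DBRecord,
    DBVariantSet,
    INDEL_CLASSES,
    MatchCriteria,
    SVCall,
)


class SizeUnavailableError(ValueError):
    """Raised when a size-similarity ratio is requested for an absent size."""


def size_similarity(size_a: Optional[float], size_b: Optional[float]) -> float:
    """Symmetric size-similarity ratio ``min(a, b) / max(a, b)`` in [0, 1].

    Raises :class:`SizeUnavailableError` when either size is absent or
    non-positive; the caller decides whether such a pair is admissible.
    """
    if size_a is None or size_b is None or size_a <= 0 or size_b <= 0:
        raise SizeUnavailableError(f"size unavailable: ({size_a}, {size_b})")
    return min(size_a, size_b) / max(size_a, size_b)


def _klass(rec: Union[SVCall, DBRecord]) -> str:
    return rec.klass


def is_match(
    query: Union[SVCall, DBRecord],
    candidate: Union[SVCall, DBRecord],
    criteria: MatchCriteria,
    *,
    missing_size_ok: bool = False,
) -> bool:
    """Decide whether ``candidate`` is the same variant as ``query``.

    Window semantics are per-breakpoint absolute deltas: |Δstart| <= W and
    |Δend| <= W, with W = ``win_indel`` for indel classes and
    ``win_inv_trans`` for inversions/translocations.  When the size rule
    applies but either size is absent, the pair is rejected unless
    ``missing_size_ok`` — unfiltered frequency estimation admits such
    candidates, filtered estimation does not.
    """
    qk, ck = _klass(query), _klass(candidate)
    if qk != ck:
        return False
    if query.chrom != candidate.chrom:
        return False
    if qk == CLASS_TRANSLOCATION and query.chrom2 != candidate.chrom2:
        return False
    win = criteria.window_for(qk)
    if abs(query.ref_start - candidate.ref_start) > win:
        return False
    if abs(query.ref_end - candidate.ref_end) > win:
        return False
    size_rule = qk in INDEL_CLASSES or (
        criteria.apply_size_to_inv_trans
        and qk in (CLASS_INVERSION, CLASS_TRANSLOCATION)
    )
    if size_rule:
        try:
            ratio = size_similarity(query.size_bp, candidate.size_bp)
        except SizeUnavailableError:
            return missing_size_ok
        if ratio < criteria.perc_similarity:
            return False
    return True


@dataclass
class Match:
    """One database record matched to a query, with match diagnostics."""

    record: DBRecord
    size_similarity: Optional[float]
    start_delta: float
    end_delta: float

    @property
    def sample_label(self) -> str:
        return self.record.sample_label

    @property
    def zygosity(self) -> str:
        return self.record.zygosity


@dataclass
class MatchResult:
    """All database matches retrieved for one query call."""

    query_id: str
    matches: List[Match] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)

    @property
    def records(self) -> List[DBRecord]:
        return [m.record for m in self.matches]


def _build_index(db: DBVariantSet) -> dict:
    index: dict = {}
    for rec in db.records:
        index.setdefault((rec.chrom, rec.sv_type_class), []).append(rec)
    return index


def _make_match(query, rec) -> Match:
    try:
        ratio: Optional[float] = size_similarity(query.size_bp, rec.size_bp)
    except SizeUnavailableError:
        ratio = None
    return Match(
        record=rec,
        size_similarity=ratio,
        start_delta=rec.ref_start - query.ref_start,
        end_delta=rec.ref_end - query.ref_end,
    )


def find_matches(
    query: Union[SVCall, DBRecord],
    db: DBVariantSet,
    criteria: MatchCriteria,
    *,
    missing_size_ok: bool = False,
) -> MatchResult:
    """Retrieve every database record matching ``query``.

    Candidate lookup goes through a per-(chromosome, class) index built
    lazily on the variant set; the result is identical to a full linear scan
    with :func:`is_match`.
    """
    if getattr(db, "_index", None) is None:
        db._index = _build_index(db)
    candidates = db._index.get((query.chrom, _klass(query)), [])
    query_id = getattr(query, "call_id", None) or getattr(query, "record_id", "") or ""
    result = MatchResult(query_id=str(query_id))
    for rec in candidates:
        if is_match(query, rec, criteria, missing_size_ok=missing_size_ok):
            result.matches.append(_make_match(query, rec))
    return result
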