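"""Population frequency of a query SV in external reference databases.

Two formulas are used.  For DGV and DECIPHER, which report no zygosity, the
frequency is simply the number of matching database variants divided by the
allele count of the cohort (twice the number of diploid samples), times 100.
For the Bionano control database (BNDB), which reports zygosity, matches are
first collapsed to one per database sample, each sample contributing 2
alleles if any of its matched records is homozygous or of unknown zygosity
and 1 if heterozygous; the allele total over samples forms the numerator.
BNDB frequency is reported both unfiltered (breakpoint/size matching only)
and filtered (additionally requiring per-class confidence thresholds and a
minimum variant size), together with the number of homozygous records among
the filtered matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

from .datamodel import (
    CLASS_DUPLICATION,
    DBRecord,
    DBVariantSet,
    HETEROZYGOUS,
    HOMOZYGOUS,
    MatchCriteria,
    SVCall,
)
from .matching import Match, MatchResult, find_matches


def allele_denominator(n_samples: int, n_excluded: int = 0) -> int:
    """Allele count of a diploid cohort after excluding ``n_excluded`` samples."""
    return 2 * (n_samples - n_excluded)


def truncate_percent(value: float, ndigits: int = 2) -> float:
    """Truncate (not round) a percentage for display, e.g. 9.188 -> 9.18."""
    factor = 10 ** ndigits
    return math.floor(value * factor) / factor


def count_alleles(matches: Iterable[Union[Match, DBRecord, Tuple[str, str]]]) -> int:
    """Zygosity-aware allele count over matched database records.

    Multiple matches from the same database sample count as a single
    variant/sample: the sample contributes 2 alleles if any of its matches is
    homozygous or of unknown zygosity, otherwise 1.  Counting unknowns as 2
    deliberately overestimates the frequency, erring on the side of flagging
    variants as common.
    """
    per_sample: dict = {}
    for m in matches:
        if isinstance(m, tuple):
            label, zyg = m
        else:
            label, zyg = m.sample_label, m.zygosity
        contribution = 1 if zyg == HETEROZYGOUS else 2
        per_sample[label] = max(per_sample.get(label, 0), contribution)
    return sum(per_sample.values())


def unique_sample_count(matches: Iterable[Union[Match, DBRecord]]) -> int:
    """Distinct supporting samples across matched records."""
    labels: set = set()
    for m in matches:
        rec = m.record if isinstance(m, Match) else m
        labels.update(rec.samples or (rec.sample_label,))
    return len(labels)


@dataclass
class FrequencyResult:
    """BNDB-style frequency figures for one query SV."""

    freq_perc_filtered: float
    freq_perc_unfiltered: float
    homozygotes: int
    n_matches_filtered: int = 0
    n_matches_unfiltered: int = 0

    def __post_init__(self) -> None:
        assert 0.0 <= self.freq_perc_filtered <= 100.0 + 1e-9
        assert self.freq_perc_filtered <= self.freq_perc_unfiltered + 1e-9


def public_db_frequency(
    query: SVCall, db: DBVariantSet, criteria: Optional[MatchCriteria] = None
) -> Tuple[int, float]:
    """Frequency of ``query`` in a public database without zygosity (DGV/DECIPHER).

    Returns ``(unique matched sample count, percent frequency)`` where the
    percentage is the matched-record count over ``2 * n_samples`` times 100.
    The unique-sample count is a separate descriptive output (the DGV_Count
    column) and does not enter the percentage.
    """
    criteria = criteria or MatchCriteria()
    if db.n_samples <= 0:
        raise ValueError(f"{db.source}: sample count not configured")
    result = find_matches(query, db, criteria, missing_size_ok=True)
    percent = len(result) / allele_denominator(db.n_samples) * 100.0
    return unique_sample_count(result.matches), percent


def passes_db_quality(rec: DBRecord, criteria: MatchCriteria) -> bool:
    """Reference-database quality gate for filtered frequency.

    A candidate passes when its confidence meets the per-class threshold
    (duplications carry no score and are exempt; an absent score is likewise
    exempt rather than treated as zero) and its size is at least
    ``min_db_size_bp`` (sizes below 1 kb are likely false positives; absent
    sizes are exempt because the size cannot be assessed).
    """
    if rec.sv_type_class != CLASS_DUPLICATION:
        threshold = criteria.confidence_threshold(rec.sv_type_class)
        if threshold is not None and rec.confidence is not None:
            if rec.confidence < threshold:
                return False
    if rec.size_bp is not None and rec.size_bp < criteria.min_db_size_bp:
        return False
    return True


def bndb_frequency(
    query: SVCall, db: DBVariantSet, criteria: Optional[MatchCriteria] = None
) -> FrequencyResult:
    """Filtered and unfiltered frequency of ``query`` in the Bionano control DB.

    Unfiltered: all breakpoint/size matches (candidates with absent sizes
    admitted), allele-counted by zygosity.  Filtered: matches that satisfy the
    size-similarity rule strictly and pass the confidence/minimum-size gate.
    ``homozygotes`` counts homozygous records among the filtered matches.
    """
    criteria = criteria or MatchCriteria()
    if db.n_samples <= 0:
        raise ValueError(f"{db.source}: sample count not configured")
    unfiltered: MatchResult = find_matches(query, db, criteria, missing_size_ok=True)
    strict: MatchResult = find_matches(query, db, criteria, missing_size_ok=False)
    filtered: List[Match] = [
        m for m in strict.matches if passes_db_quality(m.record, criteria)
    ]
    denom = allele_denominator(db.n_samples)
    return FrequencyResult(
        freq_perc_filtered=count_alleles(filtered) / denom * 100.0,
        freq_perc_unfiltered=count_alleles(unfiltered.matches) / denom * 100.0,
        homozygotes=sum(1 for m in filtered if m.record.zygosity == HOMOZYGOUS),
        n_matches_filtered=len(filtered),
        n_matches_unfiltered=len(unfiltered),
    )
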