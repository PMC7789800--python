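"""Breakpoint-window matching kernel: examples, properties, index-vs-scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call, make_db, make_record
from svannotate.datamodel import MatchCriteria
from svannotate.matching import SizeUnavailableError, find_matches, is_match, size_similarity

CRIT = MatchCriteria()


class TestSizeSimilarity:
    def test_identity(self):
        assert size_similarity(1000, 1000) == 1.0

    def test_direct_ratio(self):
        assert size_similarity(500, 1000) == 0.5

    @pytest.mark.parametrize("a,b", [(None, 100), (100, None), (0, 100), (-5, 100)])
    def test_absent_or_nonpositive_sizes_signal(self, a, b):
        with pytest.raises(SizeUnavailableError):
            size_similarity(a, b)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.integers(min_value=1, max_value=10**7),
        b=st.integers(min_value=1, max_value=10**7),
    )
    def test_symmetric_and_bounded(self, a, b):
        assert size_similarity(a, b) == size_similarity(b, a)
        assert 0 < size_similarity(a, b) <= 1


class TestIsMatch:
    def test_deletion_within_10kb_windows_and_half_size(self):
        # query deletion chr1:350,000-550,000; candidates within
        # chr1:340,000-560,000 at >=50% size similarity are the same variant
        query = make_call(start=350_000, end=550_000, size=200_000)
        candidate = make_record(start=342_000, end=556_000, size=214_000)
        assert is_match(query, candidate, CRIT)

    def test_deletion_outside_start_window_rejected(self):
        query = make_call(start=350_000, end=550_000, size=200_000)
        candidate = make_record(start=339_000, end=550_000, size=211_000)
        assert not is_match(query, candidate, CRIT)

    def test_deletion_below_size_similarity_rejected(self):
        query = make_call(start=350_000, end=550_000, size=200_000)
        candidate = make_record(start=352_000, end=548_000, size=90_000)
        assert not is_match(query, candidate, CRIT)

    def test_inversion_per_breakpoint_50kb_windows(self):
        # query inversion chr1:350,000-550,000 retrieves candidates with
        # start in [300,000, 400,000] and end in [500,000, 600,000]
        query = make_call(start=350_000, end=550_000, sv_type="inversion", size=None)
        inside = make_record(start=395_000, end=560_000, klass="inversion", size=None)
        outside = make_record(start=299_000, end=560_000, klass="inversion", size=None)
        assert is_match(query, inside, CRIT)
        assert not is_match(query, outside, CRIT)

    def test_inversion_size_rule_off_by_default_but_optional(self):
        query = make_call(start=350_000, end=550_000, sv_type="inversion", size=200_000)
        tiny = make_record(start=351_000, end=549_000, klass="inversion", size=10_000)
        assert is_match(query, tiny, CRIT)
        strict = CRIT.replace(apply_size_to_inv_trans=True)
        assert not is_match(query, tiny, strict)

    def test_self_match(self):
        query = make_call()
        twin = make_record()
        assert is_match(query, twin, CRIT)

    def test_type_and_chromosome_gates(self):
        query = make_call()
        assert not is_match(query, make_record(klass="insertion"), CRIT)
        assert not is_match(query, make_record(chrom=2), CRIT)

    def test_translocation_requires_both_chromosomes(self):
        query = make_call(
            chrom=1, start=100_000, end=200_000, sv_type="translocation_interchr", size=None
        )
        query.chrom2 = 5
        same = make_record(chrom=1, start=110_000, end=190_000, klass="translocation", size=None)
        same.chrom2 = 5
        other = make_record(chrom=1, start=110_000, end=190_000, klass="translocation", size=None)
        other.chrom2 = 6
        assert is_match(query, same, CRIT)
        assert not is_match(query, other, CRIT)

    def test_missing_candidate_size_admitted_only_when_allowed(self):
        query = make_call(size=200_000)
        sizeless = make_record(start=350_000, end=550_000, size=None)
        sizeless.size_bp = None
        assert not is_match(query, sizeless, CRIT)
        assert is_match(query, sizeless, CRIT, missing_size_ok=True)


def _random_fixture(rng, n_records):
    types = ["deletion", "insertion", "duplication", "inversion"]
    records = []
    for i in range(n_records):
        start = float(rng.integers(1, 2_000_000))
        length = float(rng.integers(1_000, 300_000))
        records.append(
            make_record(
                sample=f"S{rng.integers(1, 40)}",
                chrom=int(rng.integers(1, 4)),
                start=start,
                end=start + length,
                klass=str(rng.choice(types)),
                size=length + 1,
            )
        )
    return records


class TestFindMatches:
    def test_chromosome_gate_yields_empty(self):
        db = make_db([make_record(chrom=c) for c in (2, 3, 4)])
        assert len(find_matches(make_call(chrom=1), db, CRIT)) == 0

    def test_empty_db_is_empty_result(self):
        db = make_db([make_record()])
        db.records = []
        db._index = None
        assert len(find_matches(make_call(), db, CRIT)) == 0

    def test_indexed_equals_brute_force_scan(self):
        rng = np.random.default_rng(11)
        db = make_db(_random_fixture(rng, 300))
        for _ in range(60):
            a, b = sorted(rng.integers(1, 2_000_000, size=2))
            q = make_call(
                chrom=int(rng.integers(1, 4)),
                start=float(a),
                end=float(b),
                sv_type=str(rng.choice(["deletion", "insertion", "inversion"])),
                size=float(b - a + 1),
            )
            indexed = {id(m.record) for m in find_matches(q, db, CRIT)}
            scanned = {
                id(r) for r in db.records if is_match(q, r, CRIT)
            }
            assert indexed == scanned

    def test_widening_window_never_removes_matches(self):
        rng = np.random.default_rng(5)
        db = make_db(_random_fixture(rng, 200))
        q = make_call(start=900_000, end=1_100_000, size=200_001)
        narrow = {id(m.record) for m in find_matches(q, db, CRIT)}
        wide = {
            id(m.record)
            for m in find_matches(q, db, CRIT.replace(win_indel=50_000))
        }
        assert narrow <= wide

    def test_raising_similarity_never_adds_matches(self):
        rng = np.random.default_rng(6)
        db = make_db(_random_fixture(rng, 200))
        q = make_call(start=900_000, end=1_100_000, size=200_001)
        loose = {id(m.record) for m in find_matches(q, db, CRIT)}
        tight = {
            id(m.record)
            for m in find_matches(q, db, CRIT.replace(perc_similarity=0.9))
        }
        assert tight <= loose

    def test_matches_are_recheckable(self):
        rng = np.random.default_rng(8)
        db = make_db(_random_fixture(rng, 150))
        q = make_call(start=500_000, end=700_000, size=200_001)
        for m in find_matches(q, db, CRIT):
            assert is_match(q, m.record, CRIT)
            assert abs(m.start_delta) <= CRIT.win_indel
            assert abs(m.end_delta) <= CRIT.win_indel
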