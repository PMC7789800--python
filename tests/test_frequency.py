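"""External-database frequency formulas and zygosity-aware allele counting."""

import numpy as np
import pytest

from conftest import make_call, make_db, make_record
from svannotate.datamodel import MatchCriteria
from svannotate.frequency import (
    allele_denominator,
    bndb_frequency,
    count_alleles,
    public_db_frequency,
    truncate_percent,
    unique_sample_count,
)

CRIT = MatchCriteria()


class TestCountAlleles:
    def test_single_heterozygote(self):
        assert count_alleles([("S1", "heterozygous")]) == 1

    def test_same_sample_het_plus_hom_counts_once_as_two(self):
        # multiple matches from one sample are one variant/sample
        assert count_alleles([("S1", "heterozygous"), ("S1", "homozygous")]) == 2

    def test_mixed_cohort_hand_count(self):
        matches = [("S1", "homozygous"), ("S2", "unknown"), ("S3", "heterozygous")]
        assert count_alleles(matches) == 5

    def test_unknown_zygosity_counts_two(self):
        assert count_alleles([("S1", "unknown")]) == 2


class TestTruncation:
    def test_printed_control_db_frequency(self):
        # 43 alleles over 468 = 9.188...%, displayed truncated as 9.18
        assert truncate_percent(43 / 468 * 100) == 9.18

    def test_truncates_not_rounds(self):
        assert truncate_percent(1.999) == 1.99


class TestPublicDbFrequency:
    def test_no_matches_is_zero(self):
        db = make_db([make_record(chrom=2)], n_samples=100, source="DGV")
        count, perc = public_db_frequency(make_call(), db, CRIT)
        assert (count, perc) == (0, 0.0)

    def test_four_matches_of_hundred_samples(self):
        records = [make_record(sample=f"S{i}") for i in range(4)]
        db = make_db(records, n_samples=100, source="DGV")
        count, perc = public_db_frequency(make_call(), db, CRIT)
        assert perc == pytest.approx(4 / 200 * 100)  # 2.0%
        assert count == 4

    def test_dgv_count_is_unique_samples(self):
        records = [make_record(sample="S1") for _ in range(3)]
        db = make_db(records, n_samples=50, source="DGV")
        count, perc = public_db_frequency(make_call(), db, CRIT)
        assert count == 1
        assert perc == pytest.approx(3 / 100 * 100)

    def test_multi_sample_record_counts_once_in_numerator(self):
        rec = make_record(sample="A")
        rec.samples = ("A", "B", "C")
        db = make_db([rec], n_samples=50, source="DGV")
        count, perc = public_db_frequency(make_call(), db, CRIT)
        assert count == 3
        assert perc == pytest.approx(1 / 100 * 100)

    def test_zero_samples_is_configuration_error(self):
        with pytest.raises(ValueError):
            make_db([make_record()], n_samples=0)


def _bndb_cohort(n_hom, n_het, **record_kwargs):
    records = [
        make_record(sample=f"H{i}", zygosity="homozygous", confidence=0.9, **record_kwargs)
        for i in range(n_hom)
    ] + [
        make_record(sample=f"E{i}", zygosity="heterozygous", confidence=0.9, **record_kwargs)
        for i in range(n_het)
    ]
    return records


class TestBndbFrequency:
    def test_twelve_hom_twentyone_het_of_234_samples(self):
        db = make_db(_bndb_cohort(12, 21), n_samples=234)
        fr = bndb_frequency(make_call(), db, CRIT)
        # 12*2 + 21 = 45 alleles over 468
        assert fr.freq_perc_filtered == pytest.approx(45 / 468 * 100)
        assert fr.freq_perc_unfiltered == fr.freq_perc_filtered
        assert fr.homozygotes == 12

    def test_low_confidence_excluded_from_filtered_only(self):
        good = make_record(sample="A", zygosity="heterozygous", confidence=0.9)
        low = make_record(sample="B", zygosity="heterozygous", confidence=0.4)
        db = make_db([good, low], n_samples=100)
        fr = bndb_frequency(make_call(), db, CRIT)
        assert fr.n_matches_filtered == 1
        assert fr.n_matches_unfiltered == 2

    def test_small_variant_excluded_from_filtered(self):
        query = make_call(start=10_000, end=10_800, size=801)
        rec = make_record(start=10_000, end=10_800, size=800, confidence=0.9)
        db = make_db([rec], n_samples=100)
        fr = bndb_frequency(query, db, CRIT)
        assert fr.n_matches_filtered == 0
        assert fr.n_matches_unfiltered == 1

    def test_duplications_exempt_from_confidence(self):
        query = make_call(sv_type="duplication")
        rec = make_record(klass="duplication", confidence=None)
        db = make_db([rec], n_samples=100)
        fr = bndb_frequency(query, db, CRIT)
        assert fr.n_matches_filtered == 1

    def test_filtered_never_exceeds_unfiltered_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            records = []
            for i in range(int(rng.integers(1, 30))):
                start = float(rng.integers(340_000, 360_000))
                length = float(rng.integers(500, 400_000))
                records.append(
                    make_record(
                        sample=f"S{rng.integers(1, 10)}",
                        start=start,
                        end=start + length,
                        size=length + 1,
                        zygosity=str(
                            rng.choice(["homozygous", "heterozygous", "unknown"])
                        ),
                        confidence=float(rng.uniform(0, 1)),
                    )
                )
            db = make_db(records, n_samples=30)
            fr = bndb_frequency(make_call(), db, CRIT)
            assert fr.freq_perc_filtered <= fr.freq_perc_unfiltered + 1e-12

    def test_noop_thresholds_make_filtered_equal_unfiltered(self):
        db = make_db(_bndb_cohort(3, 5), n_samples=50)
        loose = CRIT.replace(conf_indel=0.0, conf_inv=0.0, conf_trans=0.0, min_db_size_bp=0)
        fr = bndb_frequency(make_call(), db, loose)
        assert fr.freq_perc_filtered == fr.freq_perc_unfiltered

    def test_cohort_split_invariance(self):
        # splitting every carrier into two half-cohort samples with the same
        # zygosities doubles numerator and denominator alike
        db1 = make_db(_bndb_cohort(4, 6), n_samples=50)
        doubled = _bndb_cohort(4, 6) + [
            make_record(
                sample=f"{r.sample_label}_b",
                zygosity=r.zygosity,
                confidence=r.confidence,
            )
            for r in _bndb_cohort(4, 6)
        ]
        db2 = make_db(doubled, n_samples=100)
        q = make_call()
        assert bndb_frequency(q, db1, CRIT).freq_perc_filtered == pytest.approx(
            bndb_frequency(q, db2, CRIT).freq_perc_filtered
        )


class TestDenominators:
    def test_control_db_alleles(self):
        assert allele_denominator(234) == 468

    def test_family_excluded_cohort_alleles(self):
        assert allele_denominator(8, 3) == 10
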