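"""Internal cohort database: nanoID labeling, family-excluded frequency,
duplicate-call handling and parental zygosity extraction."""

import pandas as pd
import pytest

from conftest import make_call, make_record
from svannotate.cohort import (
    InternalDB,
    build_internal_db,
    internal_frequency,
    parental_zygosity,
)
from svannotate.datamodel import DBVariantSet, MatchCriteria, QualityFlags
from svannotate.simulate import write_sv_file

CRIT = MatchCriteria()

_GOOD_FLAGS = QualityFlags(found_in_self="yes", chimeric_pass="pass")


def _internal_db(records, identities):
    from svannotate.datamodel import parse_nanoid

    variants = DBVariantSet(source="INTERNAL", n_samples=len(identities), records=records)
    return InternalDB(variants=variants, identities=[parse_nanoid(i) for i in identities])


def _cohort_record(label, zygosity="heterozygous", **kwargs):
    kwargs.setdefault("flags", _GOOD_FLAGS)
    return make_record(sample=label, zygosity=zygosity, **kwargs)


@pytest.fixture
def solo_files(tmp_path):
    files = []
    for i in range(8):
        path = tmp_path / f"sample{i}.smap"
        write_sv_file(
            path,
            [
                {
                    "chrom": 1,
                    "start": 100_000.0 + 200_000 * i,
                    "end": 150_000.0 + 200_000 * i,
                    "sv_type": "deletion",
                    "size": 50_001,
                }
            ],
        )
        files.append(path)
    return files


def _key_for(files, trio_first=True):
    rows = []
    for i, path in enumerate(files):
        if trio_first and i < 3:
            rows.append({"SampleID": path.stem, "FamilyID": 23, "Relation": i + 1})
        else:
            rows.append({"SampleID": path.stem, "FamilyID": 100 + i, "Relation": 1})
    return pd.DataFrame(rows)


class TestBuildInternalDB:
    def test_trio_labels(self, solo_files):
        db = build_internal_db(solo_files[:3], _key_for(solo_files[:3]))
        labels = {r.sample_label for r in db.variants.records}
        assert labels == {"NR23.1", "NR23.2", "NR23.3"}

    def test_eight_solo_files_give_eight_samples(self, solo_files):
        db = build_internal_db(solo_files, _key_for(solo_files, trio_first=False))
        assert db.n_samples == 8

    def test_project_prefix_applied(self, solo_files):
        db = build_internal_db(
            solo_files[:1], _key_for(solo_files[:1], trio_first=False), project="ProjX"
        )
        assert db.variants.records[0].sample_label == "ProjX_NR100.1"

    def test_empty_file_list_rejected(self):
        with pytest.raises(ValueError):
            build_internal_db([], pd.DataFrame(columns=["SampleID", "FamilyID", "Relation"]))

    def test_unmapped_file_rejected(self, solo_files):
        with pytest.raises(KeyError):
            build_internal_db(solo_files[:2], _key_for(solo_files[:1]))

    def test_duplicate_family_relation_rejected(self, solo_files):
        key = _key_for(solo_files[:2])
        key.loc[1, ["FamilyID", "Relation"]] = [23, 1]
        with pytest.raises(ValueError):
            build_internal_db(solo_files[:2], key)

    def test_tsv_round_trip(self, solo_files, tmp_path):
        db = build_internal_db(solo_files, _key_for(solo_files))
        path = tmp_path / "db.tsv"
        db.to_tsv(path)
        back = InternalDB.from_tsv(path)
        assert back.n_samples == db.n_samples
        assert len(back.variants.records) == len(db.variants.records)
        assert {r.sample_label for r in back.variants.records} == {
            r.sample_label for r in db.variants.records
        }


class TestInternalFrequency:
    def _eight_sample_db(self, extra_records=()):
        identities = ["NR23.1", "NR23.2", "NR23.3"] + [f"NR{i}.1" for i in range(30, 35)]
        records = [
            _cohort_record("NR23.1"),          # proband's own call
            _cohort_record("NR23.2"),          # mother carries it too
            _cohort_record("NR30.1", zygosity="heterozygous"),
            _cohort_record("NR31.1", zygosity="homozygous"),
        ] + list(extra_records)
        return _internal_db(records, identities)

    def test_worked_thirty_percent_example(self):
        # 1 het + 1 hom non-family carrier; 8-sample cohort, 3 related:
        # 3 alleles over 2 x (8 - 3) = 10 -> 30%
        db = self._eight_sample_db()
        fr = internal_frequency(make_call(), db, query_family=23, criteria=CRIT)
        assert fr.denominator == 10
        assert fr.freq_perc_filtered == pytest.approx(30.0)
        assert fr.freq_perc_unfiltered == pytest.approx(30.0)
        assert fr.homozygotes == 1

    def test_duplicate_caller_record_counted_once(self):
        dup = _cohort_record("NR30.1", zygosity="heterozygous")
        db = self._eight_sample_db(extra_records=[dup])
        fr = internal_frequency(make_call(), db, query_family=23, criteria=CRIT)
        assert fr.freq_perc_unfiltered == pytest.approx(30.0)

    def test_family_records_never_change_frequency(self):
        more_family = [
            _cohort_record("NR23.2", zygosity="homozygous"),
            _cohort_record("NR23.3", zygosity="homozygous"),
        ]
        base = self._eight_sample_db()
        inflated = self._eight_sample_db(extra_records=more_family)
        q = make_call()
        assert internal_frequency(q, base, 23, CRIT).freq_perc_unfiltered == (
            internal_frequency(q, inflated, 23, CRIT).freq_perc_unfiltered
        )

    def test_no_matches_is_zero(self):
        db = self._eight_sample_db()
        fr = internal_frequency(make_call(chrom=2), db, query_family=23, criteria=CRIT)
        assert (fr.freq_perc_filtered, fr.freq_perc_unfiltered) == (0.0, 0.0)

    def test_whole_cohort_family_not_computable(self):
        db = _internal_db([_cohort_record("NR23.2")], ["NR23.1", "NR23.2", "NR23.3"])
        fr = internal_frequency(make_call(), db, query_family=23, criteria=CRIT)
        assert fr.freq_perc_filtered is None
        assert fr.freq_perc_unfiltered is None

    def test_planted_hom_carriers_recover_exact_frequency(self):
        # k hom carriers among N unrelated samples -> 2k / 2N x 100 exactly
        identities = [f"NR{i}.1" for i in range(50, 60)]
        records = [
            _cohort_record(f"NR{i}.1", zygosity="homozygous") for i in (52, 55, 57)
        ]
        db = _internal_db(records, identities)
        fr = internal_frequency(make_call(), db, query_family=1, criteria=CRIT)
        assert fr.freq_perc_unfiltered == pytest.approx(2 * 3 / (2 * 10) * 100)

    def test_quality_gates_apply_to_filtered_only(self):
        records = [
            _cohort_record("NR30.1"),
            make_record(
                sample="NR31.1",
                zygosity="heterozygous",
                flags=QualityFlags(found_in_self="no", chimeric_pass="pass"),
            ),
            make_record(
                sample="NR32.1",
                zygosity="heterozygous",
                flags=_GOOD_FLAGS,
                is_nbase=True,
            ),
        ]
        identities = ["NR23.1"] + [f"NR{i}.1" for i in range(30, 37)]
        db = _internal_db(records, identities)
        fr = internal_frequency(make_call(), db, query_family=23, criteria=CRIT)
        assert fr.freq_perc_unfiltered == pytest.approx(3 / 14 * 100)
        assert fr.freq_perc_filtered == pytest.approx(1 / 14 * 100)

    def test_chimeric_gate_applies_to_duplications_not_indels(self):
        chim_fail = QualityFlags(found_in_self="yes", chimeric_pass="fail")
        records = [
            make_record(sample="NR30.1", klass="deletion", flags=chim_fail),
            make_record(sample="NR31.1", klass="duplication", flags=chim_fail),
        ]
        identities = ["NR23.1"] + [f"NR{i}.1" for i in range(30, 33)]
        db = _internal_db(records, identities)
        del_fr = internal_frequency(make_call(), db, 23, CRIT)
        dup_fr = internal_frequency(make_call(sv_type="duplication"), db, 23, CRIT)
        assert del_fr.freq_perc_filtered > 0    # indels exempt from chimeric gate
        assert dup_fr.freq_perc_filtered == 0.0


class TestParentalZygosity:
    def _family_db(self, records):
        return _internal_db(records, ["NR23.1", "NR23.2", "NR23.3"])

    def test_maternal_het_at_identical_breakpoints(self):
        db = self._family_db([_cohort_record("NR23.2", zygosity="heterozygous")])
        zyg = parental_zygosity(make_call(), db, family=23, criteria=CRIT)
        assert zyg.mother_zygosity == "heterozygous"
        assert zyg.father_zygosity == "-"

    def test_shifted_maternal_call_retained_above_90_percent(self):
        # a second maternal call with shifted start but >90% size similarity
        # collapses to the same single zygosity value
        records = [
            _cohort_record("NR23.2", zygosity="heterozygous"),
            _cohort_record(
                "NR23.2",
                zygosity="heterozygous",
                start=344_000,
                end=550_000,
                size=206_001,
            ),
        ]
        db = self._family_db(records)
        zyg = parental_zygosity(make_call(), db, family=23, criteria=CRIT)
        assert zyg.mother_zygosity == "heterozygous"

    def test_inherited_matching_uses_90_percent_similarity(self):
        # within windows but only ~60% size similarity: same-variant at the
        # default threshold, rejected for inherited-variant matching
        records = [
            _cohort_record(
                "NR23.3",
                zygosity="heterozygous",
                start=352_000,
                end=548_000,
                size=120_000,
            )
        ]
        db = self._family_db(records)
        zyg = parental_zygosity(make_call(), db, family=23, criteria=CRIT)
        assert zyg.father_zygosity == "-"

    def test_discordant_zygosities_joined_in_fixed_order(self):
        records = [
            _cohort_record("NR23.2", zygosity="heterozygous"),
            _cohort_record("NR23.2", zygosity="homozygous", start=349_000, size=201_001),
        ]
        db = self._family_db(records)
        zyg = parental_zygosity(make_call(), db, family=23, criteria=CRIT)
        assert zyg.mother_zygosity == "homozygous;heterozygous"
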