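"""Default filtration rules, sheet taxonomy and partition invariants."""

import openpyxl
import pandas as pd
import pytest

from conftest import make_call
from svannotate.datamodel import QualityFlags
from svannotate.report import (
    PipelineConfig,
    build_sheet_plan,
    categorize,
    default_filter,
    run_pipeline,
)
from svannotate.simulate import write_sv_file


def call_with_flags(sv_type="deletion", found="yes", chimeric="pass", **flag_kwargs):
    flags = QualityFlags(found_in_self=found, chimeric_pass=chimeric, **flag_kwargs)
    return make_call(sv_type=sv_type, flags=flags, call_id=f"{sv_type}_{found}_{chimeric}")


class TestDefaultFilter:
    @pytest.mark.parametrize(
        "sv_type,found,chimeric,kept",
        [
            ("deletion", "no", "pass", False),       # self-molecule check, all types
            ("deletion", "yes", "fail", True),       # chimeric gate not applied to indels
            ("insertion", "yes", "fail", True),
            ("duplication", "yes", "fail", False),   # chimeric gate for dup/inv/trans
            ("inversion", "yes", "fail", False),
            ("translocation_interchr", "yes", "fail", False),
            ("duplication", "yes", "pass", True),
            ("inversion", "yes", "pass", True),
        ],
    )
    def test_rule_table(self, sv_type, found, chimeric, kept):
        calls = [call_with_flags(sv_type, found, chimeric)]
        assert (len(default_filter(calls)) == 1) == kept


class TestCategorize:
    def _trio_call(self, sv_type, support, **kw):
        return make_call(
            sv_type=sv_type,
            flags=QualityFlags(
                found_in_self="yes", chimeric_pass="pass", parental_support=support
            ),
            call_id=f"{sv_type}_{support}_{id(object())}",
            **kw,
        )

    def test_parental_routing(self):
        calls = [
            self._trio_call("deletion", "none"),
            self._trio_call("insertion", "both"),
            self._trio_call("duplication", "mother"),
            self._trio_call("deletion", "father"),
        ]
        sheets = categorize(calls, "trio")
        assert [c.flags.parental_support for c in sheets["indel_dup_denovo"]] == ["none"]
        assert len(sheets["indel_dup_both"]) == 1
        assert len(sheets["indel_dup_mother"]) == 1
        assert len(sheets["indel_dup_father"]) == 1

    def test_cmpdhet_is_union_of_single_parent_sheets(self):
        calls = [self._trio_call("deletion", "mother") for _ in range(3)] + [
            self._trio_call("insertion", "father") for _ in range(2)
        ]
        sheets = categorize(calls, "trio")
        assert len(sheets["indel_dup_cmpdHET"]) == 5
        assert sheets["indel_dup_cmpdHET"] == (
            sheets["indel_dup_mother"] + sheets["indel_dup_father"]
        )

    def test_partition_of_filtered_indel_set(self):
        calls = [
            self._trio_call(t, s)
            for t in ("deletion", "insertion", "duplication")
            for s in ("none", "both", "mother", "father")
        ]
        sheets = categorize(calls, "trio")
        inheritance = ["indel_dup_denovo", "indel_dup_both", "indel_dup_mother", "indel_dup_father"]
        ids = [id(c) for name in inheritance for c in sheets[name]]
        assert len(ids) == len(set(ids)) == len(calls)

    def test_common_translocations_excluded_from_trans_sheet(self):
        good = self._trio_call("translocation_interchr", "none")
        common = self._trio_call("trans_interchr_common", "none")
        sheets = categorize([good, common], "trio")
        assert [c.sv_type for c in sheets["trans"]] == ["translocation_interchr"]

    def test_nbase_calls_in_no_category_sheet(self):
        nbase = self._trio_call("deletion_nbase", "none")
        sheets = categorize([nbase], "trio")
        assert all(not members for members in sheets.values())

    def test_inversion_subtypes_routed_to_inv(self):
        calls = [
            self._trio_call(t, "none")
            for t in ("inversion", "inversion_paired", "inversion_partial", "inversion_repeat")
        ]
        assert len(categorize(calls, "trio")["inv"]) == 4

    def test_duo_control_sharing(self):
        shared = make_call(
            sv_type="deletion",
            flags=QualityFlags(found_in_self="yes", control_support="yes"),
            call_id="a",
        )
        unshared = make_call(
            sv_type="deletion",
            flags=QualityFlags(found_in_self="yes", control_support="no"),
            call_id="b",
        )
        sheets = categorize([shared, unshared], "duo")
        assert [c.call_id for c in sheets["indel_dup_Shared"]] == ["a"]
        assert [c.call_id for c in sheets["indel_dup_notShared"]] == ["b"]


class TestSheetPlans:
    @pytest.mark.parametrize(
        "design,dialect,count",
        [
            ("solo", "single_enzyme", 5),
            ("solo", "svmerge", 6),
            ("duo", "single_enzyme", 6),
            ("duo", "svmerge", 7),
            ("trio", "single_enzyme", 9),
            ("trio", "svmerge", 10),
        ],
    )
    def test_tab_counts_in_written_workbooks(self, tmp_path, design, dialect, count):
        records = [
            {"chrom": 1, "start": 100_000.0, "end": 150_000.0, "sv_type": "deletion",
             "size": 50_001},
            {"chrom": 2, "start": 200_000.0, "end": 400_000.0, "sv_type": "inversion",
             "size": 200_001},
        ]
        if dialect == "svmerge":
            records.append(
                {"chrom": 1, "start": 5_000.0, "end": 6_000.0, "sv_type": "MisMatch",
                 "size": 1_001}
            )
        path = tmp_path / "in.smap"
        write_sv_file(path, records, dialect=dialect, design=design)
        out = tmp_path / "out.xlsx"
        run_pipeline(PipelineConfig(sv_path=path, design=design, out_path=out))
        wb = openpyxl.load_workbook(out)
        assert len(wb.sheetnames) == count
        assert wb.sheetnames == build_sheet_plan(design, dialect).sheets
        assert wb.sheetnames[-1] == "all"

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            build_sheet_plan("quartet", "single_enzyme")


class TestReportAssembly:
    def test_all_sheet_keeps_every_input_row(self, trio_run):
        n_input = sum(
            1
            for line in open(trio_run.bundle.proband_sv)
            if line.strip() and not line.startswith("#")
        )
        assert len(trio_run.report.sheet("all")) == n_input

    def test_partition_invariants_on_trio_bundle(self, trio_run):
        rep = trio_run.report
        inheritance = ["indel_dup_denovo", "indel_dup_both", "indel_dup_mother", "indel_dup_father"]
        n_inherit = sum(len(rep.sheet(s)) for s in inheritance)
        all_df = rep.sheet("all")
        filtered_indels = all_df[
            all_df["Type"].map(
                lambda t: t in ("insertion", "deletion", "duplication")
            )
        ]
        assert n_inherit == len(filtered_indels)
        assert len(rep.sheet("indel_dup_cmpdHET")) == len(rep.sheet("indel_dup_mother")) + len(
            rep.sheet("indel_dup_father")
        )

    def test_annotation_columns_present_in_all_sheet(self, trio_run):
        cols = set(trio_run.report.sheet("all").columns)
        for expected in (
            "DGV_Count", "DGV_Freq_Perc", "DECIPHER_Freq_Perc",
            "BNG_Freq_Perc_Filtered", "BNG_Freq_Perc_UnFiltered", "BNG_Homozygotes",
            "MotherZygosity", "FatherZygosity",
            "Internal_Freq_Perc_Filtered", "Internal_Freq_Perc_Unfiltered",
            "Internal_Homozygotes",
            "OverlapGenes_strand_perc", "Upstream_nonOverlapGenes_dist_kb",
            "Downstream_nonOverlapGenes_dist_kb",
            "Overlap_PG", "Overlap_PG_Terms",
        ):
            assert expected in cols

    def test_rerun_is_deterministic(self, trio_run):
        rerun = run_pipeline(trio_run.config)
        for name, df in trio_run.report.sheets.items():
            pd.testing.assert_frame_equal(df, rerun.sheet(name))

    def test_pg_sheet_contains_flagged_deletion(self, trio_run):
        pg = trio_run.report.sheet("all_PG_OV")
        assert (pd.to_numeric(pg["RefStartPos"]) == 995_000.0).any()
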