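"""Shared fixtures: a fully annotated synthetic trio bundle plus helpers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

from svannotate.cohort import InternalDB, build_internal_db
from svannotate.datamodel import DBRecord, DBVariantSet, SVCall
from svannotate.report import PipelineConfig, run_pipeline
from svannotate.simulate import FixtureBundle, FixtureSpec, default_trio_spec, generate_fixture


def make_call(
    chrom=1,
    start=350_000.0,
    end=550_000.0,
    sv_type="deletion",
    size=None,
    call_id="q1",
    **kwargs,
) -> SVCall:
    if size is None and sv_type not in ("translocation_interchr",):
        size = end - start + 1
    return SVCall(
        call_id=call_id,
        chrom=chrom,
        ref_start=start,
        ref_end=end,
        sv_type=sv_type,
        size_bp=size,
        **kwargs,
    )


def make_record(
    sample="S1",
    chrom=1,
    start=350_000.0,
    end=550_000.0,
    klass="deletion",
    size=None,
    **kwargs,
) -> DBRecord:
    if size is None:
        size = end - start + 1
    return DBRecord(
        sample_label=sample,
        chrom=chrom,
        ref_start=start,
        ref_end=end,
        sv_type_class=klass,
        size_bp=size,
        **kwargs,
    )


def make_db(records, n_samples=None, source="BNDB") -> DBVariantSet:
    if n_samples is None:
        n_samples = max(1, len({r.sample_label for r in records}))
    return DBVariantSet(source=source, n_samples=n_samples, records=list(records))


@dataclass
class TrioRun:
    spec: FixtureSpec
    bundle: FixtureBundle
    internal: InternalDB
    config: PipelineConfig
    report: object

    def planted_row(self, sheet: str, start: float) -> pd.Series:
        df = self.report.sheet(sheet)
        hits = df[pd.to_numeric(df["RefStartPos"]) == start]
        assert len(hits) == 1, f"expected 1 row at {start} in {sheet}, got {len(hits)}"
        return hits.iloc[0]


@pytest.fixture(scope="session")
def trio_run(tmp_path_factory) -> TrioRun:
    """Generate the default trio bundle and run the full pipeline once."""
    tmp = tmp_path_factory.mktemp("trio")
    spec = default_trio_spec(seed=7)
    bundle = generate_fixture(spec, tmp / "bundle")
    key = pd.read_csv(bundle.key_file, sep="\t")
    internal = build_internal_db(bundle.cohort_files, key)
    db_path = tmp / "internal.tsv"
    internal.to_tsv(db_path)
    config = PipelineConfig(
        sv_path=bundle.proband_sv,
        design="trio",
        bed_path=bundle.bed_file,
        dgv_path=bundle.dgv_file,
        dgv_n_samples=spec.dgv_n_samples,
        decipher_path=bundle.decipher_file,
        decipher_n_samples=spec.decipher_n_samples,
        bndb_dir=bundle.bndb_dir,
        bndb_n_samples=spec.bndb_n_samples,
        internal_db_path=db_path,
        query_nanoid=f"NR{spec.family_id}.1",
        expression_files=bundle.expression_files,
        terms=["osteoporosis"],
        snapshots=bundle.snapshot_files,
        out_path=tmp / "report.xlsx",
        tsv_dir=tmp / "sheets",
    )
    report = run_pipeline(config)
    return TrioRun(spec=spec, bundle=bundle, internal=internal, config=config, report=report)
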