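"""Multi-sheet report output.

The deliverable of a run is one Excel workbook per sample, with one tab per
variant category (the tab set depends on the analysis design and labeling
dialect).  A TSV escape hatch emits one file per sheet for pipeline use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd


def write_report(
    sheets: Dict[str, pd.DataFrame],
    path: Union[str, Path],
    tsv_dir: Optional[Union[str, Path]] = None,
) -> None:
    """Write an ordered dict of sheet-name -> DataFrame as one XLSX workbook.

    Sheet order follows dict insertion order.  When ``tsv_dir`` is given,
    each sheet is additionally written as ``<sheet>.tsv`` in that directory.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in sheets.items():
            df.to_excel(writer, sheet_name=name[:31], index=False)
    if tsv_dir is not None:
        tsv_dir = Path(tsv_dir)
        tsv_dir.mkdir(parents=True, exist_ok=True)
        for name, df in sheets.items():
            df.to_csv(tsv_dir / f"{name}.tsv", sep="\t", index=False)


def read_report(path: Union[str, Path]) -> Dict[str, pd.DataFrame]:
    """Read a written workbook back as sheet-name -> DataFrame (for checks)."""
    return pd.read_excel(path, sheet_name=None)
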