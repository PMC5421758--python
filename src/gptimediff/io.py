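"""Readers and writers for the package's plain-text formats.

Expression matrices are TSV with probes as rows (first column ``probe_id``)
and sample ids as column headers; sample sheets are TSV with columns
sample_id, cell_line, treatment, dose_uM, time_h, replicate.  Results go out
as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_line", "treatment", "dose_uM",
                        "time_h", "replicate")


def read_expression(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe id(s) in expression matrix: {dups}")
    return matrix


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def validate_matrix_sheet(matrix: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Every matrix column must appear exactly once in the sheet and vice
    versa; errors name the offending sample id."""
    matrix_ids = list(matrix.columns)
    sheet_ids = list(sheet["sample_id"])
    dup = {s for s in sheet_ids if sheet_ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample id(s) in sample sheet: {sorted(dup)}")
    missing = [s for s in matrix_ids if s not in set(sheet_ids)]
    if missing:
        raise ValueError(f"sample(s) in matrix but not in sheet: {missing}")
    extra = [s for s in sheet_ids if s not in set(matrix_ids)]
    if extra:
        raise ValueError(f"sample(s) in sheet but not in matrix: {extra}")


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), the recommended variance-stabilisation for raw-scale
    microarray intensities."""
    return np.log2(matrix + 1.0)
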