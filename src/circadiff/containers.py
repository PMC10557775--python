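"""In-memory containers shared across the pipeline.

The central object is :class:`ExpressionTimeCourse`: a gene x sample matrix of
expression values on a log10(1 + normalized count) scale, together with a
sample sheet giving, for every column, the serum age group (``young`` /
``old``), the serum donor within that group, and the time in hours since
serum addition.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

GROUPS = ("young", "old")


@dataclass
class ExpressionTimeCourse:
    """Gene x sample expression matrix with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample, values on the
        log10(1 + normalized count) scale.
    samples
        DataFrame indexed by sample id with columns ``group`` (one of
        ``young``/``old``), ``subject`` (serum donor label within the group)
        and ``time_h`` (hours since synchronization).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ("group", "subject", "time_h") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        mat_ids = list(self.values.columns)
        sheet_ids = list(self.samples.index)
        if set(mat_ids) != set(sheet_ids):
            only_mat = sorted(set(mat_ids) - set(sheet_ids))[:5]
            only_sheet = sorted(set(sheet_ids) - set(mat_ids))[:5]
            raise ValueError(
                "matrix columns and sample sheet disagree; "
                f"only in matrix: {only_mat}; only in sheet: {only_sheet}"
            )
        bad_groups = set(self.samples["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}; expected {GROUPS}")
        # align sheet to matrix column order
        self.samples = self.samples.loc[mat_ids]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_indicator(self) -> pd.Series:
        """0 for young (reference), 1 for old."""
        return (self.samples["group"] == "old").astype(int)

    # ---------------------------------------------------------------- I/O
    def write(self, matrix_tsv: str | Path, sample_csv: str | Path, header: str = "") -> None:
        """Write the matrix as TSV (first column gene id) and sheet as CSV."""
        for path, df, sep in (
            (matrix_tsv, self.values.rename_axis("gene_id"), "\t"),
            (sample_csv, self.samples.rename_axis("sample_id"), ","),
        ):
            with open(path, "w") as fh:
                if header:
                    fh.write(header)
                df.to_csv(fh, sep=sep, float_format="%.10g")

    @classmethod
    def read(cls, matrix_tsv: str | Path, sample_csv: str | Path) -> "ExpressionTimeCourse":
        values = _read_commented(matrix_tsv, sep="\t").set_index("gene_id")
        samples = _read_commented(sample_csv, sep=",").set_index("sample_id")
        return cls(values=values, samples=samples)


def _read_commented(path: str | Path, sep: str) -> pd.DataFrame:
    """Read a delimited table, skipping '#' header comment lines."""
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(_io.StringIO(text), sep=sep)
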