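"""Readers/writers for the small text formats the pipeline exchanges.

BED (genes, peaks, TAD intervals), BEDPE (loops), bedGraph (tracks), and
TSV tables. All coordinates 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED_COLS[: df.shape[1]] + list(df.columns[6:])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs >= 6 columns")
    df.columns = BEDPE_COLS[: df.shape[1]] + list(df.columns[8:])
    return df


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BEDPE_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(df: pd.DataFrame, path: str | Path, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def read_bedgraph(path: str | Path, value_col: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str},
                     names=["chrom", "start", "end", value_col])
    return df
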