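"""Flat-file readers and writers (TSV / BED / BEDPE / JSON).

All genomic coordinates are 0-based, half-open. BEDPE files carry four
appended integer count columns (white_rep1, white_rep2, beige_rep1,
beige_rep2) and a single ``#``-prefixed header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name",
    "white_rep1", "white_rep2", "beige_rep1", "beige_rep2",
]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    # restrict NA tokens so labels such as "null" survive the round trip
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=["", "NaN", "nan"])


def write_bed(df: pd.DataFrame, path) -> Path:
    """Write a BED6 file. Missing name/score/strand columns are filled."""
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"region_{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    path = Path(path)
    out[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)
    return path


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bedpe(df: pd.DataFrame, path) -> Path:
    """Write a loop table as headered BEDPE with count columns.

    An empty frame yields a valid file holding only the header line.
    """
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"loop_{i}" for i in range(len(out))]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        out.reindex(columns=BEDPE_COLUMNS).to_csv(
            fh, sep="\t", index=False, header=False
        )
    return path


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BEDPE_COLUMNS)
    return df


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
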