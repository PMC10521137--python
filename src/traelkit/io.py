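"""Readers/writers for the plain-text genomic formats the package exchanges.

All genomic coordinates are zero-based, half-open (BED convention) both in
memory and on disk. Read ends live in a pandas DataFrame with columns
``chrom, pos, strand, count`` (one row per distinct single-nucleotide break
end; ``count`` is the multiplicity).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
READ_END_COLUMNS = ["chrom", "pos", "strand", "count"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED file of stranded intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int, "name": str, "score": str, "strand": str},
    )
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def read_bed3(path: str | Path, label_column: bool = True) -> pd.DataFrame:
    """Read a BED3(+name) file, e.g. an exclusion mask or origin catalogue."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {"chrom": raw[0].astype(str), "start": raw[1].astype(int), "end": raw[2].astype(int)}
    )
    if label_column:
        out["label"] = raw[3].astype(str) if raw.shape[1] > 3 else ""
    return out


def read_ends_to_bed6(ends: pd.DataFrame) -> pd.DataFrame:
    """Read-end table → BED6 with single-nucleotide intervals, multiplicity in score."""
    return pd.DataFrame(
        {
            "chrom": ends["chrom"],
            "start": ends["pos"],
            "end": ends["pos"] + 1,
            "name": "read_end",
            "score": ends["count"],
            "strand": ends["strand"],
        }
    )


def write_read_ends(ends: pd.DataFrame, path: str | Path) -> None:
    write_bed6(read_ends_to_bed6(ends), path)


def read_read_ends(path: str | Path) -> pd.DataFrame:
    """Read a read-end BED6 back into the ``chrom, pos, strand, count`` table."""
    bed = read_bed6(path)
    if ((bed["end"] - bed["start"]) != 1).any():
        raise ValueError(f"{path}: read-end BED must contain single-nucleotide intervals")
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": bed["start"],
            "strand": bed["strand"],
            "count": bed["score"].astype(int),
        }
    )


def write_bedgraph(df: pd.DataFrame, path: str | Path, value: str = "normalized") -> None:
    """Write ``chrom, start, end, <value>`` as a 4-column bedGraph."""
    out = df[["chrom", "start", "end", value]].copy()
    out[value] = out[value].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
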