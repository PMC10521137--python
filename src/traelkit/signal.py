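"""Break-end signal extraction, filtering and windowed coverage.

TrAEL-seq reads map so that the base immediately 5' of the ligated strand
break is the informative position; every mapped read is therefore collapsed
to that single nucleotide before any counting. Reads from non-single-copy
regions (rDNA, 2-micron plasmid, mtDNA, sub-telomeres, transposons) are
removed with an exclusion mask, and the retained single-nucleotide counts
are summed in running windows and scaled to reads per million (RPM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

from .io import READ_END_COLUMNS
from .layout import GenomeLayout

logger = logging.getLogger(__name__)

_STRANDS = ("+", "-")


def extract_read_ends(reads: pd.DataFrame) -> pd.DataFrame:
    """Truncate mapped reads to the single nucleotide 5' of the strand break.

    Parameters
    ----------
    reads
        BED6-style DataFrame with ``chrom, start, end, strand`` columns
        (zero-based, half-open intervals).

    Returns
    -------
    DataFrame with columns ``chrom, pos, strand, count``: the 5'-most base of
    each read (interval start on ``+``, interval end − 1 on ``-``), with
    multiplicities aggregated over identical (chrom, pos, strand) triples.
    Records without a usable strand are dropped with a logged warning;
    zero-length intervals are an error.
    """
    if (reads["end"] <= reads["start"]).any():
        bad = reads.loc[reads["end"] <= reads["start"]].iloc[0]
        raise ValueError(
            f"zero-length or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    stranded = reads["strand"].isin(_STRANDS)
    if not stranded.all():
        n_bad = int((~stranded).sum())
        logger.warning("dropping %d read(s) without a +/- strand", n_bad)
        reads = reads.loc[stranded]
    pos = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
    ends = pd.DataFrame(
        {"chrom": reads["chrom"].to_numpy(), "pos": pos, "strand": reads["strand"].to_numpy()}
    )
    grouped = (
        ends.groupby(["chrom", "pos", "strand"], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return grouped[READ_END_COLUMNS]


def filter_and_deduplicate(
    ends: pd.DataFrame, mask: pd.DataFrame | None = None, dedup: bool = False
) -> pd.DataFrame:
    """Drop break ends inside masked regions; optionally collapse multiplicities.

    ``mask`` is a BED3-style DataFrame (``chrom, start, end``); intervals may
    overlap (union semantics). With ``dedup`` every multiplicity is collapsed
    to 1, emulating positional de-duplication. Idempotent in both stages.
    """
    out = ends
    if mask is not None and len(mask) and len(out):
        gr = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": out["chrom"],
                    "Start": out["pos"],
                    "End": out["pos"] + 1,
                    "idx": np.arange(len(out)),
                }
            )
        )
        mask_gr = pr.PyRanges(
            pd.DataFrame(
                {"Chromosome": mask["chrom"], "Start": mask["start"], "End": mask["end"]}
            )
        )
        kept = gr.overlap(mask_gr, invert=True)
        keep_idx = np.sort(kept.df["idx"].to_numpy()) if len(kept) else np.array([], dtype=int)
        n_dropped = len(out) - len(keep_idx)
        if n_dropped:
            logger.warning("mask removed %d break-end position(s)", n_dropped)
        out = out.iloc[keep_idx]
    if dedup:
        out = out.assign(count=1)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class WindowedSignal:
    """Running-window coverage of break-end counts.

    ``frame`` holds one row per window: ``chrom, start, end, raw, normalized``
    with ``normalized = raw * 1e6 / denominator`` (RPM units).
    """

    frame: pd.DataFrame
    window_size: int
    step: int
    denominator: float


def windowed_signal(
    ends: pd.DataFrame,
    layout: GenomeLayout,
    window_size: int = 1000,
    step: int = 100,
    total_mapped: int | None = None,
) -> WindowedSignal:
    """Sum break-end multiplicities in running windows and scale to RPM.

    Windows start at 0 and advance by ``step`` while their start lies inside
    the chromosome; the final window may extend past the chromosome end so
    that a non-overlapping tiling (``step == window_size``) covers every
    position exactly once. The RPM denominator is the total retained read
    count by default, or ``total_mapped`` when given.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    retained = int(ends["count"].sum()) if len(ends) else 0
    denominator = float(total_mapped) if total_mapped is not None else float(retained)
    if denominator == 0:
        logger.warning("RPM denominator is 0; normalized values reported as 0")

    frames = []
    for chrom in layout:
        length = layout.length(chrom)
        starts = np.arange(0, length, step, dtype=int)
        stops = starts + window_size
        sub = ends.loc[ends["chrom"] == chrom]
        positions = np.sort(np.repeat(sub["pos"].to_numpy(), sub["count"].to_numpy())) if len(sub) else np.array([], dtype=int)
        raw = np.searchsorted(positions, stops, side="left") - np.searchsorted(
            positions, starts, side="left"
        )
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": stops, "raw": raw})
        )
    frame = pd.concat(frames, ignore_index=True)
    frame["normalized"] = (
        frame["raw"] * 1e6 / denominator if denominator > 0 else 0.0
    )
    return WindowedSignal(frame=frame, window_size=window_size, step=step, denominator=denominator)
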