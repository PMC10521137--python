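"""Replication-fork progression metrics from break-end signal.

The analysis follows the origin-centred probe logic used for TrAEL-seq fork
mapping:

1. Candidate origins (an ARS catalogue) are scored by break-end signal in a
   10 kb window centred on each origin and the least active 40% are
   discarded — HU arrest means every *active* origin has forks, so signal in
   the window separates fired from dormant origins.
2. Each active origin gets two oriented probes, 20 kb upstream and 20 kb
   downstream, both expressed as distance-from-origin so that leftward- and
   rightward-moving forks align.
3. Probe signal is loess-smoothed (15 neighbours, order 2) and peaks are
   called; probes with more than one peak contain a second origin and are
   removed.
4. The fork distance of a retained probe is the oriented position of the
   smoothed maximum; replicate medians feed a one-way ANOVA with all-pairs
   multiple-comparison correction.

A genome-wide version of the same peak call counts fired origins: every
fired origin contributes two diverging forks, hence two peaks, so the count
is the genome-wide peak total divided by two.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .layout import GenomeLayout
from .signal import WindowedSignal
from .smoothing import loess_smooth

logger = logging.getLogger(__name__)

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


@dataclass(frozen=True)
class ForkParams:
    """Tunable parameters of the fork-progression analysis.

    activity_window
        Width (bp) of the origin-centred window used to score origin
        activity. Default 10 kb.
    activity_fraction
        Fraction of lowest-scoring candidate origins removed. Default 0.40.
    probe_half_width
        Length (bp) of each oriented probe (upstream and downstream of the
        origin). Default 20 kb.
    probe_bin
        Bin size (bp) of the probe signal vectors. Default 100 bp.
    loess_neighbours, loess_order
        Span (nearest bins) and polynomial order of the loess smoother.
    peak_prominence_fraction
        Minimum peak prominence as a fraction of the profile maximum.
    peak_min_separation
        Minimum distance (bp) between called peaks.
    strand_mode
        ``"total"`` uses both strands in every probe; ``"leading"`` restricts
        each probe side to the strand its fork is expected to label
        (forward downstream, reverse upstream).
    reference_condition
        Condition id on which origin activity is scored when several
        conditions share one catalogue.
    """

    activity_window: int = 10_000
    activity_fraction: float = 0.40
    probe_half_width: int = 20_000
    probe_bin: int = 100
    loess_neighbours: int = 15
    loess_order: int = 2
    peak_prominence_fraction: float = 0.5
    peak_min_separation: int = 2_000
    strand_mode: str = "total"
    reference_condition: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.activity_fraction < 1:
            raise ValueError("activity_fraction must be in [0, 1)")
        if self.probe_half_width <= self.activity_window / 2:
            raise ValueError("probe_half_width must exceed activity_window / 2")
        if self.loess_neighbours < self.loess_order + 1:
            raise ValueError("loess_neighbours must be at least loess_order + 1")
        if not 0 < self.peak_prominence_fraction <= 1:
            raise ValueError("peak_prominence_fraction must be in (0, 1]")
        if self.strand_mode not in ("total", "leading"):
            raise ValueError("strand_mode must be 'total' or 'leading'")


@dataclass
class ForkProbe:
    """One oriented origin-side signal vector.

    ``raw[j]`` is the break-end count in the bin covering oriented distances
    ``[j * bin_size, (j+1) * bin_size)`` from the origin; the upstream
    probe's axis is reversed so distance increases away from the origin on
    both sides. ``peaks`` holds ``(distance_bp, height, prominence)``.
    """

    origin_id: str
    chrom: str
    origin_pos: int
    side: str
    bin_size: int
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    retained: bool = True
    truncated: bool = False

    @property
    def signal(self) -> np.ndarray:
        return self.smoothed if self.smoothed is not None else self.raw


def _origin_scores(
    source: pd.DataFrame | WindowedSignal, catalogue: pd.DataFrame, window: int
) -> np.ndarray:
    half = window // 2
    scores = np.zeros(len(catalogue))
    if isinstance(source, WindowedSignal):
        frame = source.frame
        for i, row in enumerate(catalogue.itertuples(index=False)):
            centre = (frame["start"] + frame["end"]) / 2
            sel = (
                (frame["chrom"] == row.chrom)
                & (centre >= row.pos - half)
                & (centre < row.pos + half)
            )
            scores[i] = frame.loc[sel, "raw"].sum()
    else:
        for i, row in enumerate(catalogue.itertuples(index=False)):
            sel = (
                (source["chrom"] == row.chrom)
                & (source["pos"] >= row.pos - half)
                & (source["pos"] < row.pos + half)
            )
            scores[i] = source.loc[sel, "count"].sum()
    return scores


def call_active_origins(
    source: pd.DataFrame | WindowedSignal,
    catalogue: pd.DataFrame,
    params: ForkParams = ForkParams(),
) -> pd.DataFrame:
    """Keep the most active origins, dropping the bottom ``activity_fraction``.

    Each candidate origin is scored by total break-end signal in the
    ``activity_window`` centred on it (``source`` may be a read-end table or
    a :class:`~traelkit.signal.WindowedSignal`). Origins are ranked by score
    and the lowest-scoring fraction removed; the retained count is
    ``ceil((1 - fraction) * n)``, ties at the boundary resolved in favour of
    the earlier genomic coordinate.
    """
    n = len(catalogue)
    if n == 0:
        raise ValueError("origin catalogue is empty")
    catalogue = catalogue.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    scores = _origin_scores(source, catalogue, params.activity_window)
    if n > 1 and np.all(scores == scores[0]):
        logger.warning("all origin activity scores equal; retaining by coordinate order")
    n_keep = math.ceil((1 - params.activity_fraction) * n)
    # stable sort on a coordinate-sorted catalogue keeps the earlier
    # coordinate first among tied scores
    order = np.argsort(-scores, kind="stable")
    keep = np.sort(order[:n_keep])
    out = catalogue.iloc[keep].copy()
    out["activity_score"] = scores[keep]
    return out.reset_index(drop=True)


def _bin_counts(positions: np.ndarray, counts: np.ndarray, n_bins: int, bin_size: int) -> np.ndarray:
    """Histogram of weighted positions into ``n_bins`` bins of ``bin_size``."""
    idx = positions // bin_size
    valid = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[valid].astype(int), weights=counts[valid], minlength=n_bins).astype(
        float
    )


def build_probes(
    ends: pd.DataFrame,
    active: pd.DataFrame,
    layout: GenomeLayout,
    params: ForkParams = ForkParams(),
) -> list[ForkProbe]:
    """Build two oriented probes per active origin.

    The downstream probe covers ``[origin, origin + half_width)``; the
    upstream probe covers ``[origin - half_width, origin)`` with its axis
    reversed, so bin ``j`` of either probe holds signal at oriented distance
    ``[j*bin, (j+1)*bin)`` from the origin. Probes that would extend past a
    chromosome end are flagged ``truncated`` and excluded from distance
    statistics downstream.
    """
    half = params.probe_half_width
    n_bins = half // params.probe_bin
    probes: list[ForkProbe] = []
    for row in active.itertuples(index=False):
        chrom_len = layout.length(row.chrom)
        sub = ends.loc[ends["chrom"] == row.chrom]
        for side in (UPSTREAM, DOWNSTREAM):
            if side == DOWNSTREAM:
                sel = sub.loc[sub["pos"] >= row.pos]
                if params.strand_mode == "leading":
                    sel = sel.loc[sel["strand"] == "+"]
                offsets = sel["pos"].to_numpy() - row.pos
                truncated = row.pos + half > chrom_len
            else:
                sel = sub.loc[sub["pos"] < row.pos]
                if params.strand_mode == "leading":
                    sel = sel.loc[sel["strand"] == "-"]
                offsets = row.pos - sel["pos"].to_numpy()
                truncated = row.pos - half < 0
            raw = _bin_counts(offsets, sel["count"].to_numpy(), n_bins, params.probe_bin)
            if truncated:
                logger.warning(
                    "probe %s/%s truncated at chromosome boundary", row.origin_id, side
                )
            probes.append(
                ForkProbe(
                    origin_id=row.origin_id,
                    chrom=row.chrom,
                    origin_pos=row.pos,
                    side=side,
                    bin_size=params.probe_bin,
                    raw=raw,
                    truncated=truncated,
                )
            )
    return probes


def smooth_probe(probe: ForkProbe, params: ForkParams = ForkParams()) -> ForkProbe:
    """Loess-smooth a probe's raw vector (k-NN tricube, local polynomial)."""
    if len(probe.raw) < params.loess_neighbours + 1:
        raise ValueError(
            f"probe has {len(probe.raw)} bins; need at least {params.loess_neighbours + 1}"
        )
    smoothed = loess_smooth(probe.raw, params.loess_neighbours, params.loess_order)
    return replace(probe, smoothed=smoothed)


def find_signal_peaks(
    y: np.ndarray, prominence_fraction: float, min_separation_bins: int
) -> list[tuple[int, float, float]]:
    """Call peaks on a smoothed vector: local maxima with prominence at
    least ``prominence_fraction`` of the vector maximum, thinned so that
    surviving peaks are at least ``min_separation_bins`` apart (higher peaks
    win). Returns ``(bin index, height, prominence)`` sorted by index."""
    y = np.asarray(y, dtype=float)
    if len(y) == 0 or np.max(y) <= 0:
        return []
    idx, _ = sps.find_peaks(y)
    if len(idx) == 0:
        return []
    prominences = sps.peak_prominences(y, idx)[0]
    threshold = prominence_fraction * float(np.max(y))
    keep = prominences >= threshold
    idx, prominences = idx[keep], prominences[keep]
    # greedy thinning from the highest peak down; ties by lower index
    order = sorted(range(len(idx)), key=lambda i: (-y[idx[i]], idx[i]))
    chosen: list[int] = []
    for i in order:
        if all(abs(int(idx[i]) - int(idx[j])) >= min_separation_bins for j in chosen):
            chosen.append(i)
    chosen.sort(key=lambda i: idx[i])
    return [(int(idx[i]), float(y[idx[i]]), float(prominences[i])) for i in chosen]


def detect_peaks(probe: ForkProbe, params: ForkParams = ForkParams()) -> ForkProbe:
    """Populate a probe's peak list and set the single-peak retention flag.

    A probe with more than one peak spans a second origin and is dropped
    from fork-distance statistics (``retained = False``).
    """
    if probe.smoothed is None:
        raise ValueError("probe must be smoothed before peak detection")
    sep_bins = max(1, math.ceil(params.peak_min_separation / probe.bin_size))
    hits = find_signal_peaks(probe.smoothed, params.peak_prominence_fraction, sep_bins)
    peaks = [(i * probe.bin_size, h, p) for i, h, p in hits]
    retained = len(peaks) <= 1
    if not retained:
        logger.warning(
            "probe %s/%s has %d peaks; removed from distance statistics",
            probe.origin_id,
            probe.side,
            len(peaks),
        )
    return replace(probe, peaks=peaks, retained=retained)


def fork_distance(probe: ForkProbe) -> float | None:
    """Oriented distance (bp) of the smoothed signal maximum, or ``None``.

    Undefined for probes that were not retained (multi-peak), are truncated,
    or carry no signal. Ties at the maximum resolve to the smallest
    distance.
    """
    if probe.smoothed is None:
        raise ValueError("probe must be smoothed before distance extraction")
    if not probe.retained or probe.truncated:
        return None
    y = probe.smoothed
    if np.max(y) <= 0:
        return None
    top = int(np.argmax(y))
    if np.sum(y == y[top]) > 1:
        logger.info("tied maxima in probe %s/%s; smallest distance reported", probe.origin_id, probe.side)
    return float(top * probe.bin_size)


def analyze_probes(
    ends: pd.DataFrame,
    active: pd.DataFrame,
    layout: GenomeLayout,
    params: ForkParams = ForkParams(),
) -> tuple[list[ForkProbe], pd.DataFrame]:
    """Build, smooth and peak-call all probes; tabulate per-probe results."""
    probes = [
        detect_peaks(smooth_probe(p, params), params)
        for p in build_probes(ends, active, layout, params)
    ]
    rows = []
    for p in probes:
        d = fork_distance(p)
        rows.append(
            {
                "origin_id": p.origin_id,
                "chrom": p.chrom,
                "origin_pos": p.origin_pos,
                "side": p.side,
                "n_peaks": len(p.peaks),
                "retained": p.retained,
                "truncated": p.truncated,
                "fork_distance": d,
            }
        )
    return probes, pd.DataFrame(rows)


def probe_matrix(probes: list[ForkProbe], smoothed: bool = True) -> pd.DataFrame:
    """Aligned-probe matrix (rows: origin/side; columns: oriented bins),
    ordered by fork distance — the layout used for probe heat maps."""
    if not probes:
        return pd.DataFrame()
    records = {}
    distances = {}
    for p in probes:
        key = f"{p.origin_id}:{p.side}"
        records[key] = p.smoothed if smoothed and p.smoothed is not None else p.raw
        d = fork_distance(p) if p.smoothed is not None else None
        distances[key] = d if d is not None else np.inf
    mat = pd.DataFrame.from_dict(records, orient="index")
    mat.columns = [i * probes[0].bin_size for i in range(mat.shape[1])]
    return mat.loc[sorted(records, key=lambda k: (distances[k], k))]


def genome_peak_count(
    ends: pd.DataFrame, layout: GenomeLayout, params: ForkParams = ForkParams()
) -> int:
    """Total break-end signal peaks across all chromosomes.

    Each chromosome's signal is binned at ``probe_bin``, loess-smoothed and
    peak-called with the same prominence/separation criteria as probe peak
    detection (prominence relative to the per-chromosome maximum).
    """
    total_peaks = 0
    sep_bins = max(1, math.ceil(params.peak_min_separation / params.probe_bin))
    for chrom in layout:
        sub = ends.loc[ends["chrom"] == chrom]
        n_bins = math.ceil(layout.length(chrom) / params.probe_bin)
        if n_bins < params.loess_neighbours + 1:
            raise ValueError(f"chromosome {chrom} too short for smoothing")
        binned = _bin_counts(
            sub["pos"].to_numpy(), sub["count"].to_numpy(), n_bins, params.probe_bin
        )
        smoothed = loess_smooth(binned, params.loess_neighbours, params.loess_order)
        total_peaks += len(
            find_signal_peaks(smoothed, params.peak_prominence_fraction, sep_bins)
        )
    return total_peaks


def count_fired_origins(
    ends: pd.DataFrame, layout: GenomeLayout, params: ForkParams = ForkParams()
) -> int:
    """Fired-origin count: genome-wide peak total divided by two.

    Every fired origin launches two diverging forks, each producing one
    break-end peak, so half the genome-wide peak count estimates the number
    of origins that fired. An odd peak total is floor-divided with a
    warning.
    """
    total_peaks = genome_peak_count(ends, layout, params)
    if total_peaks % 2:
        logger.warning("odd genome-wide peak count %d; flooring the half", total_peaks)
    return total_peaks // 2


@dataclass
class ConditionSummary:
    """Fork distances of one biological replicate of one condition."""

    condition: str
    replicate: str
    distances: np.ndarray
    fired_origins: int | None = None

    @property
    def median_distance(self) -> float:
        """Median fork distance over the replicate's retained probes."""
        d = np.asarray(self.distances, dtype=float)
        d = d[np.isfinite(d)]
        if len(d) == 0:
            return float("nan")
        return float(np.median(d))

    @classmethod
    def from_probe_table(
        cls, table: pd.DataFrame, condition: str, replicate: str
    ) -> "ConditionSummary":
        ok = table.loc[table["retained"] & ~table["truncated"], "fork_distance"].dropna()
        return cls(condition=condition, replicate=replicate, distances=ok.to_numpy())


@dataclass
class ComparisonResult:
    """Omnibus ANOVA plus all-pairs adjusted comparisons on replicate medians."""

    group_means: pd.Series
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    method: str

    def to_frame(self) -> pd.DataFrame:
        out = self.pairwise.copy()
        out.insert(0, "omnibus_p", self.p_value)
        out.insert(0, "omnibus_F", self.f_statistic)
        return out


def compare_conditions(
    summaries: list[ConditionSummary], method: str = "tukey"
) -> ComparisonResult:
    """One-way ANOVA on replicate median distances with all-pairs correction.

    ``method`` selects the family-wise correction for the g(g-1)/2 pairwise
    comparisons: ``"tukey"`` (Tukey HSD, default), ``"sidak"`` or
    ``"bonferroni"`` (pairwise Welch t-tests with the named adjustment).
    Groups contributing a single replicate are excluded from the pairwise
    table with a warning but still enter the omnibus test.
    """
    if method not in ("tukey", "sidak", "bonferroni"):
        raise ValueError(f"unknown correction method {method!r}")
    df = pd.DataFrame(
        {
            "condition": [s.condition for s in summaries],
            "median": [s.median_distance for s in summaries],
        }
    ).dropna()
    groups = df.groupby("condition", sort=True)["median"]
    if groups.ngroups < 2:
        raise ValueError("need at least two condition groups")
    group_means = groups.mean()
    f_stat, p_val = spstats.f_oneway(*[g.to_numpy() for _, g in groups])

    sizes = groups.size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        logger.warning("excluding single-replicate group(s) from pairwise tests: %s", singletons)
    multi = df.loc[~df["condition"].isin(singletons)]

    if method == "tukey" and multi["condition"].nunique() >= 2:
        hsd = pairwise_tukeyhsd(multi["median"], multi["condition"], alpha=0.05)
        pairwise = pd.DataFrame(
            hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
        ).rename(
            columns={"group1": "group1", "group2": "group2", "meandiff": "mean_diff", "p-adj": "p_adj"}
        )[["group1", "group2", "mean_diff", "p_adj", "reject"]]
        pairwise["p_adj"] = np.asarray(hsd.pvalues, dtype=float)
        pairwise["reject"] = np.asarray(hsd.reject, dtype=bool)
    elif multi["condition"].nunique() >= 2:
        rows = []
        names = sorted(multi["condition"].unique())
        for a, b in itertools.combinations(names, 2):
            xa = multi.loc[multi["condition"] == a, "median"]
            xb = multi.loc[multi["condition"] == b, "median"]
            t, p = spstats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"group1": a, "group2": b, "mean_diff": xb.mean() - xa.mean(), "p_raw": p})
        pairwise = pd.DataFrame(rows)
        reject, p_adj, _, _ = multipletests(pairwise["p_raw"], alpha=0.05, method=method)
        pairwise["p_adj"] = p_adj
        pairwise["reject"] = reject
        pairwise = pairwise.drop(columns="p_raw")
    else:
        pairwise = pd.DataFrame(columns=["group1", "group2", "mean_diff", "p_adj", "reject"])

    return ComparisonResult(
        group_means=group_means,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pairwise,
        method=method,
    )
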