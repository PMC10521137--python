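"""Synthetic data with known ground truth for every downstream stage.

Three generators mirror the three experimental readouts the package
analyses:

* :func:`simulate_trael_experiment` — stranded single-nucleotide break ends
  clustered at the two replication forks flanking each fired origin, plus
  uniform background and PCR-style duplicates. Emulates a population of
  cells released from an HU fork arrest, where each fired origin has sent
  one fork left and one fork right by a distance drawn around a common mean.
* :func:`simulate_lfq_table` — label-free proteomic intensities across the
  three-sample proximity-labelling design (no-tag + treatment / tag alone /
  tag + treatment) with a constitutively biotinylated control protein.
* :func:`simulate_cell_fluorescence` — per-cell nuclear/cytoplasmic
  fluorescence records for a split-fluorophore interaction assay.

All generators are fully determined by their ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# TrAEL-like read ends
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ForkSimParams:
    """Parameters of the replication-fork read-end simulator.

    origins
        Per-chromosome origin positions (bp). Must lie within the layout.
    firing_probability
        Probability that an origin fires (both forks launched).
    distance_mean, distance_spread
        Mean and SD (bp) of the per-fork distance from its origin, drawn
        from a Normal truncated at 0 — each fork gets an independent draw.
    read_noise
        SD (bp) of read-end scatter around the true fork position.
    leading_fraction
        Probability that a fork's read carries the leading-strand label:
        forward strand for rightward forks, reverse for leftward. The
        method preferentially labels the leading strand; 0.8 by default.
    reads_per_fork
        Break-end reads emitted per fork.
    background_rate
        Uniform background, reads per kilobase of genome.
    duplicate_rate
        Fraction of emitted reads duplicated verbatim (PCR-style).
    probe_half_width
        Only used to warn when two origins sit closer than twice this
        value, which breaks the one-origin-per-probe assumption downstream.
    """

    origins: dict[str, tuple[int, ...]]
    firing_probability: float = 1.0
    distance_mean: float = 12_000.0
    distance_spread: float = 1_000.0
    read_noise: float = 300.0
    leading_fraction: float = 0.8
    reads_per_fork: int = 200
    background_rate: float = 0.2
    duplicate_rate: float = 0.02
    probe_half_width: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in [
            (self.firing_probability, "firing_probability"),
            (self.leading_fraction, "leading_fraction"),
            (self.duplicate_rate, "duplicate_rate"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.distance_spread < 0 or self.read_noise < 0 or self.background_rate < 0:
            raise ValueError("spread, noise and background rate must be >= 0")
        if self.reads_per_fork < 1:
            raise ValueError("reads_per_fork must be positive")


@dataclass
class TraelTruth:
    """Ground truth of a simulated fork experiment.

    ``fired`` has one row per fired origin with both fork positions and
    their distances; ``counts`` accounts for every emitted read
    (fork + background + duplicate); ``warnings`` records layout problems.
    """

    fired: pd.DataFrame
    counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)


def origin_catalogue(params: ForkSimParams) -> pd.DataFrame:
    """Origin catalogue (origin_id, chrom, pos) from simulator parameters."""
    rows = []
    for chrom in sorted(params.origins):
        for pos in sorted(params.origins[chrom]):
            rows.append({"origin_id": f"ORI_{chrom}_{pos}", "chrom": chrom, "pos": int(pos)})
    return pd.DataFrame(rows, columns=["origin_id", "chrom", "pos"])


def evenly_spaced_origins(
    layout: GenomeLayout, n_per_chromosome: int = 5, margin: int = 50_000
) -> dict[str, tuple[int, ...]]:
    """Place ``n`` origins per chromosome, evenly spaced within a margin."""
    out = {}
    for chrom in layout:
        length = layout.length(chrom)
        if 2 * margin >= length:
            raise ValueError(f"margin too large for chromosome {chrom}")
        out[chrom] = tuple(
            int(p) for p in np.linspace(margin, length - margin, n_per_chromosome)
        )
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by redraw; exact point mass when sd=0."""
    if sd == 0:
        return np.full(size, float(mean))
    draws = rng.normal(mean, sd, size)
    while np.any(draws < 0):
        bad = draws < 0
        draws[bad] = rng.normal(mean, sd, int(bad.sum()))
    return draws


def simulate_trael_experiment(
    layout: GenomeLayout, params: ForkSimParams
) -> tuple[pd.DataFrame, TraelTruth]:
    """Simulate break-end reads around the two forks of each fired origin.

    Returns a read-end table (``chrom, pos, strand, count``) and the
    :class:`TraelTruth` record. Rightward forks sit at origin + d, leftward
    at origin − d, with d drawn per fork; read ends scatter around the fork
    with ``read_noise``; strand labels follow ``leading_fraction`` with the
    two directions mirrored; background is uniform over the genome;
    duplicates are verbatim copies of already-emitted reads.
    """
    rng = np.random.default_rng(params.seed)
    warnings: list[str] = []
    catalogue = origin_catalogue(params)
    for chrom, group in catalogue.groupby("chrom"):
        if chrom not in layout:
            raise ValueError(f"origin chromosome {chrom!r} not in layout")
        pos = group["pos"].to_numpy()
        if np.any(pos < 0) or np.any(pos >= layout.length(chrom)):
            raise ValueError(f"origin position out of bounds on {chrom}")
        gaps = np.diff(np.sort(pos))
        if np.any(gaps < 2 * params.probe_half_width):
            msg = (
                f"origins on {chrom} closer than twice the probe half-width; "
                "probes will violate the single-peak assumption"
            )
            warnings.append(msg)
            logger.warning(msg)

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    fired_rows = []
    n_fork_reads = 0
    for row in catalogue.itertuples(index=False):
        if rng.random() >= params.firing_probability:
            continue
        chrom_len = layout.length(row.chrom)
        d_left, d_right = _truncated_normal(rng, params.distance_mean, params.distance_spread, 2)
        forks = {
            "left": int(np.clip(round(row.pos - d_left), 0, chrom_len - 1)),
            "right": int(np.clip(round(row.pos + d_right), 0, chrom_len - 1)),
        }
        for direction, fork_pos in forks.items():
            pos = np.rint(rng.normal(fork_pos, params.read_noise, params.reads_per_fork))
            pos = np.clip(pos, 0, chrom_len - 1).astype(int)
            leading = rng.random(params.reads_per_fork) < params.leading_fraction
            if direction == "right":
                strand = np.where(leading, "+", "-")
            else:
                strand = np.where(leading, "-", "+")
            chroms.append(np.full(params.reads_per_fork, row.chrom, dtype=object))
            positions.append(pos)
            strands.append(strand)
            n_fork_reads += params.reads_per_fork
        fired_rows.append(
            {
                "origin_id": row.origin_id,
                "chrom": row.chrom,
                "origin_pos": row.pos,
                "left_fork_pos": forks["left"],
                "right_fork_pos": forks["right"],
                "left_distance": row.pos - forks["left"],
                "right_distance": forks["right"] - row.pos,
            }
        )

    n_background = 0
    for chrom in layout:
        lam = params.background_rate * layout.length(chrom) / 1000.0
        n_bg = int(rng.poisson(lam)) if lam > 0 else 0
        if n_bg:
            pos = rng.integers(0, layout.length(chrom), n_bg)
            strand = np.where(rng.random(n_bg) < 0.5, "+", "-")
            chroms.append(np.full(n_bg, chrom, dtype=object))
            positions.append(pos)
            strands.append(strand)
            n_background += n_bg

    if chroms:
        chrom_arr = np.concatenate(chroms)
        pos_arr = np.concatenate(positions)
        strand_arr = np.concatenate(strands)
    else:
        chrom_arr = np.array([], dtype=object)
        pos_arr = np.array([], dtype=int)
        strand_arr = np.array([], dtype=object)

    n_emitted = len(pos_arr)
    n_dup = int(rng.binomial(n_emitted, params.duplicate_rate)) if n_emitted else 0
    if n_dup:
        idx = rng.integers(0, n_emitted, n_dup)
        chrom_arr = np.concatenate([chrom_arr, chrom_arr[idx]])
        pos_arr = np.concatenate([pos_arr, pos_arr[idx]])
        strand_arr = np.concatenate([strand_arr, strand_arr[idx]])

    reads = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "strand": strand_arr})
    if len(reads):
        ends = (
            reads.groupby(["chrom", "pos", "strand"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        ends = pd.DataFrame(columns=["chrom", "pos", "strand", "count"]).astype(
            {"pos": int, "count": int}
        )

    fired = pd.DataFrame(
        fired_rows,
        columns=[
            "origin_id",
            "chrom",
            "origin_pos",
            "left_fork_pos",
            "right_fork_pos",
            "left_distance",
            "right_distance",
        ],
    )
    truth = TraelTruth(
        fired=fired,
        counts={
            "fork_reads": n_fork_reads,
            "background_reads": n_background,
            "duplicates": n_dup,
            "total": n_fork_reads + n_background + n_dup,
        },
        warnings=warnings,
    )
    return ends, truth


# --------------------------------------------------------------------------
# LFQ tables
# --------------------------------------------------------------------------

SAMPLE_CLASSES = ("sample1", "sample2", "sample3")  # no-tag+HU / tag / tag+HU


@dataclass(frozen=True)
class LFQSimParams:
    """Parameters of the three-condition proximity-labelling LFQ simulator.

    Protein classes:

    * ``background`` — equal expected intensity in all three samples
      (includes the endogenously biotinylated control protein);
    * ``tag_specific`` — elevated ``tag_fold``-fold wherever the biotin
      ligase tag is present (samples 2 and 3);
    * ``treatment_enhanced`` — elevated ``treatment_fold``-fold only in the
      tagged + treated sample 3; these are the true proximity hits the
      dual-ratio analysis should recover.

    Intensities are log-normal around ``intensity_scale`` with log-SD
    ``dispersion``, multiplied by log-normal replicate noise
    (``replicate_sigma``). Zeros are injected at ``dropout_probability``
    except for the control protein, which is never dropped.
    """

    n_proteins: int = 400
    replicates: tuple[int, int, int] = (3, 3, 3)
    frac_tag_specific: float = 0.05
    frac_treatment_enhanced: float = 0.05
    tag_fold: float = 8.0
    treatment_fold: float = 8.0
    intensity_scale: float = 1.0e6
    dispersion: float = 1.0
    replicate_sigma: float = 0.2
    dropout_probability: float = 0.0
    control_id: str = "ACC1"
    control_intensity: float = 5.0e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_tag_specific + self.frac_treatment_enhanced > 1:
            raise ValueError("class fractions must sum to <= 1")
        for p, name in [
            (self.frac_tag_specific, "frac_tag_specific"),
            (self.frac_treatment_enhanced, "frac_treatment_enhanced"),
            (self.dropout_probability, "dropout_probability"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.replicates) < 1 or self.n_proteins < 1:
            raise ValueError("replicates and n_proteins must be positive")
        if self.intensity_scale <= 0 or self.dispersion <= 0 or self.control_intensity <= 0:
            raise ValueError("intensity parameters must be positive")


def simulate_lfq_table(params: LFQSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format LFQ table and per-protein truth labels.

    Returns ``(table, truth)``: the table has columns
    ``protein, sample, replicate, intensity``; the truth maps each protein
    to its class (``background`` / ``tag_specific`` / ``treatment_enhanced``
    / ``control``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    n_tag = int(round(params.frac_tag_specific * n))
    n_enh = int(round(params.frac_treatment_enhanced * n))
    classes = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_tag]] = "tag_specific"
    classes[order[n_tag : n_tag + n_enh]] = "treatment_enhanced"

    proteins = [f"P{i + 1:04d}" for i in range(n)]
    base = rng.lognormal(np.log(params.intensity_scale), params.dispersion, n)

    rows = []
    for i, protein in enumerate(proteins):
        for s_idx, sample in enumerate(SAMPLE_CLASSES):
            mult = 1.0
            if classes[i] == "tag_specific" and sample in ("sample2", "sample3"):
                mult = params.tag_fold
            elif classes[i] == "treatment_enhanced" and sample == "sample3":
                mult = params.treatment_fold
            for rep in range(1, params.replicates[s_idx] + 1):
                intensity = base[i] * mult * rng.lognormal(0.0, params.replicate_sigma)
                if rng.random() < params.dropout_probability:
                    intensity = 0.0
                rows.append(
                    {"protein": protein, "sample": sample, "replicate": rep, "intensity": intensity}
                )
    # control protein: constitutively biotinylated, never dropped out
    for s_idx, sample in enumerate(SAMPLE_CLASSES):
        for rep in range(1, params.replicates[s_idx] + 1):
            rows.append(
                {
                    "protein": params.control_id,
                    "sample": sample,
                    "replicate": rep,
                    "intensity": params.control_intensity
                    * rng.lognormal(0.0, params.replicate_sigma),
                }
            )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"protein": proteins + [params.control_id], "class": list(classes) + ["control"]}
    )
    return table, truth


# --------------------------------------------------------------------------
# Per-cell fluorescence
# --------------------------------------------------------------------------


def simulate_cell_fluorescence(
    n_per_group: tuple[int, int] = (150, 150),
    effect_size: float = 5.0,
    seed: int = 0,
    *,
    group_labels: tuple[str, str] = ("control", "interaction"),
    base_ratio: float = 1.5,
    ratio_sd: float = 0.3,
    cytoplasm_mean: float = 100.0,
    cytoplasm_sd: float = 10.0,
    area_mean: float = 60.0,
    area_sd: float = 8.0,
    background_mean: float = 10.0,
    background_sd: float = 2.0,
) -> pd.DataFrame:
    """Simulate per-cell fluorescence records for two groups.

    The second group's nuclear/cytoplasmic ratio is shifted upward by
    ``effect_size`` standard deviations of the ratio distribution.
    Integrated density is constructed so that subtracting area × background
    recovers the nuclear fluorescence exactly.
    """
    if min(n_per_group) < 1:
        raise ValueError("need at least one cell per group")
    rng = np.random.default_rng(seed)
    frames = []
    for g, (label, n) in enumerate(zip(group_labels, n_per_group)):
        shift = effect_size * ratio_sd if g == 1 else 0.0
        ratio = rng.normal(base_ratio + shift, ratio_sd, n)
        ratio = np.clip(ratio, 0.05, None)
        cyt = np.clip(rng.normal(cytoplasm_mean, cytoplasm_sd, n), 1.0, None)
        nuc = ratio * cyt
        area = np.clip(rng.normal(area_mean, area_sd, n), 1.0, None)
        bg = np.clip(rng.normal(background_mean, background_sd, n), 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{label}_{i + 1:04d}" for i in range(n)],
                    "group": label,
                    "integrated_density": area * (nuc + bg),
                    "area": area,
                    "background_mean": bg,
                    "nuclear_mean": nuc,
                    "cytoplasmic_mean": cyt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
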