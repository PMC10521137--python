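"""Dual-ratio enrichment scoring for proximity-labelling LFQ data.

The design has three samples: no-tag + treatment (sample1), tag without
treatment (sample2), and tag + treatment (sample3). Per replicate, every
protein's LFQ intensity is normalised to an endogenously biotinylated
control protein (an Acc1 analogue) measured in the same run; zeros are
first converted to 1 so the ratios are always defined. Replicates are
averaged per sample and each protein gets two log-ratio coordinates:

    y = log( avg sample3 / avg sample1 )   (tag vs no-tag)
    x = log( avg sample3 / avg sample2 )   (treatment vs no treatment)

Proteins above both thresholds — enriched by the tag *and* by the
treatment — are the proximity hits.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LFQ_COLUMNS = ["protein", "sample", "replicate", "intensity"]


def _validate(table: pd.DataFrame) -> None:
    missing = set(LFQ_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"LFQ table missing columns: {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise ValueError("negative LFQ intensity encountered")
    if table.duplicated(["protein", "sample", "replicate"]).any():
        raise ValueError("duplicate (protein, sample, replicate) rows")


def complete_table(table: pd.DataFrame) -> pd.DataFrame:
    """Insert intensity-0 rows for absent protein/sample/replicate combos,
    so every protein carries the full replicate structure."""
    _validate(table)
    samples = table[["sample", "replicate"]].drop_duplicates()
    proteins = table[["protein"]].drop_duplicates()
    full = proteins.merge(samples, how="cross")
    out = full.merge(table, on=["protein", "sample", "replicate"], how="left")
    n_missing = int(out["intensity"].isna().sum())
    if n_missing:
        logger.info("filling %d absent protein/replicate rows with intensity 0", n_missing)
    out["intensity"] = out["intensity"].fillna(0.0)
    return out


def impute_zeros(table: pd.DataFrame) -> pd.DataFrame:
    """Convert zero intensities to 1 so downstream ratios are defined."""
    _validate(table)
    out = table.copy()
    out["intensity"] = out["intensity"].where(out["intensity"] != 0, 1.0)
    return out


def normalize_to_control(table: pd.DataFrame, control_id: str = "ACC1") -> pd.DataFrame:
    """Divide every intensity by the control protein's intensity in the same
    sample/replicate. The control maps to 1 everywhere."""
    _validate(table)
    ctrl = table.loc[table["protein"] == control_id, ["sample", "replicate", "intensity"]]
    expected = table[["sample", "replicate"]].drop_duplicates()
    have = ctrl[["sample", "replicate"]].drop_duplicates()
    gap = expected.merge(have, how="left", indicator=True)
    absent = gap.loc[gap["_merge"] == "left_only", ["sample", "replicate"]]
    if len(absent):
        where = ", ".join(f"{r.sample}/rep{r.replicate}" for r in absent.itertuples())
        raise ValueError(f"control protein {control_id!r} absent from: {where}")
    ctrl = ctrl.rename(columns={"intensity": "control_intensity"})
    out = table.merge(ctrl, on=["sample", "replicate"], how="left")
    out["intensity"] = out["intensity"] / out["control_intensity"]
    return out.drop(columns="control_intensity")


def enrichment_scores(
    normalized: pd.DataFrame, log_base: float = 2.0, control_id: str = "ACC1"
) -> pd.DataFrame:
    """Per-sample averages and the two log-enrichment coordinates.

    Returns one row per protein with the per-sample mean normalized
    intensities (``avg_sample1..3``), ``x_enrichment`` (sample3 vs sample2)
    and ``y_enrichment`` (sample3 vs sample1) in the configured log base.
    """
    _validate(normalized)
    avg = (
        normalized.groupby(["protein", "sample"], sort=True)["intensity"]
        .mean()
        .unstack("sample")
    )
    for sample in ("sample1", "sample2", "sample3"):
        if sample not in avg.columns:
            raise ValueError(f"sample class {sample!r} missing from the table")
    if not (avg > 0).all().all():
        raise AssertionError("non-positive per-sample average; were zeros imputed?")
    log = np.log(avg) / np.log(log_base)
    out = pd.DataFrame(
        {
            "avg_sample1": avg["sample1"],
            "avg_sample2": avg["sample2"],
            "avg_sample3": avg["sample3"],
            "x_enrichment": log["sample3"] - log["sample2"],
            "y_enrichment": log["sample3"] - log["sample1"],
        }
    ).reset_index()
    # the control protein normalizes to exactly 1.0 in every replicate, so
    # its coordinates come out exactly (0, 0) with no special-casing
    return out


def classify_hits(
    results: pd.DataFrame, x_threshold: float = 1.0, y_threshold: float = 1.0
) -> pd.DataFrame:
    """Flag proteins above both enrichment thresholds as hits."""
    if not (np.isfinite(x_threshold) or x_threshold == -np.inf) or not (
        np.isfinite(y_threshold) or y_threshold == -np.inf
    ):
        raise ValueError("thresholds must be finite or -inf")
    out = results.copy()
    out["hit"] = (out["x_enrichment"] > x_threshold) & (out["y_enrichment"] > y_threshold)
    return out


def run_enrichment(
    table: pd.DataFrame,
    control_id: str = "ACC1",
    log_base: float = 2.0,
    x_threshold: float = 1.0,
    y_threshold: float = 1.0,
) -> pd.DataFrame:
    """Full pipeline: complete → impute zeros → normalise → score → classify."""
    staged = impute_zeros(complete_table(table))
    normalized = normalize_to_control(staged, control_id=control_id)
    scores = enrichment_scores(normalized, log_base=log_base, control_id=control_id)
    return classify_hits(scores, x_threshold=x_threshold, y_threshold=y_threshold)
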