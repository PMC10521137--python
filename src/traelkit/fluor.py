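"""Corrected nuclear fluorescence and nuclear/cytoplasmic ratio analysis.

Corrected total nuclear fluorescence (CTNF) removes background from an
integrated-density measurement of a circled nucleus:

    CTNF = integrated density − area × mean background fluorescence

The nuclear/cytoplasmic ratio of mean intensities quantifies nuclear
localisation of a reporter; two groups of cells are compared with a
two-sided t-test (Welch by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as spstats

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ["integrated_density", "area", "background_mean"]
RATIO_FIELDS = ["nuclear_mean", "cytoplasmic_mean", "group"]


def ctnf(records: pd.DataFrame) -> pd.Series:
    """Corrected total nuclear fluorescence per cell.

    Negative values (background estimate exceeding the nucleus signal) are
    returned as-is; callers can flag them via :func:`add_ctnf`.
    """
    missing = [c for c in REQUIRED_FIELDS if c not in records.columns]
    if missing:
        raise ValueError(f"missing fields: {missing}")
    sub = records[REQUIRED_FIELDS]
    if sub.isna().any().any():
        raise ValueError("missing values in fluorescence fields")
    if (records["area"] <= 0).any():
        raise ValueError("cell area must be positive")
    return records["integrated_density"] - records["area"] * records["background_mean"]


def add_ctnf(records: pd.DataFrame) -> pd.DataFrame:
    """Append ``ctnf`` and a ``ctnf_negative`` flag column."""
    out = records.copy()
    out["ctnf"] = ctnf(records)
    out["ctnf_negative"] = out["ctnf"] < 0
    n_neg = int(out["ctnf_negative"].sum())
    if n_neg:
        logger.warning("%d cell(s) have negative corrected nuclear fluorescence", n_neg)
    return out


def nc_ratio_and_compare(
    records: pd.DataFrame, equal_var: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-cell nuclear/cytoplasmic ratios plus a two-group comparison.

    Records with zero cytoplasmic intensity are excluded with a warning.
    Returns the ratio-augmented table and a summary dict with group medians,
    the t statistic and the two-sided p-value (Welch unless ``equal_var``).
    """
    missing = [c for c in RATIO_FIELDS if c not in records.columns]
    if missing:
        raise ValueError(f"missing fields: {missing}")
    usable = records.loc[records["cytoplasmic_mean"] > 0].copy()
    n_dropped = len(records) - len(usable)
    if n_dropped:
        logger.warning("excluded %d cell(s) with zero cytoplasmic intensity", n_dropped)
    usable["nc_ratio"] = usable["nuclear_mean"] / usable["cytoplasmic_mean"]

    groups = usable.groupby("group", sort=True)["nc_ratio"]
    if groups.ngroups != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups.ngroups}")
    if (groups.size() < 2).any():
        raise ValueError("each group needs at least 2 cells")
    (name_a, a), (name_b, b) = list(groups)
    t_stat, p_value = spstats.ttest_ind(a, b, equal_var=equal_var)
    summary = {
        "groups": (name_a, name_b),
        "n": (int(len(a)), int(len(b))),
        "medians": (float(np.median(a)), float(np.median(b))),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "test": "student_t" if equal_var else "welch_t",
        "n_excluded": n_dropped,
    }
    return usable, summary


def violin_export(records_with_ratio: pd.DataFrame) -> pd.DataFrame:
    """Two-column (group, value) export for violin plotting."""
    return records_with_ratio[["group", "nc_ratio"]].rename(columns={"nc_ratio": "value"})
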