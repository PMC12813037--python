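"""Day-validity filtering and cross-day averaging into 24-h profiles.

A recording day is usable only when it carries enough valid 5-minute HRV
epochs (default threshold 100, with 200 as a sensitivity setting; a day
with exactly the threshold count is valid - the exclusion rule is strictly
"fewer than").  Each subject's retained days are then averaged per
time-of-day bin into a single 288-bin Ln(HF-HRV) profile; bins observed on
no valid day stay missing (they enter the functional model as absent
observations, never as zeros or imputations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rr import GRID_BINS

logger = logging.getLogger("hrvfda.profiles")

#: default day-validity threshold (valid 5-min epochs per day);
#: 200 is the sensitivity-analysis setting
MIN_VALID_EPOCHS = 100


@dataclass
class SubjectProfile:
    """One subject's cross-day-averaged 24-h Ln(HF-HRV) profile."""

    subject_id: str
    y: np.ndarray  # 288 values, NaN where no valid day observed the bin
    n_days_contributing: np.ndarray  # 288 ints
    n_valid_days: int


def day_validity(n_valid_epochs, min_valid_epochs: int = MIN_VALID_EPOCHS):
    """Day is valid iff it has at least ``min_valid_epochs`` valid epochs."""
    return np.asarray(n_valid_epochs) >= min_valid_epochs


def valid_days_table(
    epochs: pd.DataFrame, min_valid_epochs: int = MIN_VALID_EPOCHS
) -> pd.DataFrame:
    """Per (subject, day): count of valid epochs and the validity verdict."""
    counts = (
        epochs.groupby(["subject_id", "day_index"], sort=True, observed=True)["valid"]
        .sum()
        .rename("n_valid_epochs")
        .reset_index()
    )
    counts["day_valid"] = day_validity(counts["n_valid_epochs"], min_valid_epochs)
    return counts


def build_profile(
    subject_epochs: pd.DataFrame, min_valid_epochs: int = MIN_VALID_EPOCHS
) -> SubjectProfile:
    """Average one subject's valid days into a :class:`SubjectProfile`.

    Raises ``ValueError`` when the subject has no valid day (callers that
    process whole cohorts log and drop such subjects instead).
    """
    sid = str(subject_epochs["subject_id"].iloc[0])
    days = valid_days_table(subject_epochs, min_valid_epochs)
    good_days = set(days.loc[days["day_valid"], "day_index"])
    if not good_days:
        raise ValueError(f"subject {sid}: no valid recording day")
    sel = subject_epochs[
        subject_epochs["valid"] & subject_epochs["day_index"].isin(good_days)
    ]
    y = np.full(GRID_BINS, np.nan)
    n_days = np.zeros(GRID_BINS, dtype=int)
    grp = sel.groupby("bin", observed=True)["ln_hf"]
    mean = grp.mean()
    count = grp.count()
    y[mean.index.to_numpy()] = mean.to_numpy()
    n_days[count.index.to_numpy()] = count.to_numpy()
    return SubjectProfile(sid, y, n_days, len(good_days))


def build_profiles(
    epochs: pd.DataFrame, min_valid_epochs: int = MIN_VALID_EPOCHS
) -> tuple[pd.DataFrame, list[str]]:
    """Cohort profiles in long form: one row per observed (subject, bin).

    Returns ``(profiles, excluded_subjects)`` where ``profiles`` has
    columns ``subject_id, bin, y, n_days`` and excluded subjects (no valid
    day) are listed and logged.
    """
    days = valid_days_table(epochs, min_valid_epochs)
    good = days[days["day_valid"]][["subject_id", "day_index"]]
    all_subjects = epochs["subject_id"].unique()
    excluded = sorted(set(all_subjects) - set(good["subject_id"].unique()))
    for sid in excluded:
        logger.info("subject %s excluded: no day with >= %d valid epochs",
                    sid, min_valid_epochs)
    sel = epochs.merge(good, on=["subject_id", "day_index"])
    sel = sel[sel["valid"]]
    agg = (
        sel.groupby(["subject_id", "bin"], sort=True, observed=True)["ln_hf"]
        .agg(y="mean", n_days="count")
        .reset_index()
    )
    return agg, excluded


def profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Wide subjects-by-288 matrix (NaN for missing bins), for plotting/export."""
    wide = profiles.pivot(index="subject_id", columns="bin", values="y")
    return wide.reindex(columns=range(GRID_BINS))


def exclusion_report(
    epochs: pd.DataFrame,
    recorded_days: int | pd.Series,
    min_valid_epochs: int = MIN_VALID_EPOCHS,
) -> tuple[pd.DataFrame, dict]:
    """Flowchart-style exclusion accounting for a cohort.

    ``recorded_days`` is the per-subject recorded-day count (or a single
    int applying to everyone).  Returns a per-subject table (recorded days,
    valid days, retained flag, reason) and cohort-level summary counts.
    """
    days = valid_days_table(epochs, min_valid_epochs)
    per_subject = (
        days.groupby("subject_id", observed=True)["day_valid"]
        .sum()
        .astype(int)
        .rename("n_valid_days")
        .reset_index()
    )
    if isinstance(recorded_days, pd.Series):
        per_subject["n_recorded_days"] = per_subject["subject_id"].map(recorded_days)
    else:
        per_subject["n_recorded_days"] = int(recorded_days)
    per_subject["retained"] = per_subject["n_valid_days"] >= 1
    per_subject["reason"] = np.where(
        per_subject["retained"], "",
        f"<{min_valid_epochs} valid 5-min epochs within each day",
    )
    summary = {
        "n_subjects": int(len(per_subject)),
        "n_retained": int(per_subject["retained"].sum()),
        "n_excluded_no_valid_day": int((~per_subject["retained"]).sum()),
        "mean_valid_days": float(per_subject["n_valid_days"].mean()),
        "mean_recorded_days": float(per_subject["n_recorded_days"].mean()),
    }
    return per_subject, summary
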