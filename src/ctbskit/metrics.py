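"""Per-subject plasticity metrics: ΔMEP time courses, maximum suppression,
and signed cumulative AUC over nested post-cTBS intervals.

ΔMEP at time *t* is the natural log of the ratio of the post-cTBS block mean
to the subject's baseline amplitude, ``ln(post_mean / baseline)``: negative
values mean suppression (the LTD-like response), positive values mean
facilitation. The log-ratio scale makes the metric invariant to a common
rescaling of baseline and post means, and symmetric between halving and
doubling.

The cumulative AUC over T5–T is the signed trapezoidal integral of ΔMEP
against time in minutes, anchored at the first post-cTBS time (5 min), with
no synthetic t = 0 point. Negative and positive lobes cancel. ΔMEP_Max is
the most negative ΔMEP over the available times (possibly positive when no
time point shows suppression).

Subjects missing a grid time (dropout) are excluded from that interval and
every longer one, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import POST_TIMES_MIN, baseline_amplitude

#: end times (minutes) of the nested cumulative-AUC intervals T5-T10 .. T5-T60
INTERVAL_ENDS_MIN: tuple[int, ...] = (10, 20, 30, 40, 50, 60)


class MetricsError(ValueError):
    """Base class for metric computation failures."""


class EmptyTimecourseError(MetricsError):
    """A subject has no post-cTBS blocks."""


class IntervalNotComputableError(MetricsError):
    """A cumulative-AUC interval requires a grid time the subject lacks."""


def delta_mep(post_block_mean_mv: float, baseline_mv: float) -> float:
    """ΔMEP: natural log of the baseline-corrected post-cTBS block mean."""
    if post_block_mean_mv <= 0 or baseline_mv <= 0:
        raise MetricsError("delta_mep requires positive amplitudes")
    return float(np.log(post_block_mean_mv / baseline_mv))


def percent_change(post_block_mean_mv: float, baseline_mv: float) -> float:
    """Descriptive percent change from baseline (%Δ); inference uses ΔMEP."""
    if post_block_mean_mv <= 0 or baseline_mv <= 0:
        raise MetricsError("percent_change requires positive amplitudes")
    return float(100.0 * (post_block_mean_mv - baseline_mv) / baseline_mv)


@dataclass(frozen=True)
class SubjectTimeCourse:
    """Baseline amplitude plus ΔMEP at each available post-cTBS time."""

    subject_id: str
    baseline_mv: float
    delta: dict[int, float] = field(default_factory=dict)

    @property
    def available_times(self) -> tuple[int, ...]:
        return tuple(sorted(self.delta))


@dataclass(frozen=True)
class AUCProfile:
    """Signed cumulative AUCs over nested intervals plus ΔMEP_Max."""

    subject_id: str
    auc: dict[int, float]  # interval end time -> ΔMEP·min
    delta_mep_max: float


def timecourse(subject_blocks: pd.DataFrame) -> SubjectTimeCourse:
    """Build a subject's ΔMEP time course from their block-summary slice.

    ``subject_blocks`` is one subject's slice of
    :func:`ctbskit.preprocess.block_summary`. Post blocks whose retained mean
    is undefined (all trials excluded) are treated as unavailable.
    """
    subject_ids = subject_blocks["subject_id"].unique()
    if len(subject_ids) != 1:
        raise MetricsError("timecourse expects blocks of exactly one subject")
    baseline = baseline_amplitude(subject_blocks)

    post = subject_blocks[subject_blocks["block_kind"] == "post"]
    post = post[post["retained_mean_mv"].notna()]
    if post.empty:
        raise EmptyTimecourseError(f"subject {subject_ids[0]}: no post-cTBS blocks")
    delta = {
        int(row.block_time_min): delta_mep(row.retained_mean_mv, baseline)
        for row in post.itertuples()
    }
    return SubjectTimeCourse(str(subject_ids[0]), baseline, delta)


def timecourses(blocks: pd.DataFrame) -> dict[str, SubjectTimeCourse]:
    """Per-subject time courses for a multi-subject block summary."""
    return {
        str(sid): timecourse(sub)
        for sid, sub in blocks.groupby("subject_id", sort=False)
    }


def cumulative_auc(
    tc: SubjectTimeCourse, end_time_min: int, normalize: bool = False
) -> float:
    """Signed trapezoidal integral of ΔMEP from T5 to ``end_time_min`` minutes.

    Requires every grid time from 5 to ``end_time_min`` to be available.
    With ``normalize=True`` the integral is divided by the interval length
    (a time-weighted mean ΔMEP), for cross-interval comparability.
    """
    times = [t for t in POST_TIMES_MIN if t <= end_time_min]
    if end_time_min not in POST_TIMES_MIN or end_time_min == POST_TIMES_MIN[0]:
        raise MetricsError(f"end time must be one of {INTERVAL_ENDS_MIN}")
    missing = [t for t in times if t not in tc.delta]
    if missing:
        raise IntervalNotComputableError(
            f"subject {tc.subject_id}: missing times {missing} for T5-T{end_time_min}"
        )
    values = [tc.delta[t] for t in times]
    area = float(np.trapezoid(values, times))
    if normalize:
        area /= end_time_min - POST_TIMES_MIN[0]
    return area


def delta_mep_max(tc: SubjectTimeCourse) -> float:
    """Maximum suppression: the most negative ΔMEP over available times."""
    if not tc.delta:
        raise EmptyTimecourseError(f"subject {tc.subject_id}: empty timecourse")
    return float(min(tc.delta.values()))


def auc_profile(tc: SubjectTimeCourse, normalize: bool = False) -> AUCProfile:
    """Cumulative AUCs at every computable interval end plus ΔMEP_Max."""
    auc: dict[int, float] = {}
    for end in INTERVAL_ENDS_MIN:
        try:
            auc[end] = cumulative_auc(tc, end, normalize=normalize)
        except IntervalNotComputableError:
            break  # dropout truncates from the right; longer intervals missing too
    return AUCProfile(tc.subject_id, auc, delta_mep_max(tc))


# ---------------------------------------------------------------------------
# tidy tables
# ---------------------------------------------------------------------------

def delta_table(tcs: dict[str, SubjectTimeCourse]) -> pd.DataFrame:
    """Tidy per-subject ΔMEP table: subject_id, time_min, delta_mep."""
    rows = [
        {"subject_id": sid, "time_min": t, "delta_mep": tc.delta[t]}
        for sid, tc in tcs.items()
        for t in tc.available_times
    ]
    return pd.DataFrame(rows, columns=["subject_id", "time_min", "delta_mep"])


def auc_table(
    tcs: dict[str, SubjectTimeCourse], normalize: bool = False
) -> pd.DataFrame:
    """Tidy AUC table: subject_id, interval_end_min, auc, delta_mep_max."""
    rows = []
    for sid, tc in tcs.items():
        prof = auc_profile(tc, normalize=normalize)
        for end, value in prof.auc.items():
            rows.append(
                {
                    "subject_id": sid,
                    "interval_end_min": end,
                    "auc": value,
                    "delta_mep_max": prof.delta_mep_max,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "interval_end_min", "auc", "delta_mep_max"]
    )


def grand_average(delta: pd.DataFrame) -> pd.DataFrame:
    """Per-time grand-average ΔMEP over the subjects with that time available."""
    return (
        delta.groupby("time_min")["delta_mep"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "delta_mep_mean", "std": "delta_mep_sd", "count": "n"})
    )
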