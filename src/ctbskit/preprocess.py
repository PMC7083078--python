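"""MEP trial preprocessing.

Turns long-format tables of single-pulse motor-evoked-potential (MEP)
peak-to-peak amplitudes into per-block retained means and per-subject
baseline amplitudes, applying three cleaning rules:

1. an optional pre-stimulus EMG quality filter (trials with background EMG
   above ~100 microvolts are flagged, indicating incomplete hand relaxation),
2. a per-block outlier rule flagging MEPs more than 2.5 SD from the block
   mean (single pass: mean and SD computed once, exclusions applied once),
3. an optional trial-count equalization that reduces a 90-baseline /
   30-per-post-block layout to the 40 / 20 layout of the comparison group
   (last 40 baseline trials, centered 20 of 30 per post block).

Exclusion is a flag, never a deletion: every trial row is preserved with an
``excluded`` boolean, and trials flagged on the full data stay flagged in
every downstream subset.

The canonical trial table columns are listed in :data:`TRIAL_COLUMNS`; the
post-cTBS measurement grid (minutes) is :data:`POST_TIMES_MIN`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: minutes post-cTBS at which corticomotor reactivity is reassessed
POST_TIMES_MIN: tuple[int, ...] = (5, 10, 20, 30, 40, 50, 60)

#: required columns of a long-format trial table
TRIAL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "block_kind",
    "baseline_block_index",
    "block_time_min",
    "trial_index",
    "amplitude_mv",
)

#: optional columns (blank / NaN when absent)
OPTIONAL_TRIAL_COLUMNS: tuple[str, ...] = ("pre_stim_emg_uv", "excluded")

#: subject metadata columns
SUBJECT_COLUMNS: tuple[str, ...] = ("subject_id", "group", "age_years")

DEFAULT_SD_THRESHOLD = 2.5
DEFAULT_EMG_MAX_UV = 100.0
DEFAULT_N_BASELINE = 40
DEFAULT_N_POST = 20


class PreprocessError(ValueError):
    """Base class for preprocessing failures."""


class TrialValidationError(PreprocessError):
    """The trial table violates the schema or its invariants."""


class DegenerateBlockError(PreprocessError):
    """A block has too few trials for the requested operation."""


class MissingBaselineError(PreprocessError):
    """A subject has no baseline block with a defined retained mean."""


class EqualizationError(PreprocessError):
    """Trial counts cannot be equalized to the target layout."""


# ---------------------------------------------------------------------------
# schema validation
# ---------------------------------------------------------------------------

def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table and return a normalized copy.

    Ensures required columns, positive amplitudes, the canonical post-cTBS
    time grid, and uniqueness of ``trial_index`` within each block. Adds an
    ``excluded`` column (all False) when absent.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"trial table missing columns: {missing}")
    out = trials.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
    out["excluded"] = out["excluded"].fillna(False).astype(bool)

    if not set(out["block_kind"].unique()) <= {"baseline", "post"}:
        bad = set(out["block_kind"].unique()) - {"baseline", "post"}
        raise TrialValidationError(f"unknown block_kind values: {bad}")
    if (out["amplitude_mv"] <= 0).any():
        raise TrialValidationError("amplitude_mv must be > 0 for every trial")
    post = out[out["block_kind"] == "post"]
    bad_times = set(post["block_time_min"].dropna().astype(int)) - set(POST_TIMES_MIN)
    if bad_times:
        raise TrialValidationError(
            f"post block times outside grid {POST_TIMES_MIN}: {sorted(bad_times)}"
        )
    if post["block_time_min"].isna().any():
        raise TrialValidationError("post trials require block_time_min")
    base = out[out["block_kind"] == "baseline"]
    if base["baseline_block_index"].isna().any():
        raise TrialValidationError("baseline trials require baseline_block_index")

    if out.duplicated(subset=["subject_id", "block_kind", "baseline_block_index",
                              "block_time_min", "trial_index"], keep=False).any():
        raise TrialValidationError("trial_index must be unique within each block")
    return out


def _block_id(trials: pd.DataFrame) -> pd.Series:
    """Within-kind block label: baseline index for baseline blocks, time for post."""
    return np.where(
        trials["block_kind"] == "baseline",
        trials["baseline_block_index"],
        trials["block_time_min"],
    ).astype(float)


BLOCK_KEYS = ["subject_id", "block_kind", "block_id"]


def _with_block_id(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    out["block_id"] = _block_id(out)
    return out


# ---------------------------------------------------------------------------
# cleaning rules
# ---------------------------------------------------------------------------

def emg_quality_filter(
    trials: pd.DataFrame, max_pre_stim_uv: float = DEFAULT_EMG_MAX_UV
) -> pd.DataFrame:
    """Flag trials whose pre-stimulus EMG exceeds ``max_pre_stim_uv``.

    A no-op when the table has no ``pre_stim_emg_uv`` column. Runs before the
    outlier pass so contaminated trials do not enter the block statistics.
    """
    out = trials.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
    if "pre_stim_emg_uv" not in out.columns:
        return out
    emg = out["pre_stim_emg_uv"]
    out["excluded"] = out["excluded"] | (emg.notna() & (emg > max_pre_stim_uv))
    return out


def exclude_outliers(
    trials: pd.DataFrame, sd_threshold: float = DEFAULT_SD_THRESHOLD
) -> pd.DataFrame:
    """Flag, per block, MEPs more than ``sd_threshold`` SDs from the block mean.

    Single pass: mean and sample SD (n-1 denominator) are computed once over
    the block's not-yet-excluded trials, and flags applied once. A block with
    zero SD flags nothing. Already-set flags are preserved (idempotent).

    Raises
    ------
    DegenerateBlockError
        If any block has fewer than 2 trials.
    """
    out = _with_block_id(trials)
    if "excluded" not in out.columns:
        out["excluded"] = False

    sizes = out.groupby(BLOCK_KEYS, dropna=False).size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise DegenerateBlockError(f"blocks with fewer than 2 trials: {bad}")

    grp = out[~out["excluded"]].groupby(BLOCK_KEYS, dropna=False)["amplitude_mv"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    amp = out.loc[~out["excluded"], "amplitude_mv"]
    flag = (amp - mean).abs() > sd_threshold * sd
    flag &= sd > 0  # zero-variance block: flag nothing
    out.loc[~out["excluded"], "excluded"] = flag.fillna(False)
    return out.drop(columns=["block_id"])


def equalize_counts(
    trials: pd.DataFrame,
    n_baseline: int = DEFAULT_N_BASELINE,
    n_post: int = DEFAULT_N_POST,
) -> pd.DataFrame:
    """Reduce each subject's trials to a common layout across groups.

    Keeps the last ``n_baseline`` baseline trials (ordered by baseline block
    then trial index) and, per post block, the centered ``n_post`` trials
    (a symmetric trim: 30 -> 20 keeps trial indices 6..25). Subjects already
    at the target counts pass through unchanged. Exclusion flags survive the
    subsetting untouched.

    Raises
    ------
    EqualizationError
        If a subject has fewer than ``n_baseline`` baseline trials or a post
        block smaller than ``n_post``.
    """
    pieces: list[pd.DataFrame] = []
    for subject_id, sub in trials.groupby("subject_id", sort=False):
        base = sub[sub["block_kind"] == "baseline"].sort_values(
            ["baseline_block_index", "trial_index"]
        )
        if len(base) < n_baseline:
            raise EqualizationError(
                f"subject {subject_id}: {len(base)} baseline trials < {n_baseline}"
            )
        pieces.append(base.iloc[len(base) - n_baseline:])

        post = sub[sub["block_kind"] == "post"]
        for time_min, blk in post.groupby("block_time_min"):
            blk = blk.sort_values("trial_index")
            n = len(blk)
            if n < n_post:
                raise EqualizationError(
                    f"subject {subject_id} T{int(time_min)}: {n} trials < {n_post}"
                )
            lo = (n - n_post) // 2
            pieces.append(blk.iloc[lo:lo + n_post])
    return pd.concat(pieces).sort_index()


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def block_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-block summary: trial counts and the retained (non-excluded) mean.

    Returns a frame with columns ``subject_id, block_kind, block_id,
    block_time_min, n_total, n_excluded, retained_mean_mv``. ``block_id`` is
    the baseline block index for baseline blocks and the post time for post
    blocks. A block with every trial excluded has an undefined (NaN) mean.
    """
    t = _with_block_id(trials)
    if "excluded" not in t.columns:
        t["excluded"] = False
    grp = t.groupby(BLOCK_KEYS, dropna=False)
    out = grp.agg(
        n_total=("amplitude_mv", "size"),
        n_excluded=("excluded", "sum"),
    ).reset_index()
    retained = (
        t[~t["excluded"]]
        .groupby(BLOCK_KEYS, dropna=False)["amplitude_mv"]
        .mean()
        .rename("retained_mean_mv")
        .reset_index()
    )
    out = out.merge(retained, on=BLOCK_KEYS, how="left")
    out["block_time_min"] = np.where(
        out["block_kind"] == "post", out["block_id"], np.nan
    )
    return out


def baseline_amplitude(blocks: pd.DataFrame) -> float:
    """Baseline MEP amplitude of one subject: the mean of baseline block means.

    ``blocks`` is that subject's slice of :func:`block_summary`. The average
    is the unweighted mean over blocks (mean-of-block-means), not the pooled
    trial mean, so blocks with unequal retained counts weigh equally.
    """
    base = blocks[blocks["block_kind"] == "baseline"]
    means = base["retained_mean_mv"].dropna()
    if means.empty:
        raise MissingBaselineError("no baseline block with a defined retained mean")
    return float(means.mean())


def preprocess_trials(
    trials: pd.DataFrame,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    equalize: bool = False,
    emg_max_uv: float | None = None,
    n_baseline: int = DEFAULT_N_BASELINE,
    n_post: int = DEFAULT_N_POST,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing pass over a multi-subject trial table.

    Order of operations: schema validation -> EMG quality filter (only when
    ``emg_max_uv`` is given and the column exists) -> per-block outlier
    exclusion -> optional trial-count equalization (flags are preserved into
    the subset).

    Returns ``(flagged_trials, block_summary)``.
    """
    out = validate_trials(trials)
    if emg_max_uv is not None:
        out = emg_quality_filter(out, emg_max_uv)
    out = exclude_outliers(out, sd_threshold)
    if equalize:
        out = equalize_counts(out, n_baseline=n_baseline, n_post=n_post)
    return out, block_summary(out)
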