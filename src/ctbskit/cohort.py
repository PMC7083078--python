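"""Synthetic trial-level cTBS cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so the
full pipeline can be exercised end-to-end with known ground truth:

* group-specific baseline MEP amplitudes (truncated normal, defaults
  0.37 ± 0.27 mV in the ASD group and 1.19 ± 0.41 mV in the TD group),
* group-specific post-cTBS modulation curves on the ΔMEP (log-ratio) scale —
  facilitatory in ASD, inhibitory with gradual recovery in TD,
* a subject-level additive ΔMEP offset (between-subject response
  heterogeneity), plus an age-dependent extra-suppression term in the ASD
  group only, concentrated at the subject's nadir time so that maximum
  suppression deepens with age,
* multiplicative log-normal trial noise with a configurable coefficient of
  variation, occasional extreme outlier trials, and the two site layouts
  (ASD: 3×30 baseline + 30-trial post blocks; TD: 2×20 + 20-trial blocks),
* Hardy–Weinberg genotype assignment, with a configurable number of ASD
  subjects left ungenotyped, and one subject's dropout after an early time
  point.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .genotype import hwe_genotype_probs
from .preprocess import POST_TIMES_MIN

#: default group modulation curves (ΔMEP, natural-log units) on the time grid
ASD_CURVE: dict[int, float] = {5: 0.06, 10: 0.08, 20: 0.07, 30: 0.06,
                               40: 0.05, 50: 0.03, 60: 0.02}
TD_CURVE: dict[int, float] = {5: -0.25, 10: -0.28, 20: -0.25, 30: -0.18,
                              40: -0.12, 50: -0.06, 60: -0.02}


class CohortConfig(BaseModel):
    """Generator configuration; defaults reproduce the study conditions."""

    model_config = ConfigDict(frozen=True)

    n_asd: int = Field(11, ge=1)
    n_td: int = Field(18, ge=1)
    age_range: tuple[float, float] = (10.0, 16.0)
    baseline_mean_mv: dict[str, float] = {"ASD": 0.37, "TD": 1.19}
    baseline_sd_mv: dict[str, float] = {"ASD": 0.27, "TD": 0.41}
    baseline_floor_mv: float = 0.05
    modulation_curve: dict[str, dict[int, float]] = {
        "ASD": ASD_CURVE, "TD": TD_CURVE,
    }
    between_subject_sd: float = Field(0.35, ge=0)
    age_slope_asd: float = -0.2  # ΔMEP_Max change per year, ASD only
    trial_cv: float = Field(0.5, ge=0)
    outlier_rate: float = Field(0.015, ge=0, le=1)
    outlier_factor_range: tuple[float, float] = (5.0, 10.0)
    #: (ASD subject index, last available time) or None for no dropout
    dropout: tuple[int, int] | None = (0, 10)
    maf: float = Field(0.153, ge=0, le=1)
    n_genotype_missing_asd: int = Field(3, ge=0)
    n_adhd_asd: int = Field(5, ge=0)
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self):
        for grp in ("ASD", "TD"):
            curve = self.modulation_curve.get(grp, {})
            if set(curve) != set(POST_TIMES_MIN):
                raise ValueError(f"{grp} modulation curve must cover {POST_TIMES_MIN}")
            if self.baseline_sd_mv.get(grp, -1) < 0:
                raise ValueError("baseline SDs must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")
        if self.dropout is not None and not 0 <= self.dropout[0] < self.n_asd:
            raise ValueError("dropout subject index outside the ASD group")
        if self.dropout is not None and self.dropout[1] not in POST_TIMES_MIN:
            raise ValueError("dropout time must lie on the post-cTBS grid")
        return self


#: per-group block layout: (n baseline blocks, baseline trials, post trials)
LAYOUT = {"ASD": (3, 30, 30), "TD": (2, 20, 20)}


def _lognormal_trials(rng, mean, cv, size):
    """Positive trials with expectation ``mean`` and coefficient of variation cv."""
    if cv == 0:
        return np.full(size, mean)
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * rng.lognormal(-(sigma**2) / 2, sigma, size)


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (subject metadata, trial table, ground truth) for one cohort.

    ``seed`` overrides ``config.seed``; one of the two is mandatory. The
    ground-truth dict records each subject's true baseline amplitude, true
    ΔMEP curve, and the group-level configured curves.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory (config.seed or the seed argument)")
    rng = np.random.default_rng(seed)

    model = hwe_genotype_probs(config.maf)
    geno_probs = [model.p_vv, model.p_vm, model.p_mm]
    geno_names = ["ValVal", "ValMet", "MetMet"]
    age_mid = sum(config.age_range) / 2

    subjects_rows, trial_frames, truth_subjects = [], [], {}
    for group, n_subj, prefix in (("ASD", config.n_asd, "AS"),
                                  ("TD", config.n_td, "TD")):
        n_base_blocks, n_base_trials, n_post_trials = LAYOUT[group]
        curve = config.modulation_curve[group]
        missing_geno = (
            set(rng.choice(n_subj, size=min(config.n_genotype_missing_asd, n_subj),
                           replace=False))
            if group == "ASD" else set()
        )
        adhd_set = (
            set(rng.choice(n_subj, size=min(config.n_adhd_asd, n_subj),
                           replace=False))
            if group == "ASD" else set()
        )
        for i in range(n_subj):
            sid = f"{prefix}{i + 1}"
            age = rng.uniform(*config.age_range)
            genotype = (
                "unknown" if i in missing_geno
                else geno_names[rng.choice(3, p=geno_probs)]
            )
            baseline = rng.normal(config.baseline_mean_mv[group],
                                  config.baseline_sd_mv[group])
            while baseline < config.baseline_floor_mv:  # truncated normal
                baseline = rng.normal(config.baseline_mean_mv[group],
                                      config.baseline_sd_mv[group])
            offset = rng.normal(0, config.between_subject_sd)
            true_delta = {t: curve[t] + offset for t in POST_TIMES_MIN}
            if group == "ASD" and config.age_slope_asd != 0:
                nadir = min(true_delta, key=true_delta.get)
                true_delta[nadir] += config.age_slope_asd * (age - age_mid)

            times = POST_TIMES_MIN
            if (group == "ASD" and config.dropout is not None
                    and i == config.dropout[0]):
                times = tuple(t for t in POST_TIMES_MIN if t <= config.dropout[1])

            rows = []
            for b in range(1, n_base_blocks + 1):
                amps = _lognormal_trials(rng, baseline, config.trial_cv,
                                         n_base_trials)
                rows.append(pd.DataFrame({
                    "subject_id": sid, "block_kind": "baseline",
                    "baseline_block_index": b, "block_time_min": np.nan,
                    "trial_index": np.arange(1, n_base_trials + 1),
                    "amplitude_mv": amps,
                }))
            for t in times:
                block_mean = baseline * np.exp(true_delta[t])
                amps = _lognormal_trials(rng, block_mean, config.trial_cv,
                                         n_post_trials)
                rows.append(pd.DataFrame({
                    "subject_id": sid, "block_kind": "post",
                    "baseline_block_index": np.nan, "block_time_min": t,
                    "trial_index": np.arange(1, n_post_trials + 1),
                    "amplitude_mv": amps,
                }))
            sub_trials = pd.concat(rows, ignore_index=True)
            if config.outlier_rate > 0:
                hit = rng.random(len(sub_trials)) < config.outlier_rate
                factors = rng.uniform(*config.outlier_factor_range, hit.sum())
                sub_trials.loc[hit, "amplitude_mv"] *= factors
            trial_frames.append(sub_trials)

            subjects_rows.append({
                "subject_id": sid, "group": group, "age_years": age,
                "genotype": genotype, "adhd_comorbid": i in adhd_set,
                "medications": "",
            })
            truth_subjects[sid] = {
                "group": group, "age_years": age,
                "baseline_mv": float(baseline),
                "delta_mep": {int(t): float(true_delta[t]) for t in times},
                "delta_mep_max": float(min(true_delta[t] for t in times)),
            }

    subjects = pd.DataFrame(subjects_rows)
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = {
        "seed": int(seed),
        "group_curves": {g: {int(t): v for t, v in c.items()}
                         for g, c in config.modulation_curve.items()},
        "subjects": truth_subjects,
    }
    return subjects, trials, truth


def generate_null_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cohort with no group or age effect (type-I-error calibration).

    Both groups share the TD modulation curve and the ASD age slope is
    zeroed; everything else (layouts, baselines, noise) is unchanged.
    """
    null_config = config.model_copy(update={
        "modulation_curve": {
            "ASD": dict(config.modulation_curve["TD"]),
            "TD": dict(config.modulation_curve["TD"]),
        },
        "age_slope_asd": 0.0,
    })
    return generate_cohort(null_config, seed=seed)
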