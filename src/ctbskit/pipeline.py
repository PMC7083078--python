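"""Pipeline orchestration and reporting.

Composes the analysis end-to-end — preprocess → per-subject metrics → group
inference → genotype-balance → power — from a single validated config, and
writes a reproducible bundle: per-stage CSVs, a machine-readable JSON report
citing the stage files each statistic came from, a human-readable summary,
the resolved config, and a log with package/library versions and the seed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .genotype import MET_MINUS_PREVALENCE, overall_discordance_probability
from .inference import (
    compare_groups,
    comparisons_frame,
    pearson_corr,
    select_baseline_matched_subgroups,
    sensitivity_excluding,
)
from .metrics import auc_table, delta_table, grand_average, timecourses
from .preprocess import baseline_amplitude, preprocess_trials
from .power import power_two_sample_t, required_n_per_group

log = logging.getLogger("ctbskit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class GenotypeBalanceConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    p_met_minus: float = MET_MINUS_PREVALENCE
    alpha: float = Field(0.05, gt=0, lt=1)
    source: str = "exact"  # "exact" or "mc"
    iterations: int = Field(10_000, ge=1)


class AnalysisConfig(BaseModel):
    """Resolved configuration of one full analysis run."""

    model_config = ConfigDict(frozen=True)

    trials_csv: str
    subjects_csv: str
    out_dir: str = "ctbskit-out"
    sd_threshold: float = Field(2.5, gt=0)
    equalize: bool = False
    emg_max_uv: float | None = None
    auc_normalize: bool = False
    fdr_method: str = "by"  # "by" or "bh"
    alpha: float = Field(0.05, gt=0, lt=1)
    group_a: str = "ASD"
    group_b: str = "TD"
    exclude_adhd: bool = False
    baseline_match: bool = False
    genotype_balance: GenotypeBalanceConfig = GenotypeBalanceConfig()
    target_power: float = Field(0.80, gt=0, lt=1)
    make_plots: bool = False
    seed: int = 0


def _comparisons_block(comparisons) -> list[dict]:
    return [asdict(c) for c in comparisons]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the machine-readable report dict (also written as
    ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("ctbskit %s | python %s | numpy %s | pandas %s | seed %d",
                 __version__, platform.python_version(), np.__version__,
                 pd.__version__, config.seed)
        (out / "config.json").write_text(config.model_dump_json(indent=2))

        # --- preprocess -----------------------------------------------------
        try:
            trials = pd.read_csv(config.trials_csv)
            subjects = pd.read_csv(config.subjects_csv)
            flagged, blocks = preprocess_trials(
                trials,
                sd_threshold=config.sd_threshold,
                equalize=config.equalize,
                emg_max_uv=config.emg_max_uv,
            )
        except Exception as exc:
            raise PipelineError(f"preprocess stage failed: {exc}") from exc
        flagged.to_csv(out / "trials_flagged.csv", index=False)
        blocks.to_csv(out / "block_summary.csv", index=False)
        log.info("preprocess: %d trials, %d excluded, %d blocks",
                 len(flagged), int(flagged["excluded"].sum()), len(blocks))

        # --- metrics --------------------------------------------------------
        try:
            tcs = timecourses(blocks)
            delta = delta_table(tcs)
            auc = auc_table(tcs, normalize=config.auc_normalize)
        except Exception as exc:
            raise PipelineError(f"metrics stage failed: {exc}") from exc
        delta.to_csv(out / "delta_mep.csv", index=False)
        auc.to_csv(out / "auc.csv", index=False)
        log.info("metrics: %d subjects", len(tcs))

        # --- inference ------------------------------------------------------
        try:
            comparisons = compare_groups(
                auc, subjects, config.group_a, config.group_b,
                fdr_method=config.fdr_method,
            )
            correlations = []
            max_table = auc.groupby("subject_id")["delta_mep_max"].first()
            meta = subjects.set_index("subject_id")
            for grp in (config.group_a, config.group_b):
                ids = meta.index[meta["group"] == grp].intersection(max_table.index)
                if len(ids) >= 3:
                    correlations.append(pearson_corr(
                        meta.loc[ids, "age_years"], max_table.loc[ids], group=grp))
            sensitivity = None
            if config.exclude_adhd:
                sensitivity = sensitivity_excluding(
                    auc, subjects, lambda s: bool(s.get("adhd_comorbid", False)),
                    group_a=config.group_a, group_b=config.group_b,
                    fdr_method=config.fdr_method,
                )
            matched = None
            if config.baseline_match:
                baselines = {
                    sid: baseline_amplitude(sub)
                    for sid, sub in blocks.groupby("subject_id")
                }
                bl = pd.Series(baselines)
                ids_a = meta.index[meta["group"] == config.group_a]
                ids_b = meta.index[meta["group"] == config.group_b]
                keep_a, keep_b = select_baseline_matched_subgroups(
                    bl.loc[bl.index.intersection(ids_a)],
                    bl.loc[bl.index.intersection(ids_b)],
                )
                matched_subjects = subjects[
                    subjects["subject_id"].isin(keep_a + keep_b)]
                matched = {
                    "subjects_a": sorted(keep_a), "subjects_b": sorted(keep_b),
                    "comparisons": _comparisons_block(compare_groups(
                        auc, matched_subjects, config.group_a, config.group_b,
                        fdr_method=config.fdr_method)),
                }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"inference stage failed: {exc}") from exc
        comparisons_frame(comparisons).to_csv(out / "comparisons.csv", index=False)
        pd.DataFrame([asdict(c) for c in correlations]).to_csv(
            out / "correlations.csv", index=False)
        if sensitivity is not None:
            comparisons_frame(sensitivity).to_csv(
                out / "comparisons_no_adhd.csv", index=False)
        log.info("inference: %d interval comparisons", len(comparisons))

        # --- genotype balance ----------------------------------------------
        try:
            n_a = int((subjects["group"] == config.group_a).sum())
            n_b = int((subjects["group"] == config.group_b).sum())
            gb = config.genotype_balance
            balance = overall_discordance_probability(
                n_a, n_b, gb.p_met_minus, gb.alpha,
                source=gb.source, iterations=gb.iterations, seed=config.seed,
            )
        except Exception as exc:
            raise PipelineError(f"genotype-balance stage failed: {exc}") from exc
        pd.DataFrame({
            "k": np.arange(balance.n1 + 1), "prob": balance.dist1.probs,
        }).to_csv(out / "met_counts_group_a.csv", index=False)
        pd.DataFrame({
            "k": np.arange(balance.n2 + 1), "prob": balance.dist2.probs,
        }).to_csv(out / "met_counts_group_b.csv", index=False)
        log.info("genotype balance: overall probability %.4f",
                 balance.overall_probability)

        # --- power ----------------------------------------------------------
        try:
            power_block = []
            for c in comparisons:
                if not np.isfinite(c.cohens_d):
                    continue
                d = abs(c.cohens_d)
                entry = {
                    "interval_end_min": c.interval_end_min,
                    "d": d,
                    "post_hoc_power": power_two_sample_t(
                        d, c.n_a, c.n_b, config.alpha),
                }
                if d > 0:
                    entry["required_n_per_group"] = required_n_per_group(
                        d, config.target_power, config.alpha)
                power_block.append(entry)
        except Exception as exc:
            raise PipelineError(f"power stage failed: {exc}") from exc
        pd.DataFrame(power_block).to_csv(out / "power.csv", index=False)

        report = {
            "version": __version__,
            "seed": config.seed,
            "inputs": {"trials": config.trials_csv, "subjects": config.subjects_csv},
            "stage_files": {
                "preprocess": ["trials_flagged.csv", "block_summary.csv"],
                "metrics": ["delta_mep.csv", "auc.csv"],
                "inference": ["comparisons.csv", "correlations.csv"],
                "genotype_balance": ["met_counts_group_a.csv",
                                     "met_counts_group_b.csv"],
                "power": ["power.csv"],
            },
            "grand_average_delta_mep": {
                grp: grand_average(
                    delta[delta["subject_id"].isin(
                        subjects.loc[subjects["group"] == grp, "subject_id"])]
                ).to_dict("records")
                for grp in (config.group_a, config.group_b)
            },
            "comparisons": _comparisons_block(comparisons),
            "correlations": [asdict(c) for c in correlations],
            "sensitivity_excluding_adhd": (
                _comparisons_block(sensitivity) if sensitivity is not None else None
            ),
            "baseline_matched": matched,
            "genotype_balance": {
                "n1": balance.n1, "n2": balance.n2, "alpha": balance.alpha,
                "source": balance.source,
                "p_met_minus": config.genotype_balance.p_met_minus,
                "n_significant_scenarios": len(balance.significant_scenarios),
                "overall_probability": balance.overall_probability,
            },
            "power": power_block,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        _write_summary(out / "summary.txt", report)
        if config.make_plots:
            from .plots import plot_auc_profiles, plot_timecourse

            plot_timecourse(delta, subjects, out / "timecourse.png")
            plot_auc_profiles(auc, subjects, out / "auc_profiles.png")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_summary(path: Path, report: dict) -> None:
    lines = [
        f"ctbskit {report['version']} analysis summary (seed {report['seed']})",
        "",
        "Cumulative AUC group comparisons (signed ΔMEP·min):",
    ]
    for c in report["comparisons"]:
        lines.append(
            f"  T5-T{c['interval_end_min']:<3} "
            f"mean A {c['mean_a']:+.3f} (n={c['n_a']})  "
            f"mean B {c['mean_b']:+.3f} (n={c['n_b']})  "
            f"t({c['df']}) = {c['t_stat']:.2f}  p = {c['p_raw']:.4f}  "
            f"p_FDR = {c['p_fdr']:.4f}  d = {c['cohens_d']:.2f}"
        )
    lines.append("")
    for c in report["correlations"]:
        lines.append(
            f"Age vs max suppression, {c['group']}: r = {c['r']:.2f}, "
            f"p = {c['p_two_tailed']:.3f} (n = {c['n']})"
        )
    gb = report["genotype_balance"]
    lines += [
        "",
        f"Genotype balance (n1={gb['n1']}, n2={gb['n2']}, "
        f"p_Met- = {gb['p_met_minus']}, {gb['source']}):",
        f"  overall discordance probability = {gb['overall_probability']:.4f} "
        f"over {gb['n_significant_scenarios']} significant scenarios",
        "",
        "Post hoc power / required n per group (80% power):",
    ]
    for p in report["power"]:
        req = p.get("required_n_per_group", "-")
        lines.append(
            f"  T5-T{p['interval_end_min']:<3} d = {p['d']:.2f}  "
            f"power = {100 * p['post_hoc_power']:.1f}%  n_req = {req}"
        )
    path.write_text("\n".join(lines) + "\n")


def simulate_to_dir(config: CohortConfig, seed: int, out_dir: str) -> None:
    """Generate a cohort and write trials/metadata CSVs plus ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, trials, truth = generate_cohort(config, seed=seed)
    subjects.to_csv(out / "subjects.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
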