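"""Simple summary figures: per-group ΔMEP time course and AUC profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .metrics import grand_average  # noqa: E402


def plot_timecourse(
    delta: pd.DataFrame, subjects: pd.DataFrame, path: str | Path
) -> None:
    """Grand-average ΔMEP (±SEM) against time, one line per group."""
    merged = delta.merge(subjects[["subject_id", "group"]], on="subject_id")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for grp, sub in merged.groupby("group"):
        ga = grand_average(sub)
        sem = ga["delta_mep_sd"] / ga["n"] ** 0.5
        ax.errorbar(ga["time_min"], ga["delta_mep_mean"], yerr=sem,
                    marker="o", capsize=3, label=str(grp))
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("time post-cTBS (min)")
    ax.set_ylabel(r"$\Delta$MEP (ln ratio)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_auc_profiles(
    auc: pd.DataFrame, subjects: pd.DataFrame, path: str | Path
) -> None:
    """Group-mean cumulative AUC (±SEM) for each nested interval."""
    merged = auc.merge(subjects[["subject_id", "group"]], on="subject_id")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for grp, sub in merged.groupby("group"):
        stats = sub.groupby("interval_end_min")["auc"].agg(["mean", "sem"])
        ax.errorbar(stats.index, stats["mean"], yerr=stats["sem"],
                    marker="s", capsize=3, label=str(grp))
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("interval end (min)")
    ax.set_ylabel(r"cumulative AUC ($\Delta$MEP·min)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
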