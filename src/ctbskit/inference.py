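"""Group-level inference on plasticity metrics.

Independent-samples pooled-variance (Student) t-tests per nested AUC
interval, false-discovery-rate control across the six-interval family by the
Benjamini–Yekutieli step-up procedure (valid under arbitrary dependence —
the nested intervals are strongly dependent by construction), Cohen's d
effect sizes, Pearson age correlations of maximum suppression, and two
sensitivity analyses: rerunning the comparison after excluding subjects by a
metadata predicate, and a baseline-matched subgroup search.

Pooled-variance t (not Welch) matches a df of n1 + n2 - 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import INTERVAL_ENDS_MIN


class InferenceError(ValueError):
    """Base class for inference failures."""


class DegenerateVarianceError(InferenceError):
    """Zero pooled variance with unequal means: t undefined."""


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def students_t(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; returns ``(t, df, p_two_tailed)``.

    Zero pooled variance with equal means yields ``(0, df, 1)``; with unequal
    means the statistic is undefined and :class:`DegenerateVarianceError` is
    raised.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InferenceError("each sample needs at least 2 values")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def pooled_sd(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Pooled (n-1 weighted) standard deviation of two samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    df = len(a) + len(b) - 2
    if df <= 0:
        raise InferenceError("pooled SD needs n1 + n2 > 2")
    return float(
        np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df)
    )


def cohens_d(
    sample_a: Sequence[float], sample_b: Sequence[float], signed: bool = False
) -> float:
    """Cohen's d: mean difference over pooled SD (absolute by convention)."""
    sd = pooled_sd(sample_a, sample_b)
    diff = float(np.mean(sample_a) - np.mean(sample_b))
    if sd == 0:
        if diff == 0:
            return 0.0
        raise DegenerateVarianceError("zero pooled SD with unequal means")
    d = diff / sd
    return d if signed else abs(d)


def fdr_adjust(p_values: Sequence[float], method: str = "by") -> np.ndarray:
    """Step-up FDR-adjusted p-values (``"by"`` Benjamini–Yekutieli with the
    harmonic-sum correction, or ``"bh"`` Benjamini–Hochberg), in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InferenceError("p-values must lie in [0, 1]")
    key = {"by": "fdr_by", "bh": "fdr_bh"}.get(method.lower())
    if key is None:
        raise InferenceError(f"unknown FDR method {method!r}")
    return multipletests(p, method=key)[1]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-tailed p-value."""

    group: str
    r: float
    p_two_tailed: float
    n: int


def pearson_corr(
    x: Sequence[float], y: Sequence[float], group: str = ""
) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InferenceError("pearson_corr needs equal-length samples of n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise InferenceError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(group, float(r), float(p), len(x))


# ---------------------------------------------------------------------------
# interval-family group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """One interval's two-group comparison of cumulative AUC."""

    interval_end_min: int
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    df: int
    p_raw: float
    p_fdr: float
    cohens_d: float


def compare_groups(
    auc: pd.DataFrame,
    subjects: pd.DataFrame,
    group_a: str = "ASD",
    group_b: str = "TD",
    intervals: Iterable[int] = INTERVAL_ENDS_MIN,
    fdr_method: str = "by",
) -> list[GroupComparison]:
    """Per-interval pooled t-tests of cumulative AUC between two groups.

    ``auc`` is the tidy table from :func:`ctbskit.metrics.auc_table`;
    ``subjects`` maps ``subject_id`` to ``group``. FDR adjustment is applied
    across the family of computable intervals. An interval with fewer than
    two subjects in either group is reported with NaN statistics and omitted
    from the FDR family.
    """
    merged = auc.merge(subjects[["subject_id", "group"]], on="subject_id")
    rows: list[dict] = []
    for end in intervals:
        sub = merged[merged["interval_end_min"] == end]
        a = sub.loc[sub["group"] == group_a, "auc"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "auc"].to_numpy()
        row = {
            "interval_end_min": int(end),
            "mean_a": float(np.mean(a)) if len(a) else math.nan,
            "sd_a": float(np.std(a, ddof=1)) if len(a) > 1 else math.nan,
            "n_a": len(a),
            "mean_b": float(np.mean(b)) if len(b) else math.nan,
            "sd_b": float(np.std(b, ddof=1)) if len(b) > 1 else math.nan,
            "n_b": len(b),
        }
        if len(a) >= 2 and len(b) >= 2:
            t, df, p = students_t(a, b)
            row.update(t_stat=t, df=df, p_raw=p,
                       cohens_d=cohens_d(a, b, signed=True))
        else:
            row.update(t_stat=math.nan, df=len(a) + len(b) - 2,
                       p_raw=math.nan, cohens_d=math.nan)
        rows.append(row)

    computable = [i for i, r in enumerate(rows) if not math.isnan(r["p_raw"])]
    adjusted = fdr_adjust([rows[i]["p_raw"] for i in computable], fdr_method)
    for i, r in enumerate(rows):
        r["p_fdr"] = math.nan
    for i, p_adj in zip(computable, adjusted):
        rows[i]["p_fdr"] = float(p_adj)
    return [GroupComparison(**r) for r in rows]


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Comparison list as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame([vars(c) for c in comparisons])


def sensitivity_excluding(
    auc: pd.DataFrame,
    subjects: pd.DataFrame,
    predicate: Callable[[pd.Series], bool],
    **compare_kwargs,
) -> list[GroupComparison]:
    """Rerun :func:`compare_groups` after dropping subjects matching ``predicate``.

    ``predicate`` receives each subject-metadata row; matching subjects are
    excluded (e.g. ``lambda s: s.adhd_comorbid`` removes ADHD comorbidity).
    """
    keep = subjects[~subjects.apply(predicate, axis=1)]
    for grp in (compare_kwargs.get("group_a", "ASD"), compare_kwargs.get("group_b", "TD")):
        if (keep["group"] == grp).sum() == 0:
            raise InferenceError(f"exclusion predicate empties group {grp!r}")
    return compare_groups(auc, keep, **compare_kwargs)


# ---------------------------------------------------------------------------
# baseline-matched subgroups
# ---------------------------------------------------------------------------

def _comparable(a: np.ndarray, b: np.ndarray, p_floor: float) -> bool:
    try:
        _, _, p = students_t(a, b)
    except DegenerateVarianceError:
        return False
    return p > p_floor


def select_baseline_matched_subgroups(
    baselines_a: pd.Series,
    baselines_b: pd.Series,
    p_floor: float = 0.05,
    exhaustive_limit: int = 25,
    max_combinations: int = 200_000,
) -> tuple[list, list]:
    """Largest subject subsets whose baseline amplitudes are comparable.

    Finds the largest pair of subsets (one per group, each of size >= 2)
    whose baseline MEP amplitudes do not differ by pooled t-test at
    ``p_floor``; ties in total size are broken by the smaller absolute mean
    difference. When the total candidate count is at most
    ``exhaustive_limit`` the search enumerates removal sets in order of
    increasing size (so the first qualifying size is maximal); a combination
    budget of ``max_combinations`` guards the worst case, beyond which — and
    for larger cohorts — a greedy trim repeatedly removes the single subject
    whose removal most increases the comparability p-value.

    ``baselines_a`` / ``baselines_b`` are indexed by subject id; the returned
    pair holds the retained subject ids.
    """
    a = baselines_a.astype(float)
    b = baselines_b.astype(float)
    if a.empty or b.empty:
        raise InferenceError("both groups must be non-empty")

    if len(a) + len(b) <= exhaustive_limit:
        result = _exhaustive_match(a, b, p_floor, max_combinations)
        if result is not None:
            return result
    return _greedy_match(a, b, p_floor)


def _exhaustive_match(a, b, p_floor, max_combinations):
    n1, n2 = len(a), len(b)
    tested = 0
    for removed in range(0, n1 + n2 - 3):
        best = None  # (abs mean diff, ids_a, ids_b)
        for r1 in range(max(0, removed - (n2 - 2)), min(removed, n1 - 2) + 1):
            r2 = removed - r1
            for drop1 in itertools.combinations(range(n1), r1):
                keep1 = a.drop(a.index[list(drop1)])
                for drop2 in itertools.combinations(range(n2), r2):
                    keep2 = b.drop(b.index[list(drop2)])
                    tested += 1
                    if tested > max_combinations:
                        return None  # budget exceeded: caller falls back to greedy
                    if _comparable(keep1.to_numpy(), keep2.to_numpy(), p_floor):
                        gap = abs(keep1.mean() - keep2.mean())
                        if best is None or gap < best[0]:
                            best = (gap, list(keep1.index), list(keep2.index))
        if best is not None:
            return best[1], best[2]
    raise InferenceError("no comparable subgroup pair of size >= 2 each")


def _safe_p(a: np.ndarray, b: np.ndarray) -> float:
    try:
        return students_t(a, b)[2]
    except DegenerateVarianceError:
        return -1.0


def _greedy_match(a, b, p_floor):
    keep_a, keep_b = a.copy(), b.copy()
    while True:
        if _comparable(keep_a.to_numpy(), keep_b.to_numpy(), p_floor):
            return list(keep_a.index), list(keep_b.index)
        best_p, best_move = -1.0, None
        if len(keep_a) > 2:
            for idx in keep_a.index:
                p = _safe_p(keep_a.drop(idx).to_numpy(), keep_b.to_numpy())
                if p > best_p:
                    best_p, best_move = p, ("a", idx)
        if len(keep_b) > 2:
            for idx in keep_b.index:
                p = _safe_p(keep_a.to_numpy(), keep_b.drop(idx).to_numpy())
                if p > best_p:
                    best_p, best_move = p, ("b", idx)
        if best_move is None:
            raise InferenceError("no comparable subgroup pair of size >= 2 each")
        side, idx = best_move
        if side == "a":
            keep_a = keep_a.drop(idx)
        else:
            keep_b = keep_b.drop(idx)
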