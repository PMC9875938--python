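"""Behavioural aggregation and paired inference.

Summaries follow the standard Simon Go/Nogo conventions: mean correct-Go RT
per congruency, Go accuracy (correct / responded, i.e. misses excluded), and
Nogo accuracy as the correct-omission rate.  Inference is the paired t test
with the dz effect size (mean difference / SD of differences, so
``dz = t / sqrt(n)``), with the Wilcoxon signed-rank test as the
nonparametric fallback when normality fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_sim import CONGRUENT, GO, INCONGRUENT, NOGO

__all__ = ["StatRecord", "summarize_behaviour", "paired_t", "wilcoxon_signed_rank"]


@dataclass(frozen=True)
class StatRecord:
    statistic: float
    df: int | None
    p_value: float
    effect_size_dz: float | None
    test_name: str
    n: int


def summarize_behaviour(trials: pd.DataFrame) -> pd.DataFrame:
    """Per trial-type x congruency summary table.

    Columns: n trials, mean and SE of correct-Go RT, accuracy in percent
    (Go: correct / (correct + error), excluding misses; Nogo: correct
    omissions / all), false-alarm percentage (Nogo only).  Empty cells are
    flagged rather than raising.
    """
    if trials["outcome"].isna().all():
        raise ValueError("outcomes are not populated; run simulate_behaviour first")
    rows = []
    for trial_type in (GO, NOGO):
        for congruency in (CONGRUENT, INCONGRUENT):
            sub = trials[(trials.trial_type == trial_type)
                         & (trials.congruency == congruency)]
            row = dict(trial_type=trial_type, congruency=congruency,
                       n=len(sub), cell_empty=len(sub) == 0,
                       mean_rt_ms=np.nan, se_rt_ms=np.nan,
                       accuracy_pct=np.nan, false_alarm_pct=np.nan)
            if len(sub):
                if trial_type == GO:
                    correct = sub[sub.outcome == "correct"]
                    responded = sub[sub.outcome.isin(["correct", "error"])]
                    if len(correct):
                        rt = correct.rt_ms.to_numpy(dtype=float)
                        row["mean_rt_ms"] = rt.mean()
                        row["se_rt_ms"] = rt.std(ddof=1) / np.sqrt(len(rt)) if len(rt) > 1 else 0.0
                    if len(responded):
                        row["accuracy_pct"] = 100.0 * len(correct) / len(responded)
                else:
                    n_fa = int((sub.outcome == "false_alarm").sum())
                    row["accuracy_pct"] = 100.0 * (len(sub) - n_fa) / len(sub)
                    row["false_alarm_pct"] = 100.0 * n_fa / len(sub)
            rows.append(row)
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> StatRecord:
    """Paired t test with the dz effect size (dz = t / sqrt(n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return StatRecord(statistic=float(t), df=n - 1, p_value=float(p),
                      effect_size_dz=float(t / np.sqrt(n)), test_name="paired_t", n=n)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         alternative: str = "two-sided") -> StatRecord:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  Below n = 13 the p value
    comes from exact enumeration of sign assignments; otherwise from the
    tie-corrected normal approximation.  The reported statistic is the
    normal-approximation z of T+; ``alternative`` may be ``"two-sided"`` or
    ``"greater"`` (x tending above y).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("need two equal-length vectors")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    z = (t_plus - mu) / np.sqrt(var)
    if n <= 12:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        t_null = signs @ ranks
        p_ge = (t_null >= t_plus - 1e-9).mean()
        p_le = (t_null <= t_plus + 1e-9).mean()
        p = p_ge if alternative == "greater" else min(1.0, 2.0 * min(p_ge, p_le))
    else:
        p = stats.norm.sf(z) if alternative == "greater" else 2.0 * stats.norm.sf(abs(z))
    return StatRecord(statistic=float(z), df=None, p_value=float(p),
                      effect_size_dz=None, test_name="wilcoxon_signed_rank", n=n)
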