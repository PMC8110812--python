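"""Lesion volumes, growth ratios, rank tests and effect-size summaries.

Effect sizes are probabilities of superiority (common-language effect size,
ties credited one half); p-values come from Wilcoxon signed-rank and
Mann-Whitney U tests and are additionally reported as surprisal,
s = -log2(p), in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chaco import LesionMask

__all__ = [
    "GrowthRecord",
    "EffectSummary",
    "lesion_volume",
    "growth_ratio",
    "paired_rank_test",
    "two_sample_rank_test",
    "prob_superiority_paired",
    "prob_superiority_unpaired",
    "surprisal",
    "percentage",
    "favorable_percentage",
    "shrinkage_percentage",
    "region_scan",
]


@dataclass(frozen=True)
class GrowthRecord:
    vol_T1: float
    vol_T2: float
    ratio: float
    log2_ratio: float


@dataclass(frozen=True)
class EffectSummary:
    estimate: float  # probability of superiority in [0, 1]
    p_value: float
    surprisal: float  # bits
    n: int
    all_tied: bool = False


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in ml (voxel count times voxel volume)."""
    return mask.volume_ml


def growth_ratio(vol_t1: float, vol_t2: float, floor: float | None = None) -> GrowthRecord:
    """Growth ratio vol_T2/vol_T1 and its log2, the mediator variable.

    Zero volumes are replaced by ``floor`` (e.g. half a voxel volume in ml)
    before forming the ratio; without a floor a zero volume is an error.
    """
    if vol_t1 < 0 or vol_t2 < 0:
        raise ValueError("volumes must be non-negative")
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        vol_t1 = max(vol_t1, floor)
        vol_t2 = max(vol_t2, floor)
    if vol_t1 == 0 or vol_t2 == 0:
        raise ValueError("zero volume without a floor")
    ratio = vol_t2 / vol_t1
    return GrowthRecord(vol_T1=vol_t1, vol_T2=vol_t2, ratio=ratio, log2_ratio=math.log2(ratio))


def prob_superiority_paired(x_t1, x_t2) -> float:
    """(#{delta > 0} + 0.5 * #{delta = 0}) / n for delta = x_T2 - x_T1."""
    x_t1 = np.asarray(x_t1, dtype=float)
    x_t2 = np.asarray(x_t2, dtype=float)
    if x_t1.size == 0:
        raise ValueError("empty input")
    if x_t1.shape != x_t2.shape:
        raise ValueError("paired samples must have equal length")
    d = x_t2 - x_t1
    return float((np.sum(d > 0) + 0.5 * np.sum(d == 0)) / d.size)


def prob_superiority_unpaired(x_p, x_a) -> float:
    """(#{pairs x_P > x_A} + 0.5 * ties) / (n_P * n_A)."""
    x_p = np.asarray(x_p, dtype=float)
    x_a = np.asarray(x_a, dtype=float)
    if x_p.size == 0 or x_a.size == 0:
        raise ValueError("empty input")
    diff = x_p[:, None] - x_a[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def surprisal(p: float) -> float:
    """Shannon surprisal of a p-value in bits, -log2(p)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return -math.log2(p)


def paired_rank_test(x_t1, x_t2) -> EffectSummary:
    """Two-sided Wilcoxon signed-rank test with probability-of-superiority
    effect size.  All-tied data yield p=1 flagged as undefined."""
    x_t1 = np.asarray(x_t1, dtype=float)
    x_t2 = np.asarray(x_t2, dtype=float)
    if x_t1.size < 2 or x_t1.shape != x_t2.shape:
        raise ValueError("need >= 2 paired observations of equal length")
    est = prob_superiority_paired(x_t1, x_t2)
    d = x_t2 - x_t1
    if np.all(d == 0):
        return EffectSummary(estimate=est, p_value=1.0, surprisal=0.0, n=d.size, all_tied=True)
    res = stats.wilcoxon(x_t2, x_t1, alternative="two-sided", zero_method="wilcox")
    p = float(res.pvalue)
    return EffectSummary(estimate=est, p_value=p, surprisal=surprisal(p), n=d.size)


def two_sample_rank_test(x_p, x_a) -> EffectSummary:
    """Two-sided Mann-Whitney U test with probability-of-superiority
    effect size (placebo vs alteplase convention: P(X_P > X_A))."""
    x_p = np.asarray(x_p, dtype=float)
    x_a = np.asarray(x_a, dtype=float)
    if x_p.size < 2 or x_a.size < 2:
        raise ValueError("need >= 2 observations per group")
    est = prob_superiority_unpaired(x_p, x_a)
    if np.min(np.r_[x_p, x_a]) == np.max(np.r_[x_p, x_a]):
        return EffectSummary(
            estimate=est, p_value=1.0, surprisal=0.0, n=x_p.size + x_a.size, all_tied=True
        )
    res = stats.mannwhitneyu(x_p, x_a, alternative="two-sided")
    p = float(res.pvalue)
    return EffectSummary(estimate=est, p_value=p, surprisal=surprisal(p), n=x_p.size + x_a.size)


# ---------------------------------------------------------------------------
# Cohort accounting


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """100 * count / total, rounded; the basic cohort-flow accounting step."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def favorable_percentage(favorable, ndigits: int = 1) -> float:
    """Percent favorable among subjects with a non-missing outcome."""
    fav = pd.Series(favorable, dtype=float)
    avail = fav.dropna()
    return percentage(float((avail == 1).sum()), float(len(avail)), ndigits)


def shrinkage_percentage(vol_t1, vol_t2, ndigits: int = 1) -> float:
    """Percent of subjects whose lesion shrank (vol_T2 < vol_T1)."""
    v1 = np.asarray(vol_t1, dtype=float)
    v2 = np.asarray(vol_t2, dtype=float)
    if v1.size == 0 or v1.shape != v2.shape:
        raise ValueError("need equal-length non-empty volume vectors")
    return percentage(float(np.sum(v2 < v1)), float(v1.size), ndigits)


# ---------------------------------------------------------------------------
# Mass-univariate scan


def region_scan(long_table: pd.DataFrame) -> pd.DataFrame:
    """Per-region rank-based contrasts of disconnection scores.

    ``long_table`` columns: subject, region, time (T1/T2), arm (P/A), score.
    Reports, per region: time effect P(T2>T1) (paired), treatment effect
    P(P>A) at T2 (unpaired), and interaction P(dP>dA) on within-subject
    change.  No multiplicity adjustment is applied.
    """
    required = {"subject", "region", "time", "arm", "score"}
    if not required.issubset(long_table.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    rows = []
    for region, grp in long_table.groupby("region"):
        wide = grp.pivot_table(index=["subject", "arm"], columns="time", values="score")
        wide = wide.dropna().reset_index()
        t1 = wide["T1"].to_numpy()
        t2 = wide["T2"].to_numpy()
        delta = t2 - t1
        is_p = (wide["arm"] == "P").to_numpy()
        contrasts = {}
        if len(wide) >= 2:
            contrasts["time"] = paired_rank_test(t1, t2)
        if is_p.sum() >= 2 and (~is_p).sum() >= 2:
            contrasts["treatment"] = two_sample_rank_test(t2[is_p], t2[~is_p])
            contrasts["interaction"] = two_sample_rank_test(delta[is_p], delta[~is_p])
        for effect, summ in contrasts.items():
            rows.append(
                {
                    "region": region,
                    "effect": effect,
                    "estimate": summ.estimate,
                    "p": summ.p_value,
                    "surprisal": summ.surprisal,
                    "n": summ.n,
                }
            )
    return pd.DataFrame(rows)
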