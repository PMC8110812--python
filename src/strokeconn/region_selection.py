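"""Data-driven selection of mediator brain regions.

Regions are ranked on two criteria computed from covariate-adjusted
regressions of standardized per-region disconnection change: treatment
responsiveness (linear model, standardized beta) and clinical eloquence
(logistic model of favorable outcome, standardized odds ratio).  A region
qualifies as a mediator candidate when neither 95% confidence interval is
compatible with no association; distinct mediation models are enumerated by
intersecting the top-i and top-j regions of the two rankings over a
threshold grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegionEffect",
    "MediationModelSpec",
    "responsiveness_scan",
    "eloquence_scan",
    "qualify_and_rank",
    "enumerate_models",
    "selection_table",
]


@dataclass(frozen=True)
class RegionEffect:
    region: str
    estimate: float  # standardized beta (responsiveness) or OR (eloquence)
    ci_lo: float
    ci_hi: float
    p: float
    skipped: bool = False
    note: str = ""


@dataclass(frozen=True)
class MediationModelSpec:
    """Mediator region set (growth is always an additional mediator)."""

    regions: frozenset[str]
    provenance: tuple[tuple[int, int], ...] = ()
    include_growth: bool = True

    def mediator_columns(self, growth_col: str = "log2_growth") -> list[str]:
        return [growth_col, *sorted(self.regions)]

    def name(self) -> str:
        if not self.regions:
            return "growth_only"
        return "growth+" + "+".join(sorted(self.regions))


def _analysis_frame(df: pd.DataFrame, covariates, outcome: str) -> pd.DataFrame:
    """Restrict to non-missing outcome; both the predictor standardization and
    the covariate adjustment use this single analysis subsample."""
    sub = df.dropna(subset=[outcome]).copy()
    if "log_vol_T1" in covariates and "log_vol_T1" not in sub.columns:
        sub["log_vol_T1"] = np.log(sub["vol_T1"])
    return sub


def responsiveness_scan(
    df: pd.DataFrame,
    region_cols: list[str],
    covariates: tuple[str, ...] = ("age", "nihss", "log_vol_T1"),
    exposure: str = "treated",
    outcome: str = "favorable",
    level: float = 0.95,
) -> list[RegionEffect]:
    """Standardized beta of disconnection change on treatment, per region.

    Linear regression of z-scored change on treatment plus covariates; zero
    variance regions are skipped with a diagnostic.
    """
    sub = _analysis_frame(df, covariates, outcome)
    z = stats.norm.ppf(0.5 + level / 2)
    out = []
    xmat = sm.add_constant(sub[[exposure, *covariates]].to_numpy(dtype=float))
    for col in region_cols:
        vals = sub[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            out.append(RegionEffect(col, np.nan, np.nan, np.nan, np.nan, True, "zero variance"))
            continue
        yz = (vals - vals.mean()) / sd
        res = sm.OLS(yz, xmat).fit()
        b = float(res.params[1])
        se = float(res.bse[1])
        out.append(
            RegionEffect(
                region=col,
                estimate=b,
                ci_lo=b - z * se,
                ci_hi=b + z * se,
                p=float(res.pvalues[1]),
            )
        )
    return out


def eloquence_scan(
    df: pd.DataFrame,
    region_cols: list[str],
    covariates: tuple[str, ...] = ("age", "nihss", "log_vol_T1"),
    outcome: str = "favorable",
    level: float = 0.95,
) -> list[RegionEffect]:
    """Standardized odds ratio of favorable outcome per SD of disconnection
    change, per region.  Separation is flagged; the region is retained with
    a ridge-penalized fallback fit."""
    sub = _analysis_frame(df, covariates, outcome)
    z = stats.norm.ppf(0.5 + level / 2)
    y = sub[outcome].to_numpy(dtype=float)
    cmat = sub[list(covariates)].to_numpy(dtype=float)
    out = []
    for col in region_cols:
        vals = sub[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            out.append(RegionEffect(col, np.nan, np.nan, np.nan, np.nan, True, "zero variance"))
            continue
        xz = (vals - vals.mean()) / sd
        xmat = sm.add_constant(np.c_[xz, cmat])
        note = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True) or abs(res.params[1]) > 50:
                    raise RuntimeError("separation")
                b, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
            except Exception:
                res = sm.Logit(y, xmat).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
                b = float(res.params[1])
                se = float("inf")
                p = 1.0
                note = "separation; ridge fallback"
        out.append(
            RegionEffect(
                region=col,
                estimate=float(np.exp(b)),
                ci_lo=float(np.exp(b - z * se)),
                ci_hi=float(np.exp(b + z * se)),
                p=p,
                note=note,
            )
        )
    return out


@dataclass
class RankedSelection:
    responsiveness: list[RegionEffect]
    eloquence: list[RegionEffect]
    resp_order: list[str]  # ascending p
    eloq_order: list[str]
    qualified: set[str]
    spearman_rho: float
    spearman_p: float
    warning: str = ""


def _order(effects: list[RegionEffect], is_or: bool) -> list[str]:
    """Ascending p; ties broken by |standardized effect| descending, then id.

    For odds ratios the standardized effect magnitude is |log OR|."""
    usable = [e for e in effects if not e.skipped]

    def magnitude(e: RegionEffect) -> float:
        if is_or and e.estimate > 0:
            return abs(np.log(e.estimate))
        return abs(e.estimate)

    return [e.region for e in sorted(usable, key=lambda e: (e.p, -magnitude(e), e.region))]


def qualify_and_rank(
    resp: list[RegionEffect],
    eloq: list[RegionEffect],
) -> RankedSelection:
    """Order regions by statistical evidence within each criterion and keep
    as qualified those whose responsiveness CI excludes 0 and whose
    eloquence CI excludes 1.  Reports the Spearman correlation between the
    two orderings; an empty qualified set is a warning, not an error."""
    resp_order = _order(resp, is_or=False)
    eloq_order = _order(eloq, is_or=True)
    resp_by = {e.region: e for e in resp}
    eloq_by = {e.region: e for e in eloq}
    qualified = set()
    for region in set(resp_by) & set(eloq_by):
        er, ee = resp_by[region], eloq_by[region]
        if er.skipped or ee.skipped:
            continue
        if (er.ci_lo > 0 or er.ci_hi < 0) and (ee.ci_lo > 1 or ee.ci_hi < 1):
            qualified.add(region)
    common = [r for r in resp_order if r in set(eloq_order)]
    if len(common) >= 3:
        r1 = [resp_order.index(r) for r in common]
        r2 = [eloq_order.index(r) for r in common]
        rho, p = stats.spearmanr(r1, r2)
    else:
        rho, p = np.nan, np.nan
    warning = "" if qualified else "no region qualified; proceeding with growth-only model"
    return RankedSelection(
        responsiveness=resp,
        eloquence=eloq,
        resp_order=resp_order,
        eloq_order=eloq_order,
        qualified=qualified,
        spearman_rho=float(rho) if rho == rho else np.nan,
        spearman_p=float(p) if p == p else np.nan,
        warning=warning,
    )


def enumerate_models(
    resp_order: list[str],
    eloq_order: list[str],
    qualified: set[str],
    i_max: int = 9,
    j_max: int = 15,
) -> list[MediationModelSpec]:
    """Enumerate distinct mediator sets over the (i, j) threshold grid.

    For each (i <= i_max, j <= j_max) the mediator set is
    qualified ∩ top-i(responsiveness) ∩ top-j(eloquence); distinct non-empty
    sets are collected with their generating (i, j) pairs as provenance.  If
    every cell is empty a single growth-only spec is returned.
    """
    by_set: dict[frozenset, list[tuple[int, int]]] = {}
    for i in range(1, i_max + 1):
        top_i = set(resp_order[:i])
        for j in range(1, j_max + 1):
            top_j = set(eloq_order[:j])
            members = frozenset(qualified & top_i & top_j)
            if members:
                by_set.setdefault(members, []).append((i, j))
    if not by_set:
        return [MediationModelSpec(regions=frozenset(), provenance=((0, 0),))]
    return [
        MediationModelSpec(regions=members, provenance=tuple(pairs))
        for members, pairs in sorted(by_set.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]


def selection_table(selection: RankedSelection) -> pd.DataFrame:
    """Table-2-style summary: per region both criteria, ranks, qualified flag."""
    resp_by = {e.region: e for e in selection.responsiveness}
    eloq_by = {e.region: e for e in selection.eloquence}
    rows = []
    for region in sorted(set(resp_by) | set(eloq_by)):
        er = resp_by.get(region)
        ee = eloq_by.get(region)
        rows.append(
            {
                "region": region,
                "beta": er.estimate if er else np.nan,
                "beta_ci_lo": er.ci_lo if er else np.nan,
                "beta_ci_hi": er.ci_hi if er else np.nan,
                "beta_p": er.p if er else np.nan,
                "rank_resp": selection.resp_order.index(region) + 1
                if region in selection.resp_order
                else np.nan,
                "or": ee.estimate if ee else np.nan,
                "or_ci_lo": ee.ci_lo if ee else np.nan,
                "or_ci_hi": ee.ci_hi if ee else np.nan,
                "or_p": ee.p if ee else np.nan,
                "rank_eloq": selection.eloq_order.index(region) + 1
                if region in selection.eloq_order
                else np.nan,
                "qualified": region in selection.qualified,
            }
        )
    return pd.DataFrame(rows)
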