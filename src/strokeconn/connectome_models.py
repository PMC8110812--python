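"""Parametric models of disconnection progression and clinical outcome.

Disconnection scores are semicontinuous: a two-part mixture separates the
probability of any disconnection (logistic part) from the magnitude of
positive scores, which are modelled on the natural-log scale with a
Gaussian linear mixed model

    log(chaco+) ~ time * treatment + roi * (time + log_volume) + (1 | subject)

Term tests are type II Wald chi-square, implemented by refitting models that
respect marginality.  The outcome side is an adjusted logistic regression of
favorable outcome on treatment or infarct growth with profile-likelihood
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ._stats import SeparationError, profile_ci_logit

__all__ = [
    "MixtureFit",
    "OutcomeFit",
    "ConvergenceError",
    "validate_long_table",
    "fit_mixture",
    "arm_time_ratios",
    "outcome_logistic",
    "wald_table_to_frame",
]


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed or was singular."""


_TERMS = [
    "time2",
    "treated",
    "time2:treated",
    "log_volume",
    "C(roi)",
    "time2:C(roi)",
    "log_volume:C(roi)",
]

# term -> higher-order terms containing it (marginality map)
_CONTAINS = {
    "time2": ["time2:treated", "time2:C(roi)"],
    "treated": ["time2:treated"],
    "log_volume": ["log_volume:C(roi)"],
    "C(roi)": ["time2:C(roi)", "log_volume:C(roi)"],
    "time2:treated": [],
    "time2:C(roi)": [],
    "log_volume:C(roi)": [],
}

_TERM_LABELS = {
    "time2": "Time",
    "treated": "Treatment",
    "time2:treated": "Time:Treatment",
    "log_volume": "log(Volume)",
    "C(roi)": "ROI",
    "time2:C(roi)": "ROI:Time",
    "log_volume:C(roi)": "ROI:log(Volume)",
}


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a long disconnection table.

    Requires columns subject, region, time (T1/T2), arm (P/A), chaco,
    log_volume; adds indicator columns ``time2``/``treated`` and a ``roi``
    string column.
    """
    required = {"subject", "region", "time", "arm", "chaco", "log_volume"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    if (table["chaco"] < 0).any():
        raise ValueError("chaco scores must be >= 0")
    dup = table.duplicated(subset=["subject", "region", "time"])
    if dup.any():
        raise ValueError("one row per subject x region x time required")
    if set(table["time"].unique()) != {"T1", "T2"}:
        raise ValueError("both time points T1 and T2 must be present")
    arms = table.groupby("arm")["subject"].nunique()
    if not {"P", "A"}.issubset(arms.index) or (arms < 2).any():
        raise ValueError("need >= 2 subjects per arm")
    out = table.copy()
    out["time2"] = (out["time"] == "T2").astype(int)
    out["treated"] = (out["arm"] == "A").astype(int)
    out["roi"] = out["region"].astype(str)
    return out


@dataclass
class MixtureFit:
    positive_result: object
    zero_result: object | None
    wald_table: pd.DataFrame
    formula: str
    notes: tuple[str, ...] = ()
    _data: pd.DataFrame = field(default=None, repr=False)


def _mixed_fit(data: pd.DataFrame, rhs_terms: list[str]):
    formula = "log_chaco ~ " + " + ".join(rhs_terms)
    model = smf.mixedlm(formula, data=data, groups=data["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
        except Exception as err:
            raise ConvergenceError(f"mixed model failed for {formula!r}: {err}") from err
    if not np.all(np.isfinite(res.fe_params)):
        raise ConvergenceError(f"non-finite fixed effects for {formula!r}")
    return res


def _term_columns(result, term: str) -> list[int]:
    names = result.model.exog_names
    cols = []
    for i, name in enumerate(names):
        parts = set(name.split(":"))
        tparts = term.split(":")
        norm = set()
        for p in parts:
            base = p.split("[")[0]
            norm.add(base)
        if norm == {t.split("[")[0] for t in tparts} and len(parts) == len(tparts):
            cols.append(i)
    return cols


def _wald_chi2(result, term: str) -> tuple[float, int, float]:
    cols = _term_columns(result, term)
    if not cols:
        raise ValueError(f"no design columns found for term {term!r}")
    b = np.asarray(result.fe_params)[cols]
    cov = np.asarray(result.cov_params())[np.ix_(cols, cols)]
    chi2 = float(b @ np.linalg.solve(cov, b))
    dof = len(cols)
    return chi2, dof, float(stats.chi2.sf(chi2, dof))


def fit_mixture(
    table: pd.DataFrame,
    wald_terms: list[str] | str = "all",
) -> MixtureFit:
    """Fit the two-part disconnection model on a long table.

    The positive part uses rows with chaco > 0 on the natural-log scale with
    a subject random intercept; the zero part is a logistic model of
    1[chaco > 0] with the analogous fixed-effect structure (dropping the
    log(volume) x ROI term on convergence failure, recorded in ``notes``).

    ``wald_terms`` selects which type II Wald tests to compute ('all', or a
    list of term names such as ['time2:treated']); interaction terms need no
    refit, main effects are tested in the largest model respecting
    marginality.
    """
    data = validate_long_table(table)
    notes: list[str] = []
    pos = data[data["chaco"] > 0].copy()
    if pos["subject"].nunique() < 4:
        raise ConvergenceError("too few subjects with positive scores")
    pos["log_chaco"] = np.log(pos["chaco"])
    full = _mixed_fit(pos, _TERMS)

    if wald_terms == "all":
        terms = list(_TERMS)
    elif wald_terms is None:
        terms = []
    else:
        terms = list(wald_terms)
    rows = []
    for term in terms:
        higher = _CONTAINS[term]
        if higher:
            reduced_terms = [t for t in _TERMS if t not in higher]
            res = _mixed_fit(pos, reduced_terms)
        else:
            res = full
        chi2, dof, p = _wald_chi2(res, term)
        rows.append({"term": _TERM_LABELS[term], "chi2": chi2, "dof": dof, "p": p})
    wald = pd.DataFrame(rows, columns=["term", "chi2", "dof", "p"])

    zero_res = None
    any_zero = (data["chaco"] == 0).any()
    if any_zero:
        data["any_pos"] = (data["chaco"] > 0).astype(int)
        for rhs in (_TERMS, [t for t in _TERMS if t != "log_volume:C(roi)"]):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    zero_res = smf.glm(
                        "any_pos ~ " + " + ".join(rhs),
                        data=data,
                        family=sm.families.Binomial(),
                    ).fit()
                if np.all(np.isfinite(zero_res.params)) and np.abs(zero_res.params).max() < 1e3:
                    if rhs is not _TERMS:
                        notes.append("zero part refit without log(volume) x ROI term")
                    break
                zero_res = None
            except Exception:
                zero_res = None
        if zero_res is None:
            notes.append("zero part did not converge")
    else:
        notes.append("no zero scores; zero part skipped")

    return MixtureFit(
        positive_result=full,
        zero_result=zero_res,
        wald_table=wald,
        formula="log_chaco ~ " + " + ".join(_TERMS) + " + (1|subject)",
        notes=tuple(notes),
        _data=pos,
    )


def arm_time_ratios(fit: MixtureFit, level: float = 0.95) -> dict[str, tuple[float, float, float]]:
    """Per-arm geometric T2/T1 disconnection ratios with confidence intervals.

    Marginal time contrasts on the log scale, averaged over ROIs, are
    exponentiated; the entry ``'interaction'`` is the ratio of ratios, i.e.
    the exponentiated time x treatment coefficient.
    """
    res = fit.positive_result
    names = res.model.exog_names
    k = len(names)
    rois = sorted(fit._data["roi"].unique())
    n_roi = len(rois)

    roi_time_cols = set(_term_columns(res, "time2:C(roi)"))

    def contrast(treated: int) -> np.ndarray:
        c = np.zeros(k)
        for i, name in enumerate(names):
            if name == "time2":
                c[i] = 1.0
            elif name == "time2:treated":
                c[i] = float(treated)
            elif i in roi_time_cols:
                c[i] = 1.0 / n_roi
        return c

    cov = np.asarray(res.cov_params())[:k, :k]
    fe = np.asarray(res.fe_params)
    z = stats.norm.ppf(0.5 + level / 2)
    out = {}
    for arm, treated in (("P", 0), ("A", 1)):
        c = contrast(treated)
        est = float(c @ fe)
        se = float(np.sqrt(c @ cov @ c))
        out[arm] = (np.exp(est), np.exp(est - z * se), np.exp(est + z * se))
    ci = np.zeros(k)
    ci[names.index("time2:treated")] = 1.0
    est = float(ci @ fe)
    se = float(np.sqrt(ci @ cov @ ci))
    out["interaction"] = (np.exp(est), np.exp(est - z * se), np.exp(est + z * se))
    return out


# ---------------------------------------------------------------------------
# Outcome regressions


@dataclass
class OutcomeFit:
    result: object
    table: pd.DataFrame  # term, or, ci_lo, ci_hi, p
    separation: bool = False


def outcome_logistic(
    df: pd.DataFrame,
    exposure: str = "treated",
    covariates: tuple[str, ...] = ("age", "nihss", "log_vol_T1"),
    outcome: str = "favorable",
    level: float = 0.95,
) -> OutcomeFit:
    """Adjusted logistic regression of favorable outcome.

    Returns odds ratios with profile-likelihood confidence intervals and Wald
    p-values for the exposure and covariates.  Complete separation raises
    :class:`SeparationError`.
    """
    data = df.dropna(subset=[outcome]).copy()
    if data[outcome].nunique() < 2:
        raise SeparationError("outcome is constant in the analysis sample")
    if "log_vol_T1" in covariates and "log_vol_T1" not in data.columns:
        data["log_vol_T1"] = np.log(data["vol_T1"])
    formula = f"{outcome} ~ {exposure} + " + " + ".join(covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.logit(formula, data=data).fit(disp=0, maxiter=200)
        except Exception as err:
            raise SeparationError(f"logistic fit failed: {err}") from err
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        raise SeparationError("logistic fit did not converge (possible separation)")
    rows = []
    for name in res.params.index:
        if name == "Intercept":
            continue
        lo, hi = profile_ci_logit(res, name, level=level)
        rows.append(
            {
                "term": name,
                "or": float(np.exp(res.params[name])),
                "ci_lo": float(np.exp(lo)),
                "ci_hi": float(np.exp(hi)),
                "p": float(res.pvalues[name]),
            }
        )
    return OutcomeFit(result=res, table=pd.DataFrame(rows))


def wald_table_to_frame(fit: MixtureFit) -> pd.DataFrame:
    """The type II Wald table in Table-1 row layout (term, chi2, dof, p)."""
    return fit.wald_table.copy()
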