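"""Counterfactual natural-effects mediation with multiple mediators.

Counterfactual outcome probabilities are estimated by inverse probability
weighting with ratio-of-mediator-probability weights built from two logistic
exposure models (with and without the mediators).  Natural direct, indirect
and total effects are reported on the odds-ratio scale with the identity
TE = NIE * NDE holding by construction; the proportion mediated is
log(NIE)/log(TE).

Inference is by subject-level bootstrap with bias-corrected percentile
intervals; multiple mediator models are compared on shared resamples, tested
jointly with a bootstrap step-down false-discovery-rate procedure, and
calibrated against a random-mediator-subset null distribution.

The indirect effect through the disconnection mediators alone (without
growth) is not statistically identified and is deliberately not exposed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import SeparationError, add_intercept, logit_irls, logit_predict

__all__ = [
    "CounterfactualProbs",
    "NaturalEffects",
    "BootstrapReplicates",
    "StepdownResult",
    "SubsetNullResult",
    "NonOverlapError",
    "counterfactual_probabilities",
    "natural_effects",
    "estimate_natural_effects",
    "estimate_models",
    "bootstrap_effects",
    "bc_interval",
    "nie_ratio",
    "stepdown_fdr",
    "random_subset_null",
]


class NonOverlapError(RuntimeError):
    """Fitted exposure probabilities below the overlap floor."""


@dataclass(frozen=True)
class CounterfactualProbs:
    """Expected favorable-outcome probabilities for the three regimes:
    treated with treated-level mediators, treated with placebo-level
    mediators, and placebo with placebo-level mediators."""

    p_t_m_t: float
    p_t_m_p: float
    p_p_m_p: float

    def __post_init__(self) -> None:
        for v in (self.p_t_m_t, self.p_t_m_p, self.p_p_m_p):
            if not 0.0 < v < 1.0:
                raise ValueError(f"counterfactual probability {v} outside (0, 1)")


@dataclass(frozen=True)
class NaturalEffects:
    """Odds-ratio-scale natural effects; ``proportion_mediated`` is NaN when
    the total effect is exactly null (flagged via ``pm_defined``)."""

    nde: float
    nie: float
    te: float
    proportion_mediated: float

    @property
    def pm_defined(self) -> bool:
        return not math.isnan(self.proportion_mediated)


def _odds(p: float) -> float:
    return p / (1.0 - p)


def natural_effects(probs: CounterfactualProbs) -> NaturalEffects:
    """Natural effects from counterfactual probabilities (odds-ratio scale)."""
    nde = _odds(probs.p_t_m_p) / _odds(probs.p_p_m_p)
    nie = _odds(probs.p_t_m_t) / _odds(probs.p_t_m_p)
    te = nie * nde
    if te == 1.0:
        pm = math.nan
    else:
        pm = math.log(nie) / math.log(te)
    return NaturalEffects(nde=nde, nie=nie, te=te, proportion_mediated=pm)


def _truncate(w: np.ndarray, quantiles: tuple[float, float] | None) -> np.ndarray:
    if quantiles is None or len(w) < 3:
        return w
    lo, hi = np.quantile(w, quantiles)
    return np.clip(w, lo, hi)


def _weighted_mean(y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.mean()  # normalize to mean 1 within the arm
    return float(np.sum(w * y) / np.sum(w))


def _cf_probs_arrays(
    a: np.ndarray,
    y: np.ndarray,
    cmat: np.ndarray,
    mmat: np.ndarray,
    truncate_q: tuple[float, float] | None,
    overlap_floor: float,
    base_beta: np.ndarray | None = None,
) -> CounterfactualProbs:
    xc = add_intercept(cmat)
    beta_c = logit_irls(xc, a) if base_beta is None else base_beta
    p1_c = logit_predict(xc, beta_c)
    if np.any(p1_c < overlap_floor) or np.any(p1_c > 1 - overlap_floor):
        bad = np.where((p1_c < overlap_floor) | (p1_c > 1 - overlap_floor))[0]
        raise NonOverlapError(f"exposure probabilities outside overlap floor for rows {bad[:10].tolist()}")
    treated = a == 1
    placebo = ~treated

    w_t = _truncate(1.0 / p1_c[treated], truncate_q)
    p_t_m_t = _weighted_mean(y[treated], w_t)
    w_p = _truncate(1.0 / (1.0 - p1_c[placebo]), truncate_q)
    p_p_m_p = _weighted_mean(y[placebo], w_p)

    xm = add_intercept(np.c_[mmat, cmat])
    beta_m = logit_irls(xm, a)
    p1_mc = logit_predict(xm, beta_m)
    ratio = (1.0 - p1_mc[treated]) / p1_mc[treated]
    w_cross = _truncate(ratio / (1.0 - p1_c[treated]), truncate_q)
    p_t_m_p = _weighted_mean(y[treated], w_cross)

    eps = 1e-12
    clip = lambda p: min(max(p, eps), 1 - eps)
    return CounterfactualProbs(
        p_t_m_t=clip(p_t_m_t), p_t_m_p=clip(p_t_m_p), p_p_m_p=clip(p_p_m_p)
    )


def _analysis_arrays(df, mediators, covariates, exposure, outcome):
    sub = df.dropna(subset=[outcome])
    a = sub[exposure].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    cmat = sub[list(covariates)].to_numpy(dtype=float)
    mmat = sub[list(mediators)].to_numpy(dtype=float) if mediators else np.empty((len(sub), 0))
    return a, y, cmat, mmat


def counterfactual_probabilities(
    df: pd.DataFrame,
    mediators: list[str],
    covariates: list[str],
    exposure: str = "treated",
    outcome: str = "favorable",
    truncate_q: tuple[float, float] | None = (0.01, 0.99),
    overlap_floor: float = 1e-6,
) -> CounterfactualProbs:
    """IPW estimates of the three counterfactual probabilities.

    Subjects with missing outcome are excluded.  Exposure models are simple
    logistic regressions A ~ C and A ~ M + C; mediators enter linearly.
    Weights are truncated at ``truncate_q`` quantiles (None disables) and
    normalized to mean 1 within arm.
    """
    a, y, cmat, mmat = _analysis_arrays(df, mediators, covariates, exposure, outcome)
    return _cf_probs_arrays(a, y, cmat, mmat, truncate_q, overlap_floor)


def estimate_natural_effects(
    df: pd.DataFrame,
    mediators: list[str],
    covariates: list[str],
    **kwargs,
) -> NaturalEffects:
    return natural_effects(counterfactual_probabilities(df, mediators, covariates, **kwargs))


def estimate_models(
    df: pd.DataFrame,
    specs: dict[str, list[str]],
    covariates: list[str],
    exposure: str = "treated",
    outcome: str = "favorable",
    truncate_q: tuple[float, float] | None = (0.01, 0.99),
    overlap_floor: float = 1e-6,
) -> dict[str, NaturalEffects]:
    """Estimate several mediator sets on the same data, sharing the baseline
    exposure model A ~ C across specs."""
    sub = df.dropna(subset=[outcome])
    a = sub[exposure].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    cmat = sub[list(covariates)].to_numpy(dtype=float)
    base_beta = logit_irls(add_intercept(cmat), a)
    out = {}
    for name, meds in specs.items():
        mmat = sub[list(meds)].to_numpy(dtype=float) if meds else np.empty((len(sub), 0))
        probs = _cf_probs_arrays(a, y, cmat, mmat, truncate_q, overlap_floor, base_beta=base_beta)
        out[name] = natural_effects(probs)
    return out


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapReplicates:
    """Replicate natural effects, models x k, on shared resamples."""

    estimates: dict[str, NaturalEffects]
    frames: dict[str, pd.DataFrame]  # per model: columns nde, nie, te, pm
    seed: int
    k: int
    n_redrawn: int = 0
    indices: np.ndarray | None = field(default=None, repr=False)

    def matrix(self, quantity: str = "nie") -> pd.DataFrame:
        return pd.DataFrame({name: fr[quantity].to_numpy() for name, fr in self.frames.items()})

    def model_names(self) -> list[str]:
        return list(self.frames)


def bootstrap_effects(
    df: pd.DataFrame,
    specs: dict[str, list[str]],
    covariates: list[str],
    k: int = 10_000,
    seed: int = 0,
    exposure: str = "treated",
    outcome: str = "favorable",
    truncate_q: tuple[float, float] | None = (0.01, 0.99),
    store_indices: bool = False,
    max_attempts_factor: int = 10,
) -> BootstrapReplicates:
    """Subject-level bootstrap; every spec is estimated on the same resample
    within each replicate so joint distributions are preserved.

    Degenerate resamples (a single arm, a constant outcome, or a separated
    exposure fit) are redrawn and counted.
    """
    if k < 100:
        raise ValueError("k must be >= 100")
    sub = df.dropna(subset=[outcome]).reset_index(drop=True)
    n = len(sub)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    estimates = estimate_models(
        sub, specs, covariates, exposure=exposure, outcome=outcome, truncate_q=truncate_q
    )
    names = list(specs)
    a_full = sub[exposure].to_numpy(dtype=float)
    y_full = sub[outcome].to_numpy(dtype=float)
    c_full = sub[list(covariates)].to_numpy(dtype=float)
    m_full = {
        name: (
            sub[list(meds)].to_numpy(dtype=float) if meds else np.empty((n, 0))
        )
        for name, meds in specs.items()
    }
    out = {name: np.full((k, 4), np.nan) for name in names}
    idx_store = np.zeros((k, n), dtype=np.int32) if store_indices else None
    n_redrawn = 0
    max_attempts = max_attempts_factor * k
    attempts = 0
    filled = 0
    while filled < k:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(n, size=n)
        a = a_full[idx]
        y = y_full[idx]
        if a.min() == a.max() or y.min() == y.max():
            n_redrawn += 1
            continue
        cmat = c_full[idx]
        try:
            base_beta = logit_irls(add_intercept(cmat), a)
            for name in names:
                probs = _cf_probs_arrays(
                    a, y, cmat, m_full[name][idx], truncate_q, 1e-6, base_beta=base_beta
                )
                e = natural_effects(probs)
                out[name][filled] = (e.nde, e.nie, e.te, e.proportion_mediated)
        except (SeparationError, NonOverlapError):
            n_redrawn += 1
            continue
        if idx_store is not None:
            idx_store[filled] = idx
        filled += 1
    frames = {
        name: pd.DataFrame(out[name], columns=["nde", "nie", "te", "pm"]) for name in names
    }
    return BootstrapReplicates(
        estimates=estimates,
        frames=frames,
        seed=seed,
        k=k,
        n_redrawn=n_redrawn,
        indices=idx_store,
    )


def bc_interval(
    replicates: np.ndarray,
    point_estimate: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected percentile interval (no acceleration term).

    z0 is clamped when the estimate falls outside the replicate range (a
    warning is emitted) and degenerate replicate sets yield a degenerate,
    flagged interval.
    """
    reps = np.asarray(replicates, dtype=float)
    reps = reps[~np.isnan(reps)]
    if len(reps) < 100:
        raise ValueError("need at least 100 replicates")
    if reps.min() == reps.max():
        warnings.warn("all bootstrap replicates identical; degenerate interval")
        return float(reps[0]), float(reps[0])
    frac = np.mean(reps < point_estimate)
    kk = len(reps)
    if frac <= 0.0 or frac >= 1.0:
        warnings.warn("point estimate outside replicate range; clamping bias correction")
        frac = min(max(frac, 1.0 / (kk + 1)), kk / (kk + 1.0))
    z0 = stats.norm.ppf(frac)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    alpha_lo = stats.norm.cdf(2 * z0 - zq)
    alpha_hi = stats.norm.cdf(2 * z0 + zq)
    lo, hi = np.quantile(reps, [alpha_lo, alpha_hi])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RatioResult:
    point: float
    ci: tuple[float, float]

    @property
    def significant_excess(self) -> bool:
        return self.ci[0] > 1.0 or self.ci[1] < 1.0


def nie_ratio(
    replicates: BootstrapReplicates,
    joint_name: str,
    growth_name: str,
    level: float = 0.95,
) -> RatioResult:
    """Ratio of the joint-model NIE to the growth-only NIE with a BC CI."""
    for name in (joint_name, growth_name):
        if name not in replicates.frames:
            raise KeyError(f"model {name!r} not present in replicate set")
    point = replicates.estimates[joint_name].nie / replicates.estimates[growth_name].nie
    reps = (
        replicates.frames[joint_name]["nie"].to_numpy()
        / replicates.frames[growth_name]["nie"].to_numpy()
    )
    return RatioResult(point=float(point), ci=bc_interval(reps, point, level))


# ---------------------------------------------------------------------------
# Step-down FDR


@dataclass
class StepdownResult:
    names: list[str]  # ordered by decreasing empirical NIE
    estimates: np.ndarray  # NIE scale, same order
    thresholds: np.ndarray  # NIE scale (median of outer bootstrap draws)
    threshold_lo: np.ndarray
    threshold_hi: np.ndarray
    rejected: np.ndarray  # bool, same order
    q: float

    def rejected_models(self) -> list[str]:
        return [n for n, r in zip(self.names, self.rejected) if r]


def _stepdown_thresholds(z: np.ndarray, q: float) -> np.ndarray:
    """Threshold sequence on the centered log-NIE scale.

    ``z`` is (k, m) of centered joint null draws.  At step s the threshold is
    the smallest c such that the estimated false-discovery proportion
    E[min(#{j: z_j >= c}, s)] / s is at most q, using the identity
    E[min(N(c), s)] = sum_{j<=s} P(z_(j) >= c) over order statistics.
    """
    k, m = z.shape
    row_sorted = -np.sort(-z, axis=1)  # descending per replicate
    thresholds = np.empty(m)
    prev = np.inf
    for s in range(1, m + 1):
        cols = row_sorted[:, :s]  # j-th order statistic in column j-1
        candidates = np.unique(cols)

        def fdp(c: float) -> float:
            return float(np.sum(cols >= c)) / (s * k)  # == (1/s) sum_j surv_j(c)

        # fdp is non-increasing in c; binary search for smallest c with fdp <= q
        lo_i, hi_i = 0, len(candidates) - 1
        if fdp(candidates[lo_i]) <= q:
            c = candidates[lo_i]
        elif fdp(candidates[hi_i]) > q:
            c = math.inf  # cannot control at q: never reject at this step
        else:
            while hi_i - lo_i > 1:
                mid = (lo_i + hi_i) // 2
                if fdp(candidates[mid]) <= q:
                    hi_i = mid
                else:
                    lo_i = mid
            c = candidates[hi_i]
        c = min(c, prev)
        thresholds[s - 1] = c
        prev = c
    return thresholds


def stepdown_fdr(
    replicates: BootstrapReplicates,
    q: float = 0.05,
    n_outer: int = 100,
    outer_seed: int = 1,
    level: float = 0.95,
) -> StepdownResult:
    """Bootstrap step-down procedure controlling the FDR over mediation models.

    Models are ordered by decreasing empirical NIE; centered joint bootstrap
    draws of log NIE form the null.  Null hypotheses are rejected
    sequentially while the empirical NIE exceeds its step threshold.
    Threshold uncertainty comes from re-bootstrapping the replicate set
    (``n_outer`` outer draws); the decision line is the outer median.
    """
    names = replicates.model_names()
    est = np.array([replicates.estimates[n].nie for n in names])
    order = np.argsort(-est)
    names_ord = [names[i] for i in order]
    est_ord = est[order]
    log_reps = np.log(replicates.matrix("nie").to_numpy()[:, order])
    z = log_reps - np.log(est_ord)[None, :]

    rng = np.random.default_rng(np.random.SeedSequence([outer_seed, 0xFD5]))
    k = z.shape[0]
    draws = np.empty((n_outer, len(names)))
    for b in range(n_outer):
        draws[b] = _stepdown_thresholds(z[rng.integers(k, size=k)], q)
    thr_log = np.median(draws, axis=0)
    alpha = (1 - level) / 2
    thr_lo = np.quantile(draws, alpha, axis=0)
    thr_hi = np.quantile(draws, 1 - alpha, axis=0)

    log_est = np.log(est_ord)
    rejected = np.zeros(len(names), dtype=bool)
    for s in range(len(names)):
        if log_est[s] > thr_log[s]:
            rejected[s] = True
        else:
            break
    return StepdownResult(
        names=names_ord,
        estimates=est_ord,
        thresholds=np.exp(thr_log),
        threshold_lo=np.exp(thr_lo),
        threshold_hi=np.exp(thr_hi),
        rejected=rejected,
        q=q,
    )


# ---------------------------------------------------------------------------
# Random-subset null


@dataclass
class SubsetNullResult:
    nies: np.ndarray
    subsets: list[tuple[str, ...]]
    n_failed: int

    def percentile(self, observed_nie: float) -> float:
        """Percentile (0-100) of an observed NIE within the null distribution."""
        return float(100.0 * np.mean(self.nies <= observed_nie))


def random_subset_null(
    df: pd.DataFrame,
    region_pool: list[str],
    growth_col: str,
    covariates: list[str],
    k: int = 10_000,
    size_law=None,
    seed: int = 0,
    exposure: str = "treated",
    outcome: str = "favorable",
    truncate_q: tuple[float, float] | None = (0.01, 0.99),
) -> SubsetNullResult:
    """Null NIE distribution from uniformly sampled mediator region sets.

    Each draw samples a subset size from ``size_law`` (default: uniform on
    1..4, capped at the pool size), picks that many regions uniformly, and
    estimates the joint NIE with growth included.  Failed estimations are
    redrawn and counted.
    """
    if not region_pool:
        raise ValueError("region pool must not be empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E7]))
    max_size = min(4, len(region_pool))
    if size_law is None:
        size_law = lambda r: int(r.integers(1, max_size + 1))
    sub = df.dropna(subset=[outcome]).reset_index(drop=True)
    a = sub[exposure].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    cmat = sub[list(covariates)].to_numpy(dtype=float)
    growth = sub[[growth_col]].to_numpy(dtype=float)
    regions = {r: sub[r].to_numpy(dtype=float) for r in region_pool}
    base_beta = logit_irls(add_intercept(cmat), a)
    nies = np.empty(k)
    subsets: list[tuple[str, ...]] = []
    n_failed = 0
    filled = 0
    attempts = 0
    while filled < k:
        attempts += 1
        if attempts > 10 * k + 100:
            raise RuntimeError("too many failed subset-null draws")
        size = size_law(rng)
        pick = tuple(sorted(rng.choice(region_pool, size=size, replace=False).tolist()))
        mmat = np.c_[growth, *(regions[r] for r in pick)]
        try:
            probs = _cf_probs_arrays(
                a, y, cmat, mmat, truncate_q, 1e-6, base_beta=base_beta
            )
        except (SeparationError, NonOverlapError):
            n_failed += 1
            continue
        nies[filled] = natural_effects(probs).nie
        subsets.append(pick)
        filled += 1
    return SubsetNullResult(nies=nies, subsets=subsets, n_failed=n_failed)
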