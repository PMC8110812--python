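"""Synthetic trial cohort with a fully specified causal model.

Generates block parcellations, reference tractograms, lesioned patients whose
lesions grow (or shrink) between two time points with treatment-attenuated
growth, per-region disconnection changes, and a binary favorable outcome
driven by treatment, growth, covariates and disconnection in designated
"eloquent" regions.  A Monte-Carlo oracle computes the true natural effects
of the generator by brute-force counterfactual simulation.

Two disconnection routes are provided:

* ``mechanical`` — lesions are grown as connected voxel sets and scored
  against generated reference tractograms (exercises the full pipeline);
* ``surrogate`` — per-region disconnection change is drawn from the linear
  law ``delta_r = g0 + gG * growth + gA * treated + noise`` (fast; used for
  large-sample statistical validation, with the identical outcome model).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import chaco as _chaco
from ._stats import expit
from .mediation import CounterfactualProbs, NaturalEffects, natural_effects

__all__ = [
    "CovariateParams",
    "OutcomeCoefs",
    "SurrogateChacoParams",
    "GenerativeParams",
    "PatientRecord",
    "Cohort",
    "SizingError",
    "GenerationError",
    "SpecificationError",
    "make_parcellation",
    "make_reference_tractograms",
    "simulate_patient",
    "simulate_outcome",
    "generate_cohort",
    "oracle_natural_effects",
    "write_cohort_csv",
    "write_params_yaml",
    "load_params_yaml",
]


class SizingError(ValueError):
    """Grid too small for the requested parcellation."""


class GenerationError(RuntimeError):
    """Tractogram generation produced an invalid reference subject."""


class SpecificationError(ValueError):
    """Outcome model references a disconnection value that was not supplied."""


@dataclass(frozen=True)
class CovariateParams:
    age_mean: float = 65.5
    age_sd: float = 11.0
    nihss_shape: float = 2.0
    nihss_scale: float = 3.5


@dataclass(frozen=True)
class OutcomeCoefs:
    """Coefficients of the favorable-outcome logistic model."""

    intercept: float = 2.2
    treatment: float = 0.25
    growth: float = -0.35  # per log2 unit of vol_T2/vol_T1
    region_effects: tuple[float, ...] = (-4.0, -3.0, -2.0)  # per unit delta-ChaCo
    age: float = -0.02
    nihss: float = -0.08
    log_volume: float = -0.2


@dataclass(frozen=True)
class SurrogateChacoParams:
    """Linear law for surrogate per-region disconnection change."""

    gamma0: float = 0.02
    gamma_growth: float = 0.02
    gamma_arm: float = 0.0
    gamma_arm_eloquent: float = -0.01
    noise_sd: float = 0.01


@dataclass(frozen=True)
class GenerativeParams:
    grid_shape: tuple[int, int, int] = (24, 12, 12)
    voxel_size_mm: float = 4.0
    n_regions_per_hemisphere: int = 8
    n_reference_subjects: int = 3
    streamlines_per_region_pair: int = 4
    arm_growth_log2_mean: tuple[float, float] = (0.85, 0.30)  # (placebo, alteplase)
    growth_log2_sd: float = 1.25
    baseline_volume_lognormal: tuple[float, float] = (math.log(3.0), 1.0)  # ml
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    eloquent_region_indices: tuple[int, ...] = (1, 2, 3)
    surrogate: SurrogateChacoParams = field(default_factory=SurrogateChacoParams)
    tract_jitter: float = 0.3
    self_pair_rate: float = 1.0
    p_left_hemisphere: float = 0.5
    max_shrink_fraction: float = 1.0
    exposure_confounding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        mu_p, mu_a = self.arm_growth_log2_mean
        if mu_a > mu_p:
            raise ValueError("treatment-attenuated growth requires mu_A <= mu_P")
        if self.growth_log2_sd < 0:
            raise ValueError("growth sd must be >= 0")
        if len(self.eloquent_region_indices) != len(self.outcome_coefs.region_effects):
            raise ValueError("eloquent_region_indices must match region_effects length")
        if any(i >= self.n_regions_per_hemisphere for i in self.eloquent_region_indices):
            raise ValueError("eloquent region index outside hemisphere region range")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def params_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PatientRecord:
    id: str
    arm: str  # 'P' or 'A'
    age: float
    nihss: int
    vol_T1: float
    vol_T2: float
    hemisphere: str
    lesion_T1: _chaco.LesionMask | None = None
    lesion_T2: _chaco.LesionMask | None = None
    favorable: float = math.nan
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.arm not in ("P", "A"):
            raise ValueError("arm must be 'P' or 'A'")
        if self.vol_T1 <= 0:
            raise ValueError("vol_T1 must be positive")

    @property
    def log2_growth(self) -> float:
        return math.log2(self.vol_T2 / self.vol_T1)


@dataclass
class Cohort:
    patients: list[PatientRecord]
    parcellation_id: str
    seed: int
    params_hash: str
    delta_chaco: pd.DataFrame  # indexed by patient id; columns dchaco_XX
    parcellation: _chaco.Parcellation | None = None
    reference_set: _chaco.ReferenceSet | None = None
    chaco_long: pd.DataFrame | None = None  # mechanical mode only

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        arms = {p.arm for p in self.patients}
        if arms != {"P", "A"}:
            raise ValueError("both arms must be represented")

    @property
    def frame(self) -> pd.DataFrame:
        """Analysis table: covariates, volumes, outcome, disconnection change."""
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "id": p.id,
                    "arm": p.arm,
                    "treated": int(p.arm == "A"),
                    "age": p.age,
                    "nihss": p.nihss,
                    "vol_T1": p.vol_T1,
                    "vol_T2": p.vol_T2,
                    "log2_growth": p.log2_growth,
                    "favorable": p.favorable,
                }
            )
        df = pd.DataFrame(rows).set_index("id")
        return df.join(self.delta_chaco)


# ---------------------------------------------------------------------------
# Parcellation


def make_parcellation(params: GenerativeParams) -> _chaco.Parcellation:
    """Split the grid into two hemisphere slabs with a background midline,
    then partition each slab into raster-order blocks of near-equal size."""
    nx, ny, nz = params.grid_shape
    n = params.n_regions_per_hemisphere
    hx = (nx - 1) // 2  # left slab width; >=1 background plane remains
    if hx < 1 or hx * ny * nz < n:
        raise SizingError(
            f"grid {params.grid_shape} cannot hold 2x{n} non-empty hemisphere blocks"
        )
    labels = np.zeros(params.grid_shape, dtype=np.int32)
    rows = []
    lobes = ("frontal", "parietal", "temporal", "occipital", "limbic", "subcortical")
    next_label = 1
    for hemi, x_lo in (("L", 0), ("R", nx - hx)):
        vox = np.argwhere(np.zeros((hx, ny, nz)) == 0)
        vox[:, 0] += x_lo
        chunks = np.array_split(np.arange(len(vox)), n)
        for i, chunk in enumerate(chunks):
            sel = vox[chunk]
            labels[sel[:, 0], sel[:, 1], sel[:, 2]] = next_label
            rows.append(
                {
                    "name": f"{hemi}_{i:02d}",
                    "hemisphere": hemi,
                    "lobe": lobes[i % len(lobes)],
                    "within_index": i,
                }
            )
            next_label += 1
    regions = pd.DataFrame(rows, index=np.arange(1, next_label))
    return _chaco.Parcellation(labels=labels, regions=regions, voxel_size_mm=params.voxel_size_mm)


# ---------------------------------------------------------------------------
# Reference tractograms


def _segment_walk(a: tuple, b: tuple) -> list[tuple]:
    """Axis-ordered 6-connected walk from a to b (inclusive)."""
    path = [tuple(a)]
    cur = list(a)
    for ax in range(3):
        step = 1 if b[ax] > cur[ax] else -1
        while cur[ax] != b[ax]:
            cur[ax] += step
            path.append(tuple(cur))
    return path


def _region_anchor(voxels: np.ndarray) -> tuple:
    return tuple(voxels[len(voxels) // 2])


def make_reference_tractograms(
    parcellation: _chaco.Parcellation,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
) -> _chaco.ReferenceSet:
    """Generate per-subject streamline sets for every within-hemisphere region
    pair (self-pairs included at ``self_pair_rate``), with per-subject jitter.

    With ``tract_jitter == 0`` all subjects are identical (deterministic
    anchor endpoints, straight axis-ordered paths)."""
    if params.n_reference_subjects < 1:
        raise ValueError("need at least one reference subject")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    region_voxels = {
        int(r): np.argwhere(parcellation.labels == r) for r in parcellation.region_ids
    }
    hemi_voxels = {}
    for hemi in ("L", "R"):
        ids = parcellation.regions_in_hemisphere(hemi)
        hemi_voxels[hemi] = np.vstack([region_voxels[int(r)] for r in ids])
    jitter = params.tract_jitter
    tractograms = []
    for subj in range(params.n_reference_subjects):
        streamlines: list[np.ndarray] = []
        for hemi in ("L", "R"):
            ids = sorted(int(r) for r in parcellation.regions_in_hemisphere(hemi))
            for i, r in enumerate(ids):
                for s in ids[i:]:
                    if r == s and rng.random() >= params.self_pair_rate:
                        continue
                    for _ in range(params.streamlines_per_region_pair):
                        streamlines.append(
                            _make_streamline(
                                region_voxels[r], region_voxels[s], hemi_voxels[hemi], jitter, rng
                            )
                        )
        tg = _chaco.assign_endpoints(
            _chaco.Tractogram(subject_id=f"ref_{subj:02d}", streamlines=streamlines),
            parcellation,
        )
        if np.any(tg.totals[1:] == 0):
            missing = np.where(tg.totals[1:] == 0)[0] + 1
            raise GenerationError(f"regions with zero streamlines: {missing.tolist()}")
        tractograms.append(tg)
    return _chaco.ReferenceSet(tractograms=tractograms)


def _make_streamline(
    vox_a: np.ndarray,
    vox_b: np.ndarray,
    hemi_vox: np.ndarray,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if jitter > 0:
        a = tuple(vox_a[rng.integers(len(vox_a))])
        b = tuple(vox_b[rng.integers(len(vox_b))])
    else:
        a = _region_anchor(vox_a)
        b = _region_anchor(vox_b)
        if a == b and len(vox_b) > 1:
            b = tuple(vox_b[len(vox_b) // 2 + 1])
    if jitter > 0 and rng.random() < jitter:
        w = tuple(hemi_vox[rng.integers(len(hemi_vox))])
        path = _segment_walk(a, w)[:-1] + _segment_walk(w, b)
    else:
        path = _segment_walk(a, b)
    arr = np.asarray(path, dtype=np.int64)
    keep = np.ones(len(arr), dtype=bool)
    if len(arr) > 1:
        keep[1:] = np.any(arr[1:] != arr[:-1], axis=1)
    arr = arr[keep]
    if len(arr) < 2:  # degenerate self-pair in a one-voxel region: bounce out and back
        nb = list(a)
        nb[0] += 1 if a[0] + 1 < hemi_vox[:, 0].max() + 1 else -1
        arr = np.asarray([a, tuple(nb), a], dtype=np.int64)
    return arr


# ---------------------------------------------------------------------------
# Lesions

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_connected(
    allowed: np.ndarray,
    start: tuple[int, int, int],
    target: int,
    rng: np.random.Generator,
    lesion: np.ndarray | None = None,
) -> np.ndarray:
    """Grow a 6-connected voxel set inside ``allowed`` by random boundary
    acceptance until ``target`` voxels (or the component is exhausted)."""
    shape = allowed.shape
    if lesion is None:
        lesion = np.zeros(shape, dtype=bool)
        lesion[start] = True
    else:
        lesion = lesion.copy()
    frontier: set[tuple] = set()

    def push_neighbors(v: tuple) -> None:
        for off in _NEIGHBOR_OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and allowed[w]
                and not lesion[w]
            ):
                frontier.add(w)

    for v in map(tuple, np.argwhere(lesion)):
        push_neighbors(v)
    count = int(lesion.sum())
    while count < target and frontier:
        cand = list(frontier)
        pick = cand[rng.integers(len(cand))]
        frontier.discard(pick)
        lesion[pick] = True
        count += 1
        push_neighbors(pick)
    return lesion


def _erode(lesion: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Remove random boundary voxels until ``target`` voxels remain (>=1)."""
    lesion = lesion.copy()
    shape = lesion.shape
    target = max(1, target)
    while lesion.sum() > target:
        vox = np.argwhere(lesion)
        boundary = []
        for v in vox:
            for off in _NEIGHBOR_OFFSETS:
                w = v + off
                if (
                    np.any(w < 0)
                    or np.any(w >= shape)
                    or not lesion[tuple(w)]
                ):
                    boundary.append(tuple(v))
                    break
        pick = boundary[rng.integers(len(boundary))]
        lesion[pick] = False
    return lesion


def simulate_patient(
    parcellation: _chaco.Parcellation,
    arm: str,
    params: GenerativeParams,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> PatientRecord:
    """Draw covariates and grow a two-time-point lesion for one patient."""
    if arm not in ("P", "A"):
        raise ValueError("arm must be 'P' or 'A'")
    cov = params.covariate_params
    age = cov.age_mean + cov.age_sd * rng.standard_normal()
    nihss = int(round(rng.gamma(cov.nihss_shape, cov.nihss_scale)))
    hemi = "L" if rng.random() < params.p_left_hemisphere else "R"
    allowed = np.isin(parcellation.labels, parcellation.regions_in_hemisphere(hemi))
    capacity = int(allowed.sum())
    warnings: list[str] = []

    meanlog, sdlog = params.baseline_volume_lognormal
    v1_ml = float(np.exp(meanlog + sdlog * rng.standard_normal()))
    n1 = max(1, round(v1_ml / params.voxel_volume_ml))
    if n1 > capacity:
        n1 = capacity
        warnings.append("baseline volume clipped to hemisphere capacity")

    start_idx = np.argwhere(allowed)
    start = tuple(start_idx[rng.integers(len(start_idx))])
    t1 = _grow_connected(allowed, start, n1, rng)

    mu = params.arm_growth_log2_mean[0 if arm == "P" else 1]
    g = mu if params.growth_log2_sd == 0 else mu + params.growth_log2_sd * rng.standard_normal()
    n2 = max(1, round(n1 * 2.0**g))
    n2 = max(n2, math.ceil(n1 * (1.0 - params.max_shrink_fraction)))
    if n2 > capacity:
        n2 = capacity
        warnings.append("follow-up volume clipped to hemisphere capacity")
    if n2 >= n1:
        t2 = _grow_connected(allowed, start, n2, rng, lesion=t1)
    else:
        t2 = _erode(t1, n2, rng)

    vv = params.voxel_volume_ml
    return PatientRecord(
        id=patient_id,
        arm=arm,
        age=age,
        nihss=nihss,
        vol_T1=int(t1.sum()) * vv,
        vol_T2=int(t2.sum()) * vv,
        hemisphere=hemi,
        lesion_T1=_chaco.LesionMask(t1.astype(np.uint8), params.voxel_size_mm),
        lesion_T2=_chaco.LesionMask(t2.astype(np.uint8), params.voxel_size_mm),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Outcome


def outcome_probability(
    patient: PatientRecord,
    chaco_change_profile,
    params: GenerativeParams,
) -> float:
    """P(favorable) under the generating logistic model.

    ``chaco_change_profile`` maps within-hemisphere region index -> delta
    ChaCo; a missing region with a non-zero effect is a specification error.
    """
    b = params.outcome_coefs
    lin = (
        b.intercept
        + b.treatment * (patient.arm == "A")
        + b.growth * patient.log2_growth
        + b.age * patient.age
        + b.nihss * patient.nihss
        + b.log_volume * math.log(patient.vol_T1)
    )
    for idx, beta_r in zip(params.eloquent_region_indices, b.region_effects):
        if idx not in chaco_change_profile:
            if beta_r != 0:
                raise SpecificationError(f"delta ChaCo missing for region index {idx}")
            continue
        lin += beta_r * float(chaco_change_profile[idx])
    return float(expit(np.asarray(lin)))


def simulate_outcome(
    patient: PatientRecord,
    chaco_change_profile,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> int:
    """Draw the binary favorable outcome (mRS 0-1 analogue)."""
    return int(rng.random() < outcome_probability(patient, chaco_change_profile, params))


# ---------------------------------------------------------------------------
# Cohort generation


def _assign_arms(n: int, rng: np.random.Generator, forced_balance: bool) -> np.ndarray:
    if forced_balance:
        arms = np.array(["P", "A"]).repeat([n - n // 2, n // 2])
        return rng.permutation(arms)
    return np.where(rng.random(n) < 0.5, "P", "A")


def _surrogate_deltas(
    treated: np.ndarray,
    growth: np.ndarray,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, R) surrogate delta-ChaCo draws, R = regions per hemisphere."""
    s = params.surrogate
    n = len(treated)
    nr = params.n_regions_per_hemisphere
    gamma_arm = np.full(nr, s.gamma_arm)
    gamma_arm[list(params.eloquent_region_indices)] += s.gamma_arm_eloquent
    noise = s.noise_sd * rng.standard_normal((n, nr))
    return (
        s.gamma0
        + s.gamma_growth * growth[:, None]
        + treated[:, None] * gamma_arm[None, :]
        + noise
    )


def delta_columns(params: GenerativeParams) -> list[str]:
    return [f"dchaco_{i:02d}" for i in range(params.n_regions_per_hemisphere)]


def generate_cohort(
    params: GenerativeParams,
    n: int,
    seed: int,
    mode: str = "surrogate",
    missing_fraction: float = 0.0,
    forced_balance: bool = True,
) -> Cohort:
    """Generate a full cohort, reproducible from (params, seed).

    ``missing_fraction`` removes the outcome for ``round(missing_fraction*n)``
    patients (chosen at random), emulating missing 90-day endpoints.
    """
    if n < 2:
        raise ValueError("need at least 2 patients")
    if mode not in ("surrogate", "mechanical"):
        raise ValueError("mode must be 'surrogate' or 'mechanical'")
    ss = np.random.SeedSequence([seed, params.seed])
    rng = np.random.default_rng(ss)
    arms = _assign_arms(n, rng, forced_balance)
    cols = delta_columns(params)
    parcellation = None
    reference_set = None

    chaco_long = None
    if mode == "mechanical":
        parcellation = make_parcellation(params)
        reference_set = make_reference_tractograms(
            parcellation, params, np.random.default_rng(ss.spawn(1)[0])
        )
        patients, deltas, chaco_long = _mechanical_patients(
            parcellation, reference_set, arms, params, rng
        )
    else:
        patients, deltas = _surrogate_patients(arms, params, rng)

    if params.exposure_confounding != 0.0:
        # covariate-dependent exposure overrides randomization (for IPW tests)
        cov = params.covariate_params
        for p in patients:
            z = (cov.age_mean - p.age) / cov.age_sd
            p_treat = expit(np.asarray(params.exposure_confounding * z))
            p.arm = "A" if rng.random() < p_treat else "P"

    delta_chaco = pd.DataFrame(deltas, index=[p.id for p in patients], columns=cols)
    delta_chaco.index.name = "id"

    # outcomes
    for p, drow in zip(patients, deltas):
        profile = {i: drow[i] for i in range(len(drow))}
        p.favorable = float(simulate_outcome(p, profile, params, rng))
    n_missing = round(missing_fraction * n)
    if n_missing:
        for i in rng.choice(n, size=n_missing, replace=False):
            patients[i].favorable = math.nan

    return Cohort(
        patients=patients,
        parcellation_id=f"synthetic-{params.n_regions_per_hemisphere}x2",
        seed=seed,
        params_hash=params.params_hash(),
        delta_chaco=delta_chaco,
        parcellation=parcellation,
        reference_set=reference_set,
        chaco_long=chaco_long,
    )


def _surrogate_patients(arms, params, rng):
    n = len(arms)
    cov = params.covariate_params
    age = cov.age_mean + cov.age_sd * rng.standard_normal(n)
    nihss = np.round(rng.gamma(cov.nihss_shape, cov.nihss_scale, size=n)).astype(int)
    meanlog, sdlog = params.baseline_volume_lognormal
    v1 = np.exp(meanlog + sdlog * rng.standard_normal(n))
    mu = np.where(arms == "P", *params.arm_growth_log2_mean)
    g = mu + params.growth_log2_sd * rng.standard_normal(n)
    v2 = v1 * 2.0**g
    treated = (arms == "A").astype(float)
    deltas = _surrogate_deltas(treated, g, params, rng)
    hemis = np.where(rng.random(n) < params.p_left_hemisphere, "L", "R")
    patients = [
        PatientRecord(
            id=f"s{i:05d}",
            arm=str(arms[i]),
            age=float(age[i]),
            nihss=int(nihss[i]),
            vol_T1=float(v1[i]),
            vol_T2=float(v2[i]),
            hemisphere=str(hemis[i]),
        )
        for i in range(n)
    ]
    return patients, deltas


def _mechanical_patients(parcellation, reference_set, arms, params, rng):
    patients = []
    deltas = np.zeros((len(arms), params.n_regions_per_hemisphere))
    long_rows = []
    for i, arm in enumerate(arms):
        p = simulate_patient(parcellation, str(arm), params, rng, patient_id=f"s{i:05d}")
        prof1 = _chaco.restrict_to_stroke_hemisphere(
            _chaco.chaco_score(reference_set, parcellation, p.lesion_T1, p.id, "T1"),
            p.lesion_T1,
            parcellation,
        )
        prof2 = _chaco.restrict_to_stroke_hemisphere(
            _chaco.chaco_score(reference_set, parcellation, p.lesion_T2, p.id, "T2"),
            p.lesion_T2,
            parcellation,
        )
        change = _chaco.chaco_change(prof1, prof2)
        within = parcellation.regions.loc[change.index, "within_index"].to_numpy()
        deltas[i, within] = change.to_numpy()
        for prof, vol in ((prof1, p.vol_T1), (prof2, p.vol_T2)):
            widx = parcellation.regions.loc[prof.scores.index, "within_index"].to_numpy()
            for w, score in zip(widx, prof.scores.to_numpy()):
                long_rows.append(
                    {
                        "subject": p.id,
                        "region": f"r{w:02d}",
                        "time": prof.time,
                        "arm": p.arm,
                        "chaco": float(score),
                        "log_volume": math.log(max(vol, params.voxel_volume_ml / 2)),
                    }
                )
        patients.append(p)
    return patients, deltas, pd.DataFrame(long_rows)


# ---------------------------------------------------------------------------
# Oracle


def oracle_natural_effects(
    params: GenerativeParams,
    n_mc: int = 100_000,
    seed: int = 0,
    mediators: str = "all",
) -> NaturalEffects:
    """Ground-truth natural effects by brute-force counterfactual simulation.

    For each Monte-Carlo subject the mediators are realized under both arms
    and outcome probabilities are averaged for the three (exposure,
    mediator-arm) regimes; effects follow the odds-ratio identities with
    TE = NIE * NDE.  ``mediators='growth_only'`` treats disconnection change
    as a downstream (non-mediator) variable that tracks the exposure.
    """
    if mediators not in ("all", "growth_only"):
        raise ValueError("mediators must be 'all' or 'growth_only'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0AC1E]))
    cov = params.covariate_params
    age = cov.age_mean + cov.age_sd * rng.standard_normal(n_mc)
    nihss = np.round(rng.gamma(cov.nihss_shape, cov.nihss_scale, size=n_mc))
    meanlog, sdlog = params.baseline_volume_lognormal
    v1 = np.exp(meanlog + sdlog * rng.standard_normal(n_mc))
    z = rng.standard_normal(n_mc)
    mu_p, mu_a = params.arm_growth_log2_mean
    g_p = mu_p + params.growth_log2_sd * z
    g_a = mu_a + params.growth_log2_sd * z
    noise = params.surrogate.noise_sd * rng.standard_normal((n_mc, params.n_regions_per_hemisphere))

    def deltas(treated: float, growth: np.ndarray) -> np.ndarray:
        s = params.surrogate
        nr = params.n_regions_per_hemisphere
        gamma_arm = np.full(nr, s.gamma_arm)
        gamma_arm[list(params.eloquent_region_indices)] += s.gamma_arm_eloquent
        return s.gamma0 + s.gamma_growth * growth[:, None] + treated * gamma_arm[None, :] + noise

    b = params.outcome_coefs
    base = b.age * age + b.nihss * nihss + b.log_volume * np.log(v1) + b.intercept

    def prob(exposure: float, growth: np.ndarray, dmat: np.ndarray) -> float:
        lin = base + b.treatment * exposure + b.growth * growth
        for idx, beta_r in zip(params.eloquent_region_indices, b.region_effects):
            lin = lin + beta_r * dmat[:, idx]
        return float(np.mean(expit(lin)))

    if mediators == "all":
        p_t_m_t = prob(1.0, g_a, deltas(1.0, g_a))
        p_t_m_p = prob(1.0, g_p, deltas(0.0, g_p))
        p_p_m_p = prob(0.0, g_p, deltas(0.0, g_p))
    else:
        # mediator = growth only; deltas follow the actual exposure
        p_t_m_t = prob(1.0, g_a, deltas(1.0, g_a))
        p_t_m_p = prob(1.0, g_p, deltas(1.0, g_p))
        p_p_m_p = prob(0.0, g_p, deltas(0.0, g_p))
    return natural_effects(
        CounterfactualProbs(p_t_m_t=p_t_m_t, p_t_m_p=p_t_m_p, p_p_m_p=p_p_m_p)
    )


# ---------------------------------------------------------------------------
# I/O


def write_cohort_csv(cohort: Cohort, path) -> None:
    cols = ["arm", "age", "nihss", "vol_T1", "vol_T2", "favorable"]
    cohort.frame[cols].to_csv(path)


def write_params_yaml(params: GenerativeParams, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)


def load_params_yaml(path) -> GenerativeParams:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("covariate_params", "outcome_coefs", "surrogate"):
        if key in raw and isinstance(raw[key], dict):
            cls = {
                "covariate_params": CovariateParams,
                "outcome_coefs": OutcomeCoefs,
                "surrogate": SurrogateChacoParams,
            }[key]
            sub = dict(raw[key])
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            raw[key] = cls(**sub)
    for k, v in raw.items():
        if isinstance(v, list):
            raw[k] = tuple(v)
    return GenerativeParams(**raw)
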