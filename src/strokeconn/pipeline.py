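"""End-to-end orchestration: simulate -> score -> scan -> model -> select -> mediate.

All randomness flows from one top-level seed through per-stage substreams, so
rerunning a configuration reproduces every output byte-for-byte.  Outputs are
long-format CSV tables plus JSON for nested results; a manifest keyed on the
configuration hash supports skipping a completed run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chaco as _chaco
from . import connectome_models, lesion_metrics, mediation, region_selection
from . import synthetic_cohort as sc

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_config"]

log = logging.getLogger("strokeconn")

STAGES = ("simulate", "chaco", "scan", "models", "select", "mediate")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # 'synthetic' or 'real'
    seed: int = 0
    out_dir: str = "strokeconn_out"
    n_patients: int = 60
    chaco_mode: str = "mechanical"  # synthetic mode: 'mechanical' or 'surrogate'
    missing_fraction: float = 0.0
    k_bootstrap: int = 500
    k_subset_null: int = 200
    fdr_q: float = 0.05
    i_max: int = 9
    j_max: int = 15
    params: sc.GenerativeParams = field(default_factory=sc.GenerativeParams)
    # real-data inputs
    parcellation_path: str | None = None
    tractogram_paths: tuple[str, ...] = ()
    cohort_csv: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "real":
            missing = []
            if not self.parcellation_path or not Path(self.parcellation_path).exists():
                missing.append("parcellation_path")
            if not self.tractogram_paths or not all(
                Path(p).exists() for p in self.tractogram_paths
            ):
                missing.append("tractogram_paths")
            if not self.cohort_csv or not Path(self.cohort_csv).exists():
                missing.append("cohort_csv")
            if missing:
                raise FileNotFoundError(f"real mode inputs missing or absent: {missing}")

    def config_hash(self) -> str:
        # output location does not change results identity
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "params" in raw and isinstance(raw["params"], dict):
        tmp = dict(raw["params"])
        for k, v in tmp.items():
            if isinstance(v, list):
                tmp[k] = tuple(v)
        for key, cls in (
            ("covariate_params", sc.CovariateParams),
            ("outcome_coefs", sc.OutcomeCoefs),
            ("surrogate", sc.SurrogateChacoParams),
        ):
            if key in tmp and isinstance(tmp[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in tmp[key].items()}
                tmp[key] = cls(**sub)
        raw["params"] = sc.GenerativeParams(**tmp)
    if "tractogram_paths" in raw and isinstance(raw["tractogram_paths"], list):
        raw["tractogram_paths"] = tuple(raw["tractogram_paths"])
    return PipelineConfig(**raw)


@dataclass
class ReportBundle:
    config_hash: str
    out_dir: Path
    outputs: dict[str, str]
    mediation_results: dict | None = None

    def output_hashes(self) -> dict[str, str]:
        hashes = {}
        for name, rel in sorted(self.outputs.items()):
            p = self.out_dir / rel
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return hashes


def run_pipeline(config: PipelineConfig, force: bool = False) -> ReportBundle:
    """Run all stages in dependency order and write the report bundle.

    A completed run with an identical configuration hash is reused unless
    ``force`` is set.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash and all(
            (out / rel).exists() for rel in manifest.get("outputs", {}).values()
        ):
            log.info("reusing completed run %s", chash)
            results = None
            med_path = out / manifest["outputs"].get("mediation", "")
            if med_path.is_file():
                results = json.loads(med_path.read_text())
            return ReportBundle(chash, out, manifest["outputs"], results)

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    outputs: dict[str, str] = {}

    def run_stage(name, fn, *args):
        log.info("stage %s", name)
        try:
            return fn(*args)
        except Exception:
            log.exception("stage %r failed", name)
            raise

    frame, long_table, delta_cols = run_stage(
        "simulate", _stage_inputs, config, stage_seeds["simulate"], out, outputs
    )
    run_stage("scan", _stage_growth_and_scan, frame, long_table, out, outputs)
    run_stage("models", _stage_models, frame, long_table, out, outputs)
    selection, specs = run_stage("select", _stage_select, config, frame, delta_cols, out, outputs)
    results = run_stage(
        "mediate", _stage_mediate, config, frame, specs, delta_cols, stage_seeds["mediate"], out, outputs
    )

    _write_runlog(out, config, chash, outputs)
    outputs["runlog"] = "runlog.json"
    manifest_path.write_text(json.dumps({"config_hash": chash, "outputs": outputs}, indent=2))
    return ReportBundle(chash, out, outputs, results)


# ---------------------------------------------------------------------------
# stages


def _stage_inputs(config, seed_seq, out: Path, outputs):
    if config.mode == "synthetic":
        seed = int(seed_seq.generate_state(1)[0])
        cohort = sc.generate_cohort(
            config.params,
            n=config.n_patients,
            seed=seed,
            mode=config.chaco_mode,
            missing_fraction=config.missing_fraction,
        )
        frame = cohort.frame.copy()
        long_table = cohort.chaco_long
        sc.write_cohort_csv(cohort, out / "cohort.csv")
        cohort.delta_chaco.to_csv(out / "delta_chaco.csv")
        sc.write_params_yaml(config.params, out / "params.yaml")
        outputs.update(
            cohort="cohort.csv", delta_chaco="delta_chaco.csv", params="params.yaml"
        )
        delta_cols = sc.delta_columns(config.params)
    else:
        frame, long_table, delta_cols = _load_real_inputs(config, out, outputs)
    frame["log_vol_T1"] = np.log(frame["vol_T1"])
    if long_table is None:
        long_table = _surrogate_long_table(frame, delta_cols)
    long_table.to_csv(out / "chaco_long.csv", index=False)
    outputs["chaco_long"] = "chaco_long.csv"
    return frame, long_table, delta_cols


def _surrogate_long_table(frame, delta_cols):
    # Surrogate deltas carry no T1 level; represent T1 as zero disconnection.
    rows = []
    for pid, row in frame.iterrows():
        for i, col in enumerate(delta_cols):
            for time, score, vol in (
                ("T1", 0.0, row["vol_T1"]),
                ("T2", max(row[col], 0.0), row["vol_T2"]),
            ):
                rows.append(
                    {
                        "subject": pid,
                        "region": f"r{i:02d}",
                        "time": time,
                        "arm": row["arm"],
                        "chaco": score,
                        "log_volume": math.log(max(vol, 1e-6)),
                    }
                )
    return pd.DataFrame(rows)


def _load_real_inputs(config, out: Path, outputs):
    parcellation = _chaco.read_nifti_parcellation(config.parcellation_path)
    affine = np.diag([parcellation.voxel_size_mm] * 3 + [1.0])
    tractograms = [
        _chaco.assign_endpoints(
            _chaco.read_tck(p, affine, subject_id=f"ref_{i:02d}"), parcellation
        )
        for i, p in enumerate(config.tractogram_paths)
    ]
    refset = _chaco.ReferenceSet(tractograms)
    cohort = pd.read_csv(config.cohort_csv).set_index("id")
    long_rows = []
    deltas = {}
    for pid, row in cohort.iterrows():
        profs = {}
        for time, col in (("T1", "mask_T1"), ("T2", "mask_T2")):
            mask = _chaco.read_nifti_mask(row[col])
            prof = _chaco.chaco_score(refset, parcellation, mask, str(pid), time)
            prof = _chaco.restrict_to_stroke_hemisphere(prof, mask, parcellation)
            profs[time] = prof
            vol = mask.volume_ml
            for region, score in prof.scores.items():
                long_rows.append(
                    {
                        "subject": pid,
                        "region": f"r{region:03d}",
                        "time": time,
                        "arm": row["arm"],
                        "chaco": float(score),
                        "log_volume": math.log(max(vol, 1e-6)),
                    }
                )
        change = _chaco.chaco_change(profs["T1"], profs["T2"])
        deltas[pid] = {f"dchaco_{r:03d}": v for r, v in change.items()}
    delta_df = pd.DataFrame(deltas).T
    delta_cols = sorted(delta_df.columns)
    frame = cohort.join(delta_df)
    frame["treated"] = (frame["arm"] == "A").astype(int)
    frame["log2_growth"] = np.log2(frame["vol_T2"] / frame["vol_T1"])
    delta_df.to_csv(out / "delta_chaco.csv")
    outputs["delta_chaco"] = "delta_chaco.csv"
    return frame, pd.DataFrame(long_rows), delta_cols


def _stage_growth_and_scan(frame, long_table, out: Path, outputs):
    is_p = frame["arm"] == "P"
    growth_rows = []
    for arm, sub in frame.groupby("arm"):
        growth_rows.append(
            {
                "arm": arm,
                "n": len(sub),
                "median_vol_T1": sub["vol_T1"].median(),
                "median_vol_T2": sub["vol_T2"].median(),
                "median_change": (sub["vol_T2"] - sub["vol_T1"]).median(),
                "shrink_pct": lesion_metrics.shrinkage_percentage(
                    sub["vol_T1"], sub["vol_T2"]
                ),
            }
        )
    growth = pd.DataFrame(growth_rows)
    time_test = lesion_metrics.paired_rank_test(frame["vol_T1"], frame["vol_T2"])
    arm_test = lesion_metrics.two_sample_rank_test(
        (frame.loc[is_p, "vol_T2"] - frame.loc[is_p, "vol_T1"]),
        (frame.loc[~is_p, "vol_T2"] - frame.loc[~is_p, "vol_T1"]),
    )
    tests = pd.DataFrame(
        [
            {"test": "volume_time", **asdict(time_test)},
            {"test": "growth_by_arm", **asdict(arm_test)},
        ]
    )
    growth.to_csv(out / "volume_growth.csv", index=False)
    tests.to_csv(out / "volume_tests.csv", index=False)
    scan = lesion_metrics.region_scan(long_table.rename(columns={"chaco": "score"}))
    scan.to_csv(out / "region_scan.csv", index=False)
    outputs.update(
        volume_growth="volume_growth.csv",
        volume_tests="volume_tests.csv",
        region_scan="region_scan.csv",
    )


def _stage_models(frame, long_table, out: Path, outputs):
    # Mixture model needs positive scores at both times; skip gracefully when
    # the table is degenerate (e.g. surrogate T1 all-zero tables).
    try:
        fit = connectome_models.fit_mixture(long_table)
        connectome_models.wald_table_to_frame(fit).to_csv(out / "anova_table.csv", index=False)
        ratios = connectome_models.arm_time_ratios(fit)
        (out / "arm_time_ratios.json").write_text(
            json.dumps({k: list(map(float, v)) for k, v in ratios.items()}, indent=2)
        )
        outputs.update(anova_table="anova_table.csv", arm_time_ratios="arm_time_ratios.json")
    except connectome_models.ConvergenceError as err:
        (out / "anova_table.csv").write_text(f"# mixture model unavailable: {err}\n")
        outputs["anova_table"] = "anova_table.csv"
    rows = []
    for exposure in ("treated", "log2_growth"):
        try:
            ofit = connectome_models.outcome_logistic(frame, exposure=exposure)
            tab = ofit.table.copy()
            tab.insert(0, "exposure", exposure)
            rows.append(tab)
        except Exception as err:
            log.warning("outcome model for %s failed: %s", exposure, err)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(out / "outcome_models.csv", index=False)
        outputs["outcome_models"] = "outcome_models.csv"


def _stage_select(config, frame, delta_cols, out: Path, outputs):
    resp = region_selection.responsiveness_scan(frame, delta_cols)
    eloq = region_selection.eloquence_scan(frame, delta_cols)
    selection = region_selection.qualify_and_rank(resp, eloq)
    specs = region_selection.enumerate_models(
        selection.resp_order,
        selection.eloq_order,
        selection.qualified,
        i_max=config.i_max,
        j_max=config.j_max,
    )
    region_selection.selection_table(selection).to_csv(out / "selection_table.csv", index=False)
    (out / "mediation_models.json").write_text(
        json.dumps(
            [
                {"regions": sorted(s.regions), "provenance": [list(p) for p in s.provenance]}
                for s in specs
            ],
            indent=2,
        )
    )
    outputs.update(
        selection_table="selection_table.csv", mediation_models="mediation_models.json"
    )
    return selection, specs


def _stage_mediate(config, frame, specs, delta_cols, seed_seq, out: Path, outputs):
    covariates = ["age", "nihss", "log_vol_T1"]
    model_specs = {"growth_only": ["log2_growth"]}
    for s in specs:
        if s.regions:
            model_specs[s.name()] = s.mediator_columns("log2_growth")
    seeds = seed_seq.generate_state(3)
    reps = mediation.bootstrap_effects(
        frame, model_specs, covariates, k=config.k_bootstrap, seed=int(seeds[0])
    )
    results: dict = {"models": {}, "n_redrawn": reps.n_redrawn}
    for name, est in reps.estimates.items():
        entry = {
            "nde": est.nde,
            "nie": est.nie,
            "te": est.te,
            "proportion_mediated": est.proportion_mediated,
        }
        for qty in ("nde", "nie", "te", "pm"):
            point = entry["proportion_mediated"] if qty == "pm" else entry[qty]
            if math.isnan(point):
                continue
            lo, hi = mediation.bc_interval(reps.frames[name][qty].to_numpy(), point)
            entry[f"{qty}_ci"] = [lo, hi]
        results["models"][name] = entry
    joint_names = [n for n in model_specs if n != "growth_only"]
    results["nie_ratios"] = {}
    for name in joint_names:
        r = mediation.nie_ratio(reps, name, "growth_only")
        results["nie_ratios"][name] = {
            "ratio": r.point,
            "ci": list(r.ci),
            "significant_excess": r.significant_excess,
        }
    if len(model_specs) >= 2:
        sd = mediation.stepdown_fdr(reps, q=config.fdr_q, outer_seed=int(seeds[1]))
        results["stepdown"] = {
            "order": sd.names,
            "estimates": sd.estimates.tolist(),
            "thresholds": sd.thresholds.tolist(),
            "threshold_ci": [sd.threshold_lo.tolist(), sd.threshold_hi.tolist()],
            "rejected": sd.rejected.astype(bool).tolist(),
            "q": sd.q,
        }
    if config.k_subset_null > 0 and delta_cols:
        null = mediation.random_subset_null(
            frame,
            delta_cols,
            growth_col="log2_growth",
            covariates=covariates,
            k=config.k_subset_null,
            seed=int(seeds[2]),
        )
        results["subset_null"] = {
            "median": float(np.median(null.nies)),
            "growth_only_nie": reps.estimates["growth_only"].nie,
            "observed_percentiles": {
                name: null.percentile(reps.estimates[name].nie) for name in joint_names
            },
            "n_failed": null.n_failed,
        }
    (out / "mediation.json").write_text(json.dumps(results, indent=2))
    reps.matrix("nie").to_csv(out / "nie_replicates.csv", index=False)
    outputs.update(mediation="mediation.json", nie_replicates="nie_replicates.csv")
    return results


def _write_runlog(out: Path, config, chash, outputs):
    import scipy
    import statsmodels

    runlog = {
        "config_hash": chash,
        "seed": config.seed,
        "outputs": dict(outputs),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    (out / "runlog.json").write_text(json.dumps(runlog, indent=2))
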