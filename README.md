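# strokeconn

Structural-disconnection scoring and counterfactual mediation analysis for
two-arm stroke trials, with a fully specified synthetic cohort generator for
end-to-end validation.

The package implements an analysis chain linking a treatment to functional
outcome through structural brain damage:

1. **`chaco`** — indirect disconnection scoring: binary lesion masks are
   intersected with reference whole-brain tractograms; each grey-matter
   region receives the fraction of its connected streamlines that pass
   through the lesion, averaged over reference subjects (0 = intact,
   1 = completely disconnected). Readers for NIfTI masks/parcellations and
   TCK/TRK streamlines are included.
2. **`lesion_metrics`** — volumes, growth ratios, Wilcoxon/Mann-Whitney rank
   tests, probability-of-superiority effect sizes, surprisal (bits), and
   cohort accounting helpers.
3. **`connectome_models`** — a two-part (hurdle) model of semicontinuous
   disconnection scores: logistic zero part and a Gaussian linear mixed model
   of `log(chaco+) ~ time * treatment + roi * (time + log_volume)` with a
   subject random intercept, type II Wald chi-square term tests, per-arm
   geometric T2/T1 ratios, and adjusted outcome logistic regressions with
   profile-likelihood CIs.
4. **`region_selection`** — ranks regions by treatment responsiveness
   (standardized beta) and clinical eloquence (standardized OR), qualifies
   mediator candidates by joint CI exclusion, and enumerates distinct
   mediation models over a threshold grid.
5. **`mediation`** — counterfactual natural effects (NDE/NIE/TE on the
   odds-ratio scale, TE = NIE x NDE, proportion mediated = log NIE / log TE)
   for multiple mediators via inverse-probability weighting; subject-level
   bootstrap with bias-corrected intervals; NIE-ratio model comparison;
   bootstrap step-down FDR over correlated models; random-mediator-subset
   null distribution.
6. **`synthetic_cohort`** — generates parcellations, reference tractograms,
   lesioned patients with treatment-attenuated lesion growth, disconnection
   profiles (mechanically from lesions, or from a fast surrogate law), and
   binary outcomes from a known logistic model; plus a Monte-Carlo
   counterfactual oracle for the true natural effects.
7. **`pipeline` / CLI** — orchestrates everything reproducibly from one seed.

## CLI

```bash
strokeconn run-all --config config.yaml --seed 7 --out results/
strokeconn simulate --config config.yaml --out results/ --n 60
strokeconn mediate --config config.yaml --k 2000
```

Minimal YAML config:

```yaml
mode: synthetic          # or "real" with parcellation_path / tractogram_paths / cohort_csv
seed: 7
n_patients: 60
chaco_mode: mechanical   # or "surrogate" for large statistical runs
k_bootstrap: 500
fdr_q: 0.05
params:                  # generator settings (all optional)
  n_regions_per_hemisphere: 8
  arm_growth_log2_mean: [0.85, 0.30]
```

Outputs are long-format CSV tables (cohort, disconnection long table,
per-region scans, ANOVA table, selection table) and JSON (mediation results,
run log with seeds and library versions). Reruns with an identical
configuration are detected via a manifest hash and reused.

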