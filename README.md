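# brainclock

Brain-age clocks, network efficiency and whole-brain Hopf modelling on
functional connectivity (FC) cohorts.

`brainclock` is a tested re-implementation of an analysis pipeline that asks
whether sustained creative experience (dance, music, visual arts,
real-time-strategy gaming, or short-term game training) is associated with
*delayed brain aging* as measured from M/EEG source-space connectivity. It
is aimed at computational neuroscientists who want the full chain — cohort
simulation, brain-age estimation, graph metrics, generative modelling and
spatially aware map statistics — as composable, scikit-learn-style Python.

Because the M/EEG cohorts behind such analyses are restricted, the package
ships a first-class synthetic-data module that generates age- and
expertise-structured connectivity cohorts from the same generative model
used for fitting, so every downstream stage is testable end to end without
any download.

## What it computes

**Brain-age gap (BAG).** A linear-kernel support-vector regression is
trained on vectorized FC edges (n(n−1)/2 features) with repeated 5-fold
cross-validation, inner hyperparameter tuning, and Gaussian feature
augmentation applied inside training folds only. For a subject with
predicted age ŷ and chronological age y,

    BAG_raw = ŷ − y,
    BAG_corr = BAG_raw − (β₀ + β₁ y),      (bias line fit on training
                                            out-of-fold predictions)
    BAG_centered = BAG_corr − mean(BAG_corr | domain).

BAG > 0 reads as accelerated, BAG < 0 as delayed brain aging.

**Graph efficiency.** FC matrices are binarized at proportional thresholds
ρ ∈ {0.02, …, 0.10} (top-ρ fraction of edges) and summarized by global
efficiency E = ⟨1/d_ij⟩ (integration) and local efficiency L (mean
efficiency of each node's induced neighborhood subgraph; segregation),
both in [0, 1], averaged across the threshold range.

**Hopf whole-brain model.** Each region is a Stuart–Landau oscillator,

    dx_i/dt = (a_i − (x_i² + y_i²)) x_i − ω_i y_i + G Σ_j M_ij (x_j − x_i) + β η_i,

coupled diffusively through a structural connectome M and driven by noise
of standard deviation β. In the stable regime the stationary FC follows
analytically from the continuous Lyapunov equation (no simulation); a
stochastic integrator covers the oscillatory regime. The global coupling G
is estimated per subject by sweeping G ∈ [0, 3] in steps of 0.1 and
maximizing the structural similarity index (SSIM) between model and
empirical FC.

**Spatial statistics.** Age-vulnerability maps (regional strength–age
correlations), Cohen's D effect-size maps, and map–map correlations tested
against variogram-matched surrogate maps that preserve the empirical map's
values exactly and its spatial autocorrelation approximately, with
Benjamini–Hochberg FDR across cognitive-term association profiles.

## Worked example

```python
import numpy as np
import brainclock as bc

connectome = bc.generate_structural_connectome(n_regions=78, hub_fraction=0.2,
                                               density=0.3, seed=1)
train = bc.generate_training_cohort(connectome, n_subjects=120, seed=3)

clock = bc.BrainAgeClock(n_folds=5, n_reps=2, augmentation_factor=1,
                         random_state=0)
clock.fit(train.features(), train.ages)
print(f"out-of-fold MAE = {clock.mae_:.2f} y, r = {clock.pearson_r_:.3f}")

cohort = bc.generate_cohort(bc.CohortSpec(n_per_group=12, domain="gaming"),
                            connectome, seed=60)
recs = bc.compute_bags(clock.predict(cohort.features()), cohort.ages, clock,
                       [s.domain for s in cohort.subjects])
centered = np.array([r.centered_bag for r in recs])
expert = cohort.groups == "expert"
res = bc.compare_groups(centered[expert], centered[~expert], "independent_t")
print(f"expert - control centered BAG: mean diff "
      f"{centered[expert].mean() - centered[~expert].mean():.2f} y, "
      f"t({res.df:.0f}) = {res.statistic:.2f}, p = {res.p:.3f}, "
      f"D = {res.effect_size:.2f}")

eff = bc.efficiency_over_thresholds(cohort.matrices[0])
print(f"mean global efficiency = {eff.mean_global_eff:.3f}, "
      f"mean local efficiency = {eff.mean_local_eff:.3f}")

fit = bc.GlobalCouplingEstimator(connectome=connectome, a=-0.05).fit(
    cohort.matrices[0])
print(f"fitted global coupling G = {fit.g_best_:.1f} "
      f"(SSIM = {np.nanmax(fit.ssim_curve_):.3f})")
```

Output:

```
out-of-fold MAE = 7.33 y, r = 0.897
expert - control centered BAG: mean diff -4.45 y, t(22) = -0.64, p = 0.530, D = -0.26
mean global efficiency = 0.235, mean local efficiency = 0.345
fitted global coupling G = 1.3 (SSIM = 0.534)
```

Read: on a synthetic cohort spanning 17–91 years the clock predicts age
from FC edges with a mean absolute error of about 7 years; the simulated
gaming experts carry lower (more negative) centered BAGs than their matched
controls — the delayed-aging direction — though a single 12-vs-12 domain is
underpowered on its own; their networks show the usual integration <
segregation efficiency ordering; and the coupling sweep recovers a
plausible G for one subject's FC.

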