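# Methods

This note documents the models implemented in `brainclock`, the defaults
and why they were chosen, the numerical schemes, and what the synthetic
data do and do not establish.

## Synthetic cohorts

### Structural connectome

`generate_structural_connectome(n_regions=78, hub_fraction=0.2, density=0.3)`
builds a weighted, symmetric, connected graph with exactly
`round(density · n(n−1)/2)` edges: a random spanning tree guarantees
connectedness, remaining edges attach preferentially between hub regions
(odds ×4 per hub endpoint), and lognormal edge weights are scaled by
`hub_boost = 3` per hub endpoint. Hubs occupy one spatial cluster
(an anterior "frontoparietal-like" core) while non-hubs sit on a wider
shell, so region-level maps carry genuine spatial autocorrelation for the
surrogate tests to control. 78 regions matches a cortical AAL-style
parcellation; density 0.3 is in the range of thresholded DTI connectomes.

### Latent-coupling cohort model

Each subject receives a global coupling

    g = g0 − g_age · (age − a_min)/(a_max − a_min) + g_exp · z(expertise) + ε,
    ε ~ N(0, σ_g),

and the subject's FC is the Hopf linear prediction (below) at that
coupling, with measurement noise added on the Fisher-z transform of the
off-diagonal entries (keeping matrices valid correlations). Defaults:

| parameter | default | reading |
|---|---|---|
| g0 | 1.6 | young-adult coupling, centered in the 0–3 fitting sweep |
| g_age | 1.0 | total decline across the 17–91 y span; places elderly subjects near the low end of the sweep |
| g_exp | 0.05 | coupling gain per expertise z-score; through the age scaling this maps to an expert-vs-control brain-age-gap difference of about −6 y, the order reported for expertise effects in this literature |
| σ_g (coupling_noise_sd) | 0.12 | between-subject variability ≈ 40% of the age-effect spread, which puts out-of-fold clock performance in the realistic r ≈ 0.85–0.9 band rather than at ceiling |
| measurement_noise_sd | 0.05 | Fisher-z edge noise, a mid-range estimate of FC test–retest error |
| hopf_a (generation) | −0.05 | stable side of the bifurcation, required by the analytic route (see below) |

Expertise scores are drawn in domain-native units (years of practice for
dance/music/visual arts, hours/week for gaming, in-game actions-per-minute
for the learning arm) and only ever enter comparisons after z-scoring
within cohort. Unpaired designs generate expert/control pairs matched on
age, sex and education; paired (pre/post) designs reuse each subject's ε
in both records and raise the post record's expertise by a training gain,
so within-subject change is driven by the expertise term alone.

The generator is a pure function of (spec, connectome, seed). A flag
switches matrix generation from the analytic route to full stochastic
simulation for end-to-end time-series tests.

### Term maps

Stand-ins for meta-analytic cognitive-term association maps are Gaussian
random fields: white noise smoothed with a Gaussian distance kernel of
configurable length scale over the connectome coordinates, standardized to
zero mean and unit variance.

## Connectivity pipeline

Band-pass filtering uses a 3rd-order Bessel design (8–40 Hz defaults)
applied forward–backward (`sosfiltfilt`), so the net filter is zero phase —
amplitude-correlation FC is phase-sensitive and a one-pass group delay
would bias it. The effective magnitude response is the square of the
one-pass response, which is what the filter tests assert against.
Resampling is polyphase (`resample_poly`). FC is the Pearson correlation
across regions of the (filtered) signals; whether empirical pipelines
correlate raw band-passed signals or their amplitude envelopes is often
unstated — raw band-passed signals are used here.

Proportional thresholding ranks edges on *signed* correlation (the
"highest values" convention; an absolute-value variant would be a one-line
change), retains `round_half_away(ρ · n(n−1)/2)` edges, and breaks ties by
upper-triangle index order — making edge sets nested across thresholds and
every run reproducible. Harmonization of one acquisition set to a
reference mean is an additive edgewise shift: the set mean lands exactly
on the reference and between-subject differences are untouched (before
the final clip to [−1, 1]).

## Brain-age clock

`BrainAgeClock` is a scikit-learn estimator. Design choices:

- **Linear-kernel SVR** (inside a standardization pipeline), because edge
  importance is defined as the mean |weight| per feature across folds and
  repetitions — only linear kernels have per-feature weights. The grid
  (C ∈ {0.1, 1, 10}, ε ∈ {0.1, 1}) is tuned by 3-fold inner CV on each
  training fold.
- **Augmentation inside training folds only.** Gaussian feature
  perturbations (default sd = 0.1 × pooled feature sd) with the source
  row's age; held-out folds are never augmented. A dedicated test verifies
  that zero-noise augmentation leaves out-of-fold performance unchanged up
  to the duplicated-sample reweighting.
- **Performance** is MAE and Pearson r of pooled out-of-fold predictions,
  averaged over repetitions, with no bias correction applied (correcting
  first would flatter the metrics).
- **Bias line** (slope/intercept of raw BAG on age) is fit by OLS on the
  out-of-fold training predictions, not resubstitution, to avoid optimism.
  Corrected BAGs are therefore exactly age-orthogonal on the training set.
- **Prediction** is the mean over all fold×repetition models; repetitions
  default to 15 (a fixed count — no adaptive stopping), tests and examples
  use 1–2 for speed.
- Domain centering subtracts the mean corrected BAG of each domain batch,
  experts and controls pooled.

## Graph efficiency

Global efficiency averages inverse shortest-path lengths (hop counts via
Dijkstra on the binary matrix), with 1/∞ = 0 for disconnected pairs.
Local efficiency computes, for each node with degree ≥ 2, the efficiency
of the subgraph *induced by its neighborhood* (paths may not leave the
neighborhood; a published variant allows them to — the induced-subgraph
reading is used); degree < 2 nodes contribute 0, avoiding the 0/0 in
k(k−1). Both metrics are verified exactly against an independent
brute-force oracle (walk-length reachability) on every graph with up to
six nodes.

## Hopf model numerics

**Normalization.** M is scaled so its largest row sum is 1, making G
comparable across connectomes.

**Form of the equations.** The cubic saturation is the standard
supercritical normal form (x² + y²)·x, and the rotation is antisymmetric
(−ωy in the x equation, +ωx in the y equation) so oscillation occurs at
f = ω/2π. Printed variants of these equations sometimes carry a
non-saturating (x² − y²) term or a duplicated −ω sign; both are treated as
typographic variants of the normal form, not implemented.

**Linear (Lyapunov) FC.** The drift of the linearization at the origin has
diagonal blocks diag(a − G·s) + G·M (s = row sums) and rotation blocks
±diag(ω). Stationary covariance solves A Σ + Σ Aᵀ + β² I = 0; FC is the
correlation among the x components. With uniform a and ω the symmetric
block diagonalizes and every eigenmode is an independent noisy rotation
with isotropic variance β²/(−2λ) — an O(n³) eigendecomposition instead of
an O(n³) but much larger 2n-dimensional Lyapunov solve; the general solver
remains the fallback and both routes are cross-checked. Residuals of the
Lyapunov equation are verified below 1e−8.

**Stability domain.** Diffusive coupling G Σ M_ij (x_j − x_i) has a zero
Laplacian mode (the homogeneous direction), so the linearization's
stability margin equals max(a_i) for *every* G. The analytic route is
therefore only defined for a < 0 — the noise-driven regime, which is also
where a weak-noise linear approximation is meaningful — and raises
`UnstableLinearizationError` otherwise. Cohort generation and coupling
fitting default to a = −0.05; the supercritical regime (a = 0.01, where
each node carries a self-sustained 10 Hz oscillation) remains available
through the simulator, and the linear/nonlinear consistency check is run
in the stable regime (a = −0.5, G = 2.0, three seed-averaged 600 s runs,
edgewise r ≥ 0.95 required).

**Integrator.** Euler–Maruyama with the rotational part integrated exactly
(integrating-factor splitting): each step rotates (x, y) by ω·dt, then
applies the amplitude/coupling drift and the √dt-scaled noise. A plain
explicit Euler step amplifies the oscillation by |1 + iω dt| per step — an
artificial anti-damping of order ω²dt/2 per unit time, which at 10 Hz
exceeds every physical rate at any feasible dt and silently drives the
network onto a phase-locked limit cycle. Because the rotation commutes
with the cubic term, the diffusive coupling and the isotropic noise, the
splitting adds no error beyond the Euler treatment of the non-rotational
part. Default dt = 2 ms (the integrator refuses dt > 1/(20 f)); a
divergence guard aborts with advice to reduce dt.

**SSIM.** Windowed structural similarity (uniform 7×7 window, K1 = 0.01,
K2 = 0.03, sample-covariance normalization) on the joint data range of the
two matrices, averaged over valid windows; equals 1 exactly iff the inputs
are identical. Verified against scikit-image's implementation to 1e−6.

**Coupling fit.** `fit_global_coupling` sweeps G over 0–3 in steps of 0.1,
scores the linear-model FC against the empirical FC by SSIM at every
stable grid point, and returns the argmax (ties → smallest G); unstable
grid points are recorded with undefined SSIM. Recovery of generating
couplings {0.5, 1.0, 2.0} within one grid step is verified over 20
replicates at mild observation noise (Fisher-z sd 0.02, 78 regions).

## Spatial statistics

The age-vulnerability map is the per-region Pearson correlation of nodal
strength with age (constant-strength regions get 0 with a warning);
effect-size maps are per-region Cohen's D with pooled sd.

Surrogate maps preserve spatial structure by variogram matching rather
than spherical rotation — the procedure needs only region coordinates, not
a cortical surface mesh. Each surrogate is built by (i) randomly permuting
the source map, (ii) smoothing with Gaussian distance kernels at several
length scales (geometric grid of 4 scales from 0.08 to 1 × the median
inter-region distance, plus the unsmoothed permutation), (iii)
rank-remapping each candidate onto the source's sorted values — exact
multiset preservation — and (iv) keeping the candidate whose empirical
variogram (coarse equal-width distance bins) is closest to the source's.
Scale selection happens *after* rank-remapping so that candidates share
the source's value distribution and the variogram difference reflects
spatial structure, not the variance shrinkage of smoothing.

Two-sided p-values use the add-one permutation convention
(1 + #{|r_surr| ≥ |r|}) / (n + 1), never returning 0; surrogates are
generated from the first map argument (the vulnerability map in the
pipeline's usage). Term-association profiles report absolute correlations
with surrogate p-values and Benjamini–Hochberg q-values across terms.

Known limitation: rank-remapping bounds how smooth a surrogate can be at
very short range (near-ties in a heavily smoothed field are amplified back
to full range), so the ensemble cannot reproduce the first-bin
semivariance of an arbitrarily smooth Gaussian-process map to high
relative precision. The preservation test therefore uses a source drawn
from the surrogate family itself with four coarse distance bins (25%
tolerance per bin), and the scientifically load-bearing guarantee — a
calibrated null — is tested directly: on independent smooth maps the
surrogate test's type-I rate at α = 0.05 stays within [0.02, 0.09] over
500 replicates, and a planted r = 0.5 association is detected in ≥ 80% of
replicates.

## Group statistics

Independent and paired t-tests report the statistic, two-sided p, 95% CI
of the mean difference, degrees of freedom, and Cohen's D (group a minus
group b over pooled sd; paired designs use the sd of the differences).
One-sided Mann–Whitney U is available for small samples; the direction
must be passed explicitly. Cohen's f² for correlations is r²/(1−r²).
ANCOVA (outcome ~ group + covariates, categorical covariates as indicator
codes) reports the group coefficient with partial f² from nested-model R².
The BAG percentile split labels values strictly below the 35th percentile
"younger" and strictly above the 65th "older" (linear-interpolated
percentiles). The pooled expertise–BAG association z-scores both variables
within domain before pooling; domains with constant scores are dropped
with a warning.

## Problem sizes used in tests

The default test run trains the clock on 120 subjects × 3003 edges with 2
CV repetitions, uses a 16-region connectome for simulation-heavy checks
(3 × 600 s runs for the linear/nonlinear comparison) and the 78-region
connectome wherever dimensionality matters, and runs 500-replicate null
calibrations with 100 surrogates each. These sizes were chosen so the full
suite completes in a few minutes on one CPU while every statistical check
retains enough replicates for its stated tolerance.

## What passing tests do and do not show

The synthetic generator shares its forward model with the fitting code
(the Hopf linear FC), so parameter-recovery results demonstrate internal
consistency of the pipeline — estimator correctness, fold hygiene, bias
correction, calibration — not that the model family describes real M/EEG.
The generator omits, among other things: heterogeneous regional
frequencies and bifurcation parameters, volume conduction and source
leakage, scanner/site effects beyond a global mean shift, non-Gaussian
expertise distributions, and any true causal pathway from expertise to
connectivity beyond the stipulated coupling gain. Headline numbers from
restricted empirical cohorts (e.g., clock accuracy on 1,240 real
participants) are not reproducible at desk scale and are not claimed by
the test suite.
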