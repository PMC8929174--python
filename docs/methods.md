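# Methods

## Model and estimation procedure

Each of the r region time courses x_i(t), sampled every dt seconds, is
band-passed to a narrow band (default 0.05–0.075 Hz) with a zero-phase
(forward–backward) Butterworth filter of one-pass order 7. Zero-phase
filtering is essential: the instantaneous phases are the estimation
substrate, and a causal filter would bias them by its group delay. The
analytic signal x + i·H{x} then yields amplitudes a_i(t) = |x_a| and phases
φ_i(t) = ∠x_a, unwrapped along time. Unwrapping precedes all differencing,
so the phase increments entering the regression never contain ±2π folds.

The estimator assumes the phase dynamics follow the Kuramoto model and
reads its forward-Euler discretisation with unit step as a linear model in
the couplings: for target region i,

    φ_i(s+1) − φ_i(s) − ω_i = (1/r) Σ_{j≠i} K_ij sin(φ_j(s) − φ_i(s)).

Row s of the design matrix holds (1/r)·sin(φ_j(s) − φ_i(s)); the response
is the phase increment minus ω_i. The self-coupling column is identically
zero (sin 0 = 0) and is removed; K_ii is set to 1 by convention (any
constant would do — it never touches the residual). Time is counted in
iteration steps: ω is expressed in radians per sample step, and the real
sampling interval is bookkeeping only.

Eigenfrequencies come in two modes. `band_mean` (default) sets every ω_i to
the band-centre frequency 2π·mean(band)·dt — appropriate because the band
is narrow. `fft_peak` takes each region's largest in-band peak of a plain
(untapered) periodogram; regions without a usable in-band peak fall back to
the band mean with a warning.

The per-region systems are solved through the normal equations SᵀS k = Sᵀb
with a Cholesky factorisation of SᵀS (an explicit-inverse path is retained
behind `method="explicit_inverse"`; the two agree to well below 1e-10). The
r per-region solves are mathematically identical to solving the assembled
block-diagonal system — the blocks do not interact — and are the default
execution path on cost grounds; the block assembly is exposed for
verification. Condition numbers of SᵀS are guarded: warning above 1e8,
error above 1e12. The system is over-determined whenever T ≥ r + 2; fewer
samples raise an explicit under-determined-system error.

## Reference measures

* **FC** (partial correlation): data filtered to 0.01–0.1 Hz; entry (i, j)
  is the correlation of regions i and j controlling for all remaining r−2
  regions, computed from the precision matrix, −P_ij/√(P_ii·P_jj). This is
  the full-order reading of pairwise partial correlation across the whole
  region set.
* **PS** (phase synchrony): phases from the same narrow band as K; entry
  (i, j) is the sample median over time of cos(φ_j − φ_i) (mean-of-central-
  values median for even T). Symmetric by evenness of cosine; invariant to
  common phase offsets.
* **AR**: first-order vector autoregression x(t) = A·x(t−1) + ε(t), fitted
  by multivariate least squares (statsmodels VAR) on 0.01–0.1 Hz filtered
  data. The model has no intercept; per-region demeaning is the default
  reconciliation with non-zero-mean data, and an intercept variant is
  provided (`intercept=True`) since published AR pipelines differ on this
  point. Diagonal entries are estimated, not conventioned.

Band discipline — K/PS on the narrow band, FC/AR on the wide band — is
carried on the data objects (`AnalyticPhaseSet.band`) rather than enforced
by re-filtering, so synthetic phases can enter the same code paths.

## Set-level statistics

Per coupling, subjects deviating more than 2 SD from that coupling's
cross-subject mean are excluded as outliers, then the per-coupling
statistic is computed: Spearman ρ against the regressor, Wilcoxon rank-sum
between groups, or Wilcoxon signed-rank against zero. One-sided variants
restrict to the requested sign of the statistic. The observed set size is
the number of couplings with p < P_u (default 0.05), counted over the
upper triangle for symmetric measures (FC, PS) and all off-diagonal
positions for directed ones (K, AR).

The null permutes each subject's couplings uniformly among coupling
positions, independently per subject and permutation (acting on the
upper-triangle vector for symmetric measures), and recounts. The reported
p is (1 + #{null ≥ observed}) / (1 + n_perm): the add-one convention avoids
exactly-zero p-values and resolves the ≥-versus-> ambiguity conservatively.
All permutation draws derive from a caller-supplied seed; identical seeds
give bit-identical results.

Spearman p-values use the large-sample t approximation for per-coupling
n > 9 and exact enumeration of all n! rank permutations below that; the
Wilcoxon variants use the standard normal approximations (rank-sum without
tie correction, signed-rank with tie correction and dropped zeros), each
verified against the corresponding scipy scalar routine. Couplings left
with fewer than 4 subjects after outlier removal get p = 1. The
column-wise engine is vectorised because a single cohort test evaluates
hundreds of couplings per permutation.

Covariate control (`regress_out_covariate`) replaces each coupling's values
by the residuals of an ordinary linear fit on the covariate (intercept
included) with the coupling's mean restored. Bonferroni bookkeeping covers
the small families actually tested (regressors × directions, e.g. factor 6
or 3). Phase-randomised surrogates preserve each series' amplitude
spectrum exactly while drawing Fourier phases i.i.d. uniform on (−π, π];
DC and (even-length) Nyquist bins are kept as-is so the inverse transform
is exactly real — a necessary detail the construction leaves implicit.
Randomising each region independently destroys all cross-region
dependence, making the surrogate set-size distribution an estimation-bias
control for the K and PS pipelines.

A known property of the within-subject permutation null: if a large
fraction of couplings carries *same-signed* regressor dependence, permuted
positions inherit part of that dependence and the null set sizes inflate,
which can make the test conservative at very large effects. Mixed-sign
dependence (as the simulator's default pattern produces) cancels in the
null mixture; the monotonicity-of-power property holds in that regime and
is tested there.

## Simulator

Cohorts are generated from the noisy Kuramoto model

    dφ_i/dt = ω_i + (d/r) Σ_j K_ij·M_ij·sin(φ_j − φ_i) + n·ε_i(t)

integrated with classical RK-4 — a deliberately different integrator from
the Euler-based estimator, so recovery is not a tautology. The noise
process is not specified beyond ε_i(t) in the model statement; the package
draws ε i.i.d. standard normal per oscillator once per output step and
holds it constant within that step's RK-4 substeps (stochastic forcing,
not an Itô discretisation — documented as such). One RK-4 step per output
sample is the default; sub-stepping is available and converges at fourth
order. Note the stability constraint: the fastest relaxation rate times
the substep must stay inside the RK-4 stability region (≈2.8 on the real
axis), which matters only for couplings far stronger than the default
grid.

Cohort defaults mirror the reference study conditions: s=24 subjects, r=20
oscillators, T=300 samples at dt=2 s. Initial phases are uniform on
[0, 2π); eigenfrequencies uniform within ±10 % of the band-centre value
0.785 rad/step; original couplings i.i.d. N(0, 1); the subject score
uniform on [0, 30] (a Ham-D-like range — the construction only uses its
ranks). Score dependence is injected at the inside-pattern (IC) positions
of a 13-oscillator block: each manipulated coupling is replaced by a
monotone function of the score — `plateau` (default; saturating above the
75th score percentile) or `gradual` (linear) — plus a small jitter,
rescaled to the position's original cross-subject mean and SD. This
preserves marginal magnitudes and manipulates only the correlation
structure; achieved |Spearman ρ| is verified against the target (default
0.95) and an error is raised if unreachable. Signs are drawn ±1 per
position. Bridging (BC) and reference (RC) positions stay untouched
bit-wise. The default mask M keeps only the manipulated positions in the
generation (binary), with all-ones and directional-bias builders provided.

The (noise, coupling) sweep redraws Φ0 and Ω per run while holding
K and the score fixed, runs generation → Euler-based estimation
(band-centre ω) → bidirectional set-level test per cell, and records the
median p over runs. The default grid, n ∈ {0.1, 1.0, 2.0, 3.0} ×
d ∈ {0.5, 1.5, 2.5, 3.5}, was chosen by pilot simulation to straddle the
detectability transition: at n = 0.1 every adequate-coupling cell is
significant, at n = 3 with d = 0.5 the dependence is drowned. The shipped
configuration uses 3 runs × 100 permutations per cell so the full 4×4
sweep completes in about a minute and a half; the run count and grid are
plain parameters.

## Numerical choices and degenerate inputs

* Outlier SDs use ddof=1; a zero-variance coupling excludes nobody and
  yields ρ = NaN, p = 1.
* |ρ| = 1 under the t approximation maps to p = 0 (the t statistic
  diverges); exact-enumeration p-values can never be 0.
* The surrogate of a constant series is the same constant (only DC
  energy).
* Ties in the plateau trend are broken by the injected jitter; with 24
  subjects the tie-induced Spearman loss is ≈0.015, comfortably above the
  0.95 target.
* All-zero region series raise an undefined-phase error rather than
  returning meaningless phases.
* Edge samples of filtered/Hilbert-transformed series are not trimmed (all
  T samples enter the T−1 equations); tests that quantify reconstruction
  accuracy evaluate the central 80 % of samples.

## What the synthetic data does and does not show

The generator emulates narrow-band phase dynamics with known ground-truth
couplings and score dependence. It does not model hemodynamics (no
amplitude/BOLD forward model — cos-projection is available for signal-level
fixtures), scanner noise, motion, or physiological confounds. Passing
tests therefore demonstrate that the estimation-plus-testing pipeline
recovers dependence present in Kuramoto-generated phases under the stated
noise; they do not certify sensitivity on empirical fMRI, where the
localisation of individual couplings is additionally limited (boundary
couplings absorb much of the detected set).

## Known limitations

* The estimator inherits the Euler discretisation's bias when the true
  dynamics are smoother (RK-4-generated); at weak coupling the estimates
  remain strongly correlated with d·K, which is what the set-level
  statistics consume.
* Only the ℓ₂ criterion and the first-order model are implemented;
  alternative integrators for estimation and higher-order AR comparisons
  are out of scope.
* The set-level test reports *that* a set is larger than chance, not
  *which* couplings are real; the significant-coupling list is
  descriptive, not localising.
* FDR and cluster-mass alternatives to the set statistic are deliberately
  not provided.
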