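# Methods

This note records the models, parameter choices, and numerical decisions
behind `pulmopet`, and what the synthetic phantom can and cannot stand in
for. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tracer-kinetic models

**FDG / Sokoloff.** Each ROI's dynamic FDG signal is decomposed as
`C_ROI(t) = F_b·C_p(t) + C_e(t) + C_m(t)` with a free (substrate-pool)
compartment `dC_e/dt = K₁C_p − (k₂+k₃)C_e` and a trapped (phosphorylated)
compartment `dC_m/dt = k₃C_e`, both starting empty. The equation is
implemented exactly in this form: the tissue terms are *not* scaled by
(1 − F_b), and a single C_p drives both the vascular and the exchange term
(no whole-blood/plasma split). Rates are per minute (K₁ in ml/ml/min; k₂,
k₃ in 1/min); times are in seconds.

The forward model is evaluated with an exact exponential integrator on a
0.25-s grid — exact for a piecewise-linear C_p, which is how input functions
are represented — and then *frame-averaged* (time integral over the frame
divided by its duration) rather than sampled at frame midpoints, because PET
frames accumulate counts. Against the closed form for a constant input the
solver is accurate to better than 1e-8.

**Inversion.** `fit_sokoloff` minimizes the frame-duration-weighted residual
sum of squares with trust-region bounded least squares (F_b ∈ [0, 1], rates
≥ 0, tolerances 1e-10). Because the likelihood surface has local minima in
(k₂, k₃), fitting is multistarted from the fixed 2⁴ grid
{F_b: 0.05/0.2, K₁: 0.002/0.01, k₂: 0.02/0.1, k₃: 0.005/0.02}; all 16 grid
points are scored and the best 4 refined. Ties in RSS break toward the
smaller F_b. A fit that converges from no start is returned with
`converged=False`, never silently. On noiseless data the inversion recovers
all four parameters to better than 1e-3 across a 3×3×3×3 truth grid.

**¹³NN breathhold.** Regional perfusion is read directly from the breathhold
curve: `plateau` = duration-weighted mean activity over the final 15 s;
`peak` = maximum frame activity in the first 30 s; `Q_r = plateau +
max(0, peak − plateau)`. The plateau reflects perfusion of aerated alveoli,
the early transient reflects shunting flow that passes without gas exchange.
The shunt "relative height" is reported in absolute plateau units
(`shunt_component`); the alternative fractional reading
(peak − plateau)/peak is exposed as `NnPerfusionEstimate.shunt_fraction` —
both conventions give the same Q_r, so the choice does not affect any
downstream quantity.

## Normalization algebra

Per animal-condition (30 ROIs): `F_tis = 1 − F_gas − F_b`,
`F_tis,n = F_tis/mean(F_tis)`, `Q_n = Q_r/mean(Q_r)/F_tis,n`,
`F_bn = F_b/mean(F_b)/F_tis,n`. Two identities follow *exactly* from these
definitions and are enforced as invariants (1e-10):
`mean(Q_n·F_tis,n) = mean(F_bn·F_tis,n) = 1`. Pooled analyses stack the
per-animal normalized rows (5 × 30 per condition); no mixed-effects
structure is imposed. The mean tissue fraction includes every ROI (no
near-zero-tissue exclusion). Longitudinal comparisons scale injury rows by
whole-animal ratios, `Q_a = Q_n·CO_INJ/CO_BL` and
`F_ba = F_bn·V_B,INJ/V_B,BL` with `V_B = Σ F_b·V_ROI`; baseline rows carry
`Q_a = Q_n`, `F_ba = F_bn`. Animals without a usable injury cardiac output
are excluded from the adjusted analysis only (and logged).

**ROI construction.** Masks are cut into 15 isogravitational layers by
equal *geometric height* across the vertical bounding box (isogravitational
planes are geometric, not equal-count; an equal-count alternative is
available via `method="counts"`), and into 2 contiguous axial sections.
`height_fraction` is the layer midpoint relative to the mask's vertical
extent, 0 = most dependent (dorsal in supine posture).

## Coupling statistics

**Model zoo.** Six candidate forms for F_bn vs Q_n — y=ax, y=a+bx, y=ax+bx²,
y=a+bx+cx², y=e^(ax), y=ae^(bx) — are fitted by least squares in both
variable orientations. Polynomial forms use exact linear least squares;
exponential forms are fitted in *original* space by bounded nonlinear least
squares with log-space initialization (a log-transform would change the
error model and break the BIC comparison). The Gaussian log-likelihood is
`−n/2·(ln(2π·RSS/n)+1)` and the default BIC convention counts the error
variance as a parameter: `BIC = n·ln(RSS/n) + (k+1)·ln(n)` (a
`full_gaussian` convention keeping the additive constants is switchable;
orderings agree). BIC ties within 1e-6 go to the smaller model. Absolute
BIC values are convention- and data-dependent, so only within-study
orderings are meaningful. The likelihood-ratio test between nested forms
uses `χ² = n·ln(RSS_reduced/RSS_full)` with df equal to the parameter-count
difference.

**KDE two-sample test.** The statistic is the integrated squared difference
of the two bivariate Gaussian kernel density estimates, available in closed
form: `T = ψ₁₁(2H₁) + ψ₂₂(2H₂) − 2ψ₁₂(H₁+H₂)` with ψ the V-statistic kernel
sums over all sample pairs. Bandwidths are unconstrained 2-D plug-in
matrices per sample: the sample is pre-whitened by its covariance, the
fourth-order integrated density-derivative functionals are estimated with an
isotropic pilot of normal-scale order (g = n^{−1/(d+6)}), the asymptotic
MISE criterion is minimized over all SPD matrices (Nelder-Mead on a
log-Cholesky parametrization, normal-scale start, with a normal-scale
fallback if the estimated curvature functional is degenerate), and the
optimum is mapped back. Pre-whitening makes the selector affine-equivariant,
hence the test affine-invariant.

Two inference routes are provided. The default `asymptotic` route compares T
with a *moment-matched gamma* null: the mean keeps the O(1)
smoothing-mismatch term that survives when H₁ ≠ H₂; the variance and third
cumulant come from double-centered (degenerate-part) kernel matrices on the
pooled sample, with triangle terms evaluated on a 400-point subsample when
the pooled size exceeds 400. A plain normal null was found to misstate
mid-range p-values at n ≈ 150 because the quadratic form is right-skewed;
with the gamma shape the asymptotic and permutation p-values agree to ~0.01
(median) on null replicates, and the empirical type-I error at α = 0.05 sits
inside [0.02, 0.10] for two n = 500 samples from one distribution (both
verified in the suite). The `permutation` route relabels the pooled sample
(≥ 999 permutations, seeded, bandwidths held fixed) and is preferable when
the pooled points are not exchangeable. Note that clouds built from
per-animal normalized ROIs carry within-animal dependence, which makes both
routes conservative relative to a fully independent sample — a property of
the data, not of the test.

**Stratified fits.** Independent y=a+bx fits within quantile strata of
`height_fraction` (default 3, ≥ 5 points each) express the curvilinear
injury coupling as a piecewise-linear family whose local slope falls with
Q_n.

## The synthetic phantom

The generator emulates a two-condition (baseline / endotoxin-injury) study
in five supine animals, 30 ROIs each. Defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| animals × layers × sections | 5 × 15 × 2 | study design |
| baseline coupling | F_bn = 0.32 + 0.690·Q_n | published best baseline model |
| injury coupling | F_bn = 1.684·Q_n − 0.538·Q_n² | published best injury model |
| residual sd (baseline / injury) | 0.15 / 0.08 | baseline scatter exceeds injury |
| baseline Q_n profile | affine in height, 1.5 → 0.5 | ~3:1 dependent:nondependent gradient |
| injury Q_n profile | sigmoid, mid 0.5, width 0.21 | dependent redistribution, very low nondependent flow; see below |
| per-ROI perfusion heterogeneity | lognormal, sd 0.15 | ~15% regional CV beyond the gradient, matching the displayed cloud dispersion |
| axial-section offset | ±10% | sections exist but no section effect is reported |
| F_gas profile (baseline / injury) | 0.45+0.25h / 0.25+0.40h | aeration rises with height; injury consolidates dependent lung |
| cardiac output (BL / INJ) | 4.8±0.7 / 3.7±1.1 l/min | measured physiology |
| Sokoloff truth | K₁ 0.005, k₂ 0.05, k₃ 0.01 /min, ±20% lognormal | identifiable, lung-plausible magnitudes (generator inputs, not claims) |
| FDG frames | 6×10 s, 8×30 s, 10×60 s | typical dynamic protocol (acquisition details unavailable) |
| ¹³NN frames | 30×2 s | 60-s breathhold |
| C_p(t) | linear 60-s rise, two-exponential decay (1/30, 1/600 s⁻¹, 60:40) | constant-rate infusion; true input function unavailable |
| TAC noise | Gaussian, sd = scale·(√signal + floor); FDG scale 0.08 (BL) / 0.035 (INJ) | pseudo-Poisson counts; higher injected dose at injury |
| missing CO | last animal, injury | exercises the exclusion rule |

**Exact closure through the normalization algebra.** F_b is generated by
applying the condition's coupling in normalized space and solving a fixed
point of the algebra (F_b ↦ m_b·F_bn·F_tis,n with F_tis,n depending on
F_b), so that the downstream pipeline run on a noiseless bundle reproduces
the intended (Q_n, F_bn) cloud to machine precision and per-animal model
fits return the generating coefficients to 1e-4. One subtlety is inherent:
the identity mean(F_bn·F_tis,n) = 1 means an exact coupling g must satisfy
mean(g(Q_n)·F_tis,n) = 1, and the published coefficients — printed to 2–3
decimals — miss this by ~1% at baseline (0.32 + 0.690 sums to 1.01, not 1).
The generator therefore projects the configured coupling onto the
constraint by a single scalar and records the achieved model as
`intended_coupling` (with `coupling_scale`); noiseless closure is exact
against the intended model and within ~1% of the configured one. The injury
profile width (0.21) was chosen so that the tissue-weighted mean of Q_n²
matches the value the published quadratic itself implies
(0.684/0.538 ≈ 1.27), keeping the printed injury model self-consistent to
~2%; a much steeper profile (nondependent Q_n ≈ 0) would contradict the
printed coefficients under the same identity, so "very low" nondependent
flow (top-two-layer Q_n ≈ 0.2) was preferred.

**¹³NN construction.** The breathhold curve is the plateau
(∝ aerated perfusion) plus a gamma-variate transient peaking at 8 s whose
maximum frame value equals total perfusion in activity units, so
plateau + peak excess recovers Q_r exactly by construction. Nondependent
injury ROIs (height fraction > 0.7) receive shunt fractions of 0.15–0.45.

**`sample_coupling_cloud`** draws (Q_n, F_bn) directly in coupling space —
profile plus heterogeneity, normalized to mean 1 per animal, coupling plus
residual — with no kinetics or tissue algebra. It expresses the coupling
hypothesis alone and is what the coefficient-recovery and KDE headline
checks use.

**What the phantom does not emulate:** voxel-level image formation
(reconstruction, attenuation, scatter, motion), image-derived lung masks,
tracer recirculation or delayed arrival at very low flows, non-Gaussian
residual structure, and any within-animal correlation beyond the shared
vertical profile. Passing tests therefore demonstrate the correctness and
calibration of the estimators and statistics under the stated generative
conditions, not the physiological fidelity of real PET data.

## Problem sizes and determinism

Recovery and selection checks use 200 replicates of 150 ROIs; the KDE
type-I check uses 200 replicates of two 500-point samples; Monte-Carlo F_b
recovery uses 200 noisy refits of one ROI; the full-stack closed loop runs
the complete pipeline on a noiseless five-animal bundle. Every stochastic
component takes a `numpy` `Generator` or integer seed; identical
config + seed reproduces phantoms, bundles, and pipeline outputs
byte-for-byte (independent per-animal/per-condition substreams keyed on the
seed). The pipeline writes a config hash and package versions into
`provenance.json`.

## Known limitations

- The asymptotic KDE null is a three-moment approximation; for small
  samples or strongly dependent points the permutation route is the
  reference behaviour.
- Printed BIC values from other software cannot be matched without the
  original data (convention and data unknown); only orderings are compared.
- The Sokoloff fit reports no net influx rate (Patlak-style K_i) and no
  image-derived input functions; both are out of scope.
- `fit_sokoloff` standard errors are not computed (the `stderr` field is a
  placeholder for a future delta-method implementation).
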