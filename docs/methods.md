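# Methods

This note documents the models, numerical choices, and parameter defaults of
`nirsvwm`, and what the synthetic-data generator does and does not emulate.

## Behavioural model

Looks are intervals coded `left`/`right`; looks away or to the centre are
uncoded. Uncoded gaps terminate a look; a switch is counted at every pair of
consecutive coded looks on different sides, whether or not a gap intervenes.
Trials with zero coded looks are uncodable and excluded (never zero-filled);
a participant enters group analyses only with ≥ 1 codable trial at every
load. Loads map to item counts by age band: 1/2/3 items under 24 months,
2/4/6 items otherwise, labelled low/medium/high.

Statistics: the one-sample chance test uses a one-tailed (greater) p and
Cohen's d = (mean − 0.5)/SD. The load ANOVA is a one-way repeated-measures
decomposition with η² = SS_load/SS_total and Bonferroni-corrected paired
pairwise tests (the familywise scheme is a package choice). Forward
regression enters, at each step, the candidate with the smallest partial-F
p-value if p ≤ 0.05 (the conventional entry criterion; configurable).
The outlier-robustness check removes points with either coordinate outside
mean ± 3 SD and asks whether the significance status survives refitting;
associations are reported without multiple-comparison correction by
default, matching common practice in this literature (an FDR switch
exists and is off by default).

## Optical chain

The stage order is fixed and enforced by container tags:
intensity → OD → tPCA → motion detection → trial rejection → band-pass →
Beer–Lambert → GLM.

- **OD convention.** OD(t) = −ln(I(t)/⟨I⟩) with the channel's temporal mean
  as reference, so constant signals map to zero. Because the tabulated
  molar extinction coefficients (Prahl/Gratzer compilation: at 690 nm
  ε_HbO = 276, ε_HbR = 2051.96; at 830 nm ε_HbO = 974, ε_HbR = 693.44, all
  base-10, 1/(cm·M)) are decadic, they are multiplied by ln 10 wherever
  they enter OD-domain equations; concentrations remain in molar units.
  The simulator uses the matching inverse, I = I₀·e^(−OD), with I₀ = 1.
- **Targeted PCA** estimates principal components over the union of
  contaminated samples (across channels) and removes the leading set
  explaining ≥ 97 % of segment variance, within those samples only. The
  segment mean is treated as part of the artifact (no centering), so a
  common step/spike is removed rather than preserved in the mean.
- **Motion detection** flags, per channel and wavelength, samples whose
  1-s-window excursion (max − min, sliding step one sample) exceeds
  50 × the channel SD or 0.67 OD, then dilates flags by ±1 s. Trial
  rejection drops any trial whose [−1 s, +10 s] window intersects the
  union mask (a per-channel option exists).
- **Band-pass** is a 3rd-order Butterworth, 0.016–0.5 Hz, applied
  forward–backward (zero phase). Padding is value-continuous ("even") and
  long (6/low seconds, capped at the record length): with a 0.016 Hz edge,
  odd reflection injects a broadband edge transient through the passband
  that can exceed the stopband floor by three orders of magnitude.
- **Beer–Lambert inversion** solves the per-channel 2×2 system
  ΔOD(λ) = ln10·ε(λ)·[ΔHbO, ΔHbR]·d·DPF(λ) at every sample; d is the
  source–detector distance in cm and DPF defaults to 6.0 at both
  wavelengths (configurable; the pathlength factor for young children is
  uncertain and any constant choice rescales concentrations uniformly).

## GLM

The HRF h(t) = e·u·e^(−u), u = ((t−τ)/σ)², peaks at exactly 1 at t = τ + σ
(3.1 s for HbO with τ = 0.1, σ = 3; 4.8 s for HbR with τ = 1.8). The
formula is symmetric about τ, so h is truncated to 0 for t < τ: an impulse
response must be causal. Condition regressors are unit impulses at retained
onsets convolved with the kernel (a 10-s boxcar option exists, off by
default); nuisance columns are an intercept and a linear drift — the
band-pass leaves slow residual drift that would otherwise bias condition
betas. OLS is solved per channel and chromophore by `lstsq`; rank
deficiency is a hard error naming the collinear columns.

## Forward model and masks

Channel sensitivity volumes are parametric stand-ins for photon-transport
simulations: for each channel,
F = A·exp(−d_arc/width − d_mid/axial_scale), where d_arc is distance to an
arc joining source and detector (dipping `depth_scale` = 10 mm below the
scalp plane), and d_mid the distance to the arc midpoint. The kernel is
nonnegative, peaks at the arc midpoint, is symmetric under source–detector
exchange, and decays exponentially — the properties the reconstruction and
mask logic rely on. Defaults (width 4 mm, peak amplitude 0.02 OD,
axial_scale = mean channel separation) make eight channels cover a
connected bilateral frontal patch on the default 20×20×10 grid of
2×2×2 mm voxels while the 10⁻⁴ OD threshold trims far voxels. The grid is
an abstract right-handed mm frame; no atlas registration is attempted.

Subject masks threshold the channel-summed profile at 10⁻⁴ OD; age-group
masks keep voxels covered by ≥ 75 % of subjects; the final analysis mask is
the intersection across age groups (empty intersection is a hard error).
Both constructions are anti-monotone in their thresholds by design.

## Image reconstruction

The measurement vector stacks OD-domain channel betas at λ1 then λ2,
β_dOD(λ) = d·DPF(λ)·ln10·(ε_HbO(λ)β_HbO + ε_HbR(λ)β_HbR). The Jacobian has
the 2×2 block structure [ε_HbO^λ·F^λ | ε_HbR^λ·F^λ] over masked voxels
(HbO columns then HbR), with the same d·DPF row scaling so the operator
pair is mutually consistent; a `include_dpf=False` switch reproduces the
bare ε·F form. The λ2/HbO block uses ε_HbO^λ2, as block symmetry requires.
One joint system is solved per condition across both chromophores.

Tikhonov inversion X = argmin ‖Y − LX‖² + λ‖X‖² is computed by SVD
filtering (s/(s²+λ)), numerically equivalent to the normal-equations form
but stable for ill-conditioned L. λ defaults to 0.01 × max diag(LᵀL) — a
scale-invariant shrinkage; λ = 0 with a singular LᵀL is refused with advice
to regularise.

## Group statistics

The per-voxel model is a repeated-measures ANCOVA with within factors
load (3) × chromophore (2) and centred age as a continuous between-subject
covariate, including age × within-factor interactions (the designs of
interest report chromophore × age effects, so the covariate must interact
with the within factors). It is computed by the classical univariate
decomposition: orthonormal within-subject contrasts reduce each stratum to
contrast scores that are regressed on [1, age]; each within effect is
tested against its own subject-interaction error stratum, the age main
effect against between-subject error. The implementation is fully
vectorised across voxels and assumes sphericity within strata (exact for
the 1-df chromophore stratum). Voxels with degenerate error variance
(relative SS below 10⁻¹²) are flagged and excluded from maps.

Cluster-extent correction simulates smooth Gaussian null fields matched to
the residual smoothness, thresholds two-sided at voxel p = 0.01 (the
voxel-level threshold is a package default; only the cluster-level
α = 0.05 is protocol), and returns the smallest cluster size c with
P(max cluster ≥ c) ≤ α. Smoothness is estimated from the lag-one
autocorrelation of standardised residuals (FWHM = √(8 ln 2)·σ with
σ² = −Δx²/(4 ln ρ)), floored at one voxel size since sampling cannot
resolve less. Cluster connectivity is face adjacency (6-connectivity) by
default, configurable to 18/26. Effect-priority classification labels each
voxel by its highest-priority significant chromophore-involving effect
(chrom×load×age > chrom×load > chrom×age > chrom); effects without a
chromophore term never label a voxel. The canonical-pattern rate is the
fraction of (participant, cluster) entries with opposite-signed HbO and
HbR betas; zero betas count as no pattern. In the median-split "ideal
pattern" classification, ties at the median are non-ideal (conservative
and deterministic).

## Synthetic-data generator

The generator emulates a field cohort of ~34 children aged 4–48 months:

- **Demographics** from truncated distributions matching the cohort's
  reported ranges (maternal education mean 7.94 y, SD 4.6, range 0–17;
  income range 25,000–200,000 with a log-normal shape; four age bands
  weighted 10/9/9/6). The SES composite is the mean of within-cohort
  z-scores of maternal education, paternal education, and log income —
  a documented stand-in for occupation-based scale tables that preserves
  monotonicity in education and income.
- **Looking sessions**: alternating exponential dwell times with side bias
  μ_change = 2·CP·μ̄, μ_other = 2(1−CP)·μ̄ (μ̄ = 1800 ms), equivalent to a
  two-state Markov process whose stationary occupancy equals the target
  CP; away gaps (probability 0.2, mean 500 ms) interrupt coding. Defaults:
  12 trials per load, 10 s trials, 5 s inter-trial interval.
- **Ground-truth effects**: baseline CP (0.55, 0.58, 0.50) at
  low/medium/high load, with an SES slope of 0.05 per SES-SD at the low
  and medium loads and participant noise SD 0.10 — yielding a latent
  SES→CP correlation ≈ 0.35–0.40, i.e. an R² near 0.13, the observed
  effect-size scale in this literature. A left-frontal Gaussian activation
  cluster (radius 6 mm, on a left channel's arc midpoint) has HbO
  amplitude 6 μM × load scaling (0.6/0.8/1.0), a maternal-education slope
  of 2.4 μM per education-SD, participant noise SD 6 μM, and
  HbR = −0.4 × HbO. The amplitude scale is set so that (a) evoked ΔHb sits
  in the physiological single-digit-μM range and (b) the education →
  *measured* activation correlation lands near r ≈ 0.4 (R² ≈ 0.15) after
  measurement noise — the effect is defined on the measured scale, so the
  signal-to-measurement-noise ratio is part of the calibration.
- **fNIRS forward model**: voxel time courses are HRF-convolved per
  chromophore and projected to channel OD through the same Jacobian the
  reconstruction inverts; noise adds 1/f drift (RMS 0.01 OD), cardiac
  (2.0 Hz, 0.005) and respiratory (0.4 Hz, 0.008) sinusoids with random
  phases, white noise (SD 0.003), and optional motion spikes (amplitude
  ~1 OD, 0.3 s width) at known times.

What the generator does **not** emulate: real optode-placement variability
and digitization error, scalp/skull partial-volume effects and depth bias
of real photon transport, serially correlated physiological noise beyond
the stated components, age-varying HRF shape, inter-coder disagreement in
look coding, or real atlas geometry. Passing tests therefore demonstrate
the correctness and calibration of the *pipeline* under known ground
truth, not field-data effect sizes; quantities tied to the undeposited
field data (cluster coordinates and sizes, specific F/R²/r values) are out
of reach by construction.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at deliberately modest sizes chosen to keep
Monte-Carlo error within the asserted bands: null calibration uses
1000–2000 replicates; the cluster familywise-error check uses 200 cohorts
of n = 12 on a 16×16×8 grid with 400–500 Monte-Carlo fields; sign-recovery
runs 40–100 cohorts of n = 34 on a 12×12×6 grid at 5 Hz. The end-to-end
localization check uses the default 20×20×10 grid with the 8-channel
probe, zero noise, and asserts peak recovery within one voxel.

## Known limitations

- The ANCOVA assumes sphericity in the 2-df strata; no
  Greenhouse–Geisser correction is applied (the chromophore effects of
  primary interest have 1 df and are exact).
- The cluster-threshold Monte Carlo uses Gaussian fields for F-statistic
  maps, the standard practical approximation; calibration is verified by
  simulation in the test suite.
- The parametric sensitivity kernel is not a transport solution; absolute
  reconstructed amplitudes are only meaningful relative to the generator's
  own forward model.
- Forward-selection inference (final-model F, p, R²) is reported without
  selection-adjustment, as is conventional for this procedure.
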