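# Methods

`topospect` implements a sensor-space spectral statistics pipeline for
dense-array EEG together with a synthetic-data generator that emulates a
five-participant within-subject memory-recall study (hypnosis vs normal
consciousness × near-death-experience vs autobiographical memory ×
recall phase). This note documents the models, the numerical choices,
and what the simulations do and do not establish.

## The analysis model

**Dependent variable.** Clean recordings are segmented into
non-overlapping 30-s windows per condition block. Any window whose
overlap with marked artifact segments strictly exceeds 5 s is rejected.
Within each retained window the one-sided Welch spectrum is estimated
(1-s Hann segments, 50% overlap, giving 1-Hz bins), and each frequency
band is reduced to the RMS of log power,
`sqrt(mean(log(psd)^2))` over the band's bins. The natural logarithm is
used (the base is not scientifically identified by the statistic; it
rescales all bands jointly) and the PSD is floored at 1e-12 µV²/Hz
before the log so silent synthetic channels stay finite.

Two band presets ship: `methods` (delta 0.5–3.5 Hz, alpha 9.5–11.5 Hz,
low-beta 16.5–19.5 Hz) and `results` (delta, theta 7–8 Hz, alpha
10–11 Hz), with `band_difference` providing the "specific alpha"
(alpha − theta) contrast. `propose_bands` offers a reproducible
surrogate for visual band selection: a robust log-log linear background
fit per scalp region, with contiguous runs of bins exceeding the fit by
2 robust SDs (and an absolute floor of 0.05 log units) proposed as
bands.

**Per-channel mixed model.** For one channel and band,

    power_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, tau²),  e_ij ~ N(0, sigma²)

with participant random intercepts `u_i`. The fixed-effect design
crosses three binary factors — HY_NC (hypnosis = 1), NDE_AUTOBIO
(NDE memory = 1), OBE_PE (peacefulness phase = 1; the out-of-body and
kinaesthetic phases form the reference level, matching how the recall
phases pair across memories) — plus their interactions and the
covariates age and hypnotic-susceptibility score, entered z-scored for
conditioning at n = 5 participants (a raw option exists).

Fits maximise the *full* likelihood (not REML) because the model ladder
varies the fixed effects and is compared by AIC and likelihood-ratio
tests; REML likelihoods are not comparable across fixed-effect
structures. With a single random intercept the likelihood concentrates
to one scalar, the variance ratio λ = tau²/sigma². For fixed λ the GLS
solution is a partial group-demeaning transform
(`y* = y − θ_i ȳ_i`, `θ_i = 1 − (1 + n_i λ)^(−1/2)`) followed by OLS,
and sigma² is profiled in closed form; λ is then maximised by bounded
scalar search on log λ with the λ = 0 boundary checked explicitly. This
is exact for the model class, boundary-safe, and fast enough to sit
inside the permutation loop. The test suite verifies agreement of
log-likelihood, coefficients, T-values and variance components with an
independent general-purpose mixed-model implementation.

Model selection happens once, at an a-priori reference channel (the
vertex sensor by default), over a hierarchy-respecting ladder from the
intercept-only model to the full three-way interaction with covariates.
The simplest model within 2 AIC units of the ladder minimum is chosen
(2 units is the conventional "indistinguishable" margin; configurable).
Likelihood-ratio tests of a term drop the term *and* every interaction
containing it, and the χ² degrees of freedom equal the parameter-count
difference of the nested pair.

**TFCE.** A per-channel T-map is enhanced as

    TFCE(c) = Σ_h extent(c, h)^E · h^H · Δh

where `extent(c, h)` is the size of the connected suprathreshold
component containing channel `c` in the sensor adjacency graph.
Defaults follow the EEG-TFCE literature: E = 0.666, H = 2, with 100
midpoint-rule integration steps between 0 and the map maximum (an
optional fixed upper limit `h_max` makes the threshold grid
map-independent, which restores exact monotonicity of the transform
under pointwise increases of the statistic). Enhancement is two-sided
by default: the negative part is enhanced on the negated map and
re-signed. Components are maintained incrementally with union-find over
descending thresholds; the suite checks exact agreement (1e-9) with a
brute-force threshold-loop oracle and the isolated-peak closed form
T^(H+1)/(H+1).

**Permutation inference.** The family-wise null relabels the
NDE_AUTOBIO factor. The exchangeability unit is the whole condition
block within a participant: windows inside a block are autocorrelated,
so they keep a common label. Phase labels and the covariates are held
fixed under relabelling (the phase–memory pairing is broken by design;
relabelling only the memory factor targets exactly that factor's null).
For each of the 2,200 (default; 200 in the scaled bench) relabelled
datasets every channel is refit and the maximum |TFCE| over channels
enters the null distribution; channel p-values use the add-one
estimator `p(c) = (1 + #{max_k ≥ obs_c}) / (1 + n_perm)`, so p = 0 is
impossible. Designs with fewer distinct relabelings than requested
permutations are enumerated exhaustively. Because the three bands are
tested as a family, the per-band cut-off is the family α divided by 3
and truncated to three decimals (0.05 → 0.016), reproducing the
convention of the emulated study.

Under permutation each channel's variance ratio λ is frozen at its
observed-data estimate while beta and sigma² are re-estimated by GLS.
On the observed labels this reproduces the full ML T-values exactly
(verified to 1e-9 in the suite); under relabelled designs it is the
standard fixed-components approximation that makes 10^5-fold refitting
tractable. Relabelings that make a term unidentifiable (a rank-deficient
design, e.g. an interaction column becoming all-zero) contribute T = 0
for that term. The null-calibration simulation in the acceptance suite
is the empirical check that these approximations preserve family-wise
error control.

## The synthetic-data generator

The generator draws from the same linear mixed model the analysis
assumes: per participant, channel, band and 30-s window,

    log-power = mu_band + u_participant + Σ matching effects + eps

with `mu_band` the band baseline implied by a 1/f^slope background
(log density at the band's geometric-mean frequency, anchored at
20 µV²/Hz ≈ e³ at 10 Hz — a realistic eyes-closed scalp magnitude that
keeps all log powers positive so the RMS-of-log reduces to the mean
log). Defaults, chosen once as the study conditions: 5 participants with
the published ages and susceptibility scores, eight 2-minute phase
blocks per participant in the bench preset (10-minute blocks, i.e.
20-minute recalls, in the full preset), 250 Hz sampling, participant SD
0.3, window SD 0.5 log units, and 2 s of artifact per minute arriving
as contiguous high-amplitude segments with exponential inter-arrival
times and 2-s mean duration (so the >5-s window-rejection rule is
exercised at a realistic few-percent rejection rate). Condition effects
are specified on the log-power scale as additive shifts on named
channel sets; the emulated study reports no raw-scale effect sizes, so
the bench effect magnitude (0.8 log units) is a statistical-power
choice, not a fidelity claim.

Two paths share these draws. The fast path emits the window table
directly. The signal path synthesises each 30-s window by inverse-FFT
shaping of Gaussian noise: inside each analysis band the one-sided PSD
is set to exp(target log power) exactly, outside it the 1/f background
remains; artifacts are added as broadband 200-µV excursions and
annotated. The Welch stage therefore faces a signal whose true band
power is known.

What the generator does *not* emulate: volume conduction and spatial
correlation between channels (channels are independent given the
participant intercept), non-Gaussian artifact morphology (eye blinks,
muscle), line noise, drift, or any temporal autocorrelation beyond the
block structure. Passing tests show the statistics behave correctly
when the model's assumptions hold and artifacts follow the annotated
segments; they do not certify performance on real scalp data, where
interpolation, referencing and ICA quality dominate.

## Preprocessing

First-order Butterworth high-pass at 0.1 Hz, then a second-order
Butterworth band-stop at 48–52 Hz for mains suppression. Both are
applied forward-backward (zero phase): the latency of a causal pass
would shift features relative to the annotations, and the effective
magnitude response is the squared one-pass response, which the tests
check against the transfer-function oracle. Non-session data is removed
by cropping to the condition annotations, remapping artifact spans onto
the concatenated timeline. Channels marked bad are replaced by
spherical-spline estimates (truncated Legendre kernel, order m = 4,
50 terms, ridge 1e-5), refusing when more than half the montage is bad;
independent-component cleaning is accepted as an upstream, externally
produced step and is not computed here. Average re-referencing subtracts
the per-sample channel mean and can restore the original (flat)
reference channel first, so a 256-channel input yields the full
257-channel montage.

## Phenomenology statistics

Wilcoxon signed-rank tests with the normal approximation: zero
differences dropped before ranking (Pratt handling available), average
ranks with the usual tie correction of the variance, no continuity
correction by default, two-sided p = 2(1 − Φ(|Z|)), and effect size
r = Z/√N with N counting both paired observations (N = 2 × pairs).
These conventions are the unique combination that reproduces the
printed Z → p and Z → r mappings of the emulated study. An exact
enumeration p accompanies every result: with five pairs the exact
two-sided p cannot fall below 1/16 = 0.0625, so near-0.04 p-values at
this sample size are necessarily normal-approximation values — both are
reported so the reader can see the distinction. Instrument scoring
(Greyson 16×{0,1,2} with NDE cut-off ≥ 7, SHSS:C bands low ≤ 4 /
medium 5–7 / high ≥ 8, MCQ 16×[1,7] totals, 100-mm VAS → 0–10) is
validated against the published bounds.

## Problem sizes

The bench simulations use the scaled preset — 8 channels, 5
participants, 2-minute phase blocks (≈ 32 windows per participant), 200
permutations — sized so that null calibration (200 replicates) and
power (50 replicates) runs complete on a single CPU in minutes while
retaining the full design structure. The full 257-channel, 20-minute
preset is available through the same configuration surface.

## Known limitations

- The permutation engine freezes each channel's variance ratio at the
  observed estimate; with very few participants and strong
  heteroscedasticity across relabelings this is approximate (the
  calibration simulation is the guard).
- Degrees-of-freedom corrections (Satterthwaite/Kenward–Roger), random
  slopes and crossed random effects are out of scope.
- EDF export requires an optional backend; the plain-text CSV round
  trip is the supported offline path.
- TFCE is spatial only (channel × band), not spatio-temporal.
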