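# Methods

This note documents the models, estimators, numerical choices and known
limitations of `envlrtc`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## DFA of amplitude envelopes

The estimand is the Hurst exponent `H` of a narrowband amplitude
envelope.  The chain is: band-pass FIR filter → analytic-signal modulus →
cumulative profile with global linear detrend → per-scale cubic local
detrending of non-overlapping segments → mean of per-segment RMS →
unweighted least-squares slope of `log₁₀ F(s)` vs `log₁₀ s`.

Numerical choices:

- **Segmentation** starts at sample 0, forward only; the trailing partial
  segment is discarded.  No reversed second pass is used.
- **Fluctuation** is the *mean of per-segment RMS values*, not the RMS of
  pooled residuals.  The two differ when segment variances differ.
- **Local detrending** projects each segment onto an orthonormalised cubic
  polynomial basis (QR of a centred, scaled Vandermonde matrix).  This is
  algebraically identical to per-segment least-squares polynomial fits and
  is verified against a naive `polyfit` loop to 1e-10 relative error.
- **Scale grid**: 20 log-spaced scales from `8 · fir_len` samples to
  `n_samples // 8`, floored to integers with endpoints kept exact;
  duplicates from rounding are collapsed with a warning.  The lower rule
  keeps filter-induced short-range autocorrelation out of the fitting
  range; the upper rule guarantees ≥ 8 segments per fluctuation average.
  For the five default bands at 250 Hz and 180 s this gives minima of
  4.00, 2.016, 1.216, 0.992 and 0.736 s and a common maximum of 22.5 s.
  (With a 38-tap sigma kernel the exact minimum is 1.216 s; a 39-tap
  reading would give 1.248 s.  The rule, not a hard-coded constant, is
  exposed.)
- **Fit** in base 10 (the slope is base-invariant), unweighted; the log-log
  R² is reported as a linearity diagnostic.  Any non-positive fluctuation
  raises a degenerate-fit error naming the offending scale.

### Finite-range behaviour of surrogate envelopes

The envelope of band-pass filtered white noise is a short-memory process:
its asymptotic DFA slope is 0.5.  However, the filter and the Hilbert
modulus induce short-range autocorrelation whose influence on the
fluctuation function decays only slowly with scale, so over the canonical
2.02–22.5 s alpha-band fitting range the *measured* mean exponent of such
surrogates is ≈ 0.56 rather than 0.50.  Two independent implementations
(the package's vectorised path and a naive `lfilter` + per-segment
`polyfit` loop) agree on this value, and extending the same construction
to 30-minute records yields 0.498 over 22.5–225 s, confirming it is a
finite-range crossover effect rather than estimator bias.  The surrogate
suite therefore reports what the canonical procedure actually measures;
readers comparing against the theoretical 0.5 should expect this offset.

## Band-pass filters

All filters are Hamming-windowed sinc FIRs (linear phase).  The analysis
bands at 250 Hz are theta 4–8 Hz (125 taps), alpha 8–12 (63), sigma 12–15
(38), beta-1 15–22 (31), beta-2 22–30 (23) — short kernels whose length
scales inversely with centre frequency, trading frequency selectivity for
temporal locality.  The broadband conditioning filter (0.75–65 Hz with
0.2 / 5 Hz edge transitions) is realised as a high-pass ⊗ low-pass kernel
cascade, because a single windowed-sinc kernel cannot carry two different
transition widths.

Zero-phase application uses a single pass with the (L−1)/2 group delay
compensated (for even-length kernels a half-sample delay remains, which is
irrelevant to envelope statistics).  Forward–backward filtering is
deliberately *not* used: it would double the effective filter order and
thereby invalidate the 8×-filter-length scale minimum.  Filter edge
transients (one kernel length at each end, accumulated over repeated
filtering) are recorded on the `Recording` and excluded from envelopes
before DFA.  Whether band filtering of real data should be zero-phase or
causal is not settled; zero-phase is the default and the only path the
synthetic tests exercise.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, so every downstream stage is testable without real recordings.
What it emulates, and what it does not, bounds what passing tests mean.

- **fGn** (fractional Gaussian noise) is synthesised by circulant
  covariance embedding: the wrapped autocovariance of `n` samples is
  embedded in a `2n` circulant whose FFT eigenvalues are provably
  non-negative for fGn, giving exact-covariance draws with no burn-in.
  Ensemble checks verify lag 1–5 autocovariances against the closed form
  `ρ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`.
- **Band oscillations** impose a strictly positive envelope
  `env = 1 + depth · standardized fGn` (floored at 1e-3, floor events
  logged) on a constant-amplitude carrier whose instantaneous frequency
  drifts slowly inside the band (σ = bandwidth/12, 0.5 Hz drift
  bandwidth).  Two alternatives were rejected: multiplying onto a
  noise-carrier's own Rayleigh-fluctuating envelope contaminates the
  planted scaling with an H = 0.5 component large enough to break ±0.05
  recovery, and phase-only carriers (band-filtered noise with the
  amplitude stripped) suffer phase slips that spread > 10% of power out
  of band.  The default modulation depth is 0.3: DFA is invariant to
  affine envelope transforms, so depth does not affect recovery, while
  lower depth keeps ≥ 90% of signal power inside the band (the fGn
  modulation is spectrally broadband and its sidebands are the dominant
  out-of-band leak).  The drift is kept small because the analysis
  filters have sloping passbands that convert frequency wander into
  spurious slow amplitude modulation (FM-to-AM conversion); at
  bandwidth/12 this contribution is negligible.
- **Cohorts**: ISI scores are integers drawn uniformly on [8, 28] for the
  insomnia group and [0, 7] for controls, matching the sub-clinical
  cutoff of 8 that separates the groups.  (The 7-item × 0–4 structure of
  the instrument implies a 0–28 ceiling; published descriptions sometimes
  state 0–25; the generator follows the instrument.)  Planted structure is
  `H(p, e, b) = base_h + slope · ISI_p · 1[(e,b) ∈ group mask] + ε`, with
  independent Gaussian ε per bin and clipping to (0.5, 1) — the range in
  which wake-EEG envelope exponents are observed.  Defaults: base 0.7,
  slope 0.005 /ISI-point, noise SD 0.02, with 52 ID + 43 CTRL.  The
  default group masks couple posterior ("parietal") theta bins to ID and
  anterior ("centro-frontal") beta-1 bins to CTRL.
- **Signal-level cohorts** sum one oscillation per band per channel (unit
  RMS each) plus a white noise floor (5% RMS).  End-to-end recovery of
  planted `H` through the full filter → envelope → DFA chain achieves a
  mean absolute error < 0.07 at 180 s; the residual error combines
  per-channel DFA sampling noise with a small positive bias from the
  analysis filters stripping the envelope's high-frequency sidebands.

Not emulated: eye/muscle/cardiac artifacts, line noise, volume
conduction and cross-channel correlation, cross-frequency coupling, and
1/f broadband background.  Passing tests therefore demonstrate the
correctness and calibration of the estimators and inference on clean,
structurally faithful signals — not robustness to real-world artifacts,
which the out-of-scope cleaning pipeline of a real study would address.

All randomness flows from per-object integer seeds through numpy
`SeedSequence` spawning, so every artefact is bit-reproducible.

## Cohort-level statistics

- **Aggregates**: grand-median `H` over the electrode × band plane per
  participant; per-band median across electrodes.
- **GLM**: `H ~ group + ISI + group:ISI` with type-II sums of squares
  (each main effect adjusted for the other, interaction adjusted for
  both), via statsmodels OLS + ANOVA.  Rank-deficient designs raise.
- **Rank-sum** group tests use the tie- and continuity-corrected normal
  approximation; with ≥ ~40 per group the exact small-sample path is
  unnecessary and not provided.
- **Spearman associations** use midranks; the t approximation
  `t = ρ√((n−2)/(1−ρ²))` with df = n − 2 supplies p-values.  Bootstrap
  CIs are percentile-based over paired resamples (default 1000);
  degenerate (constant) resamples are redrawn and counted.  A band's
  association is flagged *robust* when > 97.5% of bootstrap correlations
  share the point estimate's sign.
- **Eyes-open vs eyes-closed contrast**: per-band Wilcoxon signed-rank on
  across-electrode median `H` (EO − EC), plus the same test on the
  across-electrode interquartile range as a between-participant
  dispersion contrast.  No canonical test exists for the dispersion
  question; the signed-rank-on-IQR choice is this package's design
  decision.
- **Within- vs across-group correlation**: reported as within-ID,
  within-CTRL and pooled Spearman correlations plus a bootstrap
  distribution of (mean within − pooled), a non-canonical but transparent
  contrast for "the association holds within groups rather than across".

## TFCE inference

Per-bin Spearman t maps over the electrode × band lattice are enhanced as
`t_tfce(b) = Σ_k extent_k(b)^e · h_k² · dh` with e = 0.66, h = 2 (the
random-field-theory-derived defaults), where `extent_k(b)` is the size of
the connected component containing bin `b` among bins with |t| ≥ h_k.
Choices:

- **Threshold integration**: 100 midpoint steps from 0 to the map's max
  |t| (per-map dh).  Doubling the step count changes enhanced values by
  well under 1%; the isolated-bin case converges to the closed form
  `∫₀ᵗ h² dh = t³/3` within 0.01% at 100 steps.
- **Signs**: |t| is enhanced and the sign reattached (sign-symmetric
  enhancement); negative associations are treated symmetrically.
- **Connectivity**: electrodes are neighbours when their montage distance
  is ≤ the configured radius; bands are chained in spectral order
  (theta–alpha–sigma–beta1–beta2) with no wrap-around; bin neighbourhoods
  combine both, with no "diagonal" links.
- **Implementation**: a descending-threshold incremental union-find
  (numba-compiled) computes all extents in one sweep; it is tested for
  exact equality against a python flood-fill threshold loop.
- **Null**: maximum |t_tfce| over all bins per permutation of ISI across
  participants (max-statistic familywise correction, the standard choice
  consistent with multiple-comparison control); corrected
  `p = (1 + #{null ≥ |t_tfce|}) / (n_perm + 1)`, never zero.
- **Summaries** per band: extent = number of electrodes with p < 0.05,
  the peak bin (minimal p, ties broken by larger |t_tfce|), and marginal
  electrodes with 0.05 ≤ p < 0.1 listed separately.
- Constant-H bins (possible in degenerate synthetic settings) are flagged,
  excluded from enhancement, and warned about.

Calibration, computed by the test suite at reduced permutation counts for
runtime: on 200 null cohorts (no planted effect, n_perm = 200) the
proportion with any corrected p < 0.05 lies within [0.02, 0.08]; on 50
cohorts with a 6-electrode posterior-theta planting (slope 0.006 /point,
noise 0.02, n = 95) the theta extent is nonzero in ≥ 80%.

## Pipeline and problem sizes

`run_pipeline` executes preprocess → DFA → statistics → TFCE per
condition, joins EO/EC only in the condition contrast, and writes TSV
tables, a JSON report (finite values enforced) and a manifest (config
hash, package version, input checksums, stage timings).  Reruns with the
same config and seed are byte-identical except for manifest timings.

Default parameters (sampling 250 Hz, 180 s segment, 20 scales, cubic
detrend, 1000 bootstrap and permutation iterations, α = 0.05, TFCE
e = 0.66 / h = 2) are collected in `AnalysisConfig`, which rejects unknown
keys.  The broadband filter and common-average reference are off by
default: synthetic signals are band-limited and channel-independent by
construction; both switches exist for real-data use.

Test and example problem sizes are chosen to exercise the full chain at
statistically meaningful scale while staying desk-sized: 9–16 electrode
montages, 5 bands, 95-participant cohorts at the H-matrix level, 180 s
signal-level cohorts of ~12 participants, and 150–500 permutations /
bootstrap iterations in tests (1000 in the canonical defaults).

## Known limitations

- The synthetic envelope construction plants exact fGn scaling; real
  envelopes need not be Gaussian or exactly self-similar, and real-data
  effect sizes are not reproduced (no real data ships with the package).
- The analysis filters' wide transition bands (short kernels) mean the
  per-band envelopes are not sharply band-limited; cross-band leakage is
  small but nonzero for adjacent bands.
- Rank-sum and signed-rank tests use normal approximations; do not use
  them for very small groups.
- The EO/EC dispersion contrast and the within-vs-across comparison are
  reasonable but non-canonical constructions (documented above).
- Multifractal DFA, DFA of frequency (rather than amplitude)
  fluctuations, and scales below 8× the filter length are out of scope.
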