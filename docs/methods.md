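# Methods

## Scope and model

`fretbind` analyzes two observables of a surface-tethered single-molecule
binding assay — first-arrival times after sample injection and bound-state
dwell times — together with ensemble equilibrium titrations. The underlying
kinetic picture is a two-state (unbound/bound) Markov process per target
molecule: binding is a Poisson arrival at rate k_on(obs)·[protein], and
unbinding is exponential, possibly as a mixture of two populations (e.g.
complexes that did or did not engage the t1 nucleotide in the Argonaute
t1-pocket system). Equilibrium binding is a single site with one K_D per
condition.

## Synthetic-data generator

`simulate_traces` draws, per molecule, a continuous-time alternating renewal
path: exponential waits to each binding event at rate k_on(obs)·c (the same
law for first and subsequent arrivals — only first arrivals are analyzed, so
this choice affects nothing downstream), and bound dwells from the mixture
p_long·Exp(τ_long) + (1−p_long)·Exp(τ_short). `p_long` is defined as the
probability that an *event* belongs to the long-lived population, i.e. the
event-count fraction, which is exactly what the amplitude formula
A₁Δτ₁/(A₁Δτ₁+A₂Δτ₂) estimates from a fitted histogram — so simulation truth
and fitted fractions are directly comparable. The path is sampled on the
camera grid (default 0.1 s) and rendered as two intensity channels:
acceptor = E·I_total, donor = (1−E)·I_total with state-dependent FRET
efficiency E plus independent Gaussian noise per channel. There is no
blinking, no spectral crosstalk, no gamma correction, and photobleaching is
off by default (an optional exponential bleach time exists for robustness
studies); passing tests on these data therefore validates the estimators,
not robustness to photophysics artifacts absent from the model.

Defaults are the study conditions of the t1-nucleotide system: frame 0.1 s,
k_on(obs) 0.033–0.041 s⁻¹ nM⁻¹, dwell parameters per condition
(t1U: single τ 1.64 s; t1A: 1.61/8.69 s at 49.8/50.2%; t1DAP: 1.97/12.87 s
at 44.6/55.4%), flow start 5 s. The protein concentration during imaging is
a free parameter (default 1 nM, not dictated by the system); trace duration
defaults to 300 s (5 min movies, long relative to both dwell scales so
right-censoring is rare) and 300 molecules per condition, sizes at which the
pipeline estimates settle within a few percent while a full three-condition
study runs in seconds on one core.

`simulate_isotherm` evaluates the exact quadratic-depletion fraction bound
at the true K_D (receptor fixed at 0.1 nM, titration 0–70 nM roughly
log-spaced) and adds i.i.d. Gaussian noise (default SD 0.02, a typical
dot-blot quantification scatter) per replicate (default 3), clamped to
[0, 1]. The clamp makes extreme noise non-Gaussian; at the default SD it is
almost never active.

All randomness flows from one integer seed through `numpy` `SeedSequence`
spawning, so outputs are bit-identical across runs and independent of
iteration order.

## Trace processing

FRET efficiency is the background-corrected proximity ratio
E = (A−bg_A)⁺ / ((D−bg_D)⁺ + (A−bg_A)⁺); frames with zero corrected total
are NaN and hold the previous idealized state. Idealization is hysteresis
thresholding (enter bound at E ≥ 0.6, leave below 0.4, both configurable)
followed by merging runs shorter than `min_frames` (default 2) into their
surroundings, shortest runs first for determinism. No HMM or change-point
method is used: at the assay's contrast (ΔE ≈ 0.8 against noise SD ≲ 0.1)
thresholding recovers ≥ 95% of frames, and dwell estimation downstream
excludes the sub-resolution events where idealization methods differ.

Contiguous bound runs become events with dwell = run length × frame
interval. Events touching the trace start are left-censored (dropped from
dwell fitting — their start is unknown); events touching the end are
right-censored (dwell is a lower bound). First arrival is the start of the
first non-left-censored event at or after flow start.

Known resolution limits, present even with ground-truth states: unbound
gaps shorter than one frame are invisible, merging adjacent events and
inflating a 1.64 s time constant by about +1% at 1 nM; events shorter than
half a frame are lost entirely (they fall below the analysis truncation
anyway).

## Dwell-time fitting

Two routes estimate the same quantities.

*Histogram least squares* mirrors the classic procedure: uniform bins from
zero (default 0.5 s), counts normalized by the total event count, first bin
excluded from the fit mask (time-resolution artifacts), unweighted
least-squares fit of Ae^(−t/τ) or the two-component sum at bin centers
(Poisson-weighted LS is available as an option). Right-censored events
cannot enter a histogram and are excluded. Two identifiability guards apply
to the two-component fit: amplitudes are capped at 1.5 — a normalized
histogram cannot place more than the whole sample in one bin, and without
the cap the optimizer can build a quasi-delta component hidden under the
excluded first bin — and a fitted short τ below the excluded-bin boundary
collapses the fit to one component, since most of such a population's
events would sit inside the excluded bin and its weight would be pure
extrapolation. Fits with τ₁ ≈ τ₂ (ratio < 1.05) likewise collapse.

*Truncated maximum likelihood* is bin-free and is the scientific default:
the mixture likelihood is left-truncated at the same time value as the
excluded bin. On frame-quantized dwells a continuous density likelihood is
unbounded (a component can collapse onto the atom at the truncation point),
so when a `resolution` is given each dwell d contributes the interval
probability S(d−Δ/2) − S(d+Δ/2) at frame interval Δ. Right-censored dwells
may be retained as survival terms S(d); the pipeline does so (excluding
them biases the average dwell low by the share of long events cut off at
the trace end), while `fit_dwell_distribution` keeps exclusion as its
default. Mixture weights are parameterized as *untruncated* event-count
fractions, so LS amplitudes-with-formula and MLE weights estimate the same
population shares. Optimization is multi-start L-BFGS-B over
(logit w₁, log τ₁, log τ₂); the single-component truncated MLE is the
shifted sample mean (total exposure over completed events under censoring)
or a 1-D search in interval mode.

Standard errors come from the LS covariance or the inverse numerical
Hessian of the negative log-likelihood with a delta-method transform; no
bootstrap. Components are reported with τ ascending, ties broken by larger
amplitude.

*Model selection* between one and two components uses the extra-sum-of-
squares F-test (α = 0.01) in LS mode and BIC in MLE mode, with the
likelihood-ratio statistic reported alongside; both R² values are also
reported so the informal goodness-of-fit comparison is visible. The
unweighted F-test is anti-conservative on multinomial histograms (early
bins carry more variance than the tail), which is one more reason the
identifiability guards above matter; BIC is conservative and is the
default decision rule wherever the MLE route runs.

## Association fitting

First arrivals are accumulated into count(arrival ≤ t)/n_targets on the
frame grid and fit by least squares with A(1−e^(−kt)); k_on(obs) = k/c.
Molecules that never bind keep the plateau A below 1, which is why A is
free. The asymptotic SEs treat the cumulative curve's points as
independent, which they are not; they understate the replicate-to-replicate
spread and are reported as fit diagnostics only. An all-zero curve returns
a failed fit whose rate is 0 and whose amplitude is NaN rather than
fabricated parameters.

## Equilibrium fitting and comparisons

The default isotherm model is the quadratic single-site depletion solution,
because the labeled target (0.1 nM) is comparable to the K_D values
(0.45–1.9 nM) and the hyperbolic form would overestimate K_D there (the two
agree within 1% once receptor ≤ K_D/100). b_max is free, capped at 1.05
(blot transfer efficiency need not reach 1). All replicate points are fit
jointly for the headline K_D; each replicate is also fit alone to provide
per-replicate K_D values for the cross-condition test. Fold changes are
plain K_D ratios with first-order error propagation. The replicate
comparison is the classical pooled-variance two-tailed unpaired Student's
t-test in closed form (Welch is available as scipy cross-check in the test
suite); two zero-variance groups with equal means return t = 0, p = 1.

## Pipeline and reporting

`run_pipeline` executes simulate → process → fit → compare for a dictionary
of smFRET conditions and a K_D ladder, writing `report.json` (sorted keys,
numbers at 6 significant digits — the serialization contract that makes
equal-seed runs byte-identical), a human-readable `summary.txt`, and
per-stage CSV tables. Every stage's settings and derived child seed are
echoed in the report. A condition with no binding events (e.g. zero
concentration) is reported as such and no dwell fit is attempted.

## Known limitations

- No donor/acceptor crosstalk, gamma correction, blinking, or bleaching
  correction; the intensity model is two-level plus Gaussian noise.
- At most two mixture components; no global fitting across conditions; no
  k_off-vs-concentration series.
- Dwell populations with τ below the first-bin boundary (0.5 s by default)
  are declared unresolvable rather than extrapolated.
- The F-test/BIC selection assumes nested exponential families; heavy-tailed
  dwell distributions outside the mixture family will favor order 2 for the
  wrong reason.
- Isotherm noise is homoscedastic Gaussian; real blot noise is often
  signal-dependent.
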