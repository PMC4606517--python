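# fretbind

Single-molecule FRET binding kinetics and equilibrium-affinity analysis for
protein–RNA interaction studies, built around the question of how human
Argonaute2 (Ago2) recognizes the target nucleotide opposite microRNA
position 1 (the *t1* nucleotide). An adenosine at that position (t1A) — and
even more so its analogue 2,6-diaminopurine (t1DAP) — anchors Ago2 on
seed-paired target sites, and the signature of that anchoring is kinetic:
association is unchanged, but a second, long-lived population of binding
events appears.

The package is aimed at single-molecule biophysicists who have donor/acceptor
intensity traces (or want to simulate them) and dot-blot binding titrations,
and who need the complete chain from raw observables to fitted rate constants,
population fractions, dissociation constants, and cross-condition statistics —
with a synthetic-data generator so every stage is testable without microscopy
data.

## The models

**Association.** After sample injection, the time to each immobilized
target's first binding event is exponential. The accumulated fraction of
targets bound by time *t* is fit with the single-exponential growth curve

    f(t) = A (1 − e^(−k·t)),      k_on(obs) = k / [Ago2]     (s⁻¹ nM⁻¹)

**Dissociation.** The dwell time Δτ of a binding event follows a one- or
two-component exponential mixture. A fitted double-exponential decay
A₁e^(−t/Δτ₁) + A₂e^(−t/Δτ₂) resolves two populations whose event-count
shares and event-weighted mean dwell are

    pᵢ = AᵢΔτᵢ / (A₁Δτ₁ + A₂Δτ₂),
    ⟨Δτ⟩ = (A₁Δτ₁² + A₂Δτ₂²) / (A₁Δτ₁ + A₂Δτ₂) = p₁Δτ₁ + p₂Δτ₂.

Two fitting routes are provided: histogram least squares on event-normalized
dwell histograms with the first bin excluded (events at the 0.1 s camera
resolution limit are unreliable), and a bin-free maximum-likelihood fit of
the mixture left-truncated at the same boundary, using interval probabilities
at the frame resolution and survival terms for right-censored events.

**Equilibrium.** Dot-blot titrations (0–70 nM Ago2-guide against 0.1 nM
labeled target) are fit with the single-site quadratic depletion solution

    bound/R = b_max · ((P + R + K_D) − √((P + R + K_D)² − 4PR)) / (2R),

because the labeled target (R = 0.1 nM) is comparable to the sub-nanomolar
K_D values; the hyperbolic form b_max·P/(P + K_D) is available for
comparison. Conditions are compared by fold change (K_D ratio) and a
two-tailed unpaired Student's t-test on replicate K_D values.

## Worked example

Run the full synthetic study — three smFRET conditions (t1U, t1A, t1DAP) at
their published kinetic parameters plus the seven-condition K_D ladder —
and re-estimate everything from the generated traces and titrations:

```python
from fretbind import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1, out_dir="results"))
```

`results/summary.txt` from this exact call:

```
condition t1U:
  kon_obs = 0.0403 +/- 4.2e-05 /s/nM (R2 = 0.999)
  dwell fit (order 1, mle): tau = [1.67 s], fractions = [100.0%], average dwell = 1.67 s

condition t1A:
  kon_obs = 0.0302 +/- 2.3e-05 /s/nM (R2 = 0.999)
  dwell fit (order 2, mle): tau = [1.80 s, 8.79 s], fractions = [50.9%, 49.1%], average dwell = 5.23 s

condition t1DAP:
  kon_obs = 0.0378 +/- 3.2e-05 /s/nM (R2 = 0.999)
  dwell fit (order 2, mle): tau = [2.03 s, 13.16 s], fractions = [44.4%, 55.6%], average dwell = 8.22 s

Kd ladder (nM):
  t1A: Kd = 0.756 +/- 0.020 (true 0.75)
  t1G: Kd = 1.963 +/- 0.061 (true 1.9)
  t1U: Kd = 1.895 +/- 0.057 (true 1.9)
  t1C: Kd = 1.755 +/- 0.061 (true 1.8)
  t1DAP: Kd = 0.441 +/- 0.011 (true 0.45)
  t1I: Kd = 1.710 +/- 0.047 (true 1.7)
  t1m6A: Kd = 1.800 +/- 0.045 (true 1.8)
  fold_DAP_over_A: 1.71
  ttest_A_vs_DAP: t = 11.738, p = 0.0003013
  fold_DAP_over_nonA_mean: 4.14
```

Reading it: all three conditions associate at similar rates
(k_on(obs) ≈ 0.03–0.04 s⁻¹ nM⁻¹), model selection keeps one dwell population
for t1U (Δτ ≈ 1.6 s) but resolves two for t1A and t1DAP — roughly half the
events short-lived, half 5–6× longer — so the average dwell on t1A is more
than threefold that on t1U. The K_D ladder recovers the simulation truth
within a few percent, t1DAP binds ~1.7-fold tighter than t1A
(p = 3×10⁻⁴ on 3 vs 3 replicate fits) and ~4-fold tighter than the mean
non-A target. `results/report.json` holds the same numbers with standard
errors and settings; per-stage CSV tables (events, first arrivals, dwell
histograms, isotherms) are written alongside.

The same stages are scriptable from the shell:

```bash
fretbind simulate-traces --seed 1 --out traces.csv
fretbind detect-events --traces traces.csv --flow-start 5 --out events.csv
fretbind fit-dwell --events events.csv --method mle --out dwell.json
fretbind run-all --seed 1 --out results/
```

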