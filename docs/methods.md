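# Methods

This note documents the generative model behind the synthetic cohorts, the
decoding and search procedures, the numerical choices, and what the test
suite does and does not establish.

## The task

Four hindlimb nerves (RSN, LSN, RPN, LPN) are stimulated while seven
electrodes (e1–e7) record evoked potentials from the dorsal column nuclei
(DCN) surface at 40 kHz. Five signal features (SFs) summarize each
electrode's response per trial: N1 latency, P1N1 slope and P1N1 amplitude
from the slow wave, and HF peak count and HF integral from the 550–3300 Hz
band. *Feature-learnability* of an input set is the accuracy with which a
fixed small classifier can name the stimulated nerve from those inputs —
a measure of information content with chance at 25%.

## Synthetic recordings

Each trial is a 7 × T matrix (default window −20 to +80 ms, 4000 samples)
assembled from four components, all scaled per electrode by
exp(−d/λ), where d is the electrode-to-hotspot distance and λ = 0.8 mm:

1. **Stimulus artifact** — a damped 2.5 kHz oscillation at t = 0
   (amplitude 500 µV, τ = 0.4 ms). Removed before filtering by the
   extraction stage, so its exact shape is immaterial.
2. **Slow wave** — two raised-cosine lobes with compact, non-overlapping
   support (P1 spans 40% of the P1–N1 gap, N1 60%). This shape is
   deliberately stylized: its extrema are *exactly* the injected latency
   and amplitude parameters, which makes the extraction stage testable
   against closed-form truth. Defaults (cohort means): P1 at 10 ms,
   +60 µV; N1 at 20 ms, −120 µV.
3. **HF burst** — a homogeneous Poisson process on 15–55 ms (default
   0.4 events/ms) convolved with a one-cycle 1.5 kHz Gabor kernel
   (σ = 0.2 ms, unit positive peak, energy inside 550–3300 Hz), scaled by
   the per-nerve event amplitude (default 12 µV).
4. **Noise** — white Gaussian per channel (default SD 16 µV, chosen so
   the full 35-input benchmark sits near ceiling while single
   SF/electrode inputs stay well below it — the regime in which input
   minimization is a meaningful problem rather than a tie-break among
   perfect inputs).

Nerve identity enters in two ways, both scaled by `effect_scale` so that
`effect_scale = 0` is an exact null in which all four nerves share every
generative parameter:

- *nerve type*: sural responses get +1 ms P1 / +3 ms N1 latency, smaller
  N1 and a sparser, weaker burst; peroneal the opposite;
- *body side*: each nerve's hotspot sits on its own side of the midline
  (sural ±0.5 mm lateral, +0.3 mm rostral; peroneal ±0.4 mm, −0.3 mm).

`asymmetry_scale` (default 0.5) emulates the right-side dominance observed
at midline electrodes: right hotspots are pulled toward the midline by up
to 40% and right-side amplitudes gain up to +15%, both also multiplied by
`effect_scale`. Bilateral hotspots are mirror-symmetric iff
`asymmetry_scale = 0`; note that a non-zero electrode-array shift (drawn
per animal, default SD 150 µm, motivated by measured placements of up to
~430 µm) *also* lateralizes responses, so a geometric null for dominance
statistics requires both dials at zero.

Inter-animal variability multiplies amplitudes, latencies and burst rates
by shared per-animal factors (default fractional SD 0.1, clipped), which
preserves within-animal nerve orderings while making animals differ — the
mechanism that separates the WIA, PP and LOO schemes.

Default design sizes mirror the study design: 7 animals, 20 stimulus sets
of 11 trials per nerve → 880 trials/animal, 6160 total. The defaults were
chosen once so that the default cohort is cleanly separable (all 35 inputs,
WIA ≈ 100% learnability) with realistic-looking single-electrode spreads;
they are configuration, not claims about rat physiology — no
population-level amplitude or latency distributions are available to fit
them against.

### Ground-truth expectations

`ground_truth_features` returns closed-form expectations of the five SFs
per electrode. The LF features are exact (the waveform's extrema are the
parameters). The HF features use a Gaussian-process treatment of the
filtered noise, with spectral moments obtained by quadrature of the
realized filter response (the zero-phase forward–backward pass contributes
|H|² in amplitude, |H|⁴ in power):

- **peak count** = rate × window × (expected suprathreshold lobes of one
  filtered event, summing a normal tail per lobe) + a false-positive term
  from the Cartwright–Longuet-Higgins peak-height distribution;
- **integral** = rate × window × the expected rectified-minus-baseline
  area of one event, using the pointwise identity
  E|s+n| − E|n| = s·erf(s/√2σ) + σ√(2/π)(e^(−s²/2σ²) − 1), plus a
  second-order Poisson cluster correction for pairwise tail cancellation.

These expectations neglect event overlap beyond pairs (integral) or
entirely (count), the low-frequency leakage ripple through the band-pass
(≈0.2 µV at default amplitudes), and the sampling error of the estimated
baseline SD that sets the detection threshold. They are therefore exact in
the sparse, high-SNR regime (rate × kernel width ≪ 1, event peaks far from
the threshold) and approximate elsewhere; the recovery tests exercise them
in regimes where each term is clean (LF with the burst off; counts with a
single-lobe amplitude; integrals at sparse rates), and the dense default
regime is validated end-to-end through learnability rather than through
per-feature expectations.

## Feature extraction

Windows are half-open [start, end) in ms, mapped to samples by
floor(t·fs) relative to the stimulus sample. Baseline = −15 to −5 ms.

- **Artifact blanking**: samples in the artifact window (default 0–3 ms)
  are replaced by Gaussian noise matched to each channel's baseline SD,
  seeded per trial, before filtering (prevents ringing).
- **HF trace**: order-10 Butterworth band-pass 550–3300 Hz (SOS form for
  numerical stability), applied forward–backward (zero phase).
- **P1/N1**: P1 is the largest positive extremum in 5–30 ms (DCN onsets
  exceed 5 ms); N1 the most negative extremum after P1 and before 55 ms.
  If no positive extremum exceeds 2 × baseline SD the electrode is flagged
  *no-deflection* and its features are NaN; the trial continues.
- **HF peaks**: local maxima of the *signed* HF trace (flat tops count
  once) above max(3 × baseline SD, 0.5 µV). The absolute floor only
  guards the degenerate noise-free case, where 3 × (a zero SD) would count
  numerical filter-leakage ripple; any realistic noise puts the 3-SD
  threshold above it. Counting on the signed trace (positive-going maxima,
  no refractory constraint) is a documented choice; both are configurable.
- **HF integral**: rectified area over 15–55 ms minus the baseline
  rectified level scaled to the window, floored at 0 (negative outcomes
  after subtraction carry no information).
- **P1N1 amplitude is stored signed** (V(N1) − V(P1), typically negative);
  magnitude-based statistics take |·| downstream.
- Spectrograms (10 ms windows, 5 ms hop, per-trace min–max normalized with
  an all-zero guard) are diagnostic only and never feed the classifier.

## The classifier and learnability

One hidden layer of 20 tanh units, 4-way softmax output, cross-entropy
loss. Full-batch gradient descent with momentum 0.9 and an adaptive
learning rate (initial 0.05; ×1.15 after an improving epoch; a step that
worsens the loss by >4% is rejected and the rate ×0.7 with momentum
reset), early stopping on a held-out validation set (patience 6), a
performance goal of 5 × 10⁻³ cross-entropy, and a 250-epoch cap. The
architecture is the contract; the optimizer constants are defaults tuned
for convergence speed on these small dense problems and validated by the
separable-data (100%) and permuted-label (25%) oracles.

Inputs are min–max normalized to [−1, 1] over the whole table before
splitting (constant features map to 0 with a warning). Splits are
stratified by nerve — the non-train pools get floor(fraction × n) per
class, the remainder goes to training — so every class is present in every
pool; 880 trials split 616/132/132. Learnability = mean ± SEM of the
diagonal of the repeat-averaged, row-normalized confusion matrix; the SEM
is across the four class accuracies (spread over outcomes), *not* across
animals. Per-animal learnability values are retained separately and are
the pairing unit for benchmark t-tests; when any value exceeds 95% a logit
transform (values clipped to [0.5, 99.5]%) guards the ceiling. Ranking:
greater mean, then smaller SEM, then lexicographic input name.

LOO uses 10 repeats per fold (fresh train/validation allocation and
initial weights each repeat) and averages fold matrices.

## Input minimization

The adapted sequential forward search never prunes its candidate pool:
each round evaluates `current ∪ {c}` for *every* pooled candidate, in the
strategy's order (which also breaks score ties), accepts the best
extension, and re-tests everything else next round. It stops when the
accepted set is statistically near-benchmark or the pool is empty; a
benchmark itself at chance level is flagged degenerate. Two orderings:
global single-input rank, or electrode blocks ordered by mean
single-input learnability (ties: best single candidate, then index) —
the latter prioritizes few-electrode solutions. Exhaustive enumeration
scores every subset of the requested sizes at reduced repeats (default 3)
and re-scores the top 10 at full repeats; subset counts are closed-form
binomial sums. Seeds for every evaluation derive deterministically from a
root seed.

## Surface maps

Per-electrode learnability is interpolated with an exact thin-plate spline
(smoothing 0, affine polynomial part; scipy's RBF implementation) onto a
7 × 7 cell-centred grid over [−1, 1] mm². Default electrode geometry:
midline electrodes at x = 0 spaced 0.75 mm with e4 at the centre; lateral
electrodes at x = ±0.82 mm (470 µm midline gap + 350 µm electrode radius);
e1/e6 rostral, e2/e7 caudal. The rostro-caudal spacing is a documented
configuration choice — no numeric value is available for the adapted
array. Per-animal surfaces are translated by that animal's array shift
before interpolation (off-map electrodes are clipped with a warning), then
averaged cell-wise; the cell-wise SEM of per-animal mean surfaces is also
returned. Collinear or duplicate electrode positions are rejected (the
spline system is singular there).

## Statistics

- *Non-significant loci*: per (animal, SF, electrode), a one-way linear
  model of |SF| on nerve with all six pairwise contrasts under a Tukey
  family adjustment (Benjamini–Hochberg optional); contrasts with adjusted
  p > 0.05 are loci, in five categories (the two cross-side/cross-type
  pairs share one). Degenerate cells (zero variance) flag every pair.
- *Side dominance*: per (animal, SF, bilateral pair), |SF| at e4
  (two-group linear model ≡ t-test) or the per-trial sum of |SF| over all
  seven electrodes (TRM, Student's t-test); the dominant side must be
  significantly greater at α = 0.05. For N1 latency the comparison is on
  the latency itself and a note records that "greater" means *later*.
- Magnitudes |SF| are used because signed amplitudes/slopes would invert
  "greater"; configurable.
- *Bilateral ML error*: mean of the two mirror off-diagonal confusion
  cells of a pair; "at or above chance" is ≥ 25%, inclusive.
- Dominance–error association: Pearson chi-squared on the 2 × 2 table of
  {both pairs dominant} × {error ≥ 25%}; a zero margin falls back to
  Fisher's exact test, flagged.
- Cross-animal comparisons use paired tests on per-animal summaries;
  full mixed-effects machinery is intentionally out of scope.

## Problem sizes used by the test suite

Property and calibration tests run at sizes chosen to keep the suite
minutes-scale while preserving the contract being tested: the separability
and search-optimality checks use the full default cohort (6160 trials);
exhaustive-vs-SFS comparison uses 2 repeats per subset with top-5
re-scoring; chance calibration uses 50 repeats on one 880-trial animal;
statistical calibrations use directly sampled Gaussian feature tables
(≥ 500 simulated pairs / 210 cells), which exercise the statistics layer
on its own contract without re-running the trace pipeline per simulation.
The trace pipeline itself is covered by the null-cohort uniformity check
and the recovery oracles.

## Known limitations

- The generator is statistical, not biophysical: no conduction velocities,
  synaptic dynamics, stimulus-rate effects, or realistic waveform
  diversity. Passing tests show the *analysis chain* is correct and
  calibrated, not that real DCN recordings would reach any particular
  learnability.
- HF ground-truth expectations degrade at dense burst rates (see above).
- The classifier is deliberately fixed; no hyperparameter search or
  alternative model families.
- "Re-testing rejected candidates" admits lazier schedules than the one
  implemented (e.g., re-testing only every few rounds); the deterministic
  full-pool variant was chosen for reproducibility, and the candidate
  orderings only steer evaluation order and tie-breaks.
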