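# Methods

## Problem setting

Scalp EEG distinguishes three regimes relevant to epilepsy work-ups:
normal background activity, interictal activity (between seizures —
abnormal but not ictal, marked by slowing and sparse high-voltage
spikes), and ictal (seizure) activity with high-amplitude rhythmic
discharges. A recurrent classifier operating on short lag windows of a
continuous multichannel recording can label each time step, but its
performance depends strongly on hyperparameters — learning rate,
dropout, epoch budget, depth and width. This package treats that
selection as a bound-constrained minimization of the classification
error and solves it with a population metaheuristic.

## The hybrid adaptive sine-cosine algorithm (HASCA)

The base sine-cosine algorithm (SCA) moves every component *j* of every
candidate *X* around the best-so-far destination point *P**:

    X_j' = X_j + r1 · sin(r2) · |r3 · P*_j − X_j|   (r4 < 0.5)
    X_j' = X_j + r1 · cos(r2) · |r3 · P*_j − X_j|   (r4 ≥ 0.5)

with r2 ~ U[0, 2π], r3 ~ U[0, 2], r4 ~ U[0, 1] drawn fresh per component
and the amplitude scheduled as r1 = a(1 − t/T), a = 2. SCA converges
aggressively toward *P**, which loses population diversity early. HASCA
adds two counter-measures:

1. **Chaotic initialization.** Half the initial population is uniform in
   the box; the other half is produced by scaling each uniform solution
   with a logistic-map iterate, β ← μβ(1 − β) with μ = 4 (the chaotic
   regime), seed β₀ drawn by rejection outside {0, 0.25, 0.5, 0.75, 1}
   (the map's fixed/periodic points). The merged population of N is
   evaluated once — the mechanism costs no extra fitness evaluations —
   and sorted ascending (stable, so equal fitness preserves insertion
   order).

2. **Self-adaptive search alternation.** Each component update flips a
   coin against the *search mode* sm: with probability sm the component
   takes a firefly (FA) step

       X_j' = X_j + β₀ᶠ · exp(−γ r²) · (P*_j − X_j) + αₜ (κ − 0.5) s_j

   (β₀ᶠ = 1 base attractiveness, γ = 1 absorption, κ ~ N(0,1),
   s_j the bound span of dimension j), otherwise the SCA step above.
   sm starts at 0.8 and drains as sm ← max(0, sm − t/T) — a triangular
   drain that reaches 0 by t ≈ √(2T); exploration-heavy FA moves
   dominate the first iterations and pure SCA takes over afterwards.

FFE accounting is exact: a run with population N and T iterations spends
N + N·T fitness evaluations (N at initialization, N per iteration).

### Design choices in the hybrid

These points were genuinely open and were fixed once, as follows:

- **sm drain.** The recurrence subtracts t/T (a growing amount) each
  round and would go negative within a few iterations; it is clamped at
  0 to remain a probability. A conventional linear decay
  sm = sm₀(1 − t/T) is available via `HASCAConfig(sm_mode="linear")`.
- **Firefly partner.** The per-component FA move needs an attractor;
  the destination point *P** is used, matching the role it plays in the
  SCA half and keeping the per-component cost O(1).
  `HASCAConfig(partner="random_brighter")` switches to a uniformly
  chosen strictly-brighter member.
- **Distance.** r in the FA move is the Euclidean distance between the
  two full position vectors after normalizing each dimension to [0, 1]
  by its bounds, so γ = 1 behaves the same across heterogeneous
  hyperparameter ranges (learning rate spans 0.01, epochs span 100).
- **Randomization decay.** αₜ = α₀(1 − t/T) with α₀ = 0.5, and the
  noise term is scaled per dimension by the bound span — mirroring the
  package's other linear schedules.
- **Acceptance.** Moves are unconditional (no greedy filter); elitism
  lives only in *P**, which is replaced only by a strictly better
  solution, making the per-iteration best history non-increasing.
- **Repair.** Out-of-box positions are clamped component-wise.

Baseline runners `sca_optimize` (uniform init, pure SCA moves) and
`fa_optimize` (full-vector moves toward every brighter member, with the
iteration-best moving by noise only) share the identical bookkeeping so
comparisons isolate search behavior.

## Synthetic EEG generator

The generator emulates the structure of Bonn-style archives: per-class
multichannel recordings at a nominal 173.61 Hz, cut into 158-sample
windows that are shuffled (seeded) into one continuous labeled
recording. Each channel is an independent band-limited sinusoid (random
frequency within the class band, random phase) plus Poisson-placed
biphasic spikes (a full sine cycle, 12 samples ≈ 70 ms wide, placed
independently per channel) plus white noise. Default class recipes:

| class     | band (Hz) | amplitude | spikes /1000 samples | spike amp | noise sd |
|-----------|-----------|-----------|----------------------|-----------|----------|
| normal    | 8–13      | 1.0       | 0                    | —         | 0.3      |
| anomalous | 4–8       | 2.0       | 5 (per channel)      | 4.0       | 0.3      |
| seizure   | 3         | 3.0       | 0                    | —         | 0.3      |

Normal mimics an alpha background; anomalous combines the theta slowing
and higher amplitude typical of interictal epileptic EEG with sparse
high-voltage spikes; seizure is a rhythmic ~3 Hz high-amplitude
discharge. The interictal recipe deliberately differs from normal in
its *background*, not only in spikes: spikes at 5/1000 samples leave
most 15-sample lag contexts spike-free, so a spikes-only contrast would
cap instance-level accuracy near chance regardless of the model — the
generator must put class signal inside every lag window for the tuning
pipeline to have something to find.

What the generator does **not** emulate: 1/f spectral background,
artifacts (EMG, eye blinks, electrode pops), inter-channel correlation,
non-stationarity within a class, and realistic seizure evolution
(onset/offset dynamics). Passing tests therefore demonstrate that the
pipeline can discover hyperparameters that separate classes whose
short-window statistics differ — they do not certify clinical-grade
seizure detection on real recordings.

## Preprocessing chain

- **Segmentation**: floor(length/158) non-overlapping windows, trailing
  remainder dropped (4,096 samples → 25 windows, 146 dropped).
- **Recombination**: windows pooled across classes and shuffled by a
  seeded permutation; labels travel with windows.
- **Lag framing** (lags = 15): the instance at row *i* is rows
  [i−14 .. i] of all channels with the label of the window containing
  row *i*. Instances whose context spans two windows with *different*
  labels are dropped (default) because their context is systematically
  mislabeled; `boundary="last"` restores last-row labeling.
- **Split**: contiguous 70/10/20 train/validation/test in instance
  order (floor counts, remainder to test). Randomness is already
  injected at the window level, so a contiguous split keeps the
  protocol reproducible.
- **Normalization**: per-channel min-max fitted on the training split
  only, applied without clipping everywhere; a constant train channel
  maps to 0 with a warning.

## Recurrent classifier

An Elman-style recurrent network implemented in numpy: one or two
simple tanh recurrent layers (the genotype always carries a second
width; it is decoded but inert at one layer, so the search space is
fixed-size), inverted dropout after each recurrent layer, softmax
readout of the last hidden state, categorical cross-entropy, Adam with
the decoded learning rate, and early stopping on validation loss with
patience = floor(epochs/3) and best-weight restoration. Training is
full backpropagation through time, restructured so each layer's input
projection and all weight gradients are single large matrix products
and only the recurrent credit assignment is sequential; with ≤ 30
units over 15 steps this trains in about a second per configuration on
one CPU core, which is what a population search needs. Arithmetic is
single precision and the default batch size is 256: at this model size
both choices cut per-epoch overhead severalfold with no measurable
effect on the attainable error, and no convention is at stake for so
small a network.
All training randomness (init, shuffling, dropout) flows from one seed,
so identical seeds give bit-identical runs.

## Hyperparameter search spaces

Six dimensions: learning rate [0.0001, 0.01], dropout [0.05, 0.2],
epochs [30, 60] (binary) or [50, 150] (multi-class), layers [1, 2],
and per-layer neurons [lags/3, lags] = [5, 15] (binary) or
[lags/2, 2·lags] = [8, 30] (multi-class, lower bound 7.5 rounded up to
keep the integer range honest). Integer dimensions decode by rounding
half away from zero, then clamping. The objective is 1 − accuracy on
the validation split (default; a `fitness_split="test"` flag exists but
leaks the test set into selection and is off by default).

## Campaigns, metrics and statistics

A campaign is `runs` independent optimizations; run *k* derives its rng
stream and training seed from (base_seed, k). Per-run best objectives
are summarized as Best/Worst/Mean/Median/Std/Var (sample standard
deviation, n−1). The winning genotype of each run is retrained and
scored on the test split: accuracy, per-class and support-weighted
precision/recall/F1 (zero denominators reported as 0), error =
1 − accuracy, and Cohen's κ = (p_o − p_e)/(1 − p_e) computed from the
full K×K confusion matrix (κ returns 0 with a warning when p_e = 1).
Support-weighted recall equals accuracy identically — a useful internal
consistency check.

Method comparison is two-stage: Shapiro–Wilk normality per method
(delegated to scipy's vetted routine); if any sample rejects at
α = 0.05, parametric testing is unsafe and every competitor is compared
with the control by a paired two-sided Wilcoxon signed-rank test. The
signed-rank test is implemented directly: zero differences dropped,
average ranks on ties, exact p by full 2ⁿ sign enumeration for n ≤ 12,
and the tie-corrected normal approximation above that; the exact branch
is cross-checked in tests against an independent brute-force
enumeration and scipy.

## Problem sizes used in the shipped checks

The comparative benchmark property uses 10-dimensional sphere and
Rastrigin, bounds ±5.12, N = 20, T = 100, 30 seeded runs per method.
The end-to-end tuning checks use the six-agent / eight-iteration budget
(54 fitness evaluations per run): the binary task at 25 windows per
class × 8 channels with 5 independent runs, and the three-class task at
15 windows per class with a single run — the package's scaled-down
analog of a full 30-run campaign, chosen so the whole suite runs on a
single CPU core in well under half an hour.

## Known limitations

- The synthetic classes are easier than real EEG; absolute accuracies
  here do not transfer to clinical data.
- Only box constraints are supported; discreteness is handled by the
  decoder, not by discrete-aware search operators.
- The firefly baseline's per-iteration cost is O(N²·d); fine at the
  population sizes used here.
- Shapiro–Wilk is undefined for constant samples; the comparison
  harness then falls straight to the non-parametric branch.
- The exact signed-rank branch is O(2ⁿ); it caps at n = 12 by design.
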