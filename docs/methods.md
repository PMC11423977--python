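# Methods

This note documents the models, protocols and design choices behind
`cgmbench`, in the order the pipeline runs them.

## Forecasting problem

A CGM sensor reports glucose (mg/dL) nominally every 5 minutes. Given the
last `L = 24` samples (2 hours) of one sensor trace, a model predicts the
single value `p` steps ahead, `p = 6` (30 min) or `p = 12` (60 min). One
single-output model is trained per horizon; a two-headed variant would
share parameters across horizons, but single-output heads keep each
model's parameter accounting unambiguous. Models operate on z-scored
values; forecasts are mapped back to mg/dL for all evaluation.

## Synthetic cohorts

Real CGM study datasets are access-restricted, so the generator emulates
their published structure rather than their raw values. Each patient's
trace is drawn from:

* a discrete Ornstein–Uhlenbeck (AR(1)) process on the 5-minute grid
  around a basal level, with autoregressive coefficient 0.98 (≈4 h
  decorrelation) and stationary SD set by the cohort profile — CGM traces
  are smooth and strongly autocorrelated, which white noise would miss;
* meal-like excursions (Poisson-timed, ~3/day): a 30–150 mg/dL linear rise
  over 1–3 h followed by an exponential decay;
* sustained hyperglycemic plateaus (~1.5/week, 2–5 h, 330–390 mg/dL),
  which create the minor high mode of the glucose density. Published
  density plots for such cohorts show a second peak near 400 mg/dL; since
  sensors clip at 400, the plateaus are placed just below the clip so that
  clipping concentrates mass there naturally. The rate is a profile field,
  not an assertion about whether the real-world peak is saturation
  artifact or true mass;
* additive Gaussian sensor noise (4 mg/dL SD) and hard clipping to the
  sensor range [40, 400] mg/dL;
* missingness: per-sample Bernoulli dropouts (≈1%) plus Poisson-timed long
  dropouts of 65–240 min (always strictly over an hour, so they exercise
  the gap-splitting rule).

Closed-loop (automated insulin delivery) cohorts halve the basal SD and
the plateau rate, reproducing the reduced variability such therapy gives.
Four stock profiles (`paper_profiles()`) mirror the published cohort
table: 12 adults/8 weeks open-loop; 112 adolescents+adults/26 weeks
closed-loop; 101 children/28 weeks closed-loop; 451 mixed-age/26 weeks
open-loop. `miniature_profiles()` is the desk-scale default used by tests
and the experiment workbench (two cohorts, 8 patients, 2 weeks).

Per-patient seeds derive from `(master_seed, 0, patient_index)` via
`numpy.random.SeedSequence`, so enlarging a cohort never reshuffles
existing patients. Everything is bit-reproducible from
`(profile, master_seed)`.

What the generator does **not** emulate: insulin/carbohydrate kinetics and
event channels (the benchmark is CGM-only by design), circadian meal
timing, sensor calibration drift, and inter-patient correlation of
habits. Passing tests therefore demonstrate that the pipeline's machinery
is correct and that models can learn autocorrelated glucose-like dynamics;
they do not certify clinical performance on real cohorts.

## Preprocessing

1. **Grid alignment** — a strict 5-minute grid spans the first to last
   timestamp; each sample snaps to the nearest slot, ties going to the
   earlier slot (the alignment rule is otherwise unstated in the source
   protocol); unfilled slots are marked missing. Duplicate timestamps are
   an error naming the patient.
2. **Imputation and segmentation** — missing runs of ≤ 60 min (12 slots)
   are filled by linear interpolation between the flanking observations
   (exact on affine signals, by construction); runs strictly longer split
   the series into separate segments with nothing fabricated inside the
   gap ("over an hour" is read as strict). Leading/trailing missing slots
   are dropped.
3. **Normalization** — z-scoring with mean and **population** SD pooled
   over the cohort's training segments only (the convention is unstated in
   the source; population SD makes the round trip and the unit-variance
   check exact), applied unchanged to validation and test data.
4. **Splitting** — patients are partitioned 80/20 into a training pool
   and a test set (a patient never contributes to both), and the
   chronologically last 20% of each training patient's slots form the
   validation set. This honors both patient-level separation and
   chronological holdout simultaneously. `ohio_mode` instead keeps every
   patient in both sides with a chronological within-patient cut, for
   datasets that ship predefined per-patient partitions.
5. **Windowing** — each segment of length `N` yields
   `max(0, N − L − p + 1)` (input, target) pairs per horizon; windows
   never cross a segment boundary.

## Architectures and complexity accounting

All five models map `(batch, 24, 1)` z-scores to a scalar forecast, use
ReLU between hidden layers (activations are unstated in the source;
LSTM gates keep their standard sigmoid/tanh), and zero dropout (the tuned
optimum). Conventions that fix the parameter counts exactly:

* **FFN** (2 241): the affine stack 1→32→64→1 is applied *per timestep*
  with the final timestep read out — the only reading consistent with the
  published count; a flattened 24→32→64→1 variant would have 2 977
  parameters and is rejected.
* **LSTM** (11 431): two stacked layers of 30 units with *dual* bias
  vectors per gate (input-side and recurrent-side, 4h extra per layer);
  the single-bias convention gives 11 191 and is rejected.
* **SAN** (595 457): affine input projection 1→128, parameter-free
  sinusoidal positions, three post-norm encoder blocks (fused 128→384 QKV,
  128→128 output projection, 128→512→128 feed-forward, two layer norms),
  one final layer norm, 128→1 head — the unique combination matching the
  published count at the quoted dimensions.
* **CNN / TCN**: kernel size 3 (unstated in the source); CNN pools by
  global time-averaging; TCN uses blocks of two causal dilated
  convolutions with residual connections (1×1 projection on channel
  change). Their published counts (31 041 / 71 457) cannot be
  reverse-engineered without the original kernel/pooling details, so they
  are reported but not asserted.

FLOPs are analytic: `2 × multiply–accumulates` summed over every affine,
convolutional, recurrent and attention contraction for one window; biases,
nonlinearities and normalizations are not counted. The published FLOP/
memory/latency figures were measured with an unstated methodology on
unknown hardware and are not reproduced.

The networks run on a small tape-based reverse-mode autodiff engine
written on numpy (`cgmbench.nn`), with the LSTM recurrence fused into a
single node whose backward pass is the standard BPTT recursion; all
gradients are verified against central finite differences in the test
suite.

## Training protocol

Adam (β = 0.9, 0.999 — framework-default moments, documented here because
the source does not state them) minimizes per-batch RMSE on normalized
targets; the reported epoch loss is the mean of batch RMSEs. After each
epoch the validation RMSE is computed; "improvement" means any strict
decrease. Two independent patience counters, both reset on improvement:
learning rate × 0.1 after 10 flat epochs, stop after 30 flat epochs (cap
100). The returned checkpoint is the best-validation epoch. A full run
repeats 5 seeds (`base_seed … base_seed+4`) and reports mean ± population
SD per metric. Tuned learning rates: 0.01 for the FFN, 0.001 otherwise;
batch size is a per-cohort setting in the source protocol (16 for the
small cohort, 512/1024 for the large ones, always 16 for CNN/TCN).

Desk-scale runs (tests, acceptance script, workbench default) use
8-patient/2-week cohorts, ≤ 20 epochs, batch 256 and an optional cap of
6 000 training windows — sizes chosen so a full check runs in minutes on
one CPU while leaving the learning signal clearly above the persistence
baseline. They are configuration, not protocol: the paper-faithful
settings remain the defaults of `TrainConfig` and `paper_config()`.

## Evaluation

Analytical metrics on de-normalized pairs: RMSE, MAD, COD (R²),
`FIT = (1 − RMSE/RMSE_mean-predictor) · 100`, and MADP. FIT and COD
satisfy `FIT = (1 − √(1−COD))·100` whenever both are defined; constant
references leave COD/FIT undefined (flagged `None`, not silently zero);
MADP requires strictly positive references, which CGM-range data
guarantees.

Clinical scoring uses the canonical Clarke Error Grid inequalities (the
source describes the zones only qualitatively), evaluated in the order
A → E → C → D → B so boundary points resolve deterministically; a frozen
25-point labeled fixture and a full 1-mg/dL lattice scan against an
independent scalar oracle pin the implementation down. Forecasts are
clipped into the sensor range before zoning (a regression output can
leave (0, 400]; an error-grid plot would render it at the axis limit).
Zones merge into safe (A+B) and unsafe (C+D+E). Zone percentages are
pooled over windows; per-repetition means can be derived from the per-run
reports.

## Generalization assessment

Each model trained on cohort X is evaluated on every cohort Y's test set;
Y's windows stay normalized with Y's own training μ, σ (models consume
z-scores; normalization travels with the data). Each matrix cell reports
the de-normalized RMSE and a two-sample KS p-value comparing that cell's
residuals (reference − forecast) with the residuals of the model natively
trained on Y, over the same test windows; the diagonal compares a model
with itself and is 1 by convention. Significance is read at α = 0.05,
with no multiple-testing correction (matching the source protocol; users
can correct externally). The KS test delegates to
`scipy.stats.ks_2samp`: exact p by enumeration when `n·m ≤ 10 000`,
asymptotic Kolmogorov distribution otherwise — the switchover balances
fidelity and runtime. The exact branch is validated against brute-force
enumeration over all interleavings for every `n, m ≤ 6`.

**Serial dependence caveat.** Consecutive sliding windows share 23 of 24
input samples, so consecutive residuals are strongly dependent, and
residuals also cluster by patient. At large sample sizes this violates
the KS test's iid assumption and makes it anti-conservative: two cohorts
simulated from the *same* profile are flagged as different more than half
the time when full residual series (~8 000 points) are compared. The
property and acceptance tests therefore thin residuals to one per 30
windows (2.5 h spacing) before the comparison, which restores nominal
calibration (≥ 90% of same-profile replicate pairs give p > 0.05).
`cross_evaluate` keeps full-sample KS as its default — matching the
benchmark protocol, whose reported p-values inherit this caveat — and
exposes `ks_stride` for calibrated use.

Demographic slicing re-evaluates one prediction set on its female and male
windows separately (labels travel with the windows via the patient
manifest), reporting RMSE for the whole set and both slices — which obey
`RMSE²_FM = (n_F·RMSE²_F + n_M·RMSE²_M)/N` exactly — and the three
pairwise KS p-values (FM vs F, FM vs M, F vs M). Slices with fewer than
two windows are flagged rather than scored.

## Numerical and degenerate-input choices

* Population (ddof=0) SD everywhere a convention is needed (normalizer,
  repetition aggregates).
* σ = 0 training data, empty splits, empty samples, duplicate timestamps,
  window-length mismatches and out-of-range Clarke inputs raise
  `ValueError` with context rather than propagating NaNs; a non-finite
  training loss raises naming the epoch.
* Gradient-scatter for basic slices uses direct accumulation; advanced
  indexing falls back to `np.add.at`.
* Ties in grid snapping go to the earlier slot; ties in Clarke zoning are
  resolved by the fixed evaluation order; equal validation RMSE does not
  count as improvement.

## Known limitations

* The simulator's bimodal density is a stylized stand-in: no meal/insulin
  covariates, no circadian structure, no sensor drift. Results quantify
  pipeline correctness and learnability, not clinical accuracy.
* CNN/TCN parameter counts intentionally differ from the published table
  (see above); FLOP, memory and latency figures are out of scope.
* The hyperparameter grid search is not re-run; tuned values are fixed.
* Full-sample KS p-values on overlapping-window residuals are
  anti-conservative (documented above).
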