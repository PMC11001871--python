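# Methods

`pulsim` models the temporal interplay of pulsed radiotherapy (widely spaced
tumoricidal pulses) and PD-L1 checkpoint blockade in a syngeneic murine tumor
setting, as a four-stage workflow: a mechanistic cohort simulator, an
augmentation/encoding stage, a recurrent surrogate of volume change, and
interpretation/in-silico scoring layers. This note records the model, its
assumptions, the parameter choices, and the limits of what the tests show.

## Cohort simulator

Tumor volume per animal evolves multiplicatively on a daily grid of
`n_steps = 18` steps, step 1 being the first antibody administration day (the
first radiation pulse lands on step 3, i.e. day 14 post-implantation in the
emulated design):

    V(t) = V(t-1) * SF(d_t) * exp(rho - K_imm(t))

* **Growth** is exponential with rate `rho` (default 0.25/day). Untreated
  trajectories equal `V(0)*exp(rho*t)` exactly when inter-animal noise is off;
  this closed form is the simulator's oracle in the tests.
* **Radiation** acts instantaneously through the linear-quadratic surviving
  fraction `SF(d) = exp(-(alpha*d + beta*d^2))`, defaults `alpha = 0.3/Gy`,
  `beta = 0.03/Gy^2` (alpha/beta = 10 Gy, a conventional tumor value). Note a
  consequence: single doses >= 10 Gy give SF <= e^-6 and effectively sterilize
  the simulated tumor.
* **Immune-mediated kill** opens a window `[p + immune_delay,
  p + immune_delay + immune_duration]` after each pulse `p` (defaults 7 and
  10 days: the adaptive response in an immunologically cold tumor needs about
  a week to develop and persists for days). Inside a window the kill rate is
  `kappa` (0.35/day) if anti-PD-L1 is pharmacologically active, else
  `kappa_bare` (0.10/day); outside all windows it is zero. An administration
  at step `s` stays active over `[s, s + drug_persistence]`
  (`drug_persistence = 2` days, matching every-other-day dosing giving
  continuous coverage). The isotype-control antibody has no dynamic effect.
* **Inter-animal variability**: initial volume (uniform 150-200 mm^3, the
  randomization criterion) and `rho` are each multiplied by mean-1 log-normal
  noise with CV `noise_cv` (default 0.15) — volumes are positive and
  right-skewed, so log-normal is the natural choice.

The kill rates `kappa`/`kappa_bare` are free choices (no measured values
exist at this abstraction level); they were set so that, during an open
window with blockade active, net growth turns negative
(`rho - kappa = -0.10/day`) while without blockade growth merely slows — the
qualitative pattern the emulated experiments show.

The default study enumerates 26 groups: two no-radiation controls, four
single-pulse dose levels (10/15/20/40 Gy) and seven two-pulse dose/spacing
combinations (10/15/20 Gy at 1/4/10-day spacing, minus the two 15 Gy x 4-day
arms, which trims the full 28-arm cross to the 26 used), each crossed with
isotype vs anti-PD-L1 every other day; 7 or 8 animals per group; measurements
on the six uneven days (1, 4, 7, 10, 14, 18). The exact per-group measurement
days of the emulated design are not public, so these defaults are explicit,
overridable placeholders anchored to the group identities that are public
(e.g. group 3 = single 20 Gy + isotype, group 8 = two 20 Gy pulses + blockade).

## Augmentation and encoding

Group summaries (mean, sample SD with ddof = 1) are augmented into 50
pseudo-animals per group: per-step draws from `Normal(mean, sd/5)`, the SD
shrink emulating a higher-precision measurement regime, clipped below at
1 mm^3 (volumes are physical; the clip point is arbitrary but essentially
never binds at shrink 5). Each pseudo-animal becomes one sequence of 18 steps
x 2 channels:

* radiation channel: the LQ log cell kill `alpha*d + beta*d^2` on the pulse
  day, 0 elsewhere (delivery-day-only; alternatives `1 - SF` and raw dose are
  selectable via `LQConfig` to isolate this encoding guess);
* drug channel: 0 none, 1 isotype, 2 anti-PD-L1 (ordinal coding kept
  deliberately, rather than one-hot, for fidelity to the emulated encoding).

Targets are the consecutive volume changes `dVC_i = V_{i+1} - V_i`
(positive = growth), up to five per sequence, zero-padded with a boolean mask.
Six measurements give exactly five defined entries. For optimization the
targets are divided by a fixed `target_scale = 100` (loss conditioning) and
multiplied back on prediction; the constant round-trips exactly.

## Surrogate model and training

A single-layer LSTM (input/forget/output gates + cell state) with 100 hidden
units, read out many-to-one: a dense layer maps the final step's hidden state
to the fixed 5-vector of predicted changes, masked at loss time. This is the
only readout consistent with both a final-step dense layer and a multi-term
per-interval loss. The LSTM, backpropagation through time and the Adam
optimizer are implemented directly in NumPy (float64): the models are tiny,
exact run-to-run reproducibility matters more than throughput, and the
analytic gradients are verified against central finite differences to ~1e-7
relative error in the test suite.

Training: Adam (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8), batch size 100,
5000 epochs by default, gradient-norm clipping at 5, forget-gate bias
initialized at +1, all other weights uniform in ±1/sqrt(H), everything seeded.
Validation holds out two whole treatment groups (= 100 samples of a 26x50
study) rather than a random 20% of samples — holding out whole arms is the
meaningful generalization test when every sample within an arm shares its
input sequence. Leave-two-groups-out cross-validation repeats this five
times with freshly drawn pairs. Early stopping is off by default.

## Interpretation

`extract_hidden_map` records the hidden state (not the cell state; a flag
exposes the latter) at all 18 steps for one input sequence, giving a
(units x steps) map; the inputs contain no volumes, so every sample of a
group yields the identical map and per-group maps need no averaging.
Subtracting the maps of two arms isolates the represented effect of the
stimulus in which they differ. Because the recurrence is causal, arms with
identical inputs through step k have identical map columns 1..k — the
difference map's zero prefix is an exact structural identity, asserted
bit-exactly in the tests. Region summaries (mean, fraction of positive
cells) default to the four reported bands (rows 1-5, 20-45, 85-90 linked to
radiation; 65-75 to the antibody) but are fully configurable, since band
selection is itself a hypothesis.

## In-silico scoring

The endpoint is accumulated volume change, `AVC = sum_i dVC'_i` (mm^3),
lower = better control; it is definitionally the sum of the model's
prediction and tested as bit-identical to it. The offset sweep places a 2- or
4-day consecutive anti-PD-L1 course at offsets 1..14 days after the first
pulse; courses extending past step 18 are clipped to the window and flagged
(late offsets with a 4-day course necessarily collide with the horizon),
never silently dropped. Reference schemes: two 10 Gy pulses, two 20 Gy pulses
(10-day interval, first pulse step 3), and a single 40 Gy pulse.

## Recovery experiment (design and problem sizes)

The workflow's power is demonstrated by parameter recovery against simulator
ground truth. The default 26-group study cannot identify the immune delay:
every drug arm doses from step 1, so it contains no drug-timing variation.
The recovery study (`offset_recovery_config`) therefore uses control,
drug-only, radiation-only and radiation+drug arms plus single-pulse arms
whose 4-day antibody course starts 1..14 days after the pulse (daily coverage of the full sweep range). Two design
choices matter:

* **Pulse dose 6 Gy** (SF ~ 0.056): with the default LQ coefficients any
  dose >= 10 Gy sterilizes the simulated tumor, erasing the post-pulse
  dynamics the experiment must expose; 6 Gy is a deep but survivable kill.
* **Daily offset coverage (1..14)**: the sweep interrogates the learned
  offset-response curve at every day, so offsets absent from the training
  arms leave the learned curve unconstrained there; covering the sweep range
  densely is an identifiability requirement of the experiment, not a tuning
  of the simulator.

At the suite's scale (18 groups x 50 samples, 50 hidden units, 500 epochs,
~1 minute on one CPU) the trained surrogate reproduces the simulator's
tumor-control ordering (control worst, radiation+blockade best) and places
the AVC-minimizing offset within ±3 days of the true 7-day delay — the
overlap of a 4-day course (+2 persistence days) with the immune window is
maximal for offsets 7..10 and only one kill-day smaller at 11, so the
simulator truth itself is flat across those days, day-exact recovery is not
a meaningful ask, and at this training budget an occasional seed places the
minimum at the edge of that plateau. The acceptance script runs the same
experiment at the same scale.

## What the synthetic cohorts do and do not show

The generator reproduces the *structure* the analysis assumes — group-level
summaries, sparse uneven measurements, 18-day horizon, exponential growth,
dose-dependent kill, delayed blockade-dependent immune effect, inter-animal
spread — with known ground truth, which is exactly what recovery tests need.
It does not emulate measurement error models, animal dropout/euthanasia
endpoints, acquired radioresistance, immune-cell kill by radiation, or any
calibration to real measurements; passing tests therefore certify the
pipeline's correctness and its qualitative recovery power under the stated
dynamics, not quantitative fidelity to any real cohort.

## Numerical choices and degenerate inputs

Float64 throughout; seeded `numpy.random.Generator` everywhere (study,
augmentation, initialization, shuffling, fold draws), so every artifact is
bit-reproducible and the end-to-end pipeline writes byte-identical CSVs on
rerun. Scheme-comparison ties keep input order (stable mergesort). Augmented
draws are clipped at 1 mm^3; a group with fewer than two measurement steps
cannot define a change and is skipped with a warning; a non-finite training
loss aborts with a diagnostic rather than continuing; identical-animal groups
report SD exactly 0. Known limitations: single recurrent layer only (the
layer count of the emulated model is unstated), no many-to-many variant, no
feed-forward baseline, no ODE comparison models, and no schedule optimizer
beyond the explicit sweep.
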