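# Methods

This note documents the models implemented in `olfstoch`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the package's numerical conventions and known limitations.

## Response significance and reliability classes

A cell-trial is a significant response when the mean ΔF/F over the
response window exceeds the baseline mean by `threshold_sd` baseline
standard deviations (default 2.33, the one-sided Gaussian 1% point).
Baseline statistics are computed per trial from that trial's pre-onset
window; a pooled per-cell-odor mode is available (`pooled_baseline=True`).
Cells with exactly zero baseline variance are flagged and excluded rather
than divided through.

Note on the nominal false-positive rate: when the response value is a mean
over several frames while the threshold uses the frame-scale baseline SD,
white baseline noise averages down and the empirical false-positive rate
falls below the nominal tail probability. The nominal ~1% rate is realised
when the response value and the baseline samples are at the same sampling
scale (single-frame response window); with the fly grid (five-frame
response window) the rule is effectively stricter. Real imaging noise is
temporally correlated, which narrows this gap; we keep the plain
`mean + k·SD` rule because it is the convention in the field.

Classes partition the cells per odor: *reliable* (`k > T/2` responses of
`T` trials), *unreliable* (`1 ≤ k ≤ T/2`; with an even trial count an
exactly-half responder is unreliable), *silent* (`k = 0`). Population
fractions use an explicit denominator — total imaged cells by default,
responsive cells on request — and are summarised both over odor-trial
pairs and over odors, since either reduction is defensible for error bars;
both are labelled in the output.

Sample (n−1) standard deviations are used everywhere, including CV and
Fano factors; this matters at 2–6 responses per cell-odor.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:

- **Reliability continuum.** Each (cell, odor) draws a latent response
  probability from the species' reliability Gamma (fly 0.64/0.42, mouse
  0.64/0.17) truncated to [0, 1] by rejection (implemented as inverse-CDF
  on the truncated support, which is distributionally identical). The
  exposed preset samplers (`sample_preset`) draw from the fitted Gamma
  laws themselves, untruncated; truncation happens only where a draw is
  used as a probability. Truncating at 1 removes ~4% of the fly law's
  mass, which biases a naive refit (shape +9%, scale −25%) — a property
  of truncation, not of the fit.
- **Amplitude–reliability coupling.** Response amplitudes follow the
  species' response-size Gamma (fly 0.77/0.28) exactly, coupled to
  reliability through a Gaussian copula (default rank correlation 0.9) so
  that expected amplitude rises monotonically — approximately
  exponentially — with reliability while the amplitude marginal stays the
  configured Gamma. A pure log-linear mode (`coupling="exponential"`,
  `E[amp] = a·exp(b·p)`) is available; it cannot preserve the Gamma
  marginal, which is why the copula is the default.
- **Trials and frames.** Each trial responds Bernoulli(p); responding
  trials add the cell's amplitude (with Gamma-distributed trial jitter,
  CV 0.4) to the post-onset frames; all frames carry white Gaussian
  baseline noise (default sd 0.02 ΔF/F). The fly grid is 20 baseline +
  5 response frames of 0.5 s (10 s baseline, 2.5 s response window); the
  mouse grid is 22 + 10 frames of 0.453 s. All randomness flows through
  one seeded `numpy` generator; identical (config, seed) gives bitwise
  identical tensors.
- **Correlated odor pairs.** `generate_correlated_pair` shares a tuned
  fraction of cells' latent (p, amplitude) fields between two odors,
  drawing shared cells preferentially from the high-reliability tail
  (weights ∝ p²) when the target correlation exceeds 0.5, as observed for
  similar odors. The calibration target is the Pearson correlation of the
  two expected-response vectors (p·amplitude over cells) — the noise-free
  representational similarity — matched to ±0.1 by bisection on the
  shared fraction; an unreachable target raises an error. Trial-averaged
  vectors measured from the finite-trial tensor are attenuated below the
  latent value, exactly as trial averaging attenuates correlations in
  real data.

What the generator does **not** emulate: imaging artifacts (motion,
neuropil contamination, bleaching), temporally correlated baseline noise,
odor-concentration effects, and any within-trial response dynamics beyond
a boxcar. Tests passing on synthetic data therefore validate the
statistical machinery, not robustness to acquisition artifacts.

## Winner-take-all circuit model

A linear rate model of the fly PN→KC→APL circuit with 50 PN types and 150
KCs (problem size chosen so a full sweep runs in seconds; the code scales
to thousands of KCs and the statistics are insensitive to population
size):

1. claw counts per KC ~ Binomial(8, 0.85), zero draws redrawn; each claw
   samples a PN type uniformly with Gamma(4, 4) strength;
2. KC drive `K_i = Σ_j P_j s_ji` from exponential PN rates, rectified at a
   threshold `t` (default 0 — suppressing the bottom 10–20% has no effect
   on the statistics and slows sweeps);
3. APL drive `Σ_i K_i s_{K_iA}`; APL↔KC contact counts drawn once per KC,
   uniform 2–38 (mean 20), identical in both directions (the connectome
   reports the two directions' counts correlated but not the magnitude;
   we assume perfect correlation);
4. subtractive feedback `APL · s_{AK_i} · gain`, rectified at 0.

The equations are mutually recursive in principle; we implement them as a
single feedforward–inhibit–rectify pass matching their one-shot algebra.

The gain is calibrated by bisection so the noiseless active fraction
(mean over the odor panel) hits a target in the 6–11% range within ±0.5
percentage points; the active fraction is monotone in the gain, so
bisection is exact.

**Noise.** Every locus applies multiplicative Gaussian noise
`x → x(1+η(0,σ))`, drawn fresh each trial. Per-synapse noise on a KC's
`c` unit-strength contacts is applied as one draw with sd `σ/√c` — the
exact law of the mean of `c` independent draws. The single-synapse
variant instead applies one shared draw per KC on the APL→KC side
(correlated synapses). This encodes the model's central averaging law:
feedforward and per-synapse noise average away with convergence
(claws, synapse counts) while APL-source noise, shared across all
feedback synapses, does not — which is why far smaller WTA-locus noise
suffices to destabilise near-threshold cells.

**Sweep.** The default sweep grid combs KC-integration noise
(σ_KC ∈ {0.6, 0.8, 1.0}) jointly with APL-source noise restricted to the
physiologically plausible 15–30% band and gain targets 6–11%. The two
noise loci trade off against each other (APL activity is summed KC
activity, so their fluctuations compound), and APL-source noise alone at
σ ≤ 0.3 cannot reach the observed per-trial reliable:unreliable ratio of
0.72 in this model — the joint grid is where the five experimental
statistics (ratio 0.72; 5.3%/7.2% reliable/unreliable per trial;
6.1%/29% per odor) are matched, at ±25% relative tolerance per statistic
(the tolerance is a package choice; no canonical acceptance band exists
for these statistics). Each configuration is scored over replicate
circuits with fresh connectivity, panel and noise seeds.

One connectivity detail is deliberately simplified: the PN-type
popularity distribution is not published in usable form, so claws sample
types uniformly; a weighted-popularity option exists
(`CircuitParams.pn_type_weights`) but the statistics above do not depend
on it.

## Learning model

KC→MBON weights start equal (w₀ = 1) and only depress:
`w(t) = max(w(t−1) − δ·r_x, 0)`, avoid-MBON weights on rewarded trials,
approach-MBON weights on punished trials, applied sequentially. Neither
w₀ nor δ is experimentally constrained; δ = 0.5 is set so that a typical
reliable synapse (response probability ≈ 0.83, mean response ≈ 0.4)
saturates within about half of the 12-trial normal regime, i.e., "after
very few trials", while unreliable synapses need extended (100-trial)
training.

Two training modes: the **full stochastic mode** resamples each cell's
response per training trial from its reliability probability (amplitude =
its mean per-response size), seeded; the **simplified-saturation mode**
zeroes reliable-cell synapses after normal training and additionally
unreliable-cell synapses after extended training, with no sampling — the
deterministic limit of the full mode at large δ.

Discrimination for a pair trained A→reward, B→punishment is
`D_x = p_x(A)·(w_x→approach − w_x→avoid)` per cell, summed per Eq-style
totals. Class-restricted sums are exported both signed and as sums of
|D_x|; the per-pair "useful discrimination" uses the signed sum, the
per-level improvement analysis uses |D_x| (the convention is a package
choice; both are available). The per-level improvement analysis uses the
full mode, because the level gradient is carried by the
depression-rate × amplitude mechanism that the simplified mode
deliberately discards; the class-level orderings are identical in both
modes.

## Decoders and AUC

Features are per-cell response sizes with non-significant trials zeroed
and, per odor, cells outside the requested reliability class zeroed (a
cell may be kept for one odor and zeroed for another). Decoders are LDA,
kNN (k = 3, neighbour-vote probabilities) and linear SVM (C = 1,
probabilities by softmax over decision values); k and C are not
canonical, so they are recorded in output metadata. Folds are stratified
(every odor in every fold) at 20% test size, seeded.

The pairwise AUC uses midranks on ties, which preserves the
Mann–Whitney equivalence (ties counted ½); the all-to-all score is the
unweighted mean of the symmetrised pair AUCs.

## Numerical conventions and degenerate inputs

- Gamma fits: `scipy.stats.gamma.fit` with location fixed at 0; inputs
  must be ≥10 strictly positive, non-constant values; goodness is the KS
  statistic. Cumulative-frequency curves are provided for nonparametric
  plotting.
- Zero-variance vectors are excluded from correlations with a warning;
  empty classes skip a pair with a notice rather than erroring.
- Gain calibration reports a non-bracketing search instead of looping.
- An all-noiseless model run has no unreliable cells; its
  reliable:unreliable ratio is reported as `inf` and the characteristic
  check fails cleanly rather than dividing by zero.
- The mouse reliability preset uses Gamma scale 0.17; 0.28 also appears
  in the literature for the same data, and the preset value can be
  overridden per config.

## Data formats

Tensors serialize to HDF5 (one dataset + attributes) and to long CSV
(`cell, odor, trial, frame, dF_F` with `#key=value` metadata headers);
both round-trip losslessly, and the CSV loader rejects incomplete
(cell, odor, trial, frame) grids instead of padding. Analysis outputs are
tidy CSVs: the reliability table (`cell, odor, n_responses, n_trials,
p_response, label, expected_response`), overlap matrix (`odor_i, odor_j,
mean_overlap, n_responsive`), fraction summaries (`statistic, reduction,
mean, sem`), and sweep/decoder score tables with one row per
configuration × replicate or mask × model. NWB recordings are not read
directly; convert to either supported layout first.

## Known limitations

- No spiking dynamics, temporal or primacy coding in the circuit model;
  the rate model is a one-shot pass per trial.
- The learning model treats approach/avoid as two lumped MBONs and
  assumes discrimination scales with the weight difference; divisive
  read-outs are not modelled.
- Synthetic baselines are white; detection behaviour on temporally
  correlated noise is untested.
- The sweep's absolute pass counts depend on the chosen tolerance and
  grid resolution and are not comparable across studies; only the
  structure of the passing set (which loci, which bands) is meaningful.
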