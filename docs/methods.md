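# Methods

`ymaze` re-implements, as a tested library, the analysis chain used to
compare neural population codes across virtual-reality Y-maze tasks:
single-neuron trial-type selectivity with a permutation null, linear
population decoding with neuron subsampling, pairwise noise correlations
and their disruption, and hierarchical-bootstrap inference. Because the
original measurements come from live animals, the package ships a
synthetic-data generator that reproduces the statistical structure those
analyses assume; every stage is validated against ground truth or an
independent oracle on generated data.

## Task and behavior model

The task is a two-alternative visual discrimination: a wall grating
(horizontal or vertical) instructs a left or right arm choice. Rule A maps
horizontal → left and vertical → right; Rule B reverses both. In the
switching task the rule alternates in unsignaled blocks. A switch is
evaluated once before each trial and requires all three of: at least 75
trials since the previous switch (or session start), at least 85% correct
over the last 30 trials, and a correct immediately preceding trial. At most
one switch occurs per trial boundary.

Cues are drawn i.i.d. uniform. A bias-correction rule mirrors the training
protocol: after five identical choices in a row (irrespective of
correctness), the next trial's rewarded side is forced to the opposite side
and the run counter restarts, so a persistent one-sided chooser is forced
on every sixth trial. Note this triggers on choice runs, not error runs —
an agent that is always correct still receives forced trials whenever the
cue draw happens to produce five same-side trials.

The agent is deliberately not a belief-updating model: it chooses the
rewarded side with probability `p_correct`, and after each rule switch its
effective accuracy ramps linearly from chance (0.5) back to `p_correct`
over `post_switch_relearn_trials` trials, reproducing drop-and-recovery
dynamics around switches without modeling inference. Lapse trials
(probability `lapse_rate`) ignore the cue and go left with probability
`(1 + side_bias)/2`; visually guided trials (probability `guided_fraction`)
are always correct. With guided fraction *g* and accuracy *p* the expected
session performance is *g* + (1 − *g*)·*p*. Optional per-trial laser-target
assignment (control vs cortical sites) subtracts a configurable amount from
the effective accuracy, which is how inhibition effects are emulated.

## Synthetic population activity

Each neuron carries a Gaussian spatial tuning bump (height `peak_rate`,
width `tuning_width_bins`, preferred bin uniform over the maze), so the
population forms a sequence of transiently active cells along the maze.
A `fraction_selective` share of neurons has the bump raised additively by
`selectivity_strength` event-rate units on the preferred trial type, which
can be a cue–rule pair (`single`), a cue across rules (`cue`), or a choice
across rules (`choice`). Trial-to-trial variability is a shared
standard-normal latent per trial entering every neuron with loading λ
(`shared_noise_loading`) plus private Gaussian noise of SD σ
(`private_noise_sd`); for unit loadings the expected pairwise noise
correlation is λ²/(λ² + σ²). Activity is clipped at zero to resemble
deconvolved event rates; the closed-form correlation check is run with
clipping disabled because clipping distorts the Pearson coefficient.

Two noise geometries are provided. `uniform` loads the latent equally on
all neurons (the default; disruption then mostly leaves decoding
unchanged because the latent is orthogonal-ish to the discriminant and can
be estimated and cancelled). `signal` places the latent exactly in the
signal subspace — selective neurons only, signed by preference and scaled
by each neuron's tuning curve — producing information-limiting
correlations: no read-out can cancel the fluctuation, so removing the
correlations by trial shuffling *raises* decoding accuracy.

What the generator does **not** emulate: calcium indicator dynamics and
deconvolution artifacts, non-Gaussian and rate-dependent noise, more than
one latent dimension per area group, spatially drifting tuning, and
behavioral correlates of neural state (arousal, running speed coupling).
Passing tests therefore show that the *analysis code* is correct and
calibrated under the assumed structure, not that real recordings satisfy
that structure.

## Preprocessing

* **ΔF/F**: the numerator is the neuropil-corrected trace
  `F − 0.7·F_neuropil` minus its running baseline; the denominator is the
  running baseline of the raw somatic trace. Baselines are the 8th
  percentile in a 60-s sliding window, centered, truncated at the edges,
  with linear-interpolation percentiles. These window conventions are
  implementation choices, documented so results reproduce bit for bit.
* **Spatial binning**: deconvolved activity is *summed* into uniform 5-cm
  half-open bins `[lo, hi)` along the long maze axis (a 230-cm maze gives
  46 bins); frames outside the maze extent are dropped and counted.
* **Trial selection**: neural analyses use only correct trials from
  high-performance periods — at least 80% correct within a 10-trial
  window, which excludes post-switch relearning. The window anchoring is
  configurable (`any` full window containing the trial, the default;
  `trailing`; `centered`). Trials are then subsampled without replacement
  to equalize counts: 30 per trial type for two-type analyses, 15 per type
  (60 total) when all four cue–choice combinations are analyzed together.

## Selectivity

Per neuron and bin, the auROC between the two trial types' activity
distributions is computed by the Mann–Whitney rank identity with half
credit for ties (deconvolved data contain many zeros, so tie handling
matters; the rank form agrees exactly with the all-pairs count).
Trial-type selectivity is `2·|auROC − 0.5|`. Significance uses 100 label
shuffles with the add-one estimator `p = (1 + k)/(1 + 100)`, so `p < 0.01`
means the observed index beats every shuffle and the marginal
false-positive rate is 1/101 under exchangeability. By default one
permutation per shuffle is applied to all neurons jointly (cheap, and
conservative for population-level counts); independent per-neuron
permutations are available by flag. Per maze segment (first half of stem
15–75 cm, second half 75–150 cm, arms 150–220 cm) the per-neuron values
are averaged over bins whose centers fall in the segment, and the fraction
of selective neurons is computed per bin and then averaged over the
segment's bins.

For four-trial-type data, a neuron is selective within a rule if it has at
least three consecutive significant bins; the rule's direction is the
majority sign of `auROC − 0.5` over significant run bins, with conflicting
signs within a rule classed as `complex`. Across rules: selective in one
rule only → `single_trial_type`; both rules, same choice → `choice`; both
rules, opposite choices → `cue`; neither → `none`.

## Decoding

Per spatial bin, a linear SVM (fixed `C = 1`) predicts the trial type from
a uniform neuron subsample, under stratified 10-fold cross-validation with
per-feature standardization fit on the training folds only (no leakage).
Accuracy — the fraction of held-out trials predicted correctly — is
averaged over folds, bins, and repeated subsample draws. The library
default repetition schedule is 40 repetitions for populations of at most
10 neurons and 20 for larger ones; tests and the example pipeline pass a
smaller count to keep runs short. Choice decoding from running kinematics
uses a binomial GLM per bin with four predictors (pitch, roll, yaw
velocities, lateral position) and the same cross-validation; all-constant
bins report chance with a warning.

## Noise correlations and disruption

Pairwise Pearson correlations of trial-wise responses are computed
separately per trial type and averaged across types. Within a type, the
default computes `r` per spatial bin across trials and averages over bins,
which avoids conflating spatial tuning with trial-to-trial covariance; a
concatenated-bins mode (per-bin mean-subtracted) is available by flag.
Pairs involving a neuron with zero variance within a type are skipped and
logged; area-pair summaries are unweighted means over qualifying pairs.
Disruption permutes each neuron's trials independently within each trial
type: the per-type response multiset of every neuron is exactly preserved
(so mean activity, auROC, selectivity, and significance are unchanged —
bit-identical up to floating-point summation order for the mean), while
shared variability is destroyed. The disruption effect on coding is the
intact-minus-disrupted decoding accuracy with matched subsamples and folds.

## Hierarchical bootstrap

Statistics are reported as mean ± SEM where the SEM is the standard
deviation of the means of 1000 resampled datasets. Resampling draws groups
(sessions, pooled across mice) with replacement, then units (trials or
neurons) with replacement within each drawn group, with resample sizes
equal to the originals. Two distributions are compared by
`p = 2·min(P(A > B), P(A < B))` with the tail probability floored at
`1/n_boot` (so the smallest reportable p is `2/n_boot`) and capped at 1;
multiple comparisons use Bonferroni `min(1, m·p)`. Comparisons of
independently generated cohorts use independent resampling.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng`; pipeline stages
  derive their seeds from the root seed through a SHA-256 hash of a stage
  name, so adding a stage never perturbs earlier stages.
* Permutation p-values cannot be zero (add-one); constant-activity neurons
  get `p = 1` because every shuffle ties the observed index.
* Degenerate inputs are rejected loudly: single-class labels, sessions
  shorter than the filter window, empty bootstrap groups, nonpositive
  fluorescence baselines, deficient trial types in subsampling.
* Problem sizes in the shipped tests and example pipeline (tens of neurons
  per area, 8–20 spatial bins, 150–250 trials, 2–12 decoding repetitions)
  were chosen to exercise every code path at desk scale; all analysis
  functions accept full-size inputs.

## Known limitations

* The generator's single shared latent produces uniform correlation
  structure; real data show distance- and tuning-dependent correlations.
* The agent has no trial-history strategies beyond the relearning ramp, so
  behavioral metrics that depend on sequential effects (win-stay /
  lose-shift) cannot be studied with it.
* `categorize_across_rules` assumes stable tuning across blocks of the
  same rule; representational drift would dilute the categories.
* The bootstrap treats sessions as exchangeable across mice (pooled), the
  design used throughout; a mouse-level nesting is available in the data
  layout but not the default.
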