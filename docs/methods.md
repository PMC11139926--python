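# Methods

This note documents the models, statistics and design choices behind
`shapecat`: what each stage computes, what the synthetic-data generator
does and does not emulate, and where the genuinely open choices were made.

## The analysis problem

A 96-channel microelectrode array in shape-sensitive visual cortex records
multi-unit activity (MUA, binned spike counts) and local field potentials
(LFP) while 54 stimuli are presented: a factorial design of 9 silhouette
shape types x 6 semantic categories, constructed so that every shape type
contains one exemplar of every category and vice versa. The scientific
question is whether the recorded population encodes object *shape*, object
*category*, or both — and at which level of description (single channels,
pattern dissimilarity, linear decodability) each kind of information is
visible.

## Preprocessing

* **Net MUA.** Per trial and channel, the mean firing rate in the analysis
  epoch minus the mean rate in the [-300, 0) ms baseline, in spikes/s
  regardless of bin width. All windows are half-open `[start, end)` in ms
  relative to stimulus onset, so abutting bins partition time exactly.
* **LFP.** A zero-phase (symmetric FIR, 'same'-aligned) 2-300 Hz band-pass;
  trials whose broadband RMS (averaged over channels) exceeds the
  across-trial mean by more than 2 SD are flagged, never dropped silently.
  The summary statistic (per-trial RMS averaged over channels) is a package
  choice; it is exposed in the config.
* **High gamma.** Morlet wavelets with 7 cycles at 1-Hz steps across
  60-120 Hz; per trial, channel and frequency the power is divided by its
  own baseline mean, then averaged across the band (normalize-then-average,
  in that order), and 100 ms is trimmed from each trial edge to discard
  filter transients. The result is a unitless ratio with 1 = baseline.
* **Z-scored condition means.** Per channel, responses to the 54 stimuli
  are standardized to mean 0 / SD 1; constant channels map to zeros with a
  warning. Localizer responses are instead normalized by the peak of the
  intact-condition mean time course (intact peak = 1 exactly).

## Channel statistics

* **Responsiveness.** One-way ANOVA between per-trial baseline means and
  per-trial post-stimulus means (default window [50, 250) ms — the 200-ms
  interval has no documented start, so this is a config choice), threshold
  Bonferroni-corrected at alpha/n_channels, and the post mean must *exceed*
  the baseline (an increase is required; suppression does not count). The
  high-gamma variant ranks conditions per channel by mean post-stimulus
  power and restricts the test to trials of the top two conditions, which
  protects sparse responders in the noisier band-power signal.
* **Latency.** Net activity in 25-ms bins; each post-onset bin is tested
  against zero across trials (two-sided one-sample t-test at alpha 0.05,
  uncorrected — the per-bin test is otherwise unspecified, so this is a
  documented default). The latency is the start of the first run of three
  consecutive significant bins.
* **Analysis window.** The mean latency across channels is snapped to the
  nearest 50-ms bin center (25, 75, 125, ... ms) and the window spans 50 ms
  before to 150 ms after that center. Mean 123 ms gives [75, 275); mean
  65 ms gives [25, 225).
* **Two-way ANOVA.** Fixed-effects shape x category ANOVA with interaction
  per channel, Type II sums of squares (robust to the mild imbalance of
  10-19 trials per stimulus without order dependence). Effect sizes are
  classical eta² = SS_effect / SS_total — not partial — so the three
  components sum to at most 1 and are comparable across terms. Tukey HSD
  post-hocs run on each significant factor's marginal means. The batch
  path used by `tuning_table` computes the same quantities for all
  channels at once from nested least-squares fits; the test suite asserts
  its equality with the statsmodels single-channel route.
* **Selectivity class.** Significant interaction -> `interaction`
  (regardless of main effects); else a lone shape main effect ->
  `shape_only`; else a lone category main effect -> `category_only`; else
  `responsive_only`. A channel with both main effects but no interaction
  falls through to `responsive_only`; the rule is kept deterministic and
  minimal rather than inventing an extra class.
* **Swidth.** `(n - sum(r_i)/max) / (n - 1)` over the n = 54 mean net
  responses, after clipping negative net responses to zero (the index
  presumes non-negative rates). 0 = flat, 1 = single-stimulus responder.
* **d'.** `(mu_pref - mu_nonpref) / sigma` with the *pooled* SD
  `sqrt((var_pref + var_nonpref)/2)`. A printed variant of this formula
  subtracts the variances, which can be imaginary; the pooled (plus-sign)
  form is implemented, as the accompanying text ("pooled variance of the
  two distributions") requires. The non-preferred side defaults to all
  non-maximal stimuli pooled; a worst-stimulus variant is available.

## Representational analysis

* **Split-half RDM.** Trials of each stimulus are split into disjoint
  halves (odd counts put the extra trial in half A so no trial is wasted);
  the half-A stimulus-mean channel patterns are Pearson-correlated with
  the half-B patterns for every stimulus pair; coefficients are averaged
  over 100 iterations, symmetrized with the transpose, and converted to
  1 - r. The diagonal is forced to zero (its off-zero part is split-half
  reliability, which this package does not model). Splits are stratified
  per stimulus.
* **Model RDMs.** Behavioral shape/category models are *generated* block
  structures plus rating noise (the original ratings are not public);
  silhouette dissimilarity is the RMS pixel difference
  `sqrt(sum (p_i - p_j)^2) / sqrt(n_pixels)`; aspect ratio is the
  isoperimetric quotient `P^2 / (4 pi A)` (1 for a disc, 4/pi for a
  square) with a Crofton perimeter estimate, and its RDM the pairwise
  absolute differences. The aspect-ratio functional is pluggable since
  alternative shape-axis definitions exist.
* **RSA.** Rank correlation (Spearman by default; Pearson available and
  recorded in output metadata) over off-diagonal upper triangles; the null
  relabels the stimuli of one RDM — permuting rows and columns together,
  which preserves the matrix geometry — and the one-sided p is
  `(1 + #{null >= observed}) / (n_perm + 1)`.
* **MDS.** Nonmetric (Kruskal stress-1) SMACOF with 8 seeded restarts per
  dimensionality; the stress curve warm-starts each dimensionality from
  the previous best solution padded with a zero coordinate, which makes
  the curve non-increasing by construction. Intra- vs inter-cluster
  Euclidean distances in the 2-D solution are compared with a two-sample
  t-test.
* **Clustering.** Agglomerative single linkage on the dissimilarities,
  flat cut at <= 10 clusters.

## Decoding

Linear SVMs (one-vs-one, C = 1) on z-scored per-channel net activity in
100-ms windows stepped by 50 ms; 10-fold cross-validation stratified by
*stimulus* so every exemplar appears in test folds and no exemplar
identity leaks into class labels. Scaler and classifier parameters are fit
on training folds only (a canary test injects a test-only artifact and
asserts accuracy does not move). Significance per window is a one-sided
t-test of fold accuracies against the empirical chance level — the mean of
the arbitrary-grouping null, in which the 54 stimuli are randomly
partitioned into 6 groups of 9 (or 9 of 6) and the identical decode is
run. Onset is the center of the middle window of the first three
consecutive significant windows. Temporal generalization allocates entire
trials once to train/test and evaluates each train-window decoder on every
test window. The cross-dimension control trains on trials from one half of
the orthogonal factor's levels and tests on the disjoint half (shapes
split 5/4, categories 3/3; 10 seeded balanced splits averaged).

## The synthetic-data generator

Spike counts are drawn per 25-ms bin around a per-channel rate profile:
baseline rate (default 5 Hz) before the channel's latency and baseline +
gain x weight (gain default 20 Hz) afterwards, where the per-stimulus
weight in [0, 1] encodes the channel's class — graded shape-type tuning,
graded category tuning, boosted (shape, category) cells, untuned, or
silent. Latencies are normal (mean 120 ms, jitter 25 ms) snapped to the
bin grid; trials per stimulus are uniform on 10-19; class proportions
default to the observed mix (16% shape-only, 3% category-only, 48%
interaction, 10% responsive-only, rest unresponsive).

Counts are overdispersed: a Gamma-Poisson mixture with variance = 2 x mean
(Fano factor 2). Pure Poisson counts make individual stimuli far more
identifiable across 90 independent channels than real recordings are —
with clean counts, a decoder can memorize single exemplars so well that
random stimulus groupings decode far above chance, a regime the modeled
recordings do not show. Fano 2 is within the range reported for cortical
population spiking and brings the arbitrary-grouping null close to chance
while leaving per-channel statistics (ANOVA, d', latency) well powered.

Interaction channels come in the two flavors such sites show: *exemplar*
channels boost a few (default 3) exemplars of a single category on top of
a broad base response (real interaction sites are visually responsive to
most stimuli), and *cell* channels boost arbitrary cells so shape
preference differs between categories (default 50/50 mix). An optional
`interaction_halo` lets exemplar channels respond weakly to the other
exemplars of their category; it is off by default because even a small
channel-specific halo imprints category structure onto the pattern
correlations.

The `category_preferring_array` preset models the array profile in which
category becomes linearly decodable without any category-tuned channel
class: interaction channels concentrate on exemplars of one category, and
— the decisive ingredient — the whole responsive population carries a
near-uniform additive elevation (default 20% of the gain, about 4 Hz) for
that category's stimuli, emulating an array-wide preference for, say,
animal images. Because Pearson pattern correlation centers each stimulus
pattern across channels, an (almost) channel-uniform elevation leaves the
RDM — and hence RSA against a category model — essentially untouched,
while a linear decoder reads the population mean directly and the signal
generalizes across shape types by construction. This is precisely the
regime in which representational analyses report a shape-based code while
decoders extract reliable category information. The elevation does induce
weak category main effects on many individual channels (in combination
with their shape or interaction effects) — the single-channel signature
of an array-wide preference — but no category-only channel class exists
in the generating population.

The optional continuous signal is Gaussian noise plus a 60-120 Hz
band-limited component whose amplitude follows the same tuning weights,
so the high-gamma path sees the structure the spiking path sees.

What the generator does **not** emulate: correlated noise between
channels, adaptation and offset responses, oscillatory LFP structure
outside the high-gamma band, eye movements, and non-stationarities across
a session. Passing tests therefore certify the *pipeline* — its formulas,
nulls, calibration and leak-freedom — on data whose ground truth is
known; they do not certify that real recordings satisfy the generator's
independence assumptions.

## Numerical and testing choices

* Every stochastic operation takes an explicit seed or generator; the
  pipeline derives per-stage substreams from one master seed by hashing
  stage names, so adding stages never perturbs existing draws.
* Degenerate inputs have defined behavior: constant channels z-score to
  zeros (warning), a zero rectified maximum makes Swidth undefined
  (channel excluded, warning), zero pooled SD makes d' an infinite
  sentinel, stimuli with one trial are a hard error for split-half RDMs.
* Rank correlations use average ranks for ties; RSA permutation p-values
  include the identity permutation (the +1 convention), so p is never 0.
* Test problem sizes are scaled for a single CPU: split-half RDMs use 100
  iterations, acceptance-level RSA calibration 200 replicates at 200
  permutations, arbitrary-grouping nulls 25-50 repetitions, and the
  dissociation scenario 10 seeds; these sizes are package choices that
  keep Monte-Carlo error well inside the asserted margins.
* The localizer contrast reports per-window ANOVA p-values; an optional
  Holm correction across windows is available but off by default, matching
  the per-window annotation style of the modeled analysis.

## Known limitations

* The behavioral shape/category models are synthetic block structures,
  not real rating data; RSA effect sizes against them are not comparable
  to published values.
* The two-way ANOVA assumes homoscedastic Gaussian residuals; net-rate
  responses from overdispersed counts violate this mildly, which is the
  realistic situation and is absorbed by the calibration tests.
* `classify_selectivity` has no class for "both main effects without
  interaction"; such channels land in `responsive_only`.
* Real pretrained networks (VGG-19 / ResNet-50) are supported only through
  the feature-extractor interface with user-supplied weights; the shipped
  extractors are a raw-pixel identity map and a deterministic oriented
  filter bank.
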