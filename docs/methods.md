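# Methods

This note documents the models and procedures implemented in `swbtext`,
the design decisions taken where the design was genuinely open, and what
the synthetic study conditions do and do not establish.

## Text preprocessing

Cleaning runs in a fixed order: hyperlink removal → digit removal →
emoticon ("smiley") conversion → punctuation removal → lowercasing →
whitespace tokenization.  Emoticons are punctuation sequences, so they
must be rewritten to word tokens (`:-)` → `happyface`, `:-(` →
`sadface`) before the punctuation strip; hyperlinks go first so
fragments like `:/` inside a URL can never match an emoticon pattern.  A
URL is any token starting with `http://`, `https://` or `www.`.  Only
the two mappings above are treated as canonical; the shipped default map
adds common variants (`:)`, `=)`, `:D`, `:(` …), is matched
longest-pattern-first, and can be replaced wholesale from CSV.  Stop
words are deliberately retained: all downstream scoring uses closed word
lists that already account for them.  Both cleaning passes are
idempotent, a property the test suite checks by fuzzing.

## Affect features

Each status receives an integer valence sum (+1 per positive-lexicon
token, −1 per negative, repeats counted — words, not types) and a
ternary polarity by its sign.  User-level features:

* `mean_sentiment` = Σ status valence sums / number of statuses.  The
  *status count* is the normalizer, not the word count: status lengths
  are extremely uneven (the emitted length mixture is ~11 % under four
  words, ~65 % four to twenty, ~24 % longer), so the number of statuses
  is the more stable index of how much a user writes.
* `pos_freq`, `neg_freq` = proportions of positive / negative statuses,
  with neutral statuses kept in the denominator.
* `pos_neg_ratio` = (#pos + 1)/(#neg + 1).  The add-one smoothing keeps
  the ratio defined for the many users with no negative statuses; the
  raw #pos/#neg is also exposed (NaN when #neg = 0).

Per-status scores are never length-normalized.  Correlation tables use
Pearson r with two-sided p; a constant column yields NaN, never a silent
zero.

## Topic and category features

All of a user's statuses are concatenated into one document.  Category
scores count document tokens in each closed-vocabulary category and are
divided by the user's status count, the same normalization argument as
for sentiment (raw counts are also available, since the convention is
not externally fixed).  Topic words are matched as exact tokens.

Two topic scorers operate on a *truncated* word–topic table (each topic
lists at most 20 (word, p(t|w)) pairs):

* probability: p(t|u) = Σ_w p(t|w)·p(w|u), p(w|u) = count(w)/total, the
  sum running only over listed words;
* word count: each occurrence of a word listed under k topics adds 1 to
  each of those k topic scores, ignoring p(t|w).

Truncation makes the probability form pathological: a word kept in only
one topic carries p(t|w) = 1 and dominates, and p(w|u) is inflated for
users with small word counts.  The word-count form compresses the
max/min ratio over a user's positive topic scores; this is a measured
property (`compare_scoring_ratio`, checked on generated fixtures with
the pathology planted), not an assumed identity.  The word-count scores,
status-count-normalized, are what enters the prediction model.

## Feature selection

Topics and categories (never the affect features, which always enter the
model directly) are reduced by an elastic net on standardized training
columns.  The mixing parameter follows the glmnet convention; the
default 0.1 is mostly ridge, chosen small so that correlated informative
features survive together rather than being collapsed to one, as lasso
tends to do.  The penalty strength is not treated as known: it is chosen
by 10-fold cross-validation on the training split with the 1-SE rule
(largest penalty whose CV error is within one standard error of the
minimum), which errs toward sparser models; a fixed penalty can be
supplied instead.  Standardization statistics are fit on the training
rows and frozen.  Features with exactly zero coefficients are dropped.

## SWL prediction

A random forest regresses self-reported SWL on the selected features
plus the three sentiment features.  Trees are grown on bootstrap
resamples; at size n the expected out-of-bag share per round is
(1 − 1/n)^n, ≈ 36.8 % at n = 1873.  Aggregation is the mean of tree
outputs — the regression analogue of majority vote — so predictions are
confined to [min(y_train), max(y_train)].  The manual grid is ntree ∈
{500, 1000, 1500, 2000} × ntry ∈ {2, 3} (ntry = candidate features per
split, kept at these small published values on purpose), scored by OOB
Pearson r; ties break toward the smaller, cheaper configuration.
Evaluation reports Pearson r, its two-sided p, and RMSE on a held-out
test split (train fraction 0.717, reproducing a 1873/739 partition at
n = 2612).  The naive baseline predicts the training median plus a
U(0, 0.001) jitter, which keeps a correlation defined while carrying no
information.  Variable importance is plain permutation importance (mean
squared-error increase on held-out rows, averaged over repeats);
conditional importance in the `party::cforest` sense is out of scope.

## SWB profile and CES-D validity

For predictive validity a forest with the best grid configuration is
refit on *all* users and its out-of-bag predictions taken as the
machine-predicted SWL — OOB predictions are an honest internal
validation, as accurate as an equally sized test set.  The profile
bundles predicted SWL with the three sentiment features.  Validity
against CES-D depression scores (treated as an arbitrary continuous
criterion; the instrument's usual 0–60 range is the generator default
and configurable) is assessed on the CES-D subsample two ways: direct
correlations of each profile field with CES-D, and random-forest
prediction of CES-D from three nested feature sets — sentiment only (3),
self-reported SWL + sentiment (4), machine-predicted SWL + sentiment
(4) — plus the jittered-median baseline, all on one shared 70/30 split
with one shared seed.

## Activity sentiment

A status matches an activity if it contains any of the activity's terms
(single tokens, or adjacent-token bigrams for two-word terms); one
status may match several activities.  Per activity the *mean* per-status
sentiment of matched statuses is standardized across activities into
z-scores with the population-SD convention (so the reported z-scores sum
to zero with unit SD).  The mean, not the raw sum, is standardized
because sums scale with corpus size and would not be comparable across
corpora; the raw sum is reported alongside.  The shipped activity term
file (`swbtext/data/activity_terms_synthetic.csv`) is a synthetic
stand-in — the original rated term list is not redistributable — with
nine everyday activities and two raters' binary relevance labels whose
agreement matches the published level (κ ≈ 0.36).  Cohen's κ is
computed as (p_o − p_e)/(1 − p_e) with a two-sided p from the
large-sample normal approximation of κ's null standard error.

## Synthetic study conditions

The generator's defaults define the package's study conditions; they are
scaled for a desktop run (~2000 retained users, ~60 statuses each)
rather than for fidelity to any particular platform's volume.

| parameter | default | rationale |
|---|---|---|
| `n_users` / `mean_statuses` / `nb_dispersion` | 2500 / 60 / 3 | negative-binomial posting counts (overdispersed); with the ≥30-status retention filter ~80 % of users survive, emulating the published 3324→2612 filtering at desk scale |
| `swl_mean`, `swl_sd` | 4.2, 1.3 | population SWL ~truncated normal on [1, 7] with the general-population mean of 4.2 |
| `noise_sd` | 0.5 | self-report noise in SWL units; implies short-term test–retest reliability ≈0.87, consistent with the instrument's published 0.84 over two months |
| `base_positive`, `affect_effect`, `affect_noise` | 0.60, 0.02, 0.08 | positive-valence emission probability ~0.6 (most users post more positive than negative statuses) rising weakly with SWL; targets corr(mean sentiment, SWL) ≈ 0.2 |
| `topic_effect`, `topic_noise` | 0.45, 0.25 | log-propensity of the 10 informative topics per SWL z-unit, plus person-level topical-interest slack; sized so the fitted model reaches r ≈ 0.6 against latent SWL — recoverable but far from deterministic |
| `cat_effect`, responsive categories | 0.08, 6 pools × 25 words | a few closed-vocabulary categories draw on filler vocabulary outside the topic table and tilt with SWL, giving category features independent signal, as LIWC categories have on real data |
| `cesd_slope`, `cesd_affect_slope`, `cesd_topic_slope`, `cesd_noise` | −2.4, −1.2, −0.4, 10 | CES-D loads on latent SWL, on trait positivity (observable through sentiment by every feature set, which correlates the validity rows' errors) and weakly on topical slack; jointly targets corr(self-SWL, CES-D) ≈ −0.27 |
| `cesd_fraction` | 0.19 | emulates a CES-D subsample of ≈386 users within the retained population |
| `activity_rate` + per-activity valence shifts | 0.06 | ~6 % of statuses mention an activity; co-occurring valence emission is shifted per activity (religion/holidays up, death/disease strongly down), planting the cross-activity z-score pattern |

Raw text is emitted with emoticons, URLs, digits, stray punctuation and
random capitalization so the cleaning stage is genuinely exercised; the
planted tokens are recovered exactly after preprocessing.  One master
seed fans out to per-stage seeds via `numpy.random.SeedSequence`;
identical seeds yield byte-identical corpora and reports.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: real lexical semantics (words are
pseudo-words plus a small real-word activity vocabulary), timestamps and
seasonality, social-graph structure, multilingual text, sarcasm or
negation scope, and any platform's true posting dynamics.  Results on
the synthetic corpora demonstrate that the pipeline recovers structure
*of the assumed form* at realistic effect sizes; they are not evidence
about effect sizes in any real population.

## Numerical choices and degenerate inputs

* Pearson r on a constant vector is reported as NaN and flagged, never 0.
* The grid search treats undefined OOB r as worst; full ties fall back
  to the smallest (ntree, ntry).
* `pos_neg_ratio` uses add-one smoothing (see above).
* Empty documents: word-count topic scores are zero; probability scores
  raise (p(w|u) undefined), as does affect aggregation for a user with
  zero statuses — such users must be removed by the retention filter.
* Cohen's κ is undefined when both raters are constant and identical;
  this raises rather than returning 1 or 0.
* Activity z-scores require at least two activities with matches (the
  cross-activity SD is otherwise undefined); a zero SD yields all-zero
  z-scores.
* All elastic-net and forest seeds are explicit; the test suite asserts
  bytewise reproducibility of reports under a fixed master seed.

## Known limitations

* The validity ordering (self-reported SWL ≥ machine SWL ≥ sentiment as
  CES-D predictors) is a small-gap comparison at a few hundred CES-D
  users; individual replications can and do invert adjacent rows, and
  the package reports its stability over ten replications rather than a
  single verdict.
* ntry ∈ {2, 3} is small for feature sets above ~100 columns; it is kept
  because those are the published grid values, and the grid is easily
  extended via `ForestConfig`.
* The elastic-net penalty path and 1-SE rule make the *number* of
  selected features vary across seeds; only recovery of planted
  informative topics, not the selected-set size, is treated as a stable
  quantity.
* Permutation importance on correlated features distributes credit
  across the correlated group; importances are ranks, not causal
  weights.
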