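# swbtext

Subjective well-being (SWB) profiles from short social-media status texts.

SWB has two components: *affect* (the emotional component, split into
intensity and frequency) and *satisfaction with life* (SWL, a cognitive
self-evaluation usually measured by a five-item scale on a 1–7 range).
Self-reports of SWL are sparse and biased by memory; status updates are
abundant and written unprompted.  `swbtext` implements a complete,
reproducible pipeline that turns a corpus of per-user status updates into
a machine-assessed SWB profile, for researchers in computational social
science and digital phenotyping:

1. **Text cleaning** — hyperlink and digit removal, emoticon conversion
   (`:-)` → `happyface`), punctuation stripping, tokenization.
2. **Lexicon sentiment** — each status gets an integer valence sum (+1 per
   positive word, −1 per negative); user-level affect features are the
   mean sentiment (normalized by *status count*, not word count), the
   positive/negative status frequencies, and their ratio.
3. **Topic and category features** — closed-vocabulary category counts
   (LIWC-style, 66 categories) and topic scores from a truncated LDA
   word–topic table.  Both scorers are provided: the probability form
   p(t|u) = Σ_w p(t|w)·p(w|u) and the word-count form (each use of a word
   listed under a topic adds 1 to that topic, ignoring p(t|w)).  On
   truncated tables the word-count form compresses the max/min ratio of a
   user's positive topic scores, avoiding the artificial dominance of
   words kept in a single topic (where truncation forces p(t|w) = 1).
4. **Elastic-net reduction** — topics and categories are reduced by an
   elastic net (mixing 0.1, mostly ridge, so correlated informative
   features survive together; penalty chosen by 10-fold CV with the 1-SE
   rule on the training split only).
5. **Random-forest SWL model** — a manual grid over ntree ∈
   {500, 1000, 1500, 2000} × ntry ∈ {2, 3}, scored by out-of-bag (OOB)
   Pearson r (≈36.8 % of training rows are out of bag per bootstrap
   round), then evaluated on the held-out test split (r, p, RMSE), against
   a jittered-median baseline.
6. **SWB profile & predictive validity** — OOB-predicted SWL is bundled
   with the sentiment features and validated against CES-D depression
   scores (direct correlations plus random-forest prediction from three
   nested feature sets on a shared 70/30 split).
7. **Activity sentiment** — statuses mentioning everyday activities
   (religion, meals, chores, death/disease, …) are scored and the
   per-activity mean sentiments standardized into cross-activity
   z-scores; rater agreement on the activity terms is quantified by
   Cohen's κ.

Because real linked corpora of this kind cannot be redistributed, the
package ships a first-class synthetic corpus generator
(`swbtext.synthetic`) that plants the assumed structure — heavy-tailed
status counts with a ≥30-status retention filter, positively skewed
sentiment, informative topics, and a CES-D criterion negatively linked to
SWL — so every stage is testable and the whole analysis runs end to end
on a laptop.

## Worked example

```python
import pandas as pd
from swbtext import GenConfig, RunConfig, run_pipeline
from swbtext.model import ForestConfig

cfg = RunConfig(
    gen=GenConfig(n_users=400, mean_statuses=45, n_topics=60,
                  n_informative_topics=6, n_categories=20, seed=11),
    grid=(ForestConfig(500, 2), ForestConfig(500, 3)),
    seed=11,
)
result = run_pipeline(cfg, outdir="swb_run")
print(result.swl_models.round(3).to_string(index=False))
```

prints the feature-set ladder for SWL prediction (about 330 users survive
the retention filter here; ~100 form the test split):

```
                             feature_set  n_features     r     p  rmse
                                baseline           1 0.061 0.604 1.406
                     selected categories          16 0.567 0.000 1.224
                         selected topics          42 0.485 0.000 1.300
             selected topics + sentiment          45 0.501 0.000 1.302
selected topics + categories + sentiment          61 0.582 0.000 1.267
```

The baseline (training-median plus a U(0, 0.001) jitter) is uncorrelated
with self-reports, as it should be; adding sentiment to the selected
topics, then the selected categories, improves the test-set correlation,
and the full model recovers the planted signal at r ≈ 0.58 with an RMSE
of ≈1.27 SWL units.  The CES-D validity table from the same run,

```
                      feature_set  n_features      r     p   rmse
                         baseline           1 -0.194 0.507 10.571
                        sentiment           3  0.191 0.512  9.729
    self-reported SWL + sentiment           4  0.284 0.324  9.539
machine-predicted SWL + sentiment           4  0.127 0.665  9.976
```

shows the self-reported SWL as the strongest depression predictor at this
small n, and `result.activity_sentiment` the planted activity pattern
(religion and holidays high, death/disease lowest):

```
      activity  n_statuses  z_score
        chores          92     0.73
 death_disease          85    -1.85
        family         105    -0.19
       holiday          91     1.27
         maths         100    -0.99
          meal          94     0.56
      religion         159     1.26
        school          97    -0.72
talk_to_friend         107    -0.07
```

The same workflow is available from the shell (generator fields and run
settings live in one flat YAML file; flags override it):

```bash
swb synth --config cfg.yaml --seed 11 --out data/   # corpus + word-list resources
swb run   --config cfg.yaml --seed 11 --corpus data/ --out run/
```

Every run writes `manifest.json` (seeds, parameters, versions) and the
report CSVs (`table1_affect_correlations.csv` … `table4_activity_sentiment.csv`,
`selected_features.csv`, `variable_importance.csv`) to the output
directory; re-running with the same manifest settings reproduces them
byte for byte.

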