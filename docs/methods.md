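# Methods

This note documents the models, parameters and numerical choices behind
`spvscreen`, what the synthetic cohort generator does and does not emulate,
and the known limitations.

## Pipeline model

The analysis treats user-level risk screening as a staged supervised
problem:

1. **Post filtering (SPVC → SPV).** A binary post classifier is trained on
   a labeled corpus of suicide-related vs control posts: tf-idf over word
   1–5-grams (lowercased, `\w+` tokens), truncated SVD keeping components up
   to 95% cumulative explained variance (capped at 128 components and at
   `n_samples − 1`; the tail variance of a post-level tf-idf spectrum is
   noise and higher ranks only add cost), standardization, and L2 logistic
   regression. Training reports stratified 10-fold cross-validated
   precision/recall/F1/AUC. Each user's *short profile version* is the at
   most `k = 15` highest-scoring posts with probability strictly greater
   than the 0.5 threshold ("over the threshold" is strict). Score ties are
   broken by recency (more recent first), then post id — the tie-break is a
   package convention, made deterministic and documented. Users with no
   post above threshold keep an empty SPV (`has_spv = False`) and are never
   dropped before the experiment stage.

2. **SNPSY feature bank.** 9 behavioral + 5 tweet-statistic + 5 relational
   features, one rate per lexicon category, and a sentiment median
   (16 categories in the shipped synthetic lexicon → 36 features; a
   92-category dictionary would give the 112-wide bank). Conventions:
   - STTR slot counts use the *full-profile* in-window posts, and the
     normalizer `T` is the in-window post count (not the lifetime
     `statuses_total`). Slots are `floor(hour/3)` over UTC hours; the slot
     pair ring is circular (slot 7 adjacent to slot 0).
   - Weekday/weekend ratios, median inter-post gap, quarterly ratios,
     medians of SPVC scores, tweet lengths, favorites and retweets, lexicon
     rates and sentiment are computed over SPV posts. Quarters are fixed
     calendar quarters of the collection-window year.
   - Lexicon matching is greedy left-to-right, longest-match-first,
     non-overlapping within a category; counts are divided by the token
     length of the concatenated SPV text, so every rate is in [0, 1].
   - Features undefined for a user (empty SPV, fewer than 2 SPV posts for
     the gap median, missing images) are NaN at extraction and imputed with
     per-feature *training-row* medians at modeling time; the provenance
     sidecar records `has_spv` and the imputed field list per user.
   - Tokens are lowercase, punctuation-stripped whitespace tokens.

3. **Text models.** Each user is one document (concatenated preprocessed
   post text; money/phone/digit/hashtag/emoticon spans become placeholder
   tokens), in a full-profile and an SPV variant. tf-idf over 1–5-grams
   with a document-frequency floor: an n-gram is kept iff its raw document
   frequency is at least `ceil(0.05 · n_documents)`. Documents are capped
   at 2000 tokens before vectorization: concatenated full profiles are tens
   of thousands of tokens, and uncapped 4/5-gram vocabularies dominate both
   memory and model-selection runtime while adding no discriminative mass
   (the cap is configurable; it parallels the original cap of 1000 images
   per user). tf-idf uses raw term frequency and L2 normalization; the
   manifest records the settings and the stopword-list hash. The *outputted
   feature* is the out-of-fold predicted probability of a seeded,
   stratified 10-fold L2-logistic model for training users, and the
   full-training-set model's probability for test/unseen users; users with
   an empty SPV document receive the training class prior.

4. **Combination and evaluation.** Ten recipes (two BoW baselines, SNPSY,
   BoW+SNPSY via the outputted feature, image combinations, the 3-column
   ensemble, and two Mann-Whitney-selected recipes at α = .05/.001). All
   combination recipes use the SPV-variant BoW (it is the stronger text
   representation; the full-profile matrix appears only in baseline 1).
   Missing image scores are imputed with the training-row mean, except in
   the 3-column ensemble where rows with missing values are removed.
   Per task (risk vs focused, risk vs generic): stratified 70/30 split;
   Yeo-Johnson power transform with standardization fit on training rows
   only; family selection by mean 10-fold CV AUC among
   {random forest (100 trees), MLP (one hidden layer of 16, 100 iterations),
   logistic, RBF/linear SVM}; hyperparameters by 5-fold grid search on AUC
   over small conventional grids (logistic/SVM C ∈ {0.1, 1, 10}, forest
   depth ∈ {∞, 8}, MLP α ∈ {1e-4, 1e-2}); final fit on the full training
   set; stochastic learners averaged over 3 seeded runs. Class predictions
   use the 0.5 probability threshold (no threshold specialization).
   When a class has fewer members than the requested folds, folds are
   reduced with a warning. If no feature passes a selection α (possible on
   very small cohorts), the selected recipe falls back to the single
   best-P feature, with a warning.

5. **Statistics.** Feature screening is a two-sided Mann-Whitney U test per
   feature — exact distribution for tie-free samples with combined n ≤ 20,
   tie-corrected normal approximation otherwise; constant features get
   P = 1. Screening (and the power transform) are computed from training
   rows only; `ScreeningResults.audit_leakage()` recomputes both from the
   persisted split and asserts equality. A config switch
   (`screening_scope="full"`) reproduces the permissive whole-dataset
   variant for comparison. The overlapping index is estimated with
   Gaussian KDEs (Silverman bandwidth) on a shared 512-point grid spanning
   the pooled range ± 3 bandwidths, integrating the pointwise minimum by
   the trapezoidal rule; zero-variance samples fall back to a shared-bin
   histogram (logged). AUC differences between recipes use the DeLong
   midrank estimator for correlated ROC curves with a two-sided normal P;
   identical score vectors give P = 1 by convention.

## Synthetic cohort generator

The generator emulates a year-long collection of three user groups
(84 users each by default) with the contrasts the analysis assumes:

| parameter (group medians: risk / focused / generic) | default | note |
| --- | --- | --- |
| posts per user | 800 / 850 / 205 | log-normal, σ=0.5; desk scale, ≈1/3.5 of the full-scale anchors 2797.5 / 2984 / 716 (`CohortConfig.full_scale`) |
| tweet length (tokens) | 11 / 19 / 14 | log-normal, σ=0.45 |
| night-band posting mass | 0.045 / 0.030 / 0.020 | uniform over UTC 03:00–09:00; ≈ the planted STTR medians |
| weekday posting mass | 0.66 / 0.72 / 0.74 | uniform day within weekday/weekend pools |
| friends | 372 / 578.5 / 610 | log-normal, σ=0.45 |
| image score median | 0.24 / 0.23 / 0.23 | Beta at concentration 10, solved for the median |
| images per user | 130 / 860 / 55 | 2% of each group missing all scores |
| emission rates | see `DEFAULT_EMISSION_RATES` | per-unit phrase rates per lexicon category |

Post text is a sequence of *emission units*: with the per-category rates a
unit is a 1–3-token lexicon phrase, otherwise one filler word from a
~570-type vocabulary (common Spanish words plus a deterministic syllabic
tail, so the type distribution is broad as in real text and spurious
high-order n-grams stay below the BoW document-frequency floor). Risk users
emit more first-person/suicide/emotion phrases; focused controls emit
suicide vocabulary at lower rates together with news-framing vocabulary;
generic controls talk about work/money with near-zero suicide vocabulary.
A deterministic `round(0.05 · n)` slice of focused controls is generated
with all personal/emotional categories silenced (news-account-like
profiles), so the "user left without an SPV" path is exercised in every
default cohort. Timestamps are UTC only — no per-user timezone, since
platform timestamps are UTC and user location is unknown.

The corpus generator for the SPVC draws positives from the risk mixture
with personal/suicide category rates multiplied by 2.5 (capped at 0.3 per
unit), emulating a *curated* training set of clearly suicide-related posts
and clinician-written phrases rather than a raw sample of risk users'
streams; its `separation` knob interpolates the positive class between the
generic mixture and that curated mixture (0 = a generatively identical null
corpus, including post length).

What the generator does **not** emulate: realistic language (tokens are
mixture draws, with no syntax or topic drift), bursty/diurnal posting
dynamics beyond the night-band mixture, social-graph structure, platform
artifacts (retweet cascades, reply threads), or annotator noise in the
group labels. Tests passing on these cohorts therefore demonstrate the
*pipeline's* correctness and its ability to recover planted effects — not
clinical validity on real data.

Two emergent behaviors of the fitted pipeline on default cohorts are worth
noting. First, top-k SPV selection prefers long, phrase-dense posts, which
inflates the risk group's SPV-based median tweet length toward the focused
group's and compresses that planted contrast (it remains strongly
significant against generic controls). Second, with a sharply separable
SPVC a minority of generic controls yields no SPV at the 0.5 threshold;
their SPV-sourced features are imputed, and the SPV-size features
themselves remain strongly discriminative for that task.

## Problem sizes

Default experiments use 84 users per group (~190k posts per cohort), a
1000-post SPVC corpus, and the full ten-recipe, four-family protocol; one
end-to-end run takes about five minutes on one CPU. The replicate study of
cross-control asymmetry uses a reduced protocol — 1/8-scale post volumes,
SNPSY features with a fixed logistic classifier — so that 25 independent
replicate cohorts stay desk-scale; the compared quantity (held-out AUC
ordering between the two control tasks) does not depend on the full
model-selection machinery.

## Limitations

- All evaluation is on synthetic cohorts; absolute metric levels mainly
  reflect the generator's configured separability (default cohorts are
  strongly separable, so most recipes saturate near AUC 1).
- The image scorer and sentiment scorer are pluggable stand-ins (Beta
  samples and a word-list polarity scorer); no image model or trained
  sentiment model ships with the package.
- The shipped lexicon is a 16-category synthetic stand-in for proprietary
  clinical dictionaries; only the loader and format are production-grade.
- Word-embedding/CNN text baselines are out of scope (they require
  pretrained embeddings and add no testable surface here).
- No decision-threshold optimization, calibration analysis, or deployment
  logic: the package stops at cross-validated screening evaluation.
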