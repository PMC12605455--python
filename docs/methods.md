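# Methods

## The informativeness score

A word's informativeness in its sentence is the log-transformed embedding
dissimilarity between the full sentence and the sentence with that word
removed: `score = ln(1 − cos(v_full, v_partial))`. The score is defined per
word *token*, not word type: the same word in two sentences (or twice in one
sentence, under an order-sensitive encoder) generally receives different
values. The upper bound is `ln 2` (cosine −1); there is no lower bound in
principle, but values below −10 are in practice artifacts of degenerate
embedding estimates and are flagged as outliers.

Assumptions worth keeping in view:

* The sentence encoder must represent full sentences, be sensitive to word
  order, and cover the languages being scored. Scores from different
  backends (or revisions) are not comparable, so every output file records
  backend name, dimension and seed in its header.
* Words are orthographic, whitespace-delimited tokens; the tokenizer strips
  Unicode punctuation (category P\*) from chunk edges while keeping internal
  apostrophes and hyphens. Unspaced scripts are out of scope.
* Embedded strings keep their punctuation. When a word is removed, its edge
  punctuation is re-attached to the preceding remaining token (or to the
  following token for a sentence-initial word): sentence-level punctuation
  belongs to the sentence, not the removed word. This convention is a
  genuine design choice — nothing forces it — and is isolated in
  `remove_word` so alternatives are one function away.

### Numerical choices

* Cosine is clipped into [−1, 1] against floating-point overshoot.
* When cosine rounds to ≥ 1 the dissimilarity is ≤ 0 and the log is
  undefined; such values are clamped to a floor of 1e-12, giving a score of
  ≈ −27.6 with `clamped=True`. The floor guarantees clamped records fall
  below the −10 outlier threshold, so keeping the pipeline total can never
  leak a degenerate value into an analysis.
* The outlier rule is strict (`score < −10`); a score of exactly −10 is
  retained. It is applied before any summary or correlation.
* Scoring a sentence embeds the full sentence once and each leave-one-out
  variant once (n+1 embeddings); a test asserts exact agreement (1e-10)
  with a brute-force re-embedding loop, so the reuse is purely an
  optimization.

## The reference embedder

The test stand-in for a pretrained sentence encoder is a seeded hashing
encoder: each token is padded with boundary markers and split into character
trigrams; each trigram is hashed to 64 bits (BLAKE2b) and mapped to a
Gaussian vector drawn from a generator keyed by (seed, hash); trigram
vectors are summed with positional weight 0.9^token_index and the total is
L2-normalized. The construction gives bitwise reproducibility, order
sensitivity, unit norm, and sensitivity to the removal of any single token
(its trigram mass disappears and every later token's positional weight
shifts). Trigram size, decay and hash width are pinned constants: nothing
downstream depends on their particular values, only on their being fixed.
The reference embedder produces *valid* score distributions (right-skewed
dissimilarities, function words scoring low), not *the* scores a pretrained
multilingual encoder gives; distribution-level properties transfer,
particular values do not.

## Covariates

* **Zipf frequency** `log10((count + s) / (total + s·V) · 1e9)` with
  Laplace `s = 1` and `V` the vocabulary size, so out-of-vocabulary words
  get a finite low value; `s = 0` recovers the plain per-billion transform.
  How unattested words should be handled is genuinely open; smoothing keeps
  the covariate total without a special missing path.
* **Predictability** cosine between the word's static vector (word2vec-text
  format lexicons, e.g. fastText) and the unweighted mean of the in-lexicon
  vectors of the preceding words. Mean pooling is the simplest standard
  composition; sentence-initial and out-of-vocabulary cases are *missing
  data*, never errors. Lexicon lookup tries exact case first, then
  case-folded.
* **Surprisal** is a pass-through column contract only: callers may supply
  per-token values from a language model, and the table builder centers and
  scales them like any covariate. The package never computes surprisal.

Per-language summaries (mean informativeness, mean word length, mean
passage length, correlations with length/Zipf/predictability) use Pearson
correlations by default — the relations of interest are linear trends — with
Spearman as an option; correlations are computed within language, never
pooled. Fewer than 3 complete pairs or a zero-variance margin yields a
missing correlation, not a number.

## Eye-movement pipeline

Interest-area reports carry first fixation duration (FFD), gaze duration
and total fixation duration (TFD) in milliseconds per (subject, trial, word
position). Filters remove fixated words with TFD < 80 ms or > 2000 ms,
FFD > 800 ms, or gaze > 1000 ms — all comparisons strict, mirroring the
"shorter than"/"longer than" phrasing of the rules they implement; skipped
words carry no durations and pass through. The five dependent variables:
first-run skip (all words; no first-pass fixation), log FFD, log gaze,
log TFD (fixated words), and rereading (fixated words; TFD > gaze, or a
first-pass skip with any later fixation). The composite reading-skill score
z-standardizes each of five proficiency tests over the analysis sample and
averages the available z-scores per subject.

The model table inner-joins DVs with word covariates on (language, trial,
word position) and skills on subject, drops outlier-flagged words, and
centers/scales covariates pooled across languages (a per-language switch
exists; pooling preserves genuine cross-language level differences as
variance, which is the default a single joint model wants).

### The effect check and its limits

`fit_effect_check` absorbs subject and word-within-language intercepts as
categorical dummies shrunk by a ridge penalty (default 10.0) and estimates
the requested fixed effects by least squares (continuous DVs) or Newton
logistic regression (binary DVs), with interactions written `"a:b"`.
The ridge on the dummies is essential, not cosmetic: word length and
frequency are constant within a word type and the skill composite is
constant within a subject, so unpenalized dummies would absorb them exactly;
shrinking the intercepts is the least-squares analogue of treating them as
random effects, which is how such covariates are identified in the crossed
random-effects models this check stands in for. Standard errors use the
sandwich form around the penalized solve. The check is validation-grade: it
recovers planted signs and magnitudes well at simulation scale, but it is
not a mixed-model fit — no variance components, no chi-square term tests —
and the exported table plus sidecar scaling metadata exist precisely so
external mixed-model tooling can do that part.

## Synthetic generator

The generator emulates the statistical structure the validation assumes,
with every coefficient recorded in a truth object:

* **Corpus.** Per-language vocabularies with Zipfian (1/rank) frequencies;
  word lengths Poisson-shifted around a per-language mean; longer words
  occupy rarer ranks (noisy), coupling frequency and length as in real
  lexicons. Passages are translation equivalents under a fixed
  character budget: a language whose words are 1.5× longer packs ~1/1.5× as
  many tokens into the same passage.
* **Scores.** Informativeness is planted directly rather than routed
  through an embedder (couplings routed through an embedder could not be
  controlled): `offset − ln(sentence token count) + c_len·z(length) +
  c_zipf·z(zipf) + noise`, capped at ln 2, with a 0.1% rate of degenerate
  outliers below −10. The `−ln(token count)` base is the packing rule:
  removing one of fewer words moves the meaning more, which also produces
  the fewer-tokens ⇒ higher-mean-informativeness relation across the
  translation-equivalent languages.
* **Eye movements.** One row per (subject, word token): log TFD is linear
  in the scaled covariates with subject and word-type random intercepts
  (SDs 0.15 and 0.08) and residual SD 0.35 around an intercept of 5.35
  log-ms (≈ 210 ms); durations are exponentiated and rounded to integer
  milliseconds. Skipping and rereading come from logistic models — skipping
  with negative length and informativeness coefficients by default, the
  direction reading studies report. Gaze is carved from TFD (equal unless
  reread), FFD from gaze, so `ffd ≤ gaze ≤ tfd` holds in every record after
  rounding. First-pass-skipped words lose FFD/gaze; skipped-never-refixated
  words lose all durations.

Default sizes — 40 subjects × 10 passages × 30 tokens (~12,000 rows), with
planted `b_info = +0.05` on log TFD and a skill × informativeness
interaction of −0.03 — are the package's standard simulation conditions:
large enough that sign recovery is reliable, small enough that a 50-replicate
recovery study runs in well under a minute. The tail of the simulated
duration distribution dips below the 80 ms filter bound, so the filter path
is exercised (≈ 0.5–1% of rows removed).

What the generator does **not** emulate: saccade dynamics, launch-site and
preview effects, spillover, any dependence between neighboring words'
measures, realistic missingness mechanisms, or the empirical shape of real
duration distributions beyond first moments. Passing recovery tests
therefore show the pipeline's arithmetic and joins are right and that the
effect check finds what was planted — they do not show the measure predicts
real reading, which is what the optional pretrained-backend workflow and
real interest-area exports are for.

## Known limitations

* Tokenization covers space-delimited alphabetic scripts only.
* The punctuation re-attachment convention on word removal is one of
  several defensible choices; scores for punctuation-adjacent words shift
  slightly under alternatives.
* The effect check's ridge default (10.0) is a fixed surrogate for the
  variance-component ratio a mixed model would estimate; group-level
  coefficient estimates (e.g. the skill composite main effect) are mildly
  shrunk and their standard errors approximate.
* Reference-backend scores are structurally, not numerically, comparable to
  pretrained-encoder scores.
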