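# Methods

## The screening model

The package operationalizes a simple clinical hypothesis: in cognitively
healthy speakers, *what* is said and *how* it is said agree, while early
cognitive impairment shows up as a dissociation between the two. Each
spoken phrase is scored on three valence channels:

1. **Polarity** — a dictionary score on the conventional sentiment scale
   (−5 … −1, +1 … +5; no zero). Each sentiment word has a signed base
   strength; intensifiers/diminishers immediately before it shift the
   magnitude (clamped to [1, 5]); a negating word in the same modifier
   run flips the final sign, so *not very happy* scores exactly
   −(3 + 1) = −4 when *happy* is +3 and *very* is a +1 booster. A phrase
   keeps the strongest positive and strongest negative evidence; the
   scalar is the side with the larger magnitude, and an exact tie is
   neutral (scalar +1 by convention).
2. **Semantic orientation (SO-PMI)** — for each content token,
   pointwise mutual information against the seed words *excellent* and
   *poor*, estimated from presence counts over a local reference corpus
   (window = one document), with add-s smoothing
   P(t) = (c(t)+s)/(n+2s). The phrase SO is the mean token-level
   PMI(·, excellent) − PMI(·, poor), in bits, banded to +1/0/−1 at a
   threshold τ.
3. **Tone band** — the spoken-emotion label (joy, boredom, anger,
   sadness, neutral) mapped to +1/0/−1. Joy is the only positive label
   and neutral the only neutral one; boredom is treated as negative
   (low-arousal negative valence). Audio processing is out of scope;
   labels arrive as data.

Dissociation is then quantified two ways. Per group, Pearson chi-square
tests of independence (no continuity correction) on the channel-pair
tables polarity×tone and SO×tone: association (small p) is the healthy
pattern, independence the impaired one. Per phrase, a concordance rate:
the fraction of phrases whose three bands are all the same nonzero sign
or all neutral. Finally, the three-channel training file
(`class,polarity,pmi,emotion`) feeds a classifier ablation: every
non-empty feature subset × four families (decision tree, multilayer
perceptron, naive Bayes, SVM), stratified 10-fold cross-validation,
metrics pooled over the held-out folds with the impaired class
positive.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| booster shifts | {−1, +1, +2} | magnitude change applied to the next sentiment word |
| SO threshold τ | 0.5 bits | trinary banding of the continuous SO value |
| smoothing s | 0.5 | add-half pseudo-count; keeps PMI finite |
| α | 0.05 | nominal level reported with the chi-square tables |
| folds | 10 | stratified cross-validation |

The packaged default lexicon has exactly 298 positive and 465 negative
entries (the published size of the dictionary it stands in for); the
word list itself is curated here, since the original is not public.

## Design choices where the procedure was underdetermined

- **Tokenization**: lowercase, whitespace split, strip edge
  punctuation, no stemming — the simplest reproducible rule.
- **Dual→scalar reduction**: scalar = positive side iff
  positive ≥ |negative|; ties are neutral. A corollary is that a scored
  scalar of −1 cannot occur (a lone −1 ties against the default +1), so
  scalar +1 is read as the neutral polarity band wherever channels are
  collapsed; externally supplied −1 values are still ordinary
  negatives.
- **Booster/negator scope**: boosters modify only the next
  sentiment-bearing token and stack additively before clamping; a
  negator flips the sign of the whole boosted expression; an even
  number of negators cancels.
- **Contingency layout**: the text channel of each pair is collapsed to
  its sign with neutrals dropped, giving 2×3 tables with df = 2 (the
  layout consistent with the method's description); a flag keeps full
  trinary×trinary (df 4) tables.
- **Chi-square gate is advisory**: the pipeline logs the
  association/dissociation verdict and proceeds to classification
  regardless.
- **"Bayes net" realization**: categorical naive Bayes over the three
  discrete features — the closest desk-scale reading on a 3-feature
  file. Note its structural limit: with identical per-class marginals it
  cannot detect a purely joint (concordance) difference; the other
  three families can.
- **ROC scores**: class probabilities where available, otherwise
  min-max scaled decision values; AUC is the trapezoid over the pooled
  ROC points (verified in tests against the rank formulation).

## The synthetic-data generator

The generator emulates the emulated study's shape: 60 control and 22
impaired interviews, 300 phrases each. Each phrase draws a latent
valence (+, 0, −); control phrases (and the non-dissociated fraction of
impaired phrases) reproduce it independently on each channel with
probability `concordance` (default 0.95), else fall to one of the other
two levels uniformly; a dissociated impaired phrase draws all three
channels independently and uniformly. `dissociation` defaults to 1.0:
the impaired group's channels are fully independent, which is the
pattern implied by its reported non-significant chi-square values.

Defaults the study does not pin down were fixed once so that the
generated data reproduce the *reported* end-to-end behavior —
channel-pair association p ≪ 0.01 in controls with p uniform in cases,
and cross-validated separability of the combined three channels near
the published AUC (≈ 0.85–0.93 across families here):

- valence distribution (0.80, 0.12, 0.08) — reminiscence interviews
  skew strongly positive;
- concordant-phrase magnitude distribution (0, .45, .30, .15, .10) —
  everyday speech is mostly mildly valenced;
- dissociated-phrase magnitudes (0, .10, .20, .30, .40) — decoupled
  speech swings toward the extremes of the scale, as described for the
  impaired group.

Magnitude 1 carries zero mass on both sides because of the tie
convention above; a nonzero mass is allowed but warns, since those
phrases cannot be recovered exactly from text.

Phrase *text* is assembled so the real scorers recover the intended
channels: one sentiment expression realizing the intended scalar
(direct term, negated opposite term, or booster+term, chosen at
random), 1–3 content words from the pool matching the intended SO code,
and inert function-word filler. The companion reference corpus gives
excellent-pool words an 8:1 document ratio with *excellent* vs *poor*
(SO = +2.50 bits at s = 0.5), poor-pool words the mirror image, and
neutral-pool words an exact 4:4 balance (SO = 0); seed totals are
balanced so the global correction term vanishes. Recovery is therefore
exact for all three channels at defaults (verified at 100% in tests;
the construction target for SO is ≥ 95%). Emotion names are drawn
uniformly within the intended band. Interview structure is metadata
only — no serial correlation within an interview.

What the generator does *not* emulate: real lexical diversity and
syntax, out-of-vocabulary sentiment, imperfect emotion recognition,
interview-level speaker effects, and the within-paragraph polarity
flipping described for impaired speech. Passing tests therefore show
the pipeline's statistical machinery is correct and well-calibrated on
data satisfying its assumptions — not that the procedure screens real
patients.

## Numerical and degenerate-input choices

- PMI is always finite (smoothing > 0 enforced); the zero-smoothing
  limit recovers the closed forms (0 bits under independence,
  log2(10) at perfect co-occurrence with P = 0.1).
- Phrases with no in-vocabulary content terms get SO = 0, code 0, and
  an `oov` flag; phrases with no sentiment hits score the neutral
  default (1, −1).
- Contingency tables with fewer than two observed levels per channel
  raise; expected cells < 5 warn.
- Cross-validation requires at least `folds` records per class;
  single-class input raises (the pipeline logs and skips
  classification, still emitting the dissociation report).
- All artifacts are written with sorted JSON keys and no timestamps, so
  a rerun with the same config and seed is byte-identical.

## Problem sizes used in the shipped tests

Chi-square parameter recovery runs at the emulated per-group scale of
10 interviews × 300 phrases, with 500 replicates for the nominal-level
check. The classifier-ablation direction check runs the generator at 40
phrases per interview (3,280 records) — the qualitative ordering it
verifies (combined channels ≥ best single channel for every family) is
insensitive to scale, and the full 24,600-record MLP ablation adds
nothing but runtime. End-to-end determinism is checked on a 210-phrase
run.

## Known limitations

- The SO threshold τ = 0.5 bits and the smoothing s = 0.5 are
  conventions, not fitted values.
- The polarity tie convention silently folds weak negatives (−1) into
  neutral when channels are collapsed; with a richer dual-score output
  this would be unnecessary.
- Pair counting is quadratic in per-document vocabulary; the intended
  corpus format is one short document per line.
- Phrases are treated as independent units in cross-validation
  (speaker identity leaks across folds); interview-level grouping is a
  straightforward extension but is not the emulated protocol.
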