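# Methods

## The problem

Parenting style — the climate of parental rearing a person grew up
under — is conventionally measured with the short-form Chinese EMBU
questionnaire (s-EMBU-C): 21 items on a four-point Likert scale across
three dimensions, *Rejection* (6 items), *Emotional Warmth* (7 items)
and *Overprotection* (8 items).  A dimension score is the mean of its
item ratings, so each score s ∈ [1, 4].  `stylegauge` implements an
alternative, questionnaire-free assessment: predict the score triple
{s_r, s_e, s_o} from a person's microblog post history, exploiting the
association between rearing climate and the topics and emotions people
write about.

The package covers the full workflow: questionnaire scoring and
participant validity filtering; style-type classification;
lexicon-based discourse analytics; the neural assessment model with a
correlation-injection layer; training, evaluation, baselines and
ablations; and a synthetic-corpus generator that makes every stage
testable offline.

## Questionnaire scoring and style types

Scores are item means, validated against the 6/7/8 item layout.
Participants are kept only if they (1) answer an instructed-response
("polygraph") item exactly as instructed for both parents, (2) have
between 5 and 5,000 followers inclusive, and (3) wrote strictly more
than 10 original posts in the activity window.  Scores normalize to
[-1, 1] via y = (s − 2.5)/1.5.

Style types are fixed strict-inequality regions of the score cube:

* positive: (s_e > s_r + 1) & (s_e > s_o + 1)
* mixed:    (|s_e − s_r| < 1) & (|s_e − s_o| < 1)
* negative: (s_e + 1 < s_r) & (s_e + 1 < s_o)
* other:    none of the above (including exact one-point gaps, since
  every inequality is strict)

The three regions are mutually exclusive (brute-force verified on a
dense grid).  Summary percentages use one-decimal half-up rounding with
the four classified groups as denominator; a caller-supplied expected
total is reported as an `unaccounted` remainder rather than hidden.

## Lexicon analytics

Discourse is profiled against two lexicons: an 11-category topic
lexicon (social, family, friend, health, work, leisure, money,
religion, death, psychology, love) and a 7-category emotion lexicon
(happy, like, surprise, angry, sad, fear, hate).  A user's proportion
for a category is 100 × (matching tokens)/(total tokens), pooled over
all posts by default (per-post averaging by flag); a token counts once
per category but independently across categories.  Tokenization is
pluggable — whitespace (used by all tests), character unigrams, or an
external Chinese word segmenter adapter — and each profile records
which tokenizer produced it.  Matching is exact membership; a
LIWC-style trailing-asterisk prefix dialect is available but off by
default.  Group comparisons use the two-sample Student t-test with
pooled variance (Welch by flag), with the 0.05/0.01/0.001 significance
ladder and no multiple-testing correction by default (a Bonferroni flag
exists).  Degenerate inputs are conventionalized: identical-mean
zero-variance groups give t = 0, p = 1; distinct-mean zero-variance
groups give infinite t, p = 0.

The six correlation word sets union lexicon categories:
T_p = {social, family, friend, work, leisure, money, psychology},
E_p = {happy, angry}, T_m = {religion}, E_m = {like, surprise},
T_n = {health, death, love}, E_n = {sad, fear, hate}.  (The published
set layout places "angry" in E_p even though the emotion lexicon lists
it as a negative emotion; the default mapping follows that layout
verbatim and this note records the oddity.)  Each set's representation
is the arithmetic mean of its member-word embeddings.

## Embeddings

Posts are encoded one vector per post.  The `paper-encoder` adapter
wraps a pretrained sentence encoder (SentenceBERT, d_e = 384) and
raises a clear error when the optional dependency or model files are
absent.  The default `hash-fallback` encoder is fully deterministic and
offline: each whitespace token is hashed (BLAKE2b) to seed a fixed
Gaussian vector, token vectors are summed and L2-normalized.  Identical
(text, width, seed) gives bitwise-identical vectors on any platform;
texts sharing words embed nearby, so lexical structure stays linearly
visible downstream.  Word embeddings are d_w = 300 wide by default,
realized as a fixed seeded linear projection of the d_e-wide encoder
output; keeping d_e and d_w separate reconciles the published 384-wide
post embeddings with the 300-wide set representations and the 2100-wide
concatenation.  Model input is each user's last 100 posts
(chronological truncation).

## The assessment network

Forward composition, in order:

1. two stacked LSTM layers over the post-embedding sequence, hidden
   width d_h (300 published); standard cells, forget-gate bias
   initialized to 1, other parameters uniform in ±1/√fan-in, all
   seeded;
2. attention pooling: per-post scalar e_i = tanh(h_i·W1 + b1),
   H′ = Σ_i e_i h_i.  The scores are signed and unnormalized — exactly
   the published form.  Display weights (non-negative, summing to 1)
   are produced by a softmax in the reporting layer only;
3. correlation injection: C = H′ ‖ T_p″ ‖ E_p″ ‖ T_m″ ‖ E_m″ ‖ T_n″ ‖
   E_n″ (fixed order; width d_h + 6·d_w = 2100 at published sizes);
4. head: U = tanh(C·W2 + b2) (width 128), ŷ = tanh(U·W3 + b3) ∈
   (−1, 1)³, denormalized to [1, 4] for reporting.  (The published head
   formula references an undefined intermediate; the only
   shape-consistent reading, U feeding the second layer, is used.)

Variable-length batches are right-padded and masked; masked steps carry
LSTM state through unchanged and are excluded from attention and mean
pooling.  Everything is NumPy with hand-derived analytic gradients,
verified against central finite differences to 1e−4 and against an
independent brute-force composition of the forward pass to 1e−6 in the
test suite.

Ablations: `no_attention` replaces pooling by the masked mean of the
hidden states; `no_injection` sets C = H′.

## Training and evaluation

Loss is MSE on the normalized 3-vector (matching the evaluation
metric; no loss is prescribed by the architecture source).  Optimizer
is Adam at the published settings — batch 64, learning rate 1e−4, 30
epochs — with best-validation-epoch checkpointing and a non-finite-loss
abort.

Metrics: per-dimension MSE = (1/N)Σ(y−ŷ)² and MAE = (1/N)Σ|y−ŷ| on the
normalized scale (the published metric formula mixes 1/n with a sum to
N; 1/N is the only consistent reading), averaged arithmetically across
the three dimensions; a flag reports the raw 1–4 scale.

Dataset splitting follows the 475/50/50 proportions, scaled to the
corpus size, seeded and disjoint.

Baselines: (1) all of a user's posts merged into one document → TF-IDF
→ one ridge regression per dimension; (2) the 18 lexicon-category
proportions → one gradient-boosted-trees regressor per dimension.
TF-IDF settings (L2 norm, min_df = 1, sublinear tf off) and
regularization strengths are package defaults, not claims about the
original experiments.

## Synthetic corpus generator

The generator emulates the statistical structure the method assumes:
latent scores drive style-dependent word usage, buried in noise.

* **Mixture and scores.** Style mixture 0.664/0.284/0.028/0.025
  (positive/mixed/negative/other).  Scores are drawn uniformly from the
  target type's region of [1, 4]³ (the real score histograms are not
  available in machine-readable form; uniform-in-region is a documented
  stand-in, easily swapped for truncated normals), then quantized so
  that the 6/7/8 item ratings reproduce each score exactly — scoring a
  generated questionnaire returns the planted labels with zero error.
* **Emission rates.** Three anchor rate rows per lexicon (one per
  genuine style) follow the published frequency tables' pattern: topic
  rows per style, emotion rows per style × gender (the female > male
  negative-emotion pattern under the negative style included).  A
  user's own rates are a softmax blend of the anchor rows weighted by
  the user's inequality-region margins (temperature 0.5), so usage
  varies continuously with the scores — the structure a score regressor
  needs.  Anchor deviations from each category's across-style mean are
  amplified by `rate_contrast` (default 2.5, rates floored at 0.02 %),
  chosen so planted between-style contrasts meet the recoverability
  condition (≥ 2–3× the per-user sampling standard error) at
  fixture-scale token budgets; at 1× the published contrasts (fractions
  of a percent) no desk-scale corpus can resolve per-user differences
  from a few thousand tokens.
* **Posts.** Post count per user is lognormal (mean 193.5 at full
  scale, minimum 10); each post draws Poisson(30)+3 tokens.  With
  probability 0.5 a post is pure noise (filler vocabulary only); with
  probability 0.04 it is a "quotation" drawing a *different* style's
  pure rate row; otherwise tokens are drawn from the user's blended
  rates.  Token streams are bags of ASCII pseudo-words — order-free,
  matching the order-free analytics — and every user records the exact
  expected token share per category implied by its blend and the
  noise/quotation mixture, which recovery tests use as the planted
  oracle.
* **Metadata** passes the validity filters (correct polygraph answers,
  followers in [5, 5000], timestamps in a three-year window, ~90 %
  original posts).

Fixture scales: `tiny` (12 users, ≤ 20 posts) for unit tests; `small`
(300 users, ≤ 120 posts, so most users fill the 100-post model input)
for integration and acceptance.  Fixture regeneration from the same
seed is byte-identical.

What the generator does *not* emulate: real Chinese text and semantics
(the signal is purely lexical), timestamp burstiness, follower-graph
structure, or the full-corpus scale.  Passing tests therefore
demonstrate that the pipeline recovers planted lexical structure under
the stated conditions — not that the method reaches any particular
accuracy on real microblog data.

## The planted-signal study (problem sizes and protocol)

The study trains the full model, a label-shuffled control and the
no-injection ablation on the small fixture under shared seeds and
compares test MSE.  Problem sizes: widths d_e = 96, d_h = 96, d_w = 48,
d_u = 64 (scaled down from 384/300/300/128), 10 epochs, batch 64 —
three paired runs per seed, three seeds.  The control permutes labels
jointly across the training and validation sets, so neither its
gradient steps nor its best-epoch selection sees a true label.

The learning rate for this shortened run is rescaled to preserve the
total optimization movement of the published schedule: Adam moves each
parameter by about the learning rate per step, the published schedule
is ≈ 240 steps × 1e−4, and the 10-epoch desk run has 40 steps, giving
6e−4.  Running the shortened schedule at 1e−4 unscaled leaves the
network's predictions within ~1 % of their initialization, and a
sensitivity analysis shows the full-vs-control comparison then measures
optimizer artifacts rather than signal.

## Known limitations

* The attention layer's scores are signed and unnormalized; trained
  models routinely pool with negative weights, so the display softmax
  need not concentrate on the posts a human would call informative.
  In controlled experiments with a single planted informative post
  among noise, the trained attention did *not* reliably give that post
  above-average display weight — the LSTM carries the signal into
  subsequent hidden states, and nothing in the loss forces
  localization.  Attention reports are useful descriptive output, not
  a validated explanation mechanism.
* The injected set representations are constants shared by all users;
  within a single corpus the injection layer acts as additional
  trainable-bias capacity for the head rather than per-user evidence.
  The ablation study measures its practical effect.
* Hash-fallback embeddings carry lexical identity only; conclusions
  about encoder quality or real-text semantics are out of reach by
  design.
* At the printed full-scale conditions (575 users, SentenceBERT, 30
  epochs) the published error levels depend on the original dataset,
  which is not deposited; nothing here claims to reproduce them.
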