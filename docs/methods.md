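# Methods

## Task and model

The package classifies the relation between an ordered pair of entity
mentions in a single sentence. For drug–drug interactions the label set
is {advice, effect, mechanism, int, negative}; for protein–protein
interactions it is {positive, negative}. A sentence with *n* annotated
mentions yields C(n,2) candidate pairs; each candidate is turned into an
independent instance by *blinding* — the two targets become `Entity1`
and `Entity2` (in document order) and every other mention
`EntityOther` — so the classifier learns from context rather than from
entity names, and the three instances derived from one three-entity
sentence differ only in the placement of the blinding symbols.

The classifier is a multichannel convolutional network. Each channel is
one pretrained word-embedding table; stacking c channels over the task
vocabulary gives the lookup tensor D ∈ R^(c×v×d), and an encoded
sentence the input V ∈ R^(c×N×d). Convolution applies, per window size
h, M filters W ∈ R^(c×h×d); the filter response at position k sums the
elementwise product over all channels and adds a per-filter scalar bias,
then passes through a rectifier. The resulting feature map has exactly
N−h+1 positions. Max-over-time pooling keeps one scalar per filter;
pooled features concatenate over the K window sizes into r ∈ R^(KM); a
linear map W2 ∈ R^(O×KM) (no bias) produces class confidences that a
softmax normalises to probabilities. Prediction takes the argmax, ties
broken deterministically toward the lowest class index.

All of θ = (D, W, W2, b) is trained, including every embedding channel
independently (channels are not tied). Gradients are hand-derived
backpropagation in float64 NumPy, validated against central finite
differences for every parameter group (the test suite enforces max
relative error ≤ 1e−4 on a small model).

## Preprocessing and noise filters

Tokenization collapses each annotated mention — multiword or not — into
a single token covering its span and splits the remaining text on
whitespace and punctuation boundaries; token spans partition the
sentence's non-whitespace characters. Overlapping mention spans are
rejected; for discontinuous mention offsets only the first span is kept
(with a warning), since the corpus dialect allows them but no principled
single-token collapse exists.

Two lexical filters remove candidate pairs that are overwhelmingly
non-relations:

* **Rule 1 (same name / abbreviation).** Remove when the surfaces are
  equal after case-folding and trimming, or one mention sits in
  parentheses immediately after the other (the "long form (SHORT)"
  pattern), or one surface is the initial-letter acronym of the other's
  words. The test is necessarily heuristic; these three clauses cover
  the repeated-name and parenthesized-abbreviation patterns that
  dominate in practice without any external resources.
* **Rule 2 (coordinate structure).** Remove when every token strictly
  between `Entity1` and `Entity2` is a comma, "and", "or", or another
  (blinded) entity, with at least one such separator present. Adjacent
  entities with nothing between them are kept. The detector is purely
  token-set based — the pipeline deliberately uses no parser anywhere —
  and resolves the canonical "A, B, C, D or E" enumeration case.

Filters are applied to training and test data alike and each removed
instance records its reason. For binary PPI corpora the filters default
off: those corpora are small and discarding borderline candidates costs
more recall than the noise is worth.

## Training procedure

Minibatch NLL (summed over the batch; a final short batch is used
as-is) with Adadelta, ρ = 0.95 and ε = 1e−6 — the optimizer's canonical
constants. Adadelta was chosen over plain gradient descent because a
fixed learning rate makes the loss unstable on this architecture; it
needs no schedule. The PAD embedding row is pinned to zero and excluded
from updates. Instances are reshuffled every epoch; all randomness
(initialisation, shuffling, noise) flows from one integer seed through
spawned NumPy generators, making training bit-reproducible.

Regularisation: (1) Gaussian noise, resampled per batch, added to the
input embeddings of real token positions only — mean 0.001 and, since
only the mean is fixed by convention, standard deviation defaulting to
0.001 as well, both configurable; (2) after every update step each row
of W2 with L2 norm above 5 is rescaled onto the norm-5 sphere.

Defaults: M = 200 filters per window; windows H = {6,7,8,9} for the DDI
configuration and {3,4,5,6} for PPI (PPI sentences are shorter); batch
size 20; 10 epochs; no early stopping. All are constructor arguments.

## Padding and masking

Sequences shorter than max(H) are right-padded with the zero PAD
vector; within a batch, sequences are right-padded to the batch max
length. Pooling for window size h considers exactly the true feature
map of length N−h+1 (N the unpadded length): positions beyond it are
masked to −∞ after the rectifier. This keeps pooled features — and
therefore predictions — identical whether an instance is processed
alone or inside any batch, and guarantees padding never wins the max. A
sequence shorter than h keeps its single partially padded window, the
only case where PAD vectors enter a pooled feature.

## Evaluation

Per-class precision/recall/F are one-vs-rest. The headline metric is
the overall micro-F pooled over the positive classes only; including
the (dominant) negative class would inflate it to near-ceiling and is
not the convention for this task. Detection (DEC) collapses all
positive classes to one label and scores the binary task. Cross-
validation folds are grouped by source sentence, so the near-duplicate
instances a multi-entity sentence generates can never straddle a
train/test boundary; groups are dealt to the smallest fold after a
seeded shuffle, which with one instance per sentence yields exactly
balanced folds and stays within the grouping's granularity otherwise.
Document-level grouping is available through the `group_key` argument.

## Synthetic corpora

The generator emulates the DDI-style annotation layout: sentences with
2–5 entities, every pair labeled, serialisable to the XML dialect. The
gold label of a pair is a deterministic function of its context —
exactly one class-specific cue token strictly between the two entities
gives that class, anything else gives negative — so the task is fully
separable and a Bayes-optimal classifier scores micro-F 100 on
decoy-free corpora; what a passing learnability test shows is that the
implementation can recover a clean signal, not that it reaches any
particular accuracy on real prose. Cues are single tokens placed
strictly between the pair so every window-size setting can see them.
Decoy sentences exercise the filters at configurable rates: same-name
repetitions (Rule 1 targets) and comma/"and"/"or" coordinate lists
(Rule 2 targets), always labeled negative and recorded in a
ground-truth manifest of which pairs the filters should remove.

Fabricated channels are word2vec text files covering configurable
fractions of the vocabulary in consecutive wrapping slices (fractions
summing to 1 give complementary channels whose union covers
everything); cue tokens appear in every channel with class-clustered
vectors (unit class direction plus N(0, 0.05) perturbation) against a
N(0, 0.1) filler cloud. Channel dimension defaults to 25 — large enough
for five near-orthogonal class directions, small enough that the whole
study trains in seconds.

What the generator does **not** model: real lexical statistics,
discontinuous or overlapping mentions, cue ambiguity, label noise, and
long-range dependencies. Results on it bound implementation
correctness, not performance on DDIExtraction 2013 or the PPI corpora.

## Numerical choices and degenerate inputs

* float64 throughout; convolution via einsum over window offsets,
  bit-deterministic for a fixed seed.
* Softmax is computed with max-shift for stability; a gold-class
  probability of exactly 0 in the loss clamps to 1e−12 with a warning.
* Argmax ties (prediction and pooling) resolve to the lowest index.
* OOV and special-symbol embedding rows initialise uniform in
  [−0.25, 0.25], the scale of typical pretrained vectors; the blinding
  symbols are never looked up in pretrained tables.
* Non-finite gradients abort training with the offending parameter
  group named.
* Empty training sets, unknown labels, window sizes exceeding what
  padding can accommodate, and shape mismatches raise immediately.

## Study sizes

The bundled study (tests and `scripts/acceptance.py`) uses 2000
training and 500 test instances, two channels, d = 25, M = 32,
H = {3,4}, batch 20, 10 epochs — small enough to run in seconds yet
large enough that under-trained or mis-specified variants visibly fail
the ≥95 micro-F bar; the filter study uses 600 sentences with 15%
same-name and 15% coordinate decoys, giving several hundred removable
pairs per run.

## Known limitations

* Rule 1 cannot recognise abbreviations that are not initialisms
  (e.g. "ASA" for "acetylsalicylic acid" is caught only via the
  parenthesis pattern).
* Rule 2's lexical detector misses coordinate structures interrupted by
  modifiers it does not know, and would wrongly fire on a genuine
  relation expressed purely by "and" between two entities.
* Very long sentences dilute max-pooled features: a fixed window cannot
  connect entities separated by more context than max(H) tokens, a known
  weakness of window-based convolution without syntactic structure.
* One CPU, dense NumPy: fine for corpus-scale experiments (hundreds of
  batches per second at the bundled sizes), not engineered for
  million-sentence pretraining.
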