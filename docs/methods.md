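# Methods

## Problem setting

A full-text article may state, in its Results or Discussion or in a figure
legend, that an antibody did or did not bind only its designated antigen; the
Materials-and-Methods section usually registers the exact reagent with an RRID
(`AB_<digits>`). The pipeline extracts both kinds of evidence, classifies each
specificity statement with respect to the antibody it is about, links the
statement to the RRID of the same article, and stores triples
(RRID, class, evidence). Classes are ordered — *nonspecific < neutral <
specific* — which matters for tie-breaking and for weighted-κ agreement.

## Extraction

Documents are parsed into sections (JATS `<sec>` elements, or blank-line
paragraphs for plain text) with figure/table captions flagged as legends.
Sentences come from a rule-based segmenter: terminal punctuation ends a
sentence only if the preceding token is not a known dotted abbreviation
("Cat.", "No.", "Fig.", "et al.", …), not a single uppercase initial, and not a
dotted acronym, and the next character plausibly opens a sentence. The
abbreviation list is pluggable; the default errs toward *not* splitting, since
a wrongly split RRID sentence destroys its snippet.

Specificity snippets are windows `[previous, cue, next]` clipped at paragraph
and legend boundaries (never more than three sentences, never across a
paragraph); one snippet per cue-bearing sentence, adjacent cue sentences kept
as separate overlapping snippets (a de-duplication pass was considered and
rejected: both windows carry distinct context, and downstream consumers can
collapse them by center sentence). Snippets whose text never matches
`(A|a)ntibod(y|ies)` are dropped. RRID mentions match `AB_[0-9]+` with a
non-word-character guard before the match (so `LAB_123` is rejected; the guard
can be disabled) and an optional case-insensitive `RRID:` prefix absorbed into
the surface form. RRID windows enforce a one-identifier invariant: neighbour
sentences holding other RRIDs are excluded, and a sentence holding several
RRIDs is split at the character position immediately before each subsequent
mention's surface, keeping only the target's sub-string.

## Specificity classifier

The encoder is a protocol: anything mapping token ids to per-token vectors
plus a pooled position. The bundled `TinyTransformerEncoder` (2 layers, d=32,
4 heads, hashed 4096-token vocabulary) draws its weights once from a seeded
RNG and never updates them — a deterministic contextual feature map that makes
the whole pipeline runnable offline. Two of its design choices matter:

* **Damped positions.** Sinusoidal positional encodings are scaled by 0.1
  (`positional_scale`). With random, untrained embeddings, full-strength
  positions dominate token identity, and the snippet task is essentially
  order-insensitive; damping them markedly improves the features.
* **Frozen encoder, trainable head.** Training fits the linear softmax head by
  Adam on cross-entropy plus `l2_lambda · ‖head‖²`. The ℓ² penalty applies to
  the head only (the attention head itself is parameter-free). Defaults —
  learning rate 1e-2, 300 epochs, batch 16, `l2_lambda` 1e-4 — reflect this
  regime: a 64-dimensional linear head on frozen features needs many cheap
  Adam steps and light shrinkage, unlike end-to-end transformer fine-tuning
  where small learning rates and few epochs are the norm. A fine-tunable
  encoder honouring the same protocol can be substituted without touching the
  classifier.

Inputs are assembled as `[CLS] s [SEP] t`; truncation drops snippet tokens
from the end and never aspect tokens. The aspect defaults to the first
antibody-term surface form found in the snippet, falling back to the literal
"antibody"; passing the full mention span is equally supported — both
conventions exist in the aspect-based-classification literature and the choice
is left to the caller. Argmax ties break to the first label in the fixed
class order. Class weighting (inverse frequency) is available behind
`class_weighting` but off by default.

## RRID linking

The sentence-pair classifier reads `[CLS] spec [SEP] rrid` and applies a
binary logistic head to the pooled vector, threshold 0.5. The common-word
baseline tokenises both snippets, keeps *candidate* words — tokens bearing a
digit or an internal capital (clone and catalog tokens like `6E10`,
`anti-Panx1`) plus any token absent from a common-word dictionary, RRID tokens
excluded — and greedily matches candidates across the two snippets by
Jaro–Winkler similarity at a configurable threshold (1.0 / 0.9 / 0.8), each
word used at most once. The pair is linked when at least `min_common` (default
1) matches survive: a single shared clone token is exactly the evidence a
human curator uses. The bundled dictionary is a compact (~700-word) lexicon of
common English and methods-section vocabulary; `BaselineConfig.dictionary`
accepts any larger word list. Jaro–Winkler is implemented from the definition
(match window ⌊max(|s₁|,|s₂|)/2⌋−1, half-transposition count, prefix boost
p=0.1 up to 4 characters, applied without a boost-threshold); two empty
strings score 1.0.

The Siamese baseline encodes both snippets with a *single* recurrent cell
(one parameter set serves both branches, so weight sharing holds by
construction), mean-pools the hidden states, and scores
`exp(−d)` with Manhattan or Euclidean `d`, linking at 0.5. It is a
single-layer tanh RNN trained by truncated-free BPTT on squared error against
the 0/1 link label with gradient clipping at ±1 — deliberately the simplest
member of the recurrent-Siamese family, kept as a comparison point rather
than a contender.

## Evaluation

Per-class precision/recall/F1 use the zero-denominator→0 convention. Macro
aggregates are unweighted class means; weighted aggregates use gold-class
supports. `kfold_split` wraps stratified, seeded 5-fold assignment, with an
optional `groups` argument (e.g. article ids) that assigns whole groups to
folds round-robin when leakage across folds is a concern — whether snippets
from one article should share a fold is a genuinely open protocol choice, so
both modes exist. The joint rule scores a pair as a true positive for class C
only when both gold and prediction say (link=yes, class=C); a yes-link with
the wrong class is simultaneously a false positive for the predicted class and
a false negative for the gold class. Cohen's κ supports plain and
linear-ordinal weights (w_ij = |i−j|/(K−1)); identical constant annotations
(chance disagreement zero) are defined as κ=1. Reports print three decimals;
internal values stay unrounded.

## Synthetic corpus

The generator emulates the study conditions of curated corpora in this
domain: class mix defaults to (0.10, 0.10, 0.80) for
(nonspecific, neutral, specific), matching the strong skew toward successful
validations; 4–9 antibodies and 2–4 specificity statements per article with a
5% distractor rate (a statement about an unregistered antibody) put the
realized pair-level "yes" rate near 15%. Each antibody gets a globally unique
clone token (letter–digit mixes like `7B3`), target name, catalog number and
RRID; each statement instantiates one of ≥5 templates per class. The template
bank includes the known hard cases — "non-specific antibodies" used as
blocking controls or negative controls inside *positive* statements, double
negation ("did not demonstrate nonspecific binding"), and neutral statements
describing a specificity test with no result — so a classifier cannot win on a
single cue word. Statement layouts vary (mid-paragraph, paragraph edge,
figure legend) to exercise window clipping; some Materials-and-Methods
paragraphs put two RRID sentences adjacent or two RRIDs in one sentence to
exercise the isolation rules.

What the generator does **not** emulate: real article length and discourse
structure, vocabulary breadth (templates have a closed lexicon), noisy or
malformed RRIDs, OCR artifacts, and statements whose class is only inferable
from distant context. Passing tests on this corpus therefore demonstrate that
the machinery is correct and that the classifier can exploit compositional
cue patterns — not that the bundled tiny encoder would reach comparable
accuracy on real literature, where a pretrained scientific-text encoder
behind the same protocol is the intended substitution.

## Numerical choices and degenerate inputs

Softmaxes subtract the row/column max before exponentiation. A constant
interaction matrix yields uniform γ = 1/n; n=1 gives γ=[1]. Empty snippet or
aspect text is an input error; whitespace-only paragraphs segment to nothing;
an empty confusion matrix produces an all-zero report with a warning flag.
Training requires every class present (classifier) or both link labels
(linker). All randomness flows through `numpy.random.default_rng` seeds
carried in the configs; two runs with the same seed produce identical models,
predictions, and rendered corpora.

## Known limitations

* Only in-document RRID linking is attempted; catalog numbers or vendor names
  without an RRID are out of scope by design.
* The bundled dictionary is small; with threshold < 1.0 the baseline can match
  near-miss tokens across unrelated reagents (`6E1O`/`6E10` = 0.8833).
* The tiny encoder's features saturate around the mid-0.9s accuracy on the
  synthetic corpus; the architecture is exercised, not the ceiling of the
  method.
* The Siamese baseline is a minimal RNN; it records a comparison number and is
  not tuned.
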