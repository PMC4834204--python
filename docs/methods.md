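# Methods

This note documents the models and procedures implemented in `chemtagger`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the package's known limitations.

## Preprocessing

Sentence segmentation is rule-based: a terminator (`.` `!` `?`) ends a
sentence only when followed by whitespace and an uppercase letter or digit,
with three exceptions — periods in decimal numbers, periods after
single-letter abbreviations, and terminators inside unclosed brackets.
Tokenization splits on whitespace and then isolates the punctuation set
`, . ; : ( ) [ ] { } - / + =` as single-character tokens, leaving
alphanumeric runs intact; every token carries exact character offsets into
the section text, so `1,6-naphthyridonecarboxylic acid` becomes the six
tokens `1 , 6 - naphthyridonecarboxylic acid` and a mention over them the
labels `B I I I I I`.  Offsets are 0-based, end-exclusive, counted in
Unicode code points; this is the one convention the whole package shares.

Two repair rules keep the BIO layer total: a gold annotation whose boundary
falls strictly inside a token is expanded outward to token boundaries (with
a warning) rather than dropped, and a decoded `I` without a preceding `B` is
repaired to `B` — both choices favor recall, and the encode→decode round
trip is exact whenever annotations are token-aligned (which the synthetic
generator guarantees and a 1000-sentence test asserts).

## Sequence model

The labeler is a sparse linear chain over (O, B, I): emission weights on
string-valued features per token, transition weights on label pairs with a
distinguished START state.  Decoding is exact Viterbi; among equal-scoring
paths the lexicographically smallest under O < B < I is returned (computed
by a backward max pass plus a greedy forward walk), which makes decoding
deterministic and gives the all-O path for an all-zero model.

Training is an averaged structured perceptron: decode, and on a mistake add
gold feature counts and subtract predicted ones; the returned weights are
the average over all update steps (lazy/accumulator implementation).
Defaults: 10 epochs, shuffling with a dedicated RNG, averaging on;
everything is deterministic given the seed.  The perceptron was chosen over
CRF/SSVM because it is dependency-free and exactly testable (Viterbi is
verified against full 3ⁿ enumeration); the `tagger.Backend` hook accepts
any trainer/decoder pair with the same contract, so a CRF toolkit can be
substituted without touching the pipeline.  No hard transition constraints
are imposed at decode time; malformed label sequences are repaired at the
realignment stage instead, keeping the stages independent.

Prediction confidence is margin-based: for each decoded mention, the score
drop from relabeling its tokens as O is mapped through m/(1+m) to [0, 1).
The mapping is monotone, so rankings (which is all the passage-level
metrics use) are margin rankings; the absolute values are not calibrated
probabilities.

## Features

Feature families and defaults (all toggleable in `FeatureConfig`):

| family | default | notes |
|---|---|---|
| context words | window w = 2 | unigrams/bigrams/trigrams, original + lowercased, `<s>`/`</s>` padding |
| POS n-grams | on when POS supplied | POS is pass-through input; no tagger is bundled |
| word pattern | on | uppercase→A, lowercase→a, digit→0; full + squeezed |
| char prefixes/suffixes | m ∈ {1,2,3} | skipped when m exceeds the token length |
| char n-grams | n ∈ {2,3} | set semantics (types, not positions), unmarked substrings |
| chemical affixes | lexicon-driven | longest case-insensitive morpheme prefix and suffix |
| gene lexicon | lexicon-driven | single-token case-insensitive membership |
| semantic types | lexicon-driven | greedy longest multi-token match, tags the window |
| pre-annotation | file-driven | external BIO+type guess as one feature, e.g. `PRE=B_TRIVIAL` |
| Brown paths | path-file-driven | full path + prefixes of length {4, 6, 10} |
| binarized embedding | matrix-driven | only non-zero symbols emitted, `EMB3=+` |

Words absent from a representation resource contribute no feature for that
family (no "unknown" sentinel): absence of evidence is left to the other
families.

## Binarized embeddings

For embedding matrix M (V words × D dimensions), each column j gets two
thresholds: the mean of its strictly positive entries and the mean of its
strictly negative entries.  Cells strictly above the positive mean become
`+`, strictly below the negative mean `-`, all else `0`.  Ties therefore
map to 0, and a column with no positive (negative) entries gets a +∞ (−∞)
threshold so nothing crosses it — using 0-valued means instead would mark
every positive cell `+` in such columns.  The construction is invariant to
positive rescaling of M and swaps `+`/`-` under negation; both properties
are tested, and the implementation is checked cell-for-cell against an
independent per-column brute-force oracle on 200 random matrices.

## Brown clustering

Word classes are built by greedy agglomerative merging under the average
mutual information (AMI) of the class bigram model, log base 2, bigrams
counted left-to-right within sentences only.  Initialization follows the
classic scheme: the C most frequent words start as singleton classes, the
remaining words are inserted most-frequent-first, and each insertion is
followed by the merge of the pair whose merge loses the least AMI; the C
survivors are then merged to a single root.  The merge record is a binary
tree, and each word's representation is its root-to-leaf path as a bit
string, 0 denoting the earlier-created branch.  Ties in merge loss (within
1e-12) are broken by the lexicographically smallest pair of cluster
creation ids, making output deterministic.

Every candidate merge is scored by recomputing the AMI of the merged count
table (NumPy-vectorized); this is O(K⁴) per merge in the number of active
classes and deliberately favors exactness over speed — the audit hook
`on_merge` lets tests verify each greedy choice against an exhaustive
independent recomputation.  Intended scale is a desk corpus (≲10⁶ tokens,
thousands of word types, C up to a few dozen); the experiment runner uses
C = 16 over the synthetic corpora, and the word-frequency cutoff
(`min_count`, default 1) trims the tail when needed.

## Post-processing

Rule order is propagate → merge → bracket-filter: propagation first so
copied mentions are eligible for merging, the balance filter last so it
cleans every produced surface.  Propagation is case-sensitive exact match
guarded by word boundaries (flanking characters must be non-alphanumeric),
so `pirin` never fires inside `aspirin`; new mentions inherit the type and
confidence of the highest-confidence source with that surface and never
overlap existing ones.  Structure-word merging absorbs the word immediately
before or after a mention (across whitespace or a hyphen) when it is in the
lexicon, repeating to a fixpoint with a 3-pass cap.  The bracket filter
drops mentions whose `()`/`[]` fail a matching scan; braces are ignored.
Every surviving annotation is re-validated against its document, so no rule
can emit an offset/text mismatch.

Passage scores are the maximum mention confidence per (document, section),
0 when none, every section emitted — exactly 2 per document — ranked by
descending confidence with doc-id/section tie-breaks.

## Evaluation

Mention-level scores are strict and micro-averaged: a predicted mention
counts only on exact (document, section, start, end) match; entity type is
ignored by default (the strict protocol scores offsets) with a
type-sensitive flag available.  Passage-level thresholded metrics come from
the confusion matrix, with MCC reported on the percentage scale; MCC and
the ratio metrics return 0 when a denominator vanishes.  AUC_PR is average
precision — the step-interpolated sum Σ P(k)·ΔR(k) down the full ranking —
not trapezoidal interpolation; this matches scikit-learn's
`average_precision_score` (cross-checked in a test) and is documented so
the numbers are reproducible.  P_full_R is the precision at the first depth
where recall reaches 1.0, which requires the ranking to cover every
section.

## Synthetic data

The generator emulates the statistical and orthographic structure the
pipeline consumes, not patent semantics.  Pseudo-chemical names are
`prefix (infix)* suffix` concatenations over a ~36-morpheme inventory, 30%
preceded by a digit/comma/hyphen locant block and 20% followed by a
structure word that belongs to the gold span; sentences mix these names
into background text at an expected 1.0 entities per sentence (Poisson),
with uppercase gene-symbol decoys planted as confusable negatives.  The
background vocabulary is deliberately open — ~700 syllable-generated
pseudo-words plus ~60 function words — because with a small closed
vocabulary a labeler can shortcut to "unseen word = chemical" and every
condition saturates; with an open vocabulary unknown background words are
common and mentions must be recognized by form.  Mention types are drawn
from a seven-type mix mirroring the relative proportions reported for
annotated patent corpora (family and systematic names dominant, identifiers
rare).  Matched resources are derived from the same inventories: the affix
lexicon is the morpheme inventory, the gene lexicon the decoy list, and the
embedding matrix plants a strong positive loading (mean 2.0 vs noise sd
0.1) on one signal dimension for exactly the grammar-derived words, so
binarization recovers a `+` for >90% of them.

Two noise options create harder variants: `char_noise_rate` flips each
interior letter of a noised name with probability 0.25 (degrading affix and
n-gram cues while representation features still identify the token), and
`truncate_rate` removes a trailing structure word from some gold spans to
create targets for the merge rule.  Defaults for both are 0.

What passing tests show, and don't: near-perfect recovery on this generator
demonstrates that offsets, BIO bookkeeping, feature plumbing, decoding and
the rules are mechanically correct and that the feature families carry the
intended signals.  It does not demonstrate chemistry-level accuracy on real
patents, which have unbounded vocabulary, genuinely ambiguous mentions,
nested/discontinuous names and annotation-guideline subtleties the grammar
does not model.

## Experiment sizes

The recovery experiments train on 100 documents (~1000 sentences, ~550
mentions) and evaluate on 50 held-out documents from a second seed, 8
epochs, Brown C = 16 over the pooled unlabeled text, embedding dimension
10; the noised-grammar comparison uses 50/25 documents over five seed
pairs.  These sizes were chosen so a full reproduction completes in well
under a minute on one CPU while keeping several hundred evaluation
mentions per run.

## Known limitations

* The perceptron gives margins, not probabilities; passage AUC_PR is a
  ranking statistic over uncalibrated scores.
* Brown clustering is exact but O(K⁴) per merge; hundreds of clusters over
  millions of tokens call for the windowed approximate implementations.
* The sentence splitter and tokenizer are rule sets tuned for
  title/abstract prose; claims and full-text patent sections are out of
  scope, as are XML/JSON patent formats.
* Character n-grams are unmarked substrings (no start/end positional
  markers); positional marking is a possible variant, not implemented.
* Only the three documented post-processing rules are applied; no learned
  re-ranking of mentions.
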