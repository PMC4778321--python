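# Methods

## Model

The coder is example-based: it never learns weights, it compares a
diagnosis against the textual descriptions of candidate codes.  The
description *T<sub>c</sub>* of a code is the concatenation (single-space
join, duplicates kept, bottom-up through the hierarchy) of every
terminology term filed at or below the code.  Codes with no terminology
anywhere below them are flagged non-searchable and excluded from every
argmax: similarity against an empty description is undefined, and such
codes could never be justified by instances.

Two search strategies share the same similarity metric.  The flat method
takes the argmax over all searchable subcategories at once.  The
hierarchical method descends section → category → subcategory, taking the
most similar searchable code at each level; it evaluates far fewer
candidates and is robust to coincidental near-matches in unrelated
chapters, because a whole section's concatenated terminology must outscore
the others before its subcategories are considered.  Both break ties toward
the lexicographically smallest code string, which makes results
reproducible; the choice of tie-break is otherwise arbitrary.

Assumptions worth stating: one code per diagnosis (no multi-label
assignment); the terminology is trusted (its filing decides the gold
hierarchy); and queries are short noun-phrase diagnoses, not full
documents.

## Text similarity

The metric averages two directional scores; in each direction every token
occurrence of the source text contributes its best word-to-word similarity
against the target text, weighted by inverse document frequency, and
normalized by the total idf mass of the source text.  Implementation
details that matter:

* **idf without logarithm.**  `idf(w) = n_docs / df(w)`, as the metric is
  defined here; a `log_variant` switch (`1 + ln(n_docs/df)`) exists for
  experimentation but is off by default.  Unseen words get `df = 1`:
  they are maximally specific, and the floor avoids division by zero.
* **Threshold θ.**  A word contributes only if its best match reaches θ.
  θ = 0 reproduces the unthresholded metric exactly (a 0-similarity word
  contributes 0 either way).  The package asserts this identity to machine
  precision, along with monotonicity in θ and the collapse to exact-match
  overlap once θ exceeds every non-identical word similarity.
* **Duplicates.**  Repeated tokens contribute once per occurrence to both
  numerator and denominator, because the sums run over occurrences.
* **Degenerate input.**  A text that is empty after preprocessing scores 0
  with a warning rather than raising, so one malformed record cannot abort
  a batch run.
* **Identical tokens.**  `maxSim(w, T) = 1` whenever `w` appears verbatim in
  `T`, under every backend — including the vector backend for words with no
  distributional evidence (all-zero vectors otherwise score 0 against
  everything: cosine is undefined at zero norm, and 0 encodes "no
  evidence", not "dissimilar").

## Word similarity backends

* **Exact match** is the deliberately weak baseline: the indicator of
  string equality.
* **LCS** uses the character-level longest common subsequence,
  `len(LCS)/(len1+len2−len(LCS))` — a Jaccard-like form that is 1 only for
  identical strings.
* **Knowledge backend.**  Words map to concepts, concepts to ordered sememe
  lists, and sememe similarity is `α/(d+α)` with `d` the undirected
  shortest-path length in the sememe tree (the simplest reading of
  "shortest distance"; distances across a disconnected forest give
  similarity 0).  Word similarity is the maximum over concept pairs.
  Concept similarity defaults to the similarity of the two primary (first)
  sememes; a `greedy_average` strategy (greedy best-pair matching over the
  full lists, averaged) is available.  The full four-feature weighting of
  the classic HowNet-based measure needs parameters this package does not
  ship, so primary-sememe dominance is the default.  α defaults to 1.6 and
  is configurable, never hard-coded.  Out-of-lexicon words — common for
  vocational biomedical terms in a general-purpose knowledge base — fall
  back to LCS similarity.
* **Vector backend.**  Co-occurrence counts over a corpus, cosine
  similarity.  Word-dimension mode counts content words within 3 content
  words per side; character-dimension mode counts content characters within
  7 content characters per side (vocabulary rows remain words; only the
  dimensions change — useful because Chinese characters carry semantics and
  character dimensions sidestep segmentation errors).  "Per side" is a
  reading choice: the window is symmetric, and `per_side=False` exposes the
  alternative.  Preprocessing removes stop words (user-supplied list, empty
  by default) plus numerals, punctuation, separators and symbols by Unicode
  category, before windows are measured.

## Tokenization

Chinese text has no delimiters, and the segmenter used in the original
setting is an external tool.  The package therefore treats tokenization as
a pluggable contract: any callable `str -> TokenizedText`.  The default is
a greedy longest-match dictionary tokenizer over the union of terminology
segments and a user lexicon; whitespace is a hard boundary, so
pre-segmented input passes through unchanged.  This is deterministic and
self-contained, at the cost of real segmentation ambiguity — a limitation,
not a feature.

## Encoding, abstention, confidence

The similarity of the chosen code is its confidence.  If the best
similarity at any level is at or below the abstain floor (default 0), the
coder returns no code but still reports the best similarity seen, for
diagnostics.  Abstention is the mechanism by which micro-averaged precision
and recall can differ for a single-label coder — with zero abstentions the
two are identical, and the evaluation module asserts exactly that.
Categories that carry terminology but have no searchable subcategory
(undivided categories) are returned at category level rather than failing
silently; evaluation counts them correct at 3-digit only.

## Evaluation and triage

Micro-averaged P/R/F at 4-digit (equality through the subcategory digit)
and 3-digit (category truncations equal) levels; tp/fp/fn are summed over
codes before division, fn counts gold instances without a correct
assignment (wrong or abstained).  The threshold sweep re-encodes the gold
set per θ and method; the θ = 0 rows coincide with the unthresholded
metric by construction.  Triage partitions results at a confidence
threshold (0.875 default) and scores each partition separately; the report
also exposes the confidence samples of correct and incorrect assignments so
a rank-sum test can be applied externally if desired.

## Synthetic studies

The generators emulate the *structure* of the real resources, not their
content:

* **Terminology** — contiguous sections, categories with shared head words,
  exactly `n_terms_per_subcat` terms per subcategory (default 2, near the
  real library's 2.28 average), words drawn as short CJK-range strings so
  character-level LCS and character-dimension vectors are exercised
  realistically.  Defaults are a deliberately small skeleton
  (3 × 4 × 3 = 36 subcategories, roughly 1/50 of one real chapter's grain).
* **Queries** — terminology terms perturbed by synonym substitution (from a
  generated synonym table; synonyms share their base word's first
  character and, in the taxonomy, its sememe leaf) and/or single-character
  edits.  Zero noise yields verbatim terms, which is what makes the
  noise-free recovery study a pipeline identity check.
* **Corpus** — topic-structured documents dominated by one category's word
  pool, so same-category words co-occur preferentially and context vectors
  rank same-category synonyms above cross-category words (asserted with a
  margin in the tests).
* **Taxonomy** — one sememe per category, one leaf per word: same-category
  word pairs sit 2 edges apart, cross-category pairs 4, synonyms share a
  leaf.  A coverage fraction below 1 leaves words out of the lexicon to
  exercise the LCS fallback; coverage 0 reduces the knowledge backend to
  pure string similarity.

What passing these studies shows: the formulas are implemented exactly
(oracle agreement), the argmax machinery is correct (brute-force
equivalence), the hierarchy saves work (candidate counts), and the
threshold and rescue mechanisms operate as designed.  What it does not
show: real-world coding accuracy.  Synthetic vocabularies have no
polysemy, no real segmentation ambiguity, no annotation noise, and their
synonym structure is far cleaner than clinical language; absolute F-scores
on these fixtures are near 1 by construction and say nothing about
performance on hospital data.

## Problem sizes and numerics

The bundled studies use systems of roughly 8–500 subcategories, corpora of
30–120 documents, and query sets of ≤ ~100 instances — sizes chosen so the
whole verification suite re-runs in minutes on one core while still
covering the multi-section, multi-backend regime.  All randomness flows
from explicit integer seeds; backends memoize symmetric pair scores;
similarity comparisons use strict `>` over lexicographically sorted
candidates, which realizes the smallest-code tie-break without any epsilon.
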