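# icdcoder

Example-based automatic assignment of ICD-10 codes to Chinese diagnostic
statements, for clinical-NLP researchers and medical-records engineers who
need a transparent, terminology-driven coder rather than a trained
classifier.

## The method

A controlled terminology (such as China's standard diagnostic library) files
each standard diagnosis name under a 6-digit instance code.  Every ICD-10
code *c* — subcategory (`K29.1`), category (`K29`), or section (`K20-K31`)
— is described by the text *T<sub>c</sub>* obtained by concatenating all
terminology terms filed under *c* or its descendants.  A diagnosis *D* is
encoded by maximizing a semantic text similarity:

* **flat method** — `code = argmax sim(D, T_c)` over every searchable
  subcategory code;
* **hierarchical method** — pick the best section by `sim(D, T_c)`, then the
  best category under it, then the best subcategory under that category.
  This examines only on the order of
  #sections + categories-per-section + subcategories-per-category
  candidates, and resists coincidental near-matches in unrelated chapters.

The text metric is a thresholded, idf-weighted combination of word-to-word
similarity and word specificity:

```
sim(T1, T2) = 1/2 · [ Σ_{w ∈ S(T1,T2,θ)} maxSim(w, T2)·idf(w) / Σ_{w ∈ T1} idf(w)
                    + Σ_{w ∈ S(T2,T1,θ)} maxSim(w, T1)·idf(w) / Σ_{w ∈ T2} idf(w) ]
```

where `maxSim(w, T)` is the best word similarity between `w` and any token
of `T`, `idf(w)` is the plain ratio of corpus size to document frequency
(no logarithm), and `S(T1, T2, θ)` keeps only words whose best match reaches
the threshold θ — filtering out irrelevant words whose low-but-positive
similarity would otherwise leak into the score.

Word-to-word similarity is pluggable; four backends are provided:

| backend     | sim(w1, w2)                                              |
|-------------|----------------------------------------------------------|
| `exact`     | 1 iff the strings are equal                               |
| `lcs`       | `len(LCS)/(len(w1)+len(w2)−len(LCS))`, character level    |
| `knowledge` | max over concept pairs of sememe-tree similarity `α/(d+α)`; LCS fallback for out-of-lexicon words |
| `vector`    | cosine of co-occurrence context vectors (word dims, window 3/side, or character dims, window 7/side) |

The similarity of the finally chosen code, `sim(D, T_c*)`, doubles as the
**confidence** of the assignment: encodings above a confidence threshold
(0.875 by default in the `triage` command) can be recorded automatically,
the rest go to human coders.  Evaluation is micro-averaged precision /
recall / F1 at the 4-digit (subcategory) and 3-digit (category) levels.

## Worked example

The classic failure the hierarchical method fixes: the query 耳神经痛
(ear neuralgia) belongs under `H92.0`, whose only terminology term is 耳痛
(earache), but `G58.0` carries 肋间神经痛 (intercostal neuralgia), whose
exact 神经痛 match scores higher under the flat argmax.

```python
from icdcoder import *
from icdcoder.synthetic import hierarchical_rescue_fixture

sections, entries, lexicon, query, _, _ = hierarchical_rescue_fixture()
system = build_code_system(entries, sections)
config = SimilarityConfig(
    LcsBackend(), IdfModel.uniform(), theta=0.0,
    tokenizer=GreedyTokenizer(lexicon),
)

flat = encode_flat(query, system, config)
hier = encode_hierarchical(query, system, config)
print(f"flat:         {flat.code}  confidence={flat.confidence:.4f}  "
      f"candidates={flat.n_candidates_evaluated}")
print(f"hierarchical: {hier.code}  confidence={hier.confidence:.4f}  "
      f"candidates={hier.n_candidates_evaluated}")
for level, code, sim in hier.trace:
    print(f"  {level:<12} {code}  sim={sim:.4f}")
```

prints

```
flat:         G58.0  confidence=0.5000  candidates=8
hierarchical: H92.0  confidence=0.4375  candidates=7
  section      H90-H95  sim=0.4167
  category     H92  sim=0.4375
  subcategory  H92.0  sim=0.4375
```

The flat coder scores `sim(D, T_G58.0) = 0.5 > 0.4375 = sim(D, T_H92.0)` and
lands in the wrong chapter.  The hierarchical coder compares whole sections
first — the ear section's concatenated terms resemble the query more than
the nerve section's — so the descent stays in `H90-H95` and returns the
correct code, examining 7 candidates instead of all 8 subcategories (on a
real-scale system: ~262 sections + <40 + ≤10 instead of >10,000).

## Command line

```
icdcoder simulate --seed 5 --out study/           # synthetic terminology, corpus, taxonomy, gold
icdcoder build --terminology study/terminology.tsv --sections study/sections.txt --out study/system.json
icdcoder fit-vectors --corpus study/corpus.txt --mode char --out study/vectors
icdcoder encode --system study/system.json --config config.yaml --method hier --in queries.txt --out codes.tsv
icdcoder eval   --system study/system.json --config config.yaml --gold study/gold.tsv --out report.json
icdcoder sweep  --system study/system.json --config config.yaml --gold study/gold.tsv --out sweep.tsv
icdcoder triage --system study/system.json --config config.yaml --gold study/gold.tsv --threshold 0.875 --out triage.json
```

`config.yaml` keys: `backend` (exact|lcs|knowledge|vector), `theta`,
`alpha`, `idf`, `vectors`, `taxonomy_edges`, `taxonomy_lexicon`,
`tokenizer_lexicon`, `abstain_floor`, `log_idf`.

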