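# dislex

Disease mention recognition and MeSH concept normalization for
PubMed-style abstracts.

Biomedical text mining pipelines typically extract disease information in
two stages: **disease named entity recognition** (DNER) — finding the
character spans of disease names in a title + abstract — and **disease name
normalization** (DNORM) — mapping each recognized span to a concept ID in a
controlled vocabulary such as MeSH. `dislex` implements both stages as a
library and a small CLI, for people who need an inspectable, dependency-light
dictionary-lookup normalizer rather than a learned ranker.

## The model

**Recognition.** Tagging is a sequential labeling problem over BIESO labels
(Begin / Inside / End / Single / Outside: a multi-token mention is `B I* E`,
a one-token mention `S`). A first-order linear-chain CRF assigns

```
p(Y | W) = (1 / Z(W)) · exp( Σ_t Σ_i λ_i f_i(y_{t-1}, y_t, W, t) )
```

where the binary feature functions `f_i` cover four families — word identity
and part of speech of the previous/current/next token; gazetteer membership
(dictionary names BIESO-tagged at the token level, with match tag and entry
length); morphology (lemma, 2–5 character prefixes/suffixes); and word shape
(`CANCER → XXXXXX`, `p53 → xdd`) — plus a small set of feature conjunctions.
Weights `λ_i` are fit by L2-penalized maximum conditional likelihood with a
Quasi-Newton optimizer (L-BFGS); decoding is exact Viterbi; features with
|weight| < 0.05 are pruned after training. A document-level post-processing
pass then propagates every recognized surface string to its other exact
occurrences in the document.

**Normalization.** A recognized mention Q is matched against a MEDIC-style
vocabulary entry D under exact equality of preprocessed term sequences
(lowercase, punctuation → space, stopwords removed): Q = D. Around that core
sit four techniques: abbreviation resolution (short forms detected by the
classic parenthesized-definition algorithm, expanded via a frequency-bearing
lexicon with in-document long forms taking precedence); dictionary
enhancement (external synonyms of primary names, and variants with short
forms expanded, added under distinct provenance tags); query expansion
(appending `disorder / syndrome / injury / infection / abnormality` when the
original query finds nothing); and priority rules — a fixed lattice over
(query form × entry provenance), with per-ID candidate frequency and load
order breaking ties. No candidate at any level yields `-1`. Relaxed `term`
and `phrase` proximity modes are available and always rank below exact
matches.

## Worked example

```python
from dislex.corpus_io import Document
from dislex.normalize import DictionaryIndex, normalize_mention
from dislex.synth import FixtureSpec, generate_dictionary

res = generate_dictionary(FixtureSpec(seed=7))
index = DictionaryIndex(res.dictionary)

print(normalize_mention("Kidney Disease", None, res.lexicon, index))
doc = Document("pmid1", "Lidocaine safety",
               "Cocaine-induced myocardial infarction (MI) was treated. "
               "MI recurred.")
print(normalize_mention("MI", doc, res.lexicon, index))
print(normalize_mention("posterior reversible encephalopathy",
                        None, res.lexicon, index))
```

prints

```
D007674
D009203
D054038
```

`Kidney Disease` hits a vocabulary synonym of concept D007674 directly; `MI`
is first expanded to `myocardial infarction` (defined earlier in the same
document) and then matched to D009203; `posterior reversible encephalopathy`
matches nothing until query expansion appends `syndrome`, which hits a
synonym of D054038.

The same pipeline from a shell:

```
dislex synth --seed 5 --n-docs 30 --out data
dislex train --corpus data/train.pubtator --dictionary data/dictionary.tsv --model model.json
dislex tag --model model.json --in data/test_raw.pubtator --out tagged.pubtator
dislex normalize --in tagged.pubtator --dictionary data/dictionary.tsv \
       --lexicon data/abbreviations.tsv --out normalized.pubtator
dislex eval --pred normalized.pubtator --gold data/test_gold.pubtator --level docid
```

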