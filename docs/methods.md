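# Methods

## Problem setting

Input documents are PubMed-style records: a title, an abstract, and
(for gold data) disease mention annotations with character offsets and MeSH
concept IDs. The pipeline has two stages: recognition tags disease mention
spans; normalization maps each span to a concept ID in a MEDIC-style
disease vocabulary (MeSH `D...`/`C...` IDs; OMIM rows are dropped at load).
`-1` denotes "no concept".

Offsets are 0-based, end-exclusive, over `title + "\n" + abstract` — one
separator character. This is a convention, not an interoperability claim:
other corpus dialects separate title and abstract by a space; the loader
validates every annotation against the convention and rejects files that do
not satisfy it, rather than guessing.

## Recognition

### Tagging scheme and codec

Spans are encoded per sentence as BIESO labels. Encoding requires mentions
aligned to token boundaries; during training-data preparation, misaligned
spans are snapped **outward** to the smallest covering token span and
counted in a warning (an inward snap could produce empty spans). Decoding
never raises on ill-formed tagger output: each maximal run of non-O labels
yields at least one mention — well-formed segments (`S`, `B I* E`) close
exactly where they should, a dangling `I`/`E` at run start opens a mention,
and a `B`/`I` left open at a run boundary closes there. This repair
maximizes recall; the alternative (dropping ill-formed runs) silently
deletes borderline predictions.

The default tokenizer splits on whitespace and peels punctuation, but keeps
hyphen/slash-joined alphanumerics (`AMI/GI`, `Hepatitis-C`) as single
tokens; internal punctuation is exposed to the model through word shape
instead. The tokenizer is a plain callable and can be replaced wholesale.

### Features

Per token, five namespaced families (see `features.FeatureConfig` for the
switches):

* `w:` — word identity and POS of the previous/current/next token;
* `morph:` — lemma and prefixes/suffixes of length 2..min(5, len−1) of the
  three context tokens. The cap at len−1 keeps a token from being its own
  affix, which would duplicate the identity feature;
* `shape:` — character-class shape (uppercase→`X`, lowercase→`x`,
  digit→`d`, Greek→`g`, everything else preserved) of the three context
  tokens. Greek detection covers the Unicode Greek blocks and the
  spelled-out letter names alpha..omega. Out-of-bounds context and empty
  shapes take the sentinel `none`;
* `gaz:` — dictionary names are tokenized, BIESO-tagged, and indexed by
  token; a matching token contributes its tag and the matched entry's token
  length. When a token occurs in several entries the longest entry wins
  (deterministic tie-break toward B/E/I/S order);
* `conj:` — two fixed conjunctions: current word × previous word, and
  current shape × current POS. The conjugation set is deliberately small
  and configurable; larger sets did not earn their parameter count on the
  synthetic corpus.

POS and lemma come from injected annotators. The defaults are deterministic
suffix heuristics (e.g. `-itis`/`-osis` → noun; plural stripping), chosen so
the package has no model downloads and identical output everywhere; any
callable with the same signature (e.g. a spaCy wrapper) can be injected. A
failing annotator silently degrades that family to `none` values with a
logged warning rather than aborting tagging.

### CRF

The tagger is a first-order linear-chain CRF: emission weights per (feature,
label) plus a full transition matrix with a dedicated start row. Training
maximizes the conditional log-likelihood with an L2 penalty (`c2`, default
1.0) using scipy's L-BFGS-B; gradients come from forward–backward marginals
computed in log space. Decoding is exact Viterbi. Everything is
deterministic — identical corpus and configuration give bit-identical
weights, so the recorded `seed` is provenance metadata, not a randomness
source. After training, features whose largest absolute weight falls below
the prune threshold (default 0.05) are removed from the model; on the
synthetic corpus this cuts the feature table by an order of magnitude with
no measurable change in predictions.

The CRF engine lives in `dislex.crf` and is intentionally minimal (dense
emissions per sentence, ~L² transition work per token); it is comfortable at
the corpus sizes this package targets (10³–10⁴ sentences, 5 labels). A
Viterbi-vs-enumeration test pins its correctness against brute force on
short sequences.

### Post-processing

The CRF conditions on sentence-local context only, so the same string can be
recognized in one sentence and missed in another. `post_process` collects
every distinct recognized surface form and adds a mention at every other
exact, case-sensitive occurrence at word boundaries (both directions between
title and abstract), skipping occurrences overlapping an existing or
already-added mention; longer surfaces are propagated first so a short
repeat cannot block a longer one. The operation is idempotent, never removes
a mention, and can only raise recall — and, symmetrically, multiplies any
false positive by its occurrence count, which is the known cost of the
technique. Case-sensitivity is deliberate: case-insensitive propagation
would inflate exactly that failure mode.

## Normalization

### Preprocessing and exact match

Queries and entry names are normalized identically: lowercase, punctuation
replaced by a space (preserving the boundary in `Hepatitis-C`), stopwords
removed, whitespace split. The stopword list is a small fixed English list
(`normalize.DEFAULT_STOPWORDS`), overridable per index. An exact match
requires identical term sequences — same words, same count, same order.

### Abbreviation resolution

Definitions are detected with the classic parenthesized short-form
algorithm: a candidate inside `(...)` (2–10 characters, ≤ 2 words, at least
one letter, alphanumeric first character) is matched right-to-left against
the preceding words of the sentence, requiring every alphanumeric character
of the short form to appear in order and its first character to start a
word; the window is min(|SF|+5, 2·|SF|) words. Nested parentheses resolve
innermost-first (the matcher only accepts parenthesis-free contents).

The lexicon stores (short form, long form, build-time frequency), ordered by
frequency then lexicographically. Resolution of a recognized short form:
a unique long form wins outright; among several, one mentioned earlier in
the document wins (case-insensitive substring search over the text preceding
the mention; "earlier" is the package's reading of in-document precedence);
otherwise the highest build-time frequency, ties broken lexicographically.
Short-form lookup is case-sensitive (`SPH` ≠ `sph`) because abbreviations
are case-bearing. Unknown short forms pass through unchanged, so resolution
never empties a query.

### Dictionary enhancement

Two enhancement passes, each tagging its additions with a provenance:

* external synonyms: phrases from a generic synonym file keyed by primary
  name (case-insensitive) are added as `external_synonym` unless an entry of
  the same concept already preprocesses to the same term sequence;
* abbreviation expansion: entries containing a lexicon short form get an
  `abbrev_expanded` twin with the short form replaced by its long form,
  duplicates skipped.

Enhancement only ever appends entries; a golden test asserts that queries
answered by primary names are unchanged by any enhancement (priority
dominance, below).

### Query expansion

Only when the lookup finds nothing, the query is re-issued once per head
term with that term appended: `disorder, syndrome, injury, infection,
abnormality` (the default list; configurable). Expanded-query candidates
from different head terms are pooled within a priority level rather than
ordered by head-term position — the levels already separate what matters.

### Priority rules

Every candidate is a (query, entry) pair with a level from the lattice over
(query form, entry provenance):

| level | query | entry provenance |
|---|---|---|
| 1 | original | primary |
| 2 | original | synonym |
| 3 | original | external_synonym |
| 4 | original | abbrev_expanded |
| 5–8 | expanded | same order |

The lattice is monotone in both dimensions, anchored by the two stated
extremes (original × primary highest, expanded × abbrev_expanded lowest).
Selection: best non-empty level → most frequent concept ID among its
candidates → lowest load rank ("the first entry") on frequency ties → `-1`
if no candidates exist at all. Selection is deterministic and invariant
under candidate permutation.

### Proximity modes

`term` mode matches when either side's term bag contains the other's;
`phrase` mode when either side's term sequence appears contiguously and in
order inside the other. Both therefore include every exact match, giving the
containment chain exact ⊆ phrase ⊆ term that the property suite checks.
The published definitions of these matchers are not fully specified in the
available text; bidirectional containment is this package's interpretation,
fixed by two requirements — a query with an extra modifier ("chronic
hepatitis c virus infection") must reach the entry lacking it, and a
scrambled query ("virus hepatitis") must term-match but not phrase-match.
Proximity-only candidates are assigned levels strictly below all exact
levels (the exact lattice shifted by 8), so an exact match always dominates;
query expansion fires only when even the proximity lookup is empty. No
similarity score is computed; scored retrieval is out of scope.

## Evaluation

Recognition is scored at mention level under exact span matching (off-by-one
is both a false positive and a false negative). Normalization is scored at
document level on concept-ID sets: duplicates collapse, `-1` predictions are
excluded, TP/FP/FN sum over documents. P, R and F use the usual formulas
with a zero-denominator-yields-0 convention; reported values round half-up
to two decimals (which reproduces all fifteen published confusion-count
rows exactly), raw floats stay available on `EvalCounts`. Whether mention-
level recognition scoring should also require ID agreement is left out by
design: span-only for recognition, ID-set for normalization.

## Synthetic data

`dislex.synth` generates the corpora the tests and the acceptance run use.
A `FixtureSpec` fixes the study conditions: 250 documents, a 40-concept toy
vocabulary plus three embedded worked concepts (D007674, D054038, D009203),
three planted mentions per document in category mix 35% primary-name / 20%
synonym-only / 15% expansion-only / 15% abbreviation / 15% unmatchable, and
a 0.3 per-mention repetition rate. The mix gives every normalization
technique (synonym lookup, query expansion, abbreviation resolution,
`-1` assignment) a double-digit mention count per corpus while keeping
primary-name matches the most common case, as in real disease corpora.

Documents are template sentences with planted mentions at recorded offsets:
abbreviation plants emit a `long form (SF)` definition plus a later bare-SF
sentence; repetition re-emits a surface to exercise propagation; distractor
sentences use a vocabulary disjoint from disease names. Gold concept IDs are
assigned at plant time, so evaluation oracles are exact by construction, and
a test verifies that every matchable planted mention is recoverable by the
normalizer alone. All randomness flows through `random.Random(seed)` with
integer draws, so output is byte-identical across platforms for a fixed
seed.

What the generator does **not** emulate: real PubMed syntax and vocabulary
breadth, nested/overlapping/discontinuous mentions, genuinely ambiguous
vocabulary entries (one name under several concepts), misspellings, and
class imbalance at realistic sparsity. Passing the parameter-recovery test
therefore shows the pipeline is correctly wired and learnable-from-signal,
not that it attains any particular accuracy on real corpora; published
corpus-scale scores require the real corpus and vocabulary, which are not
redistributed here.

## Problem sizes and thresholds

The parameter-recovery run trains on 200 synthetic documents (~1 800
sentences) and evaluates on 50 held out, finishing in about two minutes on
one CPU — a size chosen to keep the whole suite fast while leaving the
recovery thresholds (mention-level F ≥ 0.95, document-ID F ≥ 0.9, both fixed
before implementation) a real bar rather than a formality. L-BFGS stops at
`ftol` 1e-5 / `gtol` 1e-5 / 120 iterations; on the synthetic corpus it
converges in ~30 iterations. Degenerate inputs are defined everywhere:
empty corpora raise, zero-mention corpora train an all-O model, empty
queries expand to nothing and normalize to `-1`, and an all-pruned model
logs a warning instead of failing.
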