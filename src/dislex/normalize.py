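"""Dictionary-lookup normalization of disease mentions to MeSH concept IDs.

A recognized mention Q and a dictionary entry D are both preprocessed
(lowercase; punctuation replaced by spaces; stopwords removed) and an exact
match requires the same words, in the same number and order. When the
original query finds nothing, query expansion appends one disease head term
("disorder", "syndrome", "injury", "infection", "abnormality") at a time
and retries. The dictionary itself can be enhanced beforehand with
externally sourced synonyms of primary names and with abbreviation-expanded
variants of entries containing known short forms.

Because enhancement and expansion create the same name under several
concept IDs, candidates carry a priority level over (query form, entry
provenance): an original query matching a primary name ranks highest,
an expanded query matching an abbreviation-expanded entry lowest. Within
the best non-empty level, the concept ID occurring most often among the
candidates wins; frequency ties fall back to the entry loaded first. No
candidate at any level yields "-1".

Two relaxed proximity modes are available: term match (entry contains all
query terms in any order) and phrase match (entry contains the query terms
contiguously in order); an exact match always satisfies both, and
proximity-only candidates rank strictly below every exact-match level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from dislex.abbreviation import AbbreviationLexicon, resolve
from dislex.corpus_io import Dictionary, DictionaryEntry, Document, Mention

logger = logging.getLogger(__name__)

#: Small fixed English stopword list (configurable per call).
DEFAULT_STOPWORDS = frozenset(
    """a an and as at be by for from in into is it of on or that the to
    with""".split()
)

#: Disease head terms appended during query expansion.
DEFAULT_HEAD_TERMS = ("disorder", "syndrome", "injury", "infection", "abnormality")

_PUNCT_RE = re.compile(r"[^\w\s]|_")

#: Priority lattice over (expansion_state, provenance); 1 = highest.
PRIORITY_LEVELS: dict[tuple[str, str], int] = {
    ("original", "primary"): 1,
    ("original", "synonym"): 2,
    ("original", "external_synonym"): 3,
    ("original", "abbrev_expanded"): 4,
    ("expanded", "primary"): 5,
    ("expanded", "synonym"): 6,
    ("expanded", "external_synonym"): 7,
    ("expanded", "abbrev_expanded"): 8,
}
#: Proximity-only candidates sit strictly below every exact level.
PROXIMITY_OFFSET = 8


def preprocess(
    text: str, stopword_list: Iterable[str] = DEFAULT_STOPWORDS
) -> tuple[str, ...]:
    """Lowercase, replace punctuation with spaces, drop stopwords, split.

    Replacing (not deleting) punctuation preserves the term boundary in
    names like "Hepatitis-C".
    """
    stop = set(stopword_list)
    cleaned = _PUNCT_RE.sub(" ", text.lower())
    return tuple(t for t in cleaned.split() if t not in stop)


@dataclass(frozen=True)
class NormalizedQuery:
    original_text: str
    terms: tuple[str, ...]
    expansion_state: str = "original"  # "original" | "expanded"
    head_term: str | None = None


@dataclass(frozen=True)
class CandidatePair:
    query: NormalizedQuery
    entry: DictionaryEntry
    priority_level: int


class DictionaryIndex:
    """Exact-lookup index from preprocessed name to dictionary entries.

    Entry lists preserve load rank; per-ID frequencies are tallied per
    lookup, not stored.
    """

    def __init__(
        self,
        dictionary: Dictionary,
        stopword_list: Iterable[str] = DEFAULT_STOPWORDS,
    ) -> None:
        self.stopwords = frozenset(stopword_list)
        self._exact: dict[tuple[str, ...], list[DictionaryEntry]] = {}
        self._all: list[tuple[tuple[str, ...], DictionaryEntry]] = []
        for entry in sorted(dictionary, key=lambda e: e.rank):
            terms = preprocess(entry.name, self.stopwords)
            if not terms:
                continue
            self._exact.setdefault(terms, []).append(entry)
            self._all.append((terms, entry))

    def __len__(self) -> int:
        return len(self._all)

    def exact(self, terms: tuple[str, ...]) -> list[DictionaryEntry]:
        return list(self._exact.get(terms, []))

    def scan(self) -> Iterable[tuple[tuple[str, ...], DictionaryEntry]]:
        return iter(self._all)


def _pairs(
    query: NormalizedQuery, entries: Iterable[DictionaryEntry], proximity: bool = False
) -> list[CandidatePair]:
    offset = PROXIMITY_OFFSET if proximity else 0
    return [
        CandidatePair(
            query,
            e,
            PRIORITY_LEVELS[(query.expansion_state, e.provenance)] + offset,
        )
        for e in entries
    ]


def exact_lookup(query: NormalizedQuery, index: DictionaryIndex) -> list[CandidatePair]:
    """Entries whose preprocessed name equals the query term sequence
    (same words, same count, same order)."""
    return _pairs(query, index.exact(query.terms))


def term_match(query: NormalizedQuery, index: DictionaryIndex) -> list[CandidatePair]:
    """Bag-of-terms proximity match between query and entry.

    Hits when one side's terms are all contained in the other, in any order
    — the entry may carry extra terms ("virus hepatitis" finds "hepatitis c
    virus infection") or the query may ("chronic hepatitis c virus
    infection" finds the same entry). Exact matches keep their exact
    priority level; proximity-only hits rank strictly below all exact
    levels.
    """
    if not query.terms:
        return []
    want = set(query.terms)
    exact_hits, fuzzy_hits = [], []
    for terms, entry in index.scan():
        have = set(terms)
        if want <= have or have <= want:
            (exact_hits if terms == query.terms else fuzzy_hits).append(entry)
    return _pairs(query, exact_hits) + _pairs(query, fuzzy_hits, proximity=True)


def _contains_contiguous(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    return n > 0 and any(
        haystack[i : i + n] == needle for i in range(len(haystack) - n + 1)
    )


def phrase_match(query: NormalizedQuery, index: DictionaryIndex) -> list[CandidatePair]:
    """Contiguous in-order proximity match between query and entry.

    Hits when the query terms appear contiguously in the entry or the entry
    terms appear contiguously in the query; tighter than term match, looser
    than exact equality.
    """
    if not query.terms:
        return []
    exact_hits, fuzzy_hits = [], []
    for terms, entry in index.scan():
        if _contains_contiguous(terms, query.terms) or _contains_contiguous(
            query.terms, terms
        ):
            (exact_hits if terms == query.terms else fuzzy_hits).append(entry)
    return _pairs(query, exact_hits) + _pairs(query, fuzzy_hits, proximity=True)


class ExpansionContractError(ValueError):
    """expand_query was called although the original query matched."""


def expand_query(
    query: NormalizedQuery,
    head_terms: Sequence[str] = DEFAULT_HEAD_TERMS,
    index: DictionaryIndex | None = None,
) -> list[NormalizedQuery]:
    """One expanded query per head term (original terms + appended term).

    Expansion is only meaningful when the original query found no match;
    passing ``index`` enforces that contract and raises
    :class:`ExpansionContractError` if the original query does match.
    """
    if index is not None and index.exact(query.terms):
        raise ExpansionContractError(
            f"query {query.terms!r} already has an exact match"
        )
    if not query.terms:
        return []
    return [
        NormalizedQuery(
            original_text=query.original_text,
            terms=query.terms + (h,),
            expansion_state="expanded",
            head_term=h,
        )
        for h in head_terms
    ]


def enhance_with_synonyms(
    dictionary: Dictionary, synonym_source: dict[str, list[str]]
) -> Dictionary:
    """Add externally sourced synonyms of primary names (provenance
    ``external_synonym``), skipping any already present under the concept
    (compared after preprocessing). Returns a new Dictionary."""
    out = dictionary.copy()
    existing: dict[str, set[tuple[str, ...]]] = {}
    for e in dictionary:
        existing.setdefault(e.concept_id, set()).add(preprocess(e.name))
    # case-insensitive match of primary names against the source phrases
    source_ci = {k.lower(): v for k, v in synonym_source.items()}
    n_added = 0
    for e in [e for e in dictionary if e.provenance == "primary"]:
        for syn in source_ci.get(e.name.lower(), []):
            key = preprocess(syn)
            if not key or key in existing.get(e.concept_id, set()):
                continue
            out.add(e.concept_id, syn, "external_synonym")
            existing.setdefault(e.concept_id, set()).add(key)
            n_added += 1
    logger.info("added %d external synonym entries", n_added)
    return out


def enhance_with_abbrev_expansion(
    dictionary: Dictionary, lexicon: AbbreviationLexicon
) -> Dictionary:
    """Add entries with known short forms replaced by their long forms
    (provenance ``abbrev_expanded``), skipping duplicates. Returns a new
    Dictionary."""
    out = dictionary.copy()
    existing: dict[str, set[tuple[str, ...]]] = {}
    for e in dictionary:
        existing.setdefault(e.concept_id, set()).add(preprocess(e.name))
    sfs = lexicon.short_forms()
    n_added = 0
    for e in dictionary.entries:
        words = e.name.split()
        hit = [i for i, w in enumerate(words) if w in sfs]
        if not hit:
            continue
        new_words = list(words)
        for i in hit:
            new_words[i] = resolve(words[i], None, lexicon)
        new_name = " ".join(new_words)
        key = preprocess(new_name)
        if not key or key in existing.get(e.concept_id, set()):
            continue
        out.add(e.concept_id, new_name, "abbrev_expanded")
        existing.setdefault(e.concept_id, set()).add(key)
        n_added += 1
    logger.info("added %d abbreviation-expanded entries", n_added)
    return out


def prioritize(candidates: Sequence[CandidatePair]) -> str:
    """Select the final concept ID from candidate pairs.

    Take the non-empty set at the best (lowest) priority level; within it,
    the concept ID with the highest frequency among the candidates wins;
    frequency ties go to the entry with the lowest load rank ("the first
    entry"). No candidates at all yields "-1".
    """
    if not candidates:
        return "-1"
    best_level = min(c.priority_level for c in candidates)
    pool = [c for c in candidates if c.priority_level == best_level]
    freq: dict[str, int] = {}
    first_rank: dict[str, int] = {}
    for c in pool:
        cid = c.entry.concept_id
        freq[cid] = freq.get(cid, 0) + 1
        first_rank[cid] = min(first_rank.get(cid, c.entry.rank), c.entry.rank)
    return min(freq, key=lambda cid: (-freq[cid], first_rank[cid]))


_MATCHERS = {"exact": exact_lookup, "term": term_match, "phrase": phrase_match}


def normalize_mention(
    mention: Mention | str,
    document: Document | None,
    lexicon: AbbreviationLexicon | None,
    index: DictionaryIndex,
    mode: str = "exact",
    head_terms: Sequence[str] = DEFAULT_HEAD_TERMS,
) -> str:
    """Full lookup pipeline for one mention; returns a concept ID or "-1".

    Abbreviation resolution -> preprocessing -> lookup (exact or proximity
    per ``mode``) -> query expansion when nothing matched -> priority rules.
    """
    if mode not in _MATCHERS:
        raise ValueError(f"mode must be one of {sorted(_MATCHERS)}")
    matcher = _MATCHERS[mode]
    if isinstance(mention, Mention):
        surface, offset = mention.text, mention.start
    else:
        surface, offset = mention, None
    if lexicon is not None:
        surface = resolve(surface, document, lexicon, before_offset=offset)
    query = NormalizedQuery(original_text=surface, terms=preprocess(surface, index.stopwords))
    candidates = matcher(query, index)
    if not candidates:
        for expanded in expand_query(query, head_terms):
            candidates.extend(matcher(expanded, index))
    return prioritize(candidates)


def normalize_document(
    document: Document,
    lexicon: AbbreviationLexicon | None,
    index: DictionaryIndex,
    mode: str = "exact",
) -> Document:
    """Return a copy of the document with mention concept IDs filled in."""
    mentions = [
        Mention(
            m.start,
            m.end,
            m.text,
            m.entity_type,
            normalize_mention(m, document, lexicon, index, mode=mode),
        )
        for m in document.mentions
    ]
    return Document(document.doc_id, document.title, document.abstract, mentions)
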