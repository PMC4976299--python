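import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dislex.abbreviation import AbbreviationLexicon, AbbreviationRecord
from dislex.corpus_io import Dictionary, DictionaryEntry, Document
from dislex.normalize import (
    DEFAULT_HEAD_TERMS,
    DictionaryIndex,
    ExpansionContractError,
    NormalizedQuery,
    enhance_with_abbrev_expansion,
    enhance_with_synonyms,
    exact_lookup,
    expand_query,
    normalize_mention,
    phrase_match,
    preprocess,
    prioritize,
    term_match,
)


def q(text: str) -> NormalizedQuery:
    return NormalizedQuery(text, preprocess(text))


@pytest.mark.parametrize(
    "text, terms",
    [
        ("Kidney Disease", ("kidney", "disease")),
        ("Hepatitis-C, chronic", ("hepatitis", "c", "chronic")),
        ("", ()),
        ("the disease of kidney", ("disease", "kidney")),  # stopwords dropped
    ],
)
def test_preprocess_lowercase_punct_stopwords(text, terms):
    assert preprocess(text) == terms


def test_exact_lookup_worked_example(index):
    cands = exact_lookup(q("Kidney Disease"), index)
    assert {c.entry.concept_id for c in cands} == {"D007674"}
    assert prioritize(cands) == "D007674"


def test_exact_lookup_unmatched_and_synonym_provenance(index):
    assert exact_lookup(q("zyxgarbl nonsense"), index) == []
    cands = exact_lookup(q("Renal Disease"), index)
    assert cands and all(c.entry.provenance == "synonym" for c in cands)


def test_exact_lookup_requires_same_order():
    d = Dictionary()
    d.add("D1", "hepatitis c virus", "primary")
    idx = DictionaryIndex(d)
    assert exact_lookup(q("hepatitis c virus"), idx)
    assert exact_lookup(q("virus hepatitis c"), idx) == []


def test_expand_query_produces_five_default_variants():
    variants = expand_query(q("posterior reversible encephalopathy"))
    assert len(variants) == len(DEFAULT_HEAD_TERMS) == 5
    assert {v.terms[-1] for v in variants} == set(DEFAULT_HEAD_TERMS)
    assert all(v.expansion_state == "expanded" for v in variants)
    assert all(
        v.terms[:-1] == ("posterior", "reversible", "encephalopathy")
        for v in variants
    )
    assert expand_query(q("")) == []


def test_expand_query_contract_violation(index):
    with pytest.raises(ExpansionContractError):
        expand_query(q("Kidney Disease"), index=index)


def test_expansion_reaches_the_leukoencephalopathy_concept(index, resources):
    cid = normalize_mention(
        "posterior reversible encephalopathy", None, resources.lexicon, index
    )
    assert cid == "D054038"


def test_abbreviation_then_lookup(index, resources):
    doc = Document(
        "d1",
        "Case report",
        "Cocaine-induced myocardial infarction (MI) was treated. MI recurred.",
    )
    assert normalize_mention("MI", doc, resources.lexicon, index) == "D009203"


def test_nonsense_normalizes_to_no_concept(index, resources):
    assert normalize_mention("blorbagus wungle", None, resources.lexicon, index) == "-1"


def _fixture_dictionary():
    d = Dictionary()
    d.add("D100", "kidney diseases", "primary")
    d.add("D100", "renal disease", "synonym")
    d.add("D200", "hepatitis c virus infection", "primary")
    d.add("D300", "infection", "primary")
    return d


def test_enhance_with_synonyms_adds_missing_only():
    d = _fixture_dictionary()
    source = {"kidney diseases": ["renal disorder", "nephropathy", "renal disease"]}
    out = enhance_with_synonyms(d, source)
    added = [e for e in out if e.provenance == "external_synonym"]
    # "renal disease" already present under D100 -> skipped
    assert sorted(e.name for e in added) == ["nephropathy", "renal disorder"]
    assert all(e.concept_id == "D100" for e in added)
    assert len(enhance_with_synonyms(d, {})) == len(d)


def test_enhance_with_abbrev_expansion():
    d = Dictionary()
    d.add("D400", "HIV Seroconversion", "primary")
    d.add("D500", "plain entry", "primary")
    lex = AbbreviationLexicon(
        [AbbreviationRecord("HIV", "human immunodeficiency virus", 9)]
    )
    out = enhance_with_abbrev_expansion(d, lex)
    added = [e for e in out if e.provenance == "abbrev_expanded"]
    assert [e.name for e in added] == ["human immunodeficiency virus Seroconversion"]
    # duplicate-producing expansion is skipped
    d2 = Dictionary()
    d2.add("D400", "HIV Seroconversion", "primary")
    d2.add("D400", "human immunodeficiency virus seroconversion", "synonym")
    assert len(enhance_with_abbrev_expansion(d2, lex)) == len(d2)


def test_enhancement_never_removes_entries(resources):
    d = resources.dictionary
    out = enhance_with_synonyms(d, {"Kidney Diseases": ["renal disorder"]})
    assert {(e.concept_id, e.name) for e in d} <= {(e.concept_id, e.name) for e in out}


def test_primary_match_results_unchanged_by_enhancement():
    d = _fixture_dictionary()
    enhanced = enhance_with_synonyms(
        d, {"kidney diseases": ["renal disorder", "kidney diseases infection"]}
    )
    enhanced = enhance_with_abbrev_expansion(
        enhanced,
        AbbreviationLexicon([AbbreviationRecord("HCV", "hepatitis c virus", 2)]),
    )
    for query in ("kidney diseases", "hepatitis c virus infection", "infection"):
        before = prioritize(exact_lookup(q(query), DictionaryIndex(d)))
        after = prioritize(exact_lookup(q(query), DictionaryIndex(enhanced)))
        assert before == after


def _entry(cid, rank, provenance="primary"):
    return DictionaryEntry(cid, f"name {rank}", provenance, rank)


def _pair(cid, rank, level, provenance="primary"):
    from dislex.normalize import CandidatePair

    return CandidatePair(q("x"), _entry(cid, rank, provenance), level)


def test_prioritize_level_dominance():
    # one primary-name candidate beats three synonym candidates of another ID
    cands = [
        _pair("D_PRIMARY", 10, 1),
        _pair("D_OTHER", 1, 2, "synonym"),
        _pair("D_OTHER", 2, 2, "synonym"),
        _pair("D_OTHER", 3, 2, "synonym"),
    ]
    assert prioritize(cands) == "D_PRIMARY"


def test_prioritize_frequency_then_rank():
    cands = [_pair("A", 5, 1), _pair("A", 6, 1), _pair("B", 1, 1)]
    assert prioritize(cands) == "A"
    tie = [_pair("B", 2, 1), _pair("A", 7, 1)]
    assert prioritize(tie) == "B"  # tied frequency: lowest load rank wins
    assert prioritize([]) == "-1"


def test_prioritize_permutation_invariant():
    rng = random.Random(0)
    cands = [_pair("A", 5, 1), _pair("A", 6, 1), _pair("B", 1, 1), _pair("C", 0, 2)]
    expected = prioritize(cands)
    for _ in range(20):
        rng.shuffle(cands)
        assert prioritize(cands) == expected


def test_term_and_phrase_match_worked_examples():
    d = Dictionary()
    d.add("D200", "hepatitis c virus infection", "primary")
    idx = DictionaryIndex(d)
    query = q("chronic hepatitis c virus infection")
    assert {c.entry.concept_id for c in term_match(query, idx)} == {"D200"}
    assert {c.entry.concept_id for c in phrase_match(query, idx)} == {"D200"}
    scrambled = q("virus hepatitis")
    assert {c.entry.concept_id for c in term_match(scrambled, idx)} == {"D200"}
    assert phrase_match(scrambled, idx) == []
    assert term_match(q("anything"), DictionaryIndex(Dictionary())) == []


def test_proximity_candidates_rank_below_exact(index):
    query = q("Kidney Disease")
    exact_levels = {c.priority_level for c in exact_lookup(query, index)}
    fuzzy_only = [
        c
        for c in term_match(query, index)
        if preprocess(c.entry.name) != query.terms
    ]
    assert all(c.priority_level > max(exact_levels, default=8) for c in fuzzy_only)


def test_term_mode_recovers_superset_entry():
    d = Dictionary()
    d.add("D200", "hepatitis c virus infection", "primary")
    idx = DictionaryIndex(d)
    assert (
        normalize_mention("chronic hepatitis c virus infection", None, None, idx,
                          mode="exact")
        == "-1"
    )
    assert (
        normalize_mention("chronic hepatitis c virus infection", None, None, idx,
                          mode="phrase")
        == "D200"
    )
    assert (
        normalize_mention("hepatitis c virus", None, None, idx, mode="phrase")
        == "D200"
    )
    assert (
        normalize_mention("virus hepatitis c", None, None, idx, mode="term")
        == "D200"
    )


def test_normalize_mention_idempotent_and_pure(index, resources):
    before = len(index)
    r1 = normalize_mention("Kidney Disease", None, resources.lexicon, index)
    r2 = normalize_mention("Kidney Disease", None, resources.lexicon, index)
    assert r1 == r2 == "D007674"
    assert len(index) == before


WORDS = ["alpha", "bravo", "delta", "echo", "golf", "hotel", "kilo", "lima"]


def _random_dictionary(rng: random.Random) -> Dictionary:
    d = Dictionary()
    for i in range(rng.randint(1, 50)):
        n_words = rng.randint(1, 4)
        name = " ".join(rng.choice(WORDS) for _ in range(n_words))
        d.add(f"D{i:03d}", name, rng.choice(["primary", "synonym"]))
    return d


@settings(max_examples=150, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_containment_exact_within_phrase_within_term(seed):
    rng = random.Random(seed)
    d = _random_dictionary(rng)
    idx = DictionaryIndex(d)
    query = q(" ".join(rng.choice(WORDS) for _ in range(rng.randint(1, 3))))
    exact = {c.entry.rank for c in exact_lookup(query, idx)}
    phrase = {c.entry.rank for c in phrase_match(query, idx)}
    term = {c.entry.rank for c in term_match(query, idx)}
    assert exact <= phrase <= term


@settings(max_examples=150, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_exact_lookup_equals_brute_force_scan(seed):
    rng = random.Random(seed)
    d = _random_dictionary(rng)
    idx = DictionaryIndex(d)
    query = q(" ".join(rng.choice(WORDS) for _ in range(rng.randint(1, 3))))
    brute = {e.rank for e in d if preprocess(e.name) == query.terms}
    assert {c.entry.rank for c in exact_lookup(query, idx)} == brute
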