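import pytest

from dislex.abbreviation import (
    AbbreviationLexicon,
    AbbreviationRecord,
    build_lexicon,
    find_abbreviations,
    read_lexicon_tsv,
    resolve,
    write_lexicon_tsv,
)
from dislex.corpus_io import Dictionary, Document


def test_find_short_form_in_parentheses():
    text = (
        "To evaluate the safety of lidocaine in the setting of "
        "cocaine-induced myocardial infarction (MI)."
    )
    pairs = find_abbreviations(text)
    assert len(pairs) == 1
    sf, lf, sf_span, lf_span = pairs[0]
    assert (sf, lf) == ("MI", "myocardial infarction")
    assert text[sf_span[0] : sf_span[1]] == "MI"
    assert text[lf_span[0] : lf_span[1]] == "myocardial infarction"


def test_numeric_parenthetical_is_not_a_short_form():
    assert find_abbreviations("significant values (p < 0.05) were found") == []


def test_letter_matching_rule_on_three_letter_form():
    pairs = find_abbreviations("history of secondary pulmonary hypertension (SPH)")
    assert [(sf, lf) for sf, lf, *_ in pairs] == [
        ("SPH", "secondary pulmonary hypertension")
    ]


def test_spans_valid_and_non_overlapping():
    text = (
        "acute myocardial infarction (AMI) and gastrointestinal "
        "bleeding (GI bleeding) co-occurred. renal papillary necrosis (RPN) too."
    )
    pairs = find_abbreviations(text)
    spans = sorted(s for _, _, sf_span, lf_span in pairs for s in (sf_span, lf_span))
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        assert b1 <= a2


def _doc(doc_id, abstract, title="t"):
    return Document(doc_id, title, abstract)


def test_build_lexicon_counts_occurrences():
    docs = [
        _doc("1", "we saw myocardial infarction (MI) today."),
        _doc("2", "again myocardial infarction (MI) was observed."),
    ]
    lex = build_lexicon(docs)
    assert [(r.short_form, r.long_form, r.frequency) for r in lex] == [
        ("MI", "myocardial infarction", 2)
    ]


def test_build_lexicon_empty_and_dictionary_contribution():
    assert len(build_lexicon([], Dictionary())) == 0
    d = Dictionary()
    d.add("D1", "human immunodeficiency virus (HIV) seroconversion", "primary")
    lex = build_lexicon([], d)
    assert ("HIV", "human immunodeficiency virus") in {
        (r.short_form, r.long_form) for r in lex
    }


def test_two_long_forms_for_one_short_form_both_kept():
    docs = [
        _doc("1", "acute myocardial infarction (AMI) was treated."),
        _doc("2", "antibody mediated injury (AMI) was suspected."),
    ]
    lex = build_lexicon(docs)
    assert len(lex.long_forms("AMI")) == 2


def test_resolve_single_long_form_and_unknown():
    lex = AbbreviationLexicon([AbbreviationRecord("MI", "myocardial infarction", 3)])
    assert resolve("MI", None, lex) == "myocardial infarction"
    assert resolve("XYZ", None, lex) == "XYZ"
    assert resolve("MI", None, lex) != ""


def test_document_context_dominates_frequency():
    lex = AbbreviationLexicon(
        [
            AbbreviationRecord("SPH", "spherocytosis", 50),
            AbbreviationRecord("SPH", "secondary pulmonary hypertension", 1),
        ]
    )
    doc = _doc(
        "1",
        "Patient with secondary pulmonary hypertension (SPH) worsened. "
        "SPH persisted.",
    )
    offset = doc.text.index("SPH persisted")
    assert (
        resolve("SPH", doc, lex, before_offset=offset)
        == "secondary pulmonary hypertension"
    )
    # with no document context the high-frequency sense wins
    assert resolve("SPH", None, lex) == "spherocytosis"


def test_frequency_tie_breaks_lexicographically():
    lex = AbbreviationLexicon(
        [
            AbbreviationRecord("AA", "beta form", 2),
            AbbreviationRecord("AA", "alpha form", 2),
        ]
    )
    assert resolve("AA", None, lex) == "alpha form"


def test_lexicon_tsv_round_trip(tmp_path):
    lex = AbbreviationLexicon(
        [
            AbbreviationRecord("MI", "myocardial infarction", 5),
            AbbreviationRecord("GI", "gastrointestinal", 2),
        ]
    )
    path = str(tmp_path / "lex.tsv")
    write_lexicon_tsv(lex, path)
    loaded = read_lexicon_tsv(path)
    assert [(r.short_form, r.long_form, r.frequency) for r in loaded] == [
        (r.short_form, r.long_form, r.frequency) for r in lex
    ]


def test_negative_frequency_rejected():
    with pytest.raises(ValueError):
        AbbreviationRecord("X", "y", -1)
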