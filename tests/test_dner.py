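import io

import pytest

from dislex.corpus_io import Document, Mention
from dislex.dner import DiseaseTagger, TaggerConfig, post_process, train
from dislex.evaluation import evaluate_mentions
from dislex.features import FeatureConfig, Gazetteer
from dislex.synth import FixtureSpec, generate_corpus, generate_dictionary


def _mention(doc: Document, surface: str, occurrence: int = 0) -> Mention:
    start = -1
    for _ in range(occurrence + 1):
        start = doc.text.index(surface, start + 1)
    return Mention(start, start + len(surface), surface)


def test_post_process_propagates_exact_repeats():
    doc = Document(
        "1",
        "plasticity study",
        "We measured plasticity twice. Once more, plasticity changed.",
    )
    recognized = [_mention(doc, "plasticity", occurrence=1)]
    out = post_process(doc, recognized)
    # one recognized occurrence, three occurrences in total -> two added
    assert len(out) == 3
    assert {m.text for m in out} == {"plasticity"}
    assert [m.start for m in out] == sorted(m.start for m in out)


def test_post_process_no_repeats_is_identity():
    doc = Document("1", "title here", "unique mention of nephritis only.")
    recognized = [_mention(doc, "nephritis")]
    assert post_process(doc, recognized) == sorted(
        recognized, key=lambda m: m.start
    )


def test_post_process_suppresses_overlapping_additions():
    doc = Document(
        "1",
        "t",
        "severe kidney disease progressed. kidney disease and kidney issues.",
    )
    long_m = _mention(doc, "severe kidney disease")
    short_m = _mention(doc, "kidney disease", occurrence=1)
    out = post_process(doc, [long_m, short_m])
    # "kidney disease" inside "severe kidney disease" must not be re-added;
    # "kidney" alone was never recognized so "kidney issues" is untouched
    assert long_m in out and short_m in out
    assert len(out) == 2


def test_post_process_respects_word_boundaries():
    doc = Document("1", "t", "MI was observed. MIld cases were excluded.")
    out = post_process(doc, [_mention(doc, "MI")])
    assert len(out) == 1  # no match inside "MIld"


def test_post_process_idempotent_and_monotone(corpus):
    for doc in corpus[:5]:
        # start from a depleted prediction: drop every second gold mention
        partial = doc.mentions[::2]
        once = post_process(doc, partial)
        twice = post_process(doc, once)
        assert once == twice
        assert set(partial) <= set(once)
        for a, b in zip(once, once[1:]):
            assert a.end <= b.start  # never overlapping
        # recall never decreases
        base = evaluate_mentions(
            [Document(doc.doc_id, doc.title, doc.abstract, partial)], [doc]
        )
        after = evaluate_mentions(
            [Document(doc.doc_id, doc.title, doc.abstract, once)], [doc]
        )
        assert after.recall >= base.recall


@pytest.fixture(scope="module")
def tiny_trained():
    spec = FixtureSpec(seed=3, n_docs=40)
    res = generate_dictionary(spec)
    docs = generate_corpus(spec, res)
    gaz = Gazetteer.from_dictionary(res.dictionary)
    config = TaggerConfig(
        features=FeatureConfig(), c2=1.0, max_iter=80, seed=3
    )
    tagger = train(docs[:30], config, gazetteer=gaz)
    return tagger, docs


def test_training_recovers_planted_mentions(tiny_trained):
    tagger, docs = tiny_trained
    held_out = docs[30:]
    pred = [
        Document(d.doc_id, d.title, d.abstract, tagger.predict(d))
        for d in held_out
    ]
    counts = evaluate_mentions(pred, held_out)
    assert counts.f_measure >= 0.9


def test_predictions_deterministic(tiny_trained):
    tagger, docs = tiny_trained
    assert tagger.predict(docs[0]) == tagger.predict(docs[0])


def test_predicted_mentions_carry_type_and_no_concept(tiny_trained):
    tagger, docs = tiny_trained
    for m in tagger.predict(docs[0]):
        assert m.entity_type == "Disease"
        assert m.concept_id == "-1"
        assert docs[0].text[m.start : m.end] == m.text


def test_zero_mention_corpus_predicts_all_outside():
    docs = [
        Document(f"d{i}", "A plain title", "Nothing clinical happens here at all.")
        for i in range(6)
    ]
    tagger = train(docs, TaggerConfig(max_iter=30))
    assert tagger.predict(docs[0]) == []


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        train([], TaggerConfig())


def test_model_serialization_round_trip(tiny_trained):
    tagger, docs = tiny_trained
    buf = io.StringIO()
    tagger.save(buf)
    buf.seek(0)
    loaded = DiseaseTagger.load(buf)
    assert loaded.predict(docs[0]) == tagger.predict(docs[0])
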