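"""Abbreviation detection and resolution.

``find_abbreviations`` implements the classic short-form-in-parentheses
extraction (Schwartz & Hearst): a candidate short form inside parentheses
is paired with the shortest preceding word span whose characters account
for every alphanumeric character of the short form, matched right to left,
with the short form's first character matching the first character of the
first word of the long form.

A lexicon of (short form, long form, frequency) records is built from any
corpus plus dictionary names containing parenthesized definitions.
``resolve`` expands a recognized short form using two rules, in order:
a long form already mentioned earlier in the document wins; otherwise the
long form most frequent at lexicon-build time wins (ties broken
lexicographically). A short form absent from the lexicon is returned
unchanged.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from dislex.corpus_io import Dictionary, Document, _open_text


@dataclass(frozen=True)
class AbbreviationRecord:
    short_form: str
    long_form: str
    frequency: int = 1

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be non-negative")


def _valid_short_form(sf: str) -> bool:
    # 2..10 chars, at least one letter, first char alphanumeric,
    # at most two words, not a pure number / comparison expression
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not sf[0].isalnum():
        return False
    return any(c.isalpha() for c in sf)


def _find_best_long_form(sf: str, candidate: str) -> str | None:
    """Shortest right-aligned span of ``candidate`` covering all of ``sf``.

    Characters of the short form are matched right to left inside the
    candidate; the first character of the short form must match at the
    start of a word.
    """
    s_idx = len(sf) - 1
    l_idx = len(candidate) - 1
    while s_idx >= 0:
        c = sf[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (
            candidate[l_idx].lower() != c
            or (s_idx == 0 and l_idx > 0 and candidate[l_idx - 1].isalnum())
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        s_idx -= 1
        l_idx -= 1
    # expand left to the start of the word containing position l_idx+1
    start = l_idx + 1
    long_form = candidate[start:].strip()
    return long_form or None


_PAREN_RE = re.compile(r"\(([^()]{1,60})\)")


def find_abbreviations(
    text: str,
) -> list[tuple[str, str, tuple[int, int], tuple[int, int]]]:
    """(short form, long form, sf span, lf span) for each definition in text.

    Nested parentheses are processed innermost-first (the regex matches only
    parenthesis-free contents, so inner groups are found on the first pass).
    Candidates failing the letter-matching rule are skipped.
    """
    out = []
    for m in _PAREN_RE.finditer(text):
        sf = m.group(1).strip()
        if not _valid_short_form(sf):
            continue
        # long-form search window: preceding words in the same sentence
        window_start = max(
            text.rfind(". ", 0, m.start()) + 1,
            text.rfind("\n", 0, m.start()) + 1,
            0,
        )
        before = text[window_start : m.start()].rstrip()
        words = before.split()
        max_words = min(len(sf) + 5, len(sf) * 2)
        candidate_words = words[-max_words:] if words else []
        if not candidate_words:
            continue
        candidate = " ".join(candidate_words)
        lf = _find_best_long_form(sf, candidate)
        if lf is None or not lf:
            continue
        if len(lf.split()) > max_words:
            continue
        # long form must be longer than the short form and not contain it
        if len(lf) <= len(sf) or sf.lower() in (w.lower() for w in lf.split()):
            continue
        lf_start = text.rindex(lf, window_start, m.start())
        out.append((sf, lf, (m.start(1), m.end(1)), (lf_start, lf_start + len(lf))))
    return out


class AbbreviationLexicon:
    """Ordered collection of AbbreviationRecords with lookup by short form."""

    def __init__(self, records: Iterable[AbbreviationRecord] = ()) -> None:
        self.records: list[AbbreviationRecord] = list(records)
        self._by_sf: dict[str, list[AbbreviationRecord]] = {}
        for r in self.records:
            self._by_sf.setdefault(r.short_form, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def long_forms(self, short_form: str) -> list[AbbreviationRecord]:
        return list(self._by_sf.get(short_form, []))

    def short_forms(self) -> set[str]:
        return set(self._by_sf)


def build_lexicon(
    corpora: Iterable[Document], dictionary: Dictionary | None = None
) -> AbbreviationLexicon:
    """Union of (short, long) pairs detected in corpus texts and
    parenthesized dictionary names, with occurrence frequencies; ordered by
    frequency descending then lexicographically."""
    counts: Counter[tuple[str, str]] = Counter()
    for doc in corpora:
        for sf, lf, _, _ in find_abbreviations(doc.text):
            counts[(sf, lf)] += 1
    if dictionary is not None:
        for entry in dictionary:
            for sf, lf, _, _ in find_abbreviations(entry.name):
                counts[(sf, lf)] += 1
    records = [
        AbbreviationRecord(sf, lf, n)
        for (sf, lf), n in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
        )
    ]
    return AbbreviationLexicon(records)


def resolve(
    short_form: str,
    document: Document | None,
    lexicon: AbbreviationLexicon,
    before_offset: int | None = None,
) -> str:
    """Expand a short form to a long form, or return it unchanged.

    One lexicon long form: use it. Several: prefer one mentioned earlier in
    the document (case-insensitive search over the text preceding
    ``before_offset``, or the whole text when no offset is given); otherwise
    the most frequent (ties lexicographic). Unknown short form: unchanged.
    """
    cands = lexicon.long_forms(short_form)
    if not cands:
        return short_form
    if len(cands) == 1:
        return cands[0].long_form
    if document is not None:
        hay = document.text
        if before_offset is not None:
            hay = hay[:before_offset]
        hay = hay.lower()
        in_doc = [
            (hay.index(r.long_form.lower()), r.long_form)
            for r in cands
            if r.long_form.lower() in hay
        ]
        if in_doc:
            return min(in_doc)[1]  # earliest occurrence wins
    # highest build-time frequency; ties broken lexicographically
    best = sorted(cands, key=lambda r: (-r.frequency, r.long_form))[0]
    return best.long_form


def read_lexicon_tsv(stream) -> AbbreviationLexicon:
    handle, owned = _open_text(stream)
    try:
        records = []
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sf, lf, freq = line.split("\t")
            records.append(AbbreviationRecord(sf, lf, int(freq)))
        return AbbreviationLexicon(records)
    finally:
        if owned:
            handle.close()


def write_lexicon_tsv(lexicon: AbbreviationLexicon, stream) -> None:
    handle, owned = _open_text(stream, "wt")
    try:
        for r in lexicon:
            handle.write(f"{r.short_form}\t{r.long_form}\t{r.frequency}\n")
    finally:
        if owned:
            handle.close()
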