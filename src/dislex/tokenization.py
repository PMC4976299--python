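"""Deterministic regex tokenization and lightweight linguistic annotators.

The tokenizer is pluggable throughout the package; the default splits on
whitespace and peels punctuation into separate tokens, keeping hyphenated
and slash-joined words (``AMI/GI``) as single tokens — internal punctuation
is informative for disease names and is instead surfaced through word-shape
features. POS tags and lemmas come from injected annotators; the defaults
are rule-based (suffix heuristics) so the pipeline runs with no model
downloads and identical output on every platform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable

# word = letters/digits possibly joined by internal - / ' ; else single char
_TOKEN_RE = re.compile(r"[A-Za-z0-9Ͱ-Ͽ]+(?:['\-/][A-Za-z0-9Ͱ-Ͽ]+)*|\S")

_SENT_BOUND_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(])|\n")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split text into tokens with character offsets."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences (split at .!? + space + capital, and \\n)."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUND_RE.finditer(text):
        if m.start() > start:
            spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def sentences(text: str) -> list[list[Token]]:
    """Tokenize text sentence by sentence, offsets global to the text."""
    out = []
    for s, e in sentence_spans(text):
        toks = [
            Token(t.text, t.start + s, t.end + s) for t in tokenize(text[s:e])
        ]
        if toks:
            out.append(toks)
    return out


# --- rule-based fallback annotators -------------------------------------

_NOUN_SUFFIXES = (
    "tion", "sion", "ness", "ment", "itis", "osis", "emia", "oma",
    "pathy", "ism", "ity", "ase", "gen", "ia",
)
_ADJ_SUFFIXES = ("ous", "ive", "al", "ic", "able", "ible", "ar", "ary", "ile")
_VERB_SUFFIXES = ("ing", "ed", "ize", "ise", "ate")
_ADV_SUFFIXES = ("ly",)


def suffix_pos(token: str) -> str:
    """Deterministic suffix-based POS guess (coarse Penn-style tags)."""
    if not token:
        return "none"
    if re.fullmatch(r"\d+(\.\d+)?", token):
        return "CD"
    if not token[0].isalnum():
        return "PUNCT"
    low = token.lower()
    if low.endswith(_ADV_SUFFIXES) and len(low) > 3:
        return "RB"
    if low.endswith(_VERB_SUFFIXES) and len(low) > 4:
        return "VB"
    if low.endswith(_ADJ_SUFFIXES) and len(low) > 4:
        return "JJ"
    if low.endswith(_NOUN_SUFFIXES):
        return "NN"
    if token[0].isupper():
        return "NNP"
    return "NN"


def suffix_lemma(token: str) -> str:
    """Deterministic suffix-stripping lemmatizer (plural/verbal endings)."""
    low = token.lower()
    for suf, repl in (("sses", "ss"), ("ies", "y"), ("ches", "ch"), ("shes", "sh")):
        if low.endswith(suf) and len(low) > len(suf) + 1:
            return low[: -len(suf)] + repl
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
        return low[:-1]
    return low


Annotator = Callable[[Iterable[str]], list[str]]


def default_pos_annotator(tokens: Iterable[str]) -> list[str]:
    return [suffix_pos(t) for t in tokens]


def default_lemma_annotator(tokens: Iterable[str]) -> list[str]:
    return [suffix_lemma(t) for t in tokens]
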