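"""Per-token feature extraction for the CRF tagger.

Five feature families, each namespaced in the feature name:

* ``w:``     word identity and POS of the previous/current/next token
* ``morph:`` lemma and 2–5 character prefixes/suffixes of prev/cur/next
* ``shape:`` word shape (X/x/d/g classes) of prev/cur/next
* ``gaz:``   membership of the token in a BIESO-tagged gazetteer built from
             dictionary names (match presence with its BIESO tag, and the
             token length of the matched entry; the longest entry wins)
* ``conj:``  conjunctions — current word x previous word, and current shape
             x current POS

Out-of-sequence context slots take the sentinel value ``none``, as does an
empty word shape. Extraction is a pure function of (tokens, gazetteer,
annotator outputs), so a fixed input always yields the same feature maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from dislex.corpus_io import Dictionary
from dislex.tokenization import (
    Annotator,
    Token,
    default_lemma_annotator,
    default_pos_annotator,
    tokenize,
)

logger = logging.getLogger(__name__)

NONE = "none"

_GREEK_NAMES = {
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
}


def _is_greek_char(ch: str) -> bool:
    return "Ͱ" <= ch <= "Ͽ" or "ἀ" <= ch <= "῿"


def word_shape(token: str) -> str:
    """Map a token to its orthographic shape string.

    Uppercase letters become ``X``, lowercase ``x``, digits ``d``, Greek
    letters ``g``; every other character is preserved. Tokens that are
    spelled-out Greek letter names ("alpha" ... "omega") map to a single
    ``g``. An empty token yields the sentinel ``none``.
    """
    if not token:
        return NONE
    if token.lower() in _GREEK_NAMES:
        return "g"
    out = []
    for ch in token:
        if _is_greek_char(ch):
            out.append("g")
        elif ch.isdigit():
            out.append("d")
        elif ch.isalpha() and ch.isupper():
            out.append("X")
        elif ch.isalpha() and ch.islower():
            out.append("x")
        else:
            out.append(ch)
    return "".join(out)


def affix_features(token: str, min_len: int = 2, max_len: int = 5) -> set[str]:
    """Prefixes and suffixes of length ``min_len``..``min(max_len, len-1)``.

    The cap at ``len(token) - 1`` keeps the whole token from being its own
    affix (that is already the word-identity feature). Tokens of length
    <= ``min_len`` yield the empty set.
    """
    n = len(token)
    out: set[str] = set()
    for k in range(min_len, min(max_len, n - 1) + 1):
        out.add("p=" + token[:k])
        out.add("s=" + token[-k:])
    return out


class Gazetteer:
    """Dictionary names tokenized and BIESO-tagged for token lookup.

    Each name contributes (BIESO tag, entry length in tokens) for each of
    its tokens; lookups are case-insensitive. When a token occurs in several
    entries, the tag from the longest entry wins (ties broken toward the
    more specific boundary tag order B,E,I,S to keep the choice
    deterministic).
    """

    def __init__(self, names: Iterable[str] = ()) -> None:
        self._best: dict[str, tuple[int, str]] = {}
        for name in names:
            self.add(name)

    @classmethod
    def from_dictionary(cls, dictionary: Dictionary) -> "Gazetteer":
        return cls(dictionary.names())

    _TAG_ORDER = {"B": 0, "E": 1, "I": 2, "S": 3}

    def add(self, name: str) -> None:
        toks = [t.text.lower() for t in tokenize(name)]
        if not toks:
            return
        n = len(toks)
        if n == 1:
            tags = ["S"]
        else:
            tags = ["B"] + ["I"] * (n - 2) + ["E"]
        for tok, tag in zip(toks, tags):
            cur = self._best.get(tok)
            cand = (n, tag)
            if (
                cur is None
                or cand[0] > cur[0]
                or (cand[0] == cur[0] and self._TAG_ORDER[tag] < self._TAG_ORDER[cur[1]])
            ):
                self._best[tok] = cand

    def lookup(self, token: str) -> tuple[str, int] | None:
        """(BIESO tag, matched entry length) for a token, or None."""
        hit = self._best.get(token.lower())
        if hit is None:
            return None
        length, tag = hit
        return tag, length


def gazetteer_features(
    tokens: Sequence[Token] | Sequence[str], gazetteer: Gazetteer | None
) -> list[set[str]]:
    """Per-token ``gaz:`` features: match presence (with tag) and length."""
    out: list[set[str]] = []
    for tok in tokens:
        text = tok.text if isinstance(tok, Token) else tok
        feats: set[str] = set()
        if gazetteer is not None:
            hit = gazetteer.lookup(text)
            if hit is not None:
                tag, length = hit
                feats.add(f"gaz:match={tag}")
                feats.add(f"gaz:len={length}")
        out.append(feats)
    return out


@dataclass
class FeatureConfig:
    """Feature template: which families are active and their knobs."""

    use_word: bool = True
    use_gazetteer: bool = True
    use_morph: bool = True
    use_shape: bool = True
    use_conjunctions: bool = True
    affix_min: int = 2
    affix_max: int = 5
    prune_threshold: float = 0.05

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


@dataclass
class FeatureExtractor:
    """Callable producing one feature set per token of a sentence."""

    config: FeatureConfig = field(default_factory=FeatureConfig)
    gazetteer: Gazetteer | None = None
    pos_annotator: Annotator = default_pos_annotator
    lemma_annotator: Annotator = default_lemma_annotator

    def __call__(self, tokens: Sequence[Token]) -> list[set[str]]:
        return self.extract(tokens)

    def _annotate(self, annotator: Annotator, texts: list[str], what: str) -> list[str]:
        try:
            out = annotator(texts)
            if len(out) != len(texts):
                raise ValueError(f"{what} annotator returned wrong length")
            return out
        except Exception:  # annotator failure drops the family, never crashes
            logger.warning("%s annotator failed; family omitted", what, exc_info=True)
            return [NONE] * len(texts)

    def extract(self, tokens: Sequence[Token]) -> list[set[str]]:
        cfg = self.config
        texts = [t.text for t in tokens]
        n = len(texts)
        pos = self._annotate(self.pos_annotator, texts, "POS") if cfg.use_word else [NONE] * n
        lemma = (
            self._annotate(self.lemma_annotator, texts, "lemma")
            if cfg.use_morph
            else [NONE] * n
        )
        shapes = [word_shape(t) or NONE for t in texts] if cfg.use_shape else [NONE] * n
        gaz = gazetteer_features(tokens, self.gazetteer if cfg.use_gazetteer else None)

        def ctx(seq: list[str], i: int) -> str:
            return seq[i] if 0 <= i < n else NONE

        maps: list[set[str]] = []
        for i in range(n):
            feats: set[str] = set()
            if cfg.use_word:
                for off, slot in ((-1, "prev"), (0, "cur"), (1, "next")):
                    feats.add(f"w:{slot}={ctx(texts, i + off)}")
                    feats.add(f"w:pos_{slot}={ctx(pos, i + off)}")
            if cfg.use_morph:
                for off, slot in ((-1, "prev"), (0, "cur"), (1, "next")):
                    feats.add(f"morph:lemma_{slot}={ctx(lemma, i + off)}")
                    j = i + off
                    affs = (
                        affix_features(texts[j], cfg.affix_min, cfg.affix_max)
                        if 0 <= j < n
                        else set()
                    )
                    for a in affs:
                        feats.add(f"morph:{slot}_{a}")
            if cfg.use_shape:
                for off, slot in ((-1, "prev"), (0, "cur"), (1, "next")):
                    feats.add(f"shape:{slot}={ctx(shapes, i + off)}")
            feats |= gaz[i]
            if cfg.use_conjunctions:
                feats.add(f"conj:w={ctx(texts, i)}&prev_w={ctx(texts, i - 1)}")
                feats.add(f"conj:shape={ctx(shapes, i)}&pos={ctx(pos, i)}")
            maps.append(feats)
        return maps


def prune_features(
    weighted_features: dict[str, float], threshold: float = 0.05
) -> set[str]:
    """Names of features whose |weight| meets the threshold.

    Dropping near-zero weights removes noisy features from the trained
    model; 0.05 is the default cut.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    kept = {name for name, w in weighted_features.items() if abs(w) >= threshold}
    if weighted_features and not kept:
        logger.warning("all %d features pruned", len(weighted_features))
    return kept
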