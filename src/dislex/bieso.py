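"""BIESO span <-> label-sequence codec for sequence labeling.

BIESO marks each token of a mention as Begin, Inside or End (multi-token
mentions become ``B I* E``), Single for one-token mentions, and Outside
elsewhere. The finer-grained boundary labels give the tagger explicit
start/end evidence, which is why the scheme tends to beat plain BIO.

Decoding repairs ill-formed tagger output instead of raising: any maximal
run of non-O labels is treated as one mention (an I or E without a B starts
a mention; a B or I without an E ends at the run boundary). The repair
maximizes recall and matches common practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from dislex.tokenization import Token

logger = logging.getLogger(__name__)

#: The fixed label alphabet.
BIESO_LABELS = ("B", "I", "E", "S", "O")


@dataclass(frozen=True)
class TaggedToken:
    text: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in BIESO_LABELS:
            raise ValueError(f"label {self.label!r} not in {BIESO_LABELS}")


class AlignmentError(ValueError):
    """A mention span does not align to token boundaries."""


def snap_to_tokens(
    span: tuple[int, int], tokens: Sequence[Token]
) -> tuple[int, int] | None:
    """Smallest token-aligned span covering ``span``; None if no overlap."""
    start, end = span
    covering = [t for t in tokens if t.end > start and t.start < end]
    if not covering:
        return None
    return covering[0].start, covering[-1].end


def encode_bieso(
    tokens: Sequence[Token],
    mention_spans: Sequence[tuple[int, int]],
    snap: bool = False,
) -> list[str]:
    """Label each token B/I/E/S/O for the given character spans.

    Spans must align to token boundaries unless ``snap`` is set, in which
    case misaligned spans are snapped outward to the smallest covering token
    span (counted via a logged warning).
    """
    labels = ["O"] * len(tokens)
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i for i, t in enumerate(tokens)}
    n_snapped = 0
    for span in sorted(mention_spans):
        start, end = span
        if start not in starts or end not in ends:
            if not snap:
                raise AlignmentError(
                    f"mention span {span} does not align to token boundaries"
                )
            snapped = snap_to_tokens(span, tokens)
            if snapped is None:
                logger.warning("span %s overlaps no token; dropped", (span,))
                continue
            start, end = snapped
            n_snapped += 1
        i, j = starts[start], ends[end]
        if i == j:
            labels[i] = "S"
        else:
            labels[i] = "B"
            for k in range(i + 1, j):
                labels[k] = "I"
            labels[j] = "E"
    if n_snapped:
        logger.warning("snapped %d misaligned mention span(s) outward", n_snapped)
    return labels


def decode_bieso(tagged: Sequence[TaggedToken]) -> list[tuple[int, int]]:
    """Character spans of mentions in a (possibly ill-formed) label sequence.

    Well-formed runs (``S``, ``B I* E``) decode exactly, so decode after
    encode is the identity on aligned mentions. Ill-formed runs are repaired:
    each maximal run of consecutive non-O tokens yields one span.
    """
    spans: list[tuple[int, int]] = []
    run_start: int | None = None  # index of first token in current mention
    prev_label = "O"
    for i, tok in enumerate(tagged):
        lab = tok.label
        boundary = lab in ("B", "S") and prev_label in ("E", "S")
        if lab == "O" or boundary:
            if run_start is not None:
                spans.append((tagged[run_start].start, tagged[i - 1].end))
                run_start = None
        if lab != "O" and run_start is None:
            run_start = i
        if lab in ("E", "S"):
            # a well-formed mention closes here
            spans.append((tagged[run_start].start, tok.end))
            run_start = None
        prev_label = lab
    if run_start is not None:
        spans.append((tagged[run_start].start, tagged[-1].end))
    return spans


def tag_tokens(tokens: Sequence[Token], labels: Sequence[str]) -> list[TaggedToken]:
    if len(tokens) != len(labels):
        raise ValueError("tokens and labels differ in length")
    return [TaggedToken(t.text, t.start, t.end, l) for t, l in zip(tokens, labels)]
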