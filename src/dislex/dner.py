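"""Disease named entity recognition: CRF training, tagging, post-processing.

A document's title and abstract are split into sentences, tokenized, and
labeled with BIESO tags by a first-order linear-chain CRF (Viterbi
decoding). Decoded label runs become Disease mention spans with the concept
ID left unset ("-1").

Post-processing then propagates recognition document-wide: every exact,
case-sensitive, word-boundary occurrence of an already-recognized surface
string becomes a mention too (in both the title and the abstract), unless
it would overlap an existing mention. The CRF labels from local context
only, so the same string can be tagged in one sentence and missed in
another; propagation recovers those misses (raising recall, at the price of
also propagating any false positive).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Sequence

from dislex.bieso import BIESO_LABELS, decode_bieso, encode_bieso, tag_tokens
from dislex.corpus_io import Document, Mention
from dislex.crf import CrfModel, train_crf
from dislex.features import FeatureConfig, FeatureExtractor, Gazetteer
from dislex.tokenization import sentences

logger = logging.getLogger(__name__)


@dataclass
class TaggerConfig:
    """Training configuration for the disease tagger."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    c2: float = 1.0
    max_iter: int = 120
    seed: int = 0  # recorded in metadata; training itself is deterministic


@dataclass
class DiseaseTagger:
    """A trained disease mention tagger (CRF + feature template)."""

    crf: CrfModel
    extractor: FeatureExtractor

    def predict(self, document: Document) -> list[Mention]:
        """Tag a document; returns un-normalized Disease mentions."""
        out: list[Mention] = []
        text = document.text
        for sent in sentences(text):
            feats = self.extractor(sent)
            labels = self.crf.decode(feats)
            for start, end in decode_bieso(tag_tokens(sent, labels)):
                out.append(Mention(start, end, text[start:end], "Disease", "-1"))
        return sorted(out, key=lambda m: (m.start, m.end))

    def save(self, stream: IO[str]) -> None:
        """Serialize model weights plus the feature template to one file."""
        payload = {
            "format": "dislex-tagger",
            "version": 1,
            "feature_config": self.extractor.config.to_dict(),
            "gazetteer": sorted(
                # persist the raw token->(len, tag) table
                (tok, n, tag)
                for tok, (n, tag) in (self.extractor.gazetteer._best.items()
                                      if self.extractor.gazetteer else ())
            ),
        }
        stream.write(json.dumps(payload))
        stream.write("\n")
        self.crf.to_json(stream)

    @classmethod
    def load(cls, stream: IO[str]) -> "DiseaseTagger":
        header = json.loads(stream.readline())
        if header.get("format") != "dislex-tagger":
            raise ValueError("not a dislex tagger file")
        crf = CrfModel.from_json(stream)
        gaz = None
        if header.get("gazetteer"):
            gaz = Gazetteer()
            for tok, n, tag in header["gazetteer"]:
                gaz._best[tok] = (n, tag)
        extractor = FeatureExtractor(
            config=FeatureConfig.from_dict(header["feature_config"]), gazetteer=gaz
        )
        return cls(crf=crf, extractor=extractor)


def train(
    documents: Sequence[Document],
    config: TaggerConfig | None = None,
    gazetteer: Gazetteer | None = None,
) -> DiseaseTagger:
    """Train the disease tagger on gold-annotated documents.

    Gold mention spans are BIESO-encoded per sentence (misaligned spans are
    snapped outward to token boundaries); the CRF is fit by L-BFGS and then
    pruned at the configured weight threshold.
    """
    if not documents:
        raise ValueError("training corpus is empty")
    config = config or TaggerConfig()
    extractor = FeatureExtractor(config=config.features, gazetteer=gazetteer)
    X: list[list[set[str]]] = []
    y: list[list[str]] = []
    for doc in documents:
        spans = [(m.start, m.end) for m in doc.mentions]
        for sent in sentences(doc.text):
            s0, s1 = sent[0].start, sent[-1].end
            local = [(a, b) for a, b in spans if a >= s0 and b <= s1]
            X.append(extractor(sent))
            y.append(encode_bieso(sent, local, snap=True))
    crf = train_crf(X, y, BIESO_LABELS, c2=config.c2, max_iter=config.max_iter)
    crf.meta["seed"] = config.seed
    n = crf.prune(config.features.prune_threshold)
    logger.info("pruned %d low-weight features", n)
    return DiseaseTagger(crf=crf, extractor=extractor)


def _word_boundary_occurrences(text: str, surface: str) -> list[tuple[int, int]]:
    pat = re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(surface) + r"(?![A-Za-z0-9])"
    )
    return [(m.start(), m.end()) for m in pat.finditer(text)]


def post_process(document: Document, mentions: Sequence[Mention]) -> list[Mention]:
    """Propagate recognized surface strings to their other exact occurrences.

    For every distinct recognized surface form, each other case-sensitive
    occurrence in the document (at word boundaries) that does not overlap an
    existing or already-added mention becomes a new mention with the same
    entity type. Idempotent; never removes a mention; output sorted.
    """
    text = document.text
    existing = sorted(mentions, key=lambda m: (m.start, m.end))
    occupied = [(m.start, m.end) for m in existing]

    def overlaps(a: int, b: int) -> bool:
        return any(a < e and s < b for s, e in occupied)

    added: list[Mention] = []
    # longer surfaces first so a short repeat never blocks a longer one
    surfaces: dict[str, str] = {}
    for m in existing:
        surfaces.setdefault(m.text, m.entity_type)
    for surface in sorted(surfaces, key=lambda s: (-len(s), s)):
        for a, b in _word_boundary_occurrences(text, surface):
            if not overlaps(a, b):
                added.append(Mention(a, b, surface, surfaces[surface], "-1"))
                occupied.append((a, b))
    return sorted([*existing, *added], key=lambda m: (m.start, m.end))
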