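"""Seeded synthetic dictionaries and corpora for end-to-end testing.

The generator emulates the structure of a PubMed-abstract disease corpus
paired with a MEDIC-style vocabulary: abstracts assembled from template
sentences with disease mentions planted at known offsets, parenthesized
abbreviation definitions ("myocardial infarction (MI)"), repeated surface
forms, and distractor clinical-noise sentences. Planted mentions fall into
five categories — matchable via a primary name, via a synonym only, via
query expansion only (the dictionary holds "<base> syndrome" while the text
says "<base>"), via abbreviation resolution, or not at all (gold concept ID
"-1"). Gold normalization IDs are assigned at plant time, so evaluation
oracles are exact.

Three concepts from the worked examples are always embedded: D007674
(Kidney Diseases, with the external synonyms "renal disorder" and
"nephropathy" in the synonym source), D054038 (Posterior Leukoencephalopathy
Syndrome, synonym "posterior reversible encephalopathy syndrome") and
D009203 (Myocardial Infarction, with MI in the abbreviation lexicon).

All randomness flows from the FixtureSpec seed through ``random.Random`` using
integer draws only, so a fixed seed yields byte-identical output on every
platform. It is synthetic data: real abstracts have richer syntax, nested
and discontinuous mentions, and genuinely ambiguous vocabulary entries.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from dislex.abbreviation import AbbreviationLexicon, AbbreviationRecord
from dislex.corpus_io import Dictionary, Document, Mention

MODIFIERS = [
    "chronic", "acute", "familial", "congenital", "idiopathic",
    "recurrent", "juvenile", "systemic", "progressive", "diffuse",
]
ORGANS = [
    "renal", "hepatic", "cardiac", "pulmonary", "gastric",
    "neural", "dermal", "ocular", "splenic", "lymphoid",
]
HEADS = [
    "fibrosis", "necrosis", "carcinoma", "dystrophy", "sclerosis",
    "stenosis", "atrophy", "edema", "neoplasia", "myopathy",
]
# synonym vocabulary kept disjoint from primary-name vocabulary
SYN_MODIFIERS = ["persistent", "severe", "latent", "focal", "bilateral"]
SYN_HEADS = ["degeneration", "lesion", "malformation", "hypertrophy", "insufficiency"]

# pseudo-disease stems for unmatchable mentions (never added to a dictionary)
FAKE_STEMS = ["borv", "clam", "drex", "felm", "gorn", "helv", "jarn", "krel",
              "morv", "plex", "quil", "stol", "trev", "vuln", "welt", "zarn"]
FAKE_SUFFIXES = ["itis", "oma", "osis", "algia"]

DISTRACTOR_SENTENCES = [
    "The cohort completed a baseline survey during the enrolment period.",
    "Study coordinators collected demographic details at every visit.",
    "Participants returned questionnaires by mail within two weeks.",
    "The protocol was approved by the institutional review board.",
    "Follow up interviews were scheduled at regular monthly intervals.",
    "Laboratory samples were processed at a central facility overnight.",
    "Statistical summaries were prepared by an independent analyst.",
    "Funding sources had no role in the interpretation of findings.",
]

MENTION_TEMPLATES = [
    "Patients were diagnosed with {m} after hospital admission.",
    "We observed {m} in several of the enrolled participants.",
    "Treatment markedly reduced the severity of {m} over time.",
    "The reported incidence of {m} increased steadily with age.",
    "Clinicians documented {m} during the initial examination.",
]
ABBREV_TEMPLATE = "Patients were diagnosed with {long} ({sf}) after hospital admission."
ABBREV_FOLLOWUP = "Recovery from {sf} required extended supervision."
REPEAT_TEMPLATE = "The presence of {m} was confirmed by an independent reviewer."

CATEGORIES = ("primary", "synonym", "expansion", "abbreviation", "unmatchable")


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a synthetic study.

    ``fractions`` gives the mix of planted-mention categories (primary-name
    match, synonym-only, expansion-only, abbreviation, unmatchable) and must
    sum to 1. ``repetition_rate`` is the probability that a document repeats
    one of its mention surfaces in an extra sentence.
    """

    seed: int = 0
    n_docs: int = 250
    dictionary_size: int = 40
    fractions: tuple[float, float, float, float, float] = (
        0.35, 0.20, 0.15, 0.15, 0.15,
    )
    repetition_rate: float = 0.3
    mentions_per_doc: int = 3

    def __post_init__(self) -> None:
        if self.n_docs < 0 or self.dictionary_size < 0:
            raise ValueError("n_docs and dictionary_size must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0.0 <= self.repetition_rate <= 1.0:
            raise ValueError("repetition_rate must lie in [0, 1]")


@dataclass(frozen=True)
class Plant:
    """A plantable mention: surface string, gold concept ID, category."""

    surface: str
    concept_id: str
    category: str
    long_form: str | None = None  # abbreviation category: the defining form


@dataclass
class FixtureResources:
    """Everything generate_corpus needs: vocabulary plus plant inventories."""

    dictionary: Dictionary
    synonym_source: dict[str, list[str]]
    lexicon: AbbreviationLexicon
    plants: dict[str, list[Plant]] = field(default_factory=dict)


def _sf_for(name: str) -> str:
    return "".join(w[0] for w in name.split()).upper()


def generate_dictionary(spec: FixtureSpec) -> FixtureResources:
    """Build a toy disease vocabulary, synonym source and abbreviation
    lexicon with all five mention categories exercisable."""
    rng = random.Random(spec.seed)
    dictionary = Dictionary()
    synonym_source: dict[str, list[str]] = {}
    abbrev_records: list[AbbreviationRecord] = []
    plants: dict[str, list[Plant]] = {c: [] for c in CATEGORIES}

    # --- embedded worked concepts ---------------------------------------
    dictionary.add("D007674", "Kidney Diseases", "primary")
    dictionary.add("D007674", "Kidney Disease", "synonym")
    dictionary.add("D007674", "Disease, Kidney", "synonym")
    dictionary.add("D007674", "Renal Disease", "synonym")
    synonym_source["Kidney Diseases"] = ["renal disorder", "nephropathy"]
    plants["synonym"].append(Plant("Kidney Disease", "D007674", "synonym"))

    dictionary.add("D054038", "Posterior Leukoencephalopathy Syndrome", "primary")
    dictionary.add(
        "D054038", "posterior reversible encephalopathy syndrome", "synonym"
    )
    plants["expansion"].append(
        Plant("posterior reversible encephalopathy", "D054038", "expansion")
    )

    dictionary.add("D009203", "Myocardial Infarction", "primary")
    abbrev_records.append(AbbreviationRecord("MI", "myocardial infarction", 5))
    plants["abbreviation"].append(
        Plant("MI", "D009203", "abbreviation", long_form="myocardial infarction")
    )

    # --- toy concepts ----------------------------------------------------
    used_names = {tuple(n.lower().split()) for n in dictionary.names()}

    def fresh_name(parts_fn) -> str:
        for _ in range(1000):
            name = parts_fn()
            if tuple(name.split()) not in used_names:
                used_names.add(tuple(name.split()))
                return name
        raise ValueError("could not generate a fresh name; spec too large")

    head_terms = ["disorder", "syndrome", "injury", "infection", "abnormality"]
    for k in range(spec.dictionary_size):
        cid = f"D9{k:05d}"
        kind = CATEGORIES[k % 4]  # rotate primary/synonym/expansion/abbreviation
        if kind == "primary":
            name = fresh_name(
                lambda: f"{rng.choice(MODIFIERS)} {rng.choice(ORGANS)} {rng.choice(HEADS)}"
            )
            dictionary.add(cid, name, "primary")
            plants["primary"].append(Plant(name, cid, "primary"))
        elif kind == "synonym":
            name = fresh_name(
                lambda: f"{rng.choice(MODIFIERS)} {rng.choice(ORGANS)} {rng.choice(HEADS)}"
            )
            syn = fresh_name(
                lambda: f"{rng.choice(SYN_MODIFIERS)} {rng.choice(ORGANS)} {rng.choice(SYN_HEADS)}"
            )
            dictionary.add(cid, name, "primary")
            dictionary.add(cid, syn, "synonym")
            plants["synonym"].append(Plant(syn, cid, "synonym"))
        elif kind == "expansion":
            base = fresh_name(
                lambda: f"{rng.choice(SYN_MODIFIERS)} {rng.choice(ORGANS)} {rng.choice(SYN_HEADS)}"
            )
            head = head_terms[rng.randrange(len(head_terms))]
            full = f"{base} {head}"
            used_names.add(tuple(full.split()))
            dictionary.add(cid, full, "primary")
            plants["expansion"].append(Plant(base, cid, "expansion"))
        else:  # abbreviation
            name = fresh_name(
                lambda: f"{rng.choice(MODIFIERS)} {rng.choice(ORGANS)} {rng.choice(HEADS)}"
            )
            dictionary.add(cid, name, "primary")
            sf = _sf_for(name)
            abbrev_records.append(AbbreviationRecord(sf, name, rng.randrange(1, 6)))
            plants["abbreviation"].append(
                Plant(sf, cid, "abbreviation", long_form=name)
            )

    # unmatchable pseudo-diseases (never in the dictionary)
    for stem in FAKE_STEMS:
        for suf in FAKE_SUFFIXES:
            plants["unmatchable"].append(Plant(stem + suf, "-1", "unmatchable"))

    lexicon = AbbreviationLexicon(
        sorted(abbrev_records, key=lambda r: (-r.frequency, r.short_form, r.long_form))
    )
    return FixtureResources(dictionary, synonym_source, lexicon, plants)


def _pick_category(rng: random.Random, spec: FixtureSpec) -> str:
    cum, draw = 0, rng.randrange(10_000)
    for cat, frac in zip(CATEGORIES, spec.fractions):
        cum += round(frac * 10_000)
        if draw < cum:
            return cat
    return CATEGORIES[-1]


def generate_corpus(
    spec: FixtureSpec, resources: FixtureResources
) -> list[Document]:
    """Assemble documents with gold mention spans and gold concept IDs."""
    rng = random.Random(spec.seed + 1)
    docs: list[Document] = []
    for d in range(spec.n_docs):
        chosen: list[Plant] = []
        for _ in range(spec.mentions_per_doc):
            cat = _pick_category(rng, spec)
            pool = resources.plants[cat]
            if not pool:
                continue
            chosen.append(pool[rng.randrange(len(pool))])
        # drop duplicate surfaces within a doc (repetition is added explicitly)
        seen: set[str] = set()
        chosen = [p for p in chosen if not (p.surface in seen or seen.add(p.surface))]

        mentions: list[Mention] = []
        lead = chosen[0] if chosen else None
        lead_surface = lead.long_form or lead.surface if lead else "routine care"
        title = f"Clinical outcomes of {lead_surface} in a hospital cohort"
        if lead is not None:
            start = title.index(lead_surface)
            mentions.append(
                Mention(start, start + len(lead_surface), lead_surface,
                        "Disease", lead.concept_id)
            )

        parts: list[str] = []
        offset = len(title) + 1  # "\n" separator

        def emit(sentence: str) -> int:
            nonlocal offset
            if parts:
                sentence = " " + sentence
            base = offset + (1 if parts else 0)
            parts.append(sentence)
            offset += len(sentence)
            return base

        emit(DISTRACTOR_SENTENCES[rng.randrange(len(DISTRACTOR_SENTENCES))])
        for plant in chosen:
            if plant.category == "abbreviation":
                sent = ABBREV_TEMPLATE.format(long=plant.long_form, sf=plant.surface)
                base = emit(sent)
                li = sent.index(plant.long_form)
                mentions.append(
                    Mention(base + li, base + li + len(plant.long_form),
                            plant.long_form, "Disease", plant.concept_id)
                )
                si = sent.index(f"({plant.surface})") + 1
                mentions.append(
                    Mention(base + si, base + si + len(plant.surface),
                            plant.surface, "Disease", plant.concept_id)
                )
                sent2 = ABBREV_FOLLOWUP.format(sf=plant.surface)
                base2 = emit(sent2)
                si2 = sent2.index(plant.surface)
                mentions.append(
                    Mention(base2 + si2, base2 + si2 + len(plant.surface),
                            plant.surface, "Disease", plant.concept_id)
                )
            else:
                tmpl = MENTION_TEMPLATES[rng.randrange(len(MENTION_TEMPLATES))]
                sent = tmpl.format(m=plant.surface)
                base = emit(sent)
                mi = sent.index(plant.surface)
                mentions.append(
                    Mention(base + mi, base + mi + len(plant.surface),
                            plant.surface, "Disease", plant.concept_id)
                )
            if rng.randrange(10_000) < round(spec.repetition_rate * 10_000):
                # for abbreviation plants the short form already recurs in
                # the follow-up sentence; repeat the long form instead
                rep = plant.long_form or plant.surface
                sent = REPEAT_TEMPLATE.format(m=rep)
                base = emit(sent)
                mi = sent.index(rep)
                mentions.append(
                    Mention(base + mi, base + mi + len(rep),
                            rep, "Disease", plant.concept_id)
                )
            emit(DISTRACTOR_SENTENCES[rng.randrange(len(DISTRACTOR_SENTENCES))])

        docs.append(
            Document(f"doc{d + 1:04d}", title, "".join(parts), mentions)
        )
    return docs
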