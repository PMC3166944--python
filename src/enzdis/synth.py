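"""Seeded synthetic lexicons and gold-annotated corpora.

Every stage of the chain — dictionary matching, co-occurrence detection,
preprocessing, classification, confidence tiers — is testable without any
external download: this module fabricates an enzyme lexicon (pronounceable
surface forms bound to valid synthetic EC numbers, 1-3 synonyms per
concept, optionally planted short-acronym homonyms shared with the filler
vocabulary), a disease lexicon, and a three-stratum corpus mirroring the
composition of a typical expert-annotated training set: units with at
least one enzyme, units with an enzyme-disease co-occurrence, and
unconstrained units.

Category-positive units are built from template families whose cue phrases
(causal: "caused by", "deficiency of"; therapeutic: "inhibitor",
"treatment of"; diagnostic: "marker", "diagnosis of"; ongoing research:
"potential", "further studies") appear in positives with probability
(1 + 3s)/4 and leak into negatives with probability (1 - s)/4, where s is
the cue strength. At s = 1 the classes are fully separable; at s = 0 the
cue distribution is identical in both classes, so the text carries no
label signal at all — a true null. Filler tokens are drawn Zipf-like from
a nonsense vocabulary disjoint from all lexicon surface tokens, giving
realistic tf-idf sparsity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .corpus_io import Reference, write_references
from .lexicon import DISEASE, ENZYME, Lexicon, LexiconEntry, normalize_term

CATEGORY_CUES: dict[str, tuple[str, ...]] = {
    "causal_interaction": (
        "caused by", "results from mutations of", "deficiency of", "malfunction of",
    ),
    "ongoing_research": (
        "potential role in", "further studies needed for",
        "under investigation for", "presumed link to",
    ),
    "diagnostic_usage": (
        "marker for diagnosis of", "prognostic tool for", "diagnosis of",
        "measured for detection of",
    ),
    "therapeutic_application": (
        "inhibitor for treatment of", "drug target for", "therapy with",
        "treatment of",
    ),
}

# annotated-category counts of a 5,031-unit expert corpus, as prevalences
_DEFAULT_PREVALENCE = {
    "causal_interaction": 1382 / 5031,
    "ongoing_research": 587 / 5031,
    "diagnostic_usage": 477 / 5031,
    "therapeutic_application": 366 / 5031,
}

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


def _pronounceable(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


class _WordFactory:
    """Stream of unique pronounceable nonsense words."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, min_syll: int = 2, max_syll: int = 4) -> str:
        while True:
            w = _pronounceable(self.rng, int(self.rng.integers(min_syll, max_syll + 1)))
            if w not in self.used:
                self.used.add(w)
                return w

    def acronym(self, length: int = 3) -> str:
        while True:
            a = "".join(self.rng.choice(list(_CONSONANTS.upper())) for _ in range(length))
            if a not in self.used:
                self.used.add(a)
                return a


class SyntheticLexicons(NamedTuple):
    enzyme: Lexicon
    disease: Lexicon
    homonyms: list[str]  # acronym surfaces shared with the filler vocabulary


def generate_lexicons(
    n_enzymes: int,
    n_diseases: int,
    seed: int,
    homonym_fraction: float = 0.0,
    max_synonyms: int = 3,
) -> SyntheticLexicons:
    """Synthetic enzyme and disease dictionaries.

    Each concept gets 1..max_synonyms unique surface forms (single- or
    two-token). A ``homonym_fraction`` of enzyme concepts additionally gets
    a short all-caps acronym synonym that the corpus generator also plants
    in its filler vocabulary, to exercise blacklist curation.
    """
    if n_enzymes < 1 or n_diseases < 1:
        raise ValueError("lexicon sizes must be >= 1")
    rng = np.random.default_rng(seed)
    factory = _WordFactory(rng)
    homonyms: list[str] = []

    def surfaces(k: int) -> list[str]:
        out = []
        for _ in range(k):
            if rng.random() < 0.5:
                out.append(factory.word())
            else:
                out.append(f"{factory.word()} {factory.word()}")
        return out

    enzyme_entries: list[LexiconEntry] = []
    n_homonym = int(round(homonym_fraction * n_enzymes))
    for i in range(n_enzymes):
        ec = f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 21))}.{int(rng.integers(1, 31))}.{i + 1}"
        for surf in surfaces(int(rng.integers(1, max_synonyms + 1))):
            enzyme_entries.append(LexiconEntry(surf, normalize_term(surf), ec, ENZYME))
        if i < n_homonym:
            acr = factory.acronym()
            enzyme_entries.append(LexiconEntry(acr, normalize_term(acr), ec, ENZYME))
            homonyms.append(acr)

    disease_entries: list[LexiconEntry] = []
    for i in range(n_diseases):
        did = f"D{i + 1:06d}"
        for surf in surfaces(int(rng.integers(1, max_synonyms + 1))):
            disease_entries.append(LexiconEntry(surf, normalize_term(surf), did, DISEASE))

    return SyntheticLexicons(
        Lexicon(ENZYME, enzyme_entries),
        Lexicon(DISEASE, disease_entries),
        homonyms,
    )


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults mirror a realistic corpus-selection protocol: 2,500 units with
    at least one enzyme mention, 2,000 with an enzyme-disease co-occurrence,
    500 unconstrained, with per-category prevalences proportional to
    1,382 / 587 / 477 / 366 positives out of 5,031 annotated units.
    """

    seed: int
    n_enzyme_only: int = 2500
    n_both: int = 2000
    n_random: int = 500
    category_prevalence: dict = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    n_filler_vocab: int = 2000
    cue_strength: float = 0.8
    units_per_reference: int = 3

    def __post_init__(self) -> None:
        if min(self.n_enzyme_only, self.n_both, self.n_random) < 0:
            raise ValueError("stratum counts must be >= 0")
        if not 0.0 <= self.cue_strength <= 1.0:
            raise ValueError("cue strength must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.category_prevalence.values()):
            raise ValueError("prevalences must be in [0, 1]")
        if self.units_per_reference < 1:
            raise ValueError("units_per_reference must be >= 1")


@dataclass(frozen=True)
class GoldUnit:
    """One generated text unit with its planted spans and category labels."""

    ref_id: str
    unit_index: int
    text: str
    enzyme_spans: tuple[tuple[int, int, str], ...]  # (start, end, concept_id)
    disease_spans: tuple[tuple[int, int, str], ...]
    labels: frozenset
    stratum: str

    @property
    def has_cooccurrence(self) -> bool:
        return bool(self.enzyme_spans) and bool(self.disease_spans)


@dataclass
class SyntheticCorpus:
    references: list[Reference]
    gold_units: list[GoldUnit]
    manifest: dict

    def cooccurrence_units(self) -> list[GoldUnit]:
        return [g for g in self.gold_units if g.has_cooccurrence]


def _pick_surface(rng: np.random.Generator, lex: Lexicon,
                  exclude: set[str] = frozenset()) -> tuple[str, str]:
    """(surface, concept_id) of a uniformly chosen non-excluded entry."""
    pool = [e for e in lex.entries if e.surface not in exclude]
    e = pool[int(rng.integers(0, len(pool)))]
    return e.surface, e.concept_id


class _UnitBuilder:
    """Assembles one sentence from parts, tracking entity character spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.entities: list[tuple[str, str, str]] = []  # (class, concept, surface)
        self.entity_at: list[int] = []  # part index of each entity

    def add(self, text: str) -> None:
        self.parts.append(text)

    def add_entity(self, entity_class: str, concept_id: str, surface: str) -> None:
        self.entity_at.append(len(self.parts))
        self.entities.append((entity_class, concept_id, surface))
        self.parts.append(surface)

    def render(self) -> tuple[str, list[tuple[int, int, str]], list[tuple[int, int, str]]]:
        text = ""
        offsets = []
        for p in self.parts:
            if text:
                text += " "
            offsets.append(len(text))
            text += p
        text += "."
        enz, dis = [], []
        for (cls, cid, surf), at in zip(self.entities, self.entity_at):
            span = (offsets[at], offsets[at] + len(surf), cid)
            (enz if cls == ENZYME else dis).append(span)
        return text, enz, dis


def generate_corpus(spec: CorpusSpec, lexicons: SyntheticLexicons) -> SyntheticCorpus:
    """Three-stratum gold corpus with tunable class separability.

    Deterministic for a given spec (including seed); the manifest records
    the generation parameters, the planted homonyms and per-stratum and
    per-category counts. Gold labels and spans live on the returned
    ``GoldUnit`` objects and in the gold TSV written by
    :func:`write_synthetic_corpus`.
    """
    if not lexicons.enzyme.entries or not lexicons.disease.entries:
        raise ValueError("lexicons must be non-empty")
    rng = np.random.default_rng(spec.seed)
    factory = _WordFactory(rng)
    # keep filler vocabulary disjoint from every lexicon surface token
    for lex in (lexicons.enzyme, lexicons.disease):
        for e in lex.entries:
            factory.used.update(e.surface.split())
    filler = [factory.word() for _ in range(spec.n_filler_vocab)]
    # planted homonym acronyms are also filler tokens, by design
    filler.extend(lexicons.homonyms)
    ranks = np.arange(1, len(filler) + 1, dtype=float)
    filler_p = (1.0 / ranks) / np.sum(1.0 / ranks)

    def fillers(k: int) -> list[str]:
        return [filler[i] for i in rng.choice(len(filler), size=k, p=filler_p)]

    s = spec.cue_strength
    p_pos = (1.0 + 3.0 * s) / 4.0
    p_neg = (1.0 - s) / 4.0
    categories = list(CATEGORY_CUES)

    plans: list[str] = (
        ["enzyme_only"] * spec.n_enzyme_only
        + ["both"] * spec.n_both
        + ["random"] * spec.n_random
    )
    rng.shuffle(plans)

    units: list[tuple[str, str, frozenset, list, list]] = []
    for stratum in plans:
        b = _UnitBuilder()
        b.add(fillers(1)[0].capitalize())
        for w in fillers(int(rng.integers(1, 4))):
            b.add(w)
        labels: frozenset = frozenset()
        homo = set(lexicons.homonyms)  # planted entities avoid homonym surfaces
        if stratum == "enzyme_only":
            surf, cid = _pick_surface(rng, lexicons.enzyme, exclude=homo)
            b.add_entity(ENZYME, cid, surf)
        elif stratum == "both":
            labels = frozenset(
                c for c in categories
                if rng.random() < spec.category_prevalence[c]
            )
            esurf, eid = _pick_surface(rng, lexicons.enzyme, exclude=homo)
            b.add_entity(ENZYME, eid, esurf)
            wrote_cue = False
            for c in categories:
                p = p_pos if c in labels else p_neg
                if rng.random() < p:
                    phrase = CATEGORY_CUES[c][int(rng.integers(0, len(CATEGORY_CUES[c])))]
                    for w in phrase.split():
                        b.add(w)
                    wrote_cue = True
            if not wrote_cue:
                b.add(fillers(1)[0])
            dsurf, did = _pick_surface(rng, lexicons.disease)
            b.add_entity(DISEASE, did, dsurf)
            if rng.random() < 0.2:  # occasional second enzyme
                surf2, eid2 = _pick_surface(rng, lexicons.enzyme,
                                            exclude=homo | {esurf})
                b.add(fillers(1)[0])
                b.add_entity(ENZYME, eid2, surf2)
        for w in fillers(int(rng.integers(1, 4))):
            b.add(w)
        text, enz, dis = b.render()
        units.append((stratum, text, labels, enz, dis))

    # pack units into references: unit 0 is the title, the rest the abstract
    references: list[Reference] = []
    gold_units: list[GoldUnit] = []
    upr = spec.units_per_reference
    for start in range(0, len(units), upr):
        chunk = units[start : start + upr]
        ref_id = f"R{len(references) + 1:06d}"
        title = chunk[0][1]
        abstract = " ".join(u[1] for u in chunk[1:])
        references.append(Reference(ref_id, title, abstract))
        for unit_index, (stratum, text, labels, enz, dis) in enumerate(chunk):
            gold_units.append(GoldUnit(
                ref_id, unit_index, text,
                tuple(enz), tuple(dis), labels, stratum,
            ))

    counts = {
        "enzyme_only": spec.n_enzyme_only,
        "both": spec.n_both,
        "random": spec.n_random,
    }
    label_counts = {
        c: sum(1 for g in gold_units if c in g.labels) for c in categories
    }
    manifest = {
        "seed": spec.seed,
        "cue_strength": spec.cue_strength,
        "strata": counts,
        "category_counts": label_counts,
        "homonyms": list(lexicons.homonyms),
        "n_references": len(references),
        "n_units": len(gold_units),
        "category_prevalence": dict(spec.category_prevalence),
    }
    return SyntheticCorpus(references, gold_units, manifest)


# ---------------------------------------------------------------------------
# text interchange


def write_synthetic_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> None:
    """Write corpus.tsv (record dialect), gold.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_references(corpus.references, outdir / "corpus.tsv", dialect="tsv")
    with open(outdir / "gold.tsv", "w", encoding="utf-8") as fh:
        fh.write("ref_id\tunit_index\tenzyme_spans\tdisease_spans\tlabels\tstratum\n")
        for g in corpus.gold_units:
            enz = ",".join(f"{s}:{e}:{c}" for s, e, c in g.enzyme_spans)
            dis = ",".join(f"{s}:{e}:{c}" for s, e, c in g.disease_spans)
            fh.write("\t".join([
                g.ref_id, str(g.unit_index), enz, dis,
                ",".join(sorted(g.labels)), g.stratum,
            ]) + "\n")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.manifest, fh, indent=2, sort_keys=True)
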