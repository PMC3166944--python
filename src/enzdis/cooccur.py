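"""Dictionary matching of enzyme and disease mentions and their co-occurrence.

A sentence or title that carries at least one enzyme and at least one
disease mention is the content basis of the relation table and the unit of
classification. Matching is token-boundary anchored on both sides (text and
lexicon are normalized identically); overlapping candidates are resolved
longest-leftmost, and a token region consumed by one mention cannot start
another mention of the same entity class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Reference, TextUnit, split_sentences
from .lexicon import DISEASE, ENZYME, Lexicon, tokenize_with_spans

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntityMention:
    """One dictionary hit inside a text unit (char offsets into unit text)."""

    entity_class: str
    concept_id: str
    surface: str
    char_span: tuple[int, int]


@dataclass(frozen=True)
class CooccurrenceRecord:
    """A text unit carrying at least one enzyme and one disease mention."""

    ref_id: str
    unit_index: int
    text: str
    enzyme_mentions: tuple[EntityMention, ...]
    disease_mentions: tuple[EntityMention, ...]

    def __post_init__(self) -> None:
        if not self.enzyme_mentions or not self.disease_mentions:
            raise ValueError("a co-occurrence record needs >=1 mention of each class")

    @property
    def enzyme_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.concept_id for m in self.enzyme_mentions}))

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.concept_id for m in self.disease_mentions}))

    @property
    def mentions(self) -> tuple[EntityMention, ...]:
        return tuple(sorted(self.enzyme_mentions + self.disease_mentions,
                            key=lambda m: m.char_span))


def find_entities(unit: TextUnit, lex: Lexicon) -> list[EntityMention]:
    """Longest-leftmost dictionary matching over one text unit.

    Scans token positions left to right; at each position the longest
    lexicon term starting there wins and consumes its tokens. An ambiguous
    surface form yields one mention per concept ID over the same span.
    """
    tokens = tokenize_with_spans(unit.text)
    norms = [t[0] for t in tokens]
    index = lex.index()
    maxlen = lex.max_term_length()
    mentions: list[EntityMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(maxlen, n - i), 0, -1):
            key = tuple(norms[i : i + length])
            if key in index:
                hit = (length, index[key])
                break
        if hit is None:
            i += 1
            continue
        length, concept_ids = hit
        span = (tokens[i][1], tokens[i + length - 1][2])
        surface = unit.text[span[0] : span[1]]
        for cid in concept_ids:
            mentions.append(EntityMention(lex.entity_class, cid, surface, span))
        i += length
    return mentions


def find_cooccurrences(
    refs: Iterable[Reference], enzyme_lex: Lexicon, disease_lex: Lexicon
) -> list[CooccurrenceRecord]:
    """All text units with >=1 enzyme and >=1 disease mention.

    Enzyme and disease matching are independent (a span may host mentions
    of both classes). Output is ordered by (ref_id, unit_index).
    """
    records: list[CooccurrenceRecord] = []
    for ref in refs:
        for unit in split_sentences(ref):
            enz = find_entities(unit, enzyme_lex)
            if not enz:
                continue
            dis = find_entities(unit, disease_lex)
            if not dis:
                continue
            records.append(
                CooccurrenceRecord(ref.ref_id, unit.unit_index, unit.text,
                                   tuple(enz), tuple(dis))
            )
    records.sort(key=lambda r: (r.ref_id, r.unit_index))
    return records


def evaluate_recognition(
    predicted: Mapping[tuple[str, int], bool],
    gold: Mapping[tuple[str, int], bool],
):
    """Confusion matrix for unit-level co-occurrence detection.

    A unit correctly flagged as carrying both entity classes is a true
    positive; correctly estimated absence of one or both classes is a true
    negative; flagging a unit where even one class is missing is a false
    positive; a missed co-occurrence is a false negative.
    """
    from .evaluation import ConfusionMatrix

    if set(predicted) != set(gold):
        raise ValueError("predicted and gold must cover the same unit set")
    tp = fp = tn = fn = 0
    for key, g in gold.items():
        p = predicted[key]
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# TSV interchange

_HEADER = "ref_id\tunit_index\ttext\tenzyme_ecs\tdisease_ids\tmention_spans"


def write_cooccurrences(records: Sequence[CooccurrenceRecord],
                        path: str | Path) -> None:
    """Write co-occurrence records as TSV (spans encoded as start:end pairs)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for r in records:
            spans = ",".join(f"{m.char_span[0]}:{m.char_span[1]}" for m in r.mentions)
            fh.write("\t".join([
                r.ref_id, str(r.unit_index), r.text,
                ",".join(r.enzyme_ids), ",".join(r.disease_ids), spans,
            ]) + "\n")
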