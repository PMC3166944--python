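import pytest

from enzdis import synth
from enzdis.cooccur import CooccurrenceRecord, EntityMention
from enzdis.lexicon import DISEASE, ENZYME, Lexicon, LexiconEntry, normalize_term


def make_lexicon(entity_class, pairs):
    """Lexicon from (surface, concept_id) pairs."""
    return Lexicon(entity_class, [
        LexiconEntry(s, normalize_term(s), c, entity_class) for s, c in pairs
    ])


@pytest.fixture
def enzyme_lex():
    return make_lexicon(ENZYME, [
        ("HIV-1 protease", "3.4.23.16"),
        ("protease", "3.4.21.1"),
        ("alpha-galactosidase", "3.2.1.22"),
        ("lethal toxin", "3.4.24.83"),
        ("AAA", "3.5.1.13"),
    ])


@pytest.fixture
def disease_lex():
    return make_lexicon(DISEASE, [
        ("AIDS", "D000163"),
        ("Fabry disease", "D000795"),
        ("anthrax", "D000881"),
    ])


def make_record(text, enzyme_spans, disease_spans, ref_id="R1", unit_index=0):
    """CooccurrenceRecord with mention spans given as (start, end, concept_id)."""
    enz = tuple(EntityMention(ENZYME, c, text[s:e], (s, e)) for s, e, c in enzyme_spans)
    dis = tuple(EntityMention(DISEASE, c, text[s:e], (s, e)) for s, e, c in disease_spans)
    return CooccurrenceRecord(ref_id, unit_index, text, enz, dis)


@pytest.fixture(scope="session")
def small_synth():
    """A small mid-separability synthetic corpus shared across tests."""
    lexs = synth.generate_lexicons(40, 30, seed=11, homonym_fraction=0.1)
    spec = synth.CorpusSpec(seed=12, n_enzyme_only=120, n_both=200, n_random=40,
                            cue_strength=0.9)
    return lexs, spec, synth.generate_corpus(spec, lexs)


def gold_to_records(corpus):
    """Co-occurrence records and label sets straight from the planted gold."""
    records, labels = [], []
    for g in corpus.cooccurrence_units():
        records.append(make_record(
            g.text,
            [(s, e, c) for s, e, c in g.enzyme_spans],
            [(s, e, c) for s, e, c in g.disease_spans],
            ref_id=g.ref_id, unit_index=g.unit_index,
        ))
        labels.append(g.labels)
    return records, labels
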