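"""End-to-end orchestration and content summaries of the relation table.

The chain reads literature records, segments them into units, finds
enzyme-disease co-occurrences, classifies each unit per category with the
trained ensemble, attaches confidence levels, and expands units into
(EC number, disease, reference) relation rows. Summaries include the
per-EC-class representation quotient — the class's share of distinct
enzyme-disease combinations divided by its share of known EC numbers, so a
value above 1 marks over-representation in the disease literature — and
the intersection counts of the four relation categories at each confidence
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classifier import CATEGORIES, CategoryEnsemble, UNASSIGNED
from .cooccur import CooccurrenceRecord, find_cooccurrences
from .corpus_io import Reference
from .lexicon import Lexicon, ec_class

logger = logging.getLogger(__name__)

RELATION_COLUMNS = ["ec_number", "disease_id", "ref_id", "unit_index",
                    "category", "confidence_level"]
COOCCURRENCE_COLUMNS = ["ec_number", "disease_id", "ref_id", "unit_index"]


def expand_pairs(
    record: CooccurrenceRecord, decisions: Mapping[str, int]
) -> list[dict]:
    """Relation rows for one unit: enzyme IDs x disease IDs x assigned categories.

    ``decisions`` maps category -> confidence level (0 = unassigned).
    A unit with no assigned category yields no categorized rows; its pairs
    are still retained in the uncategorized co-occurrence table.
    """
    rows = []
    for ec in record.enzyme_ids:
        for did in record.disease_ids:
            for category, level in decisions.items():
                if level > UNASSIGNED:
                    rows.append({
                        "ec_number": ec, "disease_id": did,
                        "ref_id": record.ref_id, "unit_index": record.unit_index,
                        "category": category, "confidence_level": int(level),
                    })
    return rows


def build_relation_table(
    records: Sequence[CooccurrenceRecord],
    decisions: Mapping[str, Sequence[int]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(categorized, uncategorized) tables from per-unit category levels.

    Categorized rows are unique per (ec, disease, ref, category), keeping
    the maximum confidence level over the units of a reference. The
    uncategorized table lists every distinct (ec, disease, ref, unit) pair
    found by the matcher, regardless of classification.
    """
    cat_rows: list[dict] = []
    pair_rows: list[dict] = []
    for i, rec in enumerate(records):
        per_unit = {c: decisions[c][i] for c in decisions}
        cat_rows.extend(expand_pairs(rec, per_unit))
        for ec in rec.enzyme_ids:
            for did in rec.disease_ids:
                pair_rows.append({"ec_number": ec, "disease_id": did,
                                  "ref_id": rec.ref_id, "unit_index": rec.unit_index})
    uncategorized = pd.DataFrame(pair_rows, columns=COOCCURRENCE_COLUMNS)
    uncategorized = uncategorized.drop_duplicates().reset_index(drop=True)
    if not cat_rows:
        return pd.DataFrame(columns=RELATION_COLUMNS), uncategorized
    df = pd.DataFrame(cat_rows, columns=RELATION_COLUMNS)
    # one row per (ec, disease, ref, category), max level; earliest unit wins ties
    df = df.sort_values(["confidence_level", "unit_index"],
                        ascending=[False, True], kind="mergesort")
    df = df.drop_duplicates(["ec_number", "disease_id", "ref_id", "category"])
    df = df.sort_values(RELATION_COLUMNS[:5], kind="mergesort").reset_index(drop=True)
    return df, uncategorized


@dataclass
class PipelineConfig:
    """Inputs of one end-to-end run (in-memory objects; the CLI builds them)."""

    references: Sequence[Reference]
    enzyme_lexicon: Lexicon
    disease_lexicon: Lexicon
    ensemble: CategoryEnsemble | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    relations: pd.DataFrame
    cooccurrences: pd.DataFrame
    records: list[CooccurrenceRecord]
    stage_log: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute read -> split -> match -> classify -> confidence -> table.

    Deterministic for a given config and seed. With no ensemble configured
    only the uncategorized co-occurrence table is produced.
    """
    if not config.enzyme_lexicon.entries or not config.disease_lexicon.entries:
        raise ValueError("both lexicons must be loaded before running the pipeline")
    refs = list(config.references)
    stage_log = {"n_references": len(refs)}
    records = find_cooccurrences(refs, config.enzyme_lexicon, config.disease_lexicon)
    stage_log["n_cooccurrence_units"] = len(records)
    if config.ensemble is not None and records:
        decisions = config.ensemble.classify(records)
    else:
        decisions = {c: [UNASSIGNED] * len(records) for c in CATEGORIES}
    relations, cooccurrences = build_relation_table(records, decisions)
    stage_log["n_relation_rows"] = len(relations)
    stage_log["n_distinct_pairs"] = int(
        cooccurrences[["ec_number", "disease_id", "ref_id"]].drop_duplicates().shape[0]
    ) if len(cooccurrences) else 0
    for key, value in stage_log.items():
        logger.info("%s = %s", key, value)
    return PipelineResult(relations, cooccurrences, records, stage_log)


# ---------------------------------------------------------------------------
# content summaries


def representation_quotient(
    class_combos: Mapping[int, int],
    class_totals: Mapping[int, int],
    total_a: int,
    total_b: int,
) -> dict[int, float | None]:
    """Share-normalized representation quotient per EC class.

    quotient(c) = (a_c / total_a) / (b_c / total_b) where a_c counts the
    class's distinct EC-disease combinations and b_c its known EC numbers.
    A class with b_c = 0 is undefined and reported as None.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    out: dict[int, float | None] = {}
    for c in sorted(set(class_combos) | set(class_totals)):
        a = class_combos.get(c, 0)
        b = class_totals.get(c, 0)
        if b == 0:
            logger.warning("EC class %d has no known EC numbers; quotient undefined", c)
            out[c] = None
        else:
            out[c] = (a / total_a) / (b / total_b)
    return out


def summarize_by_ec_class(
    cooccurrences: pd.DataFrame, enzyme_lexicon: Lexicon
) -> pd.DataFrame:
    """Per-EC-class summary: distinct combination counts and quotients."""
    pairs = cooccurrences[["ec_number", "disease_id"]].drop_duplicates()
    combos = {c: 0 for c in range(1, 7)}
    for ec in pairs["ec_number"]:
        combos[ec_class(ec)] = combos.get(ec_class(ec), 0) + 1
    totals = {c: 0 for c in range(1, 7)}
    for cid in enzyme_lexicon.concept_ids:
        totals[ec_class(cid)] = totals.get(ec_class(cid), 0) + 1
    total_a = sum(combos.values())
    total_b = sum(totals.values())
    if total_a == 0 or total_b == 0:
        return pd.DataFrame(columns=["ec_class", "combos_a", "ec_count_b", "quotient"])
    quotients = representation_quotient(combos, totals, total_a, total_b)
    rows = [
        {"ec_class": c, "combos_a": combos.get(c, 0), "ec_count_b": totals.get(c, 0),
         "quotient": None if quotients[c] is None else round(quotients[c], 2)}
        for c in sorted(quotients)
    ]
    return pd.DataFrame(rows)


def category_intersections(
    relations: pd.DataFrame,
    level: int,
    all_combos: pd.DataFrame | None = None,
) -> dict[frozenset, int]:
    """Distinct (EC, disease, ref) counts for every category subset.

    A combination belongs to the cell of exactly the set of categories it
    carries at confidence level >= ``level`` (cumulative semantics). When
    ``all_combos`` is given, the empty-set key counts combinations with no
    category at that level (the unassigned cell); cells partition the total.
    """
    if not 1 <= level <= 4:
        raise ValueError("level must be in 1..4")
    out: dict[frozenset, int] = {
        frozenset(subset): 0
        for r in range(1, 5)
        for subset in combinations(CATEGORIES, r)
    }
    combo_cats: dict[tuple, set] = {}
    if len(relations):
        at_level = relations[relations["confidence_level"] >= level]
        for row in at_level.itertuples(index=False):
            key = (row.ec_number, row.disease_id, row.ref_id)
            combo_cats.setdefault(key, set()).add(row.category)
    for cats in combo_cats.values():
        out[frozenset(cats)] += 1
    if all_combos is not None:
        total = {tuple(r) for r in
                 all_combos[["ec_number", "disease_id", "ref_id"]]
                 .drop_duplicates().itertuples(index=False)}
        out[frozenset()] = len(total - set(combo_cats))
    return out


def combos_at_level(relations: pd.DataFrame, level: int) -> set[tuple]:
    """Distinct (EC, disease, ref) combinations carrying any category at >= level."""
    if not len(relations):
        return set()
    sub = relations[relations["confidence_level"] >= level]
    return {(r.ec_number, r.disease_id, r.ref_id)
            for r in sub.itertuples(index=False)}
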