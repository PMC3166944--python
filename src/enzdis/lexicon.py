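"""Enzyme and disease dictionaries used as matching references.

A lexicon maps normalized surface forms to canonical concept identifiers:
four-field EC numbers for enzymes, opaque concept IDs (MeSH-style) for
diseases. Matching is case-insensitive except for short all-caps acronyms,
which are kept case-sensitive because they are the dominant source of
homonym false positives ("AAA" is both an enzyme synonym and an abdominal
aortic aneurysm). Curation is declarative: a blacklist of ambiguous surface
forms removed before matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Entity classes handled by the matcher.
ENZYME = "enzyme"
DISEASE = "disease"

# Tokens are maximal runs of letters/digits; internal hyphens stay inside
# one token ("HIV-1", "alpha-galactosidase"). Underscore is excluded.
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)

# All-caps tokens of length <= 4 match case-sensitively (acronym policy).
_ACRONYM_RE = re.compile(r"^[A-Z]{1,4}$")

# Four numeric fields, no wildcards, e.g. "3.2.1.22".
_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


def normalize_token(token: str) -> str:
    """Lowercase a token unless it is a short all-caps acronym.

    Lowercasing a few Unicode characters introduces combining marks that
    are not token characters; those are dropped so that normalization is
    idempotent under re-tokenization.
    """
    if _ACRONYM_RE.match(token):
        return token
    low = token.lower()
    parts = _TOKEN_RE.findall(low)
    return "".join(parts) if parts else low


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Tokenize ``text`` into (normalized token, start, end) triples.

    Offsets are 0-based half-open in Unicode code points.
    """
    return [
        (normalize_token(m.group()), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def normalize_term(term: str) -> tuple[str, ...]:
    """Normalize a surface form to its matching token sequence.

    Empty or whitespace-only input yields an empty tuple. The function is
    idempotent: re-normalizing the space-joined output is a fixed point.
    """
    return tuple(normalize_token(m.group()) for m in _TOKEN_RE.finditer(term))


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary row: a surface form bound to a canonical concept."""

    surface: str
    norm_tokens: tuple[str, ...]
    concept_id: str
    entity_class: str

    def __post_init__(self) -> None:
        if not self.norm_tokens:
            raise ValueError("norm_tokens must be non-empty")
        if self.entity_class == ENZYME and not _EC_RE.match(self.concept_id):
            raise ValueError(
                f"enzyme concept_id {self.concept_id!r} is not a 4-field EC number"
            )


@dataclass
class Lexicon:
    """A curated set of entries of one entity class plus its blacklist."""

    entity_class: str
    entries: list[LexiconEntry] = field(default_factory=list)
    blacklist: set[tuple[str, ...]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, ...], tuple[str, ...]] | None = None

    @property
    def concept_ids(self) -> set[str]:
        return {e.concept_id for e in self.entries}

    def index(self) -> dict[tuple[str, ...], tuple[str, ...]]:
        """Map norm_tokens -> sorted concept IDs (ambiguous forms keep all)."""
        if self._index is None:
            acc: dict[tuple[str, ...], set[str]] = {}
            for e in self.entries:
                acc.setdefault(e.norm_tokens, set()).add(e.concept_id)
            self._index = {k: tuple(sorted(v)) for k, v in acc.items()}
        return self._index

    def max_term_length(self) -> int:
        return max((len(e.norm_tokens) for e in self.entries), default=0)

    def ambiguous_forms(self) -> dict[tuple[str, ...], tuple[str, ...]]:
        """Surface forms mapping to more than one concept ID."""
        return {k: v for k, v in self.index().items() if len(v) > 1}


def load_lexicon(path: str | Path, entity_class: str) -> Lexicon:
    """Load a TSV lexicon (surface<TAB>concept_id, '#' comments, UTF-8).

    Rows whose concept_id is not a valid 4-field EC number (for enzymes) or
    whose surface normalizes to nothing are rejected with a warning.
    Duplicate (norm_tokens, concept_id) pairs are deduplicated.
    """
    entries: list[LexiconEntry] = []
    seen: set[tuple[tuple[str, ...], str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                logger.warning("%s:%d: expected 2 columns, got %d", path, lineno, len(parts))
                continue
            surface, concept_id = parts
            norm = normalize_term(surface)
            if not norm:
                logger.warning("%s:%d: surface %r normalizes to nothing", path, lineno, surface)
                continue
            if entity_class == ENZYME and not _EC_RE.match(concept_id):
                logger.warning("%s:%d: rejected concept_id %r (not an EC number)",
                               path, lineno, concept_id)
                continue
            key = (norm, concept_id)
            if key in seen:
                continue
            seen.add(key)
            entries.append(LexiconEntry(surface, norm, concept_id, entity_class))
    return Lexicon(entity_class=entity_class, entries=entries)


def apply_blacklist(lex: Lexicon, terms: Iterable[str]) -> Lexicon:
    """Return a lexicon with all entries matching blacklisted forms removed.

    Terms are normalized with the same rules as lexicon surfaces, so the
    operation is idempotent and order-independent. The removal count is
    logged.
    """
    black = {normalize_term(t) for t in terms}
    black.discard(())
    kept = [e for e in lex.entries if e.norm_tokens not in black]
    removed = len(lex.entries) - len(kept)
    logger.info("blacklist removed %d of %d %s entries", removed, len(lex.entries),
                lex.entity_class)
    return Lexicon(entity_class=lex.entity_class, entries=kept,
                   blacklist=lex.blacklist | black)


def load_blacklist(path: str | Path) -> list[str]:
    """Read a blacklist file: one surface form per line, blanks ignored."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in lex.entries:
            fh.write(f"{e.surface}\t{e.concept_id}\n")


def ec_class(ec_number: str) -> int:
    """Top-level enzyme class (1-6) of a four-field EC number."""
    return int(ec_number.split(".")[0])
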