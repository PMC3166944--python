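"""Reading literature records and segmenting them into classification units.

A record is a PMID-like identifier, a title and an (optional) abstract.
The unit of all downstream processing is a *text unit*: the whole title
(unit 0) or one abstract sentence (units 1..n). Sentence segmentation is
rule-based — split at sentence-final punctuation followed by whitespace and
an uppercase letter or digit, with an exception list of common biomedical
abbreviations — so that unit boundaries are deterministic and exactly
reconstructible from character offsets.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reference:
    """One literature record."""

    ref_id: str
    title: str
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.ref_id:
            raise ValueError("ref_id must be non-empty")
        if not self.title:
            raise ValueError("title must be non-empty")


@dataclass(frozen=True)
class TextUnit:
    """A title (unit_index 0) or one abstract sentence (1..n).

    ``char_span`` is a 0-based half-open offset pair into the source field
    (title for unit 0, abstract otherwise), counted in code points.
    """

    ref_id: str
    unit_index: int
    text: str
    char_span: tuple[int, int]


# Abbreviations that end in '.' but do not terminate a sentence. "et al."
# is covered by its final token "al.". Single-letter initials ("J.") are
# handled by a separate pattern.
_ABBREVIATIONS = {
    "e.g.", "i.e.", "al.", "dr.", "fig.", "figs.", "ca.", "vs.", "cf.",
    "etc.", "approx.", "no.", "st.", "mr.", "mrs.", "ms.", "prof.", "ref.",
    "refs.", "resp.", "sp.", "spp.", "var.", "viz.", "eq.", "eqs.", "tab.",
    "ed.", "eds.", "inc.", "jr.", "sr.", "vol.", "vols.", "min.", "max.",
    "wt.", "mol.",
}

_INITIAL_RE = re.compile(r"^[A-Za-z]\.$")

# Candidate boundary: ., ! or ? then whitespace then uppercase or digit.
_BOUNDARY_RE = re.compile(r"[.!?](?=\s+[A-Z0-9])")
_SEP_RE = re.compile(r"\s+")


def _is_abbreviation(text: str, punct_index: int) -> bool:
    """True if the '.' at ``punct_index`` ends a known abbreviation."""
    if text[punct_index] != ".":
        return False
    m = re.search(r"(\S+)$", text[: punct_index + 1])
    if m is None:
        return False
    token = m.group(1)
    return token.lower() in _ABBREVIATIONS or bool(_INITIAL_RE.match(token))


def split_sentences(ref: Reference) -> list[TextUnit]:
    """Segment a reference into its title unit and abstract sentence units.

    The title is always a single unit regardless of internal punctuation.
    Joining abstract unit texts with the removed separators reconstructs
    the abstract.
    """
    units = [TextUnit(ref.ref_id, 0, ref.title, (0, len(ref.title)))]
    abstract = ref.abstract
    if not abstract.strip():
        return units

    boundaries: list[int] = []  # index one past the sentence-final punctuation
    for m in _BOUNDARY_RE.finditer(abstract):
        if not _is_abbreviation(abstract, m.start()):
            boundaries.append(m.start() + 1)

    starts = [0] + [
        _SEP_RE.match(abstract, b).end() for b in boundaries  # type: ignore[union-attr]
    ]
    ends = boundaries + [len(abstract)]

    idx = 1
    for s, e in zip(starts, ends):
        # trim surrounding whitespace, keeping offsets consistent
        seg = abstract[s:e]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        s2, e2 = s + lstrip, e - rstrip
        if s2 >= e2:
            continue
        units.append(TextUnit(ref.ref_id, idx, abstract[s2:e2], (s2, e2)))
        idx += 1
    return units


def iter_units(refs: Iterable[Reference]) -> Iterator[TextUnit]:
    for ref in refs:
        yield from split_sentences(ref)


# ---------------------------------------------------------------------------
# dialects


def _read_tsv(path: Path, header: bool) -> Iterator[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                logger.warning("%s:%d: expected 3 columns, got %d", path, lineno, len(parts))
                continue
            yield lineno, {"ref_id": parts[0], "title": parts[1], "abstract": parts[2]}


def _read_jsonl(path: Path) -> Iterator[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                logger.warning("%s:%d: bad JSON (%s)", path, lineno, exc)
                continue
            yield lineno, obj


def _read_medline_xml(path: Path) -> Iterator[tuple[int, dict]]:
    tree = etree.parse(str(path))
    for i, cit in enumerate(tree.iter("MedlineCitation"), 1):
        pmid = cit.findtext("PMID", default="") or ""
        title = cit.findtext(".//ArticleTitle", default="") or ""
        abstract = " ".join(
            t for el in cit.iter("AbstractText") if (t := "".join(el.itertext()).strip())
        )
        yield i, {"ref_id": pmid.strip(), "title": title.strip(), "abstract": abstract}


def read_references(
    path: str | Path, dialect: str = "tsv", header: bool = False
) -> list[Reference]:
    """Read literature records in one of three dialects.

    Records with an empty title are skipped with a warning; other per-record
    problems are also non-fatal. ``dialect`` is one of ``medline_xml``,
    ``tsv`` (columns ref_id, title, abstract; optional header row) or
    ``jsonl`` (objects with keys ref_id, title, abstract).
    """
    path = Path(path)
    if dialect == "tsv":
        rows = _read_tsv(path, header)
    elif dialect == "jsonl":
        rows = _read_jsonl(path)
    elif dialect == "medline_xml":
        rows = _read_medline_xml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    refs: list[Reference] = []
    for lineno, obj in rows:
        ref_id = str(obj.get("ref_id", "") or "")
        title = str(obj.get("title", "") or "")
        abstract = str(obj.get("abstract", "") or "")
        if not title:
            logger.warning("%s record %s: empty title, skipped", path, lineno)
            continue
        if not ref_id:
            logger.warning("%s record %s: empty ref_id, skipped", path, lineno)
            continue
        refs.append(Reference(ref_id, title, abstract))
    return refs


def write_references(refs: Iterable[Reference], path: str | Path,
                     dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for r in refs:
                fh.write(f"{r.ref_id}\t{r.title}\t{r.abstract}\n")
    elif dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in refs:
                fh.write(json.dumps(
                    {"ref_id": r.ref_id, "title": r.title, "abstract": r.abstract}
                ) + "\n")
    else:
        raise ValueError(f"unsupported output dialect {dialect!r}")
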