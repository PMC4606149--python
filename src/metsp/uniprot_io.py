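"""UniProt/Swiss-Prot flat-file reading and annotation sentence extraction.

Only the three line types that carry substrate-relevant text are kept:
protein names (DE), free-text FUNCTION comments (CC) and Gene Ontology
cross-references (DR GO).  Everything else in a record — sequence,
features, organism lines — is discarded.  The module also reads and
writes the tab-separated training-instance and known transporter-substrate
pair files used by the classifier harness.
"""

from __future__ import annotations

import logging
import re
import textwrap
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Union

logger = logging.getLogger(__name__)

__all__ = [
    "FieldFlag",
    "UniProtEntry",
    "AnnotationSentence",
    "LabeledInstance",
    "KnownTSP",
    "parse_flatfile",
    "format_flatfile",
    "write_flatfile",
    "extract_sentences",
    "split_sentences",
    "read_training_file",
    "write_training_file",
    "read_known_tsps",
    "write_known_tsps",
    "merge_known_tsps",
]

ACCESSION_RE = re.compile(r"[A-Z][A-Z0-9]{5,9}")
COMPOUND_ID_RE = re.compile(r"C[0-9]{5}")
_ECO_RE = re.compile(r"\s*\{ECO:[^}]*\}")


class FieldFlag(str, Enum):
    """The three annotation fields retained from a UniProt record."""

    DE = "DE"
    CC = "CC"
    DR = "DR"


@dataclass
class UniProtEntry:
    accession: str
    secondary_accessions: list[str] = field(default_factory=list)
    de_lines: list[str] = field(default_factory=list)
    cc_function_texts: list[str] = field(default_factory=list)
    dr_go_terms: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AnnotationSentence:
    """One sentence of annotation text with its provenance."""

    accession: str
    field_flag: FieldFlag
    text: str
    index: int


@dataclass(frozen=True)
class LabeledInstance:
    """A training unit: label + accession + field flag + sentence."""

    label: str  # "positive" or "unlabeled"
    accession: str
    field_flag: FieldFlag
    text: str

    LABELS = ("positive", "unlabeled")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class KnownTSP:
    """A curated transporter-substrate pair (accession, KEGG C-number)."""

    accession: str
    compound_id: str


# ---------------------------------------------------------------------------
# flat-file parsing


def _clean_de_line(body: str) -> str | None:
    """Extract a bare protein name from a DE line body, or None to skip."""
    body = body.strip()
    if body.startswith(("Flags:", "Contains:", "Includes:")):
        return None
    if body.startswith(("RecName:", "AltName:", "SubName:")):
        body = body.split(":", 1)[1].strip()
    if "=" in body:
        key, _, value = body.partition("=")
        if key.strip() == "EC":  # enzyme numbers are identifiers, not names
            return None
        body = value
    body = _ECO_RE.sub("", body).strip().rstrip(";").strip()
    return body or None


def _parse_dr_go(body: str) -> str | None:
    """Return the GO term name from a 'DR   GO; ...' body, else None."""
    parts = [p.strip() for p in body.split(";")]
    if not parts or parts[0] != "GO" or len(parts) < 3:
        return None
    term = parts[2]
    # strip the aspect prefix (P:/F:/C:)
    if len(term) > 2 and term[1] == ":":
        term = term[2:]
    return term.strip() or None


def parse_flatfile(source: Union[str, Path, IO[str]]) -> list[UniProtEntry]:
    """Parse Swiss-Prot flat-file text into entries with DE/CC/DR content.

    ``source`` may be a path or an open text stream.  Records lacking an
    AC line (or with a malformed primary accession) are rejected with a
    warning; a truncated final record that did see an AC line is kept and
    logged.  All other line types are ignored.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return parse_flatfile(fh)

    entries: list[UniProtEntry] = []
    record_lines: list[str] = []
    record_no = 0

    def flush(truncated: bool = False) -> None:
        nonlocal record_no
        if not any(line.strip() for line in record_lines):
            record_lines.clear()
            return
        record_no += 1
        entry = _parse_record(record_lines, record_no)
        if entry is not None:
            if truncated:
                logger.warning(
                    "final record %s lacked a '//' terminator", entry.accession
                )
            entries.append(entry)
        record_lines.clear()

    for raw in source:
        line = raw.rstrip("\n")
        if line.strip() == "//":
            flush()
        else:
            record_lines.append(line)
    flush(truncated=True)
    return entries


def _parse_record(lines: list[str], record_no: int) -> UniProtEntry | None:
    accessions: list[str] = []
    de_lines: list[str] = []
    cc_blocks: list[str] = []
    dr_terms: list[str] = []
    cc_current: list[str] | None = None

    for line in lines:
        code, body = line[:2], line[5:] if len(line) > 5 else ""
        if code != "CC" and cc_current is not None:
            cc_blocks.append(" ".join(cc_current))
            cc_current = None
        if code == "AC":
            accessions.extend(
                tok.strip().rstrip(";") for tok in body.split() if tok.strip(";")
            )
        elif code == "DE":
            name = _clean_de_line(body)
            if name:
                de_lines.append(name)
        elif code == "CC":
            stripped = body.strip()
            if stripped.startswith("-!-"):
                if cc_current is not None:
                    cc_blocks.append(" ".join(cc_current))
                    cc_current = None
                topic_body = stripped[3:].strip()
                if topic_body.startswith("FUNCTION:"):
                    cc_current = [topic_body[len("FUNCTION:"):].strip()]
            elif cc_current is not None:
                if stripped.startswith("---") or stripped.startswith("Copyright"):
                    cc_blocks.append(" ".join(cc_current))
                    cc_current = None
                elif stripped:
                    cc_current.append(stripped)
        elif code == "DR":
            term = _parse_dr_go(body)
            if term:
                dr_terms.append(term)
    if cc_current is not None:
        cc_blocks.append(" ".join(cc_current))

    if not accessions:
        logger.warning("record %d has no AC line; skipped", record_no)
        return None
    primary = accessions[0]
    if not ACCESSION_RE.fullmatch(primary):
        logger.warning(
            "record %d has malformed accession %r; skipped", record_no, primary
        )
        return None
    cc_blocks = [_ECO_RE.sub("", b).strip() for b in cc_blocks]
    cc_blocks = [b for b in cc_blocks if b]
    return UniProtEntry(
        accession=primary,
        secondary_accessions=accessions[1:],
        de_lines=de_lines,
        cc_function_texts=cc_blocks,
        dr_go_terms=dr_terms,
    )


def format_flatfile(entries: Iterable[UniProtEntry]) -> str:
    """Serialize the retained DE/CC/DR content back to flat-file syntax.

    The output is a valid (minimal) Swiss-Prot dialect that re-parses to
    the same entries, which is how the parser is round-trip tested.
    """
    lines: list[str] = []
    for e in entries:
        accs = [e.accession, *e.secondary_accessions]
        lines.append("AC   " + "; ".join(accs) + ";")
        for i, name in enumerate(e.de_lines):
            kind = "RecName" if i == 0 else "AltName"
            lines.append(f"DE   {kind}: Full={name};")
        for block in e.cc_function_texts:
            wrapped = textwrap.wrap(
                "-!- FUNCTION: " + block, width=70,
                break_long_words=False, break_on_hyphens=False,
            )
            lines.append("CC   " + wrapped[0])
            for cont in wrapped[1:]:
                lines.append("CC       " + cont)
        for term in e.dr_go_terms:
            lines.append(f"DR   GO; GO:0000000; P:{term}; IEA:Synthetic.")
        lines.append("//")
    return "\n".join(lines) + ("\n" if lines else "")


def write_flatfile(entries: Iterable[UniProtEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_flatfile(entries))


# ---------------------------------------------------------------------------
# sentence splitting

# tokens before a period that never end a sentence
_NO_SPLIT_BEFORE = frozenset(
    {"e.g", "i.e", "et", "al", "cf", "ca", "sp", "spp", "subsp", "approx",
     "vs", "etc", "fig", "ref"}
)
_BOUNDARY_RE = re.compile(r"\.(\s+)(?=[A-Z0-9])")
_TRAILING_WORD_RE = re.compile(r"[A-Za-z]+(?:\.[A-Za-z]+)*$")


def split_sentences(text: str) -> list[str]:
    """Split prose on '.' + whitespace + capital/digit boundaries.

    A protected-token list (e.g., i.e., et al., sp., single letters,
    common abbreviations) suppresses spurious splits; decimals are safe
    because a digit never follows '. ' inside a number.
    """
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        before = text[: m.start()]
        word = _TRAILING_WORD_RE.search(before)
        if word is not None:
            token = word.group(0).lower()
            if token in _NO_SPLIT_BEFORE or len(token) == 1:
                continue
        pieces.append(text[start : m.start() + 1].strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [p for p in pieces if p]


def extract_sentences(entry: UniProtEntry) -> list[AnnotationSentence]:
    """Emit annotation sentences: DE names, split CC FUNCTION prose, GO terms.

    DE names and GO terms are short noun phrases and are emitted verbatim,
    one sentence each; CC FUNCTION blocks are split into sentences.
    Indices run 0..n-1 in DE, CC, DR order.
    """
    out: list[AnnotationSentence] = []

    def emit(flag: FieldFlag, text: str) -> None:
        text = " ".join(text.split())
        if text:
            out.append(
                AnnotationSentence(entry.accession, flag, text, len(out))
            )

    for name in entry.de_lines:
        emit(FieldFlag.DE, name)
    for block in entry.cc_function_texts:
        for sent in split_sentences(block):
            emit(FieldFlag.CC, sent)
    for term in entry.dr_go_terms:
        emit(FieldFlag.DR, term)
    return out


# ---------------------------------------------------------------------------
# training-instance and known-TSP files


def read_training_file(path: str | Path) -> list[LabeledInstance]:
    """Read a 4-column TSV of (label, accession, field_flag, sentence).

    Lines with the wrong column count are skipped and counted in one
    summary warning; an unrecognized label token is a hard error naming
    the offending line.
    """
    instances: list[LabeledInstance] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                skipped += 1
                continue
            label, accession, flag, text = parts
            if label not in LabeledInstance.LABELS:
                raise ValueError(
                    f"{path}:{lineno}: unknown label token {label!r}"
                )
            instances.append(
                LabeledInstance(label, accession, FieldFlag(flag), text)
            )
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)
    return instances


def write_training_file(
    instances: Iterable[LabeledInstance], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(
                f"{inst.label}\t{inst.accession}\t{inst.field_flag.value}"
                f"\t{inst.text}\n"
            )


def read_known_tsps(path: str | Path) -> set[KnownTSP]:
    """Read a TSV of (accession, kegg_compound_id) pairs, deduplicated.

    Rows whose compound id is not a C-number (C#####) are skipped with a
    warning.
    """
    pairs: set[KnownTSP] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not COMPOUND_ID_RE.fullmatch(parts[1].strip()):
                logger.warning("%s:%d: malformed pair skipped: %r",
                               path, lineno, line)
                continue
            pairs.add(KnownTSP(parts[0].strip(), parts[1].strip()))
    return pairs


def write_known_tsps(pairs: Iterable[KnownTSP], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(pairs, key=lambda x: (x.accession, x.compound_id)):
            fh.write(f"{p.accession}\t{p.compound_id}\n")


def merge_known_tsps(
    uniprot_set: set[KnownTSP],
    transportdb_set: set[KnownTSP],
    tcdb_set: set[KnownTSP],
) -> set[KnownTSP]:
    """Combine database pair sets as (UniProt ∩ TransportDB) ∪ TCDB.

    Pairs attested by both of the two large general databases are trusted,
    and the hand-classified TCDB pairs are added wholesale.
    """
    return (uniprot_set & transportdb_set) | tcdb_set
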