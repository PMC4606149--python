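"""Dictionary tagging of chemical compound names via a character Trie.

Compound names and synonyms (many names to one KEGG LIGAND C-number) are
normalized — lowercased, internal whitespace collapsed — and inserted
into a prefix tree.  Sentences are scanned left to right; at each token
boundary the longest dictionary name that matches case-insensitively and
ends on a token boundary is emitted, and scanning resumes after it, so
matches are non-overlapping and "amino acid" beats "acid".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = ["CompoundLexicon", "CompoundMatch", "load_lexicon", "tag"]

_COMPOUND_ID_RE = re.compile(r"C[0-9]{5}")


def _normalize(name: str) -> str:
    return " ".join(name.lower().split())


class _TrieNode:
    __slots__ = ("children", "compound_id")

    def __init__(self) -> None:
        self.children: dict[str, _TrieNode] = {}
        self.compound_id: str | None = None


@dataclass
class CompoundLexicon:
    """Normalized compound name -> C-number map plus its prefix tree."""

    entries: dict[str, str] = field(default_factory=dict)
    _root: _TrieNode = field(default_factory=_TrieNode, repr=False)

    def add(self, name: str, compound_id: str) -> bool:
        """Insert a (name, C-number) pair; returns False on a conflict.

        A name already present with a different id keeps its first id —
        the dictionary assumes one name maps to one compound.
        """
        norm = _normalize(name)
        if not norm:
            return False
        existing = self.entries.get(norm)
        if existing is not None:
            if existing != compound_id:
                logger.warning(
                    "conflicting ids for %r: keeping %s, ignoring %s",
                    norm, existing, compound_id,
                )
                return False
            return True
        self.entries[norm] = compound_id
        node = self._root
        for ch in norm:
            node = node.children.setdefault(ch, _TrieNode())
        node.compound_id = compound_id
        return True

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return _normalize(name) in self.entries

    def tag(self, sentence: str) -> list["CompoundMatch"]:
        return tag(self, sentence)


@dataclass(frozen=True)
class CompoundMatch:
    """One dictionary hit: id, surface form and [start, end) offsets."""

    compound_id: str
    surface: str
    start: int
    end: int


def load_lexicon(path: str | Path) -> CompoundLexicon:
    """Load a TSV lexicon of (name, kegg_compound_id) rows.

    Rows with a malformed C-number are skipped with a warning; duplicate
    names with conflicting ids keep the first id seen.
    """
    lex = CompoundLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not _COMPOUND_ID_RE.fullmatch(parts[1].strip()):
                logger.warning("%s:%d: malformed lexicon row skipped", path, lineno)
                continue
            lex.add(parts[0], parts[1].strip())
    return lex


def build_lexicon(rows: Iterable[tuple[str, str]]) -> CompoundLexicon:
    """Build a lexicon directly from (name, compound_id) pairs."""
    lex = CompoundLexicon()
    for name, cid in rows:
        lex.add(name, cid)
    return lex


def tag(lexicon: CompoundLexicon, sentence: str) -> list[CompoundMatch]:
    """Greedy leftmost-longest dictionary matching over a sentence.

    Matching is case-insensitive; a hit must be flanked by token
    boundaries (start/end of string or a non-alphanumeric character) on
    both sides, which keeps "iron" out of "ironic".  Returned matches are
    sorted by start and never overlap.
    """
    lower = sentence.lower()
    n = len(lower)
    matches: list[CompoundMatch] = []
    i = 0
    while i < n:
        if i > 0 and lower[i - 1].isalnum():
            i += 1
            continue
        node = lexicon._root
        best_end = -1
        best_id = None
        j = i
        while j < n:
            nxt = node.children.get(lower[j])
            if nxt is None:
                break
            node = nxt
            j += 1
            if node.compound_id is not None and (
                j == n or not lower[j].isalnum()
            ):
                best_end, best_id = j, node.compound_id
        if best_id is not None:
            matches.append(
                CompoundMatch(best_id, sentence[i:best_end], i, best_end)
            )
            i = best_end
        else:
            i += 1
    return matches
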