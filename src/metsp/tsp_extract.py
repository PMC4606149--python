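"""End-to-end transporter-substrate pair extraction.

For each UniProt entry the annotation sentences are scored by the
trained sentence classifier; every sentence at or above the decision
threshold that also contains a dictionary compound hit contributes
candidate (accession, compound) pairs.  Pairs are deduplicated across
sentences, keeping the maximum supporting score and all evidence
sentences, and optionally filtered against a set of already-known pairs.
"""

from __future__ import annotations

import json
import logging
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .classifiers import SentenceClassifier
from .compound_lexicon import CompoundLexicon
from .uniprot_io import (
    ACCESSION_RE,
    FieldFlag,
    KnownTSP,
    UniProtEntry,
    extract_sentences,
    parse_flatfile,
)

logger = logging.getLogger(__name__)

__all__ = ["TSPRecord", "extract_tsps", "fetch_entries", "write_tsp_tsv"]

UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{accession}.txt"


@dataclass
class TSPRecord:
    """One extracted transporter-substrate pair with its evidence."""

    accession: str
    compound_id: str
    compound_surface: str
    score: float
    sentences: list[tuple[FieldFlag, str]] = field(default_factory=list)
    novel: bool = True

    def as_dict(self) -> dict:
        return {
            "accession": self.accession,
            "compound_id": self.compound_id,
            "compound_surface": self.compound_surface,
            "score": self.score,
            "novel": self.novel,
            "sentences": [[f.value, t] for f, t in self.sentences],
        }


def extract_tsps(
    entries: Iterable[UniProtEntry],
    model: SentenceClassifier,
    lexicon: CompoundLexicon,
    t: float = 0.5,
    known_tsps: set[KnownTSP] | None = None,
    remove_known: bool = False,
) -> list[TSPRecord]:
    """Score annotation sentences and emit compound-bearing pairs.

    A pair is emitted when at least one of the entry's sentences scores
    >= ``t`` and the lexicon tags a compound in it.  The pair score is
    the maximum over its supporting sentences; ``novel`` is False for
    pairs present in ``known_tsps`` and those are dropped entirely when
    ``remove_known`` is set.  Output is sorted by accession, then
    descending score.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    if model.pipeline.vocabulary is None:
        raise ValueError("classifier is untrained (no vocabulary)")
    known = known_tsps or set()

    found: dict[tuple[str, str], TSPRecord] = {}
    for entry in entries:
        sentences = extract_sentences(entry)
        if not sentences:
            continue
        scores = model.score_many([s.text for s in sentences])
        for sent, score in zip(sentences, scores):
            if score < t:
                continue
            for match in lexicon.tag(sent.text):
                key = (entry.accession, match.compound_id)
                rec = found.get(key)
                if rec is None:
                    rec = TSPRecord(
                        accession=entry.accession,
                        compound_id=match.compound_id,
                        compound_surface=match.surface,
                        score=float(score),
                    )
                    found[key] = rec
                elif score > rec.score:
                    rec.score = float(score)
                    rec.compound_surface = match.surface
                evidence = (sent.field_flag, sent.text)
                if evidence not in rec.sentences:
                    rec.sentences.append(evidence)

    records: list[TSPRecord] = []
    for rec in found.values():
        is_known = KnownTSP(rec.accession, rec.compound_id) in known
        if is_known and remove_known:
            continue
        rec.novel = not is_known
        records.append(rec)
    records.sort(key=lambda r: (r.accession, -r.score, r.compound_id))
    return records


def fetch_entries(
    accessions: Sequence[str],
    cache_dir: str | Path,
    cache_only: bool = False,
    timeout: float = 30.0,
) -> tuple[list[UniProtEntry], dict[str, str]]:
    """Fetch flat-file records per accession, caching text on disk.

    Returns (entries, failures) where ``failures`` maps each accession
    that could not be resolved to a reason; a failed accession never
    aborts the batch.  With ``cache_only`` the network is never touched,
    which is how tests and offline runs operate.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    entries: list[UniProtEntry] = []
    failures: dict[str, str] = {}
    for acc in accessions:
        acc = acc.strip()
        if not acc:
            continue
        if not ACCESSION_RE.fullmatch(acc):
            failures[acc] = "malformed accession"
            continue
        path = cache / f"{acc}.txt"
        if not path.exists():
            if cache_only:
                failures[acc] = "not in cache (network disabled)"
                continue
            try:
                with urllib.request.urlopen(
                    UNIPROT_URL.format(accession=acc), timeout=timeout
                ) as resp:
                    path.write_bytes(resp.read())
            except (urllib.error.URLError, OSError) as exc:
                failures[acc] = f"fetch failed: {exc}"
                continue
        parsed = parse_flatfile(path)
        if not parsed:
            failures[acc] = "no parseable record"
            continue
        entries.extend(parsed)
    return entries, failures


def write_tsp_tsv(
    records: Sequence[TSPRecord],
    path: str | Path,
    include_scores: bool = True,
    include_pairs: bool = True,
) -> None:
    """Write extraction results as a TSV with one pair per row."""
    cols = ["accession", "compound_id", "compound_surface"]
    if include_scores:
        cols.append("score")
    cols += ["novel", "n_sentences", "evidence"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        if not include_pairs:
            return
        for r in records:
            row = [r.accession, r.compound_id, r.compound_surface]
            if include_scores:
                row.append(f"{r.score:.6f}")
            evidence = " | ".join(f"{f.value}:{t}" for f, t in r.sentences)
            row += [str(r.novel).lower(), str(len(r.sentences)), evidence]
            fh.write("\t".join(row) + "\n")


def write_run_report(
    path: str | Path,
    records: Sequence[TSPRecord],
    failures: dict[str, str] | None = None,
    extra: dict | None = None,
) -> None:
    """JSON run report: pair counts, per-accession failures, settings."""
    report = {
        "n_pairs": len(records),
        "n_novel": sum(1 for r in records if r.novel),
        "accessions": sorted({r.accession for r in records}),
        "failures": failures or {},
    }
    if extra:
        report.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
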