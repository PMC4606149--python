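"""Synthetic test-data generators.

Everything the package reads — UniProt flat files, compound lexicons,
labeled positive/unlabeled training files, known-pair files — can be
generated here from a seed, with the ground truth returned alongside, so
the whole repository builds and tests offline.

The generated language is deliberately stylized UniProt-ese: positive
sentences combine a transport verb phrase with one or two dictionary
compound names; true negatives use non-transport verbs (binding,
catalysis, regulation) and may still mention compounds, so that the
classifier — not the dictionary tagger alone — has to separate the
classes.  Morphological variants of the transport vocabulary
(transport / transporter / transporting / cotransporter) are included on
purpose so Porter-stem collapsing is exercised, and the filler text is
drawn from a fixed word list containing ordinary English function words
so stop-word removal is exercised too.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .compound_lexicon import CompoundLexicon, build_lexicon
from .uniprot_io import (
    FieldFlag,
    KnownTSP,
    LabeledInstance,
    UniProtEntry,
    format_flatfile,
    write_known_tsps,
    write_training_file,
)

__all__ = [
    "CorpusSpec",
    "DEFAULT_COMPOUND_POOL",
    "default_lexicon_rows",
    "gen_pu_corpus",
    "gen_flatfile",
    "gen_lexicon",
    "write_workspace",
]

# (name, KEGG C-number) pairs; the sucrose synonym set and the worked
# examples (potassium, chloride, indoleacetate) carry their real ids.
DEFAULT_COMPOUND_POOL: list[tuple[str, str]] = [
    ("potassium", "C00238"),
    ("chloride", "C00698"),
    ("sucrose", "C00089"),
    ("glucose", "C00031"),
    ("sodium", "C01330"),
    ("calcium", "C00076"),
    ("glycine", "C00037"),
    ("glutamate", "C00025"),
    ("urea", "C00086"),
    ("citrate", "C00158"),
    ("serotonin", "C00780"),
    ("dopamine", "C03758"),
    ("indoleacetate", "C00954"),
    ("maltose", "C00208"),
    ("zinc", "C00038"),
    ("arginine", "C00062"),
    ("lactate", "C00186"),
    ("phosphate", "C00009"),
]

_SYNONYM_ROWS: list[tuple[str, str]] = [
    ("cane sugar", "C00089"),
    ("saccharose", "C00089"),
    ("d-glucose", "C00031"),
    ("amino acid", "C90001"),
]

DEFAULT_TRANSPORT_VERBS = [
    "transports", "transport", "cotransports", "uptake", "exchanges",
]

_POSITIVE_TEMPLATES = [
    "Transports {c} across the plasma membrane",
    "May transport {c} and {c2}",
    "Mediates the uptake of {c} into the cell",
    "Catalyzes the electrogenic exchange of {c} for {c2}",
    "Acts as a cotransporter of {c} with {c2}",
    "Sodium-independent transporter mediating {c} efflux",
    "Probably transporting {c} in the {w} epithelium",
    "High-affinity uptake of {c} by the {w} cells",
]

_NEGATIVE_TEMPLATES_COMPOUND = [
    "Binds {c} with high affinity",
    "Catalyzes the phosphorylation of {c}",
    "Catalyzes the hydrolysis of {c} to {c2}",
    "Synthesizes {c} from {c2} precursors",
    "Its activity is inhibited by {c}",
    "Stores {c} in the {w} granules",
]

_NEGATIVE_TEMPLATES_PLAIN = [
    "Involved in the regulation of {w} development",
    "Required for {w} assembly in the nucleus",
    "Plays a role in {w} signaling and the cell cycle",
    "Component of the {w} complex that represses transcription",
    "May be involved in {w} maintenance",
    "Acts as a scaffold for the {w} kinase",
]

_FILLER_WORDS = [
    "ribosome", "chromatin", "cytoskeleton", "spindle", "axon", "myelin",
    "kidney", "liver", "neuronal", "epithelial", "intestinal", "retinal",
    "mitochondrial", "lysosomal", "vesicle", "proteasome", "telomere",
    "centrosome", "cilium", "dendrite", "hepatic", "cardiac", "synaptic",
    "nuclear", "basolateral", "apical", "vacuolar", "endosomal",
    "microtubule", "collagen",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic positive/unlabeled training corpus.

    The default shape is a desk-scale model of the real training set:
    positives outnumbered roughly 1:1.25 by unlabeled sentences, with a
    20% planted-positive contamination of the unlabeled pool.
    """

    n_positive: int = 400
    n_unlabeled: int = 500
    contamination_rate: float = 0.2
    vocab_size: int = 30
    transport_verbs: tuple[str, ...] = tuple(DEFAULT_TRANSPORT_VERBS)
    compound_pool: tuple[tuple[str, str], ...] = tuple(DEFAULT_COMPOUND_POOL)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.n_positive > 0 and not self.compound_pool:
            raise ValueError("compound_pool must be nonempty to build positives")


def default_lexicon_rows() -> list[tuple[str, str]]:
    """The compound pool plus synonym rows, ready for a lexicon file."""
    return list(DEFAULT_COMPOUND_POOL) + list(_SYNONYM_ROWS)


def _fillers(spec: CorpusSpec) -> list[str]:
    return _FILLER_WORDS[: max(1, min(spec.vocab_size, len(_FILLER_WORDS)))]


def _two_compounds(rng: random.Random, pool) -> tuple[str, str]:
    c = rng.choice(pool)[0]
    c2 = rng.choice(pool)[0]
    return c, c2


def _positive_sentence(rng: random.Random, spec: CorpusSpec) -> str:
    c, c2 = _two_compounds(rng, spec.compound_pool)
    w = rng.choice(_fillers(spec))
    return rng.choice(_POSITIVE_TEMPLATES).format(c=c, c2=c2, w=w) + "."


def _negative_sentence(rng: random.Random, spec: CorpusSpec) -> str:
    w = rng.choice(_fillers(spec))
    if spec.compound_pool and rng.random() < 0.5:
        c, c2 = _two_compounds(rng, spec.compound_pool)
        return rng.choice(_NEGATIVE_TEMPLATES_COMPOUND).format(
            c=c, c2=c2, w=w
        ) + "."
    return rng.choice(_NEGATIVE_TEMPLATES_PLAIN).format(w=w) + "."


def _accession(rng: random.Random) -> str:
    return "P%05d" % rng.randrange(100000)


def gen_pu_corpus(
    spec: CorpusSpec,
) -> tuple[list[LabeledInstance], list[int]]:
    """Generate a labeled PU corpus and its hidden per-instance truth.

    Returns (instances, truth): positives first, then the unlabeled
    pool in which a ``contamination_rate`` fraction (rounded) is secretly
    positive-templated.  ``truth[i]`` is 1 when instance i expresses a
    real transport relationship, regardless of its visible label.
    """
    rng = random.Random(spec.seed)
    instances: list[LabeledInstance] = []
    truth: list[int] = []
    for _ in range(spec.n_positive):
        instances.append(
            LabeledInstance(
                "positive", _accession(rng), FieldFlag.CC,
                _positive_sentence(rng, spec),
            )
        )
        truth.append(1)
    n_contaminated = round(spec.contamination_rate * spec.n_unlabeled)
    hidden = [1] * n_contaminated + [0] * (spec.n_unlabeled - n_contaminated)
    rng.shuffle(hidden)
    for h in hidden:
        text = (
            _positive_sentence(rng, spec)
            if h
            else _negative_sentence(rng, spec)
        )
        instances.append(
            LabeledInstance("unlabeled", _accession(rng), FieldFlag.CC, text)
        )
        truth.append(h)
    return instances, truth


def gen_flatfile(
    n_entries: int,
    seed: int,
    compound_pool: list[tuple[str, str]] | None = None,
) -> tuple[str, set[tuple[str, str]]]:
    """Generate flat-file text plus the ground-truth pair set.

    Roughly 60% of the entries are transporters whose FUNCTION sentences
    name compounds with transport language — those (accession, C-number)
    pairs form the returned truth.  The remainder are non-transport
    proteins whose sentences may still mention compounds (binding,
    catalysis), which a correct pipeline must not extract.
    """
    pool = list(compound_pool or DEFAULT_COMPOUND_POOL)
    if not pool:
        raise ValueError("compound_pool must be nonempty")
    rng = random.Random(seed)
    spec = CorpusSpec(compound_pool=tuple(pool), seed=seed)
    entries: list[UniProtEntry] = []
    truth: set[tuple[str, str]] = set()
    used: set[str] = set()
    for _ in range(n_entries):
        acc = _accession(rng)
        while acc in used:
            acc = _accession(rng)
        used.add(acc)
        is_transporter = rng.random() < 0.6
        if is_transporter:
            de = [f"Solute carrier family {rng.randrange(1, 50)} "
                  f"member {rng.randrange(1, 15)}"]
            n_pos = rng.randrange(1, 3)
            sentences = []
            for _ in range(n_pos):
                sent = _positive_sentence(rng, spec)
                sentences.append(sent)
                for name, cid in pool:
                    # compound names are single tokens here, so a plain
                    # substring-with-boundary check recovers the truth
                    low = sent.lower()
                    k = low.find(name)
                    while k != -1:
                        before_ok = k == 0 or not low[k - 1].isalnum()
                        after = k + len(name)
                        after_ok = after >= len(low) or not low[after].isalnum()
                        if before_ok and after_ok:
                            truth.add((acc, cid))
                            break
                        k = low.find(name, k + 1)
            if rng.random() < 0.5:
                sentences.append(_negative_sentence(rng, spec))
            dr = ["transmembrane transport"]
        else:
            de = [f"Uncharacterized protein {acc}"]
            sentences = [
                _negative_sentence(rng, spec)
                for _ in range(rng.randrange(1, 3))
            ]
            dr = ["protein binding"] if rng.random() < 0.5 else []
        entries.append(
            UniProtEntry(
                accession=acc,
                de_lines=de,
                cc_function_texts=[" ".join(sentences)],
                dr_go_terms=dr,
            )
        )
    return format_flatfile(entries), truth


def gen_lexicon(compound_pool: list[tuple[str, str]] | None = None) -> CompoundLexicon:
    return build_lexicon(compound_pool or default_lexicon_rows())


def write_workspace(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete offline test workspace and return its file paths.

    Produces a UniProt-format input file, a compound lexicon, a labeled
    PU training file, a known-pair file (a sample of the flat-file
    truth), the full truth table, and an accession list.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    spec = CorpusSpec(seed=seed)
    instances, truth_labels = gen_pu_corpus(spec)
    training = out / "training.tsv"
    write_training_file(instances, training)

    lexicon_path = out / "compoundName.txt"
    with open(lexicon_path, "w", encoding="utf-8") as fh:
        for name, cid in default_lexicon_rows():
            fh.write(f"{name}\t{cid}\n")

    text, pair_truth = gen_flatfile(40, seed + 1)
    input_path = out / "input.txt"
    input_path.write_text(text, encoding="utf-8")

    known = {KnownTSP(a, c) for a, c in pair_truth if rng.random() < 0.5}
    known_path = out / "known_tsps.tsv"
    write_known_tsps(known, known_path)

    truth_path = out / "truth_pairs.tsv"
    write_known_tsps({KnownTSP(a, c) for a, c in pair_truth}, truth_path)

    accessions = sorted({a for a, _ in pair_truth})
    acc_path = out / "accessions.txt"
    acc_path.write_text("\n".join(accessions) + "\n", encoding="utf-8")

    return {
        "training": training,
        "lexicon": lexicon_path,
        "input": input_path,
        "known_tsps": known_path,
        "truth_pairs": truth_path,
        "accessions": acc_path,
    }
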