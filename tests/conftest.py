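import random

import pytest

from metsp.compound_lexicon import build_lexicon
from metsp.pu_train_eval import ClassifierConfig
from metsp.synthetic import CorpusSpec, gen_pu_corpus
from metsp.uniprot_io import FieldFlag, LabeledInstance


@pytest.fixture(scope="session")
def toy_lexicon():
    return build_lexicon(
        [
            ("potassium", "C00238"),
            ("chloride", "C00698"),
            ("sucrose", "C00089"),
            ("cane sugar", "C00089"),
            ("saccharose", "C00089"),
            ("indoleacetate", "C00954"),
            ("amino acid", "C90001"),
            ("acid", "C90002"),
            ("iron", "C90003"),
        ]
    )


@pytest.fixture(scope="session")
def pu_corpus():
    """The planted-truth study corpus: 400 positives, 500 unlabeled of
    which 100 (20%) are secretly positive."""
    spec = CorpusSpec(seed=11)
    instances, truth = gen_pu_corpus(spec)
    return spec, instances, truth


@pytest.fixture(scope="session")
def separable_corpus():
    """A small linearly separable labeled corpus: the positive class
    always contains a transport verb, the negative never does."""
    rng = random.Random(3)
    pos_words = ["transports", "uptake", "exchanges", "cotransports"]
    neg_words = ["binds", "phosphorylates", "represses", "cleaves"]
    fillers = ["potassium", "chromatin", "kidney", "vesicle", "glucose"]
    instances = []
    for i in range(20):
        w = rng.choice(pos_words)
        f1, f2 = rng.sample(fillers, 2)
        instances.append(
            LabeledInstance("positive", "P%05d" % i, FieldFlag.CC,
                            f"{w} {f1} across the {f2} membrane.")
        )
    for i in range(20):
        w = rng.choice(neg_words)
        f1, f2 = rng.sample(fillers, 2)
        instances.append(
            LabeledInstance("unlabeled", "Q%05d" % i, FieldFlag.CC,
                            f"{w} {f1} in the {f2} complex.")
        )
    return instances


@pytest.fixture(scope="session")
def maxent_config():
    return ClassifierConfig(kind="maxent", prior_variance=10.0)


@pytest.fixture(scope="session")
def relabel_run(pu_corpus):
    """Four relabeling iterations on the planted study corpus (shared
    across tests: the run is deterministic and moderately expensive)."""
    from metsp.pu_train_eval import iterate_relabel

    _, instances, _ = pu_corpus
    pos = [i for i in instances if i.label == "positive"]
    unl = [i for i in instances if i.label == "unlabeled"]
    return iterate_relabel(pos, unl, ClassifierConfig(), max_iter=4, seed=42)
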