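# Methods

## Problem and pipeline

The package extracts transporter–substrate pairs from UniProt/Swiss-Prot
records in four stages:

1. **Parsing** (`uniprot_io`). Of each flat-file record only the `AC`
   accessions, `DE` protein names, `CC -!- FUNCTION:` free-text blocks and
   `DR GO;` term names are retained; all other line types (sequence,
   features, organism, non-GO cross-references) are discarded before any
   text processing. Multi-line FUNCTION blocks are unwrapped with single
   spaces; GO term names are taken without the `P:`/`F:`/`C:` aspect prefix.
   The first `AC` token is the canonical accession; records without a valid
   accession are rejected with a warning rather than aborting the parse.
2. **Sentence extraction**. `DE` names and GO terms are short noun phrases
   and are emitted whole, one sentence each. FUNCTION prose is split on the
   boundary "period + whitespace + uppercase letter or digit", with a
   protected-token list (`e.g.`, `i.e.`, `et al.`, `sp.`, `cf.`, `ca.`,
   `vs.`, `etc.`, single letters, and similar) suppressing splits;
   decimals are inherently safe because a digit never follows ". " inside a
   number. This splitter is deterministic and dependency-free, which
   matters more for reproducibility than marginal gains on pathological
   prose — UniProt FUNCTION text is controlled, declarative English.
3. **Classification** (`text_features`, `classifiers`). Sentences become
   bag-of-stems count vectors (tokenize → stop-word filter → Porter stem →
   count against a frozen vocabulary). A maximum-entropy (two-class
   softmax) model scores P(positive | sentence); a multinomial Naïve Bayes
   model is available for comparison.
4. **Pair assembly** (`compound_lexicon`, `tsp_extract`). Sentences scoring
   at or above the threshold are scanned by a Trie dictionary tagger;
   every tagged compound yields a candidate pair. Pairs are deduplicated
   per entry with the maximum supporting score and all evidence sentences
   kept, flagged or filtered against a known-pair set, and written as TSV
   plus a JSON run report.

## Models

**Maximum entropy.** Parameters are a (2 × V) weight matrix and two free
biases. Training minimizes the negative conditional log-likelihood plus a
Gaussian prior ‖W‖²/(2σ²) (biases unpenalized), via L-BFGS from a zero
initialization with an analytic gradient. Because the loss depends only on
the weight difference between the two classes while the penalty is strictly
convex in their sum, the optimum is symmetric (w₊ = −w₋), which makes the
model exactly equivalent to binary L2 logistic regression with C = 2σ² —
the equivalence the test suite exploits for its independent oracle.

**Naïve Bayes.** Closed-form multinomial estimates: class priors from class
counts, P(word | class) = (count + α)/(total + αV).

**Positive–unlabeled relabeling.** With no curated negatives, unlabeled
sentences stand in for the negative class. Each iteration trains on the
current split, scores the unlabeled pool, and promotes sentences with
score ≥ t to the positive set; iteration stops when the number moved drops
to `stop_delta` (default 0) or after `max_iter` (default 4) rounds, after
which the loop is expected to have settled. Promoting with the shared
decision threshold t, rather than a separately tuned one, keeps the loop a
single-parameter procedure. If a round empties the unlabeled pool the run
aborts with an error carrying the traces so far, since no negative class
remains to train on.

## Parameters

| parameter | default | meaning |
|---|---|---|
| σ² (`prior_variance`) | 1.0 | Gaussian prior variance on maxent weights; smaller shrinks scores toward 0.5 |
| α (`alpha`) | 1.0 | Laplace smoothing of NB word likelihoods |
| t (`threshold`) | 0.5 | decision threshold on P(positive); inclusive (score = t is positive), so the default classifies an exactly uninformative sentence as positive, favouring recall |
| `tol` | 1e-6 | gradient infinity-norm convergence tolerance |
| `max_iter` (training) | 500 | L-BFGS iteration cap |
| `max_iter` (relabeling) | 4 | relabeling rounds |
| k (CV) | 10 | folds, stratified by class |
| CV `seed` | 42 | fold-assignment seed; fold assignment is a pure function of (seed, labels) |

Feature values are raw token counts (not binary presence). Numeric tokens
are kept because compound names contain digits. The stop-word list is a
SMART-style English list shipped as a plain-text data file; any file of one
word per line can replace it.

## Evaluation choices

Cross-validation is stratified with seeded shuffling and contiguous
blocks; every instance is validated exactly once; the per-fold vocabulary
is rebuilt from the training split only, so validation text never leaks
into the features. Aggregate precision/recall/accuracy are computed from
the summed confusion counts (micro-averaging). ROC curves sweep the
distinct score values in descending order with tied scores grouped into a
single step; AUC is the trapezoidal area, which then equals the
Mann–Whitney U statistic scaled by n⁺n⁻.

## What the synthetic generator does and does not emulate

`synthetic.gen_pu_corpus` emulates the structure of the real training set:
positive sentences combine a transport verb phrase with one or two
dictionary compound names; true negatives use binding/catalysis/regulation
verbs and mention compounds half the time, so the tagger alone cannot
separate the classes; a configurable fraction of the unlabeled pool is
secretly positive-templated and the hidden truth is returned for oracle
evaluation. The default corpus is 400 positives and 500 unlabeled with 20%
contamination — a desk-scale model of the real positive:unlabeled ratio.
Morphological variants of the transport vocabulary and ordinary English
function words are included so stemming and stop-word removal are
genuinely exercised. `gen_flatfile` wraps the same sentence language in
well-formed flat-file records (≈60% transporters) and returns the
ground-truth pair set, recovered by an independent substring-with-boundary
scan rather than by the Trie tagger under test.

The generator does **not** emulate real UniProt linguistic diversity:
hedged or negated statements ("does not transport X"), substrates named
only by class ("organic anions"), cross-sentence coreference, or noisy
chemical synonymy. Passing the planted-truth and end-to-end checks
therefore demonstrates that the machinery is correct on text the model's
assumptions fit, not that the reported synthetic metrics transfer to live
UniProt releases.

## Numerical and degenerate-input conventions

- Zero weights (or an empty feature vector) score exactly 0.5 under the
  maxent model; an all-stop-word sentence vectorizes to the empty vector,
  which is legal everywhere.
- Precision and recall are defined as 0 when their denominator is 0.
- The penalized objective is checked finite every evaluation; a non-finite
  value raises naming the offending feature index.
- Duplicate lexicon names with conflicting compound ids keep the first id
  and log the conflict (the dictionary assumes name→id uniqueness).
- Model serialization is JSON with full-precision floats; a save/load
  round trip changes scores by ≤ 1e-12.
- Sub-seeds derived from a run seed stay below 2³¹.

## Known limitations

- One sentence is one evidence unit; relations spanning sentences are
  missed.
- A compound name absent from the lexicon is invisible, and genuinely
  ambiguous names (one name, several C-numbers) are resolved
  first-come-first-kept rather than contextually.
- The relabeling loop can only add positives; a mislabeled promotion is
  never revisited.
- The original toolkit's exact optimizer settings and prior are not
  recoverable, so metrics on the historical curated training set may shift
  slightly under this implementation's defaults.
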