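# metsp

Text mining of **transporter–substrate pairs (TSPs)** from semistructured
UniProt annotation text.

Membrane transporters move metabolites, drugs and ions across membranes, but
which compound a given transporter actually carries is scattered through
free-ish annotation prose rather than stored as structured data. This package
reads UniProt/Swiss-Prot records, keeps the three informative annotation
fields — protein names (`DE`), free-text `FUNCTION` comments (`CC`) and Gene
Ontology cross-references (`DR`) — splits them into sentences, and decides for
each sentence whether it expresses a real transport relationship. Compound
names in accepted sentences are mapped to KEGG LIGAND identifiers
(C-numbers) with a dictionary tagger, yielding scored
`(transporter accession, compound id)` pairs for downstream curation and
metabolic-network reconstruction.

## Method

Sentences are represented as a **bag of stems**: lowercase tokens, minus a
stop-word list, Porter-stemmed (so *transporter*, *transporting* and
*transported* all become `transport`), counted against a vocabulary frozen at
training time.

The core classifier is a **maximum-entropy model** — the two-class softmax

&nbsp;&nbsp;&nbsp;&nbsp;P(y | x) = exp(w&#8339;·x + b&#8339;) / Σ&#8342; exp(w&#8342;·x + b&#8342;)

trained by maximizing the conditional log-likelihood penalized by a Gaussian
prior ‖W‖²/(2σ²), with a deterministic quasi-Newton optimizer from a zero
start. A multinomial Naïve Bayes model with Laplace smoothing is provided for
comparison.

Only positive examples and an *unlabeled* sentence pool are available for
training (**positive-unlabeled learning**). The unlabeled pool is first used
as the negative class; then an iterative relabeling loop trains, scores the
unlabeled pool, promotes every sentence with P(positive) ≥ t into the
positive set, and repeats (by default up to four iterations or until nothing
moves). Performance is measured by stratified 10-fold cross-validation with
micro-averaged precision/recall/accuracy and a tie-aware ROC/AUC.

Compound tagging uses a character **Trie** over normalized compound names and
synonyms with greedy leftmost-longest, token-boundary-guarded matching, so
`amino acid` beats `acid` and `iron` never fires inside `ironic`. Synonyms
(e.g. *sucrose*, *cane sugar*, *saccharose*) collapse onto one C-number.

## Worked example

Everything needed to try the tool can be generated offline:

```sh
metsp fixtures --seed 5 demo                 # synthetic workspace
metsp train --training demo/training.tsv demo/model.json
metsp extract --model demo/model.json --lexicon demo/compoundName.txt \
      -f demo/query.txt -t 0.5 demo/pairs.tsv
```

With `demo/query.txt` holding a solute-carrier record whose FUNCTION line
reads *"May transport potassium and chloride."*, the run prints
`2 pair(s) written to demo/pairs.tsv` and the TSV contains:

```
accession  compound_id  compound_surface  score
A0AV02     C00238       potassium         0.686516
A0AV02     C00698       chloride          0.686516
```

Both compounds in the sentence are emitted as candidate substrates with the
sentence's classifier score (P(positive) = 0.69 from this demo model); which
candidate is the true substrate is a downstream curation decision. The
`novel` column flags pairs absent from a known-pair file (`--known-tsps`);
`-n` removes known pairs instead, and raising `-t` trades recall for
precision. `metsp cv` and `metsp relabel` expose the evaluation harness and
the PU relabeling loop on any 4-column training file
(`label<TAB>accession<TAB>field flag<TAB>sentence`).

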