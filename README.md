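# olipred

Protein-specific prediction of RNA-binding-protein (RBP) target
transcripts from 3'UTR sequence, motif and secondary-structure features.

RBPs steer the post-transcriptional life of mRNAs, and each protein binds
its own repertoire of transcripts. Given experimentally derived bound
(positive) and non-bound (negative) 3'UTR sets for one protein, `olipred`
trains a linear support-vector classifier for that protein and scores new
sequences. It is aimed at computational biologists who have CLIP-style
target sets and want protein-specific *in silico* target predictions, or
who want a clean, leakage-safe harness for evaluating RNA sequence
encodings.

## The method

Three nested feature encodings of an RNA sequence b₁…bₙ:

| schema    | dim | features                                                        |
|-----------|-----|-----------------------------------------------------------------|
| `oli`     | 256 | counts of all 4⁴ tetranucleotides                               |
| `olimo`   | 266 | oli + the 10 highest PSSM motif scores                          |
| `olimoss` | 525 | olimo + folding energy, stem density, stem count + 256 binary tetranucleotide-accessibility features |

The motif score of the length-m window at offset i is the windowed PSSM
sum  score(i) = Σ_{k=1..m} pssm(b_{i+k}, k).  Accessibility marks a
tetranucleotide occurring inside a run of ≥ 4 unpaired bases of a
dot-bracket structure.

Training folds are rebalanced with SMOTE (synthetic positives interpolated
between nearest neighbours), the SVM penalty C is grid-searched by Matthews
correlation coefficient in an inner cross-validation, and evaluation is a
stratified 10-fold cross-validation in which motif PSSMs are rebuilt from
each fold's training positives — never from test records. See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

Generate a synthetic PUM2-like dataset (planted UGUAUAUA motifs), run a
3-fold cross-validation, train and apply a model:

```sh
olipred generate --out-dir demo --seed 7
olipred eval --pos demo/positives.fasta --neg demo/negatives.fasta \
             --schema oli --folds 3 --seed 7 --report-out demo/cv.tsv
olipred train --pos demo/positives.fasta --neg demo/negatives.fasta \
              --schema oli --seed 7 --model-out demo/oli.model.json
olipred predict --model demo/oli.model.json --fasta demo/positives.fasta \
                --out demo/pred.tsv
```

The `eval` step prints a one-line summary such as

```
protein=cli schema=oli folds=3 mean_auc=0.691±0.058 pooled_auc=0.692 mean_precision=0.502
```

meaning: over 3 cross-validation folds the mean area under the ROC curve
was 0.691 (sd 0.058 across folds), the AUC of the pooled out-of-fold scores
was 0.692, and on average half the sequences predicted bound (score
≥ 0.5) truly were. `demo/cv.tsv` holds the per-fold confusion counts, AUC,
precision, MCC and the C each fold's grid search chose; `demo/pred.tsv` is
an (id, score, label) table with scores in [0,1].

The same machinery is available as a library (`olipred.run_cv`,
`olipred.train`, `olipred.encode_dataset`, …), which additionally exposes
per-fold PSSM providers, negative-resampling confidence intervals,
information-gain feature ranking, Wilcoxon method comparison and
cross-protein sensitivity matrices.

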