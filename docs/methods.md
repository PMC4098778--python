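# Methods

## The prediction problem

An RNA-binding protein (RBP) recognizes only a subset of the transcripts it
could physically encounter. Given an experimentally derived set of bound
3'UTRs (positives) and a set of non-bound or randomly chosen 3'UTRs
(negatives), `olipred` trains **one classifier per protein** that scores a
new 3'UTR's probability of being bound. Protein-specific models are the
point: different RBPs use different recognition modes (sequence motifs,
structure, composition), so a single generic RNA–protein model blurs
exactly the signal one wants to capture.

## Feature representations

Three nested encodings of a candidate RNA sequence b₁b₂…bₙ over {A,C,G,U}:

**oli (256 features).** The count of every tetranucleotide (4⁴ = 256 words,
ordered lexicographically AAAA … UUUU), from a sliding window of width 4 and
step 1. Windows containing a non-ACGU symbol (N and other IUPAC ambiguity
codes survive I/O) are skipped rather than zero-scored, so ambiguity never
masquerades as signal. Counts are **unnormalized by default**: dividing by
sequence length dilutes the absolute occurrence counts that carry the
binding signal, and normalization is kept only as a flag
(`normalize=True`) for comparisons with frequency-based encoders.

**olimo (266 features).** oli plus the 10 highest motif scores on the
sequence. A motif is a position-specific scoring matrix (PSSM) pssm(b, k),
b ∈ {A,C,G,U}, k = 1..m; the score of the window at 0-based offset i is

    score(i) = Σ_{k=1..m} pssm(b_{i+k}, k)

Regulated UTRs tend to carry more binding sites than chance predicts, so
the ten best windows, not just the best one, describe the binding-site
content. When several PSSMs are supplied, all defined window scores are
pooled before taking the top ten (motif discovery may return a variable
number of motifs, so a fixed per-motif allocation is not well defined); a
`per_motif` flag provides the alternative reading that interleaves each
motif's best scores. Sequences with fewer than ten defined windows are
padded by repeating the minimum observed score — not −∞ — to keep the
feature scale bounded for the linear kernel. PSSM scoring uses **log-odds
matrices by default**; letter-probability matrices (e.g. from MEME minimal
files) are converted with `Pssm.to_log_odds`, and either kind can be scored
directly via configuration since the windowed sum is defined for both.

**olimoss (525 features).** olimo plus secondary structure, taken from a
dot-bracket prediction (e.g. RNAfold output; folding is consumed, never
recomputed):

1. folding energy (kcal/mol, from the input);
2. stem density — the fraction of paired positions;
3. number of stems, where a stem is a *maximal helix*: a maximal run of
   stacked consecutive pairs (i,j), (i+1,j−1), …; a bulge breaks a stem.
   This is the standard helix convention (the alternative — counting
   bulge-interrupted helices as one stem — is not implemented);
4. 256 binary accessibility features: the bit for tetranucleotide t is 1
   iff some occurrence of t lies entirely inside a run of ≥ 4 consecutive
   unpaired nucleotides. Single-stranded stretches are what a protein
   surface can reach; double-stranded ones are occluded.

Feature order is frozen and versioned (a hash of the schema layout stored
with every saved model), so persisted models fail loudly rather than
silently mis-align after a layout change.

## Class balancing

Bound sets are small (tens to hundreds) against thousands of negatives.
Training folds are rebalanced with SMOTE: each synthetic positive is
x + u·(x_nn − x) with u ~ U[0,1], x a positive and x_nn one of its
k = 5 nearest positive neighbours (Euclidean distance, raw feature scale —
no standardization, so the interpolation happens in the same space the
linear kernel sees). Default target is parity with the negatives.
Interpolated accessibility bits are left fractional: re-thresholding would
be an extra transformation with no principled threshold. Synthetic rows are
flagged and the cross-validation driver asserts they never reach a test
fold. k is clamped (with a warning) when the positive set is smaller than
k + 1.

## Classifier and model selection

A linear support-vector machine per protein — linear only, because SMOTE
balances in input space, and only for the linear kernel is the input space
the kernel feature space. Within each training fold a grid search over the
penalty C picks the value with the highest mean Matthews correlation
coefficient (MCC; defined as 0 when its denominator vanishes) in an inner
5-fold stratified cross-validation; ties go to the smallest C. The default
grid spans 2⁻⁵ … 2¹⁵ at the coarse conventional spacing (powers of 16, six
values): on converged fits, held-out performance is flat across this range,
so a finer grid buys selection nothing at twice the cost; any grid can be
supplied via `GridSpec.c_values`. Fits use the deterministic primal solver
(capped at 1000 iterations; the cap only bites at the extreme C values).
The final model is refit on the whole training fold at the winning C.

Scores on [0,1] come from Platt-style logistic calibration fit on the
inner-CV out-of-fold decision values; the hard label is +1 iff
score ≥ 0.5 (the boundary score 0.5 labels positive).

## Evaluation protocol

Stratified 10-fold cross-validation (stratification prevents empty-class
folds on unbalanced data; plain 10-fold is the unstratified limit). Per
fold, *every* training artifact derives from training records only:

* PSSMs are built from that fold's positive **training** sequences only —
  the `pssm_source` callable receives exactly those sequences, and an audit
  trail records the ids it saw;
* SMOTE runs on the training fold only;
* the test fold is scored untouched, each record exactly once out-of-fold.

Violations raise a protocol error rather than a warning.

Metrics: AUC as the Mann–Whitney statistic (ties counted ½ — identical to
the trapezoidal area under the pooled ROC), precision at score threshold
0.5 (defined as 0, flagged, when nothing is predicted positive), MCC, and
pooled out-of-fold ROC/PR curves (per-fold curves remain available from the
per-fold results). Methods are compared by the two-sided Wilcoxon
signed-rank test on paired per-protein AUCs at α = 0.01, zero differences
dropped. Confidence intervals for an AUC come from repeating the entire
cross-validation over disjoint redraws of the negative pool (10 draws by
default) and taking a Student-t interval over the draw AUCs — the interval
construction is t-based because only the confidence level, not the
construction, is canonical for so few draws.

Feature importance uses information gain: each real-valued feature is
discretized at its single best threshold (scanned over midpoints of sorted
unique values) and IG = H(label) − H(label | split). Best-single-threshold
was chosen over a median split because count features are heavily skewed;
the threshold scan is exact and deterministic.

Cross-protein specificity: each protein's model applied to every other
protein's positive set gives a sensitivity matrix; diagonal entries are
resubstitution estimates unless out-of-fold sensitivities are supplied,
and resubstitution optimism is therefore documented rather than hidden.

## Synthetic data: what it emulates, and what it does not

The generator emulates a PAR-CLIP-style training set for one protein:

* positives: background sequences in which a fraction `plant_prob` (default
  0.9) carry 1–3 instances of the binding motif (default consensus
  UGUAUAUA, the PUM2 family), each instance mutated per base at
  `mutation_rate` (default 0.05). Bound UTRs typically contain more than
  one site, hence the 1–3 instances;
* negatives: i.i.d. background. Base composition defaults to AU-rich
  (A 0.30, C 0.20, G 0.20, U 0.30), as in human 3'UTRs;
* lengths uniform on 200–1500 nt, the scale of real 3'UTR sets;
* benchmark size 400 positives / 800 negatives — large enough for stable
  10-fold estimates, small enough to run on a desk machine.

`structure_mode="hairpin-toy"` emits schematic structures: every planted
motif sits in the unpaired loop of a 5-bp hairpin, one decoy accessible
loop (8 nt of background) is placed per sequence, and the remaining span
folds into filler helices whose loops are shorter than 4 nt. These
structures exercise the accessibility logic; they are **not**
thermodynamic, and their energies are a schematic −1.8 kcal/mol per pair
plus noise.

What passing on this benchmark shows: the encoders, balancing, model
selection and leakage-safe protocol recover a planted signal of realistic
strength. What it does not show: performance on real CLIP data, where
negatives share expression biases with positives, motif instances cluster,
and secondary structure is thermodynamic rather than schematic.

`pssm_from_sites` (position-wise frequencies with pseudocount 0.5,
converted to log-odds) stands in for de novo motif discovery as the
per-fold PSSM provider on synthetic data, where the planted sites of the
training positives are known; it is a count-matrix builder, not a motif
finder.

## Numerical choices and degenerate inputs

* Sequences shorter than 4 nt encode to all-zero count vectors with a
  warning; sequences shorter than a motif contribute no windows.
* PSSM windows containing ambiguity codes score NaN and are excluded from
  top-k selection.
* Probability→log-odds conversion floors probabilities at 10⁻⁴ to avoid
  −∞ cells.
* MCC with a zero denominator is 0; AUC with a single class present is an
  error, not a default.
* All randomness flows from explicit integer seeds (NumPy `default_rng`);
  per-fold seeds are drawn from a master generator so that fold work is
  reproducible yet decorrelated. Identical seeds give byte-identical
  datasets, models and reports.

## Known limitations

* Motif discovery itself is out of scope: the tool consumes PSSMs (MEME
  minimal format). The CLI's `--pssm` option scores a *static* motif file
  in every fold; fully per-fold discovery requires the library's
  `pssm_source` callable.
* Thermodynamic folding is out of scope; structures are inputs, with a thin
  adapter for an external RNAfold-compatible program.
* Undersampling and class-weight balancing are not implemented
  (oversampling to parity only).
* Accessibility is sequence-window-based, not solvent-accessibility-based.
* On the synthetic benchmark the composition-only encoder (oli) is limited
  by design: with long, length-variable, AU-rich sequences, tetranucleotide
  counts carry heavy background variance against a few planted instances,
  and a linear model recovers only part of the planted signal (mean CV AUC
  ≈ 0.73 under default conditions). The motif-aware olimo reaches ≈ 0.83;
  notably, the best single motif score alone separates at ≈ 0.88, so
  concatenating the ten motif scores with 256 raw counts under one shared
  regularizer costs measurable dilution — a property of the encoder
  definition, not of the fit (held-out AUC is flat across the whole C
  grid on converged fits).
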