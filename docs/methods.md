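# Methods

## Problem and model

Given two predicted proteins from a de novo transcriptome assembly plus
their expression levels, decide whether the pair descends from one gene
(alternative-splicing isoforms, the negative class) or from two duplicated
genes (paralogs, the positive class).  The classifier is feature-based:
a pairwise global alignment and the expression table are reduced to four
numbers (SS, ICCB, MMF, ELD), a hard similarity filter (TZ) removes
unclassifiable pairs, and a supervised model ranks the rest.

### Alignment

The builtin aligner is affine-gap global Needleman–Wunsch (Gotoh), via
`Bio.Align.PairwiseAligner`, with BLOSUM62 and BLAST-conventional
penalties: a gap of length *k* costs `gap_open + k·gap_extend` = 11 + *k*.
Terminal gaps are penalized deliberately: truncated/fragmented transcripts
are the central difficulty, and free end gaps would hide them.  Among
co-optimal alignments the aligner's canonical first traceback is returned,
so identical inputs always give identical alignments; the exact tie-break
order among co-optimal paths is the library's, not an independent
guarantee.  An external-command hook (`--aligner external`, default
template `mafft-fftnsi {input}`) lets users reproduce an existing MAFFT
pipeline bit-for-bit; it never falls back silently to the builtin path.
Alignments are computed per pair, not per family.

### Column classification and block convention

A column is a **match** iff both residues are non-gap, equal, and neither
is the ambiguity code X (X–X is a mismatch: ambiguity must not inflate
similarity).  Exactly one gap makes a **gap** column; gap–gap columns are
rejected.  For block counting, match columns are *identical* and
everything else (mismatch or gap) is *non-identical*; maximal runs of one
kind are blocks, so gaps merge with adjacent mismatches.  This is the only
convention under which the three alignment features are mutually
consistent on the same alignment — for a 32-column alignment with 20
matches in 11 blocks: SS = 20/32 = 0.625, ICCB = 1/11 ≈ 0.091,
MMF = (32 − 11)/32 ≈ 0.656 — and it makes the identity
`MMF = 1 − 1/(ICCB·L)` hold exactly, which the tests verify with rational
arithmetic.

SS uses the full alignment length (including gap columns) as the
denominator, for the same consistency reason.

### Twilight-zone filter

Protein pairs below ~20% identity sit in the twilight zone where homology
inference is unreliable; such pairs cannot be confidently called either
way.  The filter excludes pairs with SS strictly below 0.20 (the boundary
value 0.20 is kept).  Filtered pairs are reported `unclassifiable`, never
silently dropped from output.

### Expression level difference

ELD = log₂(|FPKM₁ − FPKM₂| + 1).  The log base and the +1 pseudocount are
implementation choices: the pseudocount keeps ELD defined and exactly 0
for equal expression, and since tree ensembles are invariant to monotone
feature transforms the choice cannot change RF behavior, only the SVM's
scaling (which is standardized anyway).  Any non-negative abundance unit
works; the interface says FPKM.

## Classifiers

* **Random forest** (primary): 500 trees, `mtry` = 4 variables per split.
  TZ is not a model input — after filtering it is constant — so the model
  sees exactly (ss, iccb, mmf, eld).  The paralog score is the forest's
  positive-class probability (the fraction of trees voting paralog, up to
  leaf-probability averaging).  Deterministic given its seed.
* **RBF-SVM** (comparison): features standardized to zero mean/unit
  variance on the training rows only.  (C, γ) chosen by maximizing 5-fold
  stratified cross-validated accuracy on the training data over a coarse
  21 × 19 grid (C: 10⁻⁵…10¹⁵, γ: 10⁻¹⁵…10³, decade spacing), followed by
  2 refinement rounds that re-grid one current grid-spacing either side of
  the optimum at 10× resolution.  Ties break toward smaller C, then
  smaller γ.  Degenerate CV folds are redrawn with the next seed (max 10
  attempts).  Scores are a fixed-slope logistic squash of the decision
  margin — ROC analysis needs only the ranking, so no Platt fitting.
  libsvm iterations are capped (5·10³) to bound runtime at extreme C; the
  cap only binds where the fit is hopeless anyway.

No class weighting: the validation protocol balances classes instead.

## Validation protocol

Each class is shuffled (seeded RNG) and halved; an odd class puts its
extra sample in the training half, keeping test folds balanced.  The
held-out half is dealt round-robin per class into 4 folds (sizes equal
±1, both classes in every fold).  The model trains once on the training
half; each fold yields a ROC curve (all distinct score thresholds,
trapezoidal integration — equal to the tie-corrected rank statistic) and
its AUC; the mean of the 4 AUCs is the headline number.  Confusion
metrics (accuracy, PPV, NPV, MCC) are computed per fold at the 0.5
threshold and reported per fold (mean ± SEM is the intended aggregation).
MCC with a zero denominator is reported as 0 with an `mcc_undefined`
flag.  Eligible rows are canonically sorted by pair key before splitting,
so results depend on the seed and never on input row order.

Model comparisons across matched datasets use the paired Wilcoxon
signed-rank test (statistic reported as the rank-sum of positive
differences); unpaired feature-distribution comparisons use the
Mann–Whitney U test.

## Synthetic benchmark

The generator emulates the *structure* the classifier exploits, not any
particular species:

| knob | default | rationale |
|------|---------|-----------|
| protein length | uniform 120–600 aa | typical predicted-CDS range after a 100-aa floor |
| paralog substitution rate | uniform 0.05–0.60 per site | spans recent duplicates to deep twilight-zone divergence |
| paralog indels | start prob 0.05/site, geometric mean length 3 | scattered short indels |
| isoform events | 1–2 of exon skip / mutually exclusive swap, 15–60 aa | contiguous structural differences |
| isoform scattered error | 0.005/site | assembly/sequencing noise |
| truncation | prob 0.15, removes 10–40% from one end | fragmented/misassembled transcripts |
| expression | gene log₂FPKM ~ N(2, 1.5); isoform pair = Beta(2,2) split of the gene total; paralogs drawn independently | correlated isoform vs independent paralog expression |

Substitutions are uniform over the 19 alternative residues (no rate
matrix): the features are composition-agnostic, so a realistic exchange
matrix would add complexity without changing what is being tested.

What the benchmark does **not** emulate: chimeric contigs, shared domains
between unrelated genes, family-level correlation between pairs, codon-
level evolution, and real expression noise.  Consequently the benchmark is
*much cleaner* than real assemblies: class-wise feature orderings match
the real-data picture (isoforms higher in SS/ICCB/MMF, paralogs higher in
ELD), but absolute performance saturates — the RF's half-split mean AUC is
≈ 0.999 here versus ≈ 0.90 reported on real transcriptomes.  Passing
tests therefore demonstrate correctness of the machinery and qualitative
fidelity of the signal, not real-data accuracy.  For the same reason the
RF and the SVM are statistically indistinguishable on the benchmark (both
≈ 1.0), so the suite asserts RF consistency (mean AUC ≥ 0.9 on every
seeded draw) and non-inferiority to a fixed-(C=1, γ=0.25) SVM rather than
a strict ordering that clean data cannot exhibit.

## Numerical and interface choices

* Gap character is `-`; `.` on input is normalized.  Pair lists are
  deduplicated on the sorted (id1, id2) key — direction is meaningless.
* Missing expression IDs raise, never default to 0.
* Problem sizes in the test suite: the standard benchmark draw is 2,000
  pairs; distributional checks use 500 pairs per class; null calibration
  shuffles labels over 20 seeds; the RF-vs-SVM sweep uses 10 draws of 300
  pairs; grid-search behavior is exercised on 200–400-row tables with the
  full 21 × 19 grid where the grid itself is under test and a reduced grid
  elsewhere.
* Exit codes: 0 success, 2 usage, 3 input error, 4 degenerate data.
* Optional input filters (minimum CDS length) exist but are off by
  default: upstream redundancy filtering is an assembly-pipeline concern,
  not a classifier concern.

## Known limitations

* The builtin aligner is not MAFFT; alignments (hence features) can differ
  slightly from an fftnsi-based pipeline.  Use the external hook for
  parity.
* The SVM grid search is O(|grid| · folds) SVC fits and is the slowest
  path in the package.
* Scores are rankings, not calibrated probabilities; the 0.5 call
  threshold is a convention.
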