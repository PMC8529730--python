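# picme

**Paralogs-vs-Isoforms Classifier** for de novo assembled transcriptomes.

De novo transcriptome assemblies (e.g. Trinity assemblies of non-model
organisms) contain many pairs of highly similar predicted proteins.  Two
very different biological situations produce such pairs:

* **isoforms** — alternative-splicing products of a single gene, which can
  look like "internal paralogs" when mutually exclusive exons are involved;
* **paralogs** — products of gene duplication that have diverged by point
  mutation and indels.

Telling them apart matters for comparative genomics, gene-family analysis
and expression studies, and is hard precisely where assemblies are worst:
fragmented and misassembled transcripts blur the alignment signal.

`picme` classifies a pair of proteins using five features computed from a
pairwise global alignment of the two sequences and their expression
levels:

| feature | definition |
|---------|------------|
| SS      | sequence similarity: matched columns / alignment length *L* |
| ICCB    | 1/*B*, the reciprocal of the number *B* of maximal runs of identical vs non-identical columns ("blocks") |
| MMF     | match–mismatch fraction: Σ(block length − 1)/*L* = (*L* − *B*)/*L* |
| TZ      | twilight-zone filter: pairs with SS < 20% are excluded as unclassifiable |
| ELD     | expression level difference: log₂(\|FPKM₁ − FPKM₂\| + 1) |

Gap columns count as non-identical and merge with adjacent mismatches into
single blocks, so the *B* blocks partition all *L* columns.  The four
numeric features (SS, ICCB, MMF, ELD) feed a **random forest** (500 trees,
mtry = 4; the primary model) or an **RBF-SVM** whose (C, γ) are chosen by
a two-stage grid search (21 × 19 decade-spaced points, C ∈ 10⁻⁵…10¹⁵,
γ ∈ 10⁻¹⁵…10³, refined at 10× resolution) maximizing internal
cross-validated accuracy.  Paralog is the positive class.

Validation follows a half-split protocol: each class is randomized and
halved; the model trains on one half, and the other half is split into
four class-stratified folds, each yielding a ROC curve and AUC; the four
AUCs are averaged.

Because real annotated RNA-seq datasets are not bundled, the package ships
a synthetic pair generator: isoform pairs share one gene sequence apart
from 1–2 contiguous structural events (exon skip / mutually exclusive exon
swap) plus sparse assembly noise and correlated expression; paralog pairs
are point-diverged duplicates with indels and independent expression; 15%
of pairs have one member truncated to mimic fragmented transcripts.

## Worked example (library)

```python
from picme.model import ParalogIsoformClassifier

m = ParalogIsoformClassifier.from_simulation(n_pairs=400, seed=11)
res = m.fit("rf", seed=11)
print(res.summary())
cv = res.evaluate()
print("fold AUCs:", [round(a, 4) for a in cv.fold_aucs])
print("mean AUC: ", round(cv.mean_auc, 4))
```

prints

```
Paralog/Isoform Classifier Results
========================================
method:           rf
seed:             11
eligible pairs:   400 (200 paralog / 200 isoform)
excluded (TZ):    0
features:         ss, iccb, mmf, eld
n_trees:          500
mtry:             4
seed:             11
feature importances (Gini):
  ss      0.0032
  iccb    0.3063
  mmf     0.6857
  eld     0.0048

fold AUCs: [1.0, 0.9968, 0.9984, 0.9936]
mean AUC:  0.9972
```

All 400 simulated pairs cleared the 20% twilight-zone cutoff; the forest
leans on block structure (MMF, ICCB) — isoform differences are contiguous,
paralog differences are scattered — and the held-out mean AUC of 0.997
means the ranking of paralog over isoform pairs is nearly perfect on this
clean benchmark.

## Command line

```bash
picme simulate --n 2000 --seed 42 --out-prefix sim
picme features --pairs sim.pairs.tsv --seqs sim.fasta --expr sim.expr.tsv \
               --out features.tsv
picme train    --features features.tsv --model rf --out model.joblib --seed 42
picme classify --model model.joblib --features features.tsv --out calls.tsv
picme evaluate --features features.tsv --model rf --seed 42 --out report.json
```

`calls.tsv` holds one row per pair with a paralog score in [0, 1] and a
call in {paralog, isoform, unclassifiable}; `report.json` holds the four
fold AUCs, their mean, and confusion metrics (accuracy, PPV, NPV, MCC) at
the 0.5 threshold.  Pre-aligned pairs (e.g. from MAFFT) can bypass the
builtin aligner via `--aligned-dir` or `--aligner external`.

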