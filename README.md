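# defpred

Machine-learning toolkit for recognizing **defensins** — short (10–60
residue), cysteine-rich, cationic host-defense peptides of the innate
immune system — and for telling them apart from other antimicrobial
peptides (AMPs) and from generic proteins. Defensins are promising
leads against drug-resistant pathogens, but they are hard to separate
from other AMPs by sequence similarity alone: both classes are short,
cationic and amphipathic. What does separate them is *composition* —
defensins are enriched in C, R, Y and G, while generic AMPs lean on K,
L and I — and this toolkit is built entirely on composition-based
sequence descriptors.

It is aimed at computational immunologists and peptide engineers who
want to (1) train and evaluate defensin classifiers from labeled FASTA
data, (2) scan longer proteins for defensin-like regions, and (3) rank
single-residue analogs of a peptide by predicted defensin character.

## Method

Each peptide `P` of length `L` is encoded as a fixed, named feature
vector built from eight composition families (8,610 columns in the
default registry):

* **AAC / DPC / TPC** — amino-acid, dipeptide and tripeptide
  composition: `AAC_r = 100 · n_r / L`, with overlapping k-mers over
  `L − k + 1` windows for k = 2, 3.
* **ATC / BTC** — atom (C,H,N,O,S fractions) and bond
  (total/hydrogen/single/double, per-residue mean) composition.
* **PCP** — composition of 13 physicochemical residue classes.
* **CTD** — composition, transition and distribution over seven
  three-group partitions of the alphabet (hydrophobicity, van der Waals
  volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility); 21 features per attribute.
* **PAAC** — Chou's pseudo-amino-acid composition with λ
  sequence-order correlation terms and weight w (defaults λ = 1,
  w = 0.05).

Training follows a fixed protocol: stratified 80/20 train/validation
split; an L1-penalized linear SVC (`C = 0.01`) keeps only features with
non-zero coefficients; a LightGBM ensemble ranks the survivors by split
count; the top-k (default 60) features feed a grid-searched classifier
(SVM, LR, RF, ET, KNN or MLP); performance is reported as five-fold
cross-validated and held-out Sens, Spec, Acc, MCC and AUROC, each tied
to its confusion counts:

```
Sens = 100·TP/P    Spec = 100·TN/N    Acc = 100·(TP+TN)/(P+N)
MCC  = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

A synthetic generator draws class-conditional peptides (i.i.d.
residues from per-class frequency profiles, lengths uniform on
[10, 60]) emulating the defensin/AMP/background contrasts, so the whole
pipeline is testable and calibratable without downloading curated data.

## Worked example

```python
from defpred import generate, run_pipeline

synth = generate("defensin_like", "amp_like", 200, seed=7)
result = run_pipeline(synth.dataset, top_k=30, seed=7)

print("selected features :", result.provenance["n_selected"])
print("top 5 ranked      :", result.top_features[:5])
```

Output:

```
selected features : 7
top 5 ranked      : ['PAAC1_R', 'ATC_H', 'AAC_C', 'AAC_K', 'CeTD_VW2']
chosen model      : SVM {'C': 1, 'g': 0.01, 'k': 'rbf'}
5-fold CV         : AUROC 0.961  MCC 0.795  Acc 89.7%
validation (20%)  : AUROC 0.970  MCC 0.827  Sens 95.0%  Spec 87.5%
```

The sparse selector reduces 8,610 descriptors to 7; the ranking puts
arginine and cysteine composition terms (`PAAC1_R`, `AAC_C`) near the
top — exactly the residues the defensin-like profile enriches — and the
grid-searched RBF SVM separates the two classes with held-out AUROC
0.97. `AAC_K` is informative in the other direction (lysine marks the
AMP-like class).

The same models drive the three applications:

```python
from defpred import predict, scan, design

results, errors = predict(result.bundle, peptides)       # score + label
windows = scan(result.bundle, protein, window=20)        # L−w+1 regions
analogs = design(result.bundle, parent)                  # 19·L ranked variants
```

or from the shell: `defpred gen-data | curate | featurize | select |
run-pipeline | predict | scan | design` (see `defpred --help`).

## Layout

| module         | contents                                             |
|----------------|------------------------------------------------------|
| `seqio`        | FASTA I/O, validation, curation, labeled datasets    |
| `descriptors`  | the eight composition feature families + registry    |
| `selection`    | SVC-L1 pruning, LightGBM split-count ranking, top-k  |
| `modeling`     | splits, six classifier families, grid search, metrics|
| `applications` | Predict / Scan / Design over a saved model bundle    |
| `classstats`   | Mann–Whitney composition contrasts, positional logos |
| `synthetic`    | class-conditional peptide generator and null control |
| `pipeline`, `cli` | end-to-end workflow and the `defpred` command     |

See `docs/methods.md` for modeling assumptions, parameter choices and
limitations.
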