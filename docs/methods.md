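# Methods notes

## Problem setting

Defensins are 10–60 residue, disulfide-stabilized host-defense peptides.
The toolkit frames their recognition as two binary tasks: defensin vs
other antimicrobial peptide (the hard contrast — both classes are short
and cationic) and defensin vs generic protein (the easy contrast). Both
use the same machinery; only the negative data differs. Models are
sequence-composition based by design: no secondary structure, surface
accessibility, disulfide connectivity or post-translational modification
information enters the features, so predictions degrade gracefully on
sequences where only the primary structure is known — and cannot exploit
structure where composition is uninformative.

## Input validation and curation

Sequences are restricted to the 20 standard residues; the ambiguity and
non-natural codes B, J, O, U, X, Z are invalid everywhere (strict parsing
rejects them, non-strict parsing tags them for counted removal). Default
curation keeps lengths 10–60 inclusive and deduplicates on exact sequence
identity, keeping the first occurrence — first-seen is the deterministic
tie-break; ids play no role in deduplication. Curation is idempotent and
its per-rule drop counts always sum to the number of records removed
(rule precedence per record: bad alphabet, then length, then duplicate).

## Descriptor registry

The encoder emits a versioned, ordered column registry (v1.0 = 8,610
columns); matrices are only comparable within one registry version, and a
test pins the registry's name-list hash. Choices worth recording:

* **Scales.** Count-based families (AAC, DPC, TPC, PCP, CTD) are
  percentages, matching how compositional contrasts are usually plotted;
  ATC and PAAC are fractions summing to 1 (PAAC's normalization is part
  of its definition). BTC defaults to the per-residue mean so values are
  length-comparable; the raw-sum variant is a flag.
* **CTD.** Classic whole-sequence composition/transition/distribution
  over the seven standard three-group partitions (shipped as
  `data/ctd_groups.json`, inspectable and overridable). Distribution
  breakpoints are 1-based positions of the first, 25%, 50%, 75% and last
  group member, as percent of length, computed with a ceiling index; an
  absent group contributes 0 at all five breakpoints. The feature prefix
  `CeTD` follows the naming convention established for these descriptors
  in peptide-classification feature suites.
* **PAAC.** Chou's formulation with properties hydrophobicity
  (Tanford/Chou), hydrophilicity (Hopp–Woods) and side-chain mass, each
  standardized over the alphabet with the population standard deviation.
  λ = 1 by default (the block is named `PAAC1_*`), w = 0.05. Every
  encoded peptide must be longer than λ.
* **ATC/BTC tables** are derived from the in-chain residue unit (free
  amino acid minus water): atom counts from the molecular formula, bond
  counts from the molecular graph (atoms − 1 + rings; double bonds =
  backbone carbonyl + side-chain carbonyls/imine/aromatic doubles).

## Selection and ranking

L1-penalized linear SVC (squared hinge, primal) with C = 0.01; selected
means strictly non-zero coefficient, no epsilon threshold. Features are
standardized first — L1 selection is scale-sensitive, and without it the
percent-scaled families would dominate the fraction-scaled ones. Smaller
C never selects more features (asserted over a C grid). On no-signal
data at small n the selector legitimately returns nothing; the pipeline
treats that as an error for final training but scores affected CV folds
at chance.

Ranking uses LightGBM split counts (100 trees, 31 leaves, single
thread, fixed seed): features sorted by the number of times they split
the data across all trees, ties broken lexicographically by name for
determinism; scores are reported normalized (sum 1) and cumulative. A
fit that makes no splits at all yields uniform scores with a warning.

## Protocol

Stratified 80/20 split (per-class validation count = round(0.2·class
size)) and stratified five-fold CV, both seed-deterministic.
Stratification is an explicit choice: it keeps balanced designs balanced
in small fixtures. Selection and scaling only ever see training data;
the default CV mode refits the entire selection stage inside each fold
(the honest estimate), while `frozen_selection=True` reuses the one
selection fitted on the full training split — cheaper, slightly
optimistic, and a common shortcut in published protocols.

Grid search maximizes mean CV AUROC with first-in-grid tie-breaking.
The shipped SVM grid spans γ ∈ {0.01, 0.1, 0.5, 1}: on a few dozen
standardized features, γ ≥ 0.5 makes the RBF kernel nearly diagonal and
the model memorizes, so the grid extends two decades below the
historically reported optima (which remain in the grid and can win
whenever the data favor them). The SVM trains with internal Platt-style
probability calibration so all six families emit [0, 1] scores
comparable at one threshold — decision values alone would break the
shared-threshold contract of Predict/Scan/Design.

Metrics: Sens/Spec/Acc in percent, MCC with the 0-on-zero-denominator
convention, AUROC by trapezoidal integration over all distinct
thresholds (equivalently, correctly-ordered positive/negative pairs with
half credit for ties). Single-class labels make AUROC undefined: the
threshold metrics are still computed and AUROC is reported as None with
a warning.

## Applications

Scan scores every length-w window (stride 1, default w = 20 — inside
the 10–60 training domain and near the defensin modal length); the
window score is **exactly** the standalone prediction of the
subsequence, which is why application-level scoring runs one row at a
time (batched BLAS products can differ in the last ulp across batch
shapes). Design enumerates all 19·L single-residue substitutions —
insertions, deletions and multi-site variants are out of scope — sorted
by score with (position, residue) tie-breaks. Two trained bundles
(defensin-vs-AMP and defensin-vs-protein) are selected by path; the
default decision threshold 0.5 is a stored, overridable model attribute.

## Class statistics

Per-residue composition contrasts use the Mann–Whitney U test: exact by
full enumeration of all C(n1+n2, n1) assignments when the smaller class
has ≤ 8 members (a permutation test on the actual values, hence valid
under ties; the two-sided p counts assignments with |U − n1·n2/2| at
least the observed), and the tie-corrected normal approximation
otherwise. Positional enrichment at the termini (depth 10) uses Fisher's
exact test per (position, residue) 2×2 table — exact for count data
where the classic two-sample-logo t-test is approximate. Tests are
two-sided, α = 0.05 uncorrected by default with an optional Bonferroni
flag; sequences shorter than the depth are excluded from the positional
analysis.

## Synthetic study conditions

The generator draws residues i.i.d. from per-class frequency vectors
(defensin-like: C 0.12, R 0.09, G 0.08, Y 0.07; AMP-like: K 0.10,
L 0.09, I 0.08, C 0.06; background: uniform 0.05; remaining residues
share the leftover mass equally), lengths uniform on [10, 60], with
optional planted positional motifs. The boosted residues and their
ordering mirror the qualitative compositional contrasts reported for
real defensins and AMPs; the magnitudes are calibrated constructions,
not digitized measurements. `null_pair` draws both classes from one
profile — the control for chance-level AUROC and type-I-error
calibration.

What passing on these conditions does **not** show: real defensins have
cysteine-spacing motifs, disulfide connectivity and strong residue
autocorrelation that i.i.d. sampling cannot produce, so order-sensitive
families (DPC/TPC/CTD transitions/PAAC θ) carry less signal here than
on curated data, and absolute performance numbers on synthetic data do
not transfer. The reference problem sizes used by `scripts/acceptance.py`
— 500 peptides per class, top-60 features, three null seeds — were
chosen as the smallest conditions where selection, ranking and the SVM
operating point are all exercised at stable metric values.

## Known limitations

* Whole-sequence CTD only; no segmented ("enhanced") CTD variant.
* Binary tasks only; no multiclass defensin subfamily typing.
* The selector count is data-dependent; on weak-signal data fewer than
  top-k features may survive, and the pipeline proceeds with what it has
  (warned).
* MLP at its small default budget (max_iter 100) may not converge on
  hard contrasts; convergence warnings are suppressed during training
  because the reference protocol fixes the iteration budget.
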