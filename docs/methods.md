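# Methods

## Atom codes and canonical pairs

A heavy atom's code is the triple (element, heavy degree, π electrons).
Hydrogens — implicit or explicit — are excluded from codes, degrees and
pairs. The π-electron count is defined as: an aromatic atom contributes 1
(plus any exocyclic unsaturation), a non-aromatic atom contributes
Σ(bond order − 1) over its bonds. On aromatic rings this equals the value
obtained by Kekulizing and rounding (benzene carbon → 1, naphthalene
fusion carbon → 1) but, unlike a Kekulé-based computation, it cannot
depend on which Kekulé structure RDKit happens to pick, so pair multisets
are invariant under SMILES rewriting. The convention coincides with
RDKit's own atom-pair perception, which the test suite uses as an
independent oracle. Charges, isotopes and stereochemistry are ignored:
the pair definition uses exactly three atom attributes.

A pair code stores its two atom codes in lexicographic order on
(element, degree, π), making `pair_code(a, b, d) == pair_code(b, a, d)`.
Pairs are enumerated for topological distances 1..4 inclusive by default
(bonded atoms count as distance 1; the cutoff is configurable). For
multi-fragment inputs, pairs are enumerated within fragments only and a
warning is attached, since distance is undefined across fragments;
requesting a cross-fragment distance directly raises a dedicated error so
"no path" can never be mistaken for a valid distance.

## Lookup aggregation

For each reference molecule, a pair occurring *n* times contributes the
molecule's property vector divided by *n* — exactly one contribution per
distinct pair per molecule, so the per-pair mean is an unweighted mean
over molecules, not over occurrences. Histograms are built per pair and
per property from those same contributions, over 10 equal-width bins
spanning the pair's observed range, stored as relative frequencies
(sum 1) with their bin edges; a raw-count mode exists behind a flag. When
a pair's contributions are all identical the range is degenerate: the
full mass is placed in the centre bin (index 4 of 10) with edges spanning
value ± 0.5, keeping the stored layout well-defined. Reference molecules
containing heavy elements outside C/O/N/F/S/Cl/Br are skipped at build
time with a logged count; duplicate SMILES are kept as separate molecules.
The lookup serializes to a single JSON document (schema version,
provenance, entries keyed by the canonical string `El.deg.pi-El.deg.pi@d`)
whose re-serialization after loading is byte-identical.

## Applicability domain and descriptors

A molecule is in-domain iff it parses, contains only the seven lookup
elements, has at least one pair, and every one of its pairs exists in the
lookup. Single-heavy-atom molecules are deliberately out-of-domain: their
descriptors would be identically zero. Batch filtering never raises; it
returns the ordered in-domain subset plus a report with one reason per
rejection (parse_error, forbidden_element, no_pairs, unknown_pair).

sumQAP and hQAP multiply each pair's block by its occurrence count by
default, which makes them additive over disconnected fragments; an
unweighted switch exists. spQAP is presence-gated by default (a pair's
block is its mean property vector or zeros), with count weighting as a
flag; with count weighting on both, the sum of spQAP's 11-blocks equals
sumQAP exactly. Featurizers accumulate in canonical pair order so vectors
are bit-identical across SMILES spellings of the same molecule. Feature
names are stable: `qap_sum|<property>`, `qap_hist|<property>|bin<k>`, and
`qap|<pair-string>|<property>`.

The variance filter removes columns whose population (ddof = 0) standard
deviation is strictly below 0.05, applied once on the full design matrix
before any cross-validation splitting.

## Benchmark protocol

Random forest: 500 trees, max_features = 0.3, scikit-learn. Repeat *r*
of the cross-validation draws folds with seed `random_seed + r` (shuffled
KFold; stratified for classification, which protects heavily imbalanced
sets), and the forest in fold *f* of repeat *r* uses seed
`random_seed + 1000·r + f`; reports are therefore bit-reproducible.
Regression is scored with the coefficient of determination R² (can be
negative on held-out folds) and RMSE; since "R²" is sometimes read as the
squared Pearson correlation, that variant is also computed
(`pearson_r2`), with the coefficient of determination as the default
interpretation. Classification is scored with balanced accuracy and ROC
AUC computed from class-1 probability estimates (fraction of trees), not
hard labels. Baselines predict the training mean (regression) or the
training majority class with ties broken toward the smaller label
(classification); the baseline classifier's constant class-frequency
probabilities give ROC AUC = 0.5 by construction.

The relative metric between two representations is the per-fold ratio of
their metric values minus 1, paired by (repeat, fold); it requires both
reports to share the fold structure, and pairs with a zero denominator are
dropped and counted. The Mann–Whitney U test is applied two-sided to the
pooled per-fold values (100 per side under the full protocol), unpaired:
the exact null distribution is used when both samples are tie-free and no
larger than 25, the normal approximation with tie correction otherwise,
and the fully degenerate all-equal case short-circuits to p = 1.

Reference representations (count-folded Morgan, classic atom pairs,
topological torsions, the RDKit path fingerprint, and the full RDKit
descriptor panel) come directly from RDKit generators; descriptor-panel
columns containing non-finite values are dropped.

## Synthetic data

The generator emulates the schema of a quantum-property reference
database so the pipeline is testable without any download. Molecules are
grown by seeded random attachment with single bonds and at most one ring;
element abundances are weighted toward carbon (C 0.60, N/O 0.12 each,
S 0.06, F 0.04, Cl/Br 0.03) and heavy-atom counts are drawn from the top
three sizes below the cap (7–9 by default), mirroring enumerated
reference sets in which most molecules sit at the size limit. Every pair
code carries an 11-component latent weight vector derived
deterministically from the generator seed and the pair identity; a
molecule's 11 properties are the occurrence-weighted sums of its pairs'
weights plus Gaussian noise (sd 0.1 by default). Additivity over pairs
makes sumQAP the sufficient feature for downstream tasks, so descriptor
recovery is a provable property of the pipeline. The shared pair weights
also induce correlations among the 11 properties, as in real
quantum-chemistry tables. What the generator does **not** emulate:
physically realistic property values or units, multiple/aromatic bonds
in generated molecules (reference and probe molecules are σ-bonded),
conformers, tautomers, or realistic functional-group statistics — so
passing tests demonstrate the correctness of the machinery and the
recoverability of additive pair signal, not predictive performance on
real chemistry.

Modeling tasks are derived from a reference database that is larger than
the task itself (default: a 500-molecule task drawn from a 2500-molecule
database), matching the regime where per-pair statistics are estimated
from far more molecules than any one modeling set. The latent score of a
task is a seeded linear combination of 2 of the 11 standardized sumQAP
features by default — experimental endpoints are single properties
dominated by a small number of underlying quantum quantities, not dense
mixtures of all of them. Regression adds noise with sd = `noise_sd` ×
signal sd (so SNR = 1/noise_sd; default 0.2 → SNR 5). Classification
thresholds the score at the quantile that yields the requested
minority:majority ratio (default 1:12, the imbalance of the harder public
classification sets); if the achieved ratio misses by more than 10% —
possible only with massive score ties — the task generator refuses.

## Numerical choices and edge cases

* Histogram normalization tolerance 1e-9; degenerate ranges handled as
  above.
* `variance_filter` boundary: a column at exactly the threshold is kept
  (dismissal is strict `<`).
* `relative_metric` drops zero-denominator folds rather than propagating
  infinities, and reports how many were dropped.
* Lookup JSON floats round-trip exactly (no decimal re-rounding).
* Single-class training folds cannot arise under stratified folding with
  the supported class ratios; `repeated_cv` rejects non-binary
  classification targets outright.

## Problem sizes

Default test and reproduction sizes — 200 molecules for the enumeration
oracle, 500 for domain soundness, a 2500-molecule reference database and
500-molecule task for the recovery benchmark under the full 10×10
protocol — were chosen so the complete pipeline, including the 100
forest fits, reproduces in a few minutes on a single CPU while keeping
every statistic at its protocol-scale shape (100 per-fold values per
metric).

## Known limitations

* The applicability-domain rule is binary; no soft coverage score.
* Histogram bins are per-pair equal-width; quantile binning is not
  implemented.
* Only binary classification is supported, as in the evaluation protocol.
* The CLI covers the pipeline end-to-end but not the plotting helper;
  `plot_metric_bars` is library-only.
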