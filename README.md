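# quantumpairs

Quantum-informed atom pairs (QAP) for QSAR/QSPR modeling: classic
Carhart-style atom-pair fingerprints enriched with aggregated
quantum-chemical properties from a reference database, plus the
applicability-domain rule and the repeated cross-validation protocol used
to evaluate them.

## The idea

A Carhart atom pair is the triple *(code(a), code(b), d)* where *d* is the
topological distance in bonds between two heavy atoms and each atom code is
*(element, number of heavy neighbours, number of π-bonding electrons)*.
Given a reference database of molecules with 11 quantum properties each
(dipole moment μ, isotropic polarizability α, ε(HOMO), ε(LUMO), the
HOMO–LUMO gap, ZPVE, U₀, U₂₉₈, H₂₉₈, G₂₉₈ and C_v), every pair *p* observed
in the database is assigned

* the arithmetic mean over molecules containing *p* of the molecule's
  property vector divided by the number of occurrences of *p* in that
  molecule (one contribution per molecule), and
* per-property 10-bin relative-frequency histograms of those same
  occurrence-divided contributions.

Three descriptor layouts follow for any molecule whose pairs are all known
to the lookup (the applicability domain):

| layout | definition | width |
|--------|-----------|-------|
| sumQAP | Σ over pairs of occurrence count × mean property vector | 11 |
| hQAP   | Σ over pairs of occurrence count × concatenated histograms | 110 |
| spQAP  | one 11-block per lookup pair, mean properties if present else 0 | 11 × n\_pairs |

Descriptors are evaluated with a random forest (500 trees, max_features
0.3) under 10×10-fold cross-validation — R²/RMSE for regression, balanced
accuracy/ROC AUC for classification — against mean/majority baselines and
classic RDKit representations, with per-fold relative metrics
(ratio − 1) and a two-sided Mann–Whitney U test between representations.
Descriptor columns with standard deviation < 0.05 are dismissed before
modeling.

Because the reference database itself is an external deposit, the package
ships a synthetic generator that emulates its schema (C/N/O/F/S/Cl/Br
organics, 11 correlated properties additive over atom pairs) so the whole
pipeline runs, and is tested, self-contained.

## Worked example

```python
from quantumpairs import (SyntheticSpec, build_lookup, generate_quantum_db,
                          generate_task, featurize_matrix, variance_filter,
                          BenchmarkConfig, repeated_cv)

records = generate_quantum_db(SyntheticSpec(n_molecules=800, seed=7))
lookup = build_lookup(records)                      # pair -> statistics
molecules, y = generate_task(records, seed=7, n_molecules=300)
X = variance_filter(featurize_matrix(molecules, lookup, method="sum"))
cfg = BenchmarkConfig(task="regression", n_estimators=100, n_repeats=3,
                      random_seed=7)
report = repeated_cv(X, y, cfg, representation="sumQAP")
print(report.summary()["r2"])
```

Running `python examples/03_benchmark.py` (this pipeline plus a classic
atom-pair comparison) prints

```
sumQAP     R2 = +0.865  [+0.853, +0.877]
atom_pairs R2 = +0.564  [+0.532, +0.595]
baseline   R2 = -0.074  [-0.113, -0.035]

sumQAP vs atom pairs: mean per-fold R2 ratio-1 = +0.568
Mann-Whitney p = 3.02e-11 (significant at 0.05: True)
```

i.e. on the synthetic task — whose targets are by construction additive
over atom pairs — the quantum-informed descriptors recover the signal
(mean held-out R² with its 95% CI), the classic count fingerprint recovers
part of it, and the mean-predicting baseline sits at chance; the last two
lines quantify the per-fold advantage of sumQAP and its significance.

The other examples cover lookup construction (`01_build_lookup.py`),
domain filtering and the three layouts (`02_featurize.py`), and the same
pipeline through the `qap` command-line interface (`04_cli_pipeline.sh`;
see `qap --help`).

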