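"""Applicability-domain filtering and the three QAP descriptor layouts.

Molecules whose atom pairs all occur in the lookup are in-domain; the rest
are rejected with a reason.  In-domain molecules are featurized as sumQAP
(11 values), hQAP (110 values) and spQAP (11 per known pair).
"""

from quantumpairs import (
    SyntheticSpec,
    build_lookup,
    featurize_matrix,
    filter_domain,
    generate_quantum_db,
    sample_molecules,
)

lookup = build_lookup(generate_quantum_db(SyntheticSpec(n_molecules=400, seed=7)))

# fresh molecules, plus two that must be rejected
candidates = sample_molecules(SyntheticSpec(n_molecules=8, seed=99))
candidates += ["CCP(C)C", "C"]  # phosphorus; single heavy atom
kept, report = filter_domain(candidates, lookup)

print(f"in domain: {report.n_in_domain}/{report.n_input}")
for mol_id, reason in report.rejected:
    print(f"  rejected #{mol_id}: {reason}")

for method in ("sum", "hist", "sparse"):
    matrix = featurize_matrix(kept, lookup, method=method)
    print(f"{method:6s} -> {matrix.shape[0]} x {matrix.shape[1]}  "
          f"(first feature: {matrix.feature_names[0]})")
# sum/hist widths are fixed (11, 110); the sparse width is 11 x number of
# pairs in the lookup, so it grows with the reference database coverage.
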