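#!/usr/bin/env bash
# End-to-end pipeline through the qap command-line interface.
set -euo pipefail
workdir=$(mktemp -d)

qap synth-db --n 400 --seed 7 --out "$workdir/ref.csv"
qap build-lookup --db "$workdir/ref.csv" --out "$workdir/lookup.json"
qap synth-task --db "$workdir/ref.csv" --task regression --seed 7 --out "$workdir/data.csv"
qap filter-domain --in "$workdir/data.csv" --lookup "$workdir/lookup.json" \
    --out "$workdir/curated.csv" --report "$workdir/domain.json"
qap featurize --in "$workdir/curated.csv" --lookup "$workdir/lookup.json" \
    --method sum --out "$workdir/features.csv"
qap benchmark --features "$workdir/features.csv" --targets "$workdir/curated.csv" \
    --target-col y --task regression --folds 10 --repeats 2 --seed 7 \
    --out "$workdir/report.json"
echo "artifacts in $workdir"
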