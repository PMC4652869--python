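#!/usr/bin/env bash
# End-to-end command-line workflow: simulate, analyse, summarise.
set -euo pipefail

workdir=$(mktemp -d)
cd "$workdir"

# 1. simulate a coupled Roessler pair (two observable channels)
crossembed simulate-rossler --seed 0 --duration 600 --out rossler.tsv

# 2. all-pairs cross-embedding analysis; writes complexity.tsv,
#    directionality.tsv, correlation.tsv, pairs.tsv and run_metadata.txt
crossembed crossmap rossler.tsv --tau 4 --dmax 12 --out-dir analysis

echo "--- directionality matrix (columns = source, rows = target) ---"
cat analysis/directionality.tsv

# 3. six complexity measures for the downstream channel
crossembed complexity-measures rossler.tsv --tau 4 --dmax 12

# 4. simulate the three-cluster network under model 1
crossembed simulate-network --model model1 --seed 0 --bias-seed 0 --out net.tsv
head -2 net.tsv

echo "outputs in $workdir"
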