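#!/usr/bin/env bash
# Stage-by-stage screening through the command-line interface.
# Each stage reads and writes plain TSV, so intermediate results can be
# inspected (or produced by other tooling) at any point.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

cat > "$workdir/sim.yaml" <<EOF
n_samples: 2000
n_carriers: 3
rng_seed: 5
EOF

cnvscreen simulate --config "$workdir/sim.yaml" --out-dir "$workdir/cohort"

cnvscreen normalize \
    --intensities "$workdir/cohort/intensities.tsv" \
    --manifest "$workdir/cohort/manifest.tsv" \
    --locus-map "$workdir/cohort/locus_map.tsv" \
    --regions "$workdir/cohort/regions.tsv" \
    --out "$workdir/matrix.tsv"

cnvscreen features \
    --matrix "$workdir/matrix.tsv" \
    --locus-map "$workdir/cohort/locus_map.tsv" \
    --regions "$workdir/cohort/regions.tsv" \
    --out "$workdir/features.tsv"

cnvscreen call --features "$workdir/features.tsv" \
    --diff-max -2.0 --mad-max 1.5 --out "$workdir/calls.tsv"

cnvscreen evaluate --calls "$workdir/calls.tsv" \
    --truth "$workdir/cohort/truth.tsv"

# The same composition, plus reports, in one command:
cat > "$workdir/pipeline.yaml" <<EOF
manifest: $workdir/cohort/manifest.tsv
intensities: $workdir/cohort/intensities.tsv
locus_map: $workdir/cohort/locus_map.tsv
regions: $workdir/cohort/regions.tsv
truth: $workdir/cohort/truth.tsv
out_dir: $workdir/out
EOF
cnvscreen run --config "$workdir/pipeline.yaml"
cat "$workdir/out/report.txt"
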