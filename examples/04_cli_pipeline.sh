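#!/usr/bin/env bash
# The same analysis as a shell pipeline: every stage reads and writes
# documented TSVs, so runs are resumable and each stage is independently
# testable.  Outputs land in ./run/.
set -euo pipefail

cat > plan.yaml <<'EOF'
seed: 7
replicons:
  - [60000, chromosome, linear]
  - [12000, plasmid, circular]
planted_loci:
  - {ta_type: II, distance: 30}
  - {ta_type: I, distance: 50, strands: ["+", "-"]}
  - {ta_type: II, family: mazEF, distance: 100, replicon: 1}
planted_mges:
  - {mge_class: prophage, placement: harbored, anchor_locus: 0}
  - {mge_class: IS_transposon, placement: gap, anchor_locus: 1, gap_bp: 1200}
EOF

taloci simulate --plan plan.yaml --out-dir bundle
taloci predict bundle/genome.gbk \
    --refs-protein bundle/refs_protein.fasta \
    --refs-rna bundle/refs_rna.fasta \
    --out-dir run
taloci associate --loci run/loci.tsv --mges bundle/mges.tsv \
    --genome bundle/genome.gbk --out-dir run
taloci network --links run/links.tsv --mges run/mges_effective.tsv \
    --genome bundle/genome.gbk --out-dir run
taloci stats --loci run/loci.tsv --links run/links.tsv \
    --genome bundle/genome.gbk --out-dir run

echo "--- predicted loci"
column -t run/loci.tsv | cut -c1-120
echo "--- TA-MGE links"
column -t run/links.tsv
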