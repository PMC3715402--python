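#!/bin/sh
# The whole pipeline from the shell: synthetic fixture -> centroids ->
# pockets + consensus sites -> residue selection -> viewer scene.
# Every output directory contains run_config.yaml (resolved parameters +
# input digests), and reruns with the same seed are byte-identical.
set -e
OUT=${1:-scratch/pipeline_demo}

ensitemap make-fixtures --out "$OUT/fx" --seed 1
ensitemap cluster "$OUT/fx/ensemble.pdb" --out "$OUT/clu" --threshold 2.0
ensitemap pockets "$OUT/clu/centroids.pdb" --out "$OUT/pk"
ensitemap consensus "$OUT"/fx/probes_member_0[04].pdb --out "$OUT/cs"
ensitemap select-residues "$OUT/clu/centroids.pdb" \
    --cs "$OUT/cs/consensus.tsv" --sites "$OUT/pk/site_points.tsv" \
    --out "$OUT/sel" --cutoff 3.0
ensitemap visualize "$OUT/clu/centroids.pdb" \
    --cs "$OUT/cs/consensus.tsv" --sites "$OUT/pk/site_points.tsv" \
    --out "$OUT/vis" --n-cs 5

echo
echo "cluster report:";       cat "$OUT/clu/clusters.tsv"
echo
echo "predicted regions:";    cat "$OUT/sel/regions.tsv"
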