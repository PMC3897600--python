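"""Build a stop-stripped, partitioned supermatrix from gene alignments.

Simulates per-gene alignments (13 PCGs + 2 rRNAs, widths from the
published gene lengths) along the four-superfamily tree, strips
terminal stop codons from the codon partitions, concatenates, and
exports PHYLIP/NEXUS with the partition map.
"""

from pathlib import Path
import tempfile

from ensimito.phylo import GTRParams
from ensimito.supermatrix import concatenate, export_nexus, export_phylip, strip_stop_codons
from ensimito.synthetic import ensifera_demo_tree, simulate_gene_alignments

tree = ensifera_demo_tree()
params = GTRParams(base_freqs=(0.35, 0.17, 0.11, 0.37),
                   exchangeabilities=(1.5, 6.0, 1.2, 1.0, 8.0, 1.0),
                   alpha=0.5, p_inv=0.2)
alns = simulate_gene_alignments(tree, params, seed=3)
print(f"{len(alns)} gene alignments over {len(alns[0].taxa)} taxa")

stripped = [strip_stop_codons(a) if a.kind == "codon" else a for a in alns]
matrix = concatenate(stripped)
print(f"supermatrix: {len(matrix.taxa)} taxa x {matrix.width} sites, "
      f"{len(matrix.partitions)} partitions")
for gene in ("cox1", "nad5", "rrnL"):
    lo, hi = matrix.partitions[gene]
    print(f"  {gene:>5s}: columns {lo + 1}-{hi} ({hi - lo} sites)")

with tempfile.TemporaryDirectory() as d:
    export_phylip(matrix, Path(d) / "super.phy")
    export_nexus(matrix, Path(d) / "super.nex")
    print("exports written:", sorted(p.name for p in Path(d).iterdir()))
# The partition intervals tile the matrix; the total width is close to
# the 13.4k sites of a real 13-PCG + 2-rRNA ensiferan dataset.
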