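"""Fold tRNAs onto cloverleaf templates and census their pairings.

Builds one canonical tRNA with two planted defects and one
serine-AGN-style atypical tRNA (mini 1-bp DHU arm, 9-bp anticodon stem
with a bulge, 6-bp T stem, no connectors), folds both by
template-constrained search, and prints the wobble/mismatch census and
the atypical-structure flags.
"""

from ensimito.synthetic import TrnaTemplate, generate_trna, template_for_length
from ensimito.trna import dot_bracket, flag_atypical, fold_cloverleaf, pairing_census

seq, truth = generate_trna(
    template_for_length(68),
    defects=[("acceptor", 2, "wobble"), ("anticodon", 2, "mismatch")],
    seed=5,
)
fold = fold_cloverleaf(seq, anticodon=truth.anticodon_triplet)
census = pairing_census(fold, seq)
print(f"canonical 68-nt tRNA (anticodon {truth.anticodon_triplet}):")
print(f"  {seq}")
print(f"  {dot_bracket(fold)}")
print(f"  census: {census['total']}  (planted: 1 wobble, 1 mismatch)")
print(f"  per arm: acceptor {census['acceptor']}, anticodon {census['anticodon']}")

serine = TrnaTemplate(acceptor=7, connector1=0, dhu=1, dhu_loop=5, connector2=0,
                      anticodon_stem=9, bulge=True, anticodon_loop=7, variable=0,
                      t_stem=6, t_loop=4, anticodon="GCT")
seq2, truth2 = generate_trna(serine, seed=2)
fold2 = fold_cloverleaf(seq2, anticodon="GCT")
print(f"serine-AGN-style tRNA ({len(seq2)} nt): flags {sorted(flag_atypical(fold2))}")
# The flags name exactly the departures from the canonical cloverleaf
# that the atypical serine tRNA shows.
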