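"""Kinship coefficients from a pedigree, autosomal and X-linked.

Builds a three-generation pedigree containing an inbred full-sib pair and
prints the pairwise kinship coefficients Phi that drive every diversity
correction in the package.
"""

import besthet as bh

# grandparents -> brother-sister parents -> two inbred children
ped = bh.build_pedigree(
    [
        ("gf", "0", "0", "M"), ("gm", "0", "0", "F"),
        ("p1", "gf", "gm", "M"), ("p2", "gf", "gm", "F"),
        ("c1", "p1", "p2", "M"), ("c2", "p1", "p2", "F"),
    ]
)

print("autosomal kinship (probability a random allele from each is IBD):")
print(f"  siblings p1,p2 (outbred):   {bh.kinship_pair(ped, 'p1', 'p2')}")   # 1/4
print(f"  siblings c1,c2 (inbred):    {bh.kinship_pair(ped, 'c1', 'c2')}")   # 3/8
print(f"  inbreeding F of c1:         {bh.inbreeding(ped, 'c1')}")           # 1/4

print("X-linked kinship (males hemizygous):")
print(f"  brother-sister p1,p2:       {bh.kinship_pair(ped, 'p1', 'p2', mode='x_linked')}")  # 1/4

K = bh.kinship_matrix(ped, ["c1", "c2"])
print("kinship matrix of the inbred pair (diagonal = self-kinship (1+F)/2):")
print(K.matrix)

# Monte-Carlo gene drop agrees with the recursion
mc = bh.gene_drop_identity_coeffs(ped, ("c1", "c2"), reps=200_000, seed=1)
print(f"gene-drop estimate of Phi(c1,c2): {mc['pair']:.4f} "
      f"(+/- {mc.stderr['pair']:.4f}) vs analytic 0.375")
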