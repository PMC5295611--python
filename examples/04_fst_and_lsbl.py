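"""F_ST between two simulated related samples, and branch lengths.

Simulates two populations with different 10-allele spectra, each sampled
with the 60-individual mixed relative-pair design, and shows that the
classical F_ST is upward-biased on related samples while the BLUE-based
version is not.  Closes with locus-specific branch lengths (LSBL) from
three pairwise F_ST values.
"""

import numpy as np

import besthet as bh
from besthet.differentiation import run_fst_experiment

p = np.array([0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.05, 0.03, 0.02, 0.01])
q = np.roll(p, 4)  # same alleles, shifted frequencies
design = [
    bh.PairSpec("full_sib_inbred_sibmating", 10),
    bh.PairSpec("full_sib_outbred", 10),
    bh.PairSpec("avuncular", 10),
]
res = run_fst_experiment(design, p, design, q, reps=1000, seed=3)

print(f"parametric F_ST = {res.true_fst:.4f}\n")
print(f"{'estimator':<14s}{'mean':>9s}{'bias':>10s}{'MSE':>11s}")
for tag in ("fst_hat_full", "fst_hat_red", "fst_tilde", "fst_blue"):
    s = res[tag]
    print(f"{tag:<14s}{s.mean:9.4f}{s.bias:10.5f}{s.mse:11.3e}")
print("\nThe full-sample estimator overshoots (its downward-biased H1, H2")
print("shrink the subtracted term); the BLUE-based version does not.")

# delta-method variance of the BLUE-based estimator
v = bh.fst_variance_approx(p, q, design, design, family="blue",
                           mc_reps=5000, seed=4)
print(f"delta-method Var[F_ST,BLUE] = {v:.3e} "
      f"(empirical {res['fst_blue'].variance:.3e})")

# three-population branch lengths from pairwise F_ST
L1, L2, L3 = bh.lsbl(0.21, 0.34, 0.17)
print(f"\nLSBL for f12=0.21, f13=0.34, f23=0.17: "
      f"L1={L1:.3f}, L2={L2:.3f}, L3={L3:.3f}")
print("An unusually long branch flags lineage-specific differentiation;")
print("branch sums reconstruct the pairwise values exactly.")
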