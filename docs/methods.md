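# Methods

## Model

A locus has `I` distinct alleles with population frequencies
`p_1, ..., p_I`; its gene diversity is `H = 1 - Σ p_i²`, the probability
that two allele copies drawn at random from the population differ. A
sample holds `n` individuals, individual `k` carrying `m_k` allele copies
(ploidy; 1 for males at X-linked loci, 2 for diploids, higher for
polyploids). Relatedness enters through identity by descent (IBD): the
kinship coefficient `Φ_jk` is the probability that one allele drawn from
`j` and one from `k` are IBD. Self-kinship — two draws *with replacement*
from one individual — is `Φ_kk = (1 + (m_k - 1) F_k)/m_k` with `F_k` the
inbreeding coefficient (the kinship of `k`'s parents). This diagonal
convention is what makes BLUE weights reduce to allele-copy weights for
unrelated samples of mixed ploidy, which in turn makes all estimators in
the family coincide there.

### Estimators

For any weight vector `w` summing to one, `p̆_i = Σ_k w_k X_k(i)` is an
unbiased linear estimate of `p_i` (with `X_k(i)` the fraction of `k`'s
alleles of type `i`), and

    H̆ = (1 - Σ p̆_i²) / (1 - ρ₂),      ρ₂ = w'Kw,

is an unbiased estimate of `H`. The intuition: `E[Σ p̆_i²]` exceeds
`Σ p_i²` by exactly `ρ₂ (1 - Σ p_i²)`, the probability that the two
implicitly drawn allele copies are IBD; dividing by `1 - ρ₂` removes it.
Sample-proportion weights `w_k = m_k / Σ m_j` give the estimator
`h_tilde`; BLUE weights `w = K⁻¹1 / (1'K⁻¹1)` give `h_blue`, whose
frequency estimates have minimum variance among linear unbiased ones.
BLUE weights can be negative for some kinship configurations; frequency
and diversity estimates are then reported as computed (flagged, never
clipped) to preserve unbiasedness.

The classical estimator `h_hat = [n_c/(n_c - 1)](1 - Σ p̂_i²)` (with
`n_c` = total allele copies) is the special case that *assumes*
`ρ₂ = 1/n_c`; on related or inbred samples its bias is
`(1 - n_c ρ₂) H / (n_c - 1)`. We read the `n` in this bias formula as
allele copies, not individuals: only then does the bias vanish for
unrelated outbred samples of any ploidy and the corrected estimator
collapse to the classical one there. The reduced-sample variant removes
one member of each relative pair (the lower-ploidy member of a
mixed-ploidy pair deterministically — it discards the fewest allele
copies — otherwise a seeded uniform choice).

**A caveat the simulations make visible:** removing one member of an
*inbred* relative pair leaves an inbred singleton, so the reduced-sample
estimator is not exactly unbiased on designs containing inbred pairs.
Its residual bias is predicted by the same bias formula applied to the
reduced sample (`ρ₂` from the retained individuals' self-kinships); on
the 60-individual mixed design below this is about −0.0012 at H = 0.824,
versus −0.0040 for the full-sample classical estimator. The tests assert
the predicted value, not zero.

### Variance theory

The exact variance of `H̆` is `Var[1 - Σ p̆_i²]/(1 - ρ₂)²` with

    Var[1 - Σ p̆²] = (ρ₂,₂ - ρ₂²) + 2(ρ₂² - ρ₄) Σp²
                    + 4(2ρ₄ + ρ₂ - 2ρ₃ - ρ₂,₂) Σp³
                    + (3ρ₂,₂ + 8ρ₃ - 6ρ₄ - 4ρ₂ - ρ₂²) (Σp²)²,

where `ρ₃, ρ₄, ρ₂,₂` are weighted mean IBD probabilities over trios,
quartets and pairs-of-pairs of individuals (indices range over all
individuals *with repeats*; repeated indices mean independent draws with
replacement). Two checks pin the transcription down: the polynomial
cancels exactly at a monomorphic locus, and for a single outbred diploid
at `p = (1/2, 1/2)` it yields `Var[H̆] = 1/4`, which is also obvious
directly (the estimate is 0 or 1 with equal probability). When no
individual is related to more than one other, the higher-order terms are
negligible and `Var[1 - Σ p̆²] ≈ 4ρ₂[Σp³ - (Σp²)²]`; on the 60-individual
mixed design the approximation sits within ~6% of the exact value, and
the tests hold it to 10%.

### Higher-order IBD coefficients

Pairwise `Φ` comes from the classical pedigree recursion (founders
mutually unrelated and non-inbred; X-linked mode treats males as
hemizygous, transmitting their single X to daughters only). Higher-order
coefficients come from two routes:

* **exact enumeration** over every meiosis outcome of a small pedigree
  (4^(non-founders) patterns for autosomal diploids), averaging the
  conditional allele-draw probabilities given each pattern — exact, used
  for the per-block coefficients of all experiment designs and as the
  oracle in tests;
* **gene-dropping Monte Carlo** with uniquely labeled founder alleles,
  for pedigrees too large to enumerate; returns binomial standard errors.

Experiment designs are unions of independent family blocks, so the
weighted sums use a sparse convention: trio/quartet coefficients vanish
across blocks, and cross-block pair-of-pairs coefficients factor into
`Φ_jk Φ_j'k'`. This is exact for block designs (founders unrelated); for
samples with arbitrary cross-family relatedness the user must supply the
full tuple coefficients.

### F_ST and LSBL

`F_ST = (H12 - (H1 + H2)/2)/H12` with `H12 = 1 - Σ p̆_i q̆_i`; each
estimator family supplies its own components, with the two populations
sampled independently. The delta-method variance uses the expansion
`Var[x/y] ≈ Var[x]/E[y]² + E[x]²Var[y]/E[y]⁴ - 2E[x]Cov[x,y]/E[y]³`
(written in expanded form so identical populations, where `E[x] = 0`, are
handled without 0/0). `Var[H1]` and `Var[H2]` are analytic;
`Var[H12]` and the covariances `Cov[H12, H1]`, `Cov[H12, H2]` are
estimated by seeded gene-drop Monte Carlo, since no closed forms are
implemented for the cross terms. The exact part of this decomposition
reproduces the observed variance of the numerator to Monte-Carlo
precision; the first-order ratio expansion itself truncates roughly 10%
of the observed `Var[F_ST]` at moderate sample sizes, which is the
accuracy an approximate ratio variance can honestly claim. LSBL maps
three pairwise values to branch lengths `L1 = (f12 + f13 - f23)/2` (and
cyclically), so `L_i + L_j = f_ij` holds exactly; negative branches are
reported as computed.

## Synthetic data

The generator produces samples with prescribed relatedness by gene
dropping through template pedigrees, one per catalogued pair type
(parent-offspring, outbred full-sib, full-sib from brother-sister mating,
avuncular, and male-male / male-female / female-female full-sibs at an
X-linked locus, plus unrelated singletons). Founder alleles are i.i.d.
draws from a parametric spectrum, so IBD copies are literal copies and
the simulated identity structure is exact — including the inbred and
X-linked cases that two-gene sharing probabilities cannot represent. The
lighter "copy" method (sharing 0/1/2 alleles with probabilities (0,1,0),
(¼,½,¼), (½,½,0) for the outbred autosomal types) is provided and is
distributionally equivalent there, verified by goodness-of-fit.

Default study conditions follow the simulation designs the theory is
exercised on: the mixed design of 10 inbred full-sib + 10 outbred
full-sib + 10 avuncular pairs (60 diploids, each related to exactly one
other); 10⁴ replicates for bias/MSE summaries and 10⁵ for variance
checks; a fixed synthetic 10-allele microsatellite-like spectrum
(0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.05, 0.03, 0.02, 0.01; H = 0.8236)
standing in for a high-diversity marker, and biallelic SNP grids with
minor allele frequency 0.01–0.50 in steps of 0.01 (H from 0.0198 to 0.5).
The F_ST experiments use a second spectrum obtained by permuting the
first (parametric F_ST ≈ 0.11) and 10³ replicates.

What the generator does *not* emulate: genotyping error, null alleles,
mutation, linkage between loci, population structure within a population,
or uncertainty in the pedigree itself. Passing tests therefore
demonstrate estimator properties under correctly specified kinship — the
paper-level caveat that misidentified relative pairs degrade the
BLUE-based estimator first applies to real data and is out of scope here.

## Numerical choices

* **Invertibility.** BLUE weights reject kinship matrices whose
  reciprocal condition number is below 1e-12 rather than pseudo-inverting:
  the weights are defined only for invertible K.
* **Missing data.** An individual with any missing allele copy at a locus
  is dropped from that locus, and all weights (including BLUE, via the
  principal submatrix of K) are recomputed on the retained set.
* **Degenerate inputs.** `ρ₂ ≥ 1` (e.g. a sample of one haploid) raises
  rather than returning infinity; `H12 ≤ 0` likewise. Monomorphic loci
  give estimate 0 and variance 0.
* **Normalized diversity B.** Given allele count `I` and maximum
  frequency `M`, `H_max` splits the residual mass evenly over the other
  `I − 1` alleles and `H_min` packs it into as few alleles as possible
  under the cap `M`. The minimum is a supremum when extra alleles would
  be forced to vanishing frequency; the closed forms are tested against
  brute-force grid optimization for `I ≤ 4`. Biallelic loci have
  `H_min = H_max` (M determines the spectrum), signalled as degenerate.
* **Randomness.** All stochastic routines take explicit seeds or
  generators (numpy PCG64); independent streams for multi-locus or
  multi-section runs are derived by `SeedSequence` spawning. Estimates
  are never clipped to [0, 1]; out-of-range values are flagged.
* **Variance conventions.** Experiment summaries use population variance
  (ddof = 0) so `MSE = bias² + variance` is an identity; Monte-Carlo
  standard errors use ddof = 1.

## Limitations

* Exact condensed-identity-state algebra for arbitrary complex pedigrees
  is not implemented; higher-order coefficients for large pedigrees come
  from Monte Carlo only.
* Founder relatedness/inbreeding can only be injected through a
  user-supplied kinship matrix, not through the pedigree recursion.
* Kinship is taken as known; estimating relatedness from genotypes is
  out of scope.
* The pedigree recursion covers diploid autosomal and X-linked
  (hemizygous-male) transmission; general polyploid meiosis is supported
  only through user-supplied kinship matrices and the ploidy-general
  self-kinship diagonal.
* Multi-locus F_ST is aggregated as a ratio of averages (mean numerator
  over mean denominator across loci, with per-locus values retained);
  this is a documented default, since weighted-mean schemes differ across
  the literature. Genome-scan machinery (windows, significance
  thresholds, PBS) is a non-goal.
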