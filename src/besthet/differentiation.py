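"""Population differentiation: F_ST from heterozygosities, and LSBL.

F_ST between two populations is written in terms of gene diversity as

    F_ST = (H12 - (H1 + H2)/2) / H12,

with H1, H2 the within-population diversities and H12 = 1 - sum_i p_i q_i
the between-population diversity.  Any of the within-population estimator
families (classical full/reduced, sample-proportion corrected, BLUE) can
supply the components; the between term uses the same family's frequency
estimates in each population, and the two populations are sampled
independently.

The delta-method variance of the ratio needs Var and Cov terms for the
component heterozygosities; the within-population variances are analytic
while Var[H12] and its covariances with H1, H2 are estimated by seeded
gene-drop Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .diversity import LocusSpectrum, true_heterozygosity, variance_exact
from .errors import BesthetError
from .frequency import FrequencyEstimate, blue_weights
from .identity import mean_kinship
from .simulate import (
    ExperimentDesign,
    EstimatorSummary,
    PairSpec,
    _as_spectrum,
    _summarize,
    estimator_chunk,
)

__all__ = [
    "PairwiseFst",
    "between_heterozygosity",
    "fst_from_het",
    "fst_parametric",
    "multilocus_fst",
    "lsbl",
    "fst_variance_approx",
    "run_fst_experiment",
    "FstExperimentResult",
]

#: within-population estimator family -> (heterozygosity tag, frequency key)
_FAMILIES = {
    "full": ("h_hat_full", "sample_proportion"),
    "red": ("h_hat_red", "reduced"),
    "tilde": ("h_tilde", "sample_proportion"),
    "blue": ("h_blue", "blue"),
}

_FST_TAGS = {
    "full": "fst_hat_full",
    "red": "fst_hat_red",
    "tilde": "fst_tilde",
    "blue": "fst_blue",
}


@dataclass
class PairwiseFst:
    """An F_ST value with the heterozygosity components that produced it."""

    value: float
    estimator: str
    h1: float
    h2: float
    h12: float
    variance: Optional[float] = None


def between_heterozygosity(
    freq1: FrequencyEstimate | Sequence[float],
    freq2: FrequencyEstimate | Sequence[float],
) -> float:
    """Between-population diversity 1 - sum_i p_i q_i.

    Allele universes must already be harmonized (identical allele lists in
    identical order, absent alleles at frequency zero).
    """
    if isinstance(freq1, FrequencyEstimate) and isinstance(freq2, FrequencyEstimate):
        if list(freq1.alleles) != list(freq2.alleles):
            raise BesthetError(
                "allele universes differ; harmonize to the union (absent "
                "alleles at frequency 0) before computing H12"
            )
        p, q = freq1.freqs, freq2.freqs
    else:
        p = freq1.freqs if isinstance(freq1, FrequencyEstimate) else np.asarray(freq1, float)
        q = freq2.freqs if isinstance(freq2, FrequencyEstimate) else np.asarray(freq2, float)
        if p.shape != q.shape:
            raise BesthetError("frequency vectors must have equal length")
    return float(1.0 - np.dot(p, q))


def harmonize_frequencies(
    freq1: FrequencyEstimate, freq2: FrequencyEstimate
) -> tuple[FrequencyEstimate, FrequencyEstimate]:
    """Align two frequency estimates on the union of their allele universes."""
    union = list(dict.fromkeys(list(freq1.alleles) + list(freq2.alleles)))

    def expand(f: FrequencyEstimate) -> FrequencyEstimate:
        pos = {a: i for i, a in enumerate(f.alleles)}
        v = np.zeros(len(union))
        for i, a in enumerate(union):
            if a in pos:
                v[i] = f.freqs[pos[a]]
        return FrequencyEstimate(union, v, f.weights, estimator=f.estimator)

    return expand(freq1), expand(freq2)


def fst_from_het(
    H1: float, H2: float, H12: float, estimator: str = "fst_hat_full"
) -> PairwiseFst:
    """F_ST = (H12 - (H1+H2)/2) / H12 from heterozygosity components."""
    if H12 <= 0:
        raise BesthetError(f"H12 must be positive, got {H12}")
    value = (H12 - 0.5 * (H1 + H2)) / H12
    return PairwiseFst(float(value), estimator, H1, H2, H12)


def fst_parametric(
    spectrum1: LocusSpectrum | Sequence[float],
    spectrum2: LocusSpectrum | Sequence[float],
) -> PairwiseFst:
    """Parametric F_ST from two population allele-frequency spectra."""
    s1, s2 = _as_spectrum(spectrum1), _as_spectrum(spectrum2)
    if s1.n_alleles != s2.n_alleles:
        raise BesthetError("spectra must share one harmonized allele universe")
    h1 = true_heterozygosity(s1)
    h2 = true_heterozygosity(s2)
    h12 = between_heterozygosity(s1.freqs, s2.freqs)
    return fst_from_het(h1, h2, h12, estimator="parametric")


def multilocus_fst(per_locus: Sequence[PairwiseFst]) -> PairwiseFst:
    """Ratio-of-averages aggregation of per-locus F_ST values.

    Averages the numerator H12 - (H1+H2)/2 and the denominator H12 across
    loci before taking the ratio — more stable than averaging per-locus
    ratios when low-diversity loci make single denominators small.  The
    per-locus values remain available in the inputs.
    """
    if not per_locus:
        raise BesthetError("need at least one locus")
    num = float(np.mean([f.h12 - 0.5 * (f.h1 + f.h2) for f in per_locus]))
    den = float(np.mean([f.h12 for f in per_locus]))
    if den <= 0:
        raise BesthetError("mean H12 must be positive")
    tags = {f.estimator for f in per_locus}
    tag = tags.pop() if len(tags) == 1 else "mixed"
    return PairwiseFst(num / den, tag, float(np.mean([f.h1 for f in per_locus])),
                       float(np.mean([f.h2 for f in per_locus])), den)


def lsbl(f12: float, f13: float, f23: float) -> tuple[float, float, float]:
    """Locus-specific branch lengths of the unrooted three-population tree.

    L1 = (f12 + f13 - f23)/2 and cyclic permutations, so that
    L_i + L_j = f_ij exactly.  Negative branch lengths are reported as
    computed.
    """
    L1 = 0.5 * (f12 + f13 - f23)
    L2 = 0.5 * (f12 + f23 - f13)
    L3 = 0.5 * (f13 + f23 - f12)
    return (L1, L2, L3)


# ---------------------------------------------------------------------------
# Monte-Carlo F_ST experiments
# ---------------------------------------------------------------------------

@dataclass
class FstExperimentResult:
    true_fst: float
    reps: int
    seed: Optional[int]
    summaries: dict[str, EstimatorSummary]
    values: dict[str, np.ndarray]
    components: dict[str, dict[str, np.ndarray]]  # family -> {h1,h2,h12}

    def __getitem__(self, tag: str) -> EstimatorSummary:
        return self.summaries[tag]


def _chunk_fst(
    design1: ExperimentDesign,
    design2: ExperimentDesign,
    s1: LocusSpectrum,
    s2: LocusSpectrum,
    families: Sequence[str],
    r: int,
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-family component arrays {h1, h2, h12} for r replicates."""
    het_tags = [_FAMILIES[f][0] for f in families]
    C1 = design1.simulate_counts(s1, r, rng)
    C2 = design2.simulate_counts(s2, r, rng)
    v1, q1 = estimator_chunk(design1, C1, rng, het_tags)
    v2, q2 = estimator_chunk(design2, C2, rng, het_tags)
    out: dict[str, dict[str, np.ndarray]] = {}
    for fam in families:
        tag, fkey = _FAMILIES[fam]
        p = q1[fkey]
        q = q2[fkey]
        out[fam] = {
            "h1": v1[tag],
            "h2": v2[tag],
            "h12": 1.0 - np.einsum("ri,ri->r", p, q),
        }
    return out


def run_fst_experiment(
    pair_specs1: Sequence[PairSpec],
    spectrum1,
    pair_specs2: Sequence[PairSpec],
    spectrum2,
    families: Sequence[str] = ("full", "red", "tilde", "blue"),
    reps: int = 1_000,
    seed: Optional[int] = None,
    chunk_size: int = 20_000,
) -> FstExperimentResult:
    """Replicated F_ST estimates for two simulated population samples.

    Both populations are gene-dropped independently per replicate; each
    requested family supplies its within-population heterozygosities and
    the matching between-population term.  Summaries are against the
    parametric F_ST of the two spectra.
    """
    s1, s2 = _as_spectrum(spectrum1), _as_spectrum(spectrum2)
    if s1.n_alleles != s2.n_alleles:
        raise BesthetError("spectra must share one harmonized allele universe")
    for fam in families:
        if fam not in _FAMILIES:
            raise BesthetError(f"unknown estimator family {fam!r}")
    design1 = ExperimentDesign(list(pair_specs1))
    design2 = ExperimentDesign(list(pair_specs2))
    rng = np.random.default_rng(seed)

    comp: dict[str, dict[str, list[np.ndarray]]] = {
        f: {"h1": [], "h2": [], "h12": []} for f in families
    }
    done = 0
    while done < reps:
        r = min(chunk_size, reps - done)
        chunk = _chunk_fst(design1, design2, s1, s2, families, r, rng)
        for fam in families:
            for key in ("h1", "h2", "h12"):
                comp[fam][key].append(chunk[fam][key])
        done += r

    true = fst_parametric(s1, s2).value
    components = {
        f: {k: np.concatenate(v) for k, v in comp[f].items()} for f in families
    }
    values = {}
    summaries = {}
    for fam in families:
        c = components[fam]
        if np.any(c["h12"] <= 0):
            raise BesthetError(
                f"family {fam!r} produced a nonpositive H12 replicate; "
                "the locus is too close to monomorphic for this design"
            )
        v = (c["h12"] - 0.5 * (c["h1"] + c["h2"])) / c["h12"]
        values[_FST_TAGS[fam]] = v
        summaries[_FST_TAGS[fam]] = _summarize(v, true)
    return FstExperimentResult(true, reps, seed, summaries, values, components)


def fst_variance_approx(
    spectrum1,
    spectrum2,
    pair_specs1: Sequence[PairSpec],
    pair_specs2: Sequence[PairSpec],
    family: str = "blue",
    mc_reps: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Delta-method variance of the F_ST estimator for two sample designs.

    With x = H12 - (H1+H2)/2 and y = H12 the ratio variance is

        Var[x/y] ~ Var[x]/E[y]^2 + E[x]^2 Var[y]/E[y]^4
                   - 2 E[x] Cov[x, y]/E[y]^3,

    where Var[x] = Var[H12] + Var[H1]/4 + Var[H2]/4
                   - Cov[H12, H1] - Cov[H12, H2]
    and Cov[x, y] = Var[H12] - (Cov[H12, H1] + Cov[H12, H2])/2.
    Expectations are parametric; Var[H1] and Var[H2] are analytic (exact
    variance with the design's tuple coefficients) while Var[H12] and the
    covariances are estimated by seeded gene-drop Monte Carlo.  Supported
    families: ``full``, ``tilde``, ``blue`` (the reduced estimator's
    random membership has no fixed weight vector).
    """
    if family not in ("full", "tilde", "blue"):
        raise BesthetError(
            "fst_variance_approx supports families 'full', 'tilde', 'blue'"
        )
    if mc_reps < 1000:
        raise BesthetError("mc_reps must be >= 1000")
    s1, s2 = _as_spectrum(spectrum1), _as_spectrum(spectrum2)
    if s1.n_alleles != s2.n_alleles:
        raise BesthetError("spectra must share one harmonized allele universe")
    design1 = ExperimentDesign(list(pair_specs1))
    design2 = ExperimentDesign(list(pair_specs2))

    H1 = true_heterozygosity(s1)
    H2 = true_heterozygosity(s2)
    H12 = between_heterozygosity(s1.freqs, s2.freqs)
    if H12 <= 0:
        raise BesthetError("degenerate denominator: parametric H12 is zero")

    def analytic_var(design: ExperimentDesign, spectrum: LocusSpectrum) -> float:
        if family == "blue":
            w = blue_weights(design.kinship)
        else:
            w = design.allele_copy_weights()
        coeffs = mean_kinship(design.kinship, w, require_higher=True)
        var = variance_exact(spectrum, coeffs)
        if family == "full":
            # classical scaling n/(n-1) instead of 1/(1 - rho2)
            nc = design.n_copies
            var *= ((1.0 - coeffs.rho2) * nc / (nc - 1)) ** 2
        return var

    v_h1 = analytic_var(design1, s1)
    v_h2 = analytic_var(design2, s2)

    rng = np.random.default_rng(seed)
    chunk = _chunk_fst(design1, design2, s1, s2, [family], mc_reps, rng)[family]
    h1, h2, h12 = chunk["h1"], chunk["h2"], chunk["h12"]
    v_h12 = float(np.var(h12, ddof=1))
    cov_12_1 = float(np.cov(h12, h1, ddof=1)[0, 1])
    cov_12_2 = float(np.cov(h12, h2, ddof=1)[0, 1])

    var_x = v_h12 + 0.25 * v_h1 + 0.25 * v_h2 - (cov_12_1 + cov_12_2)
    cov_xy = v_h12 - 0.5 * (cov_12_1 + cov_12_2)
    ex = H12 - 0.5 * (H1 + H2)
    ey = H12
    var_f = var_x / ey**2 + ex**2 * v_h12 / ey**4 - 2.0 * ex * cov_xy / ey**3
    return max(float(var_f), 0.0)
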