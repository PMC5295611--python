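"""Estimators of gene diversity (expected heterozygosity) and their theory.

Parametric gene diversity at a locus with allele frequencies p_i is
H = 1 - sum_i p_i^2.  Estimators implemented here:

* ``h_hat``          the classical estimator [n/(n-1)] (1 - sum p-hat_i^2),
                     with n the number of allele copies; unbiased only for
                     samples of unrelated, outbred individuals.
* ``h_hat_reduced``  h_hat after removing one member of each relative pair.
* ``h_general``      (1 - sum p_i^2) / (1 - rho2) for any unbiased linear
                     frequency estimate with weighted mean kinship rho2;
                     unbiased for arbitrary relatedness, inbreeding, ploidy.
* ``h_tilde``        the sample-proportion specialization (rho2 = Phi-bar-2,
                     allele-copy weights).
* ``h_blue``         the BLUE specialization (rho2 = kappa2, inverse-kinship
                     weights) — minimum-variance frequency estimates.

Also here: the bias of h_hat on related samples, the exact and approximate
theoretical variance of the general estimator, the (I, M)-normalized
diversity statistic B, and MSE bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import BesthetError, DegenerateEstimateError, GenotypeError
from .frequency import (
    FrequencyEstimate,
    GenotypeSample,
    blue_weights,
    linear_estimate,
    sample_proportion,
)
from .identity import MeanKinshipCoefficients
from .pedigree import KinshipSpec

__all__ = [
    "LocusSpectrum",
    "DiversityEstimate",
    "true_heterozygosity",
    "h_hat",
    "h_hat_reduced",
    "h_general",
    "h_tilde",
    "h_blue",
    "bias_h_hat",
    "variance_exact",
    "variance_approx",
    "normalized_het_B",
    "mse",
]

_NORM_TOL = 1e-9


@dataclass
class LocusSpectrum:
    """Parametric allele-frequency spectrum of one locus."""

    freqs: np.ndarray
    labels: Optional[list] = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.size < 1:
            raise BesthetError("spectrum must be a nonempty 1-d frequency vector")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise BesthetError("allele frequencies must lie in [0, 1]")
        if abs(self.freqs.sum() - 1.0) > _NORM_TOL:
            raise BesthetError(
                f"allele frequencies must sum to 1 (got {self.freqs.sum()!r})"
            )
        if self.labels is not None and len(self.labels) != self.freqs.size:
            raise BesthetError("labels length must match frequency vector")

    @classmethod
    def from_counts(cls, counts: Sequence[float], labels=None) -> "LocusSpectrum":
        c = np.asarray(counts, dtype=float)
        return cls(c / c.sum(), labels=labels)

    @property
    def n_alleles(self) -> int:
        return int(self.freqs.size)

    @property
    def max_freq(self) -> float:
        return float(self.freqs.max())


def true_heterozygosity(spectrum: LocusSpectrum | Sequence[float]) -> float:
    """Parametric gene diversity H = 1 - sum_i p_i^2."""
    if not isinstance(spectrum, LocusSpectrum):
        spectrum = LocusSpectrum(np.asarray(spectrum, dtype=float))
    return float(1.0 - np.dot(spectrum.freqs, spectrum.freqs))


@dataclass
class DiversityEstimate:
    """A heterozygosity estimate together with its provenance.

    ``estimator`` is one of ``h_hat_full``, ``h_hat_red``, ``h_general``,
    ``h_tilde``, ``h_blue``.  ``correction`` is the multiplicative factor
    applied to 1 - sum p_i^2 (n/(n-1) or 1/(1-rho2)).  ``out_of_range``
    flags estimates outside [0, 1]; unbiased estimators may exceed the
    parametric range on individual samples, so values are never clipped.
    """

    value: float
    estimator: str
    correction: float
    weights: Optional[np.ndarray] = None
    rho2: Optional[float] = None
    frequencies: Optional[FrequencyEstimate] = None
    variance: Optional[float] = None
    bias: Optional[float] = None

    @property
    def out_of_range(self) -> bool:
        return not (0.0 <= self.value <= 1.0)


def _check_rho2(rho2: float) -> None:
    if not np.isfinite(rho2):
        raise DegenerateEstimateError(f"rho2 must be finite, got {rho2!r}")
    if rho2 >= 1.0:
        raise DegenerateEstimateError(
            f"mean kinship rho2 = {rho2} >= 1: the sample carries no "
            "independent allele information and the estimator is undefined"
        )


def h_hat(sample: GenotypeSample) -> DiversityEstimate:
    """Classical estimator: [n/(n-1)] (1 - sum p-hat_i^2), n = allele copies."""
    sub, _ = sample.complete_cases()
    if sub.n == 0:
        raise GenotypeError("no complete genotypes at this locus")
    n_copies = int(sub.ploidies.sum())
    if n_copies < 2:
        raise BesthetError("h_hat requires at least 2 allele copies")
    freq = sample_proportion(sub)
    corr = n_copies / (n_copies - 1)
    value = corr * (1.0 - freq.sum_squares())
    return DiversityEstimate(
        float(value), "h_hat_full", corr, weights=freq.weights, frequencies=freq
    )


def h_hat_reduced(
    sample: GenotypeSample,
    relative_pairs: Sequence[tuple[str, str]],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DiversityEstimate:
    """h_hat on the sample with one member of each relative pair removed.

    Same-ploidy pairs lose a uniformly chosen member (seeded); mixed-ploidy
    pairs deterministically lose the lower-ploidy member (e.g. the haploid
    male of a male-female pair at an X-linked locus), which discards the
    fewest allele copies.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = {s: i for i, s in enumerate(sample.ids)}
    seen: set[str] = set()
    remove: set[str] = set()
    for a, b in relative_pairs:
        a, b = str(a), str(b)
        for m in (a, b):
            if m not in pos:
                raise BesthetError(f"pair member {m!r} not in sample")
            if m in seen:
                raise BesthetError(f"relative pairs overlap at {m!r}")
            seen.add(m)
        pa, pb = sample.ploidies[pos[a]], sample.ploidies[pos[b]]
        if pa < pb:
            remove.add(a)
        elif pb < pa:
            remove.add(b)
        else:
            remove.add(a if rng.random() < 0.5 else b)
    retained = [i for i in sample.ids if i not in remove]
    est = h_hat(sample.subset(retained))
    est.estimator = "h_hat_red"
    return est


def h_general(
    sample: GenotypeSample,
    weights: Sequence[float],
    rho2: float,
    estimator: str = "h_general",
) -> DiversityEstimate:
    """General unbiased estimator (1 - sum p_i^2)/(1 - rho2).

    ``weights`` must match the complete-case subsample; ``rho2`` is the
    weighted mean kinship of that subsample under the same weights.
    """
    _check_rho2(rho2)
    sub, _ = sample.complete_cases()
    freq = linear_estimate(sub, weights)
    corr = 1.0 / (1.0 - rho2)
    value = corr * (1.0 - freq.sum_squares())
    return DiversityEstimate(
        float(value), estimator, corr, weights=freq.weights, rho2=rho2,
        frequencies=freq,
    )


def h_tilde(sample: GenotypeSample, K: KinshipSpec) -> DiversityEstimate:
    """Unbiased estimator with sample-proportion frequencies.

    Correction 1/(1 - Phi-bar-2) where Phi-bar-2 is the allele-copy-weighted
    mean kinship of the (complete-case) sample.
    """
    sub, _ = sample.complete_cases()
    if sub.n == 0:
        raise GenotypeError("no complete genotypes at this locus")
    Ksub = K.subset(sub.ids)
    w = sub.ploidies / sub.ploidies.sum()
    phi_bar_2 = float(w @ Ksub.matrix @ w)
    est = h_general(sub, w, phi_bar_2, estimator="h_tilde")
    est.frequencies.estimator = "sample_proportion"
    return est


def h_blue(sample: GenotypeSample, K: KinshipSpec) -> DiversityEstimate:
    """Unbiased estimator with BLUE frequencies (minimum-variance weights).

    Correction 1/(1 - kappa2) where kappa2 is the mean kinship under the
    BLUE weights.  Requires an invertible kinship matrix.
    """
    sub, _ = sample.complete_cases()
    if sub.n == 0:
        raise GenotypeError("no complete genotypes at this locus")
    Ksub = K.subset(sub.ids)
    w = blue_weights(Ksub)
    kappa2 = float(w @ Ksub.matrix @ w)
    est = h_general(sub, w, kappa2, estimator="h_blue")
    est.frequencies.estimator = "blue"
    return est


def bias_h_hat(H: float, n_copies: int, rho2: float) -> float:
    """Bias of h_hat on a related/inbred sample: (1 - n rho2) H / (n - 1).

    ``n_copies`` is the total number of allele copies and ``rho2`` the
    allele-copy-weighted mean kinship; the bias vanishes when
    rho2 = 1/n_copies (unrelated outbred samples).
    """
    if n_copies < 2:
        raise BesthetError("n_copies must be >= 2")
    if not 0.0 <= rho2 < 1.0:
        raise BesthetError("rho2 must lie in [0, 1)")
    return (1.0 - n_copies * rho2) / (n_copies - 1) * H


def variance_sum_squares(
    spectrum: LocusSpectrum, coeffs: MeanKinshipCoefficients
) -> float:
    """Var[1 - sum p_i^2] for a general linear frequency estimate.

    Polynomial in sum p_i^2 and sum p_i^3 with coefficients built from the
    weighted mean kinship sums over pairs, trios, quartets and pairs of
    pairs; collapses to zero at a monomorphic locus.
    """
    if not coeffs.complete:
        raise BesthetError(
            "variance requires rho3, rho4 and rho2_2 (tuple coefficients)"
        )
    p = spectrum.freqs
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    r2, r3, r4, r22 = coeffs.rho2, coeffs.rho3, coeffs.rho4, coeffs.rho2_2
    var = (
        (r22 - r2**2)
        + 2.0 * (r2**2 - r4) * s2
        + 4.0 * (2.0 * r4 + r2 - 2.0 * r3 - r22) * s3
        + (3.0 * r22 + 8.0 * r3 - 6.0 * r4 - 4.0 * r2 - r2**2) * s2**2
    )
    return var


def variance_exact(
    spectrum: LocusSpectrum, coeffs: MeanKinshipCoefficients
) -> float:
    """Exact theoretical variance of the general unbiased estimator.

    Var[H] = Var[1 - sum p_i^2] / (1 - rho2)^2, evaluated at the parametric
    spectrum.  Tiny negative round-off is clamped to zero.
    """
    _check_rho2(coeffs.rho2)
    var = variance_sum_squares(spectrum, coeffs) / (1.0 - coeffs.rho2) ** 2
    if var < -1e-10:
        raise BesthetError(f"variance evaluated negative ({var}); check coefficients")
    return max(var, 0.0)


def variance_approx(spectrum: LocusSpectrum, rho2: float) -> float:
    """Approximate variance for samples with at most one relative each.

    4 rho2 [sum p_i^3 - (sum p_i^2)^2] / (1 - rho2)^2 — the higher-order
    mean kinship terms are negligible when no individual is related to more
    than one other.  Nonnegative since sum p^3 >= (sum p^2)^2.
    """
    _check_rho2(rho2)
    if rho2 < 0:
        raise BesthetError("rho2 must be nonnegative")
    p = spectrum.freqs
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    return 4.0 * rho2 * (s3 - s2**2) / (1.0 - rho2) ** 2


def heterozygosity_bounds(I: int, M: float) -> tuple[float, float]:
    """(H_min, H_max) attainable with I distinct alleles and max frequency M.

    H_max splits the residual mass 1-M evenly over the remaining I-1
    alleles; H_min packs it into as few alleles as possible subject to the
    cap M (the supremum when extra alleles would be forced to vanishing
    frequency).
    """
    if I < 1:
        raise BesthetError("I must be >= 1")
    if not (1.0 / I - 1e-12 <= M <= 1.0 + 1e-12):
        raise BesthetError(f"M must lie in [1/I, 1], got {M} with I={I}")
    if I == 1:
        return 0.0, 0.0
    r = 1.0 - M
    h_max = 1.0 - M**2 - r**2 / (I - 1)
    q = int(math.floor(r / M + 1e-12))
    rem = r - q * M
    h_min = 1.0 - ((q + 1) * M**2 + rem**2)
    return h_min, h_max


def normalized_het_B(H_obs: float, I: int, M: float) -> float:
    """Diversity normalized to its attainable range: B = (H - H_min)/R.

    R = H_max - H_min given the allele count I and maximum allele frequency
    M.  Raises :class:`DegenerateEstimateError` when the bounds coincide
    (R = 0, e.g. any biallelic locus, where M fixes the spectrum).
    """
    h_min, h_max = heterozygosity_bounds(I, M)
    R = h_max - h_min
    if R < 1e-12:
        raise DegenerateEstimateError(
            f"heterozygosity range is zero for I={I}, M={M}; B is undefined"
        )
    if not (h_min - 1e-9 <= H_obs <= h_max + 1e-9):
        raise BesthetError(
            f"H_obs={H_obs} outside the attainable range [{h_min}, {h_max}] "
            f"for I={I}, M={M}"
        )
    return float(np.clip((H_obs - h_min) / R, 0.0, 1.0))


def mse(bias: float, variance: float) -> float:
    """Mean squared error: squared bias plus variance."""
    if variance < 0:
        raise BesthetError("variance must be nonnegative")
    return bias * bias + variance
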