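"""Allele-fraction matrix and linear unbiased allele-frequency estimators.

For individual k of ploidy m_k, X_k(i) is the fraction of its m_k allele
copies that are of type i.  Any weight vector w with nonnegative-sum-one
entries yields an unbiased linear estimate p_i = sum_k w_k X_k(i).  Two
weightings matter in practice:

* sample proportion  p-hat:  w_k = m_k / sum_j m_j  (allele-copy weights)
* BLUE               p-tilde: w_k proportional to the column sums of the
  inverse kinship matrix, the minimum-variance unbiased linear weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BesthetError,
    GenotypeError,
    SingularKinshipError,
    WeightError,
)
from .pedigree import KinshipSpec

MISSING = {None, ".", ""}

#: reciprocal-condition-number threshold below which K is treated as singular
RCOND_THRESHOLD = 1e-12


def _is_missing(a) -> bool:
    return a in MISSING or (isinstance(a, float) and np.isnan(a))


@dataclass
class GenotypeSample:
    """Genotypes of n individuals at one locus, with per-individual ploidy.

    ``alleles[k]`` is a tuple of length ``ploidies[k]`` of allele labels
    (any hashable; ``None`` or ``"."`` marks a missing copy).  The allele
    universe is the union of observed and declared alleles, declared first.
    """

    ids: list[str]
    ploidies: np.ndarray
    alleles: list[tuple]
    locus: str = "locus"
    declared_alleles: Optional[list] = None

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.ploidies = np.asarray(self.ploidies, dtype=int)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise GenotypeError("duplicate individual ids in sample")
        if self.ploidies.shape != (n,) or len(self.alleles) != n:
            raise GenotypeError("ids, ploidies and alleles must have equal length")
        if np.any(self.ploidies < 1):
            raise GenotypeError("ploidies must be >= 1")
        self.alleles = [tuple(g) for g in self.alleles]
        for k, g in enumerate(self.alleles):
            if len(g) != self.ploidies[k]:
                raise GenotypeError(
                    f"individual {self.ids[k]!r}: {len(g)} alleles but "
                    f"ploidy {self.ploidies[k]}"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def allele_universe(self) -> list:
        seen: dict[Hashable, None] = {}
        for a in self.declared_alleles or []:
            seen.setdefault(a, None)
        for g in self.alleles:
            for a in g:
                if not _is_missing(a):
                    seen.setdefault(a, None)
        return list(seen)

    def has_missing(self, k: int) -> bool:
        return any(_is_missing(a) for a in self.alleles[k])

    def complete_cases(self) -> tuple["GenotypeSample", np.ndarray]:
        """Drop individuals with any missing allele copy at this locus.

        Returns the retained subsample and the retained index array; this is
        the package-wide missing-data policy, applied before weighting.
        """
        keep = np.array([not self.has_missing(k) for k in range(self.n)])
        idx = np.flatnonzero(keep)
        sub = GenotypeSample(
            [self.ids[i] for i in idx],
            self.ploidies[idx],
            [self.alleles[i] for i in idx],
            locus=self.locus,
            declared_alleles=self.allele_universe,
        )
        return sub, idx

    def subset(self, ids: Sequence[str]) -> "GenotypeSample":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[str(i)] for i in ids]
        return GenotypeSample(
            [self.ids[i] for i in idx],
            self.ploidies[idx],
            [self.alleles[i] for i in idx],
            locus=self.locus,
            declared_alleles=self.allele_universe,
        )


@dataclass
class FrequencyEstimate:
    """Estimated allele frequencies with the weights that produced them.

    ``estimator`` is one of ``"sample_proportion"``, ``"blue"`` or
    ``"custom"``.  ``out_of_range`` flags estimates outside [0, 1], which
    can legitimately occur for BLUE weights (they may be negative); values
    are reported as computed, never clipped, to preserve unbiasedness.
    """

    alleles: list
    freqs: np.ndarray
    weights: np.ndarray
    estimator: str = "custom"
    out_of_range: bool = False

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.out_of_range = bool(
            np.any(self.freqs < -1e-12) or np.any(self.freqs > 1 + 1e-12)
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.freqs, index=self.alleles)

    def sum_squares(self) -> float:
        return float(np.dot(self.freqs, self.freqs))


def allele_fractions(sample: GenotypeSample) -> pd.DataFrame:
    """Allele-fraction matrix X (individuals x alleles); rows sum to 1.

    Requires complete genotypes; apply :meth:`GenotypeSample.complete_cases`
    first if the locus has missing copies.
    """
    universe = sample.allele_universe
    col = {a: i for i, a in enumerate(universe)}
    X = np.zeros((sample.n, len(universe)))
    for k, g in enumerate(sample.alleles):
        for a in g:
            if _is_missing(a):
                raise GenotypeError(
                    f"individual {sample.ids[k]!r} has a missing allele copy; "
                    "drop incomplete individuals first (complete_cases)"
                )
            X[k, col[a]] += 1.0
        X[k] /= sample.ploidies[k]
    return pd.DataFrame(X, index=sample.ids, columns=universe)


def linear_estimate(
    sample: GenotypeSample,
    weights: Sequence[float],
    estimator: str = "custom",
) -> FrequencyEstimate:
    """Generic weighted allele-frequency estimate p_i = sum_k w_k X_k(i)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (sample.n,):
        raise WeightError(f"expected {sample.n} weights, got shape {w.shape}")
    if abs(w.sum() - 1.0) > 1e-8:
        raise WeightError(f"weights must sum to 1 (got {w.sum()!r})")
    X = allele_fractions(sample)
    freqs = w @ X.to_numpy()
    return FrequencyEstimate(list(X.columns), freqs, w, estimator=estimator)


def sample_proportion(sample: GenotypeSample) -> FrequencyEstimate:
    """Pooled allele counts over total allele copies (allele-copy weights)."""
    sub, _ = sample.complete_cases()
    if sub.n == 0:
        raise GenotypeError("no complete genotypes at this locus")
    w = sub.ploidies / sub.ploidies.sum()
    return linear_estimate(sub, w, estimator="sample_proportion")


def blue_weights(K: KinshipSpec | np.ndarray) -> np.ndarray:
    """BLUE weights w_k = (column sums of K^-1)_k / (1' K^-1 1).

    Raises :class:`SingularKinshipError` when the reciprocal condition
    number of K falls below ``RCOND_THRESHOLD`` — the BLUE is defined only
    for invertible kinship matrices.
    """
    M = K.matrix if isinstance(K, KinshipSpec) else np.asarray(K, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise BesthetError("kinship matrix must be square")
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < RCOND_THRESHOLD:
        raise SingularKinshipError(
            "kinship matrix is singular or ill-conditioned; the BLUE of "
            "allele frequency requires an invertible kinship matrix"
        )
    x = np.linalg.solve(M, np.ones(M.shape[0]))
    w = x / x.sum()
    if np.any(w < 0):
        warnings.warn(
            "BLUE weights contain negative entries; frequency estimates may "
            "fall outside [0, 1] (reported unclipped)",
            stacklevel=2,
        )
    return w


def blue_frequencies(sample: GenotypeSample, K: KinshipSpec) -> FrequencyEstimate:
    """BLUE of allele frequencies for a sample with kinship matrix K.

    Individuals with missing copies are dropped and the weights recomputed
    on the matching principal submatrix of K.
    """
    sub, _ = sample.complete_cases()
    if sub.n == 0:
        raise GenotypeError("no complete genotypes at this locus")
    Ksub = K.subset(sub.ids)
    w = blue_weights(Ksub)
    return linear_estimate(sub, w, estimator="blue")
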