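"""Higher-order identity-by-descent coefficients and weighted mean kinship.

The variance of diversity estimators depends on weighted mean kinship
coefficients of the sample over pairs, trios, quartets and pairs of pairs
of individuals:

    rho2   = sum_jk     w_j w_k         Phi_jk
    rho3   = sum_jkl    w_j w_k w_l     Phi_jkl
    rho4   = sum_jklm   w_j w_k w_l w_m Phi_jklm
    rho2_2 = sum_jklm   w_j w_k w_l w_m Phi_jk,lm

where Phi_jkl is the probability that three alleles, sampled one from each
listed individual (independently, with replacement for repeated indices),
are all IBD; Phi_jklm likewise for four; and Phi_jk,lm is the joint
probability that a pair sampled from (j,k) is IBD and a pair sampled from
(l,m) is IBD, the two pair draws being independent.

Two routes produce the tuple coefficients:

* :func:`gene_drop_identity_coeffs` — Monte-Carlo gene dropping: founder
  alleles get unique labels, labels are transmitted by Mendelian (or
  X-linked) rules, and one allele per listed individual is sampled per
  replicate.
* :func:`enumerate_identity_coeffs` — exact enumeration over every meiosis
  outcome of a small pedigree, averaging the conditional allele-draw
  probabilities; feasible whenever the number of transmission patterns is
  modest (it is 4^(#non-founders) for autosomal diploids).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import BesthetError, WeightError
from .pedigree import MALE, KinshipSpec, Pedigree, _check_mode

__all__ = [
    "GeneDropResult",
    "TupleCoefficients",
    "MeanKinshipCoefficients",
    "gene_drop_identity_coeffs",
    "enumerate_identity_coeffs",
    "mean_kinship",
]


# ---------------------------------------------------------------------------
# Gene-drop label transmission
# ---------------------------------------------------------------------------

def _founder_labels(ped: Pedigree, mode: str) -> dict[str, list[int]]:
    """Assign globally unique integer labels to founder allele copies."""
    labels: dict[str, list[int]] = {}
    next_label = 0
    for i in ped.topological_order():
        ind = ped[i]
        if not ind.is_founder:
            continue
        m = ped.ploidy(i, mode)
        labels[i] = list(range(next_label, next_label + m))
        next_label += m
    return labels


def _drop_labels_mc(
    ped: Pedigree, reps: int, rng: np.random.Generator, mode: str
) -> dict[str, np.ndarray]:
    """Vectorized gene drop: per-individual (reps, ploidy) label arrays."""
    founder = _founder_labels(ped, mode)
    next_label = sum(len(v) for v in founder.values())
    out: dict[str, np.ndarray] = {}
    rows = np.arange(reps)

    def pick(parent_id: Optional[str]) -> np.ndarray:
        nonlocal next_label
        if parent_id is None:
            # unknown parent: a fresh unrelated founder allele
            next_label += 1
            return np.full(reps, next_label - 1, dtype=np.int64)
        arr = out[parent_id]
        if arr.shape[1] == 1:
            return arr[:, 0]
        choice = rng.integers(arr.shape[1], size=reps)
        return arr[rows, choice]

    for i in ped.topological_order():
        ind = ped[i]
        if ind.is_founder:
            out[i] = np.tile(np.array(founder[i], dtype=np.int64), (reps, 1))
            continue
        if mode == "x_linked":
            if ind.sex == MALE:
                out[i] = pick(ind.mother)[:, None]
            else:
                if ind.father is None:
                    next_label += 1
                    pat = np.full(reps, next_label - 1, dtype=np.int64)
                else:
                    pat = out[ind.father][:, 0]
                out[i] = np.stack([pat, pick(ind.mother)], axis=1)
        else:
            out[i] = np.stack([pick(ind.father), pick(ind.mother)], axis=1)
    return out


@dataclass
class GeneDropResult:
    """Monte-Carlo identity-coefficient estimates with standard errors.

    ``estimates`` maps coefficient names (``"pair"``, ``"trio"``,
    ``"quartet"``, ``"pair_pair"``) to proportions; ``stderr`` holds the
    matching binomial standard errors; ``reps`` the replicate count.
    """

    ids: tuple[str, ...]
    estimates: dict[str, float]
    stderr: dict[str, float]
    reps: int

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


def _coeff_names(t: int) -> list[str]:
    names = ["pair"]
    if t >= 3:
        names.append("trio")
    if t == 4:
        names += ["quartet", "pair_pair"]
    return names


def gene_drop_identity_coeffs(
    ped: Pedigree,
    ids: Sequence[str],
    reps: int,
    seed: Optional[int] = None,
    mode: str = "autosomal",
    rng: Optional[np.random.Generator] = None,
) -> GeneDropResult:
    """Estimate identity coefficients for a tuple of 2-4 individuals.

    Per replicate, founder alleles receive unique labels, labels are
    transmitted through the pedigree, and one allele is sampled per listed
    individual (independently; repeats allowed).  Returned coefficients,
    depending on tuple length: ``pair`` Phi_jk for the first two ids,
    ``trio`` Phi_jkl, and for 4-tuples ``quartet`` Phi_jklm plus
    ``pair_pair`` Phi_jk,lm with the pairing following argument order.
    """
    _check_mode(mode)
    ids = tuple(str(i) for i in ids)
    if not 2 <= len(ids) <= 4:
        raise BesthetError("ids must contain 2, 3 or 4 individuals")
    if reps < 1:
        raise BesthetError("reps must be >= 1")
    for i in ids:
        ped[i]
    if mode == "x_linked":
        ped.validate_x_linked()
    if rng is None:
        rng = np.random.default_rng(seed)

    labels = _drop_labels_mc(ped, reps, rng, mode)
    rows = np.arange(reps)
    picks = []
    for i in ids:  # independent draw per position, even for repeated ids
        arr = labels[i]
        if arr.shape[1] == 1:
            picks.append(arr[:, 0])
        else:
            picks.append(arr[rows, rng.integers(arr.shape[1], size=reps)])

    est: dict[str, float] = {}
    se: dict[str, float] = {}

    def record(name: str, indicator: np.ndarray) -> None:
        p = float(np.mean(indicator))
        est[name] = p
        se[name] = math.sqrt(p * (1.0 - p) / reps)

    record("pair", picks[0] == picks[1])
    if len(ids) >= 3:
        record("trio", (picks[0] == picks[1]) & (picks[1] == picks[2]))
    if len(ids) == 4:
        record(
            "quartet",
            (picks[0] == picks[1]) & (picks[1] == picks[2]) & (picks[2] == picks[3]),
        )
        record("pair_pair", (picks[0] == picks[1]) & (picks[2] == picks[3]))
    return GeneDropResult(ids, est, se, reps)


# ---------------------------------------------------------------------------
# Exact enumeration for small pedigrees
# ---------------------------------------------------------------------------

_MAX_PATTERNS = 1 << 16


def _transmission_choices(ped: Pedigree, mode: str) -> list[tuple[str, list[str]]]:
    """Per non-founder, the list of random gamete choices it requires."""
    choices = []
    for i in ped.topological_order():
        ind = ped[i]
        if ind.is_founder:
            continue
        if mode == "x_linked":
            # only the maternal gamete is random: a daughter receives her
            # father's single X deterministically, a son no paternal X
            sources = ["mother"]
        else:
            sources = ["father", "mother"]
        choices.append((i, sources))
    return choices


def enumerate_identity_coeffs(
    ped: Pedigree, ids: Sequence[str], mode: str = "autosomal"
) -> dict[str, float]:
    """Exact identity coefficients by enumerating every meiosis outcome.

    For each equally likely transmission pattern the conditional
    probability of the IBD event is computed in closed form from the label
    multiset of each listed individual (a Rao-Blackwellized average, so
    the result is exact).  Raises if the pattern space exceeds 2^16.
    """
    _check_mode(mode)
    ids = tuple(str(i) for i in ids)
    if not 2 <= len(ids) <= 4:
        raise BesthetError("ids must contain 2, 3 or 4 individuals")
    for i in ids:
        ped[i]
    if mode == "x_linked":
        ped.validate_x_linked()

    founder = _founder_labels(ped, mode)
    next_phantom = sum(len(v) for v in founder.values())
    choices = _transmission_choices(ped, mode)

    # each choice slot picks one of the parent's alleles; enumerate products
    slot_sizes = []
    slots = []  # (child, source) in order
    for child, sources in choices:
        ind = ped[child]
        for src in sources:
            parent = ind.father if src == "father" else ind.mother
            if parent is None:
                size = 1  # phantom founder: single fresh allele, no choice
            else:
                size = ped.ploidy(parent, mode)
            slots.append((child, src, parent))
            slot_sizes.append(size)
    total = 1
    for s in slot_sizes:
        total *= s
    if total > _MAX_PATTERNS:
        raise BesthetError(
            f"pedigree too large for exact enumeration ({total} patterns); "
            "use gene_drop_identity_coeffs instead"
        )

    names = _coeff_names(len(ids))
    acc = {name: 0.0 for name in names}

    for pattern in itertools.product(*(range(s) for s in slot_sizes)):
        labels: dict[str, tuple[int, ...]] = {
            f: tuple(v) for f, v in founder.items()
        }
        phantom = next_phantom
        pi = 0
        for i in ped.topological_order():
            ind = ped[i]
            if ind.is_founder:
                continue
            alleles = []
            if mode == "x_linked":
                if ind.sex == MALE:
                    # single maternal pick
                    child, src, parent = slots[pi]
                    assert child == i
                    if parent is None:
                        alleles.append(-phantom - 1)
                        phantom += 1
                    else:
                        alleles.append(labels[parent][pattern[pi]])
                    pi += 1
                else:
                    if ind.father is None:
                        alleles.append(-phantom - 1)
                        phantom += 1
                    else:
                        alleles.append(labels[ind.father][0])
                    child, src, parent = slots[pi]
                    assert child == i and src == "mother"
                    if parent is None:
                        alleles.append(-phantom - 1)
                        phantom += 1
                    else:
                        alleles.append(labels[parent][pattern[pi]])
                    pi += 1
            else:
                for _src in ("father", "mother"):
                    child, src, parent = slots[pi]
                    assert child == i and src == _src
                    if parent is None:
                        alleles.append(-phantom - 1)
                        phantom += 1
                    else:
                        alleles.append(labels[parent][pattern[pi]])
                    pi += 1
            labels[i] = tuple(alleles)

        def draw_prob(positions: Sequence[str]) -> float:
            """P(one uniform allele draw per position are all the same label)."""
            universe = set()
            for p in positions:
                universe.update(labels[p])
            total_p = 0.0
            for lab in universe:
                prod = 1.0
                for p in positions:
                    c = labels[p].count(lab)
                    if c == 0:
                        prod = 0.0
                        break
                    prod *= c / len(labels[p])
                total_p += prod
            return total_p

        acc["pair"] += draw_prob(ids[:2])
        if len(ids) >= 3:
            acc["trio"] += draw_prob(ids[:3])
        if len(ids) == 4:
            acc["quartet"] += draw_prob(ids)
            acc["pair_pair"] += draw_prob(ids[:2]) * draw_prob(ids[2:])

    return {name: acc[name] / total for name in names}


# ---------------------------------------------------------------------------
# Tuple-coefficient container and weighted mean kinship
# ---------------------------------------------------------------------------

@dataclass
class TupleCoefficients:
    """Sparse higher-order identity coefficients, keyed by index tuples.

    Indices refer to positions in the owning sample/kinship ordering.
    Convention for unlisted tuples (exact for samples composed of mutually
    unrelated family blocks): trio and quartet coefficients default to 0;
    pair-of-pairs coefficients default to the product Phi_jk * Phi_lm.
    """

    trio: dict[tuple[int, int, int], float] = field(default_factory=dict)
    quartet: dict[tuple[int, int, int, int], float] = field(default_factory=dict)
    pair_pair: dict[tuple[int, int, int, int], float] = field(default_factory=dict)


@dataclass
class MeanKinshipCoefficients:
    """Weighted mean kinship sums rho2, rho3, rho4, rho2_2 for a weight vector."""

    rho2: float
    rho3: Optional[float]
    rho4: Optional[float]
    rho2_2: Optional[float]
    weights: np.ndarray

    @property
    def complete(self) -> bool:
        return None not in (self.rho3, self.rho4, self.rho2_2)


def mean_kinship(
    K: KinshipSpec,
    weights: Sequence[float],
    tuple_coeffs: Optional[TupleCoefficients] = None,
    require_higher: bool = False,
) -> MeanKinshipCoefficients:
    """Weighted mean kinship coefficients of a sample.

    rho2 = w' K w always; rho3, rho4 and rho2_2 additionally require tuple
    coefficients (from ``tuple_coeffs`` or ``K.tuples``), interpreted under
    the sparse default convention of :class:`TupleCoefficients`.  Indices
    range over all individuals including repeats, so diagonal terms use
    self-kinship.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (K.n,):
        raise WeightError(f"expected {K.n} weights, got shape {w.shape}")
    if abs(w.sum() - 1.0) > 1e-12:
        raise WeightError(f"weights must sum to 1 (got {w.sum()!r})")
    rho2 = float(w @ K.matrix @ w)

    tc = tuple_coeffs if tuple_coeffs is not None else K.tuples
    if tc is None:
        if require_higher:
            raise BesthetError(
                "tuple coefficients required for rho3/rho4/rho2_2 but not provided"
            )
        return MeanKinshipCoefficients(rho2, None, None, None, w)

    rho3 = 0.0
    for (j, k, l), val in tc.trio.items():
        rho3 += w[j] * w[k] * w[l] * val
    rho4 = 0.0
    for (j, k, l, m), val in tc.quartet.items():
        rho4 += w[j] * w[k] * w[l] * w[m] * val
    delta = 0.0
    for (j, k, l, m), val in tc.pair_pair.items():
        delta += w[j] * w[k] * w[l] * w[m] * (val - K.matrix[j, k] * K.matrix[l, m])
    rho2_2 = rho2 * rho2 + delta
    return MeanKinshipCoefficients(rho2, float(rho3), float(rho4), float(rho2_2), w)
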