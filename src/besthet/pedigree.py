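"""Pedigree representation and analytic kinship coefficients.

A pedigree is a directed acyclic graph of individuals with optional father
and mother links; individuals with no recorded parents are founders and are
assumed mutually unrelated and non-inbred.  Pairwise kinship coefficients
Phi_jk — the probability that one allele sampled at random from individual
j and one from k are identical by descent (IBD) — are computed by the
classical recursion on the pedigree, for autosomal and X-linked loci.

Sex is encoded as ``"M"``, ``"F"`` or ``"U"`` (unspecified).  X-linked
analyses require every sex to be specified, every father male and every
mother female; males are hemizygous (one allele, ploidy 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    CycleError,
    DanglingParentError,
    DuplicateIdError,
    SexError,
    UnknownIndividualError,
    BesthetError,
)

MALE = "M"
FEMALE = "F"
UNKNOWN_SEX = "U"

_SEX_CODES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "u": UNKNOWN_SEX, "0": UNKNOWN_SEX, "na": UNKNOWN_SEX, ".": UNKNOWN_SEX,
    "unknown": UNKNOWN_SEX, "unspecified": UNKNOWN_SEX,
}

_MISSING_PARENT = {None, "", "0", ".", "NA"}


def _normalize_sex(sex) -> str:
    if sex is None:
        return UNKNOWN_SEX
    s = str(sex).strip().lower()
    if s in _SEX_CODES:
        return _SEX_CODES[s]
    raise SexError(f"unrecognized sex code: {sex!r}")


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: str = UNKNOWN_SEX

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """Validated pedigree: acyclic, parent references resolved.

    Build with :func:`build_pedigree` (or :meth:`Pedigree.from_records`);
    the constructor performs full validation.
    """

    def __init__(self, individuals: Sequence[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise DuplicateIdError(f"duplicated individual id: {ind.id!r}")
            self._members[ind.id] = ind
        for ind in self._members.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._members:
                    raise DanglingParentError(
                        f"{ind.id!r} names parent {parent!r}, which is not in the pedigree"
                    )
        self._depth: dict[str, int] = {}
        self._compute_depths()
        # kinship memo caches keyed by mode
        self._phi_cache: dict[str, dict[tuple[str, str], float]] = {}

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable) -> "Pedigree":
        """Build from rows of (id, father, mother[, sex]).

        Missing parents may be given as None, "", "0", "." or "NA".
        Accepts tuples/lists or mappings with those keys.
        """
        inds = []
        for row in records:
            if isinstance(row, Mapping):
                rid = row["id"]
                father = row.get("father")
                mother = row.get("mother")
                sex = row.get("sex", UNKNOWN_SEX)
            else:
                row = list(row)
                if len(row) < 3:
                    raise BesthetError(f"pedigree row too short: {row!r}")
                rid, father, mother = row[0], row[1], row[2]
                sex = row[3] if len(row) > 3 else UNKNOWN_SEX

            def _clean(p):
                if p is None or str(p).strip() in _MISSING_PARENT:
                    return None
                return str(p)

            inds.append(
                Individual(str(rid), _clean(father), _clean(mother), _normalize_sex(sex))
            )
        return cls(inds)

    # -- structure ------------------------------------------------------

    def _compute_depths(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(i: str, stack: list[str]) -> int:
            if i in self._depth:
                return self._depth[i]
            if state.get(i) == 0:
                raise CycleError(
                    "pedigree cycle detected involving: " + " -> ".join(stack + [i])
                )
            state[i] = 0
            ind = self._members[i]
            d = 0
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    d = max(d, 1 + visit(parent, stack + [i]))
            state[i] = 1
            self._depth[i] = d
            return d

        for i in self._members:
            visit(i, [])

    def __contains__(self, item: str) -> bool:
        return item in self._members

    def __len__(self) -> int:
        return len(self._members)

    def __getitem__(self, item: str) -> Individual:
        try:
            return self._members[item]
        except KeyError:
            raise UnknownIndividualError(f"unknown individual id: {item!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self._members.items() if ind.is_founder]

    def depth(self, i: str) -> int:
        self[i]
        return self._depth[i]

    def topological_order(self) -> list[str]:
        """Ids ordered founders-first (parents before children)."""
        return sorted(self._members, key=lambda i: (self._depth[i], i))

    def validate_x_linked(self) -> None:
        """Check the pedigree is usable at an X-linked locus."""
        for ind in self._members.values():
            if ind.sex == UNKNOWN_SEX:
                raise SexError(
                    f"X-linked analysis requires a specified sex for {ind.id!r}"
                )
            if ind.father is not None and self._members[ind.father].sex != MALE:
                raise SexError(f"father {ind.father!r} of {ind.id!r} is not male")
            if ind.mother is not None and self._members[ind.mother].sex != FEMALE:
                raise SexError(f"mother {ind.mother!r} of {ind.id!r} is not female")

    def ploidy(self, i: str, mode: str = "autosomal") -> int:
        """Allele copies carried by ``i``: 2 autosomal, 1 for X-linked males."""
        _check_mode(mode)
        if mode == "x_linked" and self[i].sex == MALE:
            return 1
        return 2


def build_pedigree(records: Iterable) -> Pedigree:
    """Validate pedigree rows and return a :class:`Pedigree`.

    Raises :class:`DuplicateIdError`, :class:`DanglingParentError` or
    :class:`CycleError` on malformed input.
    """
    return Pedigree.from_records(records)


def read_ped(path) -> Pedigree:
    """Read a PED-style whitespace-delimited file: id father mother sex.

    "0" (or "." / "NA") marks a missing parent; a leading line starting
    with '#' is treated as a header and skipped.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise BesthetError(f"PED row needs >= 3 columns: {line!r}")
            records.append(parts[:4])
    return build_pedigree(records)


def _check_mode(mode: str) -> None:
    if mode not in ("autosomal", "x_linked"):
        raise BesthetError(f"mode must be 'autosomal' or 'x_linked', got {mode!r}")


# ---------------------------------------------------------------------------
# Kinship recursion
# ---------------------------------------------------------------------------

def kinship_pair(ped: Pedigree, j: str, k: str, mode: str = "autosomal") -> float:
    """Kinship coefficient Phi_jk by the classical pedigree recursion.

    Autosomal: for j a non-founder that is not an ancestor of k,
    Phi_jk = (Phi_{father(j),k} + Phi_{mother(j),k}) / 2, with
    Phi_jj = (1 + F_j)/2 where F_j is the kinship of j's parents, and
    founders mutually unrelated.

    X-linked: males are hemizygous; a male transmits his single X to
    every daughter and nothing to sons, so for male j, Phi_jk =
    Phi_{mother(j),k}, and male self-kinship is 1.
    """
    _check_mode(mode)
    ped[j], ped[k]
    if mode == "x_linked":
        ped.validate_x_linked()
    cache = ped._phi_cache.setdefault(mode, {})

    def phi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        val = _phi_uncached(a, b)
        cache[key] = val
        return val

    def parental_kinship(ind: Individual) -> float:
        if ind.father is None or ind.mother is None:
            return 0.0
        return phi(ind.father, ind.mother)

    def _phi_uncached(a: str, b: str) -> float:
        ia, ib = ped[a], ped[b]
        if a == b:
            if mode == "x_linked" and ia.sex == MALE:
                return 1.0
            return 0.5 * (1.0 + parental_kinship(ia))
        # Recurse on the deeper individual: it cannot be an ancestor of the
        # shallower one (depth strictly increases along descent).
        if ped.depth(a) < ped.depth(b):
            a, b = b, a
            ia, ib = ib, ia
        if ia.is_founder:
            return 0.0  # two distinct founders (a at max depth => b also founder)
        if mode == "x_linked" and ia.sex == MALE:
            return phi(ia.mother, b) if ia.mother is not None else 0.0
        total = 0.0
        for parent in (ia.father, ia.mother):
            if parent is not None:
                total += phi(parent, b)
        return 0.5 * total

    return phi(j, k)


def inbreeding(ped: Pedigree, i: str, mode: str = "autosomal") -> float:
    """Inbreeding coefficient F_i: the kinship of i's parents.

    Zero for founders; zero by convention for hemizygous X-linked males
    (their single allele cannot be autozygous).
    """
    _check_mode(mode)
    ind = ped[i]
    if mode == "x_linked":
        ped.validate_x_linked()
        if ind.sex == MALE:
            return 0.0
    if ind.father is None or ind.mother is None:
        return 0.0
    return kinship_pair(ped, ind.father, ind.mother, mode=mode)


def self_kinship(ploidy: int, f: float) -> float:
    """Probability two alleles drawn with replacement from one individual are IBD.

    For ploidy m and inbreeding coefficient f this is (1 + (m-1) f)/m,
    reducing to (1+f)/2 for diploids and 1 for haploids.
    """
    if ploidy < 1:
        raise BesthetError("ploidy must be >= 1")
    return (1.0 + (ploidy - 1) * f) / ploidy


# ---------------------------------------------------------------------------
# Kinship matrix container
# ---------------------------------------------------------------------------

@dataclass
class KinshipSpec:
    """Labeled symmetric kinship matrix, optionally with tuple coefficients.

    ``matrix[j, k]`` is Phi_jk for the individuals in ``sample_ids``; the
    diagonal holds self-kinship (1 + (m-1) f)/m.  ``tuples`` optionally
    carries higher-order identity coefficients (see
    :class:`besthet.identity.TupleCoefficients`).
    """

    sample_ids: list[str]
    matrix: np.ndarray
    ploidies: Optional[np.ndarray] = None
    tuples: Optional[object] = None  # identity.TupleCoefficients

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise BesthetError(
                f"kinship matrix shape {self.matrix.shape} does not match "
                f"{n} sample ids"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise BesthetError("kinship matrix is not symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise BesthetError("kinship entries must lie in [0, 1]")
        if self.ploidies is not None:
            self.ploidies = np.asarray(self.ploidies, dtype=int)
            if self.ploidies.shape != (n,):
                raise BesthetError("ploidies length does not match sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as e:
            raise UnknownIndividualError(
                f"id {e.args[0]!r} not in kinship matrix"
            ) from None

    def subset(self, ids: Sequence[str]) -> "KinshipSpec":
        """Principal submatrix for the given ids (tuple coefficients dropped)."""
        idx = self.index_of(ids)
        pl = self.ploidies[idx] if self.ploidies is not None else None
        return KinshipSpec(list(ids), self.matrix[np.ix_(idx, idx)], ploidies=pl)


def kinship_matrix(
    ped: Pedigree,
    sample_ids: Sequence[str],
    mode: str = "autosomal",
    ploidies: Optional[Sequence[int]] = None,
) -> KinshipSpec:
    """Assemble the kinship matrix K for a set of pedigree members.

    Off-diagonal entries come from :func:`kinship_pair`; the diagonal uses
    the ploidy-general self-kinship (1 + (m-1) f)/m with f the individual's
    inbreeding coefficient.  In X-linked mode ploidies default to 1 for
    males and 2 for females.
    """
    _check_mode(mode)
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if ploidies is None:
        ploidies = [ped.ploidy(i, mode) for i in sample_ids]
    ploidies = np.asarray(ploidies, dtype=int)
    K = np.zeros((n, n))
    for a in range(n):
        K[a, a] = self_kinship(int(ploidies[a]), inbreeding(ped, sample_ids[a], mode))
        for b in range(a + 1, n):
            K[a, b] = K[b, a] = kinship_pair(ped, sample_ids[a], sample_ids[b], mode)
    return KinshipSpec(sample_ids, K, ploidies=ploidies)
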