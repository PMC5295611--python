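"""Synthetic genotype simulation and bias/variance/MSE experiments.

Samples with a prescribed relatedness structure are generated by gene
dropping through small template pedigrees: founder alleles are drawn
i.i.d. from a parametric spectrum and transmitted by Mendelian (or
X-linked) rules, so the simulated genotypes carry exactly the IBD
structure of the template.  A lighter "copy" method
(:func:`simulate_relative`) reproduces outbred autosomal pair types by
copying 0/1/2 alleles from a proband with the pair type's IBD-sharing
probabilities; inbred and X-linked types always use gene dropping, whose
identity-state structure two-gene sharing probabilities cannot capture.

:func:`run_experiment` replays a sample design over many replicates and
summarizes each estimator's empirical bias, variance and MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .diversity import LocusSpectrum, true_heterozygosity
from .errors import BesthetError
from .frequency import GenotypeSample
from .identity import (
    MeanKinshipCoefficients,
    TupleCoefficients,
    _drop_labels_mc,
    enumerate_identity_coeffs,
    mean_kinship,
)
from .pedigree import KinshipSpec, Pedigree, build_pedigree, kinship_matrix

__all__ = [
    "PairSpec",
    "ExperimentDesign",
    "ExperimentResult",
    "EstimatorSummary",
    "PAIR_TYPES",
    "SHARING_PROBS",
    "pair_template",
    "sample_independent_genotypes",
    "simulate_relative",
    "gene_drop_sample",
    "run_experiment",
    "snp_locus_grid",
    "spawn_rngs",
]

# pair type -> (pedigree rows, member ids, required mode or None for autosomal)
_TEMPLATES: dict[str, tuple[list, tuple[str, ...], str]] = {
    "parent_offspring": (
        [("par", "0", "0", "M"), ("sp", "0", "0", "F"), ("off", "par", "sp", "U")],
        ("par", "off"),
        "autosomal",
    ),
    "full_sib_outbred": (
        [("fa", "0", "0", "M"), ("mo", "0", "0", "F"),
         ("s1", "fa", "mo", "U"), ("s2", "fa", "mo", "U")],
        ("s1", "s2"),
        "autosomal",
    ),
    "full_sib_inbred_sibmating": (
        [("gf", "0", "0", "M"), ("gm", "0", "0", "F"),
         ("p1", "gf", "gm", "M"), ("p2", "gf", "gm", "F"),
         ("c1", "p1", "p2", "U"), ("c2", "p1", "p2", "U")],
        ("c1", "c2"),
        "autosomal",
    ),
    "avuncular": (
        [("gf", "0", "0", "M"), ("gm", "0", "0", "F"),
         ("av", "gf", "gm", "U"), ("pa", "gf", "gm", "M"),
         ("sp", "0", "0", "F"), ("ni", "pa", "sp", "U")],
        ("av", "ni"),
        "autosomal",
    ),
    "mm_xlinked": (
        [("fa", "0", "0", "M"), ("mo", "0", "0", "F"),
         ("b1", "fa", "mo", "M"), ("b2", "fa", "mo", "M")],
        ("b1", "b2"),
        "x_linked",
    ),
    "mf_xlinked": (
        [("fa", "0", "0", "M"), ("mo", "0", "0", "F"),
         ("br", "fa", "mo", "M"), ("si", "fa", "mo", "F")],
        ("br", "si"),
        "x_linked",
    ),
    "ff_xlinked": (
        [("fa", "0", "0", "M"), ("mo", "0", "0", "F"),
         ("s1", "fa", "mo", "F"), ("s2", "fa", "mo", "F")],
        ("s1", "s2"),
        "x_linked",
    ),
    "unrelated_singleton": (
        [("u", "0", "0", "F")],
        ("u",),
        None,  # diploid in autosomal mode, diploid female in x_linked mode
    ),
}

PAIR_TYPES = tuple(_TEMPLATES)

#: probabilities of sharing 0/1/2 alleles IBD for the copy method
#: (outbred autosomal pair types only)
SHARING_PROBS = {
    "parent_offspring": (0.0, 1.0, 0.0),
    "full_sib_outbred": (0.25, 0.5, 0.25),
    "avuncular": (0.5, 0.5, 0.0),
}

_template_cache: dict[str, tuple[Pedigree, tuple[str, ...]]] = {}
_tuple_cache: dict[tuple[str, str], dict] = {}


def pair_template(pair_type: str) -> tuple[Pedigree, tuple[str, ...]]:
    """Template pedigree and focal member ids for a catalogued pair type."""
    if pair_type not in _TEMPLATES:
        raise BesthetError(
            f"unknown pair type {pair_type!r}; choose from {PAIR_TYPES}"
        )
    if pair_type not in _template_cache:
        rows, members, _mode = _TEMPLATES[pair_type]
        _template_cache[pair_type] = (build_pedigree(rows), members)
    return _template_cache[pair_type]


@dataclass(frozen=True)
class PairSpec:
    """A count of relative pairs (or singletons) of one type in a design."""

    pair_type: str
    count: int
    mode: str = "autosomal"

    def __post_init__(self):
        if self.pair_type not in _TEMPLATES:
            raise BesthetError(f"unknown pair type {self.pair_type!r}")
        if self.count < 0:
            raise BesthetError("count must be >= 0")
        required = _TEMPLATES[self.pair_type][2]
        if required is not None and required != self.mode:
            raise BesthetError(
                f"pair type {self.pair_type!r} requires mode {required!r}"
            )
        if self.mode not in ("autosomal", "x_linked"):
            raise BesthetError(f"invalid mode {self.mode!r}")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one master seed (SeedSequence spawn).

    The documented splitting rule for multi-locus / multi-stream runs.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Template tuple coefficients (exact, cached per pair type)
# ---------------------------------------------------------------------------

def _template_tuples(pair_type: str, mode: str) -> dict:
    """Exact within-template identity coefficients for every ordered tuple.

    Returns dict with keys 'trio' and 'quartet'/'pair_pair', mapping
    ordered tuples of member positions to exact values from meiosis
    enumeration.
    """
    key = (pair_type, mode)
    if key in _tuple_cache:
        return _tuple_cache[key]
    ped, members = pair_template(pair_type)
    m = len(members)
    out = {"trio": {}, "quartet": {}, "pair_pair": {}}
    memo: dict[tuple, dict] = {}

    def enum(pos: tuple[int, ...]) -> dict:
        ids = tuple(members[p] for p in pos)
        if ids not in memo:
            memo[ids] = enumerate_identity_coeffs(ped, ids, mode=mode)
        return memo[ids]

    import itertools

    for pos in itertools.product(range(m), repeat=3):
        out["trio"][pos] = enum(pos)["trio"]
    for pos in itertools.product(range(m), repeat=4):
        res = enum(pos)
        out["quartet"][pos] = res["quartet"]
        out["pair_pair"][pos] = res["pair_pair"]
    _tuple_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    pair_type: str
    indices: list[int]  # global member indices


@dataclass
class ExperimentDesign:
    """A relatedness design: independent family blocks with known kinship.

    Built from :class:`PairSpec` counts.  Carries the analytically
    assembled block-diagonal kinship matrix (with exact tuple
    coefficients) plus the relative-pair list for the reduced estimator.
    """

    pair_specs: list[PairSpec]
    mode: str = field(init=False)
    ids: list[str] = field(init=False)
    ploidies: np.ndarray = field(init=False)
    blocks: list[_Block] = field(init=False)
    kinship: KinshipSpec = field(init=False)
    relative_pairs: list[tuple[str, str]] = field(init=False)

    def __post_init__(self):
        specs = [s for s in self.pair_specs if s.count > 0]
        if not specs:
            raise BesthetError("design must contain at least one pair or singleton")
        modes = {s.mode for s in specs}
        if len(modes) != 1:
            raise BesthetError("all pair specs in a design must share one mode")
        self.mode = modes.pop()
        self.pair_specs = specs

        self.ids = []
        self.blocks = []
        self.relative_pairs = []
        ploidies: list[int] = []
        for spec in specs:
            ped, members = pair_template(spec.pair_type)
            for rep in range(spec.count):
                idx = []
                names = []
                for mem in members:
                    gid = f"{spec.pair_type}{rep}_{mem}"
                    idx.append(len(self.ids))
                    self.ids.append(gid)
                    names.append(gid)
                    ploidies.append(ped.ploidy(mem, self.mode))
                self.blocks.append(_Block(spec.pair_type, idx))
                if len(members) == 2:
                    self.relative_pairs.append((names[0], names[1]))
        self.ploidies = np.asarray(ploidies, dtype=int)

        n = len(self.ids)
        K = np.zeros((n, n))
        tuples = TupleCoefficients()
        for block in self.blocks:
            ped, members = pair_template(block.pair_type)
            Kb = kinship_matrix(ped, list(members), mode=self.mode)
            gi = block.indices
            for a in range(len(gi)):
                for b in range(len(gi)):
                    K[gi[a], gi[b]] = Kb.matrix[a, b]
            tt = _template_tuples(block.pair_type, self.mode)
            for pos, val in tt["trio"].items():
                tuples.trio[tuple(gi[p] for p in pos)] = val
            for pos, val in tt["quartet"].items():
                tuples.quartet[tuple(gi[p] for p in pos)] = val
            for pos, val in tt["pair_pair"].items():
                tuples.pair_pair[tuple(gi[p] for p in pos)] = val
        self.kinship = KinshipSpec(
            list(self.ids), K, ploidies=self.ploidies, tuples=tuples
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_copies(self) -> int:
        return int(self.ploidies.sum())

    def allele_copy_weights(self) -> np.ndarray:
        return self.ploidies / self.ploidies.sum()

    def mean_coeffs(self, weights: Sequence[float]) -> MeanKinshipCoefficients:
        """Exact rho2/rho3/rho4/rho2_2 for this design under given weights."""
        return mean_kinship(self.kinship, weights, require_higher=True)

    # -- simulation -----------------------------------------------------

    def simulate_values(
        self, spectrum: LocusSpectrum, reps: int, rng: np.random.Generator
    ) -> list[np.ndarray]:
        """Gene-drop allele values: per individual, a (reps, ploidy) array.

        Allele values are integer indices into ``spectrum.freqs``; founder
        alleles are i.i.d. draws from the spectrum, transmitted through the
        block template pedigrees, so IBD copies are literal copies.
        """
        out: list[Optional[np.ndarray]] = [None] * self.n
        I = spectrum.n_alleles
        for block in self.blocks:
            ped, members = pair_template(block.pair_type)
            labels = _drop_labels_mc(ped, reps, rng, self.mode)
            n_founder = sum(ped.ploidy(f, self.mode) for f in ped.founders)
            values = rng.choice(I, size=(reps, n_founder), p=spectrum.freqs)
            for mem, gi in zip(members, block.indices):
                out[gi] = np.take_along_axis(values, labels[mem], axis=1)
        return out  # type: ignore[return-value]

    def simulate_counts(
        self, spectrum: LocusSpectrum, reps: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Allele-count tensor (reps, n individuals, I alleles)."""
        C = np.zeros((reps, self.n, spectrum.n_alleles), dtype=np.int16)
        rows = np.arange(reps)
        for k, vals in enumerate(self.simulate_values(spectrum, reps, rng)):
            for t in range(vals.shape[1]):
                np.add.at(C, (rows, k, vals[:, t]), 1)
        return C

    def to_sample(
        self,
        spectrum: LocusSpectrum,
        rng: Optional[np.random.Generator] = None,
        seed: Optional[int] = None,
        locus: str = "locus",
    ) -> GenotypeSample:
        """One simulated :class:`GenotypeSample` from this design."""
        if rng is None:
            rng = np.random.default_rng(seed)
        vals = self.simulate_values(spectrum, 1, rng)
        labels = spectrum.labels or list(range(spectrum.n_alleles))
        alleles = [tuple(labels[a] for a in v[0]) for v in vals]
        return GenotypeSample(
            list(self.ids), self.ploidies.copy(), alleles, locus=locus,
            declared_alleles=list(labels),
        )


# ---------------------------------------------------------------------------
# Simple samplers
# ---------------------------------------------------------------------------

def _as_spectrum(spectrum) -> LocusSpectrum:
    return spectrum if isinstance(spectrum, LocusSpectrum) else LocusSpectrum(
        np.asarray(spectrum, dtype=float)
    )


def sample_independent_genotypes(
    spectrum,
    n: int,
    ploidies: Sequence[int] | int = 2,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GenotypeSample:
    """n unrelated individuals with allele copies i.i.d. from the spectrum."""
    spectrum = _as_spectrum(spectrum)
    if rng is None:
        rng = np.random.default_rng(seed)
    if np.isscalar(ploidies):
        ploidies = [int(ploidies)] * n
    ploidies = np.asarray(ploidies, dtype=int)
    labels = spectrum.labels or list(range(spectrum.n_alleles))
    alleles = []
    for m in ploidies:
        draws = rng.choice(spectrum.n_alleles, size=int(m), p=spectrum.freqs)
        alleles.append(tuple(labels[a] for a in draws))
    ids = [f"ind{k}" for k in range(n)]
    return GenotypeSample(ids, ploidies, alleles, declared_alleles=list(labels))


def simulate_relative(
    proband: Sequence,
    pair_type: str,
    spectrum,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple:
    """Copy method: a relative sharing 0/1/2 alleles IBD with the proband.

    Only the outbred autosomal pair types have valid two-gene sharing
    probabilities; inbred and X-linked pairs must be generated by gene
    dropping (:func:`gene_drop_sample`).
    """
    if pair_type not in SHARING_PROBS:
        raise BesthetError(
            f"pair type {pair_type!r} has no copy-method sharing probabilities; "
            "use gene_drop_sample"
        )
    proband = tuple(proband)
    if len(proband) != 2:
        raise BesthetError("copy method requires a diploid proband")
    spectrum = _as_spectrum(spectrum)
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = spectrum.labels or list(range(spectrum.n_alleles))
    shared = rng.choice(3, p=SHARING_PROBS[pair_type])
    if shared == 0:
        copied: tuple = ()
    elif shared == 1:
        copied = (proband[rng.integers(2)],)
    else:
        copied = proband
    fresh = tuple(
        labels[a]
        for a in rng.choice(spectrum.n_alleles, size=2 - shared, p=spectrum.freqs)
    )
    return copied + fresh


def gene_drop_sample(
    pair_specs: Sequence[PairSpec],
    spectrum,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GenotypeSample:
    """Simulate one sample with the IBD structure of the given pair design."""
    design = ExperimentDesign(list(pair_specs))
    return design.to_sample(_as_spectrum(spectrum), rng=rng, seed=seed)


def snp_locus_grid(
    maf_min: float, maf_max: float, step: float
) -> list[LocusSpectrum]:
    """Biallelic spectra (m, 1-m) for minor allele frequency m on a grid."""
    if not (0.0 < maf_min <= maf_max <= 0.5):
        raise BesthetError("need 0 < maf_min <= maf_max <= 0.5")
    if step <= 0:
        raise BesthetError("step must be positive")
    count = int(round((maf_max - maf_min) / step)) + 1
    out = []
    for i in range(count):
        m = maf_min + i * step
        if m > maf_max + 1e-9:
            break
        out.append(LocusSpectrum(np.array([m, 1.0 - m])))
    return out


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

ESTIMATOR_TAGS = ("h_hat_full", "h_hat_red", "h_tilde", "h_blue")


@dataclass
class EstimatorSummary:
    mean: float
    bias: float
    variance: float
    mse: float
    se_mean: float


@dataclass
class ExperimentResult:
    """Replicate-level estimator values and their bias/variance/MSE summary.

    ``variance`` uses the population convention (ddof=0) so that
    mse = bias^2 + variance holds as an identity; ``se_mean`` is the
    Monte-Carlo standard error of the replicate mean.
    """

    true_H: float
    reps: int
    seed: Optional[int]
    summaries: dict[str, EstimatorSummary]
    values: dict[str, np.ndarray]
    frequencies: dict[str, np.ndarray]
    design: ExperimentDesign

    def __getitem__(self, tag: str) -> EstimatorSummary:
        return self.summaries[tag]


def _summarize(values: np.ndarray, true_H: float) -> EstimatorSummary:
    mean = float(values.mean())
    bias = mean - true_H
    var = float(values.var(ddof=0))
    mse_emp = float(np.mean((values - true_H) ** 2))
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else np.nan
    return EstimatorSummary(mean, bias, var, mse_emp, se)


def estimator_chunk(
    design: ExperimentDesign,
    C: np.ndarray,
    rng: np.random.Generator,
    estimators: Sequence[str],
    blue_w: Optional[np.ndarray] = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Vectorized estimator values for a chunk of simulated count tensors.

    Returns (values, frequencies): per-tag (R,) heterozygosity estimates
    and per-family (R, I) frequency estimates ('sample_proportion',
    'blue', 'reduced' as applicable).
    """
    R = C.shape[0]
    m = design.ploidies
    X = C.astype(np.float64) / m[None, :, None]
    vals: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}

    need_hat = any(t in estimators for t in ("h_hat_full", "h_tilde"))
    if need_hat:
        w_hat = design.allele_copy_weights()
        p_hat = np.einsum("rni,n->ri", X, w_hat)
        ss_hat = np.einsum("ri,ri->r", p_hat, p_hat)
        freqs["sample_proportion"] = p_hat
    if "h_hat_full" in estimators:
        nc = design.n_copies
        vals["h_hat_full"] = (nc / (nc - 1)) * (1.0 - ss_hat)
    if "h_tilde" in estimators:
        w_hat = design.allele_copy_weights()
        phi_bar_2 = float(w_hat @ design.kinship.matrix @ w_hat)
        vals["h_tilde"] = (1.0 - ss_hat) / (1.0 - phi_bar_2)
    if "h_blue" in estimators:
        if blue_w is None:
            from .frequency import blue_weights

            blue_w = blue_weights(design.kinship)
        kappa2 = float(blue_w @ design.kinship.matrix @ blue_w)
        p_blue = np.einsum("rni,n->ri", X, blue_w)
        ss_blue = np.einsum("ri,ri->r", p_blue, p_blue)
        vals["h_blue"] = (1.0 - ss_blue) / (1.0 - kappa2)
        freqs["blue"] = p_blue
    if "h_hat_red" in estimators:
        mask = np.ones((R, design.n), dtype=bool)
        rows = np.arange(R)
        pos = {s: i for i, s in enumerate(design.ids)}
        for a, b in design.relative_pairs:
            ia, ib = pos[a], pos[b]
            if m[ia] < m[ib]:
                mask[:, ia] = False
            elif m[ib] < m[ia]:
                mask[:, ib] = False
            else:
                pick = rng.integers(2, size=R)
                mask[rows, np.where(pick == 1, ia, ib)] = False
        mw = mask * m[None, :]
        n_red = mw.sum(axis=1)
        w_red = mw / n_red[:, None]
        p_red = np.einsum("rn,rni->ri", w_red, X)
        ss_red = np.einsum("ri,ri->r", p_red, p_red)
        vals["h_hat_red"] = (n_red / (n_red - 1.0)) * (1.0 - ss_red)
        freqs["reduced"] = p_red
    return vals, freqs


def run_experiment(
    pair_specs: Sequence[PairSpec],
    spectrum,
    estimators: Sequence[str] = ESTIMATOR_TAGS,
    reps: int = 10_000,
    seed: Optional[int] = None,
    chunk_size: int = 20_000,
    keep_frequencies: bool = False,
) -> ExperimentResult:
    """Monte-Carlo bias/variance/MSE experiment over a sample design.

    Gene-drops ``reps`` independent samples from the design, applies each
    requested estimator, and summarizes against the parametric H of the
    spectrum.  Deterministic for a fixed seed.
    """
    spectrum = _as_spectrum(spectrum)
    if reps < 2:
        raise BesthetError("reps must be >= 2")
    for tag in estimators:
        if tag not in ESTIMATOR_TAGS:
            raise BesthetError(f"unknown estimator tag {tag!r}")
    design = ExperimentDesign(list(pair_specs))
    rng = np.random.default_rng(seed)

    blue_w = None
    if "h_blue" in estimators:
        from .frequency import blue_weights

        blue_w = blue_weights(design.kinship)  # raises early on singular K

    pieces: dict[str, list[np.ndarray]] = {t: [] for t in estimators}
    freq_pieces: dict[str, list[np.ndarray]] = {}
    done = 0
    while done < reps:
        r = min(chunk_size, reps - done)
        C = design.simulate_counts(spectrum, r, rng)
        vals, freqs = estimator_chunk(design, C, rng, estimators, blue_w=blue_w)
        for t in estimators:
            pieces[t].append(vals[t])
        if keep_frequencies:
            for fam, arr in freqs.items():
                freq_pieces.setdefault(fam, []).append(arr)
        done += r

    true_H = true_heterozygosity(spectrum)
    values = {t: np.concatenate(pieces[t]) for t in estimators}
    frequencies = {f: np.concatenate(a) for f, a in freq_pieces.items()}
    summaries = {t: _summarize(v, true_H) for t, v in values.items()}
    return ExperimentResult(
        true_H, reps, seed, summaries, values, frequencies, design
    )
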