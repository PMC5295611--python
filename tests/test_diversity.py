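"""Heterozygosity estimators, bias and variance theory, B statistic."""

import numpy as np
import pytest

import besthet as bh
from besthet.diversity import heterozygosity_bounds, variance_sum_squares
from besthet.errors import BesthetError, DegenerateEstimateError
from besthet.identity import TupleCoefficients, mean_kinship


class TestTrueHeterozygosity:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([0.15, 0.85], 0.255),
            ([0.05, 0.95], 0.095),
            ([0.01, 0.99], 0.0198),
            ([1.0], 0.0),
        ],
    )
    def test_known_values(self, freqs, expected):
        assert bh.true_heterozygosity(freqs) == pytest.approx(expected)

    def test_unnormalized_rejected(self):
        with pytest.raises(BesthetError):
            bh.LocusSpectrum(np.array([0.5, 0.4]))

    def test_upper_bound(self):
        for I in (2, 3, 5):
            assert bh.true_heterozygosity([1 / I] * I) == pytest.approx(1 - 1 / I)


class TestHHat:
    def test_one_diploid_heterozygote(self):
        s = bh.GenotypeSample(["a"], [2], [("A", "B")])
        assert bh.h_hat(s).value == pytest.approx(1.0)

    def test_monomorphic(self):
        s = bh.GenotypeSample(["a", "b"], [2, 2], [("A", "A"), ("A", "A")])
        assert bh.h_hat(s).value == 0.0

    def test_two_heterozygotes(self):
        s = bh.GenotypeSample(["a", "b"], [2, 2], [("A", "B"), ("A", "B")])
        assert bh.h_hat(s).value == pytest.approx(2 / 3)

    def test_requires_two_copies(self):
        with pytest.raises(BesthetError):
            bh.h_hat(bh.GenotypeSample(["a"], [1], [("A",)]))


class TestHHatReduced:
    def test_no_pairs_identical_to_h_hat(self):
        s = bh.GenotypeSample(
            ["a", "b", "c"], [2, 2, 2], [("A", "B"), ("A", "A"), ("B", "B")]
        )
        assert bh.h_hat_reduced(s, [], seed=0).value == bh.h_hat(s).value

    def test_haploid_member_removed_deterministically(self):
        s = bh.GenotypeSample(["m", "f"], [1, 2], [("A",), ("A", "B")])
        est = bh.h_hat_reduced(s, [("m", "f")], seed=0)
        # only the female's two copies remain: h_hat = 2 * (1 - 1/2) = 1
        assert est.value == pytest.approx(1.0)
        assert est.estimator == "h_hat_red"

    def test_retained_count_and_determinism(self):
        rng = np.random.default_rng(8)
        n_pairs = 30
        ids, alleles, pairs = [], [], []
        for i in range(n_pairs):
            a, b = f"p{i}a", f"p{i}b"
            ids += [a, b]
            alleles += [tuple(rng.choice(["A", "B", "C"], 2)) for _ in range(2)]
            pairs.append((a, b))
        s = bh.GenotypeSample(ids, [2] * (2 * n_pairs), alleles)
        e1 = bh.h_hat_reduced(s, pairs, seed=5)
        e2 = bh.h_hat_reduced(s, pairs, seed=5)
        assert e1.value == e2.value
        assert len(e1.weights) == n_pairs

    def test_overlapping_pairs_rejected(self):
        s = bh.GenotypeSample(
            ["a", "b", "c"], [2, 2, 2], [("A", "B")] * 3
        )
        with pytest.raises(BesthetError):
            bh.h_hat_reduced(s, [("a", "b"), ("b", "c")], seed=0)


class TestCorrectedEstimators:
    def test_h_general_specializations(self, sib_kinship):
        s = bh.GenotypeSample(["a", "b"], [2, 2], [("A", "B"), ("A", "A")])
        w = s.ploidies / s.ploidies.sum()
        phi_bar = float(w @ sib_kinship.matrix @ w)
        assert bh.h_general(s, w, phi_bar).value == pytest.approx(
            bh.h_tilde(s, sib_kinship).value
        )
        wb = bh.blue_weights(sib_kinship)
        kappa = float(wb @ sib_kinship.matrix @ wb)
        assert bh.h_general(s, wb, kappa).value == pytest.approx(
            bh.h_blue(s, sib_kinship).value
        )

    def test_monomorphic_zero(self, sib_kinship):
        s = bh.GenotypeSample(["a", "b"], [2, 2], [("A", "A"), ("A", "A")])
        assert bh.h_tilde(s, sib_kinship).value == 0.0
        assert bh.h_blue(s, sib_kinship).value == 0.0

    def test_full_sib_pair_hand_value(self, sib_kinship):
        s = bh.GenotypeSample(["a", "b"], [2, 2], [("A", "B"), ("A", "B")])
        assert bh.h_tilde(s, sib_kinship).value == pytest.approx(0.8)
        assert bh.h_blue(s, sib_kinship).value == pytest.approx(0.8)

    def test_single_diploid(self):
        K = bh.KinshipSpec(["a"], np.array([[0.5]]))
        s = bh.GenotypeSample(["a"], [2], [("A", "B")])
        assert bh.h_tilde(s, K).value == pytest.approx(1.0)

    def test_h_tilde_equals_h_hat_on_unrelated_samples(self):
        """Algebraic identity: Phi-bar-2 = 1/(total copies) for unrelated
        outbred samples of any ploidy mix makes the corrections coincide."""
        rng = np.random.default_rng(12)
        ploidies = [2, 2, 1, 2, 1, 2]
        ids = [f"u{i}" for i in range(len(ploidies))]
        alleles = [tuple(rng.choice(["A", "B", "C"], m)) for m in ploidies]
        s = bh.GenotypeSample(ids, ploidies, alleles)
        K = bh.KinshipSpec(ids, np.diag([1.0 / m for m in ploidies]),
                           ploidies=np.array(ploidies))
        assert bh.h_tilde(s, K).value == pytest.approx(bh.h_hat(s).value, abs=1e-12)
        assert bh.h_blue(s, K).value == pytest.approx(bh.h_hat(s).value, abs=1e-12)

    def test_degenerate_rho2_rejected(self):
        K = bh.KinshipSpec(["h"], np.array([[1.0]]))
        s = bh.GenotypeSample(["h"], [1], [("A",)])
        with pytest.raises(DegenerateEstimateError):
            bh.h_tilde(s, K)

    def test_invariance_to_relabeling_and_order(self, sib_kinship):
        s = bh.GenotypeSample(["a", "b"], [2, 2], [("A", "B"), ("A", "A")])
        relabeled = bh.GenotypeSample(["a", "b"], [2, 2], [("x", "y"), ("x", "x")])
        assert bh.h_blue(s, sib_kinship).value == pytest.approx(
            bh.h_blue(relabeled, sib_kinship).value
        )
        flipped = bh.GenotypeSample(["b", "a"], [2, 2], [("A", "A"), ("A", "B")])
        Kf = sib_kinship.subset(["b", "a"])
        assert bh.h_blue(s, sib_kinship).value == pytest.approx(
            bh.h_blue(flipped, Kf).value
        )


class TestBias:
    def test_zero_for_unrelated(self):
        assert bh.bias_h_hat(0.5, 10, 1 / 10) == pytest.approx(0.0)

    def test_full_sib_pair(self):
        assert bh.bias_h_hat(0.6, 4, 3 / 8) == pytest.approx(-0.1)

    def test_zero_H(self):
        assert bh.bias_h_hat(0.0, 8, 0.3) == 0.0

    def test_matches_monte_carlo(self, msat_spectrum):
        """Eq-predicted bias of the classical estimator agrees with its
        empirical bias over gene-drop replicates of a full-sib-pair design."""
        design = [bh.PairSpec("full_sib_outbred", 2)]
        res = bh.run_experiment(design, msat_spectrum,
                                estimators=("h_hat_full",), reps=40_000, seed=13)
        d = res.design
        w = d.allele_copy_weights()
        rho2 = float(w @ d.kinship.matrix @ w)
        predicted = bh.bias_h_hat(res.true_H, d.n_copies, rho2)
        s = res["h_hat_full"]
        assert abs(s.bias - predicted) <= 3 * s.se_mean


def _design_coeffs(design_specs, weights=None):
    d = bh.ExperimentDesign(design_specs)
    w = d.allele_copy_weights() if weights is None else weights
    return d, d.mean_coeffs(w)


class TestVarianceTheory:
    def test_monomorphic_collapses(self, mixed_design):
        _, co = _design_coeffs(mixed_design)
        assert bh.variance_exact(bh.LocusSpectrum(np.array([1.0])), co) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_single_diploid_closed_form(self):
        """One outbred diploid at p=(1/2,1/2): Var[H] = 1/4 exactly (the
        estimator is 0 or 1 with equal chance of heterozygosity 1/2)."""
        _, co = _design_coeffs([bh.PairSpec("unrelated_singleton", 1)])
        spec = bh.LocusSpectrum(np.array([0.5, 0.5]))
        assert bh.variance_exact(spec, co) == pytest.approx(0.25)

    def test_matches_empirical_variance(self, msat_spectrum):
        """Theoretical variance equals the empirical variance of the matching
        estimator over 1e5 gene-drop replicates (small-pedigree oracle)."""
        design = [bh.PairSpec("full_sib_outbred", 2),
                  bh.PairSpec("unrelated_singleton", 2)]
        d, co = _design_coeffs(design)
        theory = bh.variance_exact(msat_spectrum, co)
        res = bh.run_experiment(design, msat_spectrum,
                                estimators=("h_tilde",), reps=100_000, seed=17)
        v = res.values["h_tilde"]
        emp = v.var(ddof=1)
        m4 = np.mean((v - v.mean()) ** 4)
        se_var = np.sqrt(max(m4 - emp**2, 0.0) / v.size)
        assert abs(theory - emp) <= 3 * se_var

    def test_approx_close_for_one_relative_each(self, mixed_design, msat_spectrum):
        """Higher-order terms are negligible when each individual has at
        most one relative: the approximation tracks the exact variance."""
        _, co = _design_coeffs(mixed_design)
        exact = bh.variance_exact(msat_spectrum, co)
        approx = bh.variance_approx(msat_spectrum, co.rho2)
        assert approx == pytest.approx(exact, rel=0.10)

    @pytest.mark.parametrize("freqs", [[1.0], [0.5, 0.5]])
    def test_approx_zero_cases(self, freqs):
        assert bh.variance_approx(
            bh.LocusSpectrum(np.array(freqs)), 0.3
        ) == pytest.approx(0.0, abs=1e-15)

    def test_approx_hand_value(self):
        spec = bh.LocusSpectrum(np.array([0.95, 0.05]))
        got = bh.variance_approx(spec, 3 / 8)
        assert got == pytest.approx(0.1477, abs=5e-5)

    def test_approx_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(rng.integers(2, 8)))
            spec = bh.LocusSpectrum(p / p.sum())
            assert bh.variance_approx(spec, 0.2) >= 0.0

    def test_missing_coefficients_rejected(self, sib_kinship, msat_spectrum):
        co = bh.mean_kinship(sib_kinship, [0.5, 0.5])
        with pytest.raises(BesthetError):
            bh.variance_exact(msat_spectrum, co)


class TestNormalizedB:
    def test_endpoints(self):
        h_min, h_max = heterozygosity_bounds(4, 0.4)
        assert bh.normalized_het_B(h_max, 4, 0.4) == pytest.approx(1.0)
        assert bh.normalized_het_B(h_min, 4, 0.4) == pytest.approx(0.0)

    def test_biallelic_degenerate(self):
        with pytest.raises(DegenerateEstimateError):
            bh.normalized_het_B(0.42, 2, 0.7)

    def test_out_of_range_rejected(self):
        with pytest.raises(BesthetError):
            bh.normalized_het_B(0.99, 3, 0.5)

    @pytest.mark.parametrize("I, M", [(3, 0.5), (3, 0.8), (4, 0.3), (4, 0.6)])
    def test_bounds_match_brute_force(self, I, M):
        """Closed-form H bounds agree with brute-force optimization over a
        discretized simplex with max frequency M and <= I alleles."""
        g = 40  # grid resolution 1/g
        cap = int(round(M * g))
        best, worst = -1.0, 2.0
        # first allele pinned at the cap; enumerate the residual compositions
        for counts in _compositions(g - cap, I - 1, cap):
            p = np.array([cap] + list(counts)) / g
            h = 1 - np.sum(p**2)
            best = max(best, h)
            worst = min(worst, h)
        h_min, h_max = heterozygosity_bounds(I, M)
        assert h_max == pytest.approx(best, abs=2.0 / g)
        assert h_min == pytest.approx(worst, abs=2.0 / g)


def _compositions(total, parts, cap):
    if parts == 1:
        if 0 <= total <= cap:
            yield (total,)
        return
    for first in range(min(total, cap) + 1):
        for rest in _compositions(total - first, parts - 1, cap):
            yield (first,) + rest


class TestMse:
    @pytest.mark.parametrize(
        "bias, var, expected", [(0.0, 0.3, 0.3), (0.2, 0.0, 0.04), (-0.1, 0.02, 0.03)]
    )
    def test_identity(self, bias, var, expected):
        assert bh.mse(bias, var) == pytest.approx(expected)

    def test_negative_variance_rejected(self):
        with pytest.raises(BesthetError):
            bh.mse(0.1, -1e-3)
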