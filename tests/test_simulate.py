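"""Gene-drop simulation, the copy method, and the experiment runner."""

import numpy as np
import pytest
from scipy import stats

import besthet as bh
from besthet.errors import BesthetError
from besthet.identity import gene_drop_identity_coeffs
from besthet.simulate import SHARING_PROBS, ExperimentDesign, pair_template


class TestIndependentGenotypes:
    def test_monomorphic(self):
        s = bh.sample_independent_genotypes([1.0], 5, seed=0)
        assert all(g == (0, 0) for g in s.alleles)

    def test_allele_frequency_law_of_large_numbers(self):
        n = 50_000
        s = bh.sample_independent_genotypes([0.5, 0.5], n, seed=1)
        count = sum(g.count(0) for g in s.alleles)
        se = np.sqrt(0.25 * 2 * n)
        assert abs(count - n) <= 3 * se

    def test_deterministic(self):
        a = bh.sample_independent_genotypes([0.3, 0.7], 20, seed=7)
        b = bh.sample_independent_genotypes([0.3, 0.7], 20, seed=7)
        assert a.alleles == b.alleles


class TestCopyMethod:
    def test_parent_offspring_always_shares_one(self):
        rng = np.random.default_rng(2)
        spec = bh.LocusSpectrum(np.array([0.25] * 4))
        for _ in range(200):
            proband = (0, 1)
            rel = bh.simulate_relative(proband, "parent_offspring", spec, rng=rng)
            assert len(set(rel) & {0, 1}) >= 1

    @pytest.mark.parametrize(
        "pair_type, phi",
        [("parent_offspring", 0.25), ("full_sib_outbred", 0.25), ("avuncular", 0.125)],
    )
    def test_empirical_kinship(self, pair_type, phi):
        """The sharing probabilities imply the analytic kinship:
        Phi = P(1 shared)/4 + P(2 shared)/2."""
        p0, p1, p2 = SHARING_PROBS[pair_type]
        assert p1 / 4 + p2 / 2 == pytest.approx(phi)
        # and empirically via a monomorphic-free many-allele spectrum in
        # which identity in state implies identity by descent
        rng = np.random.default_rng(3)
        n_alleles = 2000
        spec = bh.LocusSpectrum(np.full(n_alleles, 1 / n_alleles))
        reps = 20_000
        hits = 0
        for _ in range(reps):
            proband = tuple(rng.choice(n_alleles, 2, p=spec.freqs))
            rel = bh.simulate_relative(proband, pair_type, spec, rng=rng)
            a = proband[rng.integers(2)]
            b = rel[rng.integers(2)]
            hits += a == b
        est = hits / reps
        se = np.sqrt(phi * (1 - phi) / reps)
        # tiny inflation from identity-in-state collisions (~1/n_alleles)
        assert abs(est - phi) <= 3 * se + 2 / n_alleles

    def test_uncatalogued_type_rejected(self):
        with pytest.raises(BesthetError):
            bh.simulate_relative((0, 1), "full_sib_inbred_sibmating", [0.5, 0.5], seed=0)

    def test_matches_gene_drop_distribution(self):
        """Copy method and pedigree gene drop give the same joint genotype
        distribution for outbred full siblings at a 3-allele locus."""
        spec = bh.LocusSpectrum(np.array([0.5, 0.3, 0.2]))
        reps = 30_000
        rng = np.random.default_rng(4)

        def joint_key(g1, g2):
            return (tuple(sorted(g1)), tuple(sorted(g2)))

        from collections import Counter

        copy_counts: Counter = Counter()
        for _ in range(reps):
            proband = tuple(rng.choice(3, 2, p=spec.freqs))
            rel = bh.simulate_relative(proband, "full_sib_outbred", spec, rng=rng)
            copy_counts[joint_key(proband, rel)] += 1

        design = ExperimentDesign([bh.PairSpec("full_sib_outbred", 1)])
        vals = design.simulate_values(spec, reps, np.random.default_rng(5))
        drop_counts: Counter = Counter()
        for r in range(reps):
            drop_counts[joint_key(vals[0][r], vals[1][r])] += 1

        keys = sorted(set(copy_counts) | set(drop_counts))
        a = np.array([copy_counts.get(k, 0) for k in keys])
        b = np.array([drop_counts.get(k, 0) for k in keys])
        _, pvalue, _, _ = stats.chi2_contingency(np.vstack([a, b]))
        assert pvalue > 1e-4


class TestGeneDropSample:
    @pytest.mark.parametrize(
        "pair_type, mode, phi",
        [
            ("full_sib_inbred_sibmating", "autosomal", 3 / 8),
            ("mm_xlinked", "x_linked", 0.5),
            ("mf_xlinked", "x_linked", 0.25),
            ("ff_xlinked", "x_linked", 3 / 8),
        ],
    )
    def test_template_pair_kinship(self, pair_type, mode, phi):
        """Label-tracking gene drop through each template pedigree
        reproduces the analytic pair kinship."""
        ped, members = pair_template(pair_type)
        res = gene_drop_identity_coeffs(ped, members, reps=200_000, seed=19, mode=mode)
        assert abs(res["pair"] - phi) <= 3 * max(res.stderr["pair"], 1e-4)

    def test_sample_structure(self):
        s = bh.gene_drop_sample(
            [bh.PairSpec("full_sib_outbred", 2), bh.PairSpec("unrelated_singleton", 3)],
            [0.5, 0.5], seed=5,
        )
        assert s.n == 7
        assert all(m == 2 for m in s.ploidies)

    def test_x_linked_males_haploid(self):
        s = bh.gene_drop_sample(
            [bh.PairSpec("mf_xlinked", 2, mode="x_linked")], [0.3, 0.7], seed=5
        )
        assert list(s.ploidies) == [1, 2, 1, 2]

    def test_unrelated_blocks_match_independent_sampler(self):
        """30 gene-dropped singletons are distributionally indistinguishable
        from i.i.d. sampling (genotype-class frequencies)."""
        from collections import Counter

        spec = bh.LocusSpectrum(np.array([0.6, 0.3, 0.1]))
        reps = 4000
        design = ExperimentDesign([bh.PairSpec("unrelated_singleton", 30)])
        vals = design.simulate_values(spec, reps, np.random.default_rng(6))
        drop: Counter = Counter()
        for v in vals:
            for r in range(0, reps, 40):  # thin to keep counts independent-ish
                drop[tuple(sorted(v[r]))] += 1
        rng = np.random.default_rng(7)
        iid: Counter = Counter()
        for _ in range(sum(drop.values())):
            iid[tuple(sorted(rng.choice(3, 2, p=spec.freqs)))] += 1
        keys = sorted(set(drop) | set(iid))
        a = np.array([drop.get(k, 0) for k in keys])
        b = np.array([iid.get(k, 0) for k in keys])
        _, pvalue, _, _ = stats.chi2_contingency(np.vstack([a, b]))
        assert pvalue > 1e-4

    def test_invalid_mixed_modes(self):
        with pytest.raises(BesthetError):
            ExperimentDesign(
                [bh.PairSpec("full_sib_outbred", 1),
                 bh.PairSpec("mm_xlinked", 1, mode="x_linked")]
            )

    def test_x_type_requires_x_mode(self):
        with pytest.raises(BesthetError):
            bh.PairSpec("mm_xlinked", 1, mode="autosomal")


class TestRunExperiment:
    def test_single_pair_type_tilde_equals_blue(self, msat_spectrum):
        """With only one relative pair type the BLUE weights are
        exchangeable, so the two corrected estimators coincide replicate
        by replicate."""
        res = bh.run_experiment(
            [bh.PairSpec("full_sib_outbred", 8)], msat_spectrum,
            estimators=("h_tilde", "h_blue"), reps=500, seed=23,
        )
        assert np.allclose(res.values["h_tilde"], res.values["h_blue"], atol=1e-12)

    def test_bias_prediction_on_mixed_design(self, mixed_design, msat_spectrum):
        res = bh.run_experiment(mixed_design, msat_spectrum,
                                estimators=("h_hat_full",), reps=10_000, seed=25)
        d = res.design
        w = d.allele_copy_weights()
        rho2 = float(w @ d.kinship.matrix @ w)
        predicted = bh.bias_h_hat(res.true_H, d.n_copies, rho2)
        s = res["h_hat_full"]
        assert abs(s.bias - predicted) <= 3 * s.se_mean

    def test_deterministic(self, msat_spectrum):
        kw = dict(estimators=("h_tilde",), reps=2, seed=77)
        r1 = bh.run_experiment([bh.PairSpec("avuncular", 2)], msat_spectrum, **kw)
        r2 = bh.run_experiment([bh.PairSpec("avuncular", 2)], msat_spectrum, **kw)
        assert np.array_equal(r1.values["h_tilde"], r2.values["h_tilde"])

    def test_mse_identity(self, msat_spectrum):
        res = bh.run_experiment([bh.PairSpec("full_sib_outbred", 3)], msat_spectrum,
                                estimators=("h_hat_full",), reps=1000, seed=2)
        s = res["h_hat_full"]
        assert s.mse == pytest.approx(s.bias**2 + s.variance, abs=1e-12)

    def test_mse_orderings_track_design_complexity(self, msat_spectrum):
        """MSE decreases with sample size, and second-degree-pair designs
        beat first-degree designs for the corrected estimators."""
        tags = ("h_hat_full", "h_tilde", "h_blue")
        small = bh.run_experiment([bh.PairSpec("full_sib_outbred", 5)],
                                  msat_spectrum, tags, reps=6000, seed=41)
        large = bh.run_experiment([bh.PairSpec("full_sib_outbred", 40)],
                                  msat_spectrum, tags, reps=6000, seed=41)
        for t in tags:
            assert large[t].mse < small[t].mse
        second = bh.run_experiment([bh.PairSpec("avuncular", 20)],
                                   msat_spectrum, tags, reps=6000, seed=43)
        first = bh.run_experiment([bh.PairSpec("full_sib_outbred", 20)],
                                  msat_spectrum, tags, reps=6000, seed=43)
        for t in tags:
            assert second[t].mse < first[t].mse


class TestSnpGrid:
    def test_full_grid(self):
        grid = bh.snp_locus_grid(0.01, 0.5, 0.01)
        assert len(grid) == 50
        hs = [bh.true_heterozygosity(s) for s in grid]
        assert hs[0] == pytest.approx(0.0198)
        assert hs[-1] == pytest.approx(0.5)
        assert all(b > a for a, b in zip(hs, hs[1:]))  # strictly increasing

    def test_single_point(self):
        grid = bh.snp_locus_grid(0.5, 0.5, 0.01)
        assert len(grid) == 1
        assert np.allclose(grid[0].freqs, [0.5, 0.5])

    def test_invalid_range(self):
        with pytest.raises(BesthetError):
            bh.snp_locus_grid(0.0, 0.5, 0.01)
        with pytest.raises(BesthetError):
            bh.snp_locus_grid(0.2, 0.6, 0.01)
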