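import itertools

import numpy as np
import pytest
from scipy.special import expit

from recfield import (
    ContactMap,
    LibraryDesign,
    ParentAlignment,
    RandomFieldParams,
    classify_sequence_contacts,
    classify_states,
    clopper_pearson,
    construction_error_correction,
    fit_log_parabola,
    min_novel_substitution_probability,
    random_homologous_curve,
    random_mutation_curve,
    recombination_curve,
    sample_random_alignment,
    sample_random_crossovers,
    variance_components_experiment,
)
from recfield.landscape import SubstitutionCurve
from recfield.synth import synth_contact_map


class TestClopperPearson:
    def test_published_reanalysis_interval(self):
        lo, hi = clopper_pearson(4, 13, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.09, 0.61)

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and hi < 1.0

    def test_all_successes_upper_bound_one(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0 and lo > 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    def test_interval_nests_with_level(self):
        lo95, hi95 = clopper_pearson(7, 20, 0.95)
        lo99, hi99 = clopper_pearson(7, 20, 0.99)
        assert lo99 < lo95 < hi95 < hi99


class TestConstructionErrorCorrection:
    def test_frameshift_reanalysis(self):
        res = construction_error_correction(10, 100, (9, 13))
        assert res["q_hat"] == pytest.approx(4 / 13)
        lo, hi = res["q_interval"]
        assert (round(lo, 2), round(hi, 2)) == (0.09, 0.61)
        assert res["corrected_fraction"] == pytest.approx(0.1 * 13 / 4)

    def test_no_frameshifts_leaves_fraction_raw(self):
        res = construction_error_correction(10, 100, (0, 13))
        assert res["q_hat"] == 1.0
        assert res["corrected_fraction"] == res["raw_fraction"]

    def test_corrected_at_least_raw(self):
        for shifted in range(0, 10):
            res = construction_error_correction(5, 50, (shifted, 13))
            assert res["corrected_fraction"] >= res["raw_fraction"] - 1e-12

    def test_all_frameshifted_rejected(self):
        with pytest.raises(ValueError):
            construction_error_correction(5, 50, (13, 13))


class TestFitLogParabola:
    @staticmethod
    def planted_curve(rho, D):
        m = np.arange(0.0, D + 1.0)
        probs = rho ** (m * (D - m) / (D - 1.0))
        return SubstitutionCurve(
            mode="recombination",
            bin_edges=np.arange(-0.5, D + 1.0),
            bin_centers=m,
            mean_prob=probs,
            counts=np.ones(D + 1, dtype=int),
        )

    def test_recovers_planted_tolerance_exactly(self):
        fit = fit_log_parabola(self.planted_curve(0.8, 20), D=20)
        assert fit.rho == pytest.approx(0.8, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0)

    def test_flat_curve_gives_rho_one(self):
        fit = fit_log_parabola(self.planted_curve(1.0, 20), D=20)
        assert fit.lam == 0.0 and fit.rho == 1.0

    def test_noisy_recovery_within_002(self):
        rng = np.random.default_rng(12)
        rhos = []
        for _ in range(100):
            curve = self.planted_curve(0.8, 20)
            curve.mean_prob = curve.mean_prob * np.exp(
                rng.normal(0, 0.05, curve.mean_prob.shape)
            )
            rhos.append(fit_log_parabola(curve, D=20).rho)
        assert abs(np.median(rhos) - 0.8) < 0.02

    def test_too_few_usable_bins_rejected(self):
        curve = self.planted_curve(0.8, 20)
        curve.mean_prob[:] = 0.0
        curve.mean_prob[[0, 5]] = 0.5
        with pytest.raises(ValueError, match="3 usable"):
            fit_log_parabola(curve, D=20)


class TestSampleRandomAlignment:
    def test_identity_one_identical_parents(self):
        aln = sample_random_alignment(50, 3, 1.0, seed=0)
        assert len(set(aln.rows)) == 1

    def test_identity_zero_no_conserved_columns(self):
        aln = sample_random_alignment(50, 2, 0.0, seed=1)
        assert not any(aln.conserved(i) for i in range(1, 51))

    @pytest.mark.parametrize("p,target", [(2, 0.4), (2, 0.7), (3, 0.5)])
    def test_empirical_identity_near_target(self, p, target):
        vals = []
        for seed in range(200):
            aln = sample_random_alignment(300, p, target, seed=seed)
            vals.extend(aln.pairwise_identity().values())
        assert abs(np.mean(vals) - target) < 0.02


class TestSampleRandomCrossovers:
    def test_all_boundaries_when_n_is_max(self):
        d = sample_random_crossovers(10, 9, seed=0)
        assert d.crossovers == tuple(range(1, 10))

    def test_zero_crossovers_single_block(self):
        d = sample_random_crossovers(10, 0, seed=0)
        assert d.n_blocks == 1 and d.blocks == ((1, 10),)

    def test_min_block_honored(self):
        for seed in range(50):
            d = sample_random_crossovers(30, 4, min_block=3, seed=seed)
            assert all(hi - lo + 1 >= 3 for lo, hi in d.blocks)

    def test_infeasible_min_block_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sample_random_crossovers(10, 4, min_block=3, seed=0)

    def test_boundaries_uniform(self):
        M, n, reps = 12, 3, 20_000
        counts = np.zeros(M - 1)
        for seed in range(reps):
            for x in sample_random_crossovers(M, n, seed=seed).crossovers:
                counts[x - 1] += 1
        freq = counts / reps
        expected = n / (M - 1)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert (np.abs(freq - expected) < 4 * se).all()


class TestNoveltyBound:
    def test_two_parent_bound_is_18_19(self):
        aln = ParentAlignment(("a", "b"), ("ACDE", "AGDF"))
        assert min_novel_substitution_probability(aln) == pytest.approx(
            18 / 19
        )

    def test_identical_parents_bound_is_one(self):
        aln = ParentAlignment(("a", "b"), ("ACDE", "ACDE"))
        assert min_novel_substitution_probability(aln) == 1.0


def tiny_two_parent_system(seed=0, M=16, n_crossovers=3, identity=0.4):
    aln = sample_random_alignment(M, 2, identity, seed=seed)
    design = sample_random_crossovers(M, n_crossovers, seed=seed)
    cmap = synth_contact_map(M, "random_pairs", 0.3, seed=seed)
    table = classify_states(aln, design, cmap)
    return aln, design, cmap, table


class TestRecombinationCurve:
    def test_parent_bin_probability(self, tiny, tiny_params):
        aln, design, _, table = tiny
        curve = recombination_curve(aln, design, table, tiny_params, n_bins=2)
        # bin containing m = 0 holds the two parents: sigma(-k mu_P)
        assert curve.mean_prob[0] == pytest.approx(expit(3.0))

    def test_two_parent_symmetry_by_reference_distance(self):
        """Binned by distance to one parent, the two-parent curve is
        symmetric: bin(m) = bin(D - m)."""
        aln, design, cmap, table = tiny_two_parent_system(seed=3)
        from recfield.field import prob_functional_all
        from recfield.alignment import (
            chimera_sequence,
            enumerate_library,
        )

        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        probs = prob_functional_all(table, params)
        ref = aln.rows[0]
        D = sum(a != b for a, b in zip(*aln.rows))
        per_m = {}
        for row, chim in enumerate(enumerate_library(aln, design)):
            seq = chimera_sequence(chim, aln, design)
            m = sum(a != b for a, b in zip(seq, ref))
            per_m.setdefault(m, []).append(probs[row])
        for m, vals in per_m.items():
            mirror = per_m[D - m]
            assert np.mean(vals) == pytest.approx(np.mean(mirror), rel=1e-9)

    def test_interior_dip_with_destabilizing_novel_contacts(self):
        aln, design, cmap, table = tiny_two_parent_system(seed=5)
        params = RandomFieldParams(-0.3, 0.5, 5.0, 1.0)
        curve = recombination_curve(aln, design, table, params, n_bins=5)
        interior = np.nanmin(curve.mean_prob[1:-1])
        assert interior < curve.mean_prob[0]
        assert interior < curve.mean_prob[-1]


class TestRandomMutationCurve:
    def test_m_zero_is_unmutated_parent(self, tiny, tiny_params):
        aln, _, cmap, _ = tiny
        curve = random_mutation_curve(
            aln, cmap, tiny_params, m_max=2, samples_per_m=10, seed=0
        )
        assert curve.mean_prob[0] == pytest.approx(expit(3.0))

    def test_log_probability_declines_roughly_linearly(self):
        """Past the initial p ~ 1 saturation, the mean probability of
        function declines approximately exponentially in the number of
        random mutations."""
        aln, design, cmap, table = tiny_two_parent_system(seed=7, M=30)
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        curve = random_mutation_curve(
            aln, cmap, params, m_max=8, samples_per_m=200, seed=1
        )
        logs = np.log(curve.mean_prob)
        assert (np.diff(logs) < 0).all()
        tail = curve.mean_prob < 0.5
        assert tail.sum() >= 4
        r = np.corrcoef(curve.bin_centers[tail], logs[tail])[0, 1]
        assert r < -0.97

    def test_single_site_decline_matches_analytic_expectation(self):
        """The m=1 mean probability equals the analytic average over all
        positions and substitutions (enumeration oracle)."""
        aln, design, cmap, table = tiny_two_parent_system(seed=9, M=12)
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        from recfield.alignment import AMINO_ACIDS

        ref = aln.rows[0]
        vals = []
        for pos in range(len(ref)):
            for a in AMINO_ACIDS:
                if a == ref[pos]:
                    continue
                seq = ref[:pos] + a + ref[pos + 1:]
                n_p, n_n = classify_sequence_contacts(seq, aln, cmap)
                vals.append(expit(-(n_p * params.mu_P + n_n * params.mu_N)))
        analytic = np.mean(vals)
        curve = random_mutation_curve(
            aln, cmap, params, m_max=1, samples_per_m=3000, seed=2
        )
        se = np.std(vals) / np.sqrt(3000)
        assert abs(curve.mean_prob[1] - analytic) < 4 * se


class TestRandomHomologousCurve:
    def test_endpoints_are_the_parents(self):
        aln, design, cmap, table = tiny_two_parent_system(seed=11)
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        curve = random_homologous_curve(
            aln, cmap, params, samples_per_m=5, seed=0
        )
        k = len([
            c for c in cmap.contacts
        ])
        parent_prob = expit(-(table.k * params.mu_P))
        assert curve.mean_prob[0] == pytest.approx(parent_prob)
        assert curve.mean_prob[-1] == pytest.approx(parent_prob)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scattered_substitutions_no_better_than_recombination(self, seed):
        """At matched reference-parent distance m, scattered homologous
        substitutions average at or below recombination on a local
        (chain-geometric) contact map: contiguous blocks preserve the
        contacts interior to each block, scattered substitutions do not.
        The recombination side is fully enumerated."""
        from recfield.alignment import chimera_sequence, enumerate_library
        from recfield.field import prob_functional_all

        M = 60
        aln = sample_random_alignment(M, 2, 0.5, seed=seed)
        design = sample_random_crossovers(M, 4, min_block=8, seed=seed)
        cmap = synth_contact_map(M, "geometric", 1.8, seed=seed)
        table = classify_states(aln, design, cmap)
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        ref = aln.rows[0]
        probs = prob_functional_all(table, params)
        recomb = {}
        for row, chim in enumerate(enumerate_library(aln, design)):
            seq = chimera_sequence(chim, aln, design)
            m = sum(a != b for a, b in zip(seq, ref))
            recomb.setdefault(m, []).append(probs[row])
        hcurve = random_homologous_curve(
            aln, cmap, params, samples_per_m=300, seed=seed
        )
        for m, vals in recomb.items():
            assert hcurve.mean_prob[m] <= np.mean(vals) + 1e-12


class TestVarianceComponents:
    def test_identity_dominates_synthetic_three_folds(self):
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        folds = [
            synth_contact_map(60, "random_pairs", 0.06, seed=100 + f)
            for f in range(3)
        ]
        comps, values = variance_components_experiment(
            folds, np.linspace(0.1, 0.9, 5), n_libraries=4,
            n_crossovers=7, params=params, seed=0,
        )
        d = comps.as_dict()
        assert d["parent_identity"] == max(d.values())
        assert abs(sum(d.values()) - 1.0) < 1e-9
        assert all(v >= 0 for v in d.values())

    def test_requires_two_folds_and_two_identities(self):
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        folds = [synth_contact_map(30, "random_pairs", 0.1, seed=1)]
        with pytest.raises(ValueError, match="folds"):
            variance_components_experiment(
                folds, np.array([0.3, 0.6]), 2, 3, params, 0
            )
        with pytest.raises(ValueError, match="identity"):
            variance_components_experiment(
                folds * 2, np.array([0.5]), 2, 3, params, 0
            )

    def test_degenerate_zero_variance_rejected(self):
        params = RandomFieldParams(-0.3, 0.5, 2.0, 1.0)
        # identity 1.0 everywhere: every library is all-parental, E_FL equal
        folds = [
            synth_contact_map(30, "random_pairs", 0.1, seed=s)
            for s in (1, 2)
        ]
        with pytest.raises(ValueError, match="degenerate|zero"):
            variance_components_experiment(
                folds, np.array([1.0, 1.0]), 2, 3, params, 0
            )
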