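"""Forward Wright-Fisher simulator: rescaling, trajectories, selected loci."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from lsd import (
    FitnessTable,
    LossRegimeError,
    SelectionRegime,
    build_pseudogenome,
    default_lambda,
    rescale,
    simulate_locus,
    simulate_selected_locus,
    simulate_trajectory,
    stats_vector,
    two_deme_im_model,
)
from lsd.selection import fitness_tables


class TestRegimeAndFitness:
    def test_printed_fitness_table_orientation(self):
        t1, t2 = fitness_tables(SelectionRegime(0.1, 0.05, 100.0))
        assert (t1.w_AA, t1.w_Aa, t1.w_aa) == (1.1, 1.0, 1.0)
        assert (t2.w_AA, t2.w_Aa, t2.w_aa) == (1.0, 1.0, 1.05)

    def test_dominant_option_extends_heterozygote_advantage(self):
        t1, t2 = fitness_tables(SelectionRegime(0.1, 0.05, 100.0), dominance="dominant")
        assert t1.w_Aa == 1.1 and t2.w_Aa == 1.05

    def test_invalid_regimes_rejected(self):
        with pytest.raises(ValueError):
            SelectionRegime(-0.1, 0.0, 100.0)
        with pytest.raises(ValueError):
            SelectionRegime(0.1, 0.1, 0.0)
        with pytest.raises(ValueError):
            SelectionRegime(0.1, 0.1, 100.0, f1=1.5)
        with pytest.raises(ValueError):
            FitnessTable(0.0, 1.0, 1.0)

    def test_one_deterministic_selection_step(self):
        # p=0.5, fitnesses (1.1, 1, 1): p* = (0.25*1.1 + 0.25) / 1.025
        table = FitnessTable(1.1, 1.0, 1.0)
        p = 0.5
        w_a, w_b = table.marginal(p)
        p_star = p * w_a / (p * w_a + (1 - p) * w_b)
        assert p_star == pytest.approx(0.51220, abs=5e-6)


class TestRescale:
    def test_lambda_one_is_identity(self):
        model = two_deme_im_model(n1=1000, n2=1000, m12=5.0, m21=5.0, free_parameters=())
        regime = SelectionRegime(0.01, 0.01, 4000.0)
        m2, r2 = rescale(model, regime, 1.0)
        assert m2.demes[0].initial_size == 1000.0
        assert r2.s1 == 0.01 and r2.t_onset == 4000.0

    def test_compound_parameters_invariant(self):
        model = two_deme_im_model(n1=10_000, n2=10_000, m12=5.0, m21=5.0,
                                  mutation_rate=5e-7, free_parameters=())
        regime = SelectionRegime(0.01, 0.01, 40_000.0)
        m2, r2 = rescale(model, regime, 10.0)
        n2_ = m2.demes[0].initial_size
        assert n2_ == 1000.0
        # M = N*m invariant: entries untouched, N scaled
        assert m2.migration.entries[("deme1", "deme2")] == 5.0
        # 4*N*mu invariant
        assert 4 * n2_ * m2.mutation_rate == pytest.approx(4 * 10_000 * 5e-7)
        # N*s and t/N invariant
        assert n2_ * r2.s1 == pytest.approx(10_000 * 0.01)
        assert r2.t_onset / n2_ == pytest.approx(40_000.0 / 10_000)

    def test_leaving_diffusion_regime_rejected(self):
        model = two_deme_im_model(n1=10_000, n2=10_000, m12=5.0, m21=5.0, free_parameters=())
        with pytest.raises(ValueError, match="selection"):
            rescale(model, SelectionRegime(0.1, 0.1, 1000.0), 20.0)

    def test_default_lambda_caps_deme_size(self):
        model = two_deme_im_model()
        assert default_lambda(model) == 10.0
        assert default_lambda(two_deme_im_model(n1=800, n2=800)) == 1.0


class TestTrajectory:
    def test_neutral_frequency_is_a_martingale(self):
        # s=0, m=0, unconditioned: E[p(T)] = f
        model = two_deme_im_model(n1=100, n2=100, m12=0.0, m21=0.0,
                                  mutation_rate=0.0, free_parameters=())
        regime = SelectionRegime(0.0, 0.0, 50.0, f1=0.3, f2=0.3)
        rng = np.random.default_rng(6)
        finals = np.array([
            simulate_trajectory(model, {}, regime, rng, condition=False).freqs[-1]
            for _ in range(2000)
        ])
        se = finals.std(axis=0, ddof=1) / np.sqrt(len(finals))
        assert np.all(np.abs(finals.mean(axis=0) - 0.3) < 3 * se)

    def test_strong_selection_fixes_the_favoured_allele(self):
        # deterministic recursion oracle: huge N suppresses drift
        model = two_deme_im_model(n1=500_000, n2=500_000, m12=0.0, m21=0.0,
                                  mutation_rate=0.0, free_parameters=())
        regime = SelectionRegime(0.5, 0.0, 300.0, f1=0.1, f2=0.1)
        traj = simulate_trajectory(model, {}, regime, 0, condition=False)
        assert traj.freqs[-1][0] > 0.999  # derived fixes in deme 1

    def test_conditioning_never_returns_a_lost_path(self):
        model = two_deme_im_model(n1=50, n2=50, m12=0.5, m21=0.5,
                                  mutation_rate=0.0, free_parameters=())
        regime = SelectionRegime(0.0, 0.0, 100.0, f1=0.05, f2=0.05)
        rng = np.random.default_rng(8)
        for _ in range(50):
            traj = simulate_trajectory(model, {}, regime, rng, condition=True)
            assert traj.freqs[-1].max() > 0.0

    def test_impossible_regime_raises_loss_signal(self):
        model = two_deme_im_model(n1=50, n2=50, m12=0.0, m21=0.0,
                                  mutation_rate=0.0, free_parameters=())
        # de novo neutral allele: lost with probability ~ 1 - 1/(2N)
        regime = SelectionRegime(0.0, 0.0, 400.0, origin="de_novo")
        with pytest.raises(LossRegimeError):
            simulate_trajectory(model, {}, regime, 1, resample_cap=3)


SMALL = dict(n1=200, n2=200, mutation_rate=5e-6)


class TestSelectedLocus:
    def test_seeded_run_is_bit_reproducible(self):
        model = two_deme_im_model(**SMALL)
        regime = SelectionRegime(0.2, 0.2, 200.0)
        kwargs = dict(locus_length=2000, mu=5e-6, sample_config={"deme1": 8, "deme2": 8})
        a = simulate_selected_locus(model, {"M12": 2.0, "M21": 2.0}, regime, rng=11, **kwargs)
        b = simulate_selected_locus(model, {"M12": 2.0, "M21": 2.0}, regime, rng=11, **kwargs)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_divergent_selection_elevates_fst(self):
        model = two_deme_im_model(**SMALL)
        params = {"M12": 5.0, "M21": 5.0}
        sc = {"deme1": 10, "deme2": 10}
        regime = SelectionRegime(0.5, 0.5, 400.0)
        rng = np.random.default_rng(10)
        fst_sel = np.mean([
            stats_vector(
                simulate_selected_locus(model, params, regime, 2000, 5e-6, sc, rng),
                ["deme1", "deme2"],
            )["fst_deme1_deme2"]
            for _ in range(15)
        ])
        fst_neu = np.mean([
            stats_vector(simulate_locus(model, params, sc, 2000, rng),
                         ["deme1", "deme2"])["fst_deme1_deme2"]
            for _ in range(15)
        ])
        assert fst_sel > fst_neu

    def test_survival_conditioning_keeps_derived_allele(self):
        model = two_deme_im_model(n1=100, n2=100, mutation_rate=5e-6)
        params = {"M12": 1.0, "M21": 1.0}
        regime = SelectionRegime(0.0, 0.0, 150.0, f1=0.05, f2=0.05)
        rng = np.random.default_rng(12)
        for _ in range(20):
            _, traj = simulate_selected_locus(
                model, params, regime, 1000, 5e-6, {"deme1": 6, "deme2": 6}, rng,
                retention="not_lost", return_trajectory=True,
            )
            assert traj.freqs[-1].max() > 0.0

    def test_rescaling_invariance_of_statistic_distributions(self):
        # lambda = 1 vs lambda = 5 agree in distribution (KS alpha = 0.001)
        base = two_deme_im_model(n1=500, n2=500, m12=2.0, m21=2.0,
                                 mutation_rate=2e-6, free_parameters=())
        regime = SelectionRegime(0.04, 0.04, 500.0)
        sc = {"deme1": 10, "deme2": 10}
        rng = np.random.default_rng(14)
        out = {}
        for lam in (1.0, 5.0):
            m2, r2 = rescale(base, regime, lam)
            mu2 = m2.mutation_rate
            stats = [
                stats_vector(
                    simulate_selected_locus(m2, None, r2, 2000, mu2, sc, rng),
                    ["deme1", "deme2"],
                )
                for _ in range(300)
            ]
            out[lam] = stats
        for col in ("S_total", "pi_total", "fst_deme1_deme2"):
            a = np.array([s[col] for s in out[1.0]], dtype=float)
            b = np.array([s[col] for s in out[5.0]], dtype=float)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            assert ks_2samp(a, b).pvalue > 0.001, col


class TestPseudogenome:
    def test_counts_labels_and_total_length(self):
        model = two_deme_im_model(**SMALL)
        params = {"M12": 2.0, "M21": 2.0}
        regime = SelectionRegime(0.2, 0.2, 200.0)
        genome = build_pseudogenome(
            model, params, regime, 12, 5, 2000, {"deme1": 6, "deme2": 6}, 1
        )
        assert genome.n_neutral == 12 and genome.n_selected == 5
        assert genome.total_length == 17 * 2000
        assert genome.labels.count("selected") == 5

    def test_pure_neutral_pseudogenome(self):
        model = two_deme_im_model(**SMALL)
        genome = build_pseudogenome(
            model, {"M12": 2.0, "M21": 2.0}, None, 4, 0, 1000, {"deme1": 4, "deme2": 4}, 2
        )
        assert genome.n_selected == 0 and genome.n_neutral == 4
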