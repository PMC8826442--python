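"""Group statistics, standard ellipse areas, and the diet mixing model."""
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import spongeground as sg
from spongeground.isotope import MixingModel


class TestGroupStats:
    def test_single_sample_sd_absent(self):
        df = pd.DataFrame({"group": ["g"], "d13C": [-18.4], "d15N": [8.0]})
        out = sg.group_stats(df)
        assert out.loc["g", "d13C_mean"] == -18.4
        assert np.isnan(out.loc["g", "d13C_sd"])

    def test_two_sample_arithmetic(self):
        df = pd.DataFrame({"group": ["g", "g"], "d13C": [-19.0, -18.0], "d15N": [7, 9]})
        out = sg.group_stats(df)
        assert out.loc["g", "d13C_mean"] == pytest.approx(-18.5)
        assert out.loc["g", "d13C_sd"] == pytest.approx(0.7071, abs=1e-4)

    def test_synthetic_group_recovers_spec_mean(self):
        spec = sg.IsotopeGroupSpec("G. parva (KM)", -18.40, 0.15, 8.43, 0.78, 7)
        df = pd.concat([sg.generate_isotopes([spec], seed=s) for s in range(20)])
        out = sg.group_stats(df)
        se = 0.15 / np.sqrt(7 * 20)
        assert abs(out.loc["G. parva (KM)", "d13C_mean"] + 18.40) < 3 * se

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sg.group_stats(pd.DataFrame(columns=["group", "d13C", "d15N"]))


class TestSeac:
    def test_unit_cross_four_points(self):
        m = sg.seac([(1, 0), (-1, 0), (0, 1), (0, -1)])
        assert m.sea == pytest.approx(2 * np.pi / 3, rel=1e-12)
        assert m.seac == pytest.approx(np.pi, rel=1e-12)

    def test_collinear_points_degenerate(self):
        m = sg.seac([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert m.degenerate and m.sea == 0.0 and m.seac == 0.0

    def test_small_samples_refused(self):
        with pytest.raises(ValueError, match="at least 3"):
            sg.seac([(0, 0), (1, 1)])

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, c):
        pts = np.random.default_rng(3).normal(size=(12, 2))
        base = sg.seac(pts)
        scaled = sg.seac(c * pts)
        assert scaled.sea == pytest.approx(c**2 * base.sea, rel=1e-9)
        assert scaled.seac == pytest.approx(c**2 * base.seac, rel=1e-9)


def _tight_sources():
    A = sg.SourceDistribution("A", {"d13C": -25.0, "d15N": 4.0}, {"d13C": 0.01, "d15N": 0.01})
    B = sg.SourceDistribution("B", {"d13C": -15.0, "d15N": 10.0}, {"d13C": 0.01, "d15N": 0.01})
    tef = sg.TrophicEnrichment({"d13C": 0.0, "d15N": 0.0}, {"d13C": 0.01, "d15N": 0.01})
    return A, B, tef


class TestMixingModel:
    def test_single_source_posterior_is_degenerate(self):
        A, _, tef = _tight_sources()
        X = np.tile([-25.0, 4.0], (4, 1))
        post = sg.fit_mixing(X, [A], tef, n_iter=2000, burn_in=500, seed=0)
        assert np.all(post.p_draws["A"].to_numpy() == 1.0)

    def test_two_source_linear_algebra_oracle(self):
        """Posterior mean matches the exact solution of the mixing equations."""
        A, B, tef = _tight_sources()
        p_true = np.array([0.3, 0.7])
        design = np.array([[-25.0, -15.0], [4.0, 10.0], [1.0, 1.0]])
        target = np.append(design[:2] @ p_true, 1.0)
        oracle = np.linalg.lstsq(design, target, rcond=None)[0]
        assert oracle == pytest.approx([0.3, 0.7], abs=1e-12)
        X = np.tile(design[:2] @ p_true, (5, 1))
        post = sg.fit_mixing(X, [A, B], tef, n_iter=20_000, burn_in=5_000, seed=1)
        assert post.mean_proportions["A"] == pytest.approx(oracle[0], abs=0.03)
        assert post.mean_proportions["B"] == pytest.approx(oracle[1], abs=0.03)

    def test_symmetric_configuration_gives_equal_means(self):
        A = sg.SourceDistribution("A", {"d13C": -24.0, "d15N": 4.0}, {"d13C": 0.5, "d15N": 0.5})
        B = sg.SourceDistribution("B", {"d13C": -16.0, "d15N": 12.0}, {"d13C": 0.5, "d15N": 0.5})
        tef = sg.TrophicEnrichment({"d13C": 0.0, "d15N": 0.0}, {"d13C": 0.2, "d15N": 0.2})
        X = np.tile([-20.0, 8.0], (10, 1))  # exactly at the midpoint
        post = sg.fit_mixing(X, [A, B], tef, n_iter=30_000, burn_in=10_000, seed=2)
        assert post.mean_proportions["A"] == pytest.approx(
            post.mean_proportions["B"], abs=0.03
        )

    def test_simplex_closure_on_all_draws(self, adult_consumers, default_sources, tef_scenarios):
        post = sg.fit_mixing(
            adult_consumers, default_sources, tef_scenarios["microbial"],
            n_iter=5000, burn_in=1000, seed=3,
        )
        p = post.p_draws.to_numpy()
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (post.sigma_draws.to_numpy() > 0).all()

    def test_prior_recovered_when_data_carry_no_information(self):
        """Hugely uncertain sources flatten the likelihood; the posterior
        mean returns to the uniform Dirichlet prior mean of 1/3."""
        wide = {"d13C": 1e3, "d15N": 1e3}
        srcs = [
            sg.SourceDistribution(n, {"d13C": m, "d15N": m2}, wide)
            for n, m, m2 in [("A", -25, 4), ("B", -15, 10), ("C", -20, 6)]
        ]
        tef = sg.TrophicEnrichment({"d13C": 0.0, "d15N": 0.0}, {"d13C": 0.5, "d15N": 0.5})
        X = np.tile([-20.0, 7.0], (10, 1))
        post = sg.fit_mixing(X, srcs, tef, n_iter=30_000, burn_in=10_000, seed=4)
        for name in ("A", "B", "C"):
            assert post.mean_proportions[name] == pytest.approx(1 / 3, abs=0.05)

    def test_identical_seed_identical_draws(self, adult_consumers, default_sources, tef_scenarios):
        kw = dict(n_iter=3000, burn_in=500, seed=11)
        a = sg.fit_mixing(adult_consumers, default_sources, tef_scenarios["microbial"], **kw)
        b = sg.fit_mixing(adult_consumers, default_sources, tef_scenarios["microbial"], **kw)
        pd.testing.assert_frame_equal(a.p_draws, b.p_draws)

    def test_mismatched_isotope_sets_rejected(self):
        A, B, _ = _tight_sources()
        bad_tef = sg.TrophicEnrichment({"d13C": 0.0}, {"d13C": 0.5})
        with pytest.raises(ValueError, match="lacks isotopes"):
            sg.fit_mixing(np.zeros((3, 2)), [A, B], bad_tef, n_iter=100, burn_in=10)

    def test_short_chain_flags_low_ess(self, adult_consumers, default_sources, tef_scenarios):
        with pytest.warns(UserWarning, match="effective sample size"):
            post = sg.fit_mixing(
                adult_consumers, default_sources, tef_scenarios["microbial"],
                n_iter=700, burn_in=200, thin=1, seed=5,
            )
        assert post.warnings

    def test_sklearn_params_roundtrip(self, default_sources, tef_scenarios):
        model = MixingModel(
            sources=default_sources, tef=tef_scenarios["microbial"], n_iter=1234
        )
        assert model.get_params()["n_iter"] == 1234
        cloned = clone(model).set_params(thin=5)
        assert cloned.thin == 5 and cloned.n_iter == 1234


class TestTefAlternatives:
    def test_identical_scenarios_have_zero_shift(self):
        A, B, tef = _tight_sources()
        X = np.tile([-18.0, 7.8], (5, 1))
        comp = sg.tef_alternatives(
            X, [A, B], {"s1": tef, "s2": tef}, seed=6, n_iter=5000, burn_in=1000
        )
        assert np.allclose(comp.shifts.loc["s2"].to_numpy(), 0.0, atol=1e-12)

    def test_single_source_shift_absent(self):
        A, _, tef = _tight_sources()
        comp = sg.tef_alternatives(
            np.tile([-25.0, 4.0], (3, 1)), [A], {"s1": tef}, seed=0,
            n_iter=2000, burn_in=500,
        )
        assert comp.shifts is None

    def test_higher_tef_can_displace_the_enriched_source(self):
        """Two sources differing only in d15N: the low-enrichment scenario
        needs a substantial share of the 15N-enriched member to reach the
        consumer, the high-enrichment scenario pushes the depleted member
        onto the consumer and the enriched share collapses.  The exact
        two-point mixing arithmetic gives shares 0.43 and ~0."""
        A = sg.SourceDistribution(
            "enriched", {"d13C": -20.0, "d15N": 9.0}, {"d13C": 0.3, "d15N": 0.3}
        )
        B = sg.SourceDistribution(
            "depleted", {"d13C": -20.0, "d15N": 4.8}, {"d13C": 0.3, "d15N": 0.3}
        )
        low = sg.TrophicEnrichment({"d13C": 0.5, "d15N": 1.5}, {"d13C": 0.3, "d15N": 0.3})
        high = sg.TrophicEnrichment({"d13C": 0.5, "d15N": 3.5}, {"d13C": 0.3, "d15N": 0.3})
        X = np.tile([-19.5, 8.1], (15, 1))
        comp = sg.tef_alternatives(
            X, [A, B], {"low": low, "high": high}, seed=5, n_iter=20_000, burn_in=5_000
        )
        # exact solution under "low": (8.1-1.5-4.8)/(9.0-4.8) = 0.4286
        assert comp.posteriors["low"].mean_proportions["enriched"] == pytest.approx(
            0.4286, abs=0.05
        )
        assert comp.shifts.loc["high", "enriched"] < -0.25
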