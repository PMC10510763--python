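"""Kinetic model: conservation, closed-form limits, k_MS prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drlkit import (
    RateConstants,
    SolutionComposition,
    TwoSiteRateConstants,
    closed_form_relative,
    predict_kms,
    scan_kms_vs_equivalents,
    simulate_single_site,
    simulate_two_site,
)
from drlkit.exceptions import ValidationError


class TestClosedForm:
    def test_starts_at_one_and_relaxes_to_pool_composition(self):
        times = np.linspace(0.0, 20000.0, 200)
        rel = closed_form_relative(k_off=5.4e-4, f_label=0.5, t_L=100.0, times=times)
        p = rel["bound_unlabelled"]
        assert p[times <= 100.0] == pytest.approx(1.0)
        # plateau reflects the labelled/unlabelled ratio of the ligand pool
        assert p[-1] == pytest.approx(0.5, abs=2e-5)
        np.testing.assert_allclose(p + rel["bound_labelled"], 1.0, atol=1e-12)

    @pytest.mark.parametrize("f_label", [0.25, 0.5, 0.9])
    def test_half_decay_point(self, f_label):
        k = 1e-3
        t_half = np.log(2.0) / k
        rel = closed_form_relative(k, f_label, 0.0, np.array([0.0, t_half]))
        expected = (1 - f_label) + f_label / 2.0
        assert rel["bound_unlabelled"][1] == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValidationError):
            closed_form_relative(1e-3, 1.5, 0.0, np.array([0.0, 1.0]))


class TestSingleSite:
    def test_no_label_means_no_labelled_complex(self, fig3_rates):
        comp = SolutionComposition(1e-5, ligand_unlabelled=1e-3, ligand_labelled=0.0)
        traj = simulate_single_site(fig3_rates, comp, np.linspace(0, 5000, 200))
        assert np.all(traj.species["bound_labelled"] == 0)
        # pre-equilibrated start: bound pool already at its binding equilibrium
        p = traj.species["bound_unlabelled"]
        assert np.ptp(p) / p[0] < 1e-9

    @given(
        k_on=st.floats(1e2, 1e6),
        k_off=st.floats(1e-5, 1e-1),
        equiv=st.floats(1.0, 500.0),
    )
    def test_mass_conservation(self, k_on, k_off, equiv):
        rates = RateConstants(k_on, k_off)
        comp = SolutionComposition.from_equivalents(1e-5, equiv, equiv)
        times = np.linspace(0.0, 10.0 / k_off, 50)
        traj = simulate_single_site(rates, comp, times)
        total = sum(traj.species[s] for s in traj.host_species)
        np.testing.assert_allclose(total, comp.host_total, rtol=1e-9)
        for s in traj.species.values():
            assert np.all(s >= -1e-15)

    def test_matches_closed_form_at_large_excess(self, fig3_rates, large_excess_comp, default_grid):
        traj = simulate_single_site(fig3_rates, large_excess_comp, default_grid)
        rel = traj.to_relative()
        oracle = closed_form_relative(fig3_rates.k_off, 0.5, 0.0, default_grid)
        dev = np.abs(rel["bound_unlabelled"] - oracle["bound_unlabelled"])
        assert dev.max() < 5e-3

    def test_plateau_equals_pool_label_fraction(self, fig3_rates):
        comp = SolutionComposition.from_equivalents(1e-5, 150, 50)  # f_label = 0.25
        times = np.linspace(0, 12 / fig3_rates.k_off, 400)
        rel = simulate_single_site(fig3_rates, comp, times).to_relative()
        assert rel["bound_labelled"][-1] == pytest.approx(0.25, abs=1e-3)

    def test_grid_must_cover_addition_time(self, fig3_rates, large_excess_comp):
        with pytest.raises(ValidationError):
            simulate_single_site(fig3_rates, large_excess_comp, np.linspace(10.0, 100.0, 10))

    def test_explicit_phase_one_reaches_same_state(self, fig3_rates):
        """Integrating phase I explicitly converges to the analytic pre-equilibrium."""
        pre = SolutionComposition(1e-5, 1e-3, 1e-3, t_L=0.0)
        staged = SolutionComposition(1e-5, 1e-3, 1e-3, t_L=0.0, t_u=-3600.0)
        grid = np.arange(0.0, 2000.0, 5.0)
        rel_pre = simulate_single_site(fig3_rates, pre, grid).to_relative()
        rel_staged = simulate_single_site(
            fig3_rates, staged, np.concatenate([[-3600.0], grid])
        ).to_relative()
        np.testing.assert_allclose(
            rel_staged["bound_unlabelled"][1:], rel_pre["bound_unlabelled"], atol=1e-6
        )


class TestPredictKms:
    def test_equals_k_off_at_large_excess(self, fig3_rates, large_excess_comp):
        obs = predict_kms(fig3_rates, large_excess_comp)
        assert obs.k_ms == pytest.approx(fig3_rates.k_off, rel=0.01)

    def test_small_excess_inflates_rate(self, fig3_rates):
        comp = SolutionComposition.from_equivalents(1e-5, 1.25, 1.25)
        obs = predict_kms(fig3_rates, comp)
        assert obs.k_ms > fig3_rates.k_off * 1.05

    def test_insensitive_to_association_rate(self, large_excess_comp):
        k_ms = [
            predict_kms(RateConstants(k_on, 5.4e-4), large_excess_comp).k_ms
            for k_on in (5e3, 5e4, 1e5, 5e5)
        ]
        assert (max(k_ms) - min(k_ms)) / min(k_ms) < 0.01


class TestScan:
    def test_monotone_nonincreasing_with_asymptote(self, fig3_rates):
        table = scan_kms_vs_equivalents(fig3_rates, [5, 25, 100, 200, 10000])
        k = table["k_ms"].to_numpy()
        assert np.all(np.diff(k) < 0)
        assert k[-1] / fig3_rates.k_off == pytest.approx(1.0, abs=0.01)

    def test_single_entry_matches_predict(self, fig3_rates):
        table = scan_kms_vs_equivalents(fig3_rates, [50.0])
        comp = SolutionComposition.from_equivalents(1e-5, 25.0, 25.0)
        assert len(table) == 1
        assert table["k_ms"].iloc[0] == pytest.approx(predict_kms(fig3_rates, comp).k_ms, rel=1e-9)

    def test_rejects_unsorted(self, fig3_rates):
        with pytest.raises(ValidationError):
            scan_kms_vs_equivalents(fig3_rates, [100, 5])


class TestTwoSite:
    def test_equilibrium_is_binomial_at_equal_pools(self, fig3_rates):
        rates = TwoSiteRateConstants(inner=fig3_rates, outer=RateConstants(5e4, 0.54))
        comp = SolutionComposition.from_equivalents(1e-5, 100, 100)
        times = np.linspace(0.0, 12.0 / fig3_rates.k_off, 800)
        traj = simulate_two_site(rates, comp, times)
        total = traj.species["PP"][-1] + traj.species["PL"][-1] + traj.species["LL"][-1]
        assert traj.species["PP"][-1] / total == pytest.approx(0.25, abs=1e-3)
        assert traj.species["PL"][-1] / total == pytest.approx(0.50, abs=1e-3)
        assert traj.species["LL"][-1] / total == pytest.approx(0.25, abs=1e-3)

    def test_fast_outer_site_separates_processes(self, fig3_rates):
        rates = TwoSiteRateConstants(inner=fig3_rates, outer=RateConstants(5e4, 0.54))
        comp = SolutionComposition.from_equivalents(1e-5, 100, 100)
        times = np.linspace(0.0, 5.0 / fig3_rates.k_off, 2000)
        traj = simulate_two_site(rates, comp, times)
        rel = traj.to_relative()
        # the mixed isotopologue shoots up to its plateau long before LL moves
        early = times <= 60.0
        assert rel["PL"][early].max() > 0.4
        assert rel["LL"][early].max() < 0.02

    def test_mass_conservation(self, fig3_rates):
        rates = TwoSiteRateConstants(inner=fig3_rates, outer=RateConstants(1e4, 5e-3))
        comp = SolutionComposition.from_equivalents(1e-5, 20, 20)
        traj = simulate_two_site(rates, comp, np.linspace(0, 2000, 100))
        total = sum(traj.species[s] for s in traj.host_species)
        np.testing.assert_allclose(total, comp.host_total, rtol=1e-9)

    def test_equal_rates_follow_product_form(self, fig3_rates):
        """Independent identical sites: PP/(PP+LL) = x^2/(x^2+(1-x)^2), not a
        single exponential."""
        rates = TwoSiteRateConstants(inner=fig3_rates, outer=fig3_rates)
        comp = SolutionComposition.from_equivalents(1e-5, 200, 200)
        times = np.linspace(0.0, 5.0 / fig3_rates.k_off, 500)
        traj = simulate_two_site(rates, comp, times)
        pp, ll = traj.species["PP"], traj.species["LL"]
        p = pp / (pp + ll)
        x = 0.5 + 0.5 * np.exp(-fig3_rates.k_off * times)
        oracle = x**2 / (x**2 + (1 - x) ** 2)
        np.testing.assert_allclose(p, oracle, atol=5e-3)
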