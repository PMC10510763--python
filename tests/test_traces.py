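"""Trace extraction: XIC windows, overlap correction, normalization."""

import numpy as np
import pandas as pd
import pytest

from drlkit import (
    IsotopePattern,
    NoiseModel,
    SpeciesSpec,
    XICWindow,
    correct_overlap,
    extract_xic,
    generate_drl_dataset,
    isotope_pattern,
    normalize_group,
    renormalize_pair,
    render_spectra,
)
from drlkit.containers import TimeTraces
from drlkit.exceptions import ValidationError
from drlkit.traces import build_mixing_matrix


def _peaklist(times, mz, intensities):
    return pd.DataFrame({"time_s": np.repeat(times, 1), "mz": mz, "intensity": intensities})


class TestExtractXic:
    def test_single_peak_inside_window(self):
        times = np.array([0.0, 1.0, 2.0])
        peaks = _peaklist(times, [500.1, 500.2, 500.0], [10.0, 20.0, 30.0])
        traces = extract_xic(peaks, [XICWindow(500.1, "s", half_width=0.5)])
        np.testing.assert_allclose(traces["s"], [10.0, 20.0, 30.0])

    def test_boundary_peak_is_included(self):
        peaks = _peaklist([0.0, 1.0], [500.5, 499.5], [1.0, 2.0])
        traces = extract_xic(peaks, [XICWindow(500.0, "s", half_width=0.5)])
        np.testing.assert_allclose(traces["s"], [1.0, 2.0])

    def test_empty_peaklist_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            extract_xic(pd.DataFrame(columns=["time_s", "mz", "intensity"]), [XICWindow(500.0, "s")])

    def test_round_trip_with_rendered_fixture(self, fig3_rates, large_excess_comp, ion_pair):
        grid = np.linspace(0.0, 9000.0, 60)
        traces = generate_drl_dataset(
            fig3_rates, large_excess_comp, ion_pair, NoiseModel.quiet(), grid, 1e9
        )
        peaks = render_spectra(traces, list(ion_pair.values()))
        # at half_width <= 2 the light window sees none of the heavy envelope
        xic = extract_xic(peaks, [XICWindow(1480.4, "M(Py)", half_width=2.0)])
        light_pattern = isotope_pattern(ion_pair["bound_unlabelled"].formula)
        captured = sum(
            ab for off, ab in zip(light_pattern.offsets, light_pattern.abundances) if off <= 2
        )
        np.testing.assert_allclose(xic["M(Py)"], captured * traces["M(Py)"], rtol=1e-9)


class TestCorrectOverlap:
    def test_identity_mixing_is_noop(self):
        times = np.linspace(0, 10, 5)
        traces = TimeTraces(times, {"a": np.arange(5.0), "b": np.ones(5)})
        mixing = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        out = correct_overlap(traces, mixing)
        np.testing.assert_allclose(out["a"], traces["a"], atol=1e-12)

    def test_known_bleed_inverts_exactly(self):
        b = 0.3
        true_a, true_b = np.array([10.0, 5.0, 1.0]), np.array([2.0, 4.0, 8.0])
        observed = TimeTraces(
            np.array([0.0, 1.0, 2.0]),
            {"a": true_a, "b": b * true_a + true_b},
        )
        mixing = pd.DataFrame([[1.0, 0.0], [b, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = correct_overlap(observed, mixing)
        np.testing.assert_allclose(out["a"], true_a, atol=1e-9)
        np.testing.assert_allclose(out["b"], true_b, atol=1e-9)

    def test_noisy_recovery_stays_nonnegative(self):
        rng = np.random.default_rng(3)
        true_b = np.full(50, 0.5)
        obs_b = np.clip(0.2 * 100.0 + true_b + rng.normal(0, 5.0, 50), 0, None)
        traces = TimeTraces(
            np.arange(50.0), {"a": np.full(50, 100.0), "b": obs_b}
        )
        mixing = pd.DataFrame([[1.0, 0.0], [0.2, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = correct_overlap(traces, mixing)
        assert np.all(out["b"] >= 0)

    def test_non_dominant_matrix_rejected(self):
        traces = TimeTraces(np.array([0.0, 1.0]), {"a": np.ones(2), "b": np.ones(2)})
        mixing = pd.DataFrame([[0.4, 0.6], [0.6, 0.4]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="diagonally dominant"):
            correct_overlap(traces, mixing)

    def test_full_pipeline_recovers_inputs(self, fig3_rates, large_excess_comp, ion_pair):
        """render -> XIC -> unmix round-trips the ground-truth traces to <1%."""
        grid = np.linspace(0.0, 9000.0, 40)
        traces = generate_drl_dataset(
            fig3_rates, large_excess_comp, ion_pair, NoiseModel.quiet(), grid, 1e9
        )
        peaks = render_spectra(traces, list(ion_pair.values()))
        windows = [XICWindow(1480.4, "M(Py)"), XICWindow(1485.4, "M(PyL)")]
        patterns = {
            "M(Py)": isotope_pattern(ion_pair["bound_unlabelled"].formula),
            "M(PyL)": isotope_pattern(ion_pair["bound_labelled"].formula),
        }
        mixing = build_mixing_matrix(
            windows, patterns, {"M(Py)": 1480.4, "M(PyL)": 1485.4}
        )
        # the light M+5 line bleeds into the heavy window
        assert mixing.loc["M(PyL)", "M(Py)"] > 0
        corrected = correct_overlap(extract_xic(peaks, windows), mixing)
        for name in ("M(Py)", "M(PyL)"):
            scale = traces[name].max()
            np.testing.assert_allclose(corrected[name] / scale, traces[name] / scale, atol=0.01)


class TestNormalize:
    def test_equal_intensities_give_half(self):
        traces = TimeTraces(np.array([0.0, 1.0]), {"a": np.array([3.0, 8.0]), "b": np.array([3.0, 8.0])})
        rel = normalize_group(traces, ["a", "b"])
        np.testing.assert_allclose(rel["a"], 0.5)

    def test_group_of_one_is_constant_unity(self):
        traces = TimeTraces(np.array([0.0, 1.0]), {"a": np.array([3.0, 8.0])})
        rel = normalize_group(traces, ["a"])
        np.testing.assert_allclose(rel["a"], 1.0)

    def test_all_zero_time_point_is_masked_not_dropped(self):
        traces = TimeTraces(
            np.array([0.0, 1.0, 2.0]),
            {"a": np.array([1.0, 0.0, 2.0]), "b": np.array([1.0, 0.0, 0.0])},
        )
        rel = normalize_group(traces, ["a", "b"])
        assert rel.times.size == 3
        assert rel.n_masked == 1
        assert bool(rel.mask[1]) is True
        np.testing.assert_allclose(rel["a"][[0, 2]], [0.5, 1.0])

    def test_fractions_sum_to_one(self, fig3_rates, large_excess_comp, ion_pair):
        grid = np.linspace(0.0, 5000.0, 50)
        traces = generate_drl_dataset(
            fig3_rates,
            large_excess_comp,
            ion_pair,
            NoiseModel(0.15, 100.0, 1.0, seed=5),
            grid,
            1e9,
        )
        rel = normalize_group(traces, ["M(Py)", "M(PyL)"])
        ok = ~rel.mask
        np.testing.assert_allclose(rel["M(Py)"][ok] + rel["M(PyL)"][ok], 1.0, atol=1e-12)


class TestRenormalizePair:
    def test_equal_signals_split_evenly(self):
        traces = TimeTraces(
            np.array([0.0, 1.0]),
            {"PP": np.array([4.0, 2.0]), "PL": np.array([9.0, 9.0]), "LL": np.array([4.0, 2.0])},
        )
        rel = renormalize_pair(traces, "PP", "LL")
        np.testing.assert_allclose(rel["PP"], 0.5)
        assert "PL" not in rel.species

    def test_fast_outer_fixture_recovers_inner_rate(self, fig3_rates, large_excess_comp):
        from drlkit import TwoSiteRateConstants, RateConstants, fit_first_order, simulate_two_site

        rates = TwoSiteRateConstants(inner=fig3_rates, outer=RateConstants(5e4, 0.54))
        times = np.linspace(0.0, 5.0 / fig3_rates.k_off, 1000)
        traj = simulate_two_site(rates, large_excess_comp, times)
        rel = renormalize_pair(traj.to_traces(), "PP", "LL")
        obs = fit_first_order(rel, f_label=0.5)
        assert obs.k_ms == pytest.approx(fig3_rates.k_off, rel=0.05)
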