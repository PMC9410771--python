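"""Window measurement, slope fitting, and the flux/velocity/bias estimators."""

import numpy as np
import pandas as pd
import pytest

from pulsespread.measure import (
    WindowSet,
    compute_directionality,
    compute_velocity,
    fit_initial_slopes,
    measure_window_series,
    results_to_frame,
    summarize_group,
    windows_to_pixel_masks,
    PulseSpreadResult,
)


def _series_frame(t_s, values_by_window):
    rows = []
    for wid, vals in values_by_window.items():
        role = "central" if wid == "central" else ("proximal" if wid.startswith("proximal") else "distal")
        for t, v in zip(t_s, vals):
            rows.append((t, wid, role, v))
    return pd.DataFrame(rows, columns=["time_s", "window_id", "role", "f_norm"])


class TestWindowGeometry:
    def test_windows_abut_without_overlap(self):
        ws = WindowSet(x_p=0.0, x_d=40.0, flank_lengths=(15.0,))
        w = ws.windows()
        assert w["proximal_15"] == (-15.0, 0.0)
        assert w["distal_15"] == (40.0, 55.0)
        assert ws.a == 40.0

    def test_center_of_pixel_inclusion(self):
        # pixels of 1 um starting at -2 um: centers at -1.5, -0.5, 0.5, ...
        ws = WindowSet(x_p=0.0, x_d=3.0, flank_lengths=(2.0,))
        masks = windows_to_pixel_masks(ws, -2.0, 1.0, 8)
        assert masks["central"] == (2, 5)      # centers 0.5, 1.5, 2.5
        assert masks["proximal_2"] == (0, 2)   # centers -1.5, -0.5
        assert masks["distal_2"] == (5, 7)     # centers 3.5, 4.5

    def test_window_outside_image_errors(self):
        ws = WindowSet(x_p=0.0, x_d=40.0, flank_lengths=(30.0,))
        with pytest.raises(ValueError):
            windows_to_pixel_masks(ws, 0.0, 1.0, 50)  # proximal flank off the left edge

    def test_invalid_windows(self):
        with pytest.raises(ValueError):
            WindowSet(x_p=10.0, x_d=10.0)
        with pytest.raises(ValueError):
            WindowSet(flank_lengths=(0.0,))


class TestMeasureWindowSeries:
    def _stack(self, n_frames=5, h=6, w=30):
        return np.zeros((n_frames, h, w)), np.zeros((h, w))

    def test_flanks_equal_to_preactivation_give_zero(self):
        stack, pre = self._stack()
        pre[:] = 7.0
        stack[:] = 7.0
        stack[:, :, 10:20] += np.linspace(100, 80, 5)[:, None, None]  # central signal decays
        masks = {"central": (10, 20), "proximal_5": (5, 10), "distal_5": (20, 25)}
        series = measure_window_series(stack, np.arange(5) * 30.0, pre, masks, rows=(0, 6))
        for wid in ("proximal_5", "distal_5"):
            assert np.allclose(series[series["window_id"] == wid]["f_norm"], 0.0)
        central = series[series["window_id"] == "central"]["f_norm"].to_numpy()
        assert central[0] == pytest.approx(1.0)
        assert np.all(np.diff(central) < 0)

    def test_dark_state_cutoff_discards_early_frames(self):
        stack, pre = self._stack()
        stack[:, :, 10:20] = 10.0
        masks = {"central": (10, 20)}
        t = np.array([-60.0, -30.0, 0.0, 30.0, 60.0])
        series = measure_window_series(stack, t, pre, masks, rows=(0, 6), t_start=0.0)
        got = series[series["window_id"] == "central"]["time_s"].to_numpy()
        assert np.array_equal(got, [0.0, 30.0, 60.0])

    def test_mask_and_preactivation_validation(self):
        stack, pre = self._stack()
        with pytest.raises(ValueError, match="preactivation"):
            measure_window_series(stack, np.arange(5) * 30.0, None, {"central": (0, 5)}, rows=(0, 6))
        with pytest.raises(ValueError, match="outside"):
            measure_window_series(stack, np.arange(5) * 30.0, pre, {"central": (10, 99)}, rows=(0, 6))


class TestSlopeFit:
    def test_exact_line_recovers_slope(self):
        """A distal series growing at 0.00154 per minute fits S_d = 0.154%/min."""
        t_s = np.arange(0.0, 241.0, 30.0)
        t_min = t_s / 60.0
        series = _series_frame(
            t_s,
            {
                "central": 1.0 - 0.00276 * t_min,
                "proximal_15": 0.00122 * t_min,
                "distal_15": 0.00154 * t_min,
            },
        )
        fit = fit_initial_slopes(series, t_max_min=4.0)
        assert fit.S_d == pytest.approx(0.00154, abs=1e-12)
        assert fit.S_p == pytest.approx(0.00122, abs=1e-12)
        assert fit.S_c == pytest.approx(0.00276, abs=1e-12)
        assert 100 * fit.S_d == pytest.approx(0.154)

    def test_constant_series_zero_slope(self):
        t_s = np.arange(0.0, 241.0, 30.0)
        series = _series_frame(t_s, {"central": np.ones(9), "proximal_15": np.full(9, 0.2), "distal_15": np.full(9, 0.1)})
        fit = fit_initial_slopes(series)
        assert fit.S_p == pytest.approx(0.0, abs=1e-12)
        assert fit.S_d == pytest.approx(0.0, abs=1e-12)

    def test_intercept_absorbs_offset(self):
        """A constant additive offset (residual background error) does not
        change the fitted slope because the regression has an intercept."""
        t_s = np.arange(0.0, 241.0, 30.0)
        t_min = t_s / 60.0
        base = {"central": 1.0 - 0.003 * t_min, "proximal_15": 0.001 * t_min, "distal_15": 0.002 * t_min}
        shifted = {k: v + 0.05 for k, v in base.items()}
        f1 = fit_initial_slopes(_series_frame(t_s, base))
        f2 = fit_initial_slopes(_series_frame(t_s, shifted))
        assert f1.S_d == pytest.approx(f2.S_d, abs=1e-12)

    def test_needs_three_frames(self):
        t_s = np.array([0.0, 30.0])
        series = _series_frame(t_s, {"central": [1, 1], "proximal_15": [0, 0], "distal_15": [0, 0]})
        with pytest.raises(ValueError, match="3 frames"):
            fit_initial_slopes(series)

    def test_largest_flank_selected_by_default(self):
        t_s = np.arange(0.0, 241.0, 30.0)
        t_min = t_s / 60.0
        series = _series_frame(
            t_s,
            {
                "central": 1.0 - 0.004 * t_min,
                "proximal_5": 0.0005 * t_min,
                "proximal_15": 0.001 * t_min,
                "distal_5": 0.0015 * t_min,
                "distal_15": 0.003 * t_min,
            },
        )
        fit = fit_initial_slopes(series)
        assert fit.S_d == pytest.approx(0.003, abs=1e-12)
        assert fit.S_p == pytest.approx(0.001, abs=1e-12)


class TestEstimators:
    @pytest.mark.parametrize(
        "S_p_pct, S_d_pct, velocity, pct",
        [
            (0.195, 0.299, 0.060, 60.5),   # tibial 2 wk
            (0.135, 0.178, 0.025, 56.9),   # tibial 4 wk
            (0.122, 0.154, 0.018, 55.8),   # tibial 8 wk
            (0.068, 0.096, 0.016, 58.7),   # tibial 16 wk
            (0.125, 0.202, 0.044, 61.8),   # sciatic 8 wk
        ],
    )
    def test_reported_group_flux_arithmetic(self, S_p_pct, S_d_pct, velocity, pct):
        """The published group-mean fluxes reproduce the published velocity
        (mm/d) and percent-anterograde values."""
        S_p, S_d = S_p_pct / 100.0, S_d_pct / 100.0
        assert compute_velocity(S_p, S_d, 40.0) == pytest.approx(velocity, abs=5e-4)
        got_pct, _ = compute_directionality(S_p, S_d)
        assert got_pct == pytest.approx(pct, abs=0.25)

    def test_velocity_trivial_cases(self):
        assert compute_velocity(0.001, 0.001, 40.0) == 0.0
        # units: 1 %/min differential over 40 um = 0.4 um/min = 0.576 mm/d
        assert compute_velocity(0.0, 0.01, 40.0) == pytest.approx(0.576)

    def test_directionality_limits(self):
        pct, ratio = compute_directionality(0.0, 0.002)
        assert pct == 100.0 and ratio == np.inf
        pct, _ = compute_directionality(0.002, -0.002)
        assert np.isnan(pct)

    def test_velocity_requires_positive_window(self):
        with pytest.raises(ValueError):
            compute_velocity(0.001, 0.002, 0.0)


class TestGroupSummary:
    def _frame(self, sp, sd, ids=None):
        res = [
            PulseSpreadResult.from_slopes(
                ids[i] if ids else f"a{i}",
                type("F", (), {"S_p": sp[i], "S_d": sd[i], "S_c": sp[i] + sd[i],
                               "se_S_p": 0.0, "se_S_d": 0.0, "n_frames": 9})(),
                40.0,
            )
            for i in range(len(sp))
        ]
        return results_to_frame(res)

    def test_single_axon_group_equals_axon(self):
        df = self._frame([0.00122], [0.00154])
        g = summarize_group(df, a=40.0)
        assert g["velocity_mm_per_day"][0] == pytest.approx(compute_velocity(0.00122, 0.00154, 40.0))
        assert g["pct_anterograde"][0] == pytest.approx(100 * 0.00154 / 0.00276)

    def test_group_mean_fluxes_give_reported_values(self):
        """A group whose mean S_d = 0.154 and S_p = 0.122 %/min summarizes to
        0.018 mm/d and 55.8% anterograde (population-average convention)."""
        sp = [0.00100, 0.00144]  # mean 0.00122
        sd = [0.00120, 0.00188]  # mean 0.00154
        g = summarize_group(self._frame(sp, sd), a=40.0)
        assert g["velocity_mm_per_day"][0] == pytest.approx(0.018, abs=5e-4)
        assert g["pct_anterograde"][0] == pytest.approx(55.8, abs=0.05)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        """The population-average convention is not the mean of per-axon
        percentages on a heterogeneous group."""
        sp = [0.001, 0.004]
        sd = [0.003, 0.004]   # per-axon percentages: 75%, 50%
        df = self._frame(sp, sd)
        g = summarize_group(df, a=40.0)
        mean_of_ratios = df["pct_anterograde"].mean()   # 62.5
        assert g["pct_anterograde"][0] == pytest.approx(100 * 0.0035 / 0.006)  # 58.3
        assert abs(g["pct_anterograde"][0] - mean_of_ratios) > 1.0

    def test_undefined_percentage_axons_counted(self):
        sp = [0.002, 0.003]
        sd = [-0.003, 0.004]
        g = summarize_group(self._frame(sp, sd), a=40.0)
        assert g["n_pct_excluded"][0] == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            summarize_group(self._frame([], []), a=40.0)

    def test_grouping_by_key(self):
        df = self._frame([0.001, 0.002], [0.002, 0.003], ids=["x", "y"])
        rec = pd.DataFrame({"axon_id": ["x", "y"], "group": ["g1", "g2"]})
        g = summarize_group(df, rec, ["group"], a=40.0)
        assert set(g["group"]) == {"g1", "g2"}
        assert (g["n_axons"] == 1).all()
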