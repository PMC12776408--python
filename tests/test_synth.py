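"""Unit and property tests for the synthetic planted-pattern generator."""

import math

import numpy as np
import pytest

from spatiodyn import (
    RoiTimeSeries,
    SpatiodynError,
    SyntheticConfig,
    add_noise,
    generate_dataset,
    make_parcellation,
    make_phase_lagged_sinusoids,
    make_template,
    plant_occurrences,
)
from spatiodyn.synth import NETWORK_SIGN, PROPAGATION_ORDER, draw_event_times


class TestMakeParcellation:
    def test_default_246_layout(self, parc246):
        assert parc246.n_roi == 246
        assert parc246.size("DMN") == 36
        assert parc246.size("DAN") == 30
        assert parc246.size("FPN") == 26
        # derived task-positive union: DAN and FPN are disjoint blocks
        assert parc246.size("TPN") == 56
        tpn = set(parc246.members("TPN"))
        assert tpn == set(parc246.members("DAN")) | set(parc246.members("FPN"))

    def test_each_roi_in_exactly_one_network(self, parc246):
        counts = sum(parc246.size(n) for n in
                     ("SCN", "LIM", "SMN", "VIS", "VAN", "DAN", "FPN", "DMN"))
        assert counts == 246

    def test_minimal_nine_roi_case(self, tiny_parc):
        assert tiny_parc.n_roi == 9
        assert tiny_parc.size("TPN") == 2

    def test_size_mismatch_rejected(self):
        sizes = {"SCN": 2, "LIM": 1, "SMN": 1, "VIS": 1, "VAN": 1,
                 "DAN": 1, "FPN": 1, "DMN": 1}   # sums to 9
        with pytest.raises(SpatiodynError, match="sum"):
            make_parcellation(10, sizes)

    def test_unknown_network_rejected(self):
        with pytest.raises(SpatiodynError, match="unknown|missing"):
            make_parcellation(2, {"NOPE": 2})


class TestMakeTemplate:
    def test_rows_are_zero_mean(self, traveling_template):
        assert np.abs(traveling_template.waveform.mean(axis=1)).max() < 1e-9

    def test_dmn_trough_at_window_centre(self, parc246, traveling_template):
        dmn = traveling_template.waveform[parc246.members("DMN")].mean(axis=0)
        assert np.argmin(dmn) == traveling_template.w_true // 2

    def test_standing_wave_same_phase_within_polarity_group(self, parc246):
        tpl = make_template(parc246, 32, "standing", 0.0)
        dmn_rows = tpl.waveform[parc246.members("DMN")]
        scn_rows = tpl.waveform[parc246.members("SCN")]
        dan_rows = tpl.waveform[parc246.members("DAN")]
        # all DMN-aligned rows identical; task-positive rows identical
        assert np.allclose(dmn_rows, dmn_rows[0])
        assert np.allclose(scn_rows, dmn_rows[0])
        assert np.allclose(dan_rows, dan_rows[0])
        # and the two polarity groups are anti-correlated
        r = np.corrcoef(dmn_rows[0], dan_rows[0])[0, 1]
        assert r < -0.99

    def test_traveling_wave_trough_order_follows_phases(self, parc246):
        # Oracle: each network-mean row of env·cos(2πm/W − θ) attains its
        # minimum near column W(θ+π)/2π mod W; troughs must be ordered by
        # the planted phases within each polarity group.
        w = 64
        tpl = make_template(parc246, w, "traveling", math.pi / 2)
        expected_troughs = {}
        observed_troughs = {}
        for net in ("DMN", "SCN", "LIM"):          # positive-polarity group
            theta = tpl.phase_of_roi[parc246.members(net)[0]]
            expected_troughs[net] = (w * (theta + math.pi) / (2 * math.pi)) % w
            row = tpl.waveform[parc246.members(net)].mean(axis=0)
            observed_troughs[net] = np.argmin(row)
        for net, exp in expected_troughs.items():
            assert abs(observed_troughs[net] - exp) <= 2, net
        # DMN troughs first, SCN then LIM trail (propagation order)
        assert (observed_troughs["DMN"] < observed_troughs["SCN"]
                < observed_troughs["LIM"])

    def test_dmn_dan_anticorrelated(self, parc246, traveling_template):
        dmn = traveling_template.waveform[parc246.members("DMN")].mean(axis=0)
        dan = traveling_template.waveform[parc246.members("DAN")].mean(axis=0)
        assert np.corrcoef(dmn, dan)[0, 1] < 0

    def test_phase_spacing_is_max_lag_over_eight(self, parc246):
        lag = math.pi / 2
        tpl = make_template(parc246, 32, "traveling", lag)
        # DAN is 4 steps before DMN in the propagation order, plus the π
        # polarity flip, so the planted phase gap is π − lag/2
        theta_dan = tpl.phase_of_roi[parc246.members("DAN")[0]]
        theta_dmn = tpl.phase_of_roi[parc246.members("DMN")[0]]
        gap = (theta_dan - theta_dmn) % (2 * math.pi)
        assert gap == pytest.approx(math.pi - lag / 2, abs=1e-12)
        assert set(PROPAGATION_ORDER) == set(NETWORK_SIGN)

    def test_window_too_short_rejected(self, parc246):
        with pytest.raises(SpatiodynError):
            make_template(parc246, 3, "standing", 0.0)


class TestPlantOccurrences:
    def test_nonzero_columns_exactly_at_windows(self, tiny_parc):
        tpl = make_template(tiny_parc, 10, "standing", 0.0)
        series, events = plant_occurrences(tpl, 100, [0, 50])
        nonzero = np.where(np.any(series.values != 0, axis=0))[0]
        assert set(nonzero) <= set(range(0, 10)) | set(range(50, 60))
        assert np.array_equal(events.tmx1, [0, 50])

    def test_out_of_range_event_rejected(self, tiny_parc):
        tpl = make_template(tiny_parc, 10, "standing", 0.0)
        with pytest.raises(SpatiodynError, match="exceeds"):
            plant_occurrences(tpl, 100, [95])

    def test_overlapping_events_rejected(self, tiny_parc):
        tpl = make_template(tiny_parc, 10, "standing", 0.0)
        with pytest.raises(SpatiodynError, match="overlap"):
            plant_occurrences(tpl, 100, [0, 5])

    def test_ground_truth_conservation(self, tiny_parc):
        # sum over time of the clean series == |events| × template column sums
        tpl = make_template(tiny_parc, 12, "traveling", math.pi / 2)
        series, events = plant_occurrences(tpl, 200, [3, 40, 100])
        assert np.allclose(series.values.sum(axis=1),
                           3 * tpl.waveform.sum(axis=1), atol=1e-12)


class TestAddNoise:
    def test_zero_sd_is_identity(self, tiny_parc):
        tpl = make_template(tiny_parc, 10, "standing", 0.0)
        series, _ = plant_occurrences(tpl, 50, [0])
        out = add_noise(series, 0.3, 0.0, 7)
        assert np.array_equal(out.values, series.values)

    def test_deterministic_for_fixed_seed(self):
        zeros = RoiTimeSeries(np.zeros((4, 200)), tr=1.0,
                              roi_labels=[f"r{i}" for i in range(4)])
        a = add_noise(zeros, 0.0, 1.0, 7)
        b = add_noise(zeros, 0.0, 1.0, 7)
        assert np.array_equal(a.values, b.values)

    def test_lag1_autocorrelation_matches_coefficient(self):
        zeros = RoiTimeSeries(np.zeros((3, 10000)), tr=1.0,
                              roi_labels=["a", "b", "c"])
        out = add_noise(zeros, 0.5, 1.0, 7)
        for row in out.values:
            x = row - row.mean()
            rho = np.dot(x[:-1], x[1:]) / np.dot(x, x)
            assert rho == pytest.approx(0.5, abs=0.05)

    def test_nonstationary_coefficient_rejected(self):
        zeros = RoiTimeSeries(np.zeros((2, 50)), tr=1.0, roi_labels=["a", "b"])
        with pytest.raises(SpatiodynError, match="nonstationary"):
            add_noise(zeros, 1.0, 1.0, 7)


class TestGenerateDataset:
    def test_bit_identical_for_same_seed(self):
        a = generate_dataset(SyntheticConfig(), 5)
        b = generate_dataset(SyntheticConfig(), 5)
        assert np.array_equal(a.series.values, b.series.values)
        assert np.array_equal(a.truth_events.tmx1, b.truth_events.tmx1)

    def test_infinite_snr_equals_clean_series(self, noiseless_dataset):
        clean = noiseless_dataset.clean_series
        assert np.array_equal(noiseless_dataset.series.values, clean.values)

    def test_event_count_matches_mean_interval(self):
        # 900 s of data with a 45 s mean interval → about 20 occurrences
        cfg = SyntheticConfig(tr=0.72, n_time=1250, mean_interval_seconds=45.0)
        counts = [len(generate_dataset(cfg, s).truth_events.tmx1)
                  for s in range(1, 6)]
        assert all(14 <= c <= 26 for c in counts)

    def test_events_spaced_at_least_one_window(self, snr1_dataset):
        w = snr1_dataset.template.w_true
        gaps = np.diff(snr1_dataset.truth_events.tmx1)
        assert (gaps >= w).all()

    def test_planted_network_anticorrelation_on_clean_series(self, noiseless_dataset):
        from spatiodyn import to_networks
        nets = to_networks(noiseless_dataset.clean_series,
                           noiseless_dataset.parcellation)
        dmn = nets.values[nets.roi_labels.index("DMN")]
        dan = nets.values[nets.roi_labels.index("DAN")]
        assert np.corrcoef(dmn, dan)[0, 1] < 0


class TestPhaseLaggedSinusoids:
    def test_quadrature_rows_uncorrelated(self):
        s = make_phase_lagged_sinusoids(0.05, np.array([0.0, math.pi / 2]),
                                        0.72, 2000)
        r = np.corrcoef(s.values)[0, 1]
        assert abs(r) < 0.02

    def test_equal_phases_give_identical_rows(self):
        s = make_phase_lagged_sinusoids(0.05, np.array([0.0, 0.0]), 0.72, 100)
        assert np.array_equal(s.values[0], s.values[1])

    def test_super_nyquist_rejected(self):
        with pytest.raises(SpatiodynError, match="Nyquist"):
            make_phase_lagged_sinusoids(0.8, np.array([0.0]), 0.72, 100)


def test_draw_event_times_respects_spacing_and_bounds():
    rng = np.random.default_rng(0)
    for _ in range(20):
        events = draw_event_times(1200, 33, 62.5, rng)
        assert events == sorted(events)
        assert all(b - a >= 33 for a, b in zip(events, events[1:]))
        assert events[-1] + 33 <= 1200
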