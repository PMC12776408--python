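"""Tests for the complex PCA chain: analytic signal, complex correlation,
SVD decomposition, projection, and template reconstruction."""

import math

import numpy as np
import pytest

from spatiodyn import (
    RoiTimeSeries,
    SpatiodynError,
    analytic_signal,
    complex_correlation,
    component_to_template,
    cpca_decompose,
    make_phase_lagged_sinusoids,
    project,
    run_cpca,
)
from spatiodyn.cpca import ComplexCorrMatrix, ComplexSignal

from conftest import circular_correlation


def _interior(n, frac=0.8):
    lo = int(n * (1 - frac) / 2)
    return slice(lo, n - lo)


class TestAnalyticSignal:
    def test_cosine_has_unit_modulus_interior(self):
        s = make_phase_lagged_sinusoids(0.05, np.array([0.0]), 0.72, 2000)
        z = analytic_signal(s)
        mod = np.abs(z.z[0, _interior(2000)])
        assert np.abs(mod - 1.0).max() < 0.02

    def test_sine_phase_is_quadrature_delayed(self):
        tr, n = 0.72, 2000
        t = np.arange(n) * tr
        omega = 2 * math.pi * 0.05
        s = RoiTimeSeries(np.sin(omega * t)[None, :], tr=tr, roi_labels=["a"])
        z = analytic_signal(s)
        sl = _interior(n)
        phase = np.unwrap(np.angle(z.z[0]))[sl]
        expected = omega * t[sl] - math.pi / 2
        assert np.abs(phase - expected).max() < 0.05

    def test_real_part_is_mean_removed_input(self):
        rng = np.random.default_rng(0)
        s = RoiTimeSeries(rng.normal(size=(3, 64)) + 5.0, tr=1.0,
                          roi_labels=list("abc"))
        z = analytic_signal(s)
        centered = s.values - s.values.mean(axis=1, keepdims=True)
        assert np.allclose(z.z.real, centered, atol=1e-12)

    def test_too_short_series_rejected(self):
        s = RoiTimeSeries(np.arange(14.0).reshape(2, 7), tr=1.0,
                          roi_labels=["a", "b"])
        with pytest.raises(SpatiodynError, match="unreliable"):
            analytic_signal(s)


class TestComplexCorrelation:
    def test_identical_rows_give_unit_entry(self):
        s = make_phase_lagged_sinusoids(0.05, np.array([0.3, 0.3]), 0.72, 1500)
        r = complex_correlation(analytic_signal(s))
        assert r.r[0, 1] == pytest.approx(1.0 + 0j, abs=1e-6)
        assert np.allclose(np.diag(r.r), 1.0, atol=1e-12)

    @pytest.mark.parametrize("delta", [0.3, 0.7, 1.2])
    def test_phase_lag_appears_in_argument(self, delta):
        s = make_phase_lagged_sinusoids(0.05, np.array([0.0, delta]), 0.72, 4000)
        r = complex_correlation(analytic_signal(s))
        assert np.angle(r.r[0, 1]) == pytest.approx(delta, abs=0.02)

    def test_hermitian_exactly(self):
        rng = np.random.default_rng(1)
        z = ComplexSignal(z=rng.normal(size=(6, 200))
                          + 1j * rng.normal(size=(6, 200)),
                          tr=1.0, roi_labels=[f"r{i}" for i in range(6)])
        r = complex_correlation(z)
        assert np.abs(r.r - r.r.conj().T).max() == 0.0

    def test_magnitude_bounded_by_diagonal(self):
        rng = np.random.default_rng(2)
        z = ComplexSignal(z=rng.normal(size=(5, 300))
                          + 1j * rng.normal(size=(5, 300)),
                          tr=1.0, roi_labels=[f"r{i}" for i in range(5)])
        r = complex_correlation(z).r
        bound = np.sqrt(np.outer(np.diag(r).real, np.diag(r).real))
        assert np.all(np.abs(r) <= bound + 1e-9)

    def test_zero_rms_row_rejected_by_name(self):
        z = ComplexSignal(z=np.vstack([np.zeros(50), np.ones(50)]).astype(complex),
                          tr=1.0, roi_labels=["dead", "live"])
        with pytest.raises(SpatiodynError, match="dead"):
            complex_correlation(z)


class TestCpcaDecompose:
    def test_rank_one_recovery_up_to_gauge(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=8) + 1j * rng.normal(size=8)
        u /= np.linalg.norm(u)
        r = ComplexCorrMatrix(r=np.outer(u, u.conj()),
                              roi_labels=[f"r{i}" for i in range(8)])
        res = cpca_decompose(r, 1)
        overlap = np.abs(np.vdot(res.components[:, 0], u))
        assert overlap == pytest.approx(1.0, abs=1e-9)
        assert res.singular_values[1] / res.singular_values[0] < 1e-8
        # gauge: largest-modulus entry is real-positive
        j = np.argmax(np.abs(res.components[:, 0]))
        assert res.components[j, 0].imag == pytest.approx(0.0, abs=1e-12)
        assert res.components[j, 0].real > 0

    def test_identity_matrix_spreads_variance_evenly(self):
        n = 6
        r = ComplexCorrMatrix(r=np.eye(n, dtype=complex),
                              roi_labels=[f"r{i}" for i in range(n)])
        res = cpca_decompose(r, 1)
        assert np.allclose(res.singular_values, 1.0)
        assert res.explained_fraction[0] == pytest.approx(1 / n, abs=1e-12)

    def test_two_mode_mixture_weights_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10) + 1j * rng.normal(size=10)
        a /= np.linalg.norm(a)
        b = rng.normal(size=10) + 1j * rng.normal(size=10)
        b -= np.vdot(a, b) * a       # orthogonalize
        b /= np.linalg.norm(b)
        r = ComplexCorrMatrix(r=0.7 * np.outer(a, a.conj())
                              + 0.3 * np.outer(b, b.conj()),
                              roi_labels=[f"r{i}" for i in range(10)])
        res = cpca_decompose(r, 2)
        assert res.explained_fraction[0] == pytest.approx(0.7, abs=0.05)
        assert res.explained_fraction[1] == pytest.approx(0.3, abs=0.05)

    def test_explained_fractions_sum_to_one(self):
        s = make_phase_lagged_sinusoids(0.05, np.linspace(0, 1.5, 7), 0.72, 900)
        res = run_cpca(s, n=3)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.singular_values) <= 1e-12)
        assert np.allclose(np.linalg.norm(res.components, axis=0), 1.0,
                           atol=1e-9)

    def test_non_hermitian_input_rejected(self):
        bad = np.eye(3, dtype=complex)
        bad[0, 1] = 0.5
        with pytest.raises(SpatiodynError, match="Hermitian"):
            cpca_decompose(ComplexCorrMatrix(r=bad, roi_labels=list("abc")), 1)


class TestProject:
    def test_single_mode_phase_ramp_is_linear(self):
        tr, n = 0.72, 2000
        omega = 2 * math.pi * 0.05
        s = make_phase_lagged_sinusoids(0.05, np.linspace(0, 1.0, 6), tr, n)
        res = run_cpca(s, n=1)
        sl = _interior(n)
        phase = np.unwrap(res.phase_timecourse[0])[sl]
        slope = np.polyfit(np.arange(n)[sl] * tr, phase, 1)[0]
        assert abs(slope - omega) / omega < 0.01

    def test_orthogonal_component_has_zero_amplitude(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=5) + 1j * rng.normal(size=5)
        u /= np.linalg.norm(u)
        t = np.arange(400)
        z = ComplexSignal(z=np.outer(u, np.exp(1j * 0.1 * t)), tr=1.0,
                          roi_labels=[f"r{i}" for i in range(5)])
        r = complex_correlation(z, normalize=False)
        res = cpca_decompose(r, 2)
        res = project(res, z)
        total = np.abs(res.amplitude[0]).max()
        assert np.abs(res.amplitude[1]).max() <= 1e-6 * total

    def test_projection_energy_bounded_by_signal_energy(self):
        # U's columns are orthonormal, so projecting Z on any n of them
        # cannot exceed the signal energy at any timepoint
        rng = np.random.default_rng(6)
        s = RoiTimeSeries(rng.normal(size=(7, 300)), tr=1.0,
                          roi_labels=[f"r{i}" for i in range(7)])
        res = run_cpca(s, n=4)
        z = analytic_signal(s)
        proj_energy = (np.abs(res.projections) ** 2).sum(axis=0)
        sig_energy = (np.abs(z.z) ** 2).sum(axis=0)
        assert np.all(proj_energy <= sig_energy + 1e-9)


class TestComponentToTemplate:
    def test_real_component_gives_standing_wave(self):
        comp = np.ones((4, 1)) / 2.0
        from spatiodyn.cpca import CpcaResult
        res = CpcaResult(components=comp.astype(complex),
                         singular_values=np.array([1.0]),
                         explained_fraction=np.array([1.0]),
                         roi_labels=list("abcd"), tr=1.0)
        tpl = component_to_template(res, 0, 16)
        assert np.all(tpl.waveform.argmax(axis=1) == 0)

    def test_antiphase_entries_give_anticorrelated_rows(self):
        from spatiodyn.cpca import CpcaResult
        comp = np.array([[1.0], [-1.0]], dtype=complex) / math.sqrt(2)
        res = CpcaResult(components=comp, singular_values=np.array([1.0]),
                         explained_fraction=np.array([1.0]),
                         roi_labels=["a", "b"], tr=1.0)
        tpl = component_to_template(res, 0, 16)
        assert np.corrcoef(tpl.waveform)[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_component_index_out_of_range(self):
        s = make_phase_lagged_sinusoids(0.05, np.array([0.0, 0.5]), 0.72, 500)
        res = run_cpca(s, n=1)
        with pytest.raises(SpatiodynError, match="out of range"):
            component_to_template(res, 1, 16)


class TestRecoveryAndInvariance:
    def test_phase_map_recovers_planted_phases(self, snr1_dataset):
        from spatiodyn.preprocess import zscore
        res = run_cpca(zscore(snr1_dataset.series), n=1)
        arg_u = np.angle(res.components[:, 0])
        planted = snr1_dataset.template.phase_of_roi
        # arg U tracks the planted phase delay with reversed sign (peak
        # columns are ordered by −arg U)
        assert circular_correlation(arg_u, -planted) >= 0.95

    def test_traveling_wave_peak_order_follows_phase_map(self, noiseless_dataset):
        # peak columns of the reconstructed cycle are ordered by −arg U;
        # positions are circular, so compare after rotating the phase origin
        # away from the occupied clusters
        from scipy.stats import spearmanr
        from spatiodyn import window_length_points
        ds = noiseless_dataset
        res = run_cpca(ds.series, n=1)
        w = window_length_points(24.0, ds.series.tr)
        tpl = component_to_template(res, 0, w)
        arg_u = np.angle(res.components[:, 0])
        peaks = tpl.waveform.argmax(axis=1)
        expected = w * ((-arg_u) % (2 * math.pi)) / (2 * math.pi)
        circ_err = ((peaks - expected + w / 2) % w) - w / 2
        assert np.abs(circ_err).max() <= 1.0
        peaks_rot = (peaks + w // 4) % w
        expected_rot = w * ((-arg_u + math.pi / 2) % (2 * math.pi)) / (2 * math.pi)
        assert spearmanr(peaks_rot, expected_rot).statistic >= 0.9

    def test_global_phase_gauge_invariance(self):
        rng = np.random.default_rng(7)
        z0 = rng.normal(size=(6, 400)) + 1j * rng.normal(size=(6, 400))
        labels = [f"r{i}" for i in range(6)]
        out = {}
        for alpha in (0.0, 1.1):
            z = ComplexSignal(z=z0 * np.exp(1j * alpha), tr=1.0,
                              roi_labels=labels)
            r = complex_correlation(z)
            res = project(cpca_decompose(r, 2), z)
            out[alpha] = res
        a, b = out[0.0], out[1.1]
        assert np.allclose(a.singular_values, b.singular_values, atol=1e-9)
        assert np.allclose(np.abs(a.projections), np.abs(b.projections),
                           atol=1e-9)
        # phase differences between ROIs are gauge-invariant
        da = np.angle(a.components[:, 0] / a.components[0, 0])
        db = np.angle(b.components[:, 0] / b.components[0, 0])
        assert np.allclose(da, db, atol=1e-9)
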