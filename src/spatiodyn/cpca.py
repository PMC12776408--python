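"""Complex principal component analysis of Hilbert-analytic BOLD signals.

The chain: each (mean-removed) ROI row is extended to its analytic signal
``z = x + i·H(x)``; the complex correlation matrix ``R = Z Zᴴ / T`` captures
synchronization strength in its real part and phase lag in its imaginary
part; an SVD of R yields complex spatial components whose per-ROI phases are
the phase-delay map, and projecting Z on the leading components gives their
amplitude/phase time courses.

Rows are normalized to unit RMS before the correlation step (so R has unit
diagonal and the decomposition is scale-free); this is a flag, default on,
because comparing datasets with different amplitude scales requires scale
invariance.  The SVD's arbitrary per-component global phase is fixed by
making each component's largest-modulus entry real-positive, which keeps
results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import (
    RoiTimeSeries,
    SpatiodynError,
    SpatiotemporalTemplate,
)

_HERMITIAN_TOL = 1e-9


@dataclass
class ComplexSignal:
    """Analytic signal matrix Z, [n_roi, n_time] complex."""

    z: np.ndarray
    tr: float
    roi_labels: list[str]

    @property
    def n_roi(self) -> int:
        return self.z.shape[0]

    @property
    def n_time(self) -> int:
        return self.z.shape[1]


@dataclass
class ComplexCorrMatrix:
    """Hermitian complex correlation matrix R, [n_roi, n_roi]."""

    r: np.ndarray
    roi_labels: list[str]


@dataclass
class CpcaResult:
    """Leading complex components and derived maps.

    ``components`` holds the first n left singular vectors (unit norm);
    ``singular_values`` and ``explained_fraction`` cover all N values so the
    fractions sum to 1; ``roi_phase_map`` is the spatial phase-delay map
    arg U per retained component.
    """

    components: np.ndarray          # complex [N, n]
    singular_values: np.ndarray     # all N, non-increasing
    explained_fraction: np.ndarray  # all N, sums to 1
    roi_labels: list[str]
    tr: float
    projections: np.ndarray | None = None      # complex [n, T]
    phase_timecourse: np.ndarray | None = None  # [n, T], arg A_n(t)
    amplitude: np.ndarray | None = None         # [n, T], |A_n(t)|

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def roi_phase_map(self) -> np.ndarray:
        return np.angle(self.components)


def analytic_signal(series: RoiTimeSeries) -> ComplexSignal:
    """Hilbert-analytic extension of each ROI row (means removed first)."""
    if series.n_time < 8:
        raise SpatiodynError(
            f"n_time {series.n_time} < 8: analytic signal unreliable"
        )
    x = series.values - series.values.mean(axis=1, keepdims=True)
    z = hilbert(x, axis=1)
    return ComplexSignal(z=z, tr=series.tr, roi_labels=list(series.roi_labels))


def complex_correlation(signal: ComplexSignal,
                        normalize: bool = True) -> ComplexCorrMatrix:
    """R = Z Zᴴ / T on (by default) unit-RMS rows; exactly Hermitian."""
    z = signal.z
    n_roi, n_time = z.shape
    if n_time < 2:
        raise SpatiodynError("need at least 2 timepoints")
    if normalize:
        rms = np.sqrt(np.mean(np.abs(z) ** 2, axis=1))
        dead = np.where(rms == 0)[0]
        if dead.size:
            labels = [signal.roi_labels[i] for i in dead[:5]]
            raise SpatiodynError(f"zero-RMS ROI row(s): {labels}")
        z = z / rms[:, None]
    r = (z @ z.conj().T) / n_time
    r = 0.5 * (r + r.conj().T)   # enforce exact Hermitian symmetry
    return ComplexCorrMatrix(r=r, roi_labels=list(signal.roi_labels))


def _fix_gauge(u: np.ndarray) -> np.ndarray:
    """Rotate each column so its largest-modulus entry is real-positive."""
    out = u.copy()
    for k in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, k])))
        pivot = u[j, k]
        if np.abs(pivot) > 0:
            out[:, k] = u[:, k] * (np.abs(pivot) / pivot)
    return out


def cpca_decompose(r: ComplexCorrMatrix, n: int,
                   tr: float = 1.0) -> CpcaResult:
    """SVD of the complex correlation matrix, keeping the top n components."""
    mat = r.r
    n_roi = mat.shape[0]
    if not (1 <= n <= n_roi):
        raise SpatiodynError(f"n must be in [1, {n_roi}], got {n}")
    asym = float(np.abs(mat - mat.conj().T).max())
    if asym > _HERMITIAN_TOL:
        raise SpatiodynError(
            f"correlation matrix not Hermitian (max asymmetry {asym:.2e})"
        )
    u, s, _ = np.linalg.svd(mat, hermitian=True)
    components = _fix_gauge(u[:, :n])
    total = float(s.sum())
    explained = s / total if total > 0 else np.full_like(s, 1.0 / n_roi)
    return CpcaResult(
        components=components,
        singular_values=s,
        explained_fraction=explained,
        roi_labels=list(r.roi_labels),
        tr=tr,
    )


def project(result: CpcaResult, signal: ComplexSignal) -> CpcaResult:
    """Component projections A(t) = Uᴴ Z(t), their phase and amplitude."""
    if result.components.shape[0] != signal.n_roi:
        raise SpatiodynError(
            f"components for {result.components.shape[0]} ROIs, "
            f"signal has {signal.n_roi}"
        )
    a = result.components.conj().T @ signal.z
    result.projections = a
    result.phase_timecourse = np.angle(a)
    result.amplitude = np.abs(a)
    return result


def component_to_template(result: CpcaResult, k: int,
                          w: int) -> SpatiotemporalTemplate:
    """Reconstruct one cycle of component k as a real [n_roi, W] template.

    template(β, m) = σ_k · Re(U[β, k] · e^{i 2π m / W}); a traveling-wave
    component yields per-ROI peak columns ordered by −arg U[β, k].
    """
    if w < 4:
        raise SpatiodynError(f"window W={w} < 4")
    if not (0 <= k < result.n_components):
        raise SpatiodynError(
            f"component {k} out of range [0, {result.n_components})"
        )
    m = np.arange(w)
    phase_ramp = np.exp(1j * 2 * np.pi * m / w)
    waveform = np.real(result.components[:, k][:, None] * phase_ramp[None, :])
    waveform *= result.singular_values[k]
    return SpatiotemporalTemplate(waveform=waveform, tr=result.tr,
                                  source="cpca")


def run_cpca(series: RoiTimeSeries, n: int = 1,
             normalize: bool = True) -> CpcaResult:
    """Full chain: analytic signal → complex correlation → SVD → projection."""
    z = analytic_signal(series)
    r = complex_correlation(z, normalize=normalize)
    result = cpca_decompose(r, n, tr=series.tr)
    return project(result, z)
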