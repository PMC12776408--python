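"""Band-limiting, normalization, GSR, decimation, and network aggregation.

The pipeline-order contract: decimation (which emulates acquisition at a
longer TR) is applied to the raw series *before* filtering, z-scoring or
global signal regression, so filters are designed at the new sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import (
    BASE_NETWORKS,
    NETWORK_ROW_ORDER,
    Parcellation,
    RoiTimeSeries,
    SpatiodynError,
)


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    low: float      # Hz
    high: float     # Hz

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise SpatiodynError(
                f"invalid band edges ({self.low}, {self.high})"
            )


#: Canonical infraslow sub-bands.  Slow-3 (0.073–0.198 Hz) and Slow-2
#: (0.198–0.25 Hz) are dominated by physiological noise at typical TRs and
#: are deliberately not supported.
CANONICAL_BANDS: dict[str, FrequencyBand] = {
    "Slow-5": FrequencyBand("Slow-5", 0.01, 0.027),
    "Slow-4": FrequencyBand("Slow-4", 0.027, 0.073),
    "Infraslow": FrequencyBand("Infraslow", 0.01, 0.10),
    "Infraslow+": FrequencyBand("Infraslow+", 0.01, 0.15),
}

_BAND_ALIASES = {
    "slow5": "Slow-5", "slow-5": "Slow-5", "slow_5": "Slow-5",
    "slow4": "Slow-4", "slow-4": "Slow-4", "slow_4": "Slow-4",
    "infraslow": "Infraslow",
    "infraslow+": "Infraslow+", "infraslow_plus": "Infraslow+",
    "infraslowplus": "Infraslow+",
}


def band_limits(name: str) -> FrequencyBand:
    """Canonical edges of a supported frequency band (case-tolerant)."""
    key = _BAND_ALIASES.get(name.lower(), name)
    if key not in CANONICAL_BANDS:
        raise SpatiodynError(
            f"unsupported frequency band {name!r}; supported: "
            f"{sorted(CANONICAL_BANDS)}"
        )
    return CANONICAL_BANDS[key]


def bandpass(series: RoiTimeSeries, band: FrequencyBand | str) -> RoiTimeSeries:
    """Zero-phase band-limit each ROI row (2nd-order Butterworth, filtfilt).

    The band must sit strictly below Nyquist; an infeasible band at long TR
    is an error, never silent clipping.
    """
    if isinstance(band, str):
        band = band_limits(band)
    nyquist = 1.0 / (2.0 * series.tr)
    if band.high >= nyquist:
        raise SpatiodynError(
            f"band {band.name} upper edge {band.high} Hz is at or above "
            f"Nyquist {nyquist:.4f} Hz for TR {series.tr} s"
        )
    sos = butter(2, [band.low, band.high], btype="bandpass", fs=1.0 / series.tr,
                 output="sos")
    filtered = sosfiltfilt(sos, series.values, axis=1)
    return series.copy_with(filtered)


def zscore(series: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize each ROI row to mean 0, SD 1 (population SD)."""
    mean = series.values.mean(axis=1, keepdims=True)
    sd = series.values.std(axis=1, keepdims=True)
    degenerate = np.where(sd[:, 0] == 0)[0]
    if degenerate.size:
        labels = [series.roi_labels[i] for i in degenerate[:5]]
        raise SpatiodynError(f"constant ROI row(s), cannot z-score: {labels}")
    return series.copy_with((series.values - mean) / sd)


def global_signal_regress(series: RoiTimeSeries) -> RoiTimeSeries:
    """Residualize each ROI row against [1, global mean signal]."""
    if series.n_roi < 2:
        raise SpatiodynError("GSR needs at least 2 ROIs")
    g = series.values.mean(axis=0)
    if np.ptp(g) == 0:
        raise SpatiodynError("global signal is constant; GSR undefined")
    design = np.column_stack([np.ones_like(g), g])   # [n_time, 2]
    coef, *_ = np.linalg.lstsq(design, series.values.T, rcond=None)
    residual = series.values - (design @ coef).T
    return series.copy_with(residual)


def decimate(series: RoiTimeSeries, k: int) -> RoiTimeSeries:
    """Keep every k-th timepoint starting at index 0; TR becomes k·TR.

    Deliberately no anti-alias filtering: this emulates acquiring the same
    signal at a longer TR by pure subsampling.
    """
    if k < 1:
        raise SpatiodynError(f"decimation factor must be >= 1, got {k}")
    if k >= series.n_time:
        raise SpatiodynError(
            f"decimation factor {k} >= n_time {series.n_time}"
        )
    return series.copy_with(series.values[:, ::k], tr=series.tr * k)


def to_networks(series: RoiTimeSeries, parc: Parcellation,
                include_tpn: bool = True) -> RoiTimeSeries:
    """Aggregate ROI rows to network means, in the fixed canonical order."""
    label_to_row = {lab: i for i, lab in enumerate(series.roi_labels)}
    parc_labels = set(parc.roi_labels)
    unmapped = [lab for lab in series.roi_labels if lab not in parc_labels]
    if unmapped:
        raise SpatiodynError(f"ROI(s) not in parcellation: {unmapped[:5]}")
    # map parcellation membership onto the series' row indices by label
    members_by_net: dict[str, list[int]] = {}
    order = NETWORK_ROW_ORDER if include_tpn else tuple(
        n for n in NETWORK_ROW_ORDER if n != "TPN"
    )
    for net in order:
        idx = parc.members(net)
        rows = [label_to_row[parc.roi_labels[i]] for i in idx
                if parc.roi_labels[i] in label_to_row]
        if not rows:
            raise SpatiodynError(f"network {net} has no ROIs in this series")
        members_by_net[net] = rows
    values = np.vstack([series.values[members_by_net[net]].mean(axis=0)
                        for net in order])
    return RoiTimeSeries(values=values, tr=series.tr, roi_labels=list(order))


def preprocess_series(series: RoiTimeSeries, band: str | FrequencyBand | None = None,
                      decimate_by: int = 1, gsr: bool = True,
                      standardize: bool = True) -> RoiTimeSeries:
    """Standard chain: decimate (raw) → bandpass → GSR → z-score."""
    out = series
    if decimate_by > 1:
        out = decimate(out, decimate_by)
    if band is not None:
        out = bandpass(out, band)
    if gsr:
        out = global_signal_regress(out)
    if standardize:
        out = zscore(out)
    return out
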