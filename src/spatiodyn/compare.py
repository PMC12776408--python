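"""Agreement metrics between methods, bands, TRs and scan lengths.

Covers template network-correlation matrices and DMN profiles, difference
matrices, the Modified Jaccard Index with temporal cushion, precursor
time-point analysis (mean signed lag between matched extrema), template
alignment across sampling rates, and scan-length stability curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    NETWORK_ROW_ORDER,
    Parcellation,
    RoiTimeSeries,
    SpatiodynError,
    SpatiotemporalTemplate,
)
from .preprocess import global_signal_regress, zscore

logger = logging.getLogger(__name__)

#: Networks reported in a DMN profile, in order (everything but DMN itself).
DMN_PROFILE_ORDER: tuple[str, ...] = (
    "SCN", "LIM", "SMN", "VIS", "VAN", "DAN", "FPN", "TPN",
)


@dataclass
class NetworkCorrMatrix:
    labels: list[str]
    values: np.ndarray      # symmetric, unit diagonal, entries in [−1, 1]
    flagged: list[str] = field(default_factory=list)  # degenerate rows


@dataclass
class MjiResult:
    value: float            # in [0, 1]
    matched: int
    cushion: int


@dataclass
class PtpaResult:
    mean_lag: float | None  # signed, b minus a; None when no pairs matched
    n_pairs: int
    tolerance: int

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


@dataclass
class StabilityCurve:
    durations: np.ndarray           # seconds, strictly increasing
    networks: list[str]
    dmn_corr: np.ndarray            # [n_durations, n_networks], mean over groups
    group_sd: np.ndarray            # [n_durations, n_networks], SD over groups


def _aggregate_template(template: SpatiotemporalTemplate, parc: Parcellation,
                        include_tpn: bool = True) -> tuple[list[str], np.ndarray]:
    label_to_row = {lab: i for i, lab in enumerate(parc.roi_labels)}
    order = [n for n in NETWORK_ROW_ORDER if include_tpn or n != "TPN"]
    rows = []
    for net in order:
        idx = [label_to_row[parc.roi_labels[i]] for i in parc.members(net)]
        if not idx:
            raise SpatiodynError(f"network {net} empty in parcellation")
        rows.append(template.waveform[idx].mean(axis=0))
    return order, np.vstack(rows)


def template_network_correlations(template: SpatiotemporalTemplate,
                                  parc: Parcellation) -> NetworkCorrMatrix:
    """Pearson correlations between network-mean template rows (incl. TPN).

    A constant network row cannot be correlated; its entries are set to 0
    and the network is flagged.
    """
    if template.window_points < 3:
        raise SpatiodynError("template too short to correlate (W < 3)")
    labels, agg = _aggregate_template(template, parc)
    sd = agg.std(axis=1)
    flagged = [labels[i] for i in np.where(sd == 0)[0]]
    n = len(labels)
    values = np.zeros((n, n))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(agg[ok])
        values[np.ix_(ok, ok)] = sub
    values[np.diag_indices(n)] = np.where(ok, 1.0, 1.0)
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    if flagged:
        logger.warning("constant network row(s) flagged: %s", flagged)
    return NetworkCorrMatrix(labels=labels, values=values, flagged=flagged)


def correlation_difference(m_cpca: NetworkCorrMatrix,
                           m_qpp: NetworkCorrMatrix) -> np.ndarray:
    """Elementwise m_cpca − m_qpp; positive = higher correlation in cPCA."""
    if m_cpca.labels != m_qpp.labels:
        raise SpatiodynError(
            f"label mismatch: {m_cpca.labels} vs {m_qpp.labels}"
        )
    return m_cpca.values - m_qpp.values


def dmn_profile(m: NetworkCorrMatrix) -> np.ndarray:
    """DMN-vs-other correlations in the fixed order SCN, LIM, SMN, VIS,
    VAN, DAN, FPN, TPN."""
    if "DMN" not in m.labels:
        raise SpatiodynError("matrix has no DMN row")
    dmn = m.labels.index("DMN")
    out = []
    for net in DMN_PROFILE_ORDER:
        if net not in m.labels:
            raise SpatiodynError(f"matrix has no {net} row")
        out.append(m.values[dmn, m.labels.index(net)])
    return np.array(out)


def match_events(a: np.ndarray, b: np.ndarray,
                 cushion: int) -> list[tuple[int, int]]:
    """Maximum one-to-one matching between two sorted index lists where a
    pair counts as matched iff |t_a − t_b| <= cushion.

    Implemented as the sorted two-pointer greedy sweep, which attains the
    maximum matching for interval tolerance on 1-D sorted sets (verified
    against brute force in the test suite).
    """
    if cushion < 0:
        raise SpatiodynError("cushion must be >= 0")
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        if abs(int(a[i]) - int(b[j])) <= cushion:
            pairs.append((int(a[i]), int(b[j])))
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return pairs


def mji_cushion(a: np.ndarray, b: np.ndarray, cushion: int = 8) -> MjiResult:
    """Modified Jaccard Index with temporal cushion.

    value = matched / (|a| + |b| − matched); two empty sets give 1.0 (both
    methods agree there is nothing to find).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if len(a) == 0 and len(b) == 0:
        return MjiResult(value=1.0, matched=0, cushion=cushion)
    matched = len(match_events(a, b, cushion))
    value = matched / (len(a) + len(b) - matched)
    return MjiResult(value=value, matched=matched, cushion=cushion)


def ptpa(a: np.ndarray, b: np.ndarray, tolerance: int = 16) -> PtpaResult:
    """Precursor time-point analysis: mean signed lag (b − a) over pairs
    matched within the tolerance window; undefined when nothing matches."""
    pairs = match_events(a, b, tolerance)
    if not pairs:
        return PtpaResult(mean_lag=None, n_pairs=0, tolerance=tolerance)
    lags = [tb - ta for ta, tb in pairs]
    return PtpaResult(mean_lag=float(np.mean(lags)), n_pairs=len(pairs),
                      tolerance=tolerance)


def _resample_cycle(waveform: np.ndarray, n_points: int) -> np.ndarray:
    """Periodic linear resampling of each row onto n_points cycle positions."""
    w = waveform.shape[1]
    if w == n_points:
        return waveform
    xp = np.arange(w) / w
    xq = np.arange(n_points) / n_points
    return np.vstack([np.interp(xq, xp, row, period=1.0) for row in waveform])


def template_alignment_correlation(a: SpatiotemporalTemplate,
                                   b: SpatiotemporalTemplate
                                   ) -> tuple[float, int]:
    """Best circular-shift Pearson correlation between two templates.

    Templates sampled at different TRs are first resampled (periodic linear
    interpolation) onto the finer of the two cycle grids, so a 24 s window
    at TR 0.72 can be compared with the same window at TR 2.16.  Returns
    (best correlation, shift in resampled points applied to b).
    """
    if a.n_roi != b.n_roi:
        raise SpatiodynError(f"ROI mismatch: {a.n_roi} vs {b.n_roi}")
    n = max(a.window_points, b.window_points)
    wa = _resample_cycle(a.waveform, n)
    wb = _resample_cycle(b.waveform, n)
    flat_a = (wa - wa.mean()).ravel()
    denom_a = np.linalg.norm(flat_a)
    best = (-2.0, 0)
    for shift in range(n):
        shifted = np.roll(wb, shift, axis=1)
        flat_b = (shifted - shifted.mean()).ravel()
        denom = denom_a * np.linalg.norm(flat_b)
        corr = float(flat_a @ flat_b / denom) if denom > 0 else 0.0
        if corr > best[0]:
            best = (corr, shift)
    return best


def _run_method(series: RoiTimeSeries, method: str, parc: Parcellation,
                wl_seconds: float, seed: int,
                n_starts: int = 8) -> SpatiotemporalTemplate:
    from .cpca import component_to_template, run_cpca
    from .qpp import detect_qpp, window_length_points

    if method == "qpp":
        template, _, _ = detect_qpp(series, wl_seconds=wl_seconds,
                                    n_starts=n_starts, seed=seed, parc=parc)
        return template
    if method == "cpca":
        w = window_length_points(wl_seconds, series.tr)
        result = run_cpca(series, n=1)
        return component_to_template(result, 0, w)
    raise SpatiodynError(f"unknown method {method!r}")


def stability_curve(groups: list[list[RoiTimeSeries]], durations: list[float],
                    method: str, parc: Parcellation,
                    wl_seconds: float = 24.0, seed: int = 0,
                    n_starts: int = 8) -> StabilityCurve:
    """DMN profile vs cumulative scan duration, with across-group SD.

    Scans within a group are GSR'd and z-scored individually, then
    concatenated; each duration level truncates the concatenation to
    floor(duration / TR) samples and reruns the method.  Durations shorter
    than two windows are skipped with a warning.
    """
    from .qpp import window_length_points

    if not groups or not all(groups):
        raise SpatiodynError("need at least one non-empty group of scans")
    durations = sorted(durations)
    tr = groups[0][0].tr
    w = window_length_points(wl_seconds, tr)

    concatenated: list[RoiTimeSeries] = []
    for scans in groups:
        prepped = [zscore(global_signal_regress(s)) for s in scans]
        values = np.concatenate([p.values for p in prepped], axis=1)
        concatenated.append(RoiTimeSeries(values=values, tr=tr,
                                          roi_labels=list(scans[0].roi_labels)))

    kept_durations: list[float] = []
    means: list[np.ndarray] = []
    sds: list[np.ndarray] = []
    for d_idx, duration in enumerate(durations):
        n_keep = int(math.floor(duration / tr))
        if n_keep < 2 * w:
            logger.warning("duration %.1f s (< 2 windows) skipped", duration)
            continue
        profiles = []
        for g_idx, concat in enumerate(concatenated):
            if n_keep > concat.n_time:
                raise SpatiodynError(
                    f"duration {duration} s exceeds group {g_idx} data"
                )
            sub = concat.copy_with(concat.values[:, :n_keep])
            template = _run_method(sub, method, parc, wl_seconds,
                                   seed=seed + 1000 * g_idx + d_idx,
                                   n_starts=n_starts)
            profiles.append(dmn_profile(
                template_network_correlations(template, parc)))
        profiles = np.vstack(profiles)
        kept_durations.append(duration)
        means.append(profiles.mean(axis=0))
        sds.append(profiles.std(axis=0))
    if not kept_durations:
        raise SpatiodynError("all durations shorter than two windows")
    return StabilityCurve(
        durations=np.array(kept_durations),
        networks=list(DMN_PROFILE_ORDER),
        dmn_corr=np.vstack(means),
        group_sd=np.vstack(sds),
    )
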