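"""Quasi-periodic pattern detection by iterative sliding-window matching.

Starting from a randomly seeded window, the algorithm correlates the
template with every window of the series, collects supra-threshold local
maxima of that correlation time course, and replaces the template with the
mean of the matched windows, repeating until the correlation time course
stops changing.  Multiple seeded starts are run and the solution with the
strongest summed event correlation wins; the winner is phase-aligned so the
DMN-mean row troughs at the window centre (the conventional display phase of
the pattern, and the phase at which the synthetic generator plants it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import (
    EventSet,
    Parcellation,
    RoiTimeSeries,
    SpatiodynError,
    SpatiotemporalTemplate,
)

logger = logging.getLogger(__name__)

#: Correlation-threshold schedule: tau_early for iterations 1–3 (gathering
#: loosely matching windows while the template is still noisy), tau_late
#: afterwards.  Config-exposed everywhere they are used.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.1, 0.2)

#: Convergence tolerance on the Pearson correlation between successive
#: sliding-correlation time courses.
CONVERGENCE_TOL = 0.9999

MAX_ITER_DEFAULT = 20


class RestartSignal(SpatiodynError):
    """Raised when an iteration finds no supra-threshold maxima; the caller
    should retry from another start point."""


class NoPatternFound(SpatiodynError):
    """Raised when every seeded start fails to converge on a pattern."""


@dataclass
class CorrelationTimecourse:
    """Sliding correlation c(t) of a template with the series, t = 0..T−W."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def window_length_points(wl_seconds: float, tr: float) -> int:
    """Window length in timepoints: round(wl/tr), ties away from zero."""
    if wl_seconds <= 0 or tr <= 0:
        raise SpatiodynError("window length and TR must be positive")
    w = int(np.floor(wl_seconds / tr + 0.5))
    if w < 2:
        raise SpatiodynError(
            f"window of {wl_seconds} s unresolvable at TR {tr} s ({w} point)"
        )
    return w


def sliding_correlation(series: RoiTimeSeries,
                        template: SpatiotemporalTemplate | np.ndarray
                        ) -> CorrelationTimecourse:
    """Pearson correlation of the flattened template with every window.

    c(t) correlates the [n_roi, W] segment starting at t (flattened
    ROI-major) against the flattened template.  Zero-variance segments give
    c(t) = 0 (logged, not fatal).  FFT-based, O(n_roi · T log T).
    """
    tpl = template.waveform if isinstance(template, SpatiotemporalTemplate) else np.asarray(template, dtype=float)
    x = series.values
    n_roi, n_time = x.shape
    w = tpl.shape[1]
    if tpl.shape[0] != n_roi:
        raise SpatiodynError(
            f"template has {tpl.shape[0]} ROIs, series has {n_roi}"
        )
    if w > n_time:
        raise SpatiodynError(f"template W={w} exceeds n_time={n_time}")
    n = n_roi * w

    # cross term sum_beta sum_m x[beta, t+m] * tpl[beta, m]
    cross = fftconvolve(x, tpl[:, ::-1], mode="valid", axes=1).sum(axis=0)
    ones = np.ones(w)
    s1 = np.convolve(x.sum(axis=0), ones, mode="valid")          # window sums
    s2 = np.convolve((x ** 2).sum(axis=0), ones, mode="valid")   # sums of squares
    t_sum = tpl.sum()
    t_var = (tpl ** 2).sum() - t_sum ** 2 / n
    var_x = s2 - s1 ** 2 / n
    var_x = np.maximum(var_x, 0.0)
    cov = cross - s1 * t_sum / n
    denom = np.sqrt(var_x * t_var)
    c = np.zeros_like(cov)
    ok = denom > 1e-12 * max(1.0, float(np.abs(cov).max()))
    np.divide(cov, denom, out=c, where=ok)
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.debug("sliding_correlation: %d zero-variance windows set to 0",
                     n_degenerate)
    return CorrelationTimecourse(values=np.clip(c, -1.0, 1.0), tr=series.tr)


def _local_extrema(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima, boundaries included."""
    n = len(c)
    if n == 1:
        return np.array([0]), np.array([0])
    left = np.empty(n, dtype=bool)
    right = np.empty(n, dtype=bool)
    left[0] = True
    left[1:] = c[1:] > c[:-1]
    right[-1] = True
    right[:-1] = c[:-1] >= c[1:]
    maxima = np.where(left & right)[0]
    left[0] = True
    left[1:] = c[1:] < c[:-1]
    right[-1] = True
    right[:-1] = c[:-1] <= c[1:]
    minima = np.where(left & right)[0]
    return maxima, minima


def _greedy_suppress(candidates: np.ndarray, strength: np.ndarray,
                     min_separation: int) -> np.ndarray:
    """Keep the stronger candidate whenever two are closer than
    min_separation; greedy by descending strength."""
    order = np.argsort(-strength, kind="stable")
    kept: list[int] = []
    for idx in order:
        t = candidates[idx]
        if all(abs(t - k) >= min_separation for k in kept):
            kept.append(int(t))
    return np.array(sorted(kept), dtype=int)


def find_extrema(c: CorrelationTimecourse, threshold: float,
                 min_separation: int) -> EventSet:
    """Supra-threshold local maxima (tmx1) and infra-threshold minima (tmx2),
    each list thinned so events are >= min_separation apart."""
    if not (0 < threshold < 1):
        raise SpatiodynError(f"threshold must be in (0, 1), got {threshold}")
    values = c.values
    maxima, minima = _local_extrema(values)
    maxima = maxima[values[maxima] >= threshold]
    minima = minima[values[minima] <= -threshold]
    tmx1 = _greedy_suppress(maxima, values[maxima], min_separation)
    tmx2 = _greedy_suppress(minima, -values[minima], min_separation)
    return EventSet(tmx1=tmx1, tmx2=tmx2, threshold=threshold)


def _template_from_events(x: np.ndarray, events: np.ndarray, w: int) -> np.ndarray:
    segments = [x[:, t:t + w] for t in events if t + w <= x.shape[1]]
    if not segments:
        raise RestartSignal("no full windows at matched events")
    return np.mean(segments, axis=0)


def qpp_iterate(series: RoiTimeSeries, start: int, w: int,
                thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                max_iter: int = MAX_ITER_DEFAULT
                ) -> tuple[SpatiotemporalTemplate, CorrelationTimecourse]:
    """One seeded run of the iterative template refinement.

    Raises :class:`RestartSignal` if any iteration finds no maxima above its
    threshold, so the caller can try another start point.
    """
    tau_early, tau_late = thresholds
    x = series.values
    n_time = x.shape[1]
    if start < 0 or start + w > n_time:
        raise SpatiodynError(f"start {start} + W {w} exceeds n_time {n_time}")
    template = x[:, start:start + w].copy()
    min_sep = w
    prev_c: np.ndarray | None = None
    c = sliding_correlation(series, template)
    for iteration in range(1, max_iter + 1):
        if prev_c is not None:
            num = np.corrcoef(c.values, prev_c)[0, 1]
            if num >= CONVERGENCE_TOL:
                break
        tau = tau_early if iteration <= 3 else tau_late
        events = find_extrema(c, tau, min_sep)
        if len(events.tmx1) == 0:
            raise RestartSignal(
                f"no maxima above {tau} at iteration {iteration} (start {start})"
            )
        template = _template_from_events(x, events.tmx1, w)
        prev_c = c.values
        c = sliding_correlation(series, template)
    return (
        SpatiotemporalTemplate(waveform=template, tr=series.tr, source="qpp"),
        c,
    )


def _dmn_trough_offset(template: np.ndarray, parc: Parcellation,
                       roi_labels: list[str]) -> int:
    """Signed offset of the DMN-mean row's minimum from the window centre."""
    label_to_row = {lab: i for i, lab in enumerate(roi_labels)}
    dmn_rows = [label_to_row[parc.roi_labels[i]] for i in parc.members("DMN")]
    if not dmn_rows:
        raise SpatiodynError("parcellation has no DMN members")
    dmn_mean = template[dmn_rows].mean(axis=0)
    w = template.shape[1]
    return int(np.argmin(dmn_mean)) - w // 2


def phase_align_template(series: RoiTimeSeries,
                         template: SpatiotemporalTemplate,
                         events: np.ndarray,
                         parc: Parcellation) -> tuple[SpatiotemporalTemplate,
                                                      np.ndarray, int]:
    """Re-anchor the template so the DMN-mean row troughs at the window
    centre.

    The iterative matching converges to an arbitrary translation of the
    pattern (any consistent window offset is a fixed point).  Anchoring is
    done in data space: events are shifted by the trough offset and the
    template is rebuilt from the data windows there, which keeps the
    template a true window mean (a circular roll would not match any
    contiguous data window).  Returns (template, shifted events, net shift).
    """
    w = template.window_points
    x = series.values
    total_shift = 0
    tpl = template.waveform
    events = np.asarray(events, dtype=int)
    for _ in range(4):   # re-anchor until the trough sits at the centre
        offset = _dmn_trough_offset(tpl, parc, series.roi_labels)
        if offset == 0:
            break
        events = np.clip(events + offset, 0, series.n_time - w)
        events = np.unique(events)
        tpl = _template_from_events(x, events, w)
        total_shift += offset
    return (
        SpatiotemporalTemplate(waveform=tpl, tr=series.tr, source="qpp"),
        events,
        total_shift,
    )


def detect_qpp(series: RoiTimeSeries, wl_seconds: float = 24.0,
               n_starts: int = 20, seed: int = 0,
               thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
               parc: Parcellation | None = None,
               max_iter: int = MAX_ITER_DEFAULT
               ) -> tuple[SpatiotemporalTemplate, CorrelationTimecourse, EventSet]:
    """Detect the dominant quasi-periodic pattern.

    Runs :func:`qpp_iterate` from ``n_starts`` seeded random start points,
    keeps the solution maximizing the summed correlation over its matched
    maxima, phase-aligns it (when a parcellation is given), and returns the
    template, its sliding-correlation time course, and the event set at the
    late threshold.
    """
    if n_starts < 1:
        raise SpatiodynError("n_starts must be >= 1")
    w = window_length_points(wl_seconds, series.tr)
    n_time = series.n_time
    if n_time < 2 * w:
        raise SpatiodynError(f"series too short: n_time {n_time} < 2·W {2 * w}")
    rng = np.random.default_rng(seed)
    max_start = n_time - w
    n_unique = min(n_starts, max_start + 1)
    starts = rng.choice(max_start + 1, size=n_unique, replace=False)
    tau_late = thresholds[1]
    # Two non-overlapping occurrences of a W-long pattern cannot start
    # closer than W apart; a smaller radius admits duplicate events from
    # windows straddling two adjacent occurrences.
    min_sep = w

    best: tuple[float, SpatiotemporalTemplate, CorrelationTimecourse] | None = None
    for start in starts:
        try:
            template, c = qpp_iterate(series, int(start), w, thresholds,
                                      max_iter)
        except RestartSignal as exc:
            logger.debug("start %d failed: %s", start, exc)
            continue
        events = find_extrema(c, tau_late, min_sep)
        if len(events.tmx1) == 0:
            continue
        score = float(c.values[events.tmx1].sum())
        if best is None or score > best[0]:
            best = (score, template, c)
    if best is None:
        raise NoPatternFound(
            f"no pattern found from {n_starts} starts at thresholds {thresholds}"
        )
    _, template, c = best
    events = find_extrema(c, tau_late, min_sep)
    if parc is not None and len(events.tmx1):
        template, _, shift = phase_align_template(series, template,
                                                  events.tmx1, parc)
        if shift:
            c = sliding_correlation(series, template)
            events = find_extrema(c, tau_late, min_sep)
    return template, c, events
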