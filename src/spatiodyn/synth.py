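"""Synthetic parcellated BOLD-like data with a planted quasi-periodic pattern.

The generator composes four steps, each exposed on its own:

1. :func:`make_parcellation` — assign ROIs to the eight canonical networks
   in contiguous index blocks (default: the 246-region layout).
2. :func:`make_template` — build one window of a smooth propagating pattern.
   Each ROI row is one period of a Hann-windowed cosine whose phase encodes
   both propagation order (task-positive networks lead, default mode trails,
   subcortical/limbic anchor late) and polarity (anti-correlation of the
   default-mode and task-positive networks is a π phase offset).  The window
   is anchored so the DMN-mean row has its trough at the window centre, the
   display convention the detection stage aligns to.
3. :func:`plant_occurrences` — add the template into a zero background at
   known, non-overlapping event times.
4. :func:`add_noise` — independent per-ROI AR(1) noise, seeded.

:func:`generate_dataset` runs the whole chain from a
:class:`SyntheticConfig` whose defaults are the study conditions every
recovery experiment in this package uses: 246 ROIs, TR 0.72 s, 1200
timepoints, a 24 s traveling template recurring every ~45 s, SNR 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .core import (
    BASE_NETWORKS,
    DEFAULT_NETWORK_SIZES,
    EventSet,
    Parcellation,
    RoiTimeSeries,
    SpatiodynError,
    SpatiotemporalTemplate,
)

#: Order in which the traveling wave sweeps the networks.  Task-positive
#: (FPN, DAN) regions lead, attention and sensory cortex follow, the DMN
#: trails, and subcortical/limbic regions anchor the late phase.  Phases are
#: spaced by max_phase_lag/8 along this ordering.
PROPAGATION_ORDER: tuple[str, ...] = (
    "FPN", "DAN", "VAN", "SMN", "VIS", "DMN", "SCN", "LIM",
)

#: Polarity of each network relative to the DMN: +1 networks co-activate
#: with the DMN, −1 networks (the task-positive/sensory group) are
#: anti-correlated with it.
NETWORK_SIGN: dict[str, int] = {
    "DMN": +1, "SCN": +1, "LIM": +1,
    "FPN": -1, "DAN": -1, "VAN": -1, "SMN": -1, "VIS": -1,
}


@dataclass
class PlantedTemplate:
    """Ground-truth pattern: waveform plus the phases that generated it."""

    waveform: np.ndarray            # [n_roi, W_true], zero-mean rows
    w_true: int
    phase_of_roi: np.ndarray        # radians in [0, 2π), polarity folded in
    sign_of_network: dict[str, int]
    roi_labels: list[str]

    def to_template(self, tr: float) -> SpatiotemporalTemplate:
        return SpatiotemporalTemplate(waveform=self.waveform.copy(), tr=tr,
                                      source="planted")


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference acquisition the recovery experiments
    emulate: 246 ROIs over 9 networks, TR 0.72 s, 1200 timepoints (14.4 min),
    a 24 s traveling pattern recurring on average every 45 s (one occurrence
    per 30–60 s), SNR 1 against AR(1) noise.
    """

    n_roi: int = 246
    network_sizes: dict[str, int] | None = None
    tr: float = 0.72
    n_time: int = 1200
    wl_seconds: float = 24.0
    mean_interval_seconds: float = 45.0
    snr: float = 1.0
    ar_coefficient: float = 0.3
    propagation: str = "traveling"
    max_phase_lag: float = math.pi / 2


@dataclass
class SyntheticDataset:
    """A generated cohort member with its full ground truth."""

    series: RoiTimeSeries
    truth_events: EventSet
    template: PlantedTemplate
    parcellation: Parcellation
    noise_params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def clean_series(self) -> RoiTimeSeries:
        series, _ = plant_occurrences(
            self.template, self.series.n_time,
            list(self.truth_events.tmx1), tr=self.series.tr,
        )
        return series


def make_parcellation(n_roi: int,
                      network_sizes: dict[str, int] | None = None) -> Parcellation:
    """Assign ``n_roi`` ROIs to the eight base networks in contiguous blocks.

    ``network_sizes`` must name all eight base networks and sum to ``n_roi``.
    Labels are ``<NET>_<k>`` so membership is readable in serialized files.
    """
    if network_sizes is None:
        network_sizes = dict(DEFAULT_NETWORK_SIZES)
    unknown = sorted(set(network_sizes) - set(BASE_NETWORKS))
    if unknown:
        raise SpatiodynError(f"unknown network name(s): {unknown}")
    missing = sorted(set(BASE_NETWORKS) - set(network_sizes))
    if missing:
        raise SpatiodynError(f"missing network size(s): {missing}")
    total = sum(network_sizes.values())
    if total != n_roi:
        raise SpatiodynError(
            f"network sizes sum to {total}, expected n_roi={n_roi}"
        )
    if any(v < 0 for v in network_sizes.values()):
        raise SpatiodynError("network sizes must be non-negative")
    labels: list[str] = []
    nets: list[str] = []
    for net in BASE_NETWORKS:
        for k in range(network_sizes[net]):
            labels.append(f"{net}_{k:03d}")
            nets.append(net)
    return Parcellation(roi_labels=labels, network_of=nets)


def _network_phases(max_phase_lag: float) -> dict[str, float]:
    """Per-network propagation phase, spaced max_lag/8 along the wave path."""
    return {net: k * max_phase_lag / 8.0
            for k, net in enumerate(PROPAGATION_ORDER)}


def make_template(parc: Parcellation, w_true: int, propagation: str = "traveling",
                  max_phase_lag: float = math.pi / 2) -> PlantedTemplate:
    """Build the planted pattern window.

    Each ROI row is ``hann(m) * cos(2π m / W − θ)`` with the row mean
    removed.  θ folds together the network's propagation phase (zero for
    ``standing``) and its polarity (a π offset for task-positive/sensory
    networks), referenced to the DMN so the DMN-mean row troughs at the
    window centre.
    """
    if w_true < 4:
        raise SpatiodynError(f"window length {w_true} < 4 timepoints")
    if propagation not in ("standing", "traveling"):
        raise SpatiodynError(f"unknown propagation mode: {propagation!r}")
    if propagation == "traveling" and not (0 <= max_phase_lag <= 2 * math.pi):
        raise SpatiodynError("max_phase_lag must be in [0, 2π]")

    if propagation == "standing":
        net_phase = {net: 0.0 for net in BASE_NETWORKS}
    else:
        net_phase = _network_phases(max_phase_lag)

    phase_of_roi = np.empty(parc.n_roi)
    for i, net in enumerate(parc.network_of):
        theta = net_phase[net] - net_phase["DMN"]
        if NETWORK_SIGN[net] < 0:
            theta += math.pi
        phase_of_roi[i] = theta % (2 * math.pi)

    m = np.arange(w_true)
    envelope = hann(w_true, sym=True)
    waveform = envelope[None, :] * np.cos(
        2 * math.pi * m[None, :] / w_true - phase_of_roi[:, None]
    )
    waveform -= waveform.mean(axis=1, keepdims=True)
    return PlantedTemplate(
        waveform=waveform, w_true=w_true, phase_of_roi=phase_of_roi,
        sign_of_network=dict(NETWORK_SIGN), roi_labels=list(parc.roi_labels),
    )


def plant_occurrences(template: PlantedTemplate, n_time: int,
                      event_times: list[int],
                      tr: float = 1.0) -> tuple[RoiTimeSeries, EventSet]:
    """Add the template into zeros at each event start (window [t, t+W))."""
    w = template.w_true
    events = list(event_times)
    if sorted(events) != events:
        raise SpatiodynError("event times must be sorted")
    for prev, nxt in zip(events, events[1:]):
        if nxt - prev < w:
            raise SpatiodynError(
                f"events {prev} and {nxt} overlap (spacing < W={w})"
            )
    if events and (events[0] < 0 or events[-1] + w > n_time):
        raise SpatiodynError(
            f"event window [{events[-1]}, {events[-1] + w}) exceeds n_time={n_time}"
        )
    values = np.zeros((template.waveform.shape[0], n_time))
    for t in events:
        values[:, t:t + w] += template.waveform
    series = RoiTimeSeries(values=values, tr=tr,
                           roi_labels=list(template.roi_labels))
    return series, EventSet(tmx1=np.array(events, dtype=int))


def add_noise(series: RoiTimeSeries, ar_coefficient: float, noise_sd: float,
              seed: int) -> RoiTimeSeries:
    """Add independent per-ROI AR(1) noise with stationary SD ``noise_sd``.

    The AR(1) process is ``e[t] = a·e[t−1] + ε[t]`` with innovation SD
    ``noise_sd·sqrt(1 − a²)`` and a stationary draw at t = 0, so the
    marginal SD of the noise equals ``noise_sd`` at every t.
    """
    if not (0 <= ar_coefficient < 1):
        raise SpatiodynError(
            f"ar_coefficient {ar_coefficient} outside [0, 1): nonstationary"
        )
    if noise_sd < 0:
        raise SpatiodynError("noise_sd must be >= 0")
    if noise_sd == 0:
        return series.copy_with(series.values.copy())
    rng = np.random.default_rng(seed)
    n_roi, n_time = series.values.shape
    innov_sd = noise_sd * math.sqrt(1 - ar_coefficient ** 2)
    noise = np.empty((n_roi, n_time))
    noise[:, 0] = rng.normal(0.0, noise_sd, size=n_roi)
    eps = rng.normal(0.0, innov_sd, size=(n_roi, n_time - 1))
    for t in range(1, n_time):
        noise[:, t] = ar_coefficient * noise[:, t - 1] + eps[:, t - 1]
    return series.copy_with(series.values + noise)


def draw_event_times(n_time: int, w_true: int, mean_interval_points: float,
                     rng: np.random.Generator) -> list[int]:
    """Quasi-periodic event starts: a jittered regular grid with hard
    minimum spacing ``w_true`` and every window inside [0, n_time)."""
    if mean_interval_points < w_true:
        raise SpatiodynError(
            f"mean interval {mean_interval_points} shorter than window {w_true}"
        )
    jitter_max = max(0, int((mean_interval_points - w_true) // 2))
    events: list[int] = []
    k = 0
    while True:
        base = int(round(k * mean_interval_points))
        if base + w_true > n_time:
            break
        jitter = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
        t = base + jitter
        t = max(0, min(t, n_time - w_true))
        if not events or t - events[-1] >= w_true:
            events.append(t)
        k += 1
    return events


def generate_dataset(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Compose parcellation → template → events → planting → noise.

    Deterministic for fixed (config, seed); the noise stream is drawn from a
    child seed so planting and noise are independently reproducible.
    """
    from .qpp import window_length_points

    rng = np.random.default_rng(seed)
    parc = make_parcellation(config.n_roi, config.network_sizes)
    w_true = window_length_points(config.wl_seconds, config.tr)
    template = make_template(parc, w_true, config.propagation,
                             config.max_phase_lag)
    interval_pts = config.mean_interval_seconds / config.tr
    events = draw_event_times(config.n_time, w_true, interval_pts, rng)
    clean, truth = plant_occurrences(template, config.n_time, events,
                                     tr=config.tr)
    if math.isinf(config.snr):
        noise_sd = 0.0
    else:
        if config.snr <= 0:
            raise SpatiodynError("snr must be positive or inf")
        template_rms = float(np.sqrt(np.mean(template.waveform ** 2)))
        noise_sd = template_rms / config.snr
    noise_seed = int(rng.integers(0, 2 ** 31 - 1))
    series = add_noise(clean, config.ar_coefficient, noise_sd, noise_seed)
    return SyntheticDataset(
        series=series, truth_events=truth, template=template,
        parcellation=parc,
        noise_params={"ar_coefficient": config.ar_coefficient,
                      "noise_sd": noise_sd},
        seed=seed,
    )


def make_phase_lagged_sinusoids(freq: float, phases: np.ndarray, tr: float,
                                n_time: int) -> RoiTimeSeries:
    """Analytic fixture: row β = cos(2π·freq·t·tr − phases[β])."""
    nyquist = 1.0 / (2.0 * tr)
    if freq >= nyquist:
        raise SpatiodynError(
            f"frequency {freq} Hz at or above Nyquist {nyquist:.4f} Hz (TR {tr})"
        )
    phases = np.asarray(phases, dtype=float)
    t = np.arange(n_time) * tr
    values = np.cos(2 * math.pi * freq * t[None, :] - phases[:, None])
    labels = [f"ROI_{i:03d}" for i in range(len(phases))]
    return RoiTimeSeries(values=values, tr=tr, roi_labels=labels)
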