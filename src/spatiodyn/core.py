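"""Core containers shared by every stage of the pipeline.

The central object is :class:`RoiTimeSeries`, a real matrix of shape
``[n_roi, n_time]`` with a sampling interval (TR) in seconds and one label
per ROI row.  Parcellations assign each ROI to one of eight canonical
large-scale networks (plus the derived task-positive union), templates hold
one window of a spatiotemporal pattern, and event sets hold the timepoint
indices at which a pattern occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical base networks, in the fixed order used for all aggregated
#: outputs: subcortical, limbic, somatomotor, visual, ventral attention,
#: dorsal attention, frontoparietal, default mode.
BASE_NETWORKS: tuple[str, ...] = (
    "SCN", "LIM", "SMN", "VIS", "VAN", "DAN", "FPN", "DMN",
)

#: Row order of network-aggregated series when the derived task-positive
#: network (TPN = DAN ∪ FPN) is included.
NETWORK_ROW_ORDER: tuple[str, ...] = (
    "SCN", "LIM", "SMN", "VIS", "VAN", "DAN", "FPN", "TPN", "DMN",
)

#: Default per-network ROI counts for the 246-region parcellation.  The
#: seven cortical/subcortical counts follow the canonical atlas grouping
#: (DMN 36, DAN 30, FPN 26, VAN 22, VIS 34, SMN 33, SCN 39); the limbic
#: count of 26 is the remainder that brings the total to 246.
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "SCN": 39, "LIM": 26, "SMN": 33, "VIS": 34,
    "VAN": 22, "DAN": 30, "FPN": 26, "DMN": 36,
}


class SpatiodynError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class RoiTimeSeries:
    """Parcellated BOLD-like time series: rows are ROIs, columns timepoints."""

    values: np.ndarray          # real [n_roi, n_time]
    tr: float                   # seconds
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SpatiodynError("values must be a 2-D [n_roi, n_time] matrix")
        if self.values.shape[1] < 2:
            raise SpatiodynError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise SpatiodynError("non-finite entries in time series")
        if self.tr <= 0:
            raise SpatiodynError(f"TR must be positive, got {self.tr}")
        if len(self.roi_labels) != self.values.shape[0]:
            raise SpatiodynError(
                f"{len(self.roi_labels)} labels for {self.values.shape[0]} rows"
            )

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_time * self.tr

    def copy_with(self, values: np.ndarray, tr: float | None = None,
                  roi_labels: list[str] | None = None) -> "RoiTimeSeries":
        return RoiTimeSeries(
            values=np.asarray(values, dtype=float),
            tr=self.tr if tr is None else tr,
            roi_labels=list(self.roi_labels if roi_labels is None else roi_labels),
        )


@dataclass
class Parcellation:
    """Assignment of ROIs to the eight base networks plus the derived TPN.

    ``network_of[i]`` is the base network of ROI index ``i``; the derived
    task-positive network (TPN) is the union of the DAN and FPN members.
    """

    roi_labels: list[str]
    network_of: list[str]       # base network name per ROI index

    def __post_init__(self) -> None:
        if len(self.roi_labels) != len(self.network_of):
            raise SpatiodynError("roi_labels and network_of length mismatch")
        unknown = sorted(set(self.network_of) - set(BASE_NETWORKS))
        if unknown:
            raise SpatiodynError(f"unknown network name(s): {unknown}")

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)

    def members(self, network: str) -> np.ndarray:
        """ROI indices of a base network or the derived TPN group."""
        if network == "TPN":
            return np.array(
                [i for i, n in enumerate(self.network_of) if n in ("DAN", "FPN")],
                dtype=int,
            )
        if network not in BASE_NETWORKS:
            raise SpatiodynError(f"unknown network name: {network!r}")
        return np.array(
            [i for i, n in enumerate(self.network_of) if n == network], dtype=int
        )

    def size(self, network: str) -> int:
        return len(self.members(network))


@dataclass
class SpatiotemporalTemplate:
    """One window of a recurring spatiotemporal pattern, [n_roi, W]."""

    waveform: np.ndarray        # real [n_roi, W]
    tr: float                   # seconds
    source: str = "qpp"         # {"qpp", "cpca", "planted"}

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 2 or self.waveform.shape[1] < 2:
            raise SpatiodynError("template must be [n_roi, W] with W >= 2")
        if not np.all(np.isfinite(self.waveform)):
            raise SpatiodynError("non-finite entries in template")

    @property
    def n_roi(self) -> int:
        return self.waveform.shape[0]

    @property
    def window_points(self) -> int:
        return self.waveform.shape[1]

    @property
    def window_seconds(self) -> float:
        return self.window_points * self.tr


@dataclass
class EventSet:
    """Timepoint indices of template occurrences.

    ``tmx1`` holds supra-threshold correlation maxima (pattern occurrences),
    ``tmx2`` infra-threshold minima (inverted-phase occurrences).
    """

    tmx1: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    tmx2: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.tmx1 = np.asarray(self.tmx1, dtype=int)
        self.tmx2 = np.asarray(self.tmx2, dtype=int)
        if np.any(np.diff(self.tmx1) < 0) or np.any(np.diff(self.tmx2) < 0):
            raise SpatiodynError("event indices must be sorted")

    @property
    def n_events(self) -> int:
        return len(self.tmx1) + len(self.tmx2)
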