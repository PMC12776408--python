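"""Plain-text serialization of the package's containers.

Time series travel as TSV with a ``# TR=<seconds>`` header line followed by
one row per ROI whose first column is the ROI label.  Parcellations are
two-column TSV (roi_label, network); event sets are one integer index per
line; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .core import EventSet, Parcellation, RoiTimeSeries, SpatiodynError


def write_timeseries(series: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# TR={float(series.tr)!r}\n")
        for label, row in zip(series.roi_labels, series.values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row)
                     + "\n")


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# TR="):
            raise SpatiodynError(f"{path}: missing '# TR=' header")
        tr = float(header.split("=", 1)[1])
        labels: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return RoiTimeSeries(values=np.array(rows, dtype=float), tr=tr, roi_labels=labels)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for label, net in zip(parc.roi_labels, parc.network_of):
            fh.write(f"{label}\t{net}\n")


def read_parcellation(path: str | Path) -> Parcellation:
    labels, nets = [], []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            label, net = line.rstrip("\n").split("\t")
            labels.append(label)
            nets.append(net)
    return Parcellation(roi_labels=labels, network_of=nets)


def write_events(events: EventSet, path_tmx1: str | Path,
                 path_tmx2: str | Path | None = None) -> None:
    Path(path_tmx1).write_text("".join(f"{t}\n" for t in events.tmx1))
    if path_tmx2 is not None:
        Path(path_tmx2).write_text("".join(f"{t}\n" for t in events.tmx2))


def read_event_indices(path: str | Path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.array([int(t) for t in text], dtype=int)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    return yaml.safe_load(path.read_text())
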