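"""Plain-text file formats: BOLD tables, edge lists, spike rasters, WAV, JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.io import wavfile

from .encoding import SpikeRaster, Waveform
from .fbn import RegionalBoldMatrix, Topology

__all__ = [
    "read_bold",
    "write_bold",
    "read_edge_list",
    "write_edge_list",
    "read_raster",
    "write_raster",
    "read_wav",
    "write_wav",
    "read_json",
    "write_json",
]

PathLike = Union[str, Path]


def read_bold(
    path: PathLike,
    sampling_interval: float = 1.5,
    delimiter: Optional[str] = None,
) -> RegionalBoldMatrix:
    """Delimited text, one row per region; optional header row of labels.

    The delimiter is sniffed (comma vs whitespace/tab) unless given.  A
    first row that fails to parse as numbers is treated as region labels.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if delimiter is None:
        delimiter = "," if "," in lines[0] else None  # None -> whitespace
    def split(ln):
        return [f for f in (ln.split(delimiter) if delimiter else ln.split()) if f]
    labels = None
    try:
        [float(v) for v in split(lines[0])]
    except ValueError:
        labels = split(lines[0])
        lines = lines[1:]
    values = np.array([[float(v) for v in split(ln)] for ln in lines])
    if labels is None:
        labels = [f"region_{i:03d}" for i in range(values.shape[0])]
    return RegionalBoldMatrix(
        values=values, region_labels=labels, sampling_interval=sampling_interval
    )


def write_bold(path: PathLike, bold: RegionalBoldMatrix, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(bold.region_labels) + "\n")
        for row in bold.values:
            fh.write(delimiter.join(f"{v:.10g}" for v in row) + "\n")


def write_edge_list(path: PathLike, top: Topology) -> None:
    """Two-column whitespace edge list with a `# n_nodes=<n>` header."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={top.n_nodes}\n")
        for u, v in sorted(top.edges):
            fh.write(f"{u} {v}\n")


def read_edge_list(path: PathLike) -> Topology:
    n_nodes = None
    edges = set()
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if "n_nodes=" in ln:
                n_nodes = int(ln.split("n_nodes=")[1].split()[0])
            continue
        u, v = ln.split()[:2]
        edges.add((int(u), int(v)))
    if n_nodes is None:
        n_nodes = 1 + max(max(e) for e in edges) if edges else 0
    return Topology(n_nodes=n_nodes, edges=frozenset(edges))


def write_raster(path: PathLike, raster: SpikeRaster) -> None:
    """Event-list text: header comments then `channel<TAB>timestep` lines."""
    with open(path, "w") as fh:
        fh.write(f"# channels={raster.n_channels}\n")
        fh.write(f"# timesteps={raster.n_timesteps}\n")
        fh.write(f"# dt={raster.dt:.12g}\n")
        ch, ts = np.nonzero(raster.values)
        for c, t in zip(ch, ts):
            fh.write(f"{c}\t{t}\n")


def read_raster(path: PathLike) -> SpikeRaster:
    channels = timesteps = None
    dt = None
    events = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            key, _, val = ln.lstrip("# ").partition("=")
            if key == "channels":
                channels = int(val)
            elif key == "timesteps":
                timesteps = int(val)
            elif key == "dt":
                dt = float(val)
            continue
        c, t = ln.split()[:2]
        events.append((int(c), int(t)))
    if channels is None or timesteps is None or dt is None:
        raise ValueError("raster file missing channels/timesteps/dt header")
    values = np.zeros((channels, timesteps), dtype=np.uint8)
    for c, t in events:
        values[c, t] = 1
    return SpikeRaster(values=values, dt=dt)


def read_wav(path: PathLike) -> Waveform:
    """Mono PCM WAV; integer formats are rescaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Waveform(samples=data, sample_rate=float(rate))


def write_wav(path: PathLike, w: Waveform) -> None:
    scaled = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, int(w.sample_rate), (scaled * 32767).astype(np.int16))


def write_json(path: PathLike, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
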