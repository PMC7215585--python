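"""File formats: spike TSV/HDF5, schedule and map JSON, pattern grids.

Spike TSV layout: comment header lines carrying the recording metadata,
then a ``electrode_id\ttime_ms`` header and one row per spike, sorted within
each electrode. The HDF5 layout mirrors it: one dataset per electrode under
``/spikes`` plus duration and geometry attributes on the root group.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import ElectrodeGrid, SpikeData
from .probing import ConnectivityMap
from .stimuli import PatternMask, StimulusSchedule

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_schedule",
    "write_schedule",
    "read_map",
    "write_map",
    "write_map_tsv",
    "read_pattern",
    "write_pattern",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Spike data


def write_spikes(data: SpikeData, path: str | Path) -> None:
    """Write spike data; format chosen by extension (.tsv or .h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_spikes_hdf5(data, path)
    else:
        _write_spikes_tsv(data, path)


def read_spikes(path: str | Path) -> SpikeData:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_spikes_hdf5(path)
    return _read_spikes_tsv(path)


def _write_spikes_tsv(data: SpikeData, path: Path) -> None:
    g = data.geometry
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={data.duration_ms!r}\n")
        fh.write(f"# grid_shape={g.shape[0]}x{g.shape[1]}\n")
        fh.write(f"# pitch_um={g.pitch_um!r}\n")
        fh.write(f"# inactive={','.join(map(str, g.inactive))}\n")
        fh.write("electrode_id\ttime_ms\n")
        for e in sorted(data.spikes):
            for t in data.spikes[e]:
                fh.write(f"{e}\t{float(t)!r}\n")


def _read_spikes_tsv(path: Path) -> SpikeData:
    meta: dict[str, str] = {}
    spikes: dict[int, list[float]] = {}
    header_seen = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, val = line[1:].split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["electrode_id", "time_ms"]:
                    raise ParseError(f"{path}:{ln}: expected 'electrode_id\\ttime_ms' header")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 tab-separated fields")
            try:
                e = int(parts[0])
                t = float(parts[1])
            except ValueError as err:
                raise ParseError(f"{path}:{ln}: {err}") from None
            lst = spikes.setdefault(e, [])
            if lst and t < lst[-1]:
                raise ParseError(f"{path}:{ln}: unsorted timestamp for electrode {e}")
            lst.append(t)
    if "duration_ms" not in meta:
        raise ParseError(f"{path}: missing '# duration_ms=' header")
    geometry = _geometry_from_meta(meta)
    try:
        return SpikeData(
            {e: np.asarray(v) for e, v in spikes.items()},
            float(meta["duration_ms"]),
            geometry,
        )
    except ValueError as err:
        raise ParseError(f"{path}: {err}") from None


def _geometry_from_meta(meta: dict[str, str]) -> ElectrodeGrid:
    shape = tuple(int(x) for x in meta.get("grid_shape", "16x16").split("x"))
    pitch = float(meta.get("pitch_um", 200.0))
    inactive = meta.get("inactive", "")
    inact = tuple(int(x) for x in inactive.split(",")) if inactive else None
    return ElectrodeGrid(shape, pitch, inact)


def _write_spikes_hdf5(data: SpikeData, path: Path) -> None:
    g = data.geometry
    with h5py.File(path, "w") as f:
        f.attrs["duration_ms"] = data.duration_ms
        f.attrs["grid_shape"] = list(g.shape)
        f.attrs["pitch_um"] = g.pitch_um
        f.attrs["inactive"] = list(g.inactive)
        grp = f.create_group("spikes")
        for e in sorted(data.spikes):
            grp.create_dataset(str(e), data=data.spikes[e])


def _read_spikes_hdf5(path: Path) -> SpikeData:
    with h5py.File(path, "r") as f:
        geometry = ElectrodeGrid(
            tuple(int(x) for x in f.attrs["grid_shape"]),
            float(f.attrs["pitch_um"]),
            tuple(int(x) for x in f.attrs["inactive"]),
        )
        spikes = {int(k): np.asarray(v) for k, v in f["spikes"].items()}
        return SpikeData(spikes, float(f.attrs["duration_ms"]), geometry)


# ---------------------------------------------------------------------------
# Schedules, maps, patterns


def write_schedule(schedule: StimulusSchedule, path: str | Path, labels: list[str] | None = None) -> None:
    d = schedule.to_dict()
    if labels is not None:
        d["labels"] = list(labels)
    Path(path).write_text(json.dumps(d))


def read_schedule(path: str | Path) -> StimulusSchedule:
    return StimulusSchedule.from_dict(json.loads(Path(path).read_text()))


def read_schedule_labels(path: str | Path) -> list[str] | None:
    d = json.loads(Path(path).read_text())
    return d.get("labels")


def write_map(cmap: ConnectivityMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cmap.to_dict()))


def read_map(path: str | Path) -> ConnectivityMap:
    return ConnectivityMap.from_dict(json.loads(Path(path).read_text()))


def write_map_tsv(
    cmap: ConnectivityMap, path: str | Path, stim_grid_shape: tuple[int, int] = (16, 16),
    electrode_grid_shape: tuple[int, int] = (16, 16),
) -> None:
    """Edge-list TSV with grid coordinates for both endpoints."""
    _, sc = stim_grid_shape
    _, ec = electrode_grid_shape
    cols = [
        "pre_row", "pre_col", "post_row", "post_col", "latency_ms",
        "peak_per100", "p_value", "psth_area", "psth_peak", "n_resp", "n_trials",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in cmap.connections:
            pr, pc = divmod(c.pre, sc)
            qr, qc = divmod(c.post, ec)
            fh.write(
                f"{pr}\t{pc}\t{qr}\t{qc}\t{c.latency_ms!r}\t{c.peak_per100!r}\t"
                f"{c.p_value!r}\t{c.psth_area!r}\t{c.psth_peak!r}\t"
                f"{c.n_responding_trials}\t{c.n_trials}\n"
            )


def write_pattern(pattern: PatternMask, path: str | Path) -> None:
    """Pattern mask as JSON, or as a plain 0/1 text grid for .txt paths."""
    path = Path(path)
    if path.suffix == ".txt":
        lines = ["".join("1" if v else "0" for v in row) for row in pattern.mask]
        path.write_text("\n".join(lines) + "\n")
        return
    path.write_text(
        json.dumps(
            {
                "name": pattern.name,
                "intensity": pattern.intensity,
                "mask": pattern.mask.astype(int).tolist(),
            }
        )
    )


def read_pattern(path: str | Path, name: str | None = None) -> PatternMask:
    path = Path(path)
    if path.suffix == ".txt":
        rows = [list(map(int, line.strip())) for line in path.read_text().splitlines() if line.strip()]
        return PatternMask(name or path.stem, np.asarray(rows, dtype=bool))
    d = json.loads(path.read_text())
    return PatternMask(d["name"], np.asarray(d["mask"], dtype=bool), float(d.get("intensity", 1.0)))
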