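"""Core in-memory containers: electrode geometry and spike-train recordings.

A multielectrode array (MEA) recording is represented as per-electrode sorted
spike-timestamp arrays (milliseconds) together with the array geometry.
Electrodes are addressed by their row-major index on the full grid; the four
grid corners carry no electrode on the standard 256-well layout, leaving 252
active recording sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeGrid", "SpikeData"]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry of the recording array.

    Parameters
    ----------
    shape
        (rows, cols) of the electrode grid.
    pitch_um
        Center-to-center electrode spacing in micrometers.
    inactive
        Row-major indices of grid positions without an electrode. The default
        (the four corners) yields the 252-of-256 commercial layout.
    """

    shape: tuple[int, int] = (16, 16)
    pitch_um: float = 200.0
    inactive: tuple[int, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inactive is None:
            r, c = self.shape
            corners = (0, c - 1, (r - 1) * c, r * c - 1)
            object.__setattr__(self, "inactive", tuple(sorted(set(corners))))
        else:
            object.__setattr__(self, "inactive", tuple(sorted(set(self.inactive))))

    @property
    def n_positions(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def active_ids(self) -> np.ndarray:
        """Row-major indices of positions that carry an electrode."""
        mask = np.ones(self.n_positions, dtype=bool)
        mask[list(self.inactive)] = False
        return np.flatnonzero(mask)

    @property
    def n_active(self) -> int:
        return self.n_positions - len(self.inactive)

    def coords_um(self, ids: np.ndarray | int) -> np.ndarray:
        """(x, y) position of electrode(s) in micrometers (col -> x, row -> y)."""
        ids = np.atleast_1d(np.asarray(ids, dtype=int))
        rows, cols = np.divmod(ids, self.shape[1])
        return np.stack([cols * self.pitch_um, rows * self.pitch_um], axis=-1)

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "pitch_um": self.pitch_um,
            "inactive": list(self.inactive),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        return cls(tuple(d["shape"]), float(d["pitch_um"]), tuple(d["inactive"]))


@dataclass
class SpikeData:
    """Per-electrode sorted spike timestamps with recording duration.

    ``spikes`` maps the electrode's row-major grid index to a sorted float64
    array of spike times in milliseconds within ``[0, duration_ms]``.
    """

    spikes: dict[int, np.ndarray]
    duration_ms: float
    geometry: ElectrodeGrid = field(default_factory=ElectrodeGrid)

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be non-negative")
        active = set(self.geometry.active_ids.tolist())
        clean: dict[int, np.ndarray] = {}
        for eid, t in self.spikes.items():
            eid = int(eid)
            if eid not in active:
                raise ValueError(f"electrode id {eid} not in geometry")
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"electrode {eid}: timestamps not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration_ms):
                raise ValueError(f"electrode {eid}: timestamps outside recording")
            clean[eid] = t
        self.spikes = clean

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def get(self, electrode_id: int) -> np.ndarray:
        return self.spikes.get(int(electrode_id), np.empty(0))

    def pooled(self) -> np.ndarray:
        """All spike times across electrodes, sorted."""
        if not self.spikes:
            return np.empty(0)
        return np.sort(np.concatenate([t for t in self.spikes.values()]))

    def electrode_ids(self) -> np.ndarray:
        """Active electrode ids, in grid order (including silent electrodes)."""
        return self.geometry.active_ids
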