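"""In-memory trajectory container with compact on-disk form."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Trajectory:
    """Frames of one run: times (ns), positions (nm), box, per-frame
    per-term energies, and arbitrary event logs (insertions, cluster
    checkpoints)."""

    times: list = field(default_factory=list)       # ns
    frames: list = field(default_factory=list)      # (N, 3) float32 arrays
    energies: list = field(default_factory=list)    # dict per frame
    box: float = 0.0
    events: list = field(default_factory=list)

    def append(self, time_ns: float, positions: np.ndarray,
               energies: dict | None = None) -> None:
        self.times.append(float(time_ns))
        self.frames.append(np.asarray(positions, dtype=np.float32).copy())
        self.energies.append(dict(energies) if energies else {})

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions(self, i: int) -> np.ndarray:
        return np.asarray(self.frames[i], dtype=float)

    def energy_table(self):
        """Per-frame energy log as a pandas DataFrame (time in ns)."""
        import pandas as pd

        rows = [{"time_ns": t, **e} for t, e in zip(self.times, self.energies)]
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Compressed npz; frames are stored individually so runs whose
        bead count grows (monomer insertion) round-trip too."""
        keys = sorted({k for e in self.energies for k in e})
        etab = np.array([[e.get(k, np.nan) for k in keys]
                         for e in self.energies])
        frames = {f"frame_{i:06d}": f for i, f in enumerate(self.frames)}
        np.savez_compressed(
            path, times=np.asarray(self.times), box=self.box,
            energy_keys=np.asarray(keys), energy_values=etab, **frames)

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as data:
            traj = cls(box=float(data["box"]))
            keys = [str(k) for k in data["energy_keys"]]
            names = sorted(k for k in data.files if k.startswith("frame_"))
            for t, name, evals in zip(data["times"], names,
                                      data["energy_values"]):
                traj.append(float(t), data[name], dict(zip(keys, evals)))
        return traj
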