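"""Electrode montages with 2-D scalp coordinates and neighbor graphs.

The built-in ``mi22`` layout is the 22-channel sensorimotor montage used in
cue-paced motor-imagery recordings (Fz down to POz, centered on the C-row).
Coordinates are schematic grid positions (unit = one inter-electrode step);
they are used for small-Laplacian neighborhoods and topographic export, not
for source modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "get_montage", "MI22_CHANNELS"]

# name -> (x, y): x positive toward the right ear, y positive toward the nasion
_MI22_GRID: dict[str, tuple[float, float]] = {
    "Fz": (0, 2),
    "FC3": (-2, 1), "FC1": (-1, 1), "FCz": (0, 1), "FC2": (1, 1), "FC4": (2, 1),
    "C5": (-3, 0), "C3": (-2, 0), "C1": (-1, 0), "Cz": (0, 0),
    "C2": (1, 0), "C4": (2, 0), "C6": (3, 0),
    "CP3": (-2, -1), "CP1": (-1, -1), "CPz": (0, -1), "CP2": (1, -1), "CP4": (2, -1),
    "P1": (-1, -2), "Pz": (0, -2), "P2": (1, -2),
    "POz": (0, -3),
}

MI22_CHANNELS: list[str] = list(_MI22_GRID)


@dataclass(frozen=True)
class Montage:
    """Channel names, schematic 2-D positions, and a neighbor radius."""

    name: str
    channels: tuple[str, ...]
    positions: np.ndarray  # (C, 2)
    neighbor_radius: float = 1.1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in montage {self.name!r}") from None

    def neighbors(self, channel: str | int) -> list[int]:
        """Indices of channels within ``neighbor_radius`` (the channel itself excluded)."""
        i = channel if isinstance(channel, (int, np.integer)) else self.index(channel)
        d = np.linalg.norm(self.positions - self.positions[i], axis=1)
        out = np.flatnonzero((d > 0) & (d <= self.neighbor_radius))
        return out.tolist()


def _grid_montage(n_channels: int) -> Montage:
    """Generic near-square grid layout for arbitrary channel counts."""
    ncols = int(np.ceil(np.sqrt(n_channels)))
    names, pos = [], []
    for i in range(n_channels):
        r, c = divmod(i, ncols)
        names.append(f"ch{i + 1:02d}")
        pos.append((float(c - (ncols - 1) / 2), float(-r)))
    return Montage("grid", tuple(names), np.asarray(pos))


def get_montage(name: str, n_channels: int | None = None) -> Montage:
    """Look up a montage by name.

    ``mi22`` is the built-in 22-channel sensorimotor layout; ``grid`` builds a
    generic near-square layout for ``n_channels``.
    """
    if name == "mi22":
        if n_channels not in (None, 22):
            raise ValueError("montage 'mi22' has exactly 22 channels")
        return Montage("mi22", tuple(MI22_CHANNELS),
                       np.asarray([_MI22_GRID[c] for c in MI22_CHANNELS], dtype=float))
    if name == "grid":
        if n_channels is None:
            raise ValueError("montage 'grid' requires n_channels")
        return _grid_montage(n_channels)
    raise KeyError(f"unknown montage {name!r}")
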