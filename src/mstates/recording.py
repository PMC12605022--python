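"""Core domain containers: sensor montage and multichannel EEG recording.

An :class:`EEGRecording` is the currency passed between all pipeline
stages: a ``channels x samples`` float array in microvolts, a sampling
rate, and a :class:`Montage` naming and locating each channel on a
unit sphere (10-20 convention: +x right, +y anterior, +z vertex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["Montage", "EEGRecording", "standard_1020_montage"]


@dataclass
class Montage:
    """Named electrode set with 3D unit-sphere positions (arbitrary units)."""

    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        self.channel_names = [str(n) for n in self.channel_names]
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.channel_names) < 3:
            raise ValueError("montage needs at least 3 channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index_of(self, name: str) -> int:
        """Case-insensitive channel lookup."""
        lowered = [c.lower() for c in self.channel_names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


@dataclass
class EEGRecording:
    """Multichannel EEG signal in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``; row order follows
    ``montage.channel_names``.
    """

    data: np.ndarray
    sfreq: float
    montage: Montage
    # indices (in samples of *this* record) where non-adjacent stretches of
    # the original record were spliced together by artifact rejection
    splice_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sfreq

    def copy(self, data: np.ndarray | None = None) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            sfreq=self.sfreq,
            montage=self.montage,
            splice_boundaries=list(self.splice_boundaries),
        )


def standard_1020_montage() -> Montage:
    """The 19-channel international 10-20 montage shipped with the package.

    Positions are canonical spherical coordinates (inclination/azimuth of
    the 10-20 system mapped onto the unit sphere).
    """
    names, pos = [], []
    text = (
        resources.files("mstates").joinpath("data/standard_1020.sfp").read_text()
    )
    for line in text.strip().splitlines():
        parts = line.split()
        names.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
    return Montage(channel_names=names, positions=np.array(pos))
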