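"""In-memory containers for multichannel LFP recordings and analysis blocks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ArrayLayout

__all__ = ["SessionRecording", "BlockSet"]


@dataclass
class SessionRecording:
    """A multichannel LFP recording from one session.

    Attributes
    ----------
    lfp : ndarray, shape (n_channels, n_samples)
        Voltage traces in millivolts.
    fs : float
        Sampling rate in Hz (recordings are analysed at 1 kHz).
    layout : ArrayLayout
        Electrode lattice; row ``c`` of ``lfp`` was recorded at
        ``layout.coords[retained_channels[c]]``.
    retained_channels : ndarray
        Indices into the full layout for each row of ``lfp``.  Channel
        rejection shrinks this list; all other cleaning steps preserve it.
    session_id : str
    """

    lfp: np.ndarray
    fs: float
    layout: ArrayLayout
    retained_channels: np.ndarray = field(default=None)  # type: ignore[assignment]
    session_id: str = "session-0"

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be channels x samples")
        if self.retained_channels is None:
            self.retained_channels = np.arange(self.lfp.shape[0])
        self.retained_channels = np.asarray(self.retained_channels, dtype=int)
        if len(self.retained_channels) != self.lfp.shape[0]:
            raise ValueError("retained_channels must match lfp channel count")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def coords(self) -> np.ndarray:
        """Coordinates (mm) of the retained channels."""
        return self.layout.coords[self.retained_channels]


@dataclass
class BlockSet:
    """Equal-length artifact-minimal analysis segments from one session.

    Connectivity estimation treats each block as an independent
    realization of the same stationary process; regressions never cross
    block boundaries.
    """

    blocks: list[np.ndarray]
    fs: float
    block_starts: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]
    session_id: str = "session-0"

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        if not self.blocks:
            raise ValueError("BlockSet requires at least one block")
        shape = self.blocks[0].shape
        if any(b.shape != shape for b in self.blocks):
            raise ValueError("all blocks must have identical shape")
        if self.block_starts is None:
            self.block_starts = np.full(len(self.blocks), np.nan)
        if self.interpolated_fraction is None:
            self.interpolated_fraction = np.zeros(len(self.blocks))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_channels(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def block_len(self) -> float:
        return self.blocks[0].shape[1] / self.fs

    @property
    def n_samples_total(self) -> int:
        return sum(b.shape[1] for b in self.blocks)
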