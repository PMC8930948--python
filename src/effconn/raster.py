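"""Core exchange types: binary spike rasters and calcium fluorescence traces.

A :class:`SpikeRaster` is the pipeline's central currency — a cells x frames
binary matrix sampled on a regular frame grid.  Calcium recordings enter as a
:class:`CalciumTraces` matrix with the same shape convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Acquisition frame rate of the recordings the simulator emulates (frames/s).
DEFAULT_FRAME_RATE = 27.33

#: Full spontaneous-recording duration in seconds (18.5 min).
FULL_RECORDING_DURATION_S = 1110.0


@dataclass
class SpikeRaster:
    """Binary spiking activity of a population of cells on a frame grid.

    Parameters
    ----------
    spikes
        ``(n_cells, n_frames)`` array with entries exactly 0 or 1
        (1 = the cell spiked in that frame).
    frame_rate
        Acquisition rate in frames per second.
    duration_s
        Recording length in seconds.  If omitted it is derived as
        ``n_frames / frame_rate``; when given it must satisfy
        ``n_frames == round(duration_s * frame_rate)``.
    """

    spikes: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D cells x frames matrix")
        vals = np.unique(self.spikes)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("spike raster entries must be exactly 0 or 1")
        self.spikes = self.spikes.astype(np.uint8)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration_s is None:
            self.duration_s = self.n_frames / self.frame_rate
        elif round(self.duration_s * self.frame_rate) != self.n_frames:
            raise ValueError(
                f"n_frames={self.n_frames} inconsistent with "
                f"duration_s={self.duration_s} at {self.frame_rate} frames/s"
            )

    @property
    def n_cells(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.spikes.shape[1]

    def spike_counts(self) -> np.ndarray:
        """Per-cell total spike counts ``s_i``."""
        return self.spikes.sum(axis=1).astype(np.int64)


@dataclass
class CalciumTraces:
    """Fluorescence traces, one row per cell (arbitrary units or dF/F)."""

    fluorescence: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    is_relative: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be a 2-D cells x frames matrix")
        if not np.isfinite(self.fluorescence).all():
            raise ValueError("fluorescence contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_cells(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]
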