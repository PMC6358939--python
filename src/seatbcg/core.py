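"""Core containers and mat-geometry conventions.

The sensing element is a 16 x 16 pressure mat (256 sensors) strapped to the
backrest of a driving seat and sampled at 30 Hz.  Sensors are numbered 1-256
in row-major order: sensor 1 sits at row 1 / column 1 (top-left of the mat as
drawn), sensor 16 ends the first row.  All public APIs use 1-based sensor
indices; array storage is 0-based row-major, so the two interconvert with the
helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_SIZE = 16
N_SENSORS = GRID_SIZE * GRID_SIZE


def sensor_to_rowcol(sensor: int) -> tuple[int, int]:
    """Map a 1-based sensor index to 0-based (row, col) mat coordinates."""
    if not 1 <= sensor <= N_SENSORS:
        raise ValueError(f"sensor index must be in 1..{N_SENSORS}, got {sensor}")
    return divmod(sensor - 1, GRID_SIZE)


def rowcol_to_sensor(row: int, col: int) -> int:
    """Map 0-based (row, col) mat coordinates to a 1-based sensor index."""
    if not (0 <= row < GRID_SIZE and 0 <= col < GRID_SIZE):
        raise ValueError(f"(row, col) must lie in 0..{GRID_SIZE - 1}, got {(row, col)}")
    return row * GRID_SIZE + col + 1


@dataclass
class PressureFrame:
    """A single 16 x 16 snapshot of mat pressures, in volts."""

    values: np.ndarray
    sample_time: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"frame must be {GRID_SIZE}x{GRID_SIZE}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame values must be finite")
        if np.any(self.values < 0):
            raise ValueError("frame values must be non-negative")


@dataclass
class PressureRecording:
    """Time series of mat pressures.

    Attributes
    ----------
    samples
        T x 256 array of voltages; column ``s - 1`` holds sensor ``s``.
    sample_rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_SENSORS:
            raise ValueError(f"samples must be T x {N_SENSORS}, got {self.samples.shape}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def sensor(self, sensor: int) -> np.ndarray:
        """Time series of a single 1-based sensor index."""
        if not 1 <= sensor <= N_SENSORS:
            raise ValueError(f"sensor index must be in 1..{N_SENSORS}, got {sensor}")
        return self.samples[:, sensor - 1]
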