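"""Uniformly sampled time-intensity trace of one MRM transition."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import TransitionDef


@dataclass
class Chromatogram:
    """One transition of one injection over its scheduled acquisition window."""

    transition: TransitionDef
    times: np.ndarray  # minutes, uniform, strictly increasing
    intensities: np.ndarray  # counts, >= 0
    injection_id: str = ""
    window_center: float | None = None  # minutes
    window_width_s: float = 120.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least two samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        # tolerate the jitter of times stored with 4 decimals in trace files
        if not np.allclose(dt, np.mean(dt), rtol=1e-3, atol=1.1e-4):
            raise ValueError("times must be uniformly spaced")
        if self.window_center is None:
            self.window_center = float(self.times[len(self.times) // 2])

    @property
    def dt(self) -> float:
        """Sampling step in minutes."""
        return float(self.times[1] - self.times[0])

    def covers(self, rt: float) -> bool:
        return bool(self.times[0] <= rt <= self.times[-1])
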