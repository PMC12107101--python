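"""Normalized fluorescence decay traces.

A chase experiment records fluorescence every ``sample_dt`` seconds starting
at the buffer switch (t = 0) and the whole trace is normalized to the first
frame, so a well-formed trace starts at exactly 1.0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["DecayTrace"]


@dataclass
class DecayTrace:
    """A sampled, t0-normalized fluorescence decay.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, first sample at t = 0.
    values
        Fluorescence normalized to the t = 0 frame (values[0] == 1 after
        :meth:`normalize`).
    meta
        Provenance: model, parameters, seed, backend, ...
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size < 1:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite sample times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("negative sample time")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def is_normalized(self) -> bool:
        return bool(np.isclose(self.values[0], 1.0))

    def normalize(self) -> "DecayTrace":
        """Return a copy rescaled so the first sample equals 1."""
        v0 = self.values[0]
        if v0 == 0 or not np.isfinite(v0):
            raise ValueError("cannot normalize: first sample is zero or non-finite")
        return DecayTrace(self.times.copy(), self.values / v0, dict(self.meta))
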