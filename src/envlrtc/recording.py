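"""In-memory container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONDITIONS = ("EO", "EC", "NA")


@dataclass
class Recording:
    """A channels-by-samples signal block with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes (µV for real EEG, arbitrary units for synthetic
        signals).  Must be finite.
    fs : float
        Sampling rate in Hz.
    labels : sequence of str
        One electrode label per channel, unique.
    condition : {"EO", "EC", "NA"}
        Resting-state condition tag (eyes open / eyes closed / unspecified).
    edge_transient : int
        Number of samples at each end contaminated by filter edge effects;
        downstream envelope statistics exclude this margin.  Zero for raw
        signals.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str] = field(default_factory=list)
    condition: str = "NA"
    edge_transient: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of a named channel."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.data[idx]

    def with_data(self, data: np.ndarray, **meta) -> "Recording":
        """Copy of this recording with new samples (and optional metadata)."""
        return replace(self, data=data, **meta)
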