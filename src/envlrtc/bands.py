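"""Frequency-band definitions for narrowband envelope analysis.

Each band carries the cutoff frequencies of its band-pass filter and the
length (in samples at the analysis sampling rate) of the Hamming-windowed
sinc FIR kernel used to isolate it.  The kernel length in turn fixes the
shortest detrended-fluctuation time-scale that can be analysed without
bias from filter-induced short-range autocorrelations.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with FIR design parameters.

    Parameters
    ----------
    name : str
        Band label (e.g. ``"theta"``).
    f_low, f_high : float
        Band edges in Hz, ``0 < f_low < f_high``.
    fir_len : int
        Length of the band-pass FIR kernel in samples (taps), designed for
        the analysis sampling rate (250 Hz by default throughout).
    """

    name: str
    f_low: float
    f_high: float
    fir_len: int

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"require 0 < f_low < f_high, got ({self.f_low}, {self.f_high})"
            )
        if self.fir_len < 3:
            raise ValueError(f"fir_len must be >= 3, got {self.fir_len}")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low


#: Canonical analysis bands at 250 Hz: theta, alpha, sigma, beta-1, beta-2.
#: Kernel lengths shorten as centre frequency rises, keeping a comparable
#: number of oscillation cycles under the kernel.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0, 125),
    BandDefinition("alpha", 8.0, 12.0, 63),
    BandDefinition("sigma", 12.0, 15.0, 38),
    BandDefinition("beta1", 15.0, 22.0, 31),
    BandDefinition("beta2", 22.0, 30.0, 23),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def get_band(name: str) -> BandDefinition:
    """Look up a default band by name."""
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: {BAND_ORDER}")
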