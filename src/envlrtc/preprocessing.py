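"""Deterministic signal conditioning: FIR filtering, resampling, referencing.

All filters are Hamming-windowed sinc (linear-phase) FIRs.  Band-pass
kernels use fixed per-band lengths chosen so that roughly the same number
of oscillation cycles falls under each kernel; the broadband kernel length
follows from the requested transition bandwidths.  Filtering is applied in
a single zero-phase pass by compensating the (L-1)/2 group delay, so the
timing of amplitude-envelope fluctuations is preserved.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .bands import BandDefinition
from .recording import Recording

#: Approximate Hamming-window transition width, in units of (fs / numtaps).
_HAMMING_TRANSITION = 3.3


def design_band_fir(band: BandDefinition, fs: float) -> np.ndarray:
    """Band-pass FIR kernel for one analysis band.

    Returns `band.fir_len` Hamming-windowed sinc coefficients with unit
    passband gain, symmetric (linear phase).
    """
    if band.f_high >= fs / 2:
        raise ValueError(
            f"band {band.name}: f_high={band.f_high} Hz >= Nyquist ({fs / 2} Hz)"
        )
    return scipy.signal.firwin(
        band.fir_len,
        [band.f_low, band.f_high],
        window="hamming",
        pass_zero=False,
        fs=fs,
    )


def design_broadband_fir(
    fs: float,
    f_low: float = 0.75,
    f_high: float = 65.0,
    transition_low: float = 0.2,
    transition_high: float = 5.0,
) -> np.ndarray:
    """Broadband (0.75-65 Hz) FIR with distinct per-edge transition widths.

    A single windowed-sinc kernel has one transition width, so the band-pass
    is realised as the cascade (convolution) of a high-pass kernel with a
    narrow transition and a low-pass kernel with a wide one.  The cascade is
    again symmetric, hence linear-phase.
    """
    if fs / 2 <= f_high:
        raise ValueError(f"fs={fs} too low for an f_high of {f_high} Hz")

    def _length(transition: float) -> int:
        n = int(np.ceil(_HAMMING_TRANSITION * fs / transition))
        return n + 1 if n % 2 == 0 else n  # odd length: integral group delay

    hp = scipy.signal.firwin(
        _length(transition_low), f_low, window="hamming", pass_zero=False, fs=fs
    )
    lp = scipy.signal.firwin(
        _length(transition_high), f_high, window="hamming", pass_zero=True, fs=fs
    )
    return np.convolve(hp, lp)


def apply_zero_phase(recording: Recording, coeffs: np.ndarray) -> Recording:
    """Filter every channel with a symmetric FIR, compensating group delay.

    A single forward pass shifted back by (L-1)/2 samples; for even-length
    kernels the residual half-sample delay is irrelevant to envelope
    statistics.  The output's ``edge_transient`` marks L samples at each end
    as filter-edge region (accumulating over repeated filtering).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    length = len(coeffs)
    if recording.n_samples <= 3 * length:
        raise ValueError(
            f"signal of {recording.n_samples} samples too short for a "
            f"{length}-tap kernel (need > {3 * length})"
        )
    full = scipy.signal.fftconvolve(recording.data, coeffs[None, :], mode="full")
    delay = (length - 1) // 2
    out = full[:, delay : delay + recording.n_samples]
    return recording.with_data(
        np.ascontiguousarray(out),
        edge_transient=recording.edge_transient + length,
    )


def band_filter(recording: Recording, band: BandDefinition) -> Recording:
    """Zero-phase band-pass filtering with the band's canonical kernel."""
    return apply_zero_phase(recording, design_band_fir(band, recording.fs))


def downsample(recording: Recording, target_fs: float) -> Recording:
    """Anti-aliased integer-factor decimation to ``target_fs``."""
    if target_fs == recording.fs:
        return recording.with_data(recording.data.copy())
    ratio = recording.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"target_fs={target_fs} is not an integer divisor of fs={recording.fs}"
        )
    out = scipy.signal.decimate(recording.data, q, ftype="fir", zero_phase=True)
    return Recording(
        out,
        fs=target_fs,
        labels=recording.labels,
        condition=recording.condition,
        edge_transient=int(np.ceil(recording.edge_transient / q)),
    )


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if recording.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    mean = recording.data.mean(axis=0, keepdims=True)
    return recording.with_data(recording.data - mean)


def crop_segment(recording: Recording, start: float, duration: float) -> Recording:
    """Extract ``duration`` seconds starting at ``start`` seconds."""
    i0 = int(round(start * recording.fs))
    n = int(round(duration * recording.fs))
    if start < 0 or i0 + n > recording.n_samples:
        raise ValueError(
            f"requested [{start}, {start + duration}) s outside the "
            f"{recording.duration:.3f} s recording"
        )
    return recording.with_data(recording.data[:, i0 : i0 + n].copy())
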