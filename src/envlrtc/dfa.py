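"""Detrended fluctuation analysis of narrowband amplitude envelopes.

The scaling exponent H of the amplitude envelope is estimated in four
steps: (1) the envelope is the modulus of the analytic (Hilbert) signal of
the band-filtered oscillation; (2) the envelope is cumulatively summed and
its global linear trend removed, giving the profile; (3) the profile is
split into non-overlapping segments of a given time-scale, a local cubic
trend is removed from each by least squares, and the fluctuation at that
scale is the average of the per-segment RMS residuals; (4) the slope of
log10(fluctuation) against log10(scale) over 20 logarithmically spaced
scales is H.

The scale grid runs from eight times the band-filter kernel duration (to
stay clear of filter-induced short-range autocorrelations) up to one
eighth of the record length (so at least eight segments enter every
fluctuation average).

H = 0.5 indicates an uncorrelated (random) process, 0.5 < H < 1 persistent
positive long-range correlations, H > 1 non-stationarity.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .bands import BandDefinition
from .hmatrix import HMatrix
from .preprocessing import band_filter
from .recording import Recording

__all__ = [
    "EnvelopeSeries",
    "ScaleGrid",
    "DFAResult",
    "EnvelopeDFA",
    "DegenerateFitError",
    "hilbert_envelope",
    "build_profile",
    "fluctuation_at_scale",
    "make_scale_grid",
    "estimate_hurst",
    "compute_h_matrix",
    "grand_median_h",
    "band_median_h",
]


class DegenerateFitError(ValueError):
    """Raised when a fluctuation is non-positive and log-log fitting fails."""


@dataclass
class EnvelopeSeries:
    """A non-negative amplitude-envelope series with its sampling rate."""

    values: np.ndarray
    fs: float
    band: BandDefinition | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("empty envelope")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("envelope must be non-negative")

    def __len__(self) -> int:
        return self.values.size


def hilbert_envelope(
    filtered: np.ndarray | Recording,
    fs: float | None = None,
    band: BandDefinition | None = None,
) -> EnvelopeSeries:
    """Amplitude envelope: pointwise modulus of the analytic signal.

    Meaningful only for narrowband input (a documented contract, not
    enforced).  Accepts a 1-D array plus ``fs`` or a single-channel
    :class:`Recording`.
    """
    if isinstance(filtered, Recording):
        if filtered.n_channels != 1:
            raise ValueError("hilbert_envelope expects a single channel")
        fs = filtered.fs
        x = filtered.data[0]
    else:
        if fs is None:
            raise ValueError("fs is required with array input")
        x = np.asarray(filtered, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input signal")
    return EnvelopeSeries(np.abs(scipy.signal.hilbert(x)), fs, band)


def build_profile(envelope: EnvelopeSeries | np.ndarray) -> np.ndarray:
    """Cumulative sum of the envelope with its global linear trend removed.

    The residual has exactly zero mean and zero covariance with the time
    index (ordinary least-squares identities).
    """
    values = envelope.values if isinstance(envelope, EnvelopeSeries) else np.asarray(envelope, float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to build a profile")
    y = np.cumsum(values)
    x = np.arange(y.size, dtype=float)
    x = x - x.mean()
    slope = (x @ (y - y.mean())) / (x @ x)
    return y - y.mean() - slope * x


@functools.lru_cache(maxsize=256)
def _detrend_basis(scale: int, poly_order: int) -> np.ndarray:
    """Orthonormal polynomial basis on ``scale`` points (for fast projection)."""
    x = (np.arange(scale) - (scale - 1) / 2.0) / scale
    design = np.vander(x, poly_order + 1, increasing=True)
    q, _ = np.linalg.qr(design)
    return q


def fluctuation_at_scale(
    profile: np.ndarray, scale: int, poly_order: int = 3
) -> tuple[float, int]:
    """Mean per-segment RMS of locally detrended profile segments.

    The profile is cut into non-overlapping segments of ``scale`` samples
    starting at the first sample; the trailing partial segment is
    discarded.  A local polynomial trend of order ``poly_order`` (cubic by
    default) is removed from each segment by least squares; the returned
    fluctuation is the average over segments of the per-segment RMS
    residual, together with the number of segments used.
    """
    profile = np.asarray(profile, dtype=float)
    scale = int(scale)
    if scale < poly_order + 2:
        raise ValueError(f"scale {scale} too small for order-{poly_order} detrending")
    n_seg = profile.size // scale
    if n_seg < 1:
        raise ValueError(f"scale {scale} exceeds profile length {profile.size}")
    segments = profile[: n_seg * scale].reshape(n_seg, scale)
    q = _detrend_basis(scale, poly_order)
    resid = segments - (segments @ q) @ q.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return float(rms.mean()), n_seg


@dataclass(frozen=True)
class ScaleGrid:
    """Logarithmically spaced DFA time-scales in integer samples."""

    scales: tuple[int, ...]
    fs: float

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def seconds(self) -> np.ndarray:
        return np.asarray(self.scales) / self.fs

    @property
    def min_scale(self) -> float:
        """Shortest scale in seconds."""
        return self.scales[0] / self.fs

    @property
    def max_scale(self) -> float:
        """Longest scale in seconds."""
        return self.scales[-1] / self.fs

    def __len__(self) -> int:
        return len(self.scales)


def make_scale_grid(
    band: BandDefinition,
    fs: float,
    n_samples: int,
    n_scales: int = 20,
) -> ScaleGrid:
    """Build the per-band DFA scale grid from the 8x rules.

    The minimum scale is eight times the band kernel duration
    (``8 * fir_len`` samples); the maximum is one eighth of the record
    (``n_samples // 8``).  ``n_scales`` log-spaced values are floored to
    integer sample counts; duplicates arising from rounding are collapsed
    with a warning.
    """
    smin = 8 * band.fir_len
    smax = n_samples // 8
    if smin >= smax:
        raise ValueError(
            f"record of {n_samples} samples too short for band {band.name}: "
            f"scale range [{smin}, {smax}] samples is empty"
        )
    exact = smin * (smax / smin) ** (np.arange(n_scales) / (n_scales - 1))
    scales = np.floor(exact + 1e-9).astype(int)
    scales[0], scales[-1] = smin, smax
    unique = np.unique(scales)
    if unique.size < n_scales:
        import warnings

        warnings.warn(
            f"scale grid for band {band.name}: integer rounding collapsed "
            f"{n_scales - unique.size} duplicate scales",
            stacklevel=2,
        )
    return ScaleGrid(tuple(int(s) for s in unique), fs)


@dataclass
class DFAResult:
    """Fitted DFA scaling law for one envelope.

    ``hurst`` is the slope of log10(fluctuation) on log10(scale);
    ``fit_r2`` diagnoses the log-log linearity of the scaling law, and
    ``n_segments_per_scale`` records how many segments entered each
    fluctuation average.
    """

    hurst: float
    intercept: float
    fit_r2: float
    grid: ScaleGrid
    fluctuations: np.ndarray
    n_segments_per_scale: np.ndarray
    band: BandDefinition | None = None

    def summary(self) -> str:
        lines = [
            "Detrended fluctuation analysis of amplitude envelope",
            "====================================================",
            f"band:            {self.band.name if self.band else 'n/a'}",
            f"scales:          {len(self.grid)} "
            f"({self.grid.min_scale:.3g}-{self.grid.max_scale:.3g} s)",
            f"Hurst exponent:  {self.hurst:.4f}",
            f"log10 intercept: {self.intercept:.4f}",
            f"fit R^2:         {self.fit_r2:.4f}",
            f"segments/scale:  {self.n_segments_per_scale.min()}-"
            f"{self.n_segments_per_scale.max()}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-scale diagnostics table."""
        return pd.DataFrame(
            {
                "scale_samples": list(self.grid.scales),
                "scale_seconds": self.grid.seconds,
                "fluctuation": self.fluctuations,
                "n_segments": self.n_segments_per_scale,
            }
        )

    def plot(self, ax=None):
        """Log-log fluctuation plot with the fitted scaling line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sec = self.grid.seconds
        ax.loglog(sec, self.fluctuations, "o", color="k", label="fluctuation")
        fit = 10 ** (self.intercept + self.hurst * np.log10(np.asarray(self.grid.scales)))
        ax.loglog(sec, fit, "-", color="0.5", label=f"H = {self.hurst:.3f}")
        ax.set_xlabel("time-scale (s)")
        ax.set_ylabel("mean RMS fluctuation")
        ax.legend()
        return ax


class EnvelopeDFA:
    """DFA scaling model of one amplitude envelope.

    Parameters
    ----------
    envelope : EnvelopeSeries or ndarray
        Non-negative amplitude series (pass ``fs`` with array input).
    grid : ScaleGrid, optional
        Explicit scale grid; by default built from ``band`` and the
        envelope length via :func:`make_scale_grid`.
    poly_order : int
        Local detrending order (cubic by default).

    ``fit()`` returns a :class:`DFAResult`.
    """

    def __init__(
        self,
        envelope: EnvelopeSeries | np.ndarray,
        fs: float | None = None,
        band: BandDefinition | None = None,
        grid: ScaleGrid | None = None,
        poly_order: int = 3,
        n_scales: int = 20,
    ) -> None:
        if not isinstance(envelope, EnvelopeSeries):
            if fs is None:
                raise ValueError("fs is required with array input")
            envelope = EnvelopeSeries(envelope, fs, band)
        self.envelope = envelope
        self.band = band or envelope.band
        if grid is None:
            if self.band is None:
                raise ValueError("either an explicit grid or a band is required")
            grid = make_scale_grid(self.band, envelope.fs, len(envelope), n_scales)
        if grid.scales[-1] > len(envelope):
            raise ValueError("scale grid exceeds envelope length")
        self.grid = grid
        self.poly_order = poly_order

    def fit(self) -> DFAResult:
        profile = build_profile(self.envelope)
        fluctuations = np.empty(len(self.grid))
        n_segments = np.empty(len(self.grid), dtype=int)
        for i, scale in enumerate(self.grid.scales):
            fluctuations[i], n_segments[i] = fluctuation_at_scale(
                profile, scale, self.poly_order
            )
        if np.any(fluctuations <= 0):
            bad = np.asarray(self.grid.scales)[fluctuations <= 0]
            raise DegenerateFitError(
                f"non-positive fluctuation at scale(s) {bad.tolist()} samples "
                "(constant envelope?)"
            )
        logs = np.log10(np.asarray(self.grid.scales, dtype=float))
        logf = np.log10(fluctuations)
        slope, intercept = np.polyfit(logs, logf, 1)
        pred = intercept + slope * logs
        ss_res = float(np.sum((logf - pred) ** 2))
        ss_tot = float(np.sum((logf - logf.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return DFAResult(
            hurst=float(slope),
            intercept=float(intercept),
            fit_r2=r2,
            grid=self.grid,
            fluctuations=fluctuations,
            n_segments_per_scale=n_segments,
            band=self.band,
        )


def estimate_hurst(
    envelope: EnvelopeSeries | np.ndarray,
    grid: ScaleGrid,
    fs: float | None = None,
    poly_order: int = 3,
) -> DFAResult:
    """Functional wrapper: fit :class:`EnvelopeDFA` on an explicit grid."""
    return EnvelopeDFA(envelope, fs=fs, grid=grid, poly_order=poly_order).fit()


def _trimmed_envelope(env: EnvelopeSeries, n_edge: int) -> EnvelopeSeries:
    if n_edge <= 0:
        return env
    if len(env) <= 2 * n_edge:
        raise ValueError("envelope shorter than twice the edge-transient margin")
    return EnvelopeSeries(env.values[n_edge:-n_edge], env.fs, env.band)


def _participant_h(
    rec: Recording, bands: Sequence[BandDefinition], poly_order: int, n_scales: int
) -> np.ndarray:
    out = np.empty((rec.n_channels, len(bands)))
    for b, band in enumerate(bands):
        filtered = band_filter(rec, band)
        grid: ScaleGrid | None = None
        for e in range(filtered.n_channels):
            try:
                env = _trimmed_envelope(
                    hilbert_envelope(filtered.data[e], rec.fs, band),
                    filtered.edge_transient,
                )
                if grid is None:
                    grid = make_scale_grid(band, rec.fs, len(env), n_scales)
                out[e, b] = EnvelopeDFA(
                    env, grid=grid, poly_order=poly_order
                ).fit().hurst
            except Exception as exc:
                raise RuntimeError(
                    f"DFA failed for electrode {rec.labels[e]!r}, "
                    f"band {band.name!r}: {exc}"
                ) from exc
    return out


def compute_h_matrix(
    recordings: Mapping[str, Recording],
    bands: Sequence[BandDefinition],
    condition: str = "NA",
    poly_order: int = 3,
    n_scales: int = 20,
    n_jobs: int = 1,
) -> HMatrix:
    """Run the full band-filter -> envelope -> DFA chain over a cohort.

    ``recordings`` maps participant id to a multichannel
    :class:`Recording`; all must share sampling rate and channel labels.
    Filter edge transients are excluded from the envelopes before DFA.
    Deterministic; optionally parallel over participants via joblib.
    """
    pids = list(recordings)
    if not pids:
        raise ValueError("empty cohort")
    first = recordings[pids[0]]
    for pid in pids:
        rec = recordings[pid]
        if rec.fs != first.fs or rec.labels != first.labels:
            raise ValueError(
                f"participant {pid!r} has inconsistent fs or channel labels"
            )
    def _wrapped(pid: str) -> np.ndarray:
        try:
            return _participant_h(recordings[pid], bands, poly_order, n_scales)
        except RuntimeError as exc:
            raise RuntimeError(f"participant {pid!r}: {exc}") from exc

    if n_jobs != 1:
        from joblib import Parallel, delayed

        per_participant = Parallel(n_jobs=n_jobs)(
            delayed(_wrapped)(pid) for pid in pids
        )
    else:
        per_participant = [_wrapped(pid) for pid in pids]
    h = np.stack(per_participant)
    return HMatrix(
        h, pids, list(first.labels), [b.name for b in bands], condition
    )


def grand_median_h(hm: HMatrix) -> pd.Series:
    """Per-participant median of H over the electrode x band plane."""
    return hm.grand_median()


def band_median_h(hm: HMatrix) -> pd.DataFrame:
    """Per-participant, per-band median of H across electrodes."""
    return hm.band_median()
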