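"""Synthetic signals, montages and cohorts with planted LRTC structure.

The generators emulate the statistical structure the analysis assumes in
real resting-state EEG: narrowband oscillations whose amplitude envelopes
carry long-range temporal correlations with a controllable Hurst exponent,
a sensor layout with a neighbourhood graph, and a two-group cohort whose
insomnia-severity scores (ISI) are linked to envelope persistence in
chosen (electrode, band) bins.  Everything is seeded; independent random
streams are split off a master seed through ``numpy`` seed sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .bands import BandDefinition
from .hmatrix import HMatrix
from .preprocessing import design_band_fir
from .recording import Recording

logger = logging.getLogger(__name__)

Bin = tuple[str, str]  # (electrode label, band name)


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FgnSpec:
    """Exact-covariance fractional Gaussian noise.

    ``hurst`` in (0, 1): 0.5 is white noise, 0.5-1 gives persistent
    positive autocorrelations (LRTC), below 0.5 anti-persistence.
    """

    n_samples: int
    hurst: float
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


def fgn_autocorrelation(lags: np.ndarray, hurst: float) -> np.ndarray:
    """Closed-form fGn autocorrelation rho(k) = ((|k|+1)^2H - 2|k|^2H + ||k|-1|^2H)/2."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _fgn_samples(rng: np.random.Generator, n: int, hurst: float) -> np.ndarray:
    """One unit-variance fGn realisation by circulant covariance embedding.

    The target covariance is embedded in a 2n-circulant whose eigenvalues
    are the FFT of the wrapped autocovariance; for fGn they are provably
    non-negative, so the synthesis is exact (no burn-in, no bias).
    """
    r = fgn_autocorrelation(np.arange(n + 1), hurst)
    row = np.concatenate([r, r[-2:0:-1]])  # wrapped covariance, length 2n
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # guard vanishing negatives from roundoff
    z = rng.standard_normal(2 * n) + 1j * rng.standard_normal(2 * n)
    y = np.fft.ifft(np.sqrt(lam) * np.fft.fft(z))
    return y.real[:n]


def generate_fgn(spec: FgnSpec) -> np.ndarray:
    """Stationary Gaussian series with prescribed Hurst exponent."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return spec.sd * _fgn_samples(rng, spec.n_samples, spec.hurst)


# ---------------------------------------------------------------------------
# sensor montage
# ---------------------------------------------------------------------------

@dataclass
class SensorMontage:
    """Electrode labels and positions in an abstract 2-D/3-D layout space.

    Two electrodes are neighbours when their Euclidean distance is at most
    ``neighbor_radius`` (self-pairs excluded).
    """

    labels: Sequence[str]
    positions: np.ndarray
    neighbor_radius: float

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if self.positions.shape[0] != len(self.labels):
            raise ValueError("one position per label required")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def adjacency(self) -> np.ndarray:
        """Symmetric, irreflexive boolean neighbour matrix."""
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        adj = d <= self.neighbor_radius * (1 + 1e-9)
        np.fill_diagonal(adj, False)
        return adj

    def edges(self) -> np.ndarray:
        """Neighbour pairs as an (n_edges, 2) index array with i < j."""
        adj = self.adjacency()
        i, j = np.nonzero(np.triu(adj, k=1))
        return np.column_stack([i, j])

    def to_frame(self) -> pd.DataFrame:
        pos = self.positions
        if pos.shape[1] == 2:
            pos = np.column_stack([pos, np.zeros(len(pos))])
        return pd.DataFrame(
            {"label": self.labels, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]}
        )


def generate_montage(
    n_electrodes: int,
    layout: str = "grid",
    neighbor_radius: float | None = None,
) -> SensorMontage:
    """Deterministic synthetic sensor layout.

    ``grid`` places electrodes row-major on a near-square unit-step lattice
    (default radius 1.0: rook neighbourhoods); ``ring`` places them on a
    unit circle (default radius: the adjacent chord, giving each electrode
    exactly two neighbours).
    """
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    if layout == "grid":
        n_cols = int(np.ceil(np.sqrt(n_electrodes)))
        idx = np.arange(n_electrodes)
        positions = np.column_stack([idx % n_cols, idx // n_cols]).astype(float)
        radius = 1.0 if neighbor_radius is None else neighbor_radius
    elif layout == "ring":
        theta = 2 * np.pi * np.arange(n_electrodes) / n_electrodes
        positions = np.column_stack([np.cos(theta), np.sin(theta)])
        radius = (
            2 * np.sin(np.pi / n_electrodes)
            if neighbor_radius is None
            else neighbor_radius
        )
    else:
        raise ValueError(f"unknown layout {layout!r} (use 'grid' or 'ring')")
    labels = [f"E{i + 1:03d}" for i in range(n_electrodes)]
    montage = SensorMontage(labels, positions, radius)
    if not montage.adjacency().any():
        raise ValueError(
            f"neighbor_radius={radius} isolates every electrode in the layout"
        )
    return montage


def grid_region(montage: SensorMontage, region: str) -> list[str]:
    """Labels in the posterior/anterior third of a layout (by y coordinate).

    A crude stand-in for scalp regions: larger y is 'posterior' (parietal),
    smaller y 'anterior' (frontal), the rest 'central'.
    """
    y = montage.positions[:, 1]
    lo, hi = y.min(), y.max()
    third = (hi - lo) / 3 if hi > lo else 0.0
    if region == "posterior":
        keep = y >= hi - third
    elif region == "anterior":
        keep = y <= lo + third
    elif region == "central":
        keep = (y > lo + third) & (y < hi - third)
    else:
        raise ValueError(f"unknown region {region!r}")
    return [lab for lab, k in zip(montage.labels, keep) if k]


# ---------------------------------------------------------------------------
# narrowband oscillations with planted envelope Hurst exponents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillationSpec:
    """A narrowband oscillation whose amplitude envelope has a known H."""

    band: BandDefinition
    duration: float
    fs: float
    envelope_hurst: float
    modulation_depth: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.band.f_high:
            raise ValueError(
                f"fs={self.fs} must exceed twice f_high={self.band.f_high}"
            )
        if not 0.0 < self.envelope_hurst < 1.0:
            raise ValueError("envelope_hurst must lie in (0, 1)")
        if not 0.0 < self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in (0, 1]")
        min_scale_s = 8 * self.band.fir_len / self.fs
        if self.duration < 8 * min_scale_s:
            raise ValueError(
                f"duration {self.duration} s too short: the DFA scale grid "
                f"needs >= {8 * min_scale_s:.2f} s for band {self.band.name}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


_ENVELOPE_FLOOR = 1e-3


def _planted_envelope(
    rng: np.random.Generator, n: int, hurst: float, depth: float
) -> np.ndarray:
    """Strictly positive envelope 1 + depth * standardized fGn, floored.

    Flooring events (negative excursions of the modulation) are counted and
    logged; they distort the planted autocorrelation only in the far tail
    of the Gaussian, so recovery of ``hurst`` is unaffected at moderate
    depths.
    """
    g = _fgn_samples(rng, n, hurst)
    g = (g - g.mean()) / g.std()
    env = 1.0 + depth * g
    n_floored = int(np.sum(env < _ENVELOPE_FLOOR))
    if n_floored:
        logger.debug("envelope floored at %d/%d samples", n_floored, n)
        env = np.maximum(env, _ENVELOPE_FLOOR)
    return env


#: FM drift parameters of the synthetic carrier: the instantaneous
#: frequency wanders around the band centre with a standard deviation of
#: bandwidth/12 and a drift bandwidth of 0.5 Hz.  The drift is kept small
#: because the analysis band-filters have sloping passbands: a larger
#: frequency wander would be converted into spurious slow amplitude
#: modulation (FM-to-AM conversion) that contaminates the envelope's
#: planted scaling behaviour.
_DRIFT_SIGMA_FRACTION = 1 / 12
_DRIFT_BANDWIDTH_HZ = 0.5


def _carrier_phase(
    rng: np.random.Generator, band: BandDefinition, fs: float, n: int
) -> np.ndarray:
    """Phase of a constant-amplitude carrier with slow in-band frequency drift."""
    lp = scipy.signal.firwin(int(4 * fs) | 1, _DRIFT_BANDWIDTH_HZ, fs=fs)
    white = rng.standard_normal(n + len(lp))
    drift = scipy.signal.fftconvolve(white, lp, mode="same")[
        len(lp) // 2 : len(lp) // 2 + n
    ]
    drift = drift / drift.std() * (band.bandwidth * _DRIFT_SIGMA_FRACTION)
    f_inst = band.center + drift
    return 2 * np.pi * np.cumsum(f_inst) / fs


def generate_band_oscillation(spec: OscillationSpec) -> Recording:
    """Narrowband oscillation whose Hilbert envelope has Hurst ``envelope_hurst``.

    The carrier is a constant-amplitude oscillation whose instantaneous
    frequency drifts slowly inside the band; the amplitude is imposed as a
    strictly positive fGn-derived envelope.  Imposing the envelope (rather
    than multiplying onto a noise carrier's own Rayleigh-fluctuating
    envelope) keeps the Hilbert envelope equal to the planted one, so DFA
    on the extracted envelope recovers ``envelope_hurst`` without a
    white-noise bias from carrier amplitude fluctuations.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_env, rng_carrier = (np.random.default_rng(s) for s in ss.spawn(2))
    n = spec.n_samples
    env = _planted_envelope(rng_env, n, spec.envelope_hurst, spec.modulation_depth)
    phase = _carrier_phase(rng_carrier, spec.band, spec.fs, n)
    data = env * np.cos(phase)
    return Recording(data[None, :], fs=spec.fs, labels=[f"{spec.band.name}-osc"])


def generate_white_surrogate(
    band: BandDefinition,
    fs: float,
    duration: float,
    seed: int = 0,
    rescale_mean: float | None = None,
) -> Recording:
    """Band-pass filtered Gaussian white noise (envelope has H ~ 0.5).

    If ``rescale_mean`` is given, the signal is scaled so the mean Hilbert
    envelope amplitude equals it (used to overlay surrogates on a reference
    signal's fluctuation plot).
    """
    if fs <= 2 * band.f_high:
        raise ValueError(f"fs={fs} must exceed twice f_high={band.f_high}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(duration * fs))
    pad = 4 * band.fir_len
    white = rng.standard_normal(n + 2 * pad)
    kernel = design_band_fir(band, fs)
    data = scipy.signal.fftconvolve(white, kernel, mode="same")[pad : pad + n]
    if rescale_mean is not None:
        env_mean = np.abs(scipy.signal.hilbert(data)).mean()
        data = data * (rescale_mean / env_mean)
    return Recording(data[None, :], fs=fs, labels=[f"{band.name}-surrogate"])


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with group-specific ISI-H association structure.

    ``effect_mask`` maps each group to the set of (electrode, band) bins
    where that group's ISI score is linearly coupled to H with slope
    ``slope_per_isi_point`` (H units per ISI point).  ISI scores are
    integers drawn uniformly within each group's range; the insomnia group
    must sit at or above the sub-clinical cutoff of 8, controls below it.
    """

    n_id: int = 52
    n_ctrl: int = 43
    isi_range_id: tuple[int, int] = (8, 28)
    isi_range_ctrl: tuple[int, int] = (0, 7)
    base_h: float = 0.7
    effect_mask: Mapping[str, frozenset[Bin]] = field(
        default_factory=lambda: {"ID": frozenset(), "CTRL": frozenset()}
    )
    slope_per_isi_point: float = 0.005
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_id < 1 or self.n_ctrl < 1:
            raise ValueError("both groups must be non-empty")
        if self.isi_range_id[0] < 8:
            raise ValueError("ID group ISI must start at the cutoff of 8 or above")
        if self.isi_range_ctrl[1] >= 8:
            raise ValueError("CTRL group ISI must stay below the cutoff of 8")
        for lo, hi in (self.isi_range_id, self.isi_range_ctrl):
            if lo > hi:
                raise ValueError(f"empty ISI range ({lo}, {hi})")
        if not 0.5 < self.base_h < 1.0:
            raise ValueError("base_h must lie in (0.5, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_effect_masks(
    montage: SensorMontage, bands: Sequence[BandDefinition]
) -> dict[str, frozenset[Bin]]:
    """Group-specific spatio-spectral association profiles.

    Emulates the finding structure the analysis is designed to resolve:
    the insomnia group's ISI couples to posterior (parietal) theta
    envelopes, the control group's to anterior (centro-frontal) beta-1.
    Bands absent from ``bands`` are silently dropped from the masks.
    """
    names = {b.name for b in bands}
    masks: dict[str, frozenset[Bin]] = {"ID": frozenset(), "CTRL": frozenset()}
    if "theta" in names:
        masks["ID"] = frozenset(
            (e, "theta") for e in grid_region(montage, "posterior")
        )
    if "beta1" in names:
        masks["CTRL"] = frozenset(
            (e, "beta1") for e in grid_region(montage, "anterior")
        )
    return masks


def _validate_mask(
    spec: CohortSpec, montage: SensorMontage, bands: Sequence[BandDefinition]
) -> None:
    known = {(e, b.name) for e in montage.labels for b in bands}
    for group, mask in spec.effect_mask.items():
        stray = set(mask) - known
        if stray:
            raise ValueError(f"effect_mask[{group}] has unknown bins: {sorted(stray)}")


_H_CLIP = (0.5 + 1e-4, 1.0 - 1e-4)


def generate_cohort_h(
    spec: CohortSpec,
    montage: SensorMontage,
    bands: Sequence[BandDefinition],
) -> tuple[pd.DataFrame, HMatrix]:
    """Cohort table plus planted participants x electrodes x bands H values.

    H(p, e, b) = base_h + slope * ISI_p * 1[(e, b) in group mask] + noise,
    clipped to the open interval (0.5, 1) where amplitude-envelope scaling
    exponents of wake EEG are observed.
    """
    _validate_mask(spec, montage, bands)
    ss = np.random.SeedSequence(spec.seed)
    rng_cohort, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    n = spec.n_id + spec.n_ctrl
    groups = ["ID"] * spec.n_id + ["CTRL"] * spec.n_ctrl
    isi = np.concatenate(
        [
            rng_cohort.integers(spec.isi_range_id[0], spec.isi_range_id[1] + 1, spec.n_id),
            rng_cohort.integers(
                spec.isi_range_ctrl[0], spec.isi_range_ctrl[1] + 1, spec.n_ctrl
            ),
        ]
    )
    age = rng_cohort.integers(21, 71, n)
    # female proportions matching the study cohort composition per group
    sex = np.where(
        rng_cohort.random(n) < np.where(np.asarray(groups) == "ID", 43 / 52, 32 / 43),
        "F",
        "M",
    )
    cohort = pd.DataFrame(
        {
            "id": [f"S{i + 1:03d}" for i in range(n)],
            "group": groups,
            "isi": isi,
            "age": age,
            "sex": sex,
        }
    )

    band_names = [b.name for b in bands]
    mask = np.zeros((2, montage.n_electrodes, len(bands)))  # ID row 0, CTRL row 1
    for gi, group in enumerate(("ID", "CTRL")):
        for e_label, b_name in spec.effect_mask.get(group, ()):
            mask[gi, montage.labels.index(e_label), band_names.index(b_name)] = 1.0
    g_idx = (cohort["group"] == "CTRL").to_numpy().astype(int)
    h = (
        spec.base_h
        + spec.slope_per_isi_point * isi[:, None, None] * mask[g_idx]
        + rng_noise.normal(0.0, spec.noise_sd, (n, montage.n_electrodes, len(bands)))
    )
    h = np.clip(h, *_H_CLIP)
    hm = HMatrix(h, cohort["id"], montage.labels, band_names, "NA")
    return cohort, hm


def generate_cohort_recordings(
    spec: CohortSpec,
    montage: SensorMontage,
    bands: Sequence[BandDefinition],
    duration: float = 180.0,
    fs: float = 250.0,
    modulation_depth: float = 0.3,
    noise_floor: float = 0.05,
    condition: str = "NA",
) -> Iterator[tuple[str, Recording, HMatrix]]:
    """Signal-level cohort: yields (participant id, Recording, planted HMatrix).

    Each channel sums, over the analysis bands, one narrowband oscillation
    whose planted envelope Hurst exponent equals that participant's
    H(electrode, band), plus a broadband white-noise floor scaled to
    ``noise_floor`` times the single-band RMS.  The same planted HMatrix
    (one participant slice per yield) is what an end-to-end run should
    recover.
    """
    cohort, hm = generate_cohort_h(spec, montage, bands)
    ss = np.random.SeedSequence((spec.seed, 1))
    n = int(round(duration * fs))
    for p, pid in enumerate(cohort["id"]):
        data = np.zeros((montage.n_electrodes, n))
        for e in range(montage.n_electrodes):
            for b, band in enumerate(bands):
                osc = generate_band_oscillation(
                    OscillationSpec(
                        band=band,
                        duration=duration,
                        fs=fs,
                        envelope_hurst=hm.h[p, e, b],
                        modulation_depth=modulation_depth,
                        seed=int(
                            np.random.SeedSequence(
                                (spec.seed, 1, p, e, b)
                            ).generate_state(1)[0]
                            % (2**31)
                        ),
                    )
                )
                sig = osc.data[0]
                data[e] += sig / sig.std()
            rng_floor = np.random.default_rng(
                np.random.SeedSequence((spec.seed, 2, p, e))
            )
            data[e] += noise_floor * rng_floor.standard_normal(n)
        rec = Recording(
            data, fs=fs, labels=list(montage.labels), condition=condition
        )
        yield pid, rec, HMatrix(
            hm.h[p : p + 1],
            [pid],
            montage.labels,
            [b.name for b in bands],
            condition,
        )


def cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Cohort table alone (ids, groups, ISI, demographics) for a spec."""
    montage = generate_montage(4, "ring")
    cohort, _ = generate_cohort_h(
        CohortSpec(**{**spec.__dict__, "effect_mask": {"ID": frozenset(), "CTRL": frozenset()}}),
        montage,
        [],
    )
    return cohort
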