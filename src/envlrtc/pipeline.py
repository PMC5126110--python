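"""Pipeline orchestration, configuration and on-disk formats.

A run reads a cohort directory (cohort table, montage, per-participant
recordings), conditions each recording (crop, optional broadband filter /
downsampling / common-average reference), estimates the H matrix through
the band-filter -> envelope -> DFA chain, fits the cohort-level model and
writes a machine-readable report plus a manifest.  All randomness derives
from the single configured seed, so reruns are byte-identical except for
the manifest's timing fields.

Recordings are stored as plain TSV matrices (channels x samples) with a
JSON sidecar (``<name>.tsv.json``) holding the sampling rate, labels and
condition; EDF input is supported through ``mne`` when installed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import DEFAULT_BANDS, BandDefinition
from .dfa import compute_h_matrix
from .hmatrix import HMatrix
from .model import LrtcStudy
from .preprocessing import (
    apply_zero_phase,
    common_average_reference,
    crop_segment,
    design_broadband_fir,
    downsample,
)
from .recording import Recording
from .stats import condition_contrast
from .synthetic import (
    CohortSpec,
    SensorMontage,
    default_effect_masks,
    generate_cohort_recordings,
    generate_montage,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All analysis parameters, with canonical defaults.

    The defaults encode the standard analysis: 250 Hz sampling, the five
    bands with their FIR kernel lengths, the first 180 s segment, 20 DFA
    scales with cubic detrending, 1000 bootstrap iterations, and TFCE with
    e = 0.66, h = 2 and 1000 permutations at alpha = 0.05.
    """

    fs: float = 250.0
    segment_start: float = 0.0
    segment_duration: float = 180.0
    bands: list[list] = field(
        default_factory=lambda: [
            [b.name, b.f_low, b.f_high, b.fir_len] for b in DEFAULT_BANDS
        ]
    )
    n_scales: int = 20
    poly_order: int = 3
    n_boot: int = 1000
    alpha: float = 0.05
    tfce_e: float = 0.66
    tfce_h: float = 2.0
    n_perm: int = 1000
    n_steps: int = 100
    apply_broadband: bool = False
    apply_car: bool = False
    seed: int = 0
    input_dir: str = ""
    out_dir: str = ""

    def band_definitions(self) -> list[BandDefinition]:
        return [BandDefinition(n, lo, hi, int(l)) for n, lo, hi, l in self.bands]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a TSV matrix plus JSON sidecar."""
    path = Path(path)
    pd.DataFrame(rec.data).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6e"
    )
    sidecar = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "condition": rec.condition,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read an EDF or delimited-matrix recording.

    ``fmt`` is inferred from the extension when omitted (``.edf`` vs
    anything else).  Delimited matrices are channels x samples with a JSON
    sidecar ``<path>.json`` carrying ``fs`` (required), ``labels`` and
    ``condition``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the 'mne' package") from exc
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:
            raise ValueError(f"failed to parse EDF file {path}: {exc}") from exc
        return Recording(
            raw.get_data(), fs=float(raw.info["sfreq"]), labels=list(raw.ch_names)
        )
    if fmt == "delimited":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        if "fs" not in sidecar:
            raise ValueError(f"sidecar {sidecar_path} lacks 'fs'")
        data = pd.read_csv(path, sep="\t", header=None, dtype=float).to_numpy()
        data = np.atleast_2d(data)
        return Recording(
            data,
            fs=float(sidecar["fs"]),
            labels=sidecar.get("labels") or [],
            condition=sidecar.get("condition", "NA"),
        )
    raise ValueError(f"unknown format {fmt!r}")


def read_montage(path: str | Path) -> SensorMontage:
    frame = pd.read_csv(path, sep="\t")
    pos = frame[["x", "y", "z"]].to_numpy()
    radius = float(frame.attrs.get("neighbor_radius", 0) or 0)
    if "neighbor_radius" in frame.columns:
        radius = float(frame["neighbor_radius"].iloc[0])
    return SensorMontage(list(frame["label"]), pos, radius or 1.0)


def write_montage(montage: SensorMontage, path: str | Path) -> None:
    frame = montage.to_frame()
    frame["neighbor_radius"] = montage.neighbor_radius
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# cohort simulation to disk
# ---------------------------------------------------------------------------

def simulate_cohort_dir(
    out_dir: str | Path,
    n_id: int = 12,
    n_ctrl: int = 12,
    n_electrodes: int = 9,
    band_names: Sequence[str] = ("theta", "beta1"),
    duration: float = 180.0,
    fs: float = 250.0,
    slope_per_isi_point: float = 0.005,
    noise_sd: float = 0.02,
    seed: int = 0,
    condition: str = "EO",
) -> Path:
    """Generate a self-contained synthetic cohort directory.

    Writes ``cohort.tsv``, ``montage.tsv``, ``planted_h.tsv`` and one
    recording (TSV + sidecar) per participant under ``recordings/``.
    """
    from .bands import get_band

    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    bands = [get_band(n) for n in band_names]
    montage = generate_montage(n_electrodes, "grid")
    spec = CohortSpec(
        n_id=n_id,
        n_ctrl=n_ctrl,
        effect_mask=default_effect_masks(montage, bands),
        slope_per_isi_point=slope_per_isi_point,
        noise_sd=noise_sd,
        seed=seed,
    )
    write_montage(montage, out / "montage.tsv")
    planted = []
    cohort = None
    for pid, rec, hm1 in generate_cohort_recordings(
        spec, montage, bands, duration=duration, fs=fs, condition=condition
    ):
        write_recording(rec, out / "recordings" / f"{pid}_{condition}.tsv")
        planted.append(hm1.to_frame())
    from .synthetic import generate_cohort_h

    cohort, _ = generate_cohort_h(spec, montage, bands)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    pd.concat(planted).to_csv(
        out / "planted_h.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return out


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything a run produced, before/after writing to disk."""

    config: AnalysisConfig
    h_matrices: dict[str, HMatrix]
    study_results: dict[str, object]
    contrast: pd.DataFrame | None
    report: dict
    manifest: dict


def _preprocess(rec: Recording, config: AnalysisConfig) -> Recording:
    if rec.fs != config.fs:
        rec = downsample(rec, config.fs)
    if config.apply_broadband:
        rec = apply_zero_phase(rec, design_broadband_fir(rec.fs))
    if config.apply_car:
        rec = common_average_reference(rec)
    return crop_segment(rec, config.segment_start, config.segment_duration)


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Execute preprocess -> DFA -> group stats -> TFCE and write outputs."""
    t_start = time.time()
    input_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    cohort = pd.read_csv(input_dir / "cohort.tsv", sep="\t")
    montage = read_montage(input_dir / "montage.tsv")
    bands = config.band_definitions()

    rec_dir = input_dir / "recordings"
    by_condition: dict[str, dict[str, Recording]] = {}
    timings: dict[str, float] = {}
    t0 = time.time()
    for pid in cohort["id"]:
        matches = sorted(rec_dir.glob(f"{pid}_*.tsv")) or sorted(
            rec_dir.glob(f"{pid}.tsv")
        )
        if not matches:
            raise FileNotFoundError(f"no recording found for participant {pid!r}")
        for path in matches:
            rec = read_recording(path)
            cond = rec.condition if rec.condition != "NA" else "EO"
            by_condition.setdefault(cond, {})[pid] = _preprocess(rec, config)
    timings["read_preprocess"] = time.time() - t0

    h_matrices: dict[str, HMatrix] = {}
    study_results: dict[str, object] = {}
    report: dict = {"conditions": {}}
    for ci, (cond, recs) in enumerate(sorted(by_condition.items())):
        t0 = time.time()
        hm = compute_h_matrix(
            recs,
            bands,
            condition=cond,
            poly_order=config.poly_order,
            n_scales=config.n_scales,
        )
        timings[f"dfa_{cond}"] = time.time() - t0
        h_matrices[cond] = hm
        sub_cohort = cohort.set_index("id").loc[hm.participant_ids].reset_index()
        study = LrtcStudy(hm, sub_cohort, montage)
        t0 = time.time()
        result = study.fit(
            n_boot=config.n_boot,
            n_perm=config.n_perm,
            n_steps=config.n_steps,
            alpha=config.alpha,
            seed=config.seed + ci,
        )
        timings[f"stats_{cond}"] = time.time() - t0
        study_results[cond] = result
        report["conditions"][cond] = result.to_report()

    contrast = None
    if {"EO", "EC"} <= set(h_matrices):
        contrast = condition_contrast(h_matrices["EO"], h_matrices["EC"])
        report["condition_contrast"] = contrast.to_dict(orient="index")

    manifest = {
        "config_hash": config.digest(),
        "version": __version__,
        "inputs": {
            str(p.relative_to(input_dir)): hashlib.sha256(p.read_bytes()).hexdigest()[
                :16
            ]
            for p in sorted(input_dir.rglob("*"))
            if p.is_file()
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
    }

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for cond, hm in h_matrices.items():
            hm.to_frame().to_csv(
                out_dir / f"h_{cond}.tsv", sep="\t", index=False, float_format="%.8g"
            )
            result = study_results[cond]
            for group, tf in result.tfce.items():
                tf.to_frame().to_csv(
                    out_dir / f"tfce_{cond}_{group}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.8g",
                )
        if contrast is not None:
            contrast.to_csv(
                out_dir / "condition_contrast.tsv", sep="\t", float_format="%.8g"
            )
        write_report(report, out_dir / "report.json")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(
        config=config,
        h_matrices=h_matrices,
        study_results=study_results,
        contrast=contrast,
        report=report,
        manifest=manifest,
    )


def _check_finite(obj, path="report") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not (obj == obj and abs(obj) != float("inf")):
        raise ValueError(f"non-finite value at {path}")


def write_report(report: dict, path: str | Path) -> None:
    """Serialise the results report as JSON, refusing non-finite numbers."""
    _check_finite(report)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
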