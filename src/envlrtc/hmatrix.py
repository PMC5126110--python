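"""Container for Hurst exponents organised as participants x electrodes x bands."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class HMatrix:
    """Hurst exponents for one condition of a cohort.

    Parameters
    ----------
    h : ndarray, shape (n_participants, n_electrodes, n_bands)
        DFA scaling exponents of the band-amplitude envelopes.
    participant_ids : sequence of str
    electrodes : sequence of str
    bands : sequence of str
        Band names in spectral order (low to high frequency).
    condition : {"EO", "EC", "NA"}
    """

    h: np.ndarray
    participant_ids: Sequence[str]
    electrodes: Sequence[str]
    bands: Sequence[str]
    condition: str = "NA"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.participant_ids = list(self.participant_ids)
        self.electrodes = list(self.electrodes)
        self.bands = list(self.bands)
        expected = (len(self.participant_ids), len(self.electrodes), len(self.bands))
        if self.h.shape != expected:
            raise ValueError(f"h has shape {self.h.shape}, expected {expected}")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("H matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.h.shape

    def grand_median(self) -> pd.Series:
        """Median of H over the electrode x band plane, per participant.

        The aggregate used for participant-level group/association models.
        """
        med = np.median(self.h.reshape(self.h.shape[0], -1), axis=1)
        return pd.Series(med, index=self.participant_ids, name="grand_median_h")

    def band_median(self) -> pd.DataFrame:
        """Median of H across electrodes, per participant and band."""
        med = np.median(self.h, axis=1)
        return pd.DataFrame(med, index=self.participant_ids, columns=self.bands)

    def electrode_iqr(self) -> pd.DataFrame:
        """Across-electrode interquartile range of H per participant and band.

        A per-participant dispersion summary used for condition contrasts of
        between-electrode variability.
        """
        q75, q25 = np.percentile(self.h, [75, 25], axis=1)
        return pd.DataFrame(q75 - q25, index=self.participant_ids, columns=self.bands)

    def select_participants(self, ids: Sequence[str]) -> "HMatrix":
        """Sub-matrix restricted to the given participant ids, in that order."""
        index = {p: i for i, p in enumerate(self.participant_ids)}
        try:
            rows = [index[p] for p in ids]
        except KeyError as exc:
            raise KeyError(f"unknown participant id {exc.args[0]!r}") from None
        return HMatrix(
            self.h[rows], list(ids), self.electrodes, self.bands, self.condition
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: participant, electrode, band, condition, h."""
        p, e, b = np.meshgrid(
            np.arange(len(self.participant_ids)),
            np.arange(len(self.electrodes)),
            np.arange(len(self.bands)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "participant": np.asarray(self.participant_ids)[p.ravel()],
                "electrode": np.asarray(self.electrodes)[e.ravel()],
                "band": np.asarray(self.bands)[b.ravel()],
                "condition": self.condition,
                "h": self.h.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HMatrix":
        """Rebuild from the long format written by :meth:`to_frame`.

        Participant, electrode and band orders follow first appearance in the
        table; every (participant, electrode, band) cell must be present
        exactly once.
        """
        conditions = frame["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"expected a single condition, got {list(conditions)}")
        pids = list(dict.fromkeys(frame["participant"]))
        electrodes = list(dict.fromkeys(frame["electrode"]))
        bands = list(dict.fromkeys(frame["band"]))
        pivot = frame.set_index(["participant", "electrode", "band"])["h"]
        if pivot.index.duplicated().any():
            raise ValueError("duplicate (participant, electrode, band) rows")
        shape = (len(pids), len(electrodes), len(bands))
        if len(frame) != int(np.prod(shape)):
            raise ValueError("incomplete participant x electrode x band table")
        h = np.empty(shape)
        for i, p in enumerate(pids):
            for j, e in enumerate(electrodes):
                for k, b in enumerate(bands):
                    h[i, j, k] = pivot[(p, e, b)]
        return cls(h, pids, electrodes, bands, str(conditions[0]))
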