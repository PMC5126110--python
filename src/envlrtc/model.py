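"""Cohort-level model of envelope LRTC vs insomnia severity.

:class:`LrtcStudy` couples an :class:`~envlrtc.hmatrix.HMatrix` (one
condition's Hurst exponents) with a cohort table and a sensor montage;
``fit()`` runs the participant-level inference chain — type-II GLM on the
grand-median H, rank-sum and Spearman follow-ups, per-band bootstrap
correlation profiles, and spatio-spectral TFCE permutation inference per
group — and returns an :class:`LrtcStudyResult` carrying estimates,
uncertainties and diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as gstats
from .hmatrix import HMatrix
from .synthetic import SensorMontage
from .tfce import TfceParams, TfceResult, summarize_spatiospectral, tfce_correlation

GROUPS = ("ID", "CTRL")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Split a master seed into n reproducible 31-bit child seeds."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


@dataclass
class LrtcStudyResult:
    """Fitted cohort-level results for one resting-state condition."""

    condition: str
    glm: pd.DataFrame
    ranksum_z: float
    ranksum_p: float
    grand_median_corr: dict[str, gstats.CorrelationResult]
    band_profiles: dict[str, dict[str, gstats.CorrelationResult]]
    tfce: dict[str, TfceResult]
    tfce_summary: dict[str, pd.DataFrame]
    within_vs_across: dict
    alpha: float = 0.05
    grand_medians: pd.Series = field(default=None, repr=False)  # type: ignore

    def summary(self) -> str:
        lines = [
            f"Envelope-LRTC study, condition {self.condition}",
            "=" * 46,
            "",
            "Type-II GLM on grand-median H (~ group + ISI + group:ISI)",
            self.glm.round(4).to_string(),
            "",
            f"Rank-sum group difference: z = {self.ranksum_z:.3f}, "
            f"p = {self.ranksum_p:.3f}",
            "",
            "Grand-median H vs ISI (Spearman):",
        ]
        for label, res in self.grand_median_corr.items():
            lines.append(
                f"  {label:6s} rho = {res.rho:+.3f}, t = {res.t:+.3f} "
                f"(df = {res.df}), p = {res.p:.4f}"
            )
        lines.append("")
        lines.append("Per-band profiles (median-across-electrode H vs ISI):")
        for group, profile in self.band_profiles.items():
            for band, res in profile.items():
                ci = (
                    f"[{res.ci_low:+.3f}, {res.ci_high:+.3f}]"
                    if res.ci_low is not None
                    else "[-, -]"
                )
                flag = " robust" if res.robust else ""
                lines.append(
                    f"  {group:5s} {band:6s} rho = {res.rho:+.3f} "
                    f"95% CI {ci}{flag}"
                )
        lines.append("")
        for group, summ in self.tfce_summary.items():
            lines.append(f"TFCE ({group}): extent (electrodes with p < {self.alpha}) "
                         "and peak per band")
            cols = ["extent", "peak_rho", "peak_t", "peak_t_tfce", "peak_p"]
            lines.append(summ[cols].round(3).to_string())
            lines.append("")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable report mirroring the results structure."""

        def corr_dict(res: gstats.CorrelationResult) -> dict:
            return {
                "rho": res.rho,
                "n": res.n,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "ci": [res.ci_low, res.ci_high],
                "robust": res.robust,
            }

        report = {
            "condition": self.condition,
            "glm": {
                term: {
                    "F": float(row["F"]),
                    "df": [float(row["df_num"]), float(row["df_den"])],
                    "p": float(row["p"]),
                }
                for term, row in self.glm.iterrows()
            },
            "ranksum": {"z": self.ranksum_z, "p": self.ranksum_p},
            "grand_median_corr": {
                k: corr_dict(v) for k, v in self.grand_median_corr.items()
            },
            "band_profiles": {
                g: {b: corr_dict(r) for b, r in prof.items()}
                for g, prof in self.band_profiles.items()
            },
            "tfce": {
                g: summ.drop(
                    columns=["significant_electrodes", "marginal_electrodes"]
                ).to_dict(orient="index")
                for g, summ in self.tfce_summary.items()
            },
            "within_vs_across": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.within_vs_across.items()
            },
        }
        return report

    def plot_band_profiles(self, ax=None):
        """Per-band correlation profiles with bootstrap CIs, per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        bands = list(next(iter(self.band_profiles.values())))
        xs = np.arange(len(bands))
        for off, (group, profile) in zip((-0.1, 0.1), self.band_profiles.items()):
            rho = [profile[b].rho for b in bands]
            lo = [profile[b].rho - (profile[b].ci_low or np.nan) for b in bands]
            hi = [(profile[b].ci_high or np.nan) - profile[b].rho for b in bands]
            ax.errorbar(xs + off, rho, yerr=[lo, hi], fmt="o", label=group)
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xticks(xs, bands)
        ax.set_ylabel("Spearman rho (ISI vs band-median H)")
        ax.legend()
        return ax


class LrtcStudy:
    """Model object binding H exponents, cohort table and montage.

    Parameters
    ----------
    hm : HMatrix
        Hurst exponents for one condition; participant order must match
        ``cohort['id']``.
    cohort : DataFrame
        Columns ``id``, ``group`` (ID/CTRL), ``isi``.
    montage : SensorMontage
        Provides the electrode neighbourhood for TFCE.
    """

    def __init__(self, hm: HMatrix, cohort: pd.DataFrame, montage: SensorMontage):
        if list(cohort["id"]) != list(hm.participant_ids):
            raise ValueError("cohort ids do not match the H matrix participants")
        if list(montage.labels) != list(hm.electrodes):
            raise ValueError("montage labels do not match the H matrix electrodes")
        missing = set(cohort["group"].unique()) - set(GROUPS)
        if missing:
            raise ValueError(f"unknown group labels: {sorted(missing)}")
        self.hm = hm
        self.cohort = cohort.reset_index(drop=True)
        self.montage = montage

    @classmethod
    def from_frames(
        cls, h_frame: pd.DataFrame, cohort: pd.DataFrame, montage: SensorMontage
    ) -> "LrtcStudy":
        """Build from a long-format H table (participant, electrode, band, h)."""
        hm = HMatrix.from_frame(h_frame)
        cohort = cohort.set_index("id").loc[hm.participant_ids].reset_index()
        return cls(hm, cohort, montage)

    def fit(
        self,
        n_boot: int = 1000,
        n_perm: int = 1000,
        n_steps: int = 100,
        alpha: float = 0.05,
        seed: int = 0,
        run_tfce: bool = True,
    ) -> LrtcStudyResult:
        """Run the full participant-level inference chain."""
        cohort = self.cohort
        gm = self.hm.grand_median()
        band_med = self.hm.band_median()
        isi = cohort["isi"].to_numpy(dtype=float)
        is_id = (cohort["group"] == "ID").to_numpy()

        glm = gstats.glm_type2(gm.to_numpy(), cohort)
        z, p = gstats.ranksum_test(gm.to_numpy()[is_id], gm.to_numpy()[~is_id])

        seeds = _child_seeds(seed, 3 * len(GROUPS) + 1)
        corr = {
            "ID": gstats.spearman_test(isi[is_id], gm.to_numpy()[is_id]),
            "CTRL": gstats.spearman_test(isi[~is_id], gm.to_numpy()[~is_id]),
            "pooled": gstats.spearman_test(isi, gm.to_numpy()),
        }

        band_profiles: dict[str, dict[str, gstats.CorrelationResult]] = {}
        tfce_res: dict[str, TfceResult] = {}
        tfce_summ: dict[str, pd.DataFrame] = {}
        for gi, group in enumerate(GROUPS):
            sel = is_id if group == "ID" else ~is_id
            band_profiles[group] = {
                band: gstats.bootstrap_rho_ci(
                    isi[sel],
                    band_med.loc[sel, band].to_numpy(),
                    n_boot=n_boot,
                    seed=seeds[gi],
                )
                for band in self.hm.bands
            }
            if run_tfce:
                params = TfceParams(
                    n_steps=n_steps,
                    n_perm=n_perm,
                    alpha=alpha,
                    seed=seeds[len(GROUPS) + gi],
                )
                sub = self.hm.select_participants(cohort.loc[sel, "id"])
                tfce_res[group] = tfce_correlation(
                    sub, isi[sel], self.montage, params
                )
                tfce_summ[group] = summarize_spatiospectral(tfce_res[group], alpha)

        wva = gstats.within_vs_across_correlation(
            cohort, gm.to_numpy(), n_boot=n_boot, seed=seeds[-1]
        )
        return LrtcStudyResult(
            condition=self.hm.condition,
            glm=glm,
            ranksum_z=z,
            ranksum_p=p,
            grand_median_corr=corr,
            band_profiles=band_profiles,
            tfce=tfce_res,
            tfce_summary=tfce_summ,
            within_vs_across=wva,
            alpha=alpha,
            grand_medians=gm,
        )
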