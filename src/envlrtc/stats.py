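"""Participant-level inference: correlations, rank tests, and the type-II GLM.

The cohort-level questions are (1) does the aggregate envelope-scaling
exponent H differ between the insomnia (ID) and control (CTRL) groups,
(2) is it associated with insomnia severity (ISI), and (3) do those
associations have group-specific spectral profiles.  Group differences
use Wilcoxon rank-sum tests, associations Spearman correlations with a
t-approximation (df = n - 2) and bootstrap confidence intervals, and the
joint model is a linear model H ~ group + ISI + group:ISI evaluated with
type-II sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .hmatrix import HMatrix

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "spearman_test",
    "bootstrap_rho_ci",
    "ranksum_test",
    "glm_type2",
    "condition_contrast",
    "within_vs_across_correlation",
]


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    return float(scipy.stats.spearmanr(x, y).statistic)


def rho_to_t(rho: float, n: int) -> float:
    """t-statistic of a correlation coefficient, df = n - 2.

    |rho| at (or within numerical precision of) 1 maps to an infinite t.
    """
    if abs(rho) >= 1.0 - 1e-12:
        return float(np.inf) if rho > 0 else float(-np.inf)
    return float(rho * np.sqrt((n - 2) / (1.0 - rho * rho)))


@dataclass
class CorrelationResult:
    """A Spearman correlation with its t-approximation and bootstrap CI."""

    rho: float
    n: int
    t: float
    p: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    robust: bool | None = None
    n_redrawn: int = 0

    @property
    def df(self) -> int:
        return self.n - 2


def spearman_test(x, y) -> CorrelationResult:
    """Spearman rho with two-sided p from the t distribution (df = n - 2).

    A perfect monotone relation (|rho| = 1) yields an infinite t, flagged
    by p = 0.
    """
    rho = spearman_rho(x, y)
    n = int(np.asarray(x).size)
    t = rho_to_t(rho, n)
    if np.isinf(t):
        p = 0.0
    else:
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, n=n, t=t, p=p)


def bootstrap_rho_ci(
    x,
    y,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 100,
) -> CorrelationResult:
    """Percentile bootstrap CI for the Spearman correlation.

    Pairs are resampled with replacement; resamples in which either
    variable is constant (rho undefined) are redrawn and counted in
    ``n_redrawn``.  ``robust`` is True when more than 97.5% of bootstrap
    correlations share the sign of the point estimate — the criterion used
    to call a band's association consistently signed.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 5:
        raise ValueError("need at least 5 pairs for a bootstrap CI")
    base = spearman_test(x, y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = x.size
    rhos = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) > 0 and np.ptp(yb) > 0:
                rhos[b] = scipy.stats.spearmanr(xb, yb).statistic
                break
            n_redrawn += 1
        else:
            raise RuntimeError("bootstrap resamples persistently degenerate")
    lo, hi = np.percentile(rhos, [50 * (1 - level), 50 * (1 + level)])
    sign_frac = np.mean(np.sign(rhos) == np.sign(base.rho)) if base.rho != 0 else 0.0
    return CorrelationResult(
        rho=base.rho,
        n=n,
        t=base.t,
        p=base.p,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        robust=bool(sign_frac > 0.975),
        n_redrawn=n_redrawn,
    )


def ranksum_test(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum z (tie- and continuity-corrected) and two-sided p.

    Uses the normal approximation, appropriate for the group sizes this
    analysis targets (n >= ~40 per group); an exact small-sample path is
    deliberately not provided.  If every pooled value is tied the variance
    vanishes and (z, p) = (0, 1).
    """
    a, b = _as_vector(a, "a"), _as_vector(b, "b")
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    var = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
    if var <= 0:
        return 0.0, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def glm_type2(response, cohort: pd.DataFrame) -> pd.DataFrame:
    """Linear model ``response ~ group + isi + group:isi`` with type-II tests.

    Each main effect is adjusted for the other main effect (respecting
    marginality); the interaction is adjusted for both.  Returns a table
    with one row per term (``group``, ``isi``, ``group:isi``) and columns
    ``F``, ``df_num``, ``df_den``, ``p``.
    """
    response = _as_vector(response, "response")
    if len(response) != len(cohort):
        raise ValueError("response length does not match the cohort table")
    data = cohort.copy()
    data["_y"] = response
    n_terms = 4  # intercept, group, isi, interaction
    if len(data) <= n_terms:
        raise ValueError("more model terms than observations")
    model = smf.ols("_y ~ C(group) * isi", data=data).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < n_terms:
        raise ValueError("rank-deficient design (constant group or ISI?)")
    anova = sm.stats.anova_lm(model, typ=2)
    rename = {"C(group)": "group", "isi": "isi", "C(group):isi": "group:isi"}
    rows = []
    for term, label in rename.items():
        rows.append(
            {
                "term": label,
                "F": float(anova.loc[term, "F"]),
                "df_num": float(anova.loc[term, "df"]),
                "df_den": float(anova.loc["Residual", "df"]),
                "p": float(anova.loc[term, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def condition_contrast(hm_eo: HMatrix, hm_ec: HMatrix) -> pd.DataFrame:
    """Paired eyes-open vs eyes-closed contrasts of H, per band.

    For each band: a Wilcoxon signed-rank test on the across-electrode
    median H (EO - EC), and the same test on the across-electrode
    interquartile range as a contrast of between-participant dispersion.
    The dispersion contrast's test is a design choice of this package
    (no canonical test exists for it).
    """
    if hm_eo.participant_ids != hm_ec.participant_ids:
        raise ValueError("conditions cover different participants")
    if hm_eo.bands != hm_ec.bands:
        raise ValueError("conditions cover different bands")
    med_eo, med_ec = hm_eo.band_median(), hm_ec.band_median()
    iqr_eo, iqr_ec = hm_eo.electrode_iqr(), hm_ec.electrode_iqr()
    rows = []
    for band in hm_eo.bands:
        d_med = med_eo[band] - med_ec[band]
        d_iqr = iqr_eo[band] - iqr_ec[band]
        rows.append(
            {
                "band": band,
                "median_diff": float(np.median(d_med)),
                "w_median": _signed_rank(d_med)[0],
                "p_median": _signed_rank(d_med)[1],
                "iqr_diff": float(np.median(d_iqr)),
                "w_iqr": _signed_rank(d_iqr)[0],
                "p_iqr": _signed_rank(d_iqr)[1],
            }
        )
    return pd.DataFrame(rows).set_index("band")


def _signed_rank(diff: pd.Series) -> tuple[float, float]:
    d = np.asarray(diff, dtype=float)
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = scipy.stats.wilcoxon(d, zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue)


def within_vs_across_correlation(
    cohort: pd.DataFrame,
    grand_medians,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare within-group with pooled (across-group) ISI-H correlations.

    Returns the within-ID, within-CTRL and pooled Spearman correlations
    plus a bootstrap distribution of (mean within-group rho) - (pooled
    rho).  A positive difference indicates the association is stronger
    inside each group than across the combined cohort, the pattern
    expected when the groups' H levels are offset or their association
    profiles differ.  The exact contrast is a design choice of this
    package (labelled non-canonical).
    """
    gm = _as_vector(grand_medians, "grand_medians")
    if len(gm) != len(cohort):
        raise ValueError("grand_medians length does not match cohort")
    isi = cohort["isi"].to_numpy(dtype=float)
    is_id = (cohort["group"] == "ID").to_numpy()
    if is_id.all() or (~is_id).all():
        raise ValueError("both groups must be non-empty")
    rho_id = spearman_rho(isi[is_id], gm[is_id])
    rho_ctrl = spearman_rho(isi[~is_id], gm[~is_id])
    rho_pooled = spearman_rho(isi, gm)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx_id, idx_ctrl = np.nonzero(is_id)[0], np.nonzero(~is_id)[0]
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        bi = rng.choice(idx_id, idx_id.size)
        bc = rng.choice(idx_ctrl, idx_ctrl.size)
        both = np.concatenate([bi, bc])
        try:
            w_id = spearman_rho(isi[bi], gm[bi])
            w_ctrl = spearman_rho(isi[bc], gm[bc])
            pooled = spearman_rho(isi[both], gm[both])
        except ValueError:  # degenerate resample
            diffs[b] = np.nan
            continue
        diffs[b] = 0.5 * (w_id + w_ctrl) - pooled
    diffs = diffs[np.isfinite(diffs)]
    return {
        "rho_within_id": rho_id,
        "rho_within_ctrl": rho_ctrl,
        "rho_pooled": rho_pooled,
        "mean_within_minus_pooled": 0.5 * (rho_id + rho_ctrl) - rho_pooled,
        "boot_diff_ci": tuple(np.percentile(diffs, [2.5, 97.5])),
        "boot_diff_frac_positive": float(np.mean(diffs > 0)),
        "n_boot_effective": int(diffs.size),
    }
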