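"""TFCE enhancement, permutation null and spatio-spectral summaries."""

import numpy as np
import pytest

from conftest import brute_force_tfce
from envlrtc.bands import DEFAULT_BANDS
from envlrtc.hmatrix import HMatrix
from envlrtc.stats import spearman_test
from envlrtc.synthetic import CohortSpec, generate_cohort_h, generate_montage
from envlrtc.tfce import (
    AdjacencyStructure,
    StatMap,
    TfceParams,
    correlation_stat_map,
    corrected_pvalues,
    permutation_null,
    summarize_spatiospectral,
    tfce_correlation,
    tfce_enhance,
)

BANDS5 = [b.name for b in DEFAULT_BANDS]


def _hm(h, condition="EO"):
    h = np.asarray(h, dtype=float)
    return HMatrix(
        h,
        [f"p{i}" for i in range(h.shape[0])],
        [f"E{i + 1:03d}" for i in range(h.shape[1])],
        BANDS5[: h.shape[2]],
        condition,
    )


class TestAdjacency:
    def test_combined_neighbourhood_rule(self, grid9):
        adj = AdjacencyStructure(grid9, ["theta", "alpha", "sigma"])
        edges = {tuple(sorted(e)) for e in map(tuple, adj.edges)}
        # spatial neighbour at the same band: electrodes 0 and 1 at band 0
        assert (adj.flat(0, 0), adj.flat(1, 0)) in edges
        # spectral neighbour at the same electrode: bands 0-1 at electrode 0
        assert (adj.flat(0, 0), adj.flat(0, 1)) in edges
        # no diagonal (different electrode AND different band) links
        assert (adj.flat(0, 0), adj.flat(1, 1)) not in edges
        # band chain has no wrap-around
        assert (adj.flat(0, 0), adj.flat(0, 2)) not in edges

    def test_csr_lists_match_edges(self, grid9):
        adj = AdjacencyStructure(grid9, ["theta", "alpha"])
        degree = np.diff(adj.indptr)
        counts = np.zeros(adj.n_bins, dtype=int)
        for a, b in adj.edges:
            counts[a] += 1
            counts[b] += 1
        assert np.array_equal(degree, counts)


class TestStatMap:
    def test_single_bin_equals_spearman_test(self):
        rng = np.random.default_rng(0)
        h = 0.6 + 0.2 * rng.random((20, 1, 1))
        isi = rng.integers(0, 25, 20).astype(float)
        stat = correlation_stat_map(_hm(h), isi)
        ref = spearman_test(isi, h[:, 0, 0])
        assert stat.rho[0, 0] == pytest.approx(ref.rho)
        assert stat.t[0, 0] == pytest.approx(ref.t)
        assert stat.n == 20

    def test_constant_bin_flagged(self):
        rng = np.random.default_rng(1)
        h = 0.6 + 0.2 * rng.random((15, 2, 1))
        h[:, 1, 0] = 0.7
        isi = rng.integers(0, 25, 15).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            stat = correlation_stat_map(_hm(h), isi)
        assert not stat.valid[1, 0]
        assert stat.valid[0, 0]

    def test_null_maps_centred_on_zero(self):
        rng = np.random.default_rng(2)
        h = 0.6 + 0.2 * rng.random((30, 3, 2))
        means = []
        for rep in range(50):
            isi = rng.permutation(30).astype(float)
            stat = correlation_stat_map(_hm(h), isi)
            means.append(stat.t.mean())
        assert abs(np.mean(means)) < 0.1


class TestEnhance:
    def test_zero_map_stays_zero(self, grid9):
        adj = AdjacencyStructure(grid9, ["theta", "alpha"])
        out = tfce_enhance(np.zeros((9, 2)), adj)
        assert np.array_equal(out, np.zeros((9, 2)))

    def test_isolated_bin_matches_closed_form(self, grid9):
        """One bin at t=2: t_tfce -> integral of h'^2 from 0 to 2 = 8/3."""
        adj = AdjacencyStructure(grid9, ["theta", "alpha"])
        t = np.zeros((9, 2))
        t[4, 0] = 2.0
        out = tfce_enhance(t, adj, TfceParams(n_steps=100))
        assert out[4, 0] == pytest.approx(8.0 / 3.0, rel=0.01)

    def test_uniform_fully_connected_closed_form(self):
        montage = generate_montage(4, "ring", neighbor_radius=3.0)
        adj = AdjacencyStructure(montage, ["theta"])
        out = tfce_enhance(np.full((4, 1), 1.5), adj, TfceParams(n_steps=400))
        expected = 4**0.66 * 1.5**3 / 3
        assert np.allclose(out, expected, rtol=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_match_with_brute_force(self, seed):
        montage = generate_montage(16, "grid")
        adj = AdjacencyStructure(montage, ["theta", "alpha"])
        t = np.random.default_rng(seed).normal(0, 1.5, (16, 2))
        params = TfceParams(n_steps=57)
        fast = tfce_enhance(t, adj, params)
        assert np.array_equal(fast, brute_force_tfce(t, adj, params))

    def test_sign_symmetry(self, grid9):
        adj = AdjacencyStructure(grid9, ["theta", "alpha"])
        t = np.random.default_rng(5).normal(size=(9, 2))
        plus = tfce_enhance(t, adj)
        minus = tfce_enhance(-t, adj)
        assert np.allclose(minus, -plus)

    def test_order_preserving_on_uniform_topology(self):
        montage = generate_montage(6, "ring", neighbor_radius=3.0)  # complete graph
        adj = AdjacencyStructure(montage, ["theta"])
        t = np.array([[0.2], [0.5], [0.9], [1.4], [1.7], [2.0]])
        out = tfce_enhance(t, adj)
        assert np.all(np.diff(out.ravel()) > 0)

    def test_shape_mismatch_rejected(self, grid9):
        adj = AdjacencyStructure(grid9, ["theta"])
        with pytest.raises(ValueError):
            tfce_enhance(np.zeros((9, 2)), adj)


@pytest.fixture(scope="module")
def cohort_hm():
    montage = generate_montage(9, "grid")
    spec = CohortSpec(n_id=30, n_ctrl=20, noise_sd=0.02, seed=3)
    cohort, hm = generate_cohort_h(spec, montage, list(DEFAULT_BANDS))
    return montage, cohort, hm


class TestPermutationNull:
    def test_seeded_reproducibility(self, cohort_hm):
        montage, cohort, hm = cohort_hm
        adj = AdjacencyStructure(montage, hm.bands)
        isi = cohort["isi"].to_numpy(dtype=float)
        params = TfceParams(n_perm=100, seed=9)
        a = permutation_null(hm, isi, adj, params)
        b = permutation_null(hm, isi, adj, params)
        assert np.array_equal(a, b)

    def test_null_quantiles_stable_in_n_perm(self, cohort_hm):
        montage, cohort, hm = cohort_hm
        adj = AdjacencyStructure(montage, hm.bands)
        isi = cohort["isi"].to_numpy(dtype=float)
        small = permutation_null(hm, isi, adj, TfceParams(n_perm=200, seed=1))
        large = permutation_null(hm, isi, adj, TfceParams(n_perm=1000, seed=2))
        q_small = np.quantile(small, [0.5, 0.9])
        q_large = np.quantile(large, [0.5, 0.9])
        # Monte-Carlo agreement: within ~25% on these heavy-tailed maxima
        assert np.all(np.abs(q_small - q_large) / q_large < 0.25)


class TestCorrectedP:
    def test_extremes_and_median(self):
        null = np.arange(1.0, 200.0)
        p = corrected_pvalues(np.array([500.0, np.median(null)]), null)
        assert p[0] == pytest.approx(1 / 200)
        assert p[1] == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_statistic(self):
        null = np.random.default_rng(0).exponential(size=500)
        stats = np.sort(np.random.default_rng(1).exponential(size=50))
        p = corrected_pvalues(stats, null)
        assert np.all(np.diff(p) <= 1e-12)


class TestSummary:
    def _result(self, p, t_tfce=None, rho=None, t=None):
        p = np.asarray(p, dtype=float)
        n_e, n_b = p.shape
        stat = StatMap(
            rho if rho is not None else np.zeros_like(p),
            t if t is not None else np.zeros_like(p),
            n=20,
            electrodes=[f"E{i + 1:03d}" for i in range(n_e)],
            bands=BANDS5[:n_b],
        )
        from envlrtc.tfce import TfceResult

        return TfceResult(
            stat=stat,
            t_tfce=t_tfce if t_tfce is not None else np.zeros_like(p),
            p=p,
            null=np.ones(99),
            params=TfceParams(),
        )

    def test_extent_matches_manual_count(self):
        p = np.array(
            [[0.01, 0.2], [0.04, 0.06], [0.5, 0.03], [0.9, 0.8], [0.049, 0.11]]
        )
        summ = summarize_spatiospectral(self._result(p), alpha=0.05)
        assert summ.loc["theta", "extent"] == 3
        assert summ.loc["alpha", "extent"] == 1
        assert summ.loc["alpha", "marginal_electrodes"] == ["E002"]

    def test_peak_reported_even_without_significance(self):
        p = np.full((4, 1), 0.7)
        tt = np.array([[1.0], [3.0], [2.0], [0.5]])
        summ = summarize_spatiospectral(self._result(p, t_tfce=tt))
        assert summ.loc["theta", "extent"] == 0
        assert summ.loc["theta", "peak_electrode"] == "E002"

    def test_tie_broken_by_larger_enhancement(self):
        p = np.array([[0.2], [0.2], [0.5]])
        tt = np.array([[1.0], [4.0], [2.0]])
        summ = summarize_spatiospectral(self._result(p, t_tfce=tt))
        assert summ.loc["theta", "peak_electrode"] == "E002"


class TestEndToEnd:
    def test_planted_mask_detected(self):
        """Strong posterior-theta planting yields positive extent for ID."""
        montage = generate_montage(16, "grid")
        bands = list(DEFAULT_BANDS)
        post = [lab for lab, pos in zip(montage.labels, montage.positions) if pos[1] == 3]
        mask = frozenset((e, "theta") for e in post)
        spec = CohortSpec(
            n_id=52,
            n_ctrl=43,
            effect_mask={"ID": mask, "CTRL": frozenset()},
            slope_per_isi_point=0.006,
            noise_sd=0.02,
            seed=21,
        )
        cohort, hm = generate_cohort_h(spec, montage, bands)
        is_id = (cohort["group"] == "ID").to_numpy()
        sub = hm.select_participants(cohort.loc[is_id, "id"])
        res = tfce_correlation(
            sub,
            cohort.loc[is_id, "isi"].to_numpy(dtype=float),
            montage,
            TfceParams(n_perm=200, seed=4),
        )
        summ = summarize_spatiospectral(res)
        assert summ.loc["theta", "extent"] > 0
        assert set(summ.loc["theta", "significant_electrodes"]) <= set(montage.labels)
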