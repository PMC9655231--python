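"""Getis-Ord G* and local Moran's I against independently coded oracles.

The oracle implementations below are written directly from the definitions
with explicit Python loops (no shared code with the package), and the
analytic randomization moments are additionally checked against exhaustive
enumeration of all value-to-unit assignments at small n.
"""

import itertools

import numpy as np
import pytest

import hotgrid as hg


def naive_gstar(x, W):
    """Direct double-loop G* and z under randomization (independent oracle)."""
    n = len(x)
    xbar = sum(x) / n
    sigma2 = sum((v - xbar) ** 2 for v in x) / n
    total = sum(x)
    stats, zs = [], []
    for i in range(n):
        num = sum(W[i][j] * x[j] for j in range(n))
        wi = sum(W[i][j] for j in range(n))
        g = num / total
        eg = wi / n
        var = wi * (n - wi) * sigma2 / ((n - 1) * n ** 2 * xbar ** 2)
        stats.append(g)
        zs.append((g - eg) / var ** 0.5 if var > 0 else float("nan"))
    return np.array(stats), np.array(zs)


def naive_moran(x, W):
    """Direct double-loop local Moran and z (independent oracle)."""
    n = len(x)
    xbar = sum(x) / n
    m2 = sum((v - xbar) ** 2 for v in x) / n
    stats, zs = [], []
    for i in range(n):
        lag = sum(W[i][j] * (x[j] - xbar) for j in range(n))
        stat = (x[i] - xbar) / m2 * lag
        wi = sum(W[i][j] for j in range(n))
        b2 = (sum((v - xbar) ** 4 for v in x) / n) / m2 ** 2
        ei = -wi / (n - 1)
        var = (wi * (n - b2) / (n - 1)
               + (wi ** 2 - wi) * (2 * b2 - n) / ((n - 1) * (n - 2))
               - wi ** 2 / (n - 1) ** 2)
        stats.append(stat)
        zs.append((stat - ei) / var ** 0.5 if var > 0 else float("nan"))
    return np.array(stats), np.array(zs)


class TestGetisOrdGstar:
    def test_uniform_field_corner_share(self):
        lat = hg.build_regular_grid(3, 3)
        w = hg.contiguity_weights(lat, "queen", include_self=True)
        res = hg.getis_ord_gstar(hg.CellField(np.full(9, 5.0)), w)
        assert res.stat[0] == pytest.approx(4 / 9)

    def test_uniform_field_z_flagged(self):
        lat = hg.build_regular_grid(3, 3)
        w = hg.contiguity_weights(lat, "queen", include_self=True)
        res = hg.getis_ord_gstar(hg.CellField(np.full(9, 5.0)), w)
        assert np.all(np.isnan(res.z))  # zero variance: z undefined

    def test_whole_area_window_is_one(self, grid5x5, field_1_to_25):
        w = hg.contiguity_weights(grid5x5, "distance", threshold=100.0,
                                  include_self=True)
        res = hg.getis_ord_gstar(field_1_to_25, w)
        np.testing.assert_allclose(res.stat, 1.0)

    def test_matches_independent_implementation(self, grid5x5, field_1_to_25):
        w = hg.contiguity_weights(grid5x5, "queen", include_self=True)
        res = hg.getis_ord_gstar(field_1_to_25, w)
        stats, zs = naive_gstar(field_1_to_25.values.tolist(),
                                w.matrix.toarray().tolist())
        np.testing.assert_allclose(res.stat, stats, atol=1e-6)
        np.testing.assert_allclose(res.z, zs, atol=1e-6)

    def test_moments_match_exhaustive_enumeration(self):
        """Analytic E and Var of G* equal the exact moments over all
        assignments of the observed values to units."""
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        lat = hg.build_regular_grid(2, 3)
        w = hg.contiguity_weights(lat, "rook", include_self=True)
        W = w.matrix.toarray()
        draws = np.array([(W @ np.array(p)) / x.sum()
                          for p in itertools.permutations(x)])
        res = hg.getis_ord_gstar(hg.CellField(x), w)
        n, xbar, s2 = 6, x.mean(), x.var()
        wi = w.row_sums().astype(float)
        np.testing.assert_allclose(draws.mean(0), wi / n, atol=1e-12)
        np.testing.assert_allclose(
            draws.var(0), wi * (n - wi) * s2 / ((n - 1) * n ** 2 * xbar ** 2),
            atol=1e-12)
        # and the reported z uses exactly these moments
        np.testing.assert_allclose(
            res.z, (res.stat - draws.mean(0)) / draws.std(0), atol=1e-10)

    def test_requires_self_weight(self, grid5x5, field_1_to_25):
        w = hg.contiguity_weights(grid5x5, "queen", include_self=False)
        with pytest.raises(ValueError):
            hg.getis_ord_gstar(field_1_to_25, w)


class TestLocalMoran:
    def test_zero_at_mean_valued_unit(self):
        lat = hg.build_regular_grid(1, 3)
        w = hg.contiguity_weights(lat, "rook")
        x = np.array([1.0, 2.0, 3.0])  # centre unit sits at the mean
        res = hg.local_morans_i(hg.CellField(x), w)
        assert res.stat[1] == pytest.approx(0.0)

    def test_zero_when_neighbours_at_mean(self):
        lat = hg.build_regular_grid(1, 5)
        w = hg.contiguity_weights(lat, "rook")
        x = np.array([1.0, 4.0, 10.0, 4.0, 1.0])  # mean 4 = centre neighbours
        res = hg.local_morans_i(hg.CellField(x), w)
        assert res.stat[2] == pytest.approx(0.0)  # lag term vanishes

    def test_matches_independent_implementation(self, grid5x5, field_1_to_25):
        w = hg.contiguity_weights(grid5x5, "queen")
        res = hg.local_morans_i(field_1_to_25, w)
        stats, zs = naive_moran(field_1_to_25.values.tolist(),
                                w.matrix.toarray().tolist())
        np.testing.assert_allclose(res.stat, stats, atol=1e-6)
        np.testing.assert_allclose(res.z, zs, atol=1e-6)

    def test_moments_match_exhaustive_enumeration(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        lat = hg.build_regular_grid(2, 3)
        w = hg.contiguity_weights(lat, "rook")
        W = w.matrix.toarray()
        xbar, m2 = x.mean(), x.var()
        draws = []
        for p in itertools.permutations(x):
            z = np.array(p) - xbar
            draws.append(z / m2 * (W @ z))
        draws = np.array(draws)
        res = hg.local_morans_i(hg.CellField(x), w)
        np.testing.assert_allclose(
            res.z, (res.stat - draws.mean(0)) / draws.std(0), atol=1e-10)

    def test_affine_invariance(self, grid5x5):
        rng = np.random.default_rng(8)
        x = rng.poisson(5, 25).astype(float)
        w = hg.contiguity_weights(grid5x5, "queen")
        r1 = hg.local_morans_i(hg.CellField(x), w)
        r2 = hg.local_morans_i(hg.CellField(3.0 * x + 7.0), w)
        np.testing.assert_allclose(r1.stat, r2.stat, atol=1e-9)
        np.testing.assert_allclose(r1.z, r2.z, atol=1e-9)

    def test_sign_structure(self, grid5x5):
        rng = np.random.default_rng(9)
        x = rng.poisson(5, 25).astype(float)
        w = hg.contiguity_weights(grid5x5, "queen")
        res = hg.local_morans_i(hg.CellField(x), w)
        lag = w.matrix @ (x - x.mean())
        expect = np.sign((x - x.mean()) * lag)
        nz = expect != 0
        np.testing.assert_array_equal(np.sign(res.stat[nz]), expect[nz])


class TestExtractHotspots:
    def _result(self, p, z, stat=None, method="gstar", mean_x=0.0):
        stat = z if stat is None else stat
        return hg.LocalStatResult(stat=np.asarray(stat, float),
                                  z=np.asarray(z, float),
                                  p=np.asarray(p, float), method=method,
                                  mean_x=mean_x, var_x=1.0)

    def test_no_significant_units(self, grid5x5):
        w = hg.contiguity_weights(grid5x5, "queen")
        res = self._result(np.full(25, 0.5), np.ones(25))
        lab = hg.extract_hotspots(res, hg.CellField(np.ones(25)), w)
        assert not lab.mask.any() and lab.n_clusters == 0

    def test_moran_low_low_cluster_excluded(self):
        lat = hg.build_regular_grid(1, 4)
        w = hg.contiguity_weights(lat, "rook")
        x = np.array([0.0, 0.0, 9.0, 9.0])
        p = np.array([0.01, 0.01, 0.01, 0.01])
        stat = np.array([2.0, 2.0, 2.0, 2.0])
        res = self._result(p, stat, stat=stat, method="moran",
                           mean_x=float(x.mean()))
        lab = hg.extract_hotspots(res, hg.CellField(x), w)
        # only units above the mean survive despite equal significance
        np.testing.assert_array_equal(lab.mask, [False, False, True, True])

    def test_bh_matches_step_up_oracle(self, grid5x5):
        w = hg.contiguity_weights(grid5x5, "queen")
        rng = np.random.default_rng(10)
        p = np.linspace(0.001, 0.1, 10)
        pv = np.concatenate([p, np.full(15, 0.8)])
        pv = rng.permutation(pv)
        res = self._result(pv, np.ones(25))
        lab = hg.extract_hotspots(res, hg.CellField(np.ones(25)), w,
                                  alpha=0.05, correction="bh")
        # brute-force BH step-up: largest k with p_(k) <= k alpha / m
        m = 25
        srt = np.sort(pv)
        ks = np.flatnonzero(srt <= (np.arange(1, m + 1) * 0.05 / m))
        expected = np.zeros(m, dtype=bool)
        if ks.size:
            expected = pv <= srt[ks.max()]
        np.testing.assert_array_equal(lab.mask, expected)

    def test_clusters_are_contiguous_groups(self):
        lat = hg.build_regular_grid(1, 5)
        w = hg.contiguity_weights(lat, "rook")
        p = np.array([0.01, 0.01, 0.9, 0.01, 0.9])
        res = self._result(p, np.ones(5))
        lab = hg.extract_hotspots(res, hg.CellField(np.ones(5)), w)
        assert lab.n_clusters == 2
        assert lab.cluster_id[0] == lab.cluster_id[1] != lab.cluster_id[3]


class TestModelInterface:
    def test_analytic_and_permutation_agree_on_strong_signal(self, grid30x40):
        """Flagged sets coincide for planted z > 4 signals."""
        mask = hg.default_shapes()
        _, fld, _ = hg.generate_counts(mask, 30, 40, seed=21)
        ana = hg.GetisOrdGStar(fld, grid30x40).fit(alpha=0.05)
        per = hg.GetisOrdGStar(fld, grid30x40).fit(
            alpha=0.05, inference="permutation", n_sim=999, seed=5)
        strong = ana.result.z > 4
        np.testing.assert_array_equal(ana.labeling.mask[strong],
                                      per.labeling.mask[strong])

    def test_summary_and_frame(self, grid5x5, field_1_to_25):
        res = hg.LocalMoran(field_1_to_25, grid5x5).fit()
        assert "local Moran" in res.summary()
        df = res.to_frame()
        assert {"stat", "z", "p_value", "hotspot", "cluster_id"} <= set(df.columns)
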