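import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmm_scell import (ClusterParams, cell_entropy, cluster_cells,
                       de_two_group, entropy_by_cluster, marker_summary,
                       zinb_fit)
from tmm_scell.characterization import _moment_init, _zinb_nll_terms, _aggregate


def rzinb(n, pi, mu, theta, rng):
    nb = rng.negative_binomial(theta, theta / (theta + mu), size=n)
    return np.where(rng.random(n) < pi, 0, nb)


class TestCellEntropy:
    def test_uniform_closed_form(self):
        h = cell_entropy(np.ones((1, 100)))
        assert h[0] == pytest.approx(np.log(100), abs=1e-12)

    def test_one_hot_is_zero(self):
        x = np.zeros((1, 50))
        x[0, 7] = 3.0
        assert cell_entropy(x)[0] == 0.0

    def test_bounds_on_random_cells(self, rng):
        x = rng.random((40, 64)) ** 3
        h = cell_entropy(x)
        assert (h >= 0).all() and (h <= np.log(64)).all()
        assert (h < np.log(64)).all()  # strictly below for non-uniform cells

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            cell_entropy(np.zeros((2, 5)))


class TestClusterCells:
    def test_recovers_planted_blobs(self, rng):
        a = rng.normal(0, 0.3, size=(40, 10))
        b = rng.normal(8, 0.3, size=(40, 10))
        x = np.vstack([a, b])
        labels = cluster_cells(x, ClusterParams(n_clusters=2, n_pcs=3, seed=0))
        truth = np.array([0] * 40 + [1] * 40)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert set(labels) == {1, 2}

    def test_seed_determinism(self, rng):
        x = rng.random((50, 8))
        p = ClusterParams(n_clusters=4, n_pcs=3, seed=11)
        np.testing.assert_array_equal(cluster_cells(x, p), cluster_cells(x, p))

    def test_boundary_n_clusters(self, rng):
        x = rng.random((5, 4))
        labels = cluster_cells(x, ClusterParams(n_clusters=4, n_pcs=2, seed=0))
        assert len(labels) == 5

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_cells(np.random.rand(5, 4), ClusterParams(n_clusters=5))


class TestEntropyByCluster:
    def test_constant_cluster_summary(self):
        entropy = np.array([2.0, 2.0, 1.0, 3.0])
        labels = np.array([1, 1, 2, 2])
        table = entropy_by_cluster(entropy, labels)
        row = table[table.cluster == 1].iloc[0]
        assert row.mean_entropy == 2.0 and row.median_entropy == 2.0

    def test_tmm_percentages_sum_to_100(self):
        entropy = np.linspace(1, 2, 6)
        labels = np.array([1, 1, 1, 2, 2, 2])
        calls = pd.DataFrame({"label": ["TEL", "NDTMM", "TEL", "ALT-like",
                                        "ALT-like", "NDTMM"]})
        table = entropy_by_cluster(entropy, labels, calls)
        pct_cols = [c for c in table.columns if c.startswith("pct_")]
        np.testing.assert_allclose(table[pct_cols].sum(axis=1), 100.0)

    def test_planted_high_entropy_cluster_on_top(self, rng):
        entropy = np.concatenate([rng.normal(5, 0.1, 30),
                                  rng.normal(2, 0.1, 60)])
        labels = np.array([1] * 30 + [2] * 60)
        table = entropy_by_cluster(entropy, labels)
        top = table.sort_values("mean_entropy").iloc[-1]
        assert top.cluster == 1 and top.q_vs_rest < 0.01

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            entropy_by_cluster(np.ones(3), np.ones(4))


class TestMarkerSummary:
    def _calls(self, labels):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(labels))],
                             "label": labels})

    def test_constant_marker_p_is_one(self):
        x = np.ones((8, 3))
        calls = self._calls(["TEL"] * 4 + ["NDTMM"] * 4)
        out = marker_summary(x, ["m0", "m1", "m2"], ["m1"], calls)
        assert (out["p_vs_rest"] == 1.0).all()

    def test_small_group_gets_na(self):
        x = np.arange(10, dtype=float).reshape(5, 2)
        calls = self._calls(["TEL"] + ["NDTMM"] * 4)
        out = marker_summary(x, ["m0", "m1"], ["m0"], calls)
        row = out[out.tmm_type == "TEL"].iloc[0]
        assert row.n_cells == 1 and np.isnan(row.p_vs_rest)
        assert row["mean"] == x[0, 0]

    def test_planted_shift_recovered_as_top_mean(self, rng):
        labels = ["TEL+ALT-like"] * 30 + ["NDTMM"] * 30 + ["TEL"] * 30
        x = rng.poisson(3, size=(90, 2)).astype(float)
        x[:30, 0] *= 2.0  # MKI67-like boost in TEL+ALT-like cells
        out = marker_summary(x, ["MKI67", "other"], ["MKI67"],
                             self._calls(labels))
        best = out[out.marker == "MKI67"].sort_values("mean").iloc[-1]
        assert best.tmm_type == "TEL+ALT-like"

    def test_missing_markers(self, rng):
        x = rng.random((6, 2))
        calls = self._calls(["TEL"] * 3 + ["NDTMM"] * 3)
        with pytest.warns(UserWarning):
            out = marker_summary(x, ["g0", "g1"], ["g1", "absent"], calls)
        assert set(out.marker) == {"g1"}
        with pytest.raises(ValueError):
            marker_summary(x, ["g0", "g1"], ["absent"], calls)


class TestZinbFit:
    def test_parameter_recovery(self, rng):
        x = rzinb(2000, 0.3, 5.0, 2.0, rng)
        fit = zinb_fit(x)
        assert fit.pi == pytest.approx(0.3, abs=0.1)
        assert fit.mu == pytest.approx(5.0, rel=0.15)
        assert fit.theta == pytest.approx(2.0, rel=0.15)

    def test_pure_nb_gives_small_pi(self, rng):
        x = rng.negative_binomial(2.0, 2 / 7, size=2000)
        assert zinb_fit(x).pi < 0.05

    def test_all_zero_boundary(self):
        fit = zinb_fit(np.zeros(50, dtype=int))
        assert fit.boundary and fit.pi == 1.0 and np.isnan(fit.mu)

    def test_optimizer_never_degrades_init(self, rng):
        for _ in range(5):
            x = rzinb(300, rng.uniform(0, 0.6), rng.uniform(1, 10), 1.5, rng)
            if (x == 0).all():
                continue
            fit = zinb_fit(x)
            vals, wts = _aggregate(x)
            nll_init = _zinb_nll_terms(vals, wts, *_moment_init(x))
            assert -fit.loglik <= nll_init + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            zinb_fit(np.array([1, 2, 3]))  # too few
        with pytest.raises(ValueError):
            zinb_fit(np.full(20, 0.5))  # non-integer


class TestDeTwoGroup:
    def test_planted_zero_inflation_shift_is_DEs(self, rng):
        n = 150
        genes = []
        for _ in range(30):
            mu = rng.uniform(3, 8)
            a = rzinb(n, 0.6, mu, 2.0, rng)
            b = rzinb(n, 0.2, mu, 2.0, rng)
            genes.append(np.concatenate([a, b]))
        counts = np.column_stack(genes)
        res = de_two_group(counts, [f"g{i}" for i in range(30)],
                           np.arange(n), np.arange(n, 2 * n))
        detected = res[res.de_class != "none"]
        assert len(detected) > 10
        assert (detected.de_class == "DEs").mean() > 0.5

    def test_planted_abundance_shift_is_DEa(self, rng):
        n = 150
        genes = []
        for _ in range(30):
            a = rzinb(n, 0.3, 4.0, 2.0, rng)
            b = rzinb(n, 0.3, 8.0, 2.0, rng)
            genes.append(np.concatenate([a, b]))
        counts = np.column_stack(genes)
        res = de_two_group(counts, [f"g{i}" for i in range(30)],
                           np.arange(n), np.arange(n, 2 * n))
        detected = res[res.de_class != "none"]
        assert len(detected) > 10
        assert (detected.de_class == "DEa").mean() > 0.5

    def test_pvalues_valid_and_small_groups_rejected(self, rng):
        counts = rng.poisson(2, size=(40, 5))
        res = de_two_group(counts, [f"g{i}" for i in range(5)],
                           np.arange(20), np.arange(20, 40))
        for col in ("p_overall", "p_zero", "p_abund"):
            assert ((res[col] >= 0) & (res[col] <= 1)).all()
        with pytest.raises(ValueError):
            de_two_group(counts, [f"g{i}" for i in range(5)],
                         np.arange(5), np.arange(20, 40))
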