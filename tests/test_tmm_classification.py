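import numpy as np
import pandas as pd
import pytest

from tmm_scell import (GeneSetCollection, PermutationParams, bh_fdr,
                       call_tmm_types, classify_cells, exchangeable_ranks,
                       lognormalize, permutation_pvalues, tmm_frequency)


def naive_bh(p):
    """O(m^2) step-up oracle: q_(i) = min_{j>=i} p_(j)*m/j, in input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_hand_case(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.37]).tolist() == [0.37]

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(200):
            m = rng.integers(1, 30)
            p = np.round(rng.random(m), 3)  # ties included
            np.testing.assert_allclose(bh_fdr(p), naive_bh(p), atol=1e-12)


class TestExchangeableRanks:
    def test_each_gene_marginal_is_a_permutation_of_cells(self, rng):
        x = rng.poisson(1.0, size=(30, 10)).astype(float)
        u_ranks = exchangeable_ranks(x, seed=0)
        # within every cell, ranks are a permutation of 1..n_genes
        for row in u_ranks:
            assert sorted(row.tolist()) == list(range(1, 11))

    def test_seed_determinism(self, rng):
        x = rng.random((20, 8))
        np.testing.assert_array_equal(exchangeable_ranks(x, 3),
                                      exchangeable_ranks(x, 3))
        assert (exchangeable_ranks(x, 3) != exchangeable_ranks(x, 4)).any()


class TestPermutationPvalues:
    def test_bounds_and_add_one_floor(self, rng):
        x = rng.random((60, 300))
        # set genes strongly up in half the cells only: the test is relative
        # across cells, so a cell-specific boost is what it must detect
        x[:30, :5] += 100.0
        ids = [f"g{i}" for i in range(300)]
        p = permutation_pvalues(x, ids, ids[:5],
                                PermutationParams(n_perm=999, seed=0))
        assert (p >= 1 / 1000 - 1e-12).all() and (p <= 1.0).all()
        # boosted cells reach the add-one floor: ES exceeds all 999 nulls
        assert p[:30].min() == pytest.approx(1 / 1000)
        assert np.median(p[:30]) < 0.05

    def test_cells_without_activity_get_large_p(self, rng):
        x = rng.random((60, 40))
        x[:30, :5] += 100.0
        ids = [f"g{i}" for i in range(40)]
        p = permutation_pvalues(x, ids, ids[:5],
                                PermutationParams(n_perm=500, seed=0))
        # the un-boosted half ranks at the bottom of the gene's cross-cell
        # quantiles, so its enrichment is below essentially every null draw
        assert np.median(p[30:]) > 0.9

    def test_determinism(self, rng):
        x = rng.random((25, 30))
        ids = [f"g{i}" for i in range(30)]
        params = PermutationParams(n_perm=200, seed=5)
        np.testing.assert_array_equal(
            permutation_pvalues(x, ids, ids[:4], params),
            permutation_pvalues(x, ids, ids[:4], params))

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            PermutationParams(n_perm=50)


def _qframe(tel_qs, alt_qs):
    n = len(tel_qs)
    return pd.DataFrame({"TELSET": tel_qs, "ALTSET": alt_qs},
                        index=[f"c{i}" for i in range(n)])


_SETS = GeneSetCollection({"TELSET": ["a", "b", "c"], "ALTSET": ["d", "e", "f"]},
                          {"TELSET": "TEL", "ALTSET": "ALT"})


class TestClassifyCells:
    @pytest.mark.parametrize("tel_q,alt_q,expected", [
        (0.001, 0.5, "TEL"),
        (0.5, 0.001, "ALT-like"),
        (0.001, 0.005, "TEL+ALT-like"),
        (0.5, 0.5, "NDTMM"),
    ])
    def test_truth_table(self, tel_q, alt_q, expected):
        calls = classify_cells(_qframe([tel_q], [alt_q]), _SETS,
                               PermutationParams(fdr_threshold=0.01))
        assert calls["label"].tolist() == [expected]

    def test_group_rules_combine_member_sets(self):
        sets = GeneSetCollection(
            {"T1": ["a"], "T2": ["b"], "A1": ["c"]},
            {"T1": "TEL", "T2": "TEL", "A1": "ALT"})
        q = pd.DataFrame({"T1": [0.001], "T2": [0.5], "A1": [0.9]},
                         index=["c0"])
        lab = {rule: classify_cells(
            q, sets, PermutationParams(group_rule=rule))["label"][0]
            for rule in ("any", "all")}
        assert lab == {"any": "TEL", "all": "NDTMM"}

    def test_missing_group_rejected(self):
        sets = GeneSetCollection({"T1": ["a"]}, {"T1": "TEL"})
        q = pd.DataFrame({"T1": [0.5]}, index=["c0"])
        with pytest.raises(ValueError):
            classify_cells(q, sets)


class TestCallTmmTypes:
    def test_deterministic_and_consistent_with_truth_table(self, small_cohort):
        counts, truth, sets, cfg = small_cohort
        norm = lognormalize(counts)
        params = PermutationParams(n_perm=300, seed=9)
        calls1, q1 = call_tmm_types(norm, counts.gene_ids, counts.cell_ids,
                                    sets, params)
        calls2, _ = call_tmm_types(norm, counts.gene_ids, counts.cell_ids,
                                   sets, params)
        assert calls1.equals(calls2)
        thr = params.fdr_threshold
        tel = calls1["tel_q"] < thr
        alt = calls1["alt_q"] < thr
        expected = np.where(tel & alt, "TEL+ALT-like",
                            np.where(tel, "TEL",
                                     np.where(alt, "ALT-like", "NDTMM")))
        assert (calls1["label"].to_numpy() == expected).all()


class TestTmmFrequency:
    def test_percentages(self):
        calls = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(10)],
            "label": ["ALT-like"] * 4 + ["NDTMM"] * 6,
        })
        types = pd.Series(["tumor"] * 10,
                          index=[f"c{i}" for i in range(10)], name="cell_type")
        freq = tmm_frequency(calls, types)
        alt = freq[(freq.cell_type == "tumor") & (freq.tmm_type == "ALT-like")]
        assert alt["percent"].iloc[0] == pytest.approx(40.0)
        assert freq.groupby("cell_type")["percent"].sum().iloc[0] == \
            pytest.approx(100.0)

    def test_single_cell(self):
        calls = pd.DataFrame({"cell_id": ["c0"], "label": ["TEL"]})
        types = pd.Series(["epi"], index=["c0"], name="cell_type")
        freq = tmm_frequency(calls, types)
        assert freq.loc[freq.tmm_type == "TEL", "percent"].iloc[0] == 100.0

    def test_unmatched_cells_rejected(self):
        calls = pd.DataFrame({"cell_id": ["c0"], "label": ["TEL"]})
        types = pd.Series(["epi"], index=["other"], name="cell_type")
        with pytest.raises(ValueError):
            tmm_frequency(calls, types)
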