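"""geNorm, NormFinder, BestKeeper and geometric-mean rank integration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import haustostage as hs
from haustostage.stability import (
    bestkeeper,
    competition_rank,
    genorm,
    integrate_ranks,
    normfinder,
    rank_stability,
)


def _df(rows, index, columns=None):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows, index=index, columns=columns or [f"s{i}" for i in range(rows.shape[1])]
    )


class TestGenorm:
    def test_constant_ratio_pair_m_zero(self):
        q = _df([[1, 3, 2], [2, 6, 4]], ["A", "B"])  # B = 2A everywhere
        res = genorm(q)
        assert res.m_values["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.m_values["B"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_candidate_raises_all_m(self):
        rng = np.random.default_rng(0)
        base = _df(np.exp(rng.normal(0, 0.1, (3, 8))), ["A", "B", "C"])
        res_before = genorm(base)
        noisy = base.copy()
        noisy.loc["D"] = np.exp(rng.normal(0, 2.0, 8))
        res_after = genorm(noisy)
        for cand in ("A", "B", "C"):
            assert res_after.m_values[cand] > res_before.m_values[cand]

    def test_hand_computed_three_by_four(self):
        q = _df([[1, 2, 4, 8], [2, 4, 8, 16], [1, 4, 4, 16]], ["A", "B", "C"])
        log_q = np.log2(q)

        def sd_ratio(j, k):
            return float(np.std(log_q.loc[j] - log_q.loc[k], ddof=1))

        expected = {
            "A": np.mean([sd_ratio("A", "B"), sd_ratio("A", "C")]),
            "B": np.mean([sd_ratio("B", "A"), sd_ratio("B", "C")]),
            "C": np.mean([sd_ratio("C", "A"), sd_ratio("C", "B")]),
        }
        res = genorm(q)
        for cand, want in expected.items():
            assert res.m_values[cand] == pytest.approx(want, rel=1e-12)

    def test_final_pair_shares_rank_one(self):
        rng = np.random.default_rng(1)
        q = pd.DataFrame(
            np.exp(rng.normal(0, [[0.05], [0.05], [0.3], [0.6], [1.0]], (5, 10))),
            index=list("ABCDE"),
        )
        res = genorm(q)
        assert sorted(res.ranks.tolist()) == [1, 1, 3, 4, 5]
        assert set(res.ranks[res.ranks == 1].index) == {"A", "B"}

    def test_pairwise_variation_count(self):
        rng = np.random.default_rng(2)
        q = pd.DataFrame(np.exp(rng.normal(0, 0.3, (5, 8))), index=list("ABCDE"))
        res = genorm(q)
        assert list(res.pairwise_variations.index) == ["V2/3", "V3/4", "V4/5"]

    def test_non_positive_rejected(self):
        with pytest.raises(hs.DataValidationError):
            genorm(_df([[1, 0], [1, 1], [2, 2]], ["A", "B", "C"]))

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(3)
        q = pd.DataFrame(np.exp(rng.normal(0, 0.4, (4, 8))), index=list("ABCD"))
        res = genorm(q)
        res_perm = genorm(q.loc[["C", "A", "D", "B"]])
        pd.testing.assert_series_equal(
            res.m_values.sort_index(), res_perm.m_values.sort_index()
        )


class TestNormfinder:
    GROUPS = pd.Series(["g1"] * 6 + ["g2"] * 6, index=[f"s{i}" for i in range(12)])

    def _panel(self, seed=0, n=8, sd=0.5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(0, sd, (n, 12)),
            index=[f"cand{i}" for i in range(n)],
            columns=self.GROUPS.index,
        )

    def test_constant_candidate_minimal(self):
        y = self._panel()
        y.loc["cand0"] = 7.0
        sv = normfinder(y, self.GROUPS)
        assert sv.idxmin() == "cand0"

    def test_global_shift_equal_sv(self):
        y = self._panel(seed=1)
        y.loc["cand1"] = y.loc["cand2"] + 3.0
        sv = normfinder(y, self.GROUPS)
        assert sv["cand1"] == pytest.approx(sv["cand2"], rel=1e-9)

    def test_group_shifted_candidate_ranked_last(self):
        y = self._panel(seed=2, sd=0.3)
        y.loc["cand3", self.GROUPS == "g2"] += 2.0
        sv = normfinder(y, self.GROUPS)
        assert sv.idxmax() == "cand3"

    def test_matches_direct_equation_coding(self):
        """Loop-based evaluation of the grouped variance/bias model."""
        y = self._panel(seed=4)
        groups = self.GROUPS
        sv = normfinder(y, groups)

        u = y - y.mean(axis=0)
        g_ids = ["g1", "g2"]
        expected = {}
        for cand in y.index:
            a, v = {}, {}
            for g in g_ids:
                cols = groups.index[groups == g]
                vals = u.loc[cand, cols]
                a[g] = vals.mean()
                v[g] = vals.var(ddof=1)
            mean_a = np.mean(list(a.values()))
            d = {g: a[g] - mean_a for g in g_ids}
            sampling = np.mean([v[g] / 6 for g in g_ids])
            gamma2 = max(0.0, sum(d[g] ** 2 for g in g_ids) / (len(g_ids) - 1) - sampling)
            total = 0.0
            for g in g_ids:
                se2 = v[g] / 6
                shrink = gamma2 / (gamma2 + se2) if (gamma2 + se2) > 0 else 0.0
                total += (abs(d[g] * shrink) + np.sqrt(se2)) / len(g_ids)
            expected[cand] = total
        for cand, want in expected.items():
            assert sv[cand] == pytest.approx(want, rel=1e-9)

    def test_single_group_falls_back_with_warning(self):
        y = self._panel(seed=5)
        with pytest.warns(UserWarning, match="falling back"):
            sv = normfinder(y, pd.Series("g1", index=y.columns))
        assert (sv >= 0).all()


class TestBestkeeper:
    def test_exact_copies_r_one(self):
        y = _df([[20, 21, 22, 23], [20, 21, 22, 23]], ["A", "B"])
        res = bestkeeper(y)
        assert res.r["A"] == pytest.approx(1.0)
        assert res.r["B"] == pytest.approx(1.0)

    def test_hand_computed_index_and_r(self):
        y = _df(
            [[20, 21, 22, 23, 24, 25], [30, 30.5, 31, 31.5, 32, 32.5], [25, 24, 23, 26, 22, 21]],
            ["A", "B", "C"],
        )
        res = bestkeeper(y)
        index = y.mean(axis=0)
        for cand in y.index:
            want = stats.pearsonr(y.loc[cand], index)[0]
            assert res.r[cand] == pytest.approx(want, rel=1e-12)

    def test_constant_candidate_flagged_and_ranked_last(self):
        y = _df([[20, 21, 22, 24], [22, 22, 22, 22], [19, 22, 20, 25]], ["A", "B", "C"])
        res = bestkeeper(y)
        assert res.undefined["B"]
        ranking = integrate_ranks(
            pd.Series(0.1, index=y.index), pd.Series(0.1, index=y.index), res.r
        )
        assert ranking.table.loc["B", "rank_bestkeeper"] == 3


class TestIntegrateRanks:
    # per-method scores printed for the two validation panels; competition
    # ranks derived from them reproduce the published rank columns
    HOST_FREE = dict(
        m={"Cc006757": 0.48, "Cc028808": 0.48, "Cc036327": 0.58, "Cc028378": 0.78, "Cc002986": 0.87},
        sv={"Cc028808": 0.32, "Cc028378": 0.43, "Cc036327": 0.49, "Cc006757": 0.51, "Cc002986": 0.52},
        r={"Cc006757": 0.95, "Cc028808": 0.95, "Cc036327": 0.91, "Cc028378": 0.74, "Cc002986": 0.27},
        gm={"Cc028808": 1.00, "Cc006757": 1.59, "Cc036327": 3.00, "Cc028378": 3.17, "Cc002986": 5.00},
    )
    HOST_INDUCED = dict(
        m={"Cc002986": 0.29, "Cc028378": 0.29, "Cc006757": 0.36, "Cc028808": 0.39, "Cc036327": 0.51},
        sv={"Cc028378": 0.19, "Cc006757": 0.27, "Cc002986": 0.27, "Cc028808": 0.29, "Cc036327": 0.42},
        r={"Cc028378": 0.95, "Cc006757": 0.94, "Cc028808": 0.88, "Cc002986": 0.88, "Cc036327": 0.52},
        gm={"Cc028378": 1.00, "Cc002986": 1.82, "Cc006757": 2.29, "Cc028808": 3.63, "Cc036327": 5.00},
    )

    @pytest.mark.parametrize("panel", [HOST_FREE, HOST_INDUCED], ids=["host-free", "host-induced"])
    def test_published_panel_gm(self, panel):
        ranking = integrate_ranks(
            pd.Series(panel["m"]), pd.Series(panel["sv"]), pd.Series(panel["r"])
        )
        for cand, want in panel["gm"].items():
            assert ranking.table.loc[cand, "GM"] == pytest.approx(want, abs=5e-3)

    @pytest.mark.parametrize(
        "ranks, want", [((3, 3, 3), 3.00), ((1, 4, 1), 1.59), ((4, 2, 4), 3.17)]
    )
    def test_gm_closed_form(self, ranks, want):
        assert round(float(np.prod(ranks) ** (1 / 3)), 2) == want

    def test_strict_consensus_ordering(self):
        idx = list("ABCD")
        m = pd.Series([0.1, 0.2, 0.3, 0.4], index=idx)
        sv = pd.Series([0.05, 0.06, 0.07, 0.08], index=idx)
        r = pd.Series([0.99, 0.98, 0.97, 0.96], index=idx)
        ranking = integrate_ranks(m, sv, r)
        assert ranking.table["GM"].tolist() == [1.0, 2.0, 3.0, 4.0]
        assert ranking.ordering == idx

    def test_competition_ranking_skips_after_tie(self):
        ranks = competition_rank(pd.Series([0.48, 0.48, 0.58, 0.78, 0.87]))
        assert ranks.tolist() == [1, 1, 3, 4, 5]

    def test_length_mismatch_rejected(self):
        with pytest.raises(hs.DataValidationError):
            integrate_ranks(
                pd.Series({"A": 1.0}), pd.Series({"A": 1.0, "B": 2.0}), pd.Series({"A": 0.5})
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        idx = list("ABCDE")
        m = pd.Series(rng.uniform(0.2, 1, 5), index=idx)
        sv = pd.Series(rng.uniform(0.1, 0.5, 5), index=idx)
        r = pd.Series(rng.uniform(0.2, 0.99, 5), index=idx)
        a = integrate_ranks(m, sv, r).table
        perm = ["D", "A", "E", "C", "B"]
        b = integrate_ranks(m[perm], sv[perm], r[perm]).table
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def test_rank_stability_on_simulated_cq(recovery_study):
    """Full ranking from Cq data of five synthetic reference candidates with
    graded stability: the noisiest candidate ranks last."""
    rng = np.random.default_rng(9)
    samples = recovery_study.kept.samples
    sds = [0.05, 0.08, 0.2, 0.4, 0.8]
    cq = pd.DataFrame(
        [22 + rng.normal(0, sd, len(samples.sample_ids)) for sd in sds],
        index=[f"ref{i}" for i in range(5)],
        columns=samples.sample_ids,
    )
    ranking = rank_stability(cq, groups=samples.stages)
    assert ranking.table.index[-1] == "ref4"
    assert ranking.pairwise_variations is not None
    assert (ranking.table["GM"] >= 1).all()
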