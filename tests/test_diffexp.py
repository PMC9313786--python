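"""Exact NB test, dispersion estimation, BH, contrasts and Venn algebra."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import haustostage as hs
from haustostage.diffexp import DispersionEstimate

from test_normalize import _cm


def binomial_split_pvalue(a: int, b: int) -> float:
    """Exact conditional binomial(1/2) two-sided p: sum of all split
    probabilities no larger than the observed split's (exact fractions)."""
    total = a + b
    if total == 0:
        return 1.0
    obs = comb(total, a)
    num = sum(comb(total, x) for x in range(total + 1) if comb(total, x) <= obs)
    return float(Fraction(num, 2**total))


class TestExactTest:
    def test_symmetric_split_p_one(self):
        assert hs.nb_exact_test([5], [5], phi=0.0) == 1.0

    def test_extreme_split(self):
        assert hs.nb_exact_test([0], [10], phi=0.0) == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_moderate_split(self):
        assert hs.nb_exact_test([2], [8], phi=0.0) == pytest.approx(112 / 1024, rel=1e-9)

    def test_zero_total_degenerate(self):
        assert hs.nb_exact_test([0, 0], [0], phi=0.3) == 1.0

    def test_matches_binomial_enumeration_all_totals_to_30(self):
        for total in range(1, 31):
            for a in range(total + 1):
                got = hs.nb_exact_test([a], [total - a], phi=0.0)
                want = binomial_split_pvalue(a, total - a)
                assert got == pytest.approx(want, rel=1e-9), (a, total - a)

    def test_monotone_in_split_imbalance(self):
        # widening the gap at fixed total never increases the p-value
        for total in (6, 11, 20):
            ps = [hs.nb_exact_test([a], [total - a], phi=0.0) for a in range(total // 2 + 1)]
            assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(len(ps) - 1))

    def test_dispersion_widens_p(self):
        p0 = hs.nb_exact_test([2], [12], phi=0.0)
        p1 = hs.nb_exact_test([2], [12], phi=0.5)
        assert p1 > p0

    def test_library_imbalance_shifts_null(self):
        # 2x library in B makes a 1:2 split the expected outcome
        assert hs.nb_exact_test([5], [10], lib_a=1.0, lib_b=2.0, phi=0.0) == 1.0


class TestBh:
    def test_single_p_identity(self):
        assert hs.bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_computed_step_up(self):
        assert np.allclose(hs.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(
            hs.bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_max_p_maps_to_itself(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert hs.bh_adjust(p).max() == pytest.approx(p.max())

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        ours = hs.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(hs.DataValidationError):
            hs.bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_permutation_equivariance(self, p):
        p = np.asarray(p)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(hs.bh_adjust(p)[perm], hs.bh_adjust(p[perm]))


class TestFilterExpressed:
    def _matrix(self):
        counts = np.zeros((5, 12), dtype=int)
        counts[0] = 0  # all-zero: removed
        counts[1, :2] = [1, 1]  # only 2 samples: removed
        counts[2, :3] = 1  # 3 samples, sum CPM = 3.0 exactly at equal libraries
        counts[3] = 100  # comfortably expressed
        counts[4, 0] = 5000  # 1 sample only: removed despite large CPM
        # fillers to equalize library sizes at 1e6
        filler = 1_000_000 - counts.sum(axis=0)
        counts = np.vstack([counts, filler])
        return _cm(counts, stages=(["niS", "SWE", "ATT", "PEN"] * 3))

    def test_boundary_rules(self):
        kept = hs.filter_expressed(self._matrix(), min_samples=3, min_total_cpm=3.0)
        ids = set(kept.transcript_ids)
        assert "t2" in ids  # inclusive boundary: exactly 3 samples, sum CPM 3.0
        assert "t3" in ids
        assert {"t0", "t1", "t4"} & ids == set()

    def test_all_removed_raises(self):
        cm = _cm(np.ones((2, 12), dtype=int))
        with pytest.raises(hs.DataValidationError, match="review"):
            hs.filter_expressed(cm, min_samples=13, min_total_cpm=0)


class TestDispersion:
    def test_poisson_data_small_phi(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(500, 12))
        est = hs.estimate_common_dispersion(_cm(counts, stages=["niS", "SWE", "ATT", "PEN"] * 3))
        assert est.common_phi < 0.05

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(3)
        phi = 0.2
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + 50.0), size=(500, 12))
        est = hs.estimate_common_dispersion(_cm(counts, stages=["niS", "SWE", "ATT", "PEN"] * 3))
        assert 0.1 <= est.common_phi <= 0.3

    def test_single_replicate_rejected(self):
        counts = np.ones((10, 2), dtype=int)
        with pytest.raises(hs.DataValidationError, match="replicates"):
            hs.estimate_common_dispersion(_cm(counts, stages=["niS", "SWE"]))


class TestRunContrast:
    def test_antisymmetry(self, recovery_study):
        kept = recovery_study.kept
        disp = DispersionEstimate(0.1)
        ab = hs.run_contrast(kept, "niS", "SWE", dispersion=disp)
        ba = hs.run_contrast(kept, "SWE", "niS", dispersion=disp)
        assert np.allclose(ab.table["log2FC"], -ba.table["log2FC"])
        assert np.allclose(ab.table["p_value"], ba.table["p_value"])

    def test_null_data_type_i_error_controlled(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(60, size=(400, 6))
        cm = _cm(counts, stages=["niS"] * 3 + ["SWE"] * 3)
        res = hs.run_contrast(cm, "niS", "SWE")
        frac_raw = (res.table["p_value"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 400)
        assert frac_raw <= 0.05 + 3 * se
        assert len(res.significant) == 0

    def test_planted_effect_power(self, recovery_study):
        truth, kept = recovery_study.truth, recovery_study.kept
        res = recovery_study.contrasts[("niS", "SWE")]
        planted = [t for t, r in truth.items() if r == "marker:SWE" and t in res.table.index]
        flagged_up = set(res.significant_up())
        assert len(flagged_up.intersection(planted)) / len(planted) >= 0.9

    def test_unknown_stage_rejected(self, recovery_study):
        with pytest.raises(hs.DataValidationError):
            hs.run_contrast(recovery_study.kept, "niS", "MAT")


class TestVennRegions:
    def _result(self, universe, sig):
        table = pd.DataFrame(
            {
                "log2FC": [2.0 if t in sig else 0.0 for t in universe],
                "p_value": 0.5,
                "FDR": [0.01 if t in sig else 0.9 for t in universe],
                "direction": ["up" if t in sig else "ns" for t in universe],
            },
            index=universe,
        )
        return hs.ContrastResult("niS", "SWE", table, DispersionEstimate(0.1))

    def test_identical_sets(self):
        uni = [f"t{i}" for i in range(6)]
        sig = uni[:3]
        regions = hs.stage_overlap_sets({s: self._result(uni, sig) for s in ("SWE", "ATT", "PEN")})
        assert regions["SWE&ATT&PEN"] == set(sig)
        assert regions["SWE"] == set() and regions["ATT"] == set()

    def test_disjoint_sets(self):
        uni = [f"t{i}" for i in range(9)]
        results = {
            "SWE": self._result(uni, uni[0:2]),
            "ATT": self._result(uni, uni[3:5]),
            "PEN": self._result(uni, uni[6:8]),
        }
        regions = hs.stage_overlap_sets(results)
        assert regions["SWE"] == set(uni[0:2])
        assert regions["ATT"] == set(uni[3:5])
        assert regions["SWE&ATT"] == set() and regions["SWE&ATT&PEN"] == set()

    def test_hand_built_regions(self):
        uni = [f"t{i}" for i in range(10)]
        results = {
            "SWE": self._result(uni, ["t0", "t1", "t2", "t3"]),
            "ATT": self._result(uni, ["t2", "t3", "t4"]),
            "PEN": self._result(uni, ["t3", "t4", "t5"]),
        }
        regions = hs.stage_overlap_sets(results)
        assert regions["SWE"] == {"t0", "t1"}
        assert regions["SWE&ATT"] == {"t2"}
        assert regions["SWE&ATT&PEN"] == {"t3"}
        assert regions["ATT&PEN"] == {"t4"}
        assert regions["PEN"] == {"t5"}
        assert regions["ATT"] == set()

    def test_mismatched_universe_rejected(self):
        results = {
            "SWE": self._result(["a", "b"], ["a"]),
            "ATT": self._result(["a", "c"], ["a"]),
            "PEN": self._result(["a", "b"], ["a"]),
        }
        with pytest.raises(hs.DataValidationError, match="universe"):
            hs.stage_overlap_sets(results)
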