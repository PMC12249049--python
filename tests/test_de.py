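import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rmcseq.de import (DesignSpec, MethodResult, bh_adjust, calibrate_methods,
                       estimate_log2fc, run_method, METHOD_NAMES)
from rmcseq.io import CountMatrix
from rmcseq.preprocess import NormalizedMatrix, normalize
from rmcseq.simulate import SimulationConfig, simulate_counts
from tests.conftest import expressed_subset, make_null_config


def _with_housekeeping(row, n_stable=5, level=1000):
    """One test gene plus constant housekeeping genes, so median-of-ratios
    size factors stay at 1 and the test gene's values are untouched."""
    row = np.asarray(row)
    mat = np.vstack([row] + [np.full(row.size, level)] * n_stable)
    return CountMatrix([f"g{i}" for i in range(n_stable + 1)],
                       [f"s{j}" for j in range(row.size)], mat)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                           [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, np.nan]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_dominates_p_and_order_preserving(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestEstimateLog2FC:
    def _nm(self, values):
        values = np.asarray(values, float)
        return NormalizedMatrix(values, [f"g{i}" for i in range(len(values))],
                                [f"s{j}" for j in range(values.shape[1])],
                                "size_factor", np.ones(values.shape[1]))

    def test_closed_forms(self):
        nm = self._nm([[31, 31, 15, 15], [10, 10, 10, 10]])
        d = DesignSpec(nm.sample_ids, [True, True, False, False])
        lfc = estimate_log2fc(nm, d, pseudocount=1)
        assert np.isclose(lfc.iloc[0], 1.0)  # log2(32/16)
        assert lfc.iloc[1] == 0.0

    def test_scaling_changes_bounded_by_pseudocount_algebra(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(5, 10, size=(50, 8))
        nm = self._nm(v)
        d = DesignSpec(nm.sample_ids, [True] * 4 + [False] * 4)
        l1 = estimate_log2fc(nm, d)
        l2 = estimate_log2fc(self._nm(2 * v), d)
        m = v.mean(axis=1).min()
        bound = np.log2((2 * m + 1) / (2 * m)) + np.log2((m + 1) / m)
        assert np.max(np.abs(l2 - l1)) <= bound


class TestWilcoxonExact:
    def test_complete_separation_3v3_matches_enumeration(self):
        """Two-sided exact p for complete separation at n=3/3: enumerate all
        C(6,3)=20 assignments of the rank-sum statistic."""
        vals = np.array([10.0, 11, 12, 1, 2, 3])
        obs_u = 9.0  # all case values exceed all control values
        count_extreme = 0
        for idx in itertools.combinations(range(6), 3):
            grp = np.array(idx)
            rest = np.array([i for i in range(6) if i not in idx])
            u = sum((vals[a] > vals[b]) for a in grp for b in rest)
            if min(u, 9 - u) <= min(obs_u, 9 - obs_u):
                count_extreme += 1
        expected = count_extreme / 20
        assert np.isclose(expected, 0.1)

        counts = _with_housekeeping([100, 110, 120, 10, 20, 30])
        d = DesignSpec(counts.sample_ids, [True, True, True, False, False, False])
        res = run_method("wilcoxon", counts, d)
        assert np.isclose(res.table.loc["g0", "p"], expected)

    def test_large_groups_use_normal_approximation(self):
        cfg = make_null_config(seed=31, n_genes=300, n=20)
        sub, d = expressed_subset(simulate_counts(cfg))
        res = run_method("wilcoxon", sub, d)
        assert res.params["mode"] == "asymptotic"
        assert ((res.table["p"] >= 0) & (res.table["p"] <= 1)).all()


class TestFirth:
    def test_finite_under_complete_separation(self):
        counts = _with_housekeeping([200, 210, 190, 205, 10, 12, 9, 11])
        d = DesignSpec(counts.sample_ids, [True] * 4 + [False] * 4)
        res = run_method("firth", counts, d)
        p = res.table["p"].iloc[0]
        assert 0 < p < 1
        assert res.table["status"].iloc[0] == "tested"


class TestNBWald:
    def test_planted_lfc_one_recovered(self):
        cfg = SimulationConfig(n_genes=1000, n_cases=20, n_controls=20,
                               pi_de=0.2, lfc_min=1.0, lfc_max=1.0,
                               baseline_meanlog=float(np.log(100)),
                               baseline_sdlog=0.5, seed=13,
                               case_age_mean=60, control_age_mean=60)
        study = simulate_counts(cfg)
        sub, d = expressed_subset(study)
        res = run_method("nb_wald", sub, d)
        genes = [g for g in study.true_de_genes if g in set(sub.gene_ids)]
        est = res.table.loc[genes, "log2fc"] * np.sign(study.true_lfc.loc[genes])
        assert 0.85 <= est.median() <= 1.15


@pytest.fixture(scope="module")
def null_results(null_study):
    sub, d = expressed_subset(null_study)
    return {m: run_method(m, sub, d)
            for m in ["nb_wald", "voom_like", "wilcoxon"]}


class TestNullCalibration:
    @pytest.mark.parametrize("method", ["nb_wald", "voom_like", "wilcoxon"])
    def test_pvalues_near_uniform(self, null_results, method):
        """KS distance from U(0,1) of null p-values stays below 0.05."""
        p = null_results[method].table["p"].to_numpy()
        ks = stats.kstest(p, "uniform").statistic
        assert ks <= 0.05

    def test_fdr_consistent_with_step_up(self, null_results):
        t = null_results["nb_wald"].table
        assert np.allclose(t["fdr"].to_numpy(),
                           bh_adjust(t["p"].to_numpy()))
        assert (t["fdr"].to_numpy() >= t["p"].to_numpy() - 1e-15).all()


class TestPowerMonotonicity:
    def test_detection_rate_increases_with_effect(self):
        """Aggregated over seeds, power at |lfc|=2 >= at 1 >= at 0.5."""
        rates = {}
        for lfc in (0.5, 1.0, 2.0):
            hits = total = 0
            for seed in range(3):
                cfg = SimulationConfig(
                    n_genes=400, n_cases=15, n_controls=15, pi_de=0.25,
                    lfc_min=lfc, lfc_max=lfc, seed=700 + seed,
                    baseline_meanlog=float(np.log(80)), baseline_sdlog=0.5,
                    case_age_mean=60, control_age_mean=60)
                study = simulate_counts(cfg)
                sub, d = expressed_subset(study)
                res = run_method("nb_wald", sub, d)
                de = [g for g in study.true_de_genes if g in set(sub.gene_ids)]
                hits += (res.table.loc[de, "fdr"] < 0.05).sum()
                total += len(de)
            rates[lfc] = hits / total
        assert rates[2.0] >= rates[1.0] >= rates[0.5]


class TestRunMethodContract:
    def test_unknown_method_rejected(self, toy_counts):
        d = DesignSpec(toy_counts.sample_ids, [True] * 3 + [False] * 3)
        with pytest.raises(ValueError, match="unknown"):
            run_method("deseq3", toy_counts, d)

    def test_all_methods_emit_aligned_tables(self, toy_counts):
        d = DesignSpec(toy_counts.sample_ids, [True] * 3 + [False] * 3)
        for m in METHOD_NAMES:
            res = run_method(m, toy_counts, d)
            assert res.gene_ids == toy_counts.gene_ids
            assert ((res.table["p"] >= 0) & (res.table["p"] <= 1)).all()


class TestCalibrateMethods:
    @staticmethod
    def _stub_runner(factor):
        import zlib

        def run(name, counts, design):
            rng = np.random.default_rng(
                zlib.crc32(f"{design.seed}-{name}".encode()) % 2**31)
            p = np.clip(rng.uniform(size=counts.n_genes) * factor, 0, 1)
            return MethodResult(name, pd.DataFrame(
                {"log2fc": 0.0, "p": p, "fdr": bh_adjust(p), "status": "tested"},
                index=counts.gene_ids))
        return run

    def test_uniform_stub_near_nominal(self, toy_counts):
        cm = CountMatrix([f"g{i}" for i in range(2000)],
                         [f"s{j}" for j in range(8)],
                         np.ones((2000, 8), dtype=int))
        d = DesignSpec(cm.sample_ids, [True] * 4 + [False] * 4, seed=5)
        rates = calibrate_methods(cm, d, B=50, methods=["stub"],
                                  runner=self._stub_runner(1.0))
        assert 0.04 <= rates["stub"] <= 0.06

    def test_anticonservative_stub_doubled(self):
        cm = CountMatrix([f"g{i}" for i in range(2000)],
                         [f"s{j}" for j in range(8)],
                         np.ones((2000, 8), dtype=int))
        d = DesignSpec(cm.sample_ids, [True] * 4 + [False] * 4, seed=6)
        rates = calibrate_methods(cm, d, B=50, methods=["stub"],
                                  runner=self._stub_runner(0.5))
        assert abs(rates["stub"] - 0.10) < 0.01

    def test_reproducible_and_validated(self):
        cm = CountMatrix([f"g{i}" for i in range(100)],
                         [f"s{j}" for j in range(8)],
                         np.ones((100, 8), dtype=int))
        d = DesignSpec(cm.sample_ids, [True] * 4 + [False] * 4, seed=7)
        r1 = calibrate_methods(cm, d, B=20, methods=["stub"],
                               runner=self._stub_runner(1.0))
        r2 = calibrate_methods(cm, d, B=20, methods=["stub"],
                               runner=self._stub_runner(1.0))
        assert r1 == r2
        with pytest.raises(ValueError):
            calibrate_methods(cm, d, B=5, methods=["stub"],
                              runner=self._stub_runner(1.0))
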