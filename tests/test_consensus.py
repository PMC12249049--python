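import numpy as np
import pandas as pd
import pytest

from rmcseq.consensus import (RMCConfig, RMCModel, classify_gene,
                              compare_with_single_method, rmc_combine,
                              single_method_classes, vote_matrix, CLASSES)
from rmcseq.de import DesignSpec, MethodResult, bh_adjust
from rmcseq.io import CountMatrix
from tests.conftest import expressed_subset


class TestClassifyGene:
    @pytest.mark.parametrize("row_sum,mean_norm,lfc,fdr,expected", [
        (0, 0.0, np.nan, np.nan, "ZCG"),
        (40, 5.0, np.nan, np.nan, "LCG"),
        (4000, 100.0, 0.5, 0.5, "EEG"),
        (4000, 100.0, 0.2, 0.01, "NRG"),
        # published blood-panel rows: ALDOA and MTSS1
        (4000, 100.0, 0.8515, 0.0014, "URG"),
        (4000, 100.0, -0.6198, 0.0011, "DRG"),
        # inclusive boundaries at the printed thresholds
        (4000, 100.0, 0.40, 0.049, "URG"),
        (4000, 100.0, -0.40, 0.049, "DRG"),
        (4000, 100.0, 0.39, 0.01, "NRG"),
        (4000, 10.0, 1.0, 0.01, "URG"),  # exactly at the low-count gate
    ])
    def test_precedence_rules(self, row_sum, mean_norm, lfc, fdr, expected):
        assert classify_gene(row_sum, mean_norm, lfc, fdr) == expected

    def test_missing_fdr_past_gate_raises(self):
        with pytest.raises(ValueError, match="FDR"):
            classify_gene(500, 50.0, 1.0, float("nan"))

    def test_published_blood_panel_all_rows_reproduced(self):
        """Applying the classification rules to all 20 printed (log2FC, FDR)
        pairs reproduces every printed label: 19 up, 1 down."""
        from rmcseq.io import load_blood_deg_panel

        panel = load_blood_deg_panel()
        labels = [classify_gene(1000, 100.0, row.log2fc, row.fdr)
                  for row in panel.itertuples()]
        assert labels == list(panel["classification"])
        assert labels.count("URG") == 19 and labels.count("DRG") == 1


def _method(name, genes, p, lfc, native=True):
    p = np.asarray(p, float)
    return MethodResult(name, pd.DataFrame(
        {"log2fc": np.asarray(lfc, float), "p": p, "fdr": bh_adjust(p),
         "status": "tested"}, index=genes), native_effect=native)


def _high_counts(genes, n_samples=10, value=500):
    return CountMatrix(list(genes), [f"s{j}" for j in range(n_samples)],
                       np.full((len(genes), n_samples), value))


class TestVoteMatrix:
    def test_vote_boundaries(self):
        genes = ["g0", "g1", "g2"]
        m = [_method(f"m{i}", genes, [0.001, 0.001, 0.9],
                     [0.40, 0.39, 1.0]) for i in range(3)]
        vm = vote_matrix(m)
        assert (vm.loc["g0"] == "up").all()      # inclusive boundary
        assert (vm.loc["g1"] == "none").all()    # below effect threshold
        assert (vm.loc["g2"] == "none").all()    # not significant

    def test_all_fdr_one_votes_none(self):
        genes = [f"g{i}" for i in range(4)]
        m = [_method(f"m{i}", genes, [1.0] * 4, [2.0] * 4) for i in range(3)]
        assert (vote_matrix(m).to_numpy() == "none").all()

    def test_universe_mismatch_rejected(self):
        a = _method("a", ["g0"], [0.5], [0.0])
        b = _method("b", ["g1"], [0.5], [0.0])
        c = _method("c", ["g0"], [0.5], [0.0])
        with pytest.raises(ValueError, match="universe"):
            vote_matrix([a, b, c])


class TestRMCCombine:
    def test_unanimous_gene_is_urg_not_rescued(self):
        genes = [f"g{i}" for i in range(20)]
        p = np.full(20, 0.9)
        p[0] = 1e-6
        lfc = np.zeros(20)
        lfc[0] = 1.0
        methods = [_method(f"m{i}", genes, p, lfc) for i in range(5)]
        counts = _high_counts(genes)
        res = rmc_combine(methods, counts)
        assert res.table.loc["g0", "label"] == "URG"
        assert bool(res.table.loc["g0", "rescued"]) is False
        assert res.table.loc["g0", "n_up"] == 5

    def test_all_large_p_gives_eeg(self):
        genes = [f"g{i}" for i in range(5)]
        methods = [_method(f"m{i}", genes, [0.9] * 5, [0.0] * 5)
                   for i in range(3)]
        res = rmc_combine(methods, _high_counts(genes))
        assert (res.table["label"] == "EEG").all()

    def test_quorum_blocked_gene_rescued_by_recursion(self):
        """Hand-built 5-method toy: three tiny p-values but only two in-range
        votes; full-quorum fails, dropping the most discordant method lets
        the gene pass at depth 1 with rescued=true."""
        genes = [f"g{i}" for i in range(30)]
        base_p = np.linspace(0.3, 0.9, 30)
        base_lfc = np.zeros(30)
        specs = [  # (p_g0, lfc_g0); median effect 0.45 passes the gate but
            # only m0/m1 vote up: m2's effect sits below 0.40 and m3/m4 are
            # not individually significant
            (0.0005, 1.0), (0.001, 1.1), (0.0015, 0.39),
            (0.40, 0.45), (0.45, -0.1),
        ]
        methods = []
        for i, (pg, eg) in enumerate(specs):
            p = base_p.copy()
            p[0] = pg
            lfc = base_lfc.copy()
            lfc[0] = eg
            methods.append(_method(f"m{i}", genes, p, lfc))
        res = rmc_combine(methods, _high_counts(genes))
        row = res.table.loc["g0"]
        assert row["n_up"] == 2            # quorum of 3 (of 5) not met
        assert bool(row["is_deg"]) is True
        assert bool(row["rescued"]) is True
        assert row["label"] == "URG"

    def test_partition_invariant(self, planted_study):
        sub, d = expressed_subset(planted_study)
        fit = RMCModel(sub, d, methods=["nb_wald", "voom_like", "wilcoxon"]).fit()
        counts = fit.consensus.class_counts()
        assert counts.sum() == sub.n_genes
        assert set(fit.consensus.table["label"]) <= set(CLASSES)

    def test_fewer_than_three_methods_rejected(self):
        genes = ["g0"]
        m = [_method("a", genes, [0.5], [0.0]),
             _method("b", genes, [0.5], [0.0])]
        with pytest.raises(ValueError):
            rmc_combine(m, _high_counts(genes))

    def test_duplicate_method_never_flips_direction(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        p[:5] = 1e-5
        lfc = rng.normal(0, 0.2, 20)
        lfc[:3] = 1.0
        lfc[3:5] = -1.0
        ms = [_method(f"m{i}", genes, p, lfc) for i in range(3)]
        res3 = rmc_combine(ms, _high_counts(genes))
        res4 = rmc_combine(ms + [_method("m9", genes, p, lfc)],
                           _high_counts(genes))
        for g in genes:
            a, b = res3.table.loc[g, "label"], res4.table.loc[g, "label"]
            assert not (a == "URG" and b == "DRG")
            assert not (a == "DRG" and b == "URG")

    def test_determinism(self, planted_study):
        sub, d = expressed_subset(planted_study)
        model = RMCModel(sub, d, methods=["nb_wald", "voom_like", "wilcoxon"])
        t1 = model.fit().consensus.table
        t2 = model.fit().consensus.table
        pd.testing.assert_frame_equal(t1, t2)


class TestCompareWithSingleMethod:
    def test_identity_comparison_empty_differences(self):
        genes = [f"g{i}" for i in range(10)]
        p = np.linspace(1e-6, 0.9, 10)
        lfc = np.linspace(2, -2, 10)
        ms = [_method(f"m{i}", genes, p, lfc) for i in range(3)]
        cons = rmc_combine(ms, _high_counts(genes))
        single = single_method_classes(ms[0], _high_counts(genes))
        venn, flow = compare_with_single_method(cons, single)
        assert venn["consensus_only"] == 0 and venn["single_only"] == 0
        # flow row sums conserve the single-method class counts
        assert (flow.sum(axis=1).reindex(single.value_counts().index)
                == single.value_counts()).all()

    def test_universe_mismatch_rejected(self):
        genes = [f"g{i}" for i in range(4)]
        ms = [_method(f"m{i}", genes, [0.5] * 4, [0.0] * 4) for i in range(3)]
        cons = rmc_combine(ms, _high_counts(genes))
        bad = pd.Series(["EEG"] * 3, index=genes[:3])
        with pytest.raises(ValueError):
            compare_with_single_method(cons, bad)


class TestRMCConfig:
    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RMCConfig(fdr_threshold=0.0)
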