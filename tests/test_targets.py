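import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rmcseq.io import SampleTable
from rmcseq.targets import (correlate_clinical, gini_separability,
                            group_compare, select_targets, stratify_clinical)


class TestGiniSeparability:
    def test_disjoint_supports_give_one(self):
        expr = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array([False, False, False, True, True, True])
        assert gini_separability(expr, labels) == 1.0

    def test_constant_expression_gives_zero(self):
        assert gini_separability(np.ones(8), np.r_[np.ones(4, bool),
                                                   np.zeros(4, bool)]) == 0.0

    def test_toy_matches_exhaustive_threshold_enumeration(self):
        """controls (1,2,3), cases (2,3,4): brute-force over all candidate
        midpoint thresholds."""
        expr = np.array([1.0, 2, 3, 2, 3, 4])
        labels = np.array([False, False, False, True, True, True])

        def gini(p):
            return 2 * p * (1 - p)

        n = 6
        best = np.inf
        for thr in (1.5, 2.5, 3.5):
            left = expr <= thr
            nl, nr = left.sum(), n - left.sum()
            pl = labels[left].mean()
            pr = labels[~left].mean()
            best = min(best, (nl * gini(pl) + nr * gini(pr)) / n)
        expected = (gini(0.5) - best) / gini(0.5)
        assert np.isclose(gini_separability(expr, labels), expected)

    def test_random_labels_score_near_zero(self):
        """Permutation null: with labels independent of expression the mean
        score over trials stays at or below 0.1 for n=200."""
        rng = np.random.default_rng(0)
        expr = rng.normal(size=200)
        scores = []
        for _ in range(50):
            labels = np.zeros(200, bool)
            labels[rng.choice(200, 100, replace=False)] = True
            scores.append(gini_separability(expr, labels))
        assert np.mean(scores) <= 0.1

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        expr = rng.normal(size=20)
        labels = np.zeros(20, bool)
        labels[rng.choice(20, 10, replace=False)] = True
        base = gini_separability(expr, labels)
        assert np.isclose(base, gini_separability(np.exp(expr), labels))
        assert np.isclose(base,
                          gini_separability(2 * expr + 7, labels))


class TestSelectTargets:
    def test_planted_separable_genes_recovered(self, planted_targets_fit):
        fit, study = planted_targets_fit
        tab = select_targets(fit.consensus, fit.normmat,
                             fit.model.design.is_case, seed=42)
        sel = set(tab.index[tab["selected"]])
        truth = set(study.true_de_genes)
        assert len(sel & truth) >= 27
        assert len(sel - truth) <= 5
        assert (tab["gini"].between(0, 1)).all()

    def test_deterministic_under_seed(self, planted_targets_fit):
        fit, _ = planted_targets_fit
        t1 = select_targets(fit.consensus, fit.normmat,
                            fit.model.design.is_case, seed=9)
        t2 = select_targets(fit.consensus, fit.normmat,
                            fit.model.design.is_case, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_study_selects_nothing(self, null_study):
        from rmcseq.consensus import RMCModel
        from tests.conftest import expressed_subset

        sub, d = expressed_subset(null_study)
        fit = RMCModel(sub, d, methods=["nb_wald", "voom_like", "wilcoxon"]).fit()
        with pytest.warns(UserWarning, match="no candidate"):
            tab = select_targets(fit.consensus, fit.normmat, d.is_case, seed=1)
        assert tab.empty or tab["selected"].mean() <= 0.01


@pytest.fixture(scope="session")
def planted_targets_fit():
    """30 strongly separable planted genes (|log2FC| = 2) among 2000."""
    from rmcseq.consensus import RMCModel
    from rmcseq.de import DesignSpec
    from rmcseq.simulate import SimulationConfig, simulate_counts

    cfg = SimulationConfig(n_genes=2000, n_cases=20, n_controls=20,
                           pi_de=0.015, lfc_min=2.0, lfc_max=2.0, seed=42,
                           case_age_mean=60, control_age_mean=60)
    study = simulate_counts(cfg)
    design = DesignSpec.from_samples(study.samples, study.counts.sample_ids,
                                     seed=42)
    fit = RMCModel(study.counts, design).fit()
    return fit, study


class TestStratifyClinical:
    def _samples(self, **cols):
        n = len(next(iter(cols.values())))
        return SampleTable(pd.DataFrame({
            "sample_id": [f"c{i}" for i in range(n)],
            "condition": ["case"] * n, **cols}))

    def test_onset_age_printed_cutoffs(self):
        st = self._samples(onset_age=[20.0, 30, 40, 45, 55, 60, 25, 58, 28])
        spec = stratify_clinical(st, "onset_age")
        ages = st.data["onset_age"]
        assert all(ages[s] < 35 for s in spec.group_a)
        assert all(ages[s] > 50 for s in spec.group_b)
        in_neither = set(st.sample_ids) - set(spec.group_a) - set(spec.group_b)
        assert all(35 <= ages[s] <= 50 for s in in_neither)

    def test_vonsattel_grade_2_vs_4(self):
        st = self._samples(vonsattel=[2, 2, 2, 4, 4, 4, 3, 3])
        spec = stratify_clinical(st, "vonsattel")
        assert len(spec.group_a) == 3 and len(spec.group_b) == 3
        with pytest.raises(ValueError):
            stratify_clinical(self._samples(vonsattel=[3] * 8), "vonsattel")

    def test_cag_quartile_arithmetic(self):
        st = self._samples(cag=list(range(40, 60)))
        spec = stratify_clinical(st, "cag")
        assert len(spec.group_a) == 5 and len(spec.group_b) == 5

    def test_lifespan_strata_from_onset_and_death(self):
        onset = np.linspace(30, 60, 12)
        st = self._samples(onset_age=list(onset),
                           death_age=list(onset + np.linspace(5, 27, 12)))
        spec = stratify_clinical(st, "lifespan")
        assert len(spec.group_a) >= 3 and len(spec.group_b) >= 3


class TestCorrelateClinical:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        r, p, line = correlate_clinical(x, x)
        assert np.isclose(r, 1.0) and p < 1e-10
        r2, _, _ = correlate_clinical(x, -x)
        assert np.isclose(r2, -1.0)

    def test_default_clinical_generator_magnitudes(self):
        from rmcseq.simulate import simulate_clinical

        clin = simulate_clinical(146, seed=1)
        r, _, _ = correlate_clinical(clin["cag"], clin["onset_age"])
        assert 0.75 <= abs(r) <= 0.95
        r2, _, _ = correlate_clinical(clin["onset_age"], clin["death_age"])
        assert r2 > 0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_clinical(np.ones(5), np.arange(5.0))


class TestGroupCompare:
    def test_identical_groups_f_near_zero(self):
        out = group_compare({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert out["F"] < 1e-20 and out["p"] > 0.99

    def test_hand_computed_three_group_anova(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 3, 4]),
                  "c": np.array([5.0, 6, 7])}
        vals = np.concatenate(list(groups.values()))
        grand = vals.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2
                         for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_manual = (ss_between / 2) / (ss_within / 6)
        out = group_compare(groups)
        assert abs(out["F"] - f_manual) < 1e-10
        assert len(out["tukey"]) == 3  # all pairwise contrasts

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            out = group_compare({k: rng.normal(size=8) for k in "abc"})
            ps.append(out["p"])
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").statistic <= 0.1

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0], "b": [1.0, 2]})
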