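"""Statistical battery: brute-force oracles, effect sizes, classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from nwreflex import clinstats as cs
from nwreflex.signal_io import ParticipantRecord, load_reference_cohort


class TestWilcoxon:
    def test_identical_samples_no_effect(self):
        res = cs.wilcoxon_rank_sum([1, 2, 3], [3, 2, 1])
        assert res.effect_size == pytest.approx(0.0, abs=1e-9)

    def test_all_constant_degenerate(self):
        res = cs.wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert res.p_value == 1.0 and res.effect_size == 0.0

    def test_exact_enumeration_example(self):
        # perfect separation of 3 vs 3: two-tailed exact p = 2/20 = 0.1
        res = cs.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        res1 = cs.wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], tails="one",
                                    alternative="greater")
        assert res1.p_value == pytest.approx(0.05)

    def test_exact_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, size=5).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            res = cs.wilcoxon_rank_sum(x, y)
            # independent enumeration oracle
            pooled = np.concatenate([x, y])
            ranks = sstats.rankdata(pooled)
            w_obs = ranks[:5].sum()
            sums = [ranks[list(i)].sum()
                    for i in itertools.combinations(range(11), 5)]
            sums = np.array(sums)
            p_ge = (sums >= w_obs - 1e-9).mean()
            p_le = (sums <= w_obs + 1e-9).mean()
            expected = min(1.0, 2 * min(p_ge, p_le))
            assert res.p_value == pytest.approx(expected)

    def test_large_sample_matches_scipy_asymptotics(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        res = cs.wilcoxon_rank_sum(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_one_tailed_leq_two_tailed(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(0.5, 1, 8)
            y = rng.normal(0, 1, 7)
            p2 = cs.wilcoxon_rank_sum(x, y).p_value
            p1 = min(cs.wilcoxon_rank_sum(x, y, "one", "greater").p_value,
                     cs.wilcoxon_rank_sum(x, y, "one", "less").p_value)
            assert p1 <= p2 + 1e-12

    def test_effect_size_r_convention(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2, 1, 20)
        y = rng.normal(0, 1, 20)
        res = cs.wilcoxon_rank_sum(x, y)
        assert res.effect_kind == "r"
        assert res.effect_size > 0.5  # large separation -> large effect


class TestFisherPhi:
    def test_reference_cohort_association(self):
        t = cs.Contingency2x2(2, 6, 6, 1)
        res = cs.fisher_exact_2x2(t)
        assert res.p_value == pytest.approx(0.04, abs=0.005)
        assert cs.phi_coefficient(t) == pytest.approx(0.61, abs=0.005)

    def test_no_association(self):
        assert cs.fisher_exact_2x2(cs.Contingency2x2(1, 1, 1, 1)).p_value == 1.0
        assert cs.phi_coefficient(cs.Contingency2x2(1, 1, 1, 1)) == 0.0

    def test_perfect_association(self):
        t = cs.Contingency2x2(0, 5, 5, 0)
        assert cs.fisher_exact_2x2(t).p_value == pytest.approx(2 / 252, rel=1e-6)
        assert cs.phi_coefficient(cs.Contingency2x2(5, 0, 0, 5)) == 1.0

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            cs.fisher_exact_2x2(cs.Contingency2x2(0, 0, 3, 4))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0 or a + b + c + d > 30:
            return
        t = cs.Contingency2x2(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert cs.fisher_exact_2x2(t).p_value == pytest.approx(
            cs.hypergeom_enumeration_p(t), rel=1e-8)


class TestKendallTauB:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
    ])
    def test_perfect_monotone(self, x, y, expected):
        assert cs.kendall_tau_b(x, y).statistic == pytest.approx(expected)

    def test_tie_example_matches_bruteforce(self):
        x, y = (1, 2, 2, 3), (1, 3, 2, 4)
        assert cs.kendall_tau_b(x, y).statistic == pytest.approx(
            cs.kendall_tau_b_bruteforce(x, y))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_vectors_with_ties_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        x = rng.integers(0, 8, n).astype(float)
        y = rng.integers(0, 8, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert cs.kendall_tau_b(x, y).statistic == pytest.approx(
            cs.kendall_tau_b_bruteforce(x, y), abs=1e-12)

    def test_zero_variance_flagged(self):
        res = cs.kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert res.effect_kind == "none" and "degenerate" in res.note


class TestEta:
    def test_reference_cohort_value(self):
        recs = load_reference_cohort()
        g = [float(r.CPG_neuropathic) for r in recs]
        v = [r.SCAT_mean for r in recs]
        assert cs.eta_coefficient(g, v) == pytest.approx(0.69, abs=0.005)

    def test_equal_means_zero(self):
        assert cs.eta_coefficient([0, 0, 1, 1], [2.0, 4.0, 4.0, 2.0]) == 0.0

    def test_separated_groups_one(self):
        assert cs.eta_coefficient([0, 0, 1, 1], [1.0, 1.0, 5.0, 5.0]) == 1.0

    def test_eta_squared_equals_anova_r_squared(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = rng.integers(0, 2, 30)
            y = rng.normal(g * 0.8, 1.0)
            eta = cs.eta_coefficient(g, y)
            # independent SS identity via the ANOVA F statistic
            f, _ = sstats.f_oneway(y[g == 0], y[g == 1])
            df_b, df_w = 1, len(y) - 2
            r2 = (f * df_b) / (f * df_b + df_w)
            assert eta ** 2 == pytest.approx(r2, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cs.eta_coefficient([0, 0, 1, 1], [3.0, 3.0, 3.0, 3.0])


class TestClassifyClinical:
    def test_reference_cohort_screening_counts(self):
        recs = load_reference_cohort()
        flags = [cs.classify_clinical(r) for r in recs]
        assert sum(f.scipi_positive for f in flags) == 8
        assert sum(bool(f.spasticity_relevant) for f in flags) == 8

    def test_nrs_boundary(self):
        r = ParticipantRecord(participant_id="S", group="SCI",
                              NRS_spontaneous=4)
        assert cs.classify_clinical(r).nrs_relevant is True
        r2 = ParticipantRecord(participant_id="S", group="SCI",
                               NRS_spontaneous=3)
        assert cs.classify_clinical(r2).nrs_relevant is False

    def test_any_joint_rule(self):
        r = ParticipantRecord(participant_id="S", group="SCI",
                              MAS_joint_scores=(0.5, 1.5))
        assert cs.classify_clinical(r).spasticity_relevant is True
        r2 = ParticipantRecord(participant_id="S", group="SCI",
                               MAS_joint_scores=(0.5, 1.0),
                               SCAT_joint_scores=(1.0,))
        assert cs.classify_clinical(r2).spasticity_relevant is False

    def test_means_only_fallback(self):
        r = ParticipantRecord(participant_id="S", group="SCI", MAS_mean=2.2)
        assert cs.classify_clinical(r).spasticity_relevant is True
        r2 = ParticipantRecord(participant_id="S", group="SCI")
        assert cs.classify_clinical(r2).spasticity_relevant is None


class TestBattery:
    def test_clinical_only_reproduces_reference_results(self):
        recs = load_reference_cohort()
        df = cs.run_battery(None, recs)
        fisher = df[df.analysis == "fisher_CPG_vs_spasticity"].iloc[0]
        assert fisher.p_value == pytest.approx(0.04, abs=0.005)
        assert fisher.effect_size == pytest.approx(0.61, abs=0.005)
        eta_scat = df[df.analysis == "eta_CPG_vs_SCAT"].iloc[0]
        assert eta_scat.effect_size == pytest.approx(0.69, abs=0.005)

    def test_simulated_cohort_report_complete(self, small_detections,
                                              small_cohort):
        from nwreflex import aggregate
        summaries = aggregate.summaries_to_frame(
            aggregate.summarize_participant(small_detections))
        df = cs.run_battery(summaries, small_cohort.records)
        for name in ("response_rate_TW2_SCI_vs_NDC", "latency_TW2_SCI_vs_NDC",
                     "auc_TW2_SCI_vs_NDC", "pain_rating_SCI_vs_NDC",
                     "responders_TW2_SCI_vs_NDC", "tau_rate_TW2_vs_MAS",
                     "eta_CPG_vs_SCAT", "fisher_CPG_vs_spasticity"):
            assert name in set(df.analysis), name
        report = cs.battery_report(df)
        assert "statistical battery" in report
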