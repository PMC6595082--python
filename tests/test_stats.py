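"""PVC records, exclusion, D_Ave, ANOVA and power analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from longivol import (
    CohortTable,
    apply_exclusion,
    d_ave_methods,
    d_ave_scans,
    distance_matrix,
    group_anova,
    power_analysis,
    pvc,
    subject_pvc,
)


def records(rows):
    """rows: (subject, group, scan, side, pvc) tuples -> CohortTable."""
    df = pd.DataFrame(rows, columns=["subject", "group", "scan", "side", "pvc"])
    df["method"] = "toy"
    df["v_bl"] = 1000.0
    df["v_fu"] = 1000.0 * (1 + df["pvc"] / 100.0)
    return CohortTable(df)


class TestPvc:
    @pytest.mark.parametrize("v_bl,v_fu,expected", [
        (1000.0, 950.0, -5.0),
        (1234.5, 1234.5, 0.0),
        (2412.7, 2291.5, (2291.5 - 2412.7) / 2412.7 * 100),
    ])
    def test_values(self, v_bl, v_fu, expected):
        assert pvc(v_bl, v_fu) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pvc(0.0, 100.0)


class TestExclusion:
    def test_strictly_greater_than_threshold(self):
        t = records([("s1", "CTRL", "A", "L", -26.0),
                     ("s2", "CTRL", "A", "L", -25.0),
                     ("s3", "CTRL", "A", "L", 25.0),
                     ("s4", "CTRL", "A", "L", 25.0001)])
        out = apply_exclusion(t, threshold=25.0)
        assert out.df["excluded"].tolist() == [True, False, False, True]

    def test_flags_do_not_delete(self):
        rows = [(f"s{i}", "CTRL", "A", "L", p) for i, p in
                enumerate([-30, 10, 28, -5, 40, 3, 2, 1, 0, -1])]
        out = apply_exclusion(records(rows))
        assert len(out.df) == 10
        assert (~out.df["excluded"]).sum() == 7


class TestSubjectPvc:
    def test_left_right_mean(self):
        t = records([("s1", "CTRL", "A", "L", -4.0),
                     ("s1", "CTRL", "A", "R", -2.0)])
        out = subject_pvc(apply_exclusion(t))
        assert out["pvc"].tolist() == [-3.0]

    def test_flagged_side_drops_subject_scan(self):
        t = records([("s1", "CTRL", "A", "L", -40.0),
                     ("s1", "CTRL", "A", "R", -2.0),
                     ("s2", "CTRL", "A", "L", -1.0),
                     ("s2", "CTRL", "A", "R", -3.0)])
        out = subject_pvc(apply_exclusion(t))
        assert out["subject"].tolist() == ["s2"]

    def test_matches_brute_force_tabulation(self):
        rng = np.random.default_rng(11)
        rows = []
        for s in range(12):
            for scan in "AB":
                for side in "LR":
                    rows.append((f"s{s:02d}", "MCI", scan, side,
                                 rng.normal(-2, 3)))
        t = apply_exclusion(records(rows))
        out = subject_pvc(t).set_index(["subject", "scan"])["pvc"]
        # independent tabulation: plain dict arithmetic over raw rows
        expect = {}
        for subj, grp, scan, side, p in rows:
            expect.setdefault((subj, scan), []).append(p)
        for key, vals in expect.items():
            assert out[key] == pytest.approx(sum(vals) / len(vals))


class TestDAve:
    def test_identical_vectors_zero(self):
        assert d_ave_scans([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_hand_value(self):
        # pairs (0,2) and (2,0): sqrt((4 + 4)/2) = 2
        assert d_ave_scans([0.0, 2.0], [2.0, 0.0]) == pytest.approx(2.0)

    def test_independent_noise_closed_form(self):
        # A = v + eps_A, B = v + eps_B with sd 1.5 -> RMS(A-B) = sqrt(2)*1.5
        rng = np.random.default_rng(5)
        v = rng.normal(-2.5, 3.0, 160)
        a = v + rng.normal(0, 1.5, 160)
        b = v + rng.normal(0, 1.5, 160)
        assert d_ave_scans(a, b) == pytest.approx(np.sqrt(2) * 1.5, rel=0.12)

    def test_methods_symmetric_and_scales_linearly(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert d_ave_methods(x, y) == d_ave_methods(y, x)
        assert d_ave_methods(3 * x, 3 * y) == pytest.approx(3 * d_ave_methods(x, y))
        assert d_ave_methods(x, x) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            d_ave_scans([1.0, 2.0], [1.0])


class TestDistanceMatrix:
    @staticmethod
    def subject_frame(values):
        n = len(values)
        return pd.DataFrame({
            "subject": [f"s{i // 2}" for i in range(n)],
            "scan": ["A", "B"] * (n // 2),
            "pvc": values,
        })

    def test_identical_methods_zero_matrix(self):
        f = self.subject_frame([-1.0, -2.0, -3.0, -4.0])
        dm = distance_matrix({"m1": f, "m2": f.copy()})
        np.testing.assert_array_equal(dm.to_numpy(), 0.0)

    def test_entries_match_pairwise_calls_and_symmetry(self):
        rng = np.random.default_rng(3)
        frames = {m: self.subject_frame(rng.normal(size=20)) for m in
                  ("m1", "m2", "m3")}
        dm = distance_matrix(frames)
        np.testing.assert_allclose(dm.to_numpy(), dm.to_numpy().T)
        assert np.all(np.diag(dm.to_numpy()) == 0.0)
        for a in frames:
            for b in frames:
                if a != b:
                    assert dm.loc[a, b] == pytest.approx(d_ave_methods(
                        frames[a]["pvc"].to_numpy(), frames[b]["pvc"].to_numpy()))

    def test_needs_two_methods(self):
        with pytest.raises(ValueError):
            distance_matrix({"m1": self.subject_frame([1.0, 2.0])})


def subject_table(groups: dict) -> pd.DataFrame:
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"subject": f"{g}{i // 2}", "group": g,
                         "scan": "AB"[i % 2], "method": "toy", "pvc": v})
    return pd.DataFrame(rows)


class TestGroupAnova:
    def test_identical_observations_f_zero(self):
        t = subject_table({"CTRL": [1.0] * 4, "MCI": [1.0] * 4, "AD": [1.0] * 4})
        res = group_anova(t, mode="pooled")
        assert res.F == 0.0
        assert (res.posthoc["p_adj"] == 1.0).all()

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(-1, 2, 12), rng.normal(-4, 2, 10)
        res = group_anova(subject_table({"CTRL": a.tolist(), "AD": b.tolist()}),
                          mode="pooled")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t ** 2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_three_groups_match_hand_sums_of_squares(self):
        groups = {"CTRL": [-1.0, -2.0, 0.0, -1.5],
                  "MCI": [-3.0, -2.5, -4.0, -2.0],
                  "AD": [-5.0, -4.5, -6.0, -3.5]}
        res = group_anova(subject_table(groups), mode="pooled")
        # independent sums-of-squares computation
        allv = [v for vs in groups.values() for v in vs]
        grand = sum(allv) / len(allv)
        ssb = sum(len(vs) * (sum(vs) / len(vs) - grand) ** 2
                  for vs in groups.values())
        ssw = sum((v - sum(vs) / len(vs)) ** 2
                  for vs in groups.values() for v in vs)
        dfb, dfw = 2, len(allv) - 3
        f_hand = (ssb / dfb) / (ssw / dfw)
        assert res.F == pytest.approx(f_hand, rel=1e-12)
        assert (res.df_between, res.df_error) == (dfb, dfw)
        assert res.p_value == pytest.approx(sps.f.sf(f_hand, dfb, dfw), rel=1e-12)

    def test_pooled_df_pattern_for_full_cohort(self):
        # 80 subjects x 2 scans in 3 groups -> F(2, 157)
        rng = np.random.default_rng(2)
        t = subject_table({"CTRL": rng.normal(-1, 1, 40).tolist(),
                           "MCI": rng.normal(-2, 1, 80).tolist(),
                           "AD": rng.normal(-4, 1, 40).tolist()})
        res = group_anova(t, mode="pooled")
        assert (res.df_between, res.df_error) == (2, 157)

    def test_mixed_mode_uses_subject_level_error(self):
        rng = np.random.default_rng(4)
        t = subject_table({"CTRL": rng.normal(-1, 1, 20).tolist(),
                           "MCI": rng.normal(-2, 1, 20).tolist()})
        res = group_anova(t, mode="mixed")
        assert res.mode == "mixed"
        # 20 subjects in 2 groups -> between-subject error df = 18
        assert (res.df_between, res.df_error) == (1, 18)
        assert 0.0 <= res.p_value <= 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_anova(subject_table({"CTRL": [1.0, 2.0]}), mode="pooled")


class TestPowerAnalysis:
    def test_reference_contrast_values(self):
        # printed group stats of two published methods: d and per-group N
        res = power_analysis(-1.42, 2.650, -4.47, 3.598)
        assert res.n_per_group == 17
        assert res.cohen_d == pytest.approx(0.96, abs=0.01)
        res = power_analysis(-1.30, 1.752, -3.90, 2.599)
        assert res.n_per_group == 11
        assert res.cohen_d == pytest.approx(1.17, abs=0.005)

    def test_unit_effect_size(self):
        # d = 1 exactly: N = 2 (1.9600 + 0.8416)^2 = 15.698 -> 16
        res = power_analysis(0.0, 1.0, 1.0, 1.0)
        assert res.cohen_d == pytest.approx(1.0)
        assert res.n_per_group == 16

    def test_pooling_is_unweighted_root_mean_variance(self):
        res = power_analysis(0.0, 1.0, 1.0, 3.0)
        assert res.sigma_pooled == pytest.approx(np.sqrt((1 + 9) / 2))

    def test_monotonicity(self):
        base = power_analysis(0.0, 2.0, 2.0, 2.0).n_per_group
        assert power_analysis(0.0, 2.0, 3.0, 2.0).n_per_group < base
        assert power_analysis(0.0, 3.0, 2.0, 3.0).n_per_group > base

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="zero effect"):
            power_analysis(-1.0, 2.0, -1.0, 2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_analysis(0.0, -1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            power_analysis(0.0, 1.0, 1.0, 1.0, alpha=1.5)
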