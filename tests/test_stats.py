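"""Inferential battery: mixed ANOVA, correlation grid, McNemar, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hubcog.stats import (
    correlation_grid,
    hub_vs_nonhub_frequency,
    mcnemar_test,
    mixed_anova,
    subgroup_filter,
    wholebrain_group_tests,
)


def cs_data(rng, n_per_group=20, k=5, rho=0.5, group_delta=0.0):
    """Compound-symmetric subjects x nodes data, two groups."""
    out, groups = [], []
    for g, delta in (("patient", group_delta), ("control", 0.0)):
        subj = rng.normal(0, np.sqrt(rho), (n_per_group, 1))
        eps = rng.normal(0, np.sqrt(1 - rho), (n_per_group, k))
        out.append(delta + subj + eps)
        groups += [g] * n_per_group
    return np.vstack(out), np.array(groups)


class TestMixedAnova:
    def test_matches_hand_computed_cell_means_oracle(self):
        """3 subjects/group, 3 nodes: every F and df from explicit textbook
        sums of squares."""
        y = np.array([
            [4.0, 6.0, 5.0], [5.0, 7.0, 7.0], [3.0, 5.0, 6.0],   # patients
            [6.0, 8.0, 9.0], [7.0, 9.0, 8.0], [8.0, 10.0, 11.0],  # controls
        ])
        groups = np.array(["p"] * 3 + ["c"] * 3)
        res = mixed_anova(y, groups)

        # independent hand computation
        gm = y.mean()
        subj = y.mean(1)
        ss_total = ((y - gm) ** 2).sum()
        ss_subjects = 3 * ((subj - gm) ** 2).sum()
        mp, mc = subj[:3].mean(), subj[3:].mean()
        ss_group = 3 * 3 * ((mp - gm) ** 2 + (mc - gm) ** 2)
        ss_sw = ss_subjects - ss_group
        node = y.mean(0)
        ss_node = 6 * ((node - gm) ** 2).sum()
        cellp, cellc = y[:3].mean(0), y[3:].mean(0)
        ss_int = 3 * (((cellp - y[:3].mean() - node + gm) ** 2).sum()
                      + ((cellc - y[3:].mean() - node + gm) ** 2).sum())
        ss_err = ss_total - ss_subjects - ss_node - ss_int

        assert res.F_group == pytest.approx((ss_group / 1) / (ss_sw / 4), abs=1e-10)
        assert res.df_group == (1, 4)
        assert res.F_node == pytest.approx((ss_node / 2) / (ss_err / 8), abs=1e-10)
        assert res.F_interaction == pytest.approx(
            (ss_int / 2) / (ss_err / 8), abs=1e-10)
        assert res.df_node == (2, 8) and res.df_interaction == (2, 8)
        assert res.eta_p2_group == pytest.approx(
            ss_group / (ss_group + ss_sw), abs=1e-12)

    def test_sums_of_squares_are_additive(self, rng):
        y, groups = cs_data(rng, 12, 6)
        ss = mixed_anova(y, groups).sums_of_squares
        assert ss["total"] == pytest.approx(
            ss["group"] + ss["subj_within"] + ss["node"]
            + ss["interaction"] + ss["error_within"], rel=1e-10)

    def test_gg_epsilon_is_exactly_one_for_two_levels(self, rng):
        y, groups = cs_data(rng, 10, 2)
        res = mixed_anova(y, groups)
        assert res.gg_epsilon == 1.0

    def test_gg_epsilon_within_theoretical_bounds(self, rng):
        for k in (3, 5, 8):
            y, groups = cs_data(rng, 15, k)
            res = mixed_anova(y, groups)
            assert 1.0 / (k - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_agrees_with_pingouin(self, rng):
        """Independent cross-check of the full decomposition."""
        pg = pytest.importorskip("pingouin")
        y, groups = cs_data(rng, 9, 4, group_delta=0.6)
        df = pd.DataFrame(y, columns=[f"n{j}" for j in range(4)])
        df["group"] = groups
        df["subject"] = range(len(df))
        long = df.melt(["group", "subject"], var_name="node")
        aov = pg.mixed_anova(long, dv="value", within="node",
                             subject="subject", between="group")
        res = mixed_anova(y, groups)
        row_g = aov[aov.Source == "group"].iloc[0]
        row_i = aov[aov.Source == "Interaction"].iloc[0]
        assert res.F_group == pytest.approx(row_g.F, rel=1e-9)
        assert res.p_group == pytest.approx(row_g.p_unc, rel=1e-9)
        assert res.eta_p2_group == pytest.approx(row_g.np2, rel=1e-9)
        assert res.F_interaction == pytest.approx(row_i.F, rel=1e-9)
        # pingouin's epsilon uses the pooled within covariance only when the
        # data are centered per group first
        wide = pd.DataFrame(
            np.vstack([y[groups == g] - y[groups == g].mean(0)
                       for g in ("patient", "control")]),
            columns=[f"n{j}" for j in range(4)])
        assert res.gg_epsilon == pytest.approx(
            float(pg.epsilon(wide, correction="gg")), rel=1e-6)

    def test_type_I_rate_calibrated_under_compound_symmetry(self):
        """Between-group rejection rate at alpha=.05 stays nominal under the
        exchangeable null."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 500
        for _ in range(reps):
            y, groups = cs_data(rng, 20, 5)
            if mixed_anova(y, groups).p_group < 0.05:
                rejections += 1
        assert 0.03 < rejections / reps < 0.07

    def test_log_transform_needs_positive_values(self, rng):
        # heavy-tailed cells fail Shapiro, triggering the log transform,
        # which must refuse non-positive values without the shift opt-in
        y = np.exp(3 * rng.normal(0, 1, (16, 3)))
        y[0, 0] = -3.0
        groups = np.array(["a"] * 8 + ["b"] * 8)
        with pytest.raises(ValueError, match="non-positive"):
            mixed_anova(y, groups, normality_check=True, log_shift=False)
        res = mixed_anova(y, groups, normality_check=True, log_shift=True)
        assert res.log_transformed

    def test_unbalanced_nodes_error(self, rng):
        y, groups = cs_data(rng, 6, 3)
        y[0, 1] = np.nan
        with pytest.raises(ValueError, match="balanced"):
            mixed_anova(y, groups)


class TestWholebrain:
    def test_identical_groups_give_p_one(self):
        vals = pd.DataFrame({"m": np.r_[np.arange(10.0), np.arange(10.0)]})
        groups = pd.Series(["patient"] * 10 + ["control"] * 10)
        res = wholebrain_group_tests(vals, groups, bonferroni=4)
        assert res.p[0] == pytest.approx(1.0)

    def test_bonferroni_divisor_applied(self, rng):
        vals = pd.DataFrame({
            "a": np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)]})
        groups = pd.Series(["patient"] * 30 + ["control"] * 30)
        res = wholebrain_group_tests(vals, groups, bonferroni=4)
        assert res.p_bonf[0] == pytest.approx(min(res.p[0] * 4, 1.0))


class TestCorrelationGrid:
    def grid_inputs(self, rng, n=40, n_nodes=4):
        vals = {"assortativity": pd.DataFrame(
            rng.normal(0, 1, (n, n_nodes)),
            index=range(n), columns=range(n_nodes))}
        doms = pd.DataFrame({"attention_processing_speed": rng.normal(0, 1, n)},
                            index=range(n))
        classes = {0: "hub", 1: "hub", 2: "nonhub", 3: "nonhub"}
        return vals, doms, classes

    def test_perfect_linear_relation(self, rng):
        vals, doms, classes = self.grid_inputs(rng)
        vals["assortativity"][0] = 2.0 * doms["attention_processing_speed"]
        grid = correlation_grid(vals, doms, classes, alpha_divisor=1)
        row = grid[(grid.node_id == 0)].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.significant

    def test_r_invariant_to_positive_affine_transforms(self, rng):
        vals, doms, classes = self.grid_inputs(rng)
        g1 = correlation_grid(vals, doms, classes)
        vals2 = {"assortativity": vals["assortativity"] * 3.5 + 2.0}
        doms2 = doms * 0.1 - 7.0
        g2 = correlation_grid(vals2, doms2, classes)
        assert np.allclose(g1.r, g2.r, atol=1e-12)

    def test_multiplicity_threshold_controls_flags(self, rng):
        """Independent normals are almost never flagged at alpha/1008."""
        flags = 0
        cells = 0
        for rep in range(60):
            vals, doms, classes = self.grid_inputs(
                np.random.default_rng(rep), n=100)
            grid = correlation_grid(vals, doms, classes, alpha_divisor=1008)
            flags += int(grid.significant.sum())
            cells += len(grid)
        assert flags / cells <= 0.002

    def test_pairwise_missing_handled(self, rng):
        vals, doms, classes = self.grid_inputs(rng)
        vals["assortativity"].iloc[0, 0] = np.nan
        grid = correlation_grid(vals, doms, classes)
        assert grid[grid.node_id == 0].n.iloc[0] == 39


class TestMcNemar:
    def test_chi_square_closed_form(self):
        chi2, p, method = mcnemar_test(10, 2)  # discordant 12 < 25 -> exact
        assert method == "exact"
        chi2, p, method = mcnemar_test(20, 10)
        assert method == "chi2"
        assert chi2 == pytest.approx((20 - 10) ** 2 / 30)

    def test_symmetric_discordance_gives_p_one(self):
        _, p, _ = mcnemar_test(6, 6)
        assert p == pytest.approx(1.0)

    def test_exact_binomial_closed_form(self):
        _, p, _ = mcnemar_test(8, 0)
        assert p == pytest.approx(2 * 0.5 ** 8)

    def test_no_discordant_pairs(self):
        _, p, note = mcnemar_test(0, 0)
        assert p == 1.0 and "no discordant" in note

    def test_hub_excess_detected_with_per_node_pairing(self):
        rows = []
        for dom in ("attention_processing_speed", "proxy_IQ"):
            for nid in range(12):
                rows.append(dict(metric="assortativity", node_id=nid,
                                 node_class="hub", domain=dom,
                                 r=0.6, p=1e-9, n=100, significant=True))
            for nid in range(12, 42):
                rows.append(dict(metric="assortativity", node_id=nid,
                                 node_class="nonhub", domain=dom,
                                 r=0.0, p=0.9, n=100, significant=False))
        grid = pd.DataFrame(rows)
        res = hub_vs_nonhub_frequency(grid, pairing="paired_nodes")
        # cycling pairing: one pair per node of the larger class (30) and
        # domain (2); every pair is hub-significant / nonhub-not
        assert res.b[0] == 60 and res.c[0] == 0
        assert res.p_bonf[0] < 0.05
        maj = hub_vs_nonhub_frequency(grid, pairing="majority")
        assert maj.b[0] == 2 and maj.n_pairs[0] == 2


class TestSubgroupFilter:
    def make_cohort(self):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(50)],
            "putamen_involved": [i >= 14 for i in range(50)],
        })

    def test_filters_flagged_patients(self):
        out = subgroup_filter(self.make_cohort(), "putamen_involved == False")
        assert len(out) == 14

    def test_idempotent(self):
        c = self.make_cohort()
        once = subgroup_filter(c, "putamen_involved == False")
        twice = subgroup_filter(once, "putamen_involved == False")
        assert once.equals(twice)

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="no subjects"):
            subgroup_filter(self.make_cohort(), "subject_id == 'nope'")

    def test_callable_predicate(self):
        out = subgroup_filter(self.make_cohort(),
                              lambda r: not r.putamen_involved)
        assert len(out) == 14
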