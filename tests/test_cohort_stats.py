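"""Outlier removal, normality gating, group tests and correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from respiroflux import cohort_stats as cs
from respiroflux.errors import DataError


def two_group_table(ctrl, dis, param="plt_basal"):
    rows = []
    for i, v in enumerate(ctrl):
        rows.append(dict(animal_id=f"c{i}", group="control", **{param: v}))
    for i, v in enumerate(dis):
        rows.append(dict(animal_id=f"d{i}", group="disease", **{param: v}))
    return pd.DataFrame(rows)


class TestRout:
    def test_constant_vector_removes_nothing(self):
        kept, removed, _ = cs.rout_outliers([5, 5, 5, 5, 5], 0.01)
        assert removed.size == 0 and kept.size == 5

    def test_frozen_oracle_vector(self):
        # worked through the robust-fit + FDR steps by hand before coding:
        # location ~10.5, RSDR = 1.5 * 7/6, only the 1000 survives BH at Q=1%
        kept, removed, diag = cs.rout_outliers([10, 11, 9, 10, 12, 11, 1000], 0.01)
        assert list(removed) == [1000.0]
        assert diag.rsdr == pytest.approx(1.75, abs=0.02)
        assert sorted(kept) == [9, 10, 10, 11, 11, 12]

    def test_removal_monotone_in_q(self, rng):
        for _ in range(20):
            x = np.concatenate([rng.normal(0, 1, 12), rng.normal(12, 1, 2)])
            _, rem_tight, dt = cs.rout_outliers(x, 0.001)
            _, rem_loose, dl = cs.rout_outliers(x, 0.01)
            assert set(dt.removed_indices) <= set(dl.removed_indices)

    def test_false_discovery_control_on_clean_normals(self, rng):
        clean = 0
        reps = 400
        for _ in range(reps):
            _, removed, _ = cs.rout_outliers(rng.standard_normal(30), 0.01)
            clean += removed.size == 0
        assert clean / reps >= 0.97

    def test_planted_outlier_is_caught(self, rng):
        hits = 0
        for _ in range(100):
            x = np.append(rng.standard_normal(20), 15.0)
            _, removed, _ = cs.rout_outliers(x, 0.01)
            hits += 15.0 in removed
        assert hits >= 95


class TestNormalityGate:
    def test_normal_draws_gate_normal(self):
        ok = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(30)
            ok += cs.normality_gate(x)[0] == cs.NORMAL
        assert ok >= 90  # type-I error of the gate is ~5%

    def test_lognormal_draws_gate_non_normal(self):
        ok = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).standard_normal(30))
            ok += cs.normality_gate(x)[0] == cs.NON_NORMAL
        assert ok >= 95

    def test_degenerate_inputs(self):
        gate, info = cs.normality_gate([3.0, 3.0, 3.0, 3.0])
        assert gate == cs.NON_NORMAL and "warning" in info
        gate, info = cs.normality_gate([1.0, 2.0])
        assert gate == cs.NON_NORMAL and "warning" in info

    def test_group_centering_removes_shift_artifact(self, rng):
        # a large group shift must not trip the pooled gate
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(50, 1, 15)])
        g = np.array(["a"] * 15 + ["b"] * 15)
        assert cs.normality_gate(x, g)[0] == cs.NORMAL
        assert cs.normality_gate(x)[0] == cs.NON_NORMAL


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        t = two_group_table([1, 2, 3], [1, 2, 3])
        r = cs.compare_groups(t, "plt_basal", rout_q=None, gate=cs.NORMAL)
        assert r.difference == pytest.approx(0.0)
        assert r.p_two_tailed == pytest.approx(1.0)

    def test_welch_matches_textbook_formula(self):
        a, b = [10.0, 12.0, 14.0, 16.0], [20.0, 22.0, 24.0, 26.0]
        t = two_group_table(a, b)
        r = cs.compare_groups(t, "plt_basal", rout_q=None, gate=cs.NORMAL)
        va, vb = np.var(a, ddof=1) / 4, np.var(b, ddof=1) / 4
        se = math.sqrt(va + vb)
        t_stat = (np.mean(b) - np.mean(a)) / se
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        p = 2 * stats.t.sf(abs(t_stat), df)
        assert r.statistic == pytest.approx(t_stat, abs=1e-12)
        assert r.p_two_tailed == pytest.approx(p, abs=1e-12)
        assert r.difference == pytest.approx(10.0)
        assert r.difference_se == pytest.approx(se, abs=1e-12)

    def test_mann_whitney_exact_matches_enumeration(self, rng):
        a = [1.2, 3.4, 2.2, 5.9, 0.7]
        b = [4.1, 6.3, 8.8, 7.2]
        t = two_group_table(a, b)
        r = cs.compare_groups(t, "plt_basal", rout_q=None, gate=cs.NON_NORMAL)
        pooled = np.array(a + b)
        n1 = len(b)
        u_obs = sum((np.array(b)[:, None] > np.array(a)[None, :]).sum() for _ in [0])
        us = []
        for comb in itertools.combinations(range(9), n1):
            grp = pooled[list(comb)]
            rest = pooled[[i for i in range(9) if i not in comb]]
            us.append((grp[:, None] > rest[None, :]).sum())
        us = np.array(us)
        p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert r.test == "mann_whitney"
        assert r.p_two_tailed == pytest.approx(p_enum, abs=1e-12)
        # Hodges-Lehmann median difference
        hl = np.median((np.array(b)[:, None] - np.array(a)[None, :]).ravel())
        assert r.difference == pytest.approx(hl)

    def test_power_against_shift(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(0, 1, 15)
            b = rng.normal(2, 1, 15)  # delta = 2 SD
            t = two_group_table(a, b)
            r = cs.compare_groups(t, "plt_basal")
            hits += (r.difference > 0) and (r.p_two_tailed < 0.05)
        assert hits >= 95

    def test_empty_group_is_error(self):
        t = two_group_table([1, 2, 3], [])
        t = t[t.group == "control"]
        t.loc[len(t)] = dict(animal_id="d0", group="disease", plt_basal=np.nan)
        with pytest.raises(DataError, match="plt_basal"):
            cs.compare_groups(t, "plt_basal")


class TestCorrelate:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10.0)
        t = pd.DataFrame(dict(animal_id=range(10), group="control",
                              plt_basal=x, sm_p=x, sm_l=-x))
        r = cs.correlate(t, "plt_basal", "sm_p", method="pearson")
        assert r.estimate == pytest.approx(1.0)
        assert r.p_two_tailed < 1e-10
        r2 = cs.correlate(t, "plt_basal", "sm_l", method="pearson")
        assert r2.estimate == pytest.approx(-1.0)

    def test_pearson_matches_brute_force_formula(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        t = pd.DataFrame(dict(animal_id=range(20), group="control",
                              plt_basal=x, sm_p=y))
        r = cs.correlate(t, "plt_basal", "sm_p", method="pearson")
        xc, yc = x - x.mean(), y - y.mean()
        brute = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert r.estimate == pytest.approx(brute, abs=1e-12)
        assert r.ci95_low <= r.estimate <= r.ci95_high

    def test_symmetry_in_arguments(self, rng):
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        t = pd.DataFrame(dict(animal_id=range(12), group="control",
                              plt_basal=x, sm_p=y))
        a = cs.correlate(t, "plt_basal", "sm_p", method="pearson")
        b = cs.correlate(t, "sm_p", "plt_basal", method="pearson")
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed, abs=1e-12)

    def test_exact_permutation_p_close_to_analytic(self, rng):
        x = rng.normal(size=8)
        y = 0.9 * x + 0.5 * rng.normal(size=8)
        t = pd.DataFrame(dict(animal_id=range(8), group="control",
                              plt_basal=x, sm_p=y))
        analytic = cs.correlate(t, "plt_basal", "sm_p", method="pearson")
        p_perm = cs.permutation_p(x, y, statistic="pearson")  # all 8! pairings
        assert p_perm == pytest.approx(analytic.p_two_tailed, abs=0.01)

    def test_spearman_ci_uses_adjusted_se(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        t = pd.DataFrame(dict(animal_id=range(30), group="control",
                              plt_basal=x, sm_p=y))
        r = cs.correlate(t, "plt_basal", "sm_p", method="spearman")
        z = math.atanh(r.estimate)
        half = stats.norm.ppf(0.975) * 1.03 / math.sqrt(30 - 3)
        assert r.ci95_low == pytest.approx(math.tanh(z - half), abs=1e-12)
        assert r.ci95_high == pytest.approx(math.tanh(z + half), abs=1e-12)

    def test_zero_variance_flagged(self):
        t = pd.DataFrame(dict(animal_id=range(6), group="control",
                              plt_basal=[1.0] * 6, sm_p=np.arange(6.0)))
        r = cs.correlate(t, "plt_basal", "sm_p")
        assert r.estimate is None and "ZERO_VARIANCE" in r.flags


class TestCorrelationMatrix:
    def test_toy_matrix_shape_and_symmetry(self, rng):
        x1 = rng.normal(size=12)
        x2 = rng.normal(size=12)
        t = pd.DataFrame(dict(animal_id=range(12), group="control",
                              plt_basal=x1, plt_atp=x2,
                              sm_p=-x1 + 0.1 * rng.normal(size=12),
                              sm_l=x2 + 0.1 * rng.normal(size=12)))
        results, mats, report = cs.correlation_matrix(t, rout_q=None)
        assert len(results) == 4
        assert mats["estimate"].shape == (2, 2)
        swapped, _, _ = cs.correlation_matrix(
            t.rename(columns={"plt_basal": "sm_basal2", "sm_p": "plt_p2"}), rout_q=None)
        # swapping an x with a y transposes that cell's estimate
        orig = next(r for r in results if r.x_parameter == "plt_basal"
                    and r.y_parameter == "sm_p")
        swap = next(r for r in swapped if r.x_parameter == "plt_p2"
                    and r.y_parameter == "sm_basal2")
        assert swap.estimate == pytest.approx(orig.estimate, abs=1e-12)

    def test_all_null_column_omitted_with_report(self, rng):
        t = pd.DataFrame(dict(animal_id=range(8), group="control",
                              plt_basal=rng.normal(size=8),
                              sm_p=rng.normal(size=8), sm_l=np.nan))
        results, mats, report = cs.correlation_matrix(t, rout_q=None)
        assert all(r.y_parameter != "sm_l" for r in results)
        assert any(e.get("rule") == "ALL_NULL_COLUMN_OMITTED" for e in report)

    def test_control_restriction(self, rng):
        n = 20
        t = pd.DataFrame(dict(
            animal_id=range(2 * n),
            group=["control"] * n + ["disease"] * n,
            plt_basal=rng.normal(size=2 * n),
            sm_p=rng.normal(size=2 * n)))
        results, mats, _ = cs.correlation_matrix(t, cohort="control", rout_q=None)
        assert results[0].n == n

    def test_clean_table_idempotent(self, rng):
        t = pd.DataFrame(dict(
            animal_id=range(20), group=["control"] * 10 + ["disease"] * 10,
            plt_basal=np.append(rng.normal(size=19), 40.0)))
        c1, g1, log1 = cs.clean_table(t)
        c2, g2, log2 = cs.clean_table(c1)
        assert len(log1) >= 1 and len(log2) == 0
        pd.testing.assert_frame_equal(c1, c2)
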