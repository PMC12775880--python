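import itertools

import numpy as np
import pytest
from scipy import stats

from statpilot.dataset_io import DataError, Dataset, Observation
from statpilot.inference import (
    kruskal_wallis,
    mann_whitney_u,
    mixed_anova,
    one_way_anova,
    paired_t_test,
    rm_anova,
    t_test,
    two_way_anova,
    wilcoxon_signed_rank,
)


class TestTTest:
    def test_identical_groups_null(self):
        tr, es = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert tr.statistic == pytest.approx(0) and tr.p == pytest.approx(1)
        assert es.value == pytest.approx(0)

    def test_pooled_sd_and_d_direct_arithmetic(self):
        tr, es = t_test([0, 1, 2], [1, 2, 3])
        assert es.denominator == pytest.approx(1.0)  # pooled sd
        assert es.value == pytest.approx(-1.0)
        assert tr.df == (4.0,)

    def test_student_equals_welch_for_equal_n_and_var(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        s, _ = t_test(a, b, "student")
        w, _ = t_test(a, b, "welch")
        assert s.statistic == pytest.approx(w.statistic, abs=1e-12)
        assert s.df == w.df

    def test_welch_d_still_uses_pooled_sd(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 4, 12)
        _, d_student = t_test(a, b, "student")
        _, d_welch = t_test(a, b, "welch")
        assert d_welch.value == d_student.value

    def test_degenerate_inputs(self):
        with pytest.raises(DataError):
            t_test([1.0], [2.0, 3.0])
        with pytest.raises(DataError):
            t_test([2.0, 2.0], [2.0, 2.0])


class TestPairedT:
    def test_constant_shift_is_degenerate(self):
        with pytest.raises(DataError, match="degenerate"):
            paired_t_test([(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)])

    def test_d_direct_arithmetic(self):
        diffs = np.array([0.9, 1.1, 1.0, 1.0])
        pairs = [(d, 0.0) for d in diffs]
        _, es = paired_t_test(pairs)
        assert es.value == pytest.approx(diffs.mean() / diffs.std(ddof=1))
        assert es.name == "cohens_d_paired"

    def test_swapping_negates_t_and_d(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        t1, d1 = paired_t_test(list(zip(x, y)))
        t2, d2 = paired_t_test(list(zip(y, x)))
        assert t1.statistic == pytest.approx(-t2.statistic)
        assert d1.value == pytest.approx(-d2.value)


class TestOneWayAnova:
    def test_direct_arithmetic(self):
        om = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert om.statistic == pytest.approx(1.5)  # SSB = 1.5, SSW = 4, df (1, 4)
        assert om.df == (1.0, 4.0)

    def test_identical_groups_f_zero(self):
        om = one_way_anova([[1.0, 2.0, 3.0]] * 3)
        assert om.statistic == pytest.approx(0.0)

    def test_all_constant_errors(self):
        with pytest.raises(DataError):
            one_way_anova([[2.0, 2.0], [2.0, 2.0]])

    def test_f_equals_t_squared_for_two_groups(self, rng):
        for _ in range(20):
            a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 9)
            om = one_way_anova([a, b])
            tr, _ = t_test(a, b, "student")
            assert om.statistic == pytest.approx(tr.statistic ** 2, abs=1e-10)
            assert om.p == pytest.approx(tr.p, abs=1e-12)

    def test_welch_variant_handles_heteroscedasticity(self, rng):
        a, b, c = rng.normal(0, 1, 10), rng.normal(0, 5, 10), rng.normal(0, 10, 10)
        om = one_way_anova([a, b, c], variant="welch")
        assert om.test_name == "Welch's ANOVA"
        assert om.df[0] == 2.0 and om.df[1] < 27  # Satterthwaite df shrink


class TestKruskalWallis:
    def test_no_tie_direct_arithmetic(self):
        om = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert om.statistic == pytest.approx(7.2)
        assert om.branch == "nonparametric"

    def test_label_permutation_invariance(self):
        g = [[1, 4, 7], [2, 5, 8], [3, 6, 9]]
        h1 = kruskal_wallis(g).statistic
        h2 = kruskal_wallis(g[::-1]).statistic
        assert h1 == pytest.approx(h2)

    def test_all_tied_convention(self):
        om = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert om.statistic == 0.0 and om.p == 1.0 and "tied" in om.notes

    def test_h_equals_z_squared_of_uncorrected_mwu(self, rng):
        """k = 2, no ties: H equals the square of the untied MWU normal z."""
        for _ in range(10):
            a = rng.permutation(np.arange(1.0, 8.0))[:4]
            b = np.setdiff1d(np.arange(1.0, 8.0), a)[:3]
            h = kruskal_wallis([a, b]).statistic
            u = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=False).statistic
            n1, n2 = len(a), len(b)
            z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
            assert h == pytest.approx(z ** 2, abs=1e-10)

    def test_chi2_p_close_to_permutation_p_small_n(self, rng):
        """Chi-square approximation vs full permutation null for n = (3,3,3)."""
        x = rng.normal(0, 1, 9)
        h_obs = kruskal_wallis([x[:3], x[3:6], x[6:]]).statistic
        # exhaustive relabelling null distribution of H
        count = total = 0
        for perm in itertools.permutations(range(9)):
            xp = x[list(perm)]
            h = kruskal_wallis([xp[:3], xp[3:6], xp[6:]]).statistic
            count += h >= h_obs - 1e-12
            total += 1
            if total >= 5040:  # 7! distinct enough arrangements for the check
                break
        p_perm = count / total
        p_chi2 = kruskal_wallis([x[:3], x[3:6], x[6:]]).p
        assert abs(p_chi2 - p_perm) < 0.03


class TestMannWhitney:
    def test_separated_groups_exact(self):
        tr = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert tr.statistic == 0.0
        assert tr.p == pytest.approx(0.1)  # 2/20 arrangements as extreme
        assert "exact" in tr.notes

    def test_identical_samples_u_half(self):
        tr = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert tr.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_complementarity(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0, 1, 8)
        u1 = mann_whitney_u(a, b).statistic
        u2 = mann_whitney_u(b, a).statistic
        assert u1 + u2 == pytest.approx(len(a) * len(b))

    def test_large_or_tied_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        assert "normal approximation" in mann_whitney_u(a, b).notes


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        with pytest.raises(DataError):
            wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])

    def test_all_positive_differences(self):
        pairs = [(d, 0.0) for d in (1.0, 2.0, 3.0, 4.0, 5.0)]
        tr = wilcoxon_signed_rank(pairs)
        assert tr.statistic == 15.0  # V+ = n(n+1)/2
        assert tr.p == pytest.approx(2 / 32)  # two-sided exact

    def test_negation_maps_v_to_complement(self, rng):
        x = rng.normal(0.5, 1, 8)
        pairs = [(v, 0.0) for v in x]
        anti = [(0.0, v) for v in x]
        v1 = wilcoxon_signed_rank(pairs).statistic
        v2 = wilcoxon_signed_rank(anti).statistic
        n = len(x)
        assert v1 + v2 == pytest.approx(n * (n + 1) / 2)

    def test_zero_differences_dropped_and_noted(self):
        tr = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 0.5), (3.0, 1.0), (4.0, 0.1)])
        assert "1 zero difference(s) dropped" in tr.notes
        assert tr.n_used == 3


def test_rank_tests_invariant_under_monotone_transform(rng):
    a, b, c = rng.uniform(1, 2, 6), rng.uniform(1.2, 2.2, 7), rng.uniform(1.4, 2.4, 5)
    f = lambda x: np.exp(3 * np.asarray(x))  # strictly monotone
    assert kruskal_wallis([a, b, c]).statistic == \
        pytest.approx(kruskal_wallis([f(a), f(b), f(c)]).statistic)
    assert mann_whitney_u(a, b).p == pytest.approx(mann_whitney_u(f(a), f(b)).p)


# ---- repeated-measures / two-factor designs -----------------------------

def make_rm_dataset(table):
    """table[s][g] -> Dataset with subjects; groups g1..gk."""
    k = len(table[0])
    labels = [f"g{j + 1}" for j in range(k)]
    obs = [Observation(labels[j], float(table[s][j]), subject=f"s{s}")
           for s in range(len(table)) for j in range(k)]
    return Dataset(obs, labels)


def rm_oracle(table):
    """Cell-means oracle: two-way (subject + condition) decomposition."""
    y = np.asarray(table, float)  # subjects x conditions
    s, k = y.shape
    gm = y.mean()
    m_cond = y.mean(axis=0)
    m_subj = y.mean(axis=1)
    ss_cond = s * ((m_cond - gm) ** 2).sum()
    ss_subj = k * ((m_subj - gm) ** 2).sum()
    ss_tot = ((y - gm) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (s - 1)))
    return f, (k - 1, (k - 1) * (s - 1))


class TestRmAnova:
    def test_flat_profiles_give_f_zero(self):
        table = [[b, b, b] for b in (1.0, 5.0, 2.0, 7.0)]
        om = rm_anova(make_rm_dataset(table))
        assert om.statistic == pytest.approx(0.0, abs=1e-10)
        assert "sphericity not assessed" in om.notes

    def test_matches_cell_means_oracle(self, rng):
        table = rng.normal(0, 1, (4, 3)) + np.array([0.0, 1.0, 2.0])
        om = rm_anova(make_rm_dataset(table.tolist()))
        f, df = rm_oracle(table)
        assert om.statistic == pytest.approx(f, abs=1e-8)
        assert om.df == (float(df[0]), float(df[1]))

    def test_missing_cell_named_in_error(self):
        ds = make_rm_dataset([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        obs = [o for o in ds.observations if not (o.subject == "s1" and o.group == "g3")]
        broken = Dataset(obs, ds.group_order)
        with pytest.raises(DataError, match="s1.*g3"):
            rm_anova(broken)


def make_twoway_dataset(cells):
    """cells[(a, b)] -> list of values."""
    obs = [Observation(a, float(v), factor2=b) for (a, b), vals in cells.items()
           for v in vals]
    return Dataset(obs, sorted({a for a, _ in cells}))


def twoway_oracle(cells):
    """Classical balanced decomposition from cell means."""
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    n = len(next(iter(cells.values())))
    y = np.array([[np.mean(cells[(a, b)]) for b in b_levels] for a in a_levels])
    allv = np.concatenate([np.asarray(v, float) for v in cells.values()])
    gm = allv.mean()
    ss_a = n * len(b_levels) * ((y.mean(axis=1) - gm) ** 2).sum()
    ss_b = n * len(a_levels) * ((y.mean(axis=0) - gm) ** 2).sum()
    ss_ab = n * ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True)
                  + gm) ** 2).sum()
    ss_err = sum(((np.asarray(v, float) - np.mean(v)) ** 2).sum()
                 for v in cells.values())
    df_err = allv.size - len(a_levels) * len(b_levels)
    return {
        "A": (ss_a / (len(a_levels) - 1)) / (ss_err / df_err),
        "B": (ss_b / (len(b_levels) - 1)) / (ss_err / df_err),
        "AB": (ss_ab / ((len(a_levels) - 1) * (len(b_levels) - 1))) / (ss_err / df_err),
    }


class TestTwoWayAnova:
    def test_additive_noise_free_interaction_zero(self):
        cells = {(a, b): [i + 2 * j + d for d in (0.0, 0.1, -0.1)]
                 for i, a in enumerate("pq") for j, b in enumerate(["u", "v"])}
        res = two_way_anova(make_twoway_dataset(cells))
        inter = [r for r in res if "interaction" in r.test_name][0]
        assert inter.statistic == pytest.approx(0.0, abs=1e-10)

    def test_balanced_2x2_matches_cell_means_oracle(self, rng):
        cells = {(a, b): list(rng.normal(i + j, 1, 5))
                 for i, a in enumerate("pq") for j, b in enumerate(["u", "v"])}
        res = {r.test_name: r for r in two_way_anova(make_twoway_dataset(cells))}
        oracle = twoway_oracle(cells)
        assert res["Two-Way ANOVA: Group"].statistic == pytest.approx(oracle["A"], abs=1e-8)
        assert res["Two-Way ANOVA: Factor2"].statistic == pytest.approx(oracle["B"], abs=1e-8)
        assert res["Two-Way ANOVA: interaction"].statistic == \
            pytest.approx(oracle["AB"], abs=1e-8)

    def test_unbalanced_design_notes_type_ii(self, rng):
        cells = {(a, b): list(rng.normal(0, 1, n))
                 for (a, b), n in zip(itertools.product("pq", "uv"), (3, 5, 4, 6))}
        res = two_way_anova(make_twoway_dataset(cells))
        assert all("Type-II" in r.notes for r in res)

    def test_empty_cell_errors(self, rng):
        cells = {("p", "u"): [1.0, 2.0], ("p", "v"): [2.0, 3.0], ("q", "u"): [0.0, 1.0]}
        with pytest.raises(DataError, match="empty"):
            two_way_anova(make_twoway_dataset(cells))


def make_mixed_dataset(data):
    """data[group][subject] = profile over within levels."""
    obs = []
    w_labels = None
    for g, subjects in data.items():
        for sname, profile in subjects.items():
            w_labels = [f"t{j + 1}" for j in range(len(profile))]
            for j, v in enumerate(profile):
                obs.append(Observation(g, float(v), subject=sname, factor2=w_labels[j]))
    return Dataset(obs, list(data))


def splitplot_oracle(data):
    """Hand-coded balanced split-plot decomposition."""
    groups = list(data)
    n = len(data[groups[0]])  # subjects per group
    k = len(next(iter(data[groups[0]].values())))  # within levels
    y = np.array([[data[g][s] for s in data[g]] for g in groups], float)  # g x n x k
    gm = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_w = y.mean(axis=(0, 1))
    m_gs = y.mean(axis=2)  # subject means
    m_gw = y.mean(axis=1)
    ss_between = n * k * ((m_g - gm) ** 2).sum()
    ss_subj = k * ((m_gs - m_g[:, None]) ** 2).sum()
    ss_within = len(groups) * n * ((m_w - gm) ** 2).sum()
    ss_inter = n * ((m_gw - m_g[:, None] - m_w[None, :] + gm) ** 2).sum()
    ss_tot = ((y - gm) ** 2).sum()
    ss_err_w = ss_tot - ss_between - ss_subj - ss_within - ss_inter
    g_ = len(groups)
    f_between = (ss_between / (g_ - 1)) / (ss_subj / (g_ * (n - 1)))
    f_within = (ss_within / (k - 1)) / (ss_err_w / (g_ * (n - 1) * (k - 1)))
    f_inter = (ss_inter / ((g_ - 1) * (k - 1))) / (ss_err_w / (g_ * (n - 1) * (k - 1)))
    return f_between, f_within, f_inter


class TestMixedAnova:
    def test_null_design_small_f(self, rng):
        data = {g: {f"{g}{s}": list(rng.normal(0, 1, 3)) for s in range(6)}
                for g in ("x", "y")}
        res = mixed_anova(make_mixed_dataset(data))
        assert all(r.p > 1e-4 for r in res)  # no systematic effects injected

    def test_matches_split_plot_oracle(self, rng):
        data = {g: {f"{g}{s}": list(rng.normal(0, 1, 3) + np.arange(3) + (g == "y"))
                    for s in range(4)} for g in ("x", "y")}
        res = mixed_anova(make_mixed_dataset(data))
        f_b, f_w, f_i = splitplot_oracle(data)
        got = {r.test_name: r.statistic for r in res}
        assert got["Mixed ANOVA: between (Group)"] == pytest.approx(f_b, abs=1e-8)
        assert got["Mixed ANOVA: within (Factor2)"] == pytest.approx(f_w, abs=1e-8)
        assert got["Mixed ANOVA: interaction"] == pytest.approx(f_i, abs=1e-8)

    def test_between_f_equals_anova_on_subject_means(self, rng):
        data = {g: {f"{g}{s}": list(rng.normal((g == "y") * 2, 1, 4)) for s in range(5)}
                for g in ("x", "y")}
        res = {r.test_name: r for r in mixed_anova(make_mixed_dataset(data))}
        subj_means = [[np.mean(p) for p in data[g].values()] for g in ("x", "y")]
        om = one_way_anova(subj_means)
        assert res["Mixed ANOVA: between (Group)"].statistic == \
            pytest.approx(om.statistic, abs=1e-8)

    def test_incomplete_within_errors(self, rng):
        data = {g: {f"{g}{s}": [1.0, 2.0, 3.0] for s in range(4)} for g in ("x", "y")}
        ds = make_mixed_dataset(data)
        obs = [o for o in ds.observations if not (o.subject == "x0" and o.factor2 == "t3")]
        with pytest.raises(DataError, match="incomplete"):
            mixed_anova(Dataset(obs, ds.group_order))
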