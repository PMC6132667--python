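"""ANOVA and post-hoc procedures against algebraic and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vsdcortex.errors import DegenerateInputError, InvalidParameterError
from vsdcortex.stats import (anova_factorial, anova_mixed, anova_oneway,
                             bonferroni, newman_keuls, tukey)


# ---------------------------------------------------------------------------
# one-way

def test_two_group_f_equals_squared_pooled_t(rng):
    a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
    res = anova_oneway([a, b])
    t = sps.ttest_ind(a, b)
    assert res.F == pytest.approx(t.statistic ** 2, rel=1e-12)
    assert res.p == pytest.approx(t.pvalue, rel=1e-10)


def test_oneway_hand_computed_example():
    res = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
    assert res.F == pytest.approx(3.0, rel=1e-12)
    assert (res.df_num, res.df_den) == (2, 6)
    assert res.ss_partition["between"] == pytest.approx(6.0)
    assert res.ss_partition["within"] == pytest.approx(6.0)


def test_oneway_all_equal_flagged_degenerate():
    res = anova_oneway([[2.0, 2.0], [2.0, 2.0]])
    assert res.flagged_degenerate and np.isnan(res.F)


def test_oneway_needs_two_groups():
    with pytest.raises(InvalidParameterError):
        anova_oneway([[1, 2, 3]])


# ---------------------------------------------------------------------------
# factorial

def _factorial_data(rng, ka=2, kb=4, n_cell=5, interaction=0.0):
    y, fa, fb = [], [], []
    a_eff = rng.normal(size=ka)
    b_eff = rng.normal(size=kb)
    for i in range(ka):
        for j in range(kb):
            vals = 1.0 + a_eff[i] + b_eff[j] + interaction * i * j \
                + rng.normal(0, 0.5, size=n_cell)
            y.extend(vals)
            fa.extend([f"a{i}"] * n_cell)
            fb.extend([f"b{j}"] * n_cell)
    return np.array(y), fa, fb


def test_additive_construction_has_zero_interaction():
    y, fa, fb = [], [], []
    for i in range(2):
        for j in range(3):
            for r in range(3):
                y.append(2.0 + i * 1.5 + j * 0.7)   # exactly additive
                fa.append(i)
                fb.append(j)
    res = {r.effect: r for r in anova_factorial(np.array(y) +
                                                np.tile([0.01, -0.01, 0.0], 6),
                                                fa, fb)}
    assert res["A:B"].ss_effect == pytest.approx(0.0, abs=1e-10)


def test_balanced_factorial_matches_projection_oracle(rng):
    y, fa, fb = _factorial_data(rng, interaction=0.6)
    ours = {r.effect: r for r in anova_factorial(y, fa, fb)}
    # oracle: balanced textbook decomposition from cell means
    df = pd.DataFrame({"y": y, "a": fa, "b": fb})
    grand = df["y"].mean()
    n_cell = 5
    ka, kb = 2, 4
    ss_a = kb * n_cell * sum((g - grand) ** 2
                             for g in df.groupby("a")["y"].mean())
    ss_b = ka * n_cell * sum((g - grand) ** 2
                             for g in df.groupby("b")["y"].mean())
    cell = df.groupby(["a", "b"])["y"].mean()
    ss_cells = n_cell * sum((c - grand) ** 2 for c in cell)
    ss_ab = ss_cells - ss_a - ss_b
    assert ours["A"].ss_effect == pytest.approx(ss_a, rel=1e-10)
    assert ours["B"].ss_effect == pytest.approx(ss_b, rel=1e-10)
    assert ours["A:B"].ss_effect == pytest.approx(ss_ab, rel=1e-10)


def test_unbalanced_factorial_matches_statsmodels_type2(rng):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    y, fa, fb = _factorial_data(rng, interaction=0.4)
    keep = np.ones(len(y), dtype=bool)
    keep[[0, 1, 7, 21]] = False              # mildly unbalanced, like n=16 vs 11
    df = pd.DataFrame({"y": y[keep],
                       "a": np.array(fa)[keep], "b": np.array(fb)[keep]})
    ours = {r.effect: r for r in anova_factorial(df["y"], df["a"], df["b"])}
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    assert ours["A"].F == pytest.approx(table.loc["C(a)", "F"], rel=1e-8)
    assert ours["B"].F == pytest.approx(table.loc["C(b)", "F"], rel=1e-8)
    assert ours["A:B"].F == pytest.approx(table.loc["C(a):C(b)", "F"], rel=1e-8)
    assert ours["A"].p == pytest.approx(table.loc["C(a)", "PR(>F)"], rel=1e-8)


def test_factorial_empty_cell_rejected(rng):
    y = rng.normal(size=6)
    with pytest.raises(InvalidParameterError):
        anova_factorial(y, ["a0"] * 3 + ["a1"] * 3,
                        ["b0", "b0", "b1", "b0", "b0", "b0"])


# ---------------------------------------------------------------------------
# mixed (split-plot)

def _mixed_data(rng, n_per_group=(6, 6), within_effect=1.0,
                interaction=0.0, subject_sd=1.0):
    rows = []
    sid = 0
    for g, n_g in enumerate(n_per_group):
        for s in range(n_g):
            subj = rng.normal(0, subject_sd)
            for w in range(2):
                rows.append({
                    "y": 3.0 + 0.8 * g + within_effect * w
                    + interaction * g * w + subj + rng.normal(0, 0.4),
                    "g": f"g{g}", "w": f"w{w}", "s": f"s{sid}"})
            sid += 1
    return pd.DataFrame(rows)


def test_mixed_within_effect_absent_gives_near_zero_f(rng):
    df = _mixed_data(rng, within_effect=0.0, subject_sd=2.0)
    res = {r.effect: r for r in anova_mixed(df["y"], df["g"], df["w"], df["s"])}
    # no within effect by construction: F ~ F(1, df) central, far from large
    assert res["within"].F < 8.0
    assert res["within"].ss_effect >= 0.0


def test_mixed_matches_pingouin_on_balanced_design(rng):
    pg = pytest.importorskip("pingouin")
    df = _mixed_data(rng, within_effect=0.9, interaction=0.5)
    ours = {r.effect: r for r in anova_mixed(df["y"], df["g"], df["w"], df["s"])}
    table = pg.mixed_anova(data=df, dv="y", within="w", between="g",
                           subject="s")
    table = table.set_index("Source")
    assert ours["between"].F == pytest.approx(table.loc["g", "F"], rel=1e-8)
    assert ours["within"].F == pytest.approx(table.loc["w", "F"], rel=1e-8)
    assert ours["between:within"].F == pytest.approx(
        table.loc["Interaction", "F"], rel=1e-8)
    assert ours["between"].p == pytest.approx(table.loc["g", "p_unc"], rel=1e-6)


def test_mixed_handles_unbalanced_groups_against_stratum_oracle(rng):
    df = _mixed_data(rng, n_per_group=(8, 5), within_effect=0.7,
                     interaction=0.4)
    ours = {r.effect: r for r in anova_mixed(df["y"], df["g"], df["w"], df["s"])}
    # oracle for the within stratum: per-subject tone difference is a
    # one-way ANOVA problem (2 within levels): interaction F equals the
    # between-groups F on the paired differences; within F is the squared
    # one-sample t of the (group-centered) mean difference
    wide = df.pivot_table(index=["s", "g"], columns="w", values="y").reset_index()
    d = wide["w1"] - wide["w0"]
    groups = [d[wide["g"] == g].to_numpy() for g in ("g0", "g1")]
    f_int = anova_oneway(groups).F
    assert ours["between:within"].F == pytest.approx(f_int, rel=1e-8)
    # between stratum: one-way ANOVA on subject means
    m = wide[["w0", "w1"]].mean(axis=1)
    f_between = anova_oneway([m[wide["g"] == g].to_numpy()
                              for g in ("g0", "g1")]).F
    assert ours["between"].F == pytest.approx(f_between, rel=1e-8)
    # dfs follow the split-plot layout
    assert ours["between"].df_den == 13 - 2
    assert ours["within"].df_den == (13 - 2) * (2 - 1)


def test_mixed_cohort_with_group_by_tone_interaction_detects_it(rng):
    # control discriminates tones, the demyelinated group does not: the
    # group x tone interaction must be large at small residual noise
    df = _mixed_data(rng, n_per_group=(12, 10), within_effect=2.0,
                     interaction=-2.0, subject_sd=0.3)
    res = {r.effect: r for r in anova_mixed(df["y"], df["g"], df["w"], df["s"])}
    assert res["between:within"].F > 10.0
    assert res["between:within"].p < 0.01


def test_mixed_rejects_incomplete_subjects(rng):
    df = _mixed_data(rng).iloc[:-1]
    with pytest.raises(InvalidParameterError):
        anova_mixed(df["y"], df["g"], df["w"], df["s"])


# ---------------------------------------------------------------------------
# post-hoc procedures

def test_newman_keuls_two_groups_coincides_with_tukey(rng):
    means, mse, df_err, n = [1.0, 1.9], 0.8, 18, 10
    nk = newman_keuls(means, mse, df_err, n)
    tk = tukey(means, mse, df_err, n)
    assert nk.pairs[0][4] == tk.pairs[0][4]
    assert nk.pairs[0][2] == pytest.approx(tk.pairs[0][2])


def test_equal_means_nothing_significant():
    nk = newman_keuls([10.0, 10.0, 10.0], 1.0, 12, 5)
    assert not any(sig for *_, sig in nk.pairs)


def test_newman_keuls_matches_stepdown_enumeration_oracle():
    """Four ordered group means scored against an explicit stepdown
    enumeration with studentized-range critical values."""
    means = [10.0, 11.0, 14.0, 14.5]
    mse, df_err, n = 4.0, 20, 6
    nk = newman_keuls(means, mse, df_err, n, labels=list("ABCD"))
    # independent enumeration
    q_crit = {r: sps.studentized_range.ppf(0.95, r, df_err) for r in (2, 3, 4)}
    se = np.sqrt(mse / n)
    decided = {}
    for r in (4, 3, 2):
        for i in range(0, 4 - r + 1):
            j = i + r - 1
            blocked = any(decided.get((a, b)) is False
                          for a in range(0, i + 1) for b in range(j, 4)
                          if (b - a + 1) > r)
            q_obs = (means[j] - means[i]) / se
            decided[(i, j)] = (not blocked) and q_obs > q_crit[r]
    expect = {("A", "B"): decided[(0, 1)], ("A", "C"): decided[(0, 2)],
              ("A", "D"): decided[(0, 3)], ("B", "C"): decided[(1, 2)],
              ("B", "D"): decided[(1, 3)], ("C", "D"): decided[(2, 3)]}
    got = {(a, b): sig for a, b, _, _, sig in nk.pairs}
    assert got == expect
    # sanity on the scenario itself: extremes differ, the (C, D) pair does not
    assert got[("A", "D")] is True and got[("C", "D")] is False


def test_newman_keuls_monotone_under_stretch_widening(rng):
    """Adding an intermediate group (widening every stretch) never turns a
    non-significant pair significant."""
    mse, df_err, n = 2.0, 24, 8
    base = [5.0, 6.0, 9.0]
    wide = [5.0, 6.0, 7.5, 9.0]
    nk3 = newman_keuls(base, mse, df_err, n, labels=["x", "y", "z"])
    nk4 = newman_keuls(wide, mse, df_err, n, labels=["x", "y", "m", "z"])
    dec3 = {(a, b): s for a, b, _, _, s in nk3.pairs}
    dec4 = {(a, b): s for a, b, _, _, s in nk4.pairs}
    for pair, sig in dec3.items():
        if not sig:
            assert dec4[pair] is False


def test_tukey_adjusted_p_against_scipy_distribution(rng):
    means, mse, df_err, n = [0.0, 0.5, 2.0], 1.0, 27, 10
    tk = tukey(means, mse, df_err, n, labels=list("abc"))
    for a, b, q, p_adj, sig in tk.pairs:
        assert p_adj == pytest.approx(
            float(sps.studentized_range.sf(q, 3, 27)), rel=1e-10)
        assert sig == (p_adj < 0.05)


def test_bonferroni_caps_at_one():
    res = bonferroni([0.5, 0.04, 0.001], alpha=0.05)
    adj = [p for *_, p, _ in res.pairs]
    assert adj == pytest.approx([1.0, 0.12, 0.003])
    assert [s for *_, s in res.pairs] == [False, False, True]


def test_posthoc_degenerate_mse_rejected():
    with pytest.raises(DegenerateInputError):
        newman_keuls([1.0, 2.0], 0.0, 10, 5)
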