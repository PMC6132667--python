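"""Inferential layer: one-way / factorial / mixed ANOVA with Newman-Keuls,
Bonferroni and Tukey post-hoc procedures.

The group comparisons of the modeled study use classical fixed-effects
ANOVA.  Unbalanced factorial designs (the slice counts differ mildly
between groups) use Type II sums of squares, so main effects are assessed
after the other main effect but ignoring the interaction.  The mixed
(split-plot) ANOVA treats the experimental group as the between-subject
factor and the repeated measure (e.g. tone frequency) as the within-subject
factor; the between-subject error is subjects-within-groups, the within
error is the within x subjects(group) interaction.  No sphericity
correction is applied (with two within levels it would be vacuous anyway);
this is recorded in the result metadata.

Studentized-range quantiles come from scipy's numerical CDF inversion
rather than lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidParameterError


@dataclass
class AnovaResult:
    effect: str
    df_num: int
    df_den: int
    F: float
    p: float
    ss_effect: float
    ss_error: float
    ss_partition: dict = field(default_factory=dict)
    partial_eta_sq: float = float("nan")
    flagged_degenerate: bool = False
    notes: str = ""


@dataclass
class PosthocResult:
    method: str            # newman_keuls | bonferroni | tukey
    alpha: float
    # (group_a, group_b, statistic, adjusted_p_or_critical, significant)
    pairs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers

def _as_groups(groups):
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise InvalidParameterError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise InvalidParameterError("each group needs >= 2 observations")
        if not np.isfinite(g).all():
            raise InvalidParameterError("non-finite observation")
    return gs


def _dummy(levels, codes):
    """Sum-to-zero (effect) coding: k levels -> k-1 columns."""
    k = len(levels)
    X = np.zeros((codes.size, k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
    X[codes == k - 1, :] = -1.0
    return X


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _interaction(Xa, Xb):
    n = Xa.shape[0]
    cols = [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1])
            for j in range(Xb.shape[1])]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _codes(values):
    levels = sorted(set(values))
    lut = {v: i for i, v in enumerate(levels)}
    return levels, np.array([lut[v] for v in values], dtype=int)


# ---------------------------------------------------------------------------
# omnibus tests

def anova_oneway(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA: F = MS_between / MS_within."""
    gs = _as_groups(groups)
    all_y = np.concatenate(gs)
    grand = all_y.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_y.size - len(gs)
    partition = {"between": ss_between, "within": ss_within,
                 "total": float(((all_y - grand) ** 2).sum())}
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult("group", df_b, df_w, float("nan"), float("nan"),
                               ss_between, ss_within, partition,
                               flagged_degenerate=True,
                               notes="all observations equal")
        return AnovaResult("group", df_b, df_w, float("inf"), 0.0,
                           ss_between, ss_within, partition,
                           partial_eta_sq=1.0, flagged_degenerate=True,
                           notes="zero residual variance")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    eta = ss_between / (ss_between + ss_within)
    return AnovaResult("group", df_b, df_w, float(F), p,
                       float(ss_between), float(ss_within), partition,
                       partial_eta_sq=float(eta))


def anova_factorial(y, factor_a, factor_b) -> list[AnovaResult]:
    """Two-way factorial ANOVA (A, B, A x B) with Type II sums of squares.

    Balanced designs reduce to the textbook decomposition; unbalanced ones
    use Type II (each main effect adjusted for the other, ignoring the
    interaction).
    """
    y = np.asarray(y, dtype=float).ravel()
    la, ca = _codes(list(factor_a))
    lb, cb = _codes(list(factor_b))
    if y.size != ca.size or y.size != cb.size:
        raise InvalidParameterError("y and factors differ in length")
    # every cell must be populated
    cells = set(zip(ca.tolist(), cb.tolist()))
    if len(cells) != len(la) * len(lb):
        raise InvalidParameterError("empty design cell")

    one = np.ones((y.size, 1))
    Xa, Xb = _dummy(la, ca), _dummy(lb, cb)
    Xab = _interaction(Xa, Xb)
    rss_b = _rss(np.hstack([one, Xb]), y)
    rss_a = _rss(np.hstack([one, Xa]), y)
    rss_ab_main = _rss(np.hstack([one, Xa, Xb]), y)
    rss_full = _rss(np.hstack([one, Xa, Xb, Xab]), y)

    ss_a = rss_b - rss_ab_main
    ss_b = rss_a - rss_ab_main
    ss_int = rss_ab_main - rss_full
    ss_err = rss_full
    df_a, df_b_ = len(la) - 1, len(lb) - 1
    df_int = df_a * df_b_
    df_err = y.size - len(la) * len(lb)
    if df_err <= 0:
        raise InvalidParameterError("no residual degrees of freedom")
    partition = {"A": ss_a, "B": ss_b, "A:B": ss_int, "residual": ss_err}

    def mk(effect, ss, df):
        if ss_err == 0:
            return AnovaResult(effect, df, df_err, float("nan"), float("nan"),
                               ss, ss_err, partition, flagged_degenerate=True,
                               notes="zero residual variance")
        F = (ss / df) / (ss_err / df_err)
        return AnovaResult(effect, df, df_err, float(F),
                           float(sps.f.sf(F, df, df_err)),
                           float(ss), float(ss_err), partition,
                           partial_eta_sq=float(ss / (ss + ss_err)))
    return [mk("A", ss_a, df_a), mk("B", ss_b, df_b_),
            mk("A:B", ss_int, df_int)]


def anova_mixed(y, between, within, subject) -> list[AnovaResult]:
    """Mixed (split-plot) ANOVA: one between-subject and one within-subject
    factor, complete within-subject data.

    The between effect is tested against subjects-within-groups; the within
    effect and the interaction against within x subjects(group).  Returns
    results for [between, within, between x within].
    """
    y = np.asarray(y, dtype=float).ravel()
    lg, cg = _codes(list(between))
    lw, cw = _codes(list(within))
    ls, cs = _codes(list(subject))
    if not (y.size == cg.size == cw.size == cs.size):
        raise InvalidParameterError("y and factors differ in length")
    n_w, n_s = len(lw), len(ls)

    # each subject belongs to exactly one group and has every within level once
    subj_group = np.full(n_s, -1)
    for s, g in zip(cs, cg):
        if subj_group[s] == -1:
            subj_group[s] = g
        elif subj_group[s] != g:
            raise InvalidParameterError("subject appears in multiple groups")
    counts = np.zeros((n_s, n_w), dtype=int)
    for s, w in zip(cs, cw):
        counts[s, w] += 1
    if not (counts == 1).all():
        raise InvalidParameterError(
            "each subject needs exactly one observation per within level")

    # between-subject stratum, computed on subject means
    subj_mean = np.zeros(n_s)
    for s in range(n_s):
        subj_mean[s] = y[cs == s].mean()
    grand = subj_mean.mean()
    ss_g = n_w * sum((subj_mean[subj_group == g].mean() - grand) ** 2
                     * (subj_group == g).sum() for g in range(len(lg)))
    ss_subj = n_w * sum((subj_mean[s] - subj_mean[subj_group == subj_group[s]].mean()) ** 2
                        for s in range(n_s))
    df_g, df_subj = len(lg) - 1, n_s - len(lg)

    # within-subject stratum via nested OLS comparisons
    Xs = np.zeros((y.size, n_s))
    Xs[np.arange(y.size), cs] = 1.0        # subject dummies absorb group
    Xw = _dummy(lw, cw)
    Xg = _dummy(lg, cg)
    Xgw = _interaction(Xg, Xw)
    rss_s = _rss(Xs, y)
    rss_sw = _rss(np.hstack([Xs, Xw]), y)
    rss_full = _rss(np.hstack([Xs, Xw, Xgw]), y)
    ss_w = rss_s - rss_sw
    ss_gw = rss_sw - rss_full
    ss_err = rss_full
    df_w = n_w - 1
    df_gw = (len(lg) - 1) * (n_w - 1)
    df_err = (n_s - len(lg)) * (n_w - 1)
    if df_subj <= 0 or df_err <= 0:
        raise InvalidParameterError("not enough subjects for the design")

    partition = {"between": ss_g, "subjects(group)": ss_subj, "within": ss_w,
                 "between:within": ss_gw, "within_error": ss_err}
    notes = "no sphericity correction applied"

    def mk(effect, ss, df, ss_e, df_e):
        if ss_e == 0:
            return AnovaResult(effect, df, df_e, float("nan"), float("nan"),
                               ss, ss_e, partition, flagged_degenerate=True,
                               notes=notes + "; zero error variance")
        F = (ss / df) / (ss_e / df_e)
        return AnovaResult(effect, df, df_e, float(F),
                           float(sps.f.sf(F, df, df_e)),
                           float(ss), float(ss_e), partition,
                           partial_eta_sq=float(ss / (ss + ss_e)), notes=notes)
    return [mk("between", ss_g, df_g, ss_subj, df_subj),
            mk("within", ss_w, df_w, ss_err, df_err),
            mk("between:within", ss_gw, df_gw, ss_err, df_err)]


# ---------------------------------------------------------------------------
# post-hoc procedures

def _pair_q(mi, mj, ni, nj, mse):
    nh = 2.0 / (1.0 / ni + 1.0 / nj)     # harmonic mean (Tukey-Kramer)
    return abs(mj - mi) / np.sqrt(mse / nh)


def newman_keuls(group_means, mse, df_error, n_per_group,
                 alpha: float = 0.05, labels=None) -> PosthocResult:
    """Newman-Keuls stepdown on ordered group means.

    Means are sorted; a stretch of ``r`` ordered means is tested with the
    studentized-range critical value q(r, df, alpha).  A non-significant
    stretch blocks all pairs strictly inside it — they are declared
    non-significant without testing (the stepdown rule).  Unequal group
    sizes use the harmonic mean of the pair.
    """
    means = np.asarray(group_means, dtype=float)
    k = means.size
    n = np.broadcast_to(np.asarray(n_per_group, dtype=float), (k,))
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if mse < 0 or df_error < 1:
        raise InvalidParameterError("need mse >= 0 and df_error >= 1")
    if mse == 0:
        raise DegenerateInputError("zero error variance; q undefined")
    order = np.argsort(means, kind="stable")
    m, nn = means[order], n[order]
    lab = [labels[i] for i in order]

    significant = {}
    blocked = set()
    for r in range(k, 1, -1):
        qc = float(sps.studentized_range.ppf(1.0 - alpha, r, df_error))
        for i in range(0, k - r + 1):
            j = i + r - 1
            if (i, j) in blocked:
                sig = False
            else:
                sig = _pair_q(m[i], m[j], nn[i], nn[j], mse) > qc
            significant[(i, j)] = sig
            if not sig:
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        if (a, b) != (i, j):
                            blocked.add((a, b))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            r = j - i + 1
            q_obs = _pair_q(m[i], m[j], nn[i], nn[j], mse)
            qc = float(sps.studentized_range.ppf(1.0 - alpha, r, df_error))
            pairs.append((lab[i], lab[j], float(q_obs), qc,
                          bool(significant[(i, j)])))
    return PosthocResult(method="newman_keuls", alpha=alpha, pairs=pairs)


def tukey(group_means, mse, df_error, n_per_group,
          alpha: float = 0.05, labels=None) -> PosthocResult:
    """Tukey(-Kramer) HSD: every pair against q(k, df, alpha)."""
    means = np.asarray(group_means, dtype=float)
    k = means.size
    n = np.broadcast_to(np.asarray(n_per_group, dtype=float), (k,))
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if mse <= 0:
        raise DegenerateInputError("zero error variance; q undefined")
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            q_obs = _pair_q(means[i], means[j], n[i], n[j], mse)
            p_adj = float(np.clip(sps.studentized_range.sf(q_obs, k, df_error),
                                  0.0, 1.0))
            pairs.append((labels[i], labels[j], float(q_obs), p_adj,
                          bool(p_adj < alpha)))
    return PosthocResult(method="tukey", alpha=alpha, pairs=pairs)


def bonferroni(pvalues, alpha: float = 0.05, pairs=None) -> PosthocResult:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    if pairs is None:
        pairs = [(f"c{i}", "", float("nan")) for i in range(m)]
    adj = np.minimum(1.0, m * p)
    out = [(pa[0], pa[1], float(p[i]), float(adj[i]), bool(adj[i] < alpha))
           for i, pa in enumerate(pairs)]
    return PosthocResult(method="bonferroni", alpha=alpha, pairs=out)
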