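"""Group-comparison statistics for the arousal parameters.

The battery mirrors what a two-day clinical EEG study reports:

- two-sample t-tests from *summary statistics* (Welch and pooled-variance
  Student variants), so printed tables are directly checkable;
- Pearson chi-square on 2x2 contingency tables (no continuity correction);
- paired t-tests;
- mixed repeated-measures ANOVA (one between-subject factor, one or two
  within-subject factors) with Mauchly's sphericity test and a
  Greenhouse-Geisser correction applied *conditionally* when Mauchly's test
  is significant;
- nonparametric post-hocs: Mann-Whitney U, Wilcoxon signed-rank, Friedman.

Because two arousal outcomes (MVV and ASS) are tested, omnibus results are
evaluated at an alpha-adjusted level of 0.025 (Bonferroni over two outcomes).

The mixed ANOVA uses the classical univariate (split-plot) approach: each
within-subject effect is projected onto an orthonormal contrast basis, and
Type-III sums of squares are computed per contrast against the pooled
within-group error.  For a two-level within factor the F statistic equals the
square of the paired t on the same data, and the Greenhouse-Geisser epsilon
is exactly 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "ALPHA_OMNIBUS",
    "StatResult",
    "welch_t_from_summary",
    "pooled_t_from_summary",
    "chi_square_2x2",
    "paired_t",
    "mixed_rm_anova",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman",
]

#: alpha level for the MVV/ASS omnibus tests (two outcome parameters)
ALPHA_OMNIBUS = 0.025


@dataclass
class StatResult:
    """One inferential test result."""

    name: str
    statistic: float
    df: object                   # float, int or tuple
    p: float
    effect: dict = field(default_factory=dict)
    alpha: float = 0.05
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"StatResult({self.name}: stat={self.statistic:.4g}, "
                f"df={self.df}, p={self.p:.4g})")


# ----------------------------------------------------------------------
# t tests
# ----------------------------------------------------------------------

def _t_from_summary(m1, s1, n1, m2, s2, n2, equal_var: bool) -> StatResult:
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("degenerate standard deviations")
    t, p = sst.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
        name = "pooled t"
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        name = "Welch t"
    return StatResult(name=name, statistic=float(t), df=float(df), p=float(p),
                      effect={"mean_difference": m1 - m2})


def welch_t_from_summary(m1, s1, n1, m2, s2, n2) -> StatResult:
    """Welch (unequal-variance) two-sample t from summary statistics."""
    return _t_from_summary(m1, s1, n1, m2, s2, n2, equal_var=False)


def pooled_t_from_summary(m1, s1, n1, m2, s2, n2) -> StatResult:
    """Student (pooled-variance) two-sample t from summary statistics."""
    return _t_from_summary(m1, s1, n1, m2, s2, n2, equal_var=True)


def paired_t(x_before, x_after) -> StatResult:
    """Paired t-test on before/after vectors."""
    x_before = np.asarray(x_before, dtype=float)
    x_after = np.asarray(x_after, dtype=float)
    if x_before.shape != x_after.shape or x_before.size < 2:
        raise ValueError("paired t needs two equal-length vectors of n >= 2")
    d = x_before - x_after
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences: paired t is undefined "
                         "(all pairwise differences identical)")
    t, p = sst.ttest_rel(x_before, x_after)
    return StatResult(name="paired t", statistic=float(t), df=int(d.size - 1),
                      p=float(p), effect={"mean_difference": float(d.mean())})


# ----------------------------------------------------------------------
# chi-square
# ----------------------------------------------------------------------

def chi_square_2x2(a, b, c, d) -> StatResult:
    """Pearson chi-square (df = 1, *no* continuity correction) on [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: chi-square undefined")
    res = sst.chi2_contingency(table, correction=False)
    return StatResult(name="chi-square", statistic=float(res.statistic), df=1,
                      p=float(res.pvalue), effect={"table": table.tolist()})


# ----------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ----------------------------------------------------------------------

def _orthonormal_contrasts(p: int) -> np.ndarray:
    """(p, p-1) orthonormal contrast basis orthogonal to the constant vector."""
    if p < 2:
        raise ValueError("factor needs >= 2 levels")
    h = np.zeros((p, p - 1))
    for j in range(1, p):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _gg_mauchly(Z: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Greenhouse-Geisser epsilon and Mauchly test from contrast scores.

    Z is (N, q); the covariance is pooled within groups with error df N - g.
    Returns (epsilon, mauchly_W, mauchly_p).
    """
    q = Z.shape[1]
    if q == 1:
        return 1.0, 1.0, 1.0
    uniq = np.unique(groups)
    n_e = Z.shape[0] - uniq.size
    if n_e <= q:
        return 1.0, np.nan, np.nan
    S = np.zeros((q, q))
    for g in uniq:
        zg = Z[groups == g]
        dev = zg - zg.mean(axis=0)
        S += dev.T @ dev
    S /= n_e
    tr = np.trace(S)
    eps = (tr**2) / (q * np.trace(S @ S)) if tr > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    det = np.linalg.det(S)
    if det <= 0 or tr <= 0:
        return eps, np.nan, np.nan
    W = det / (tr / q) ** q
    f = 1.0 - (2 * q**2 + q + 2) / (6.0 * q * n_e)
    chi2 = -f * n_e * math.log(W)
    dfm = q * (q + 1) // 2 - 1
    return eps, float(W), float(sst.chi2.sf(chi2, dfm))


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    between: Optional[str] = None,
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA on a long-format table.

    Parameters
    ----------
    data
        Long table with one row per (subject, within-cell) observation.  The
        within-subject design must be complete and balanced; missing cells
        raise an error naming the offending subjects.
    dv, subject, within, between
        Column names of the dependent variable, the subject identifier, the
        within-subject factor(s) (one or two) and the optional
        between-subjects factor.
    alpha_sphericity
        Mauchly significance level below which the Greenhouse-Geisser
        corrected p-value is adopted as ``p_reported``.

    Returns
    -------
    DataFrame with one row per effect: F, df1/df2, uncorrected p, GG epsilon,
    Mauchly W and p, GG-corrected p, and ``p_reported`` (GG-corrected only
    when Mauchly's test is significant, mirroring the conditional rule).
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within-subject factors supported")
    levels = {w: sorted(pd.unique(data[w])) for w in within}
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full_cols = (pd.MultiIndex.from_product([levels[w] for w in within])
                 if len(within) > 1 else pd.Index(levels[within[0]]))
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any(axis=None):
        bad = sorted(wide.index[wide.isna().any(axis=1)].tolist())
        raise ValueError(f"incomplete within-subject design for subjects: {bad}")
    Y = wide.to_numpy(dtype=float)
    N = Y.shape[0]

    if between is not None:
        gmap = data.groupby(subject)[between].agg(lambda s: s.iloc[0])
        groups = gmap.reindex(wide.index).to_numpy()
        glabels = np.unique(groups)
        g = glabels.size
        if g < 2 or min((groups == lab).sum() for lab in glabels) < 2:
            raise ValueError("need >= 2 subjects in each of >= 2 groups")
    else:
        groups = np.zeros(N, dtype=int)
        glabels = np.array([0])
        g = 1

    rows = []

    # between-subjects effect on subject means
    if between is not None:
        means = Y.mean(axis=1)
        samples = [means[groups == lab] for lab in glabels]
        F, p = sst.f_oneway(*samples)
        rows.append({"effect": between, "F": float(F), "df1": g - 1, "df2": N - g,
                     "p": float(p), "eps": np.nan, "mauchly_W": np.nan,
                     "mauchly_p": np.nan, "p_gg": np.nan, "p_reported": float(p)})

    # within-subject effects (and their interaction with the between factor)
    shapes = [len(levels[w]) for w in within]
    contrasts = {w: _orthonormal_contrasts(len(levels[w])) for w in within}
    ones = {w: np.ones((len(levels[w]), 1)) / math.sqrt(len(levels[w])) for w in within}

    effects = []
    for r in range(1, len(within) + 1):
        effects.extend(itertools.combinations(within, r))

    for eff in effects:
        M = np.ones((1, 1))
        for w in within:
            M = np.kron(M, contrasts[w] if w in eff else ones[w])
        Z = Y @ M                     # (N, q) contrast scores
        q = Z.shape[1]
        gmeans = np.stack([Z[groups == lab].mean(axis=0) for lab in glabels])
        resid = np.concatenate([Z[groups == lab] - gmeans[i]
                                for i, lab in enumerate(glabels)])
        sse = float((resid**2).sum())
        df_err = q * (N - g)
        mse = sse / df_err

        # Type-III (unweighted) effect SS; with one group this is N * mean^2
        inv_n = sum(1.0 / (groups == lab).sum() for lab in glabels)
        u = gmeans.mean(axis=0)
        ss_eff = float((u**2).sum() * g**2 / inv_n)
        eps, mW, mp = _gg_mauchly(Z, groups)
        name = " * ".join(eff)
        F = (ss_eff / q) / mse
        p = float(sst.f.sf(F, q, df_err))
        p_gg = float(sst.f.sf(F, q * eps, df_err * eps))
        use_gg = np.isfinite(mp) and mp < alpha_sphericity
        rows.append({"effect": name, "F": float(F), "df1": q, "df2": df_err,
                     "p": p, "eps": eps, "mauchly_W": mW, "mauchly_p": mp,
                     "p_gg": p_gg, "p_reported": p_gg if use_gg else p})

        if between is not None:
            # group x within interaction: SS(group | intercept) per contrast,
            # i.e. RSS(common mean) - RSS(separate group means)
            wmean = Z.mean(axis=0)
            rss_red = float(((Z - wmean) ** 2).sum())
            ss_int = rss_red - sse
            df_int = q * (g - 1)
            Fi = (ss_int / df_int) / mse
            pi = float(sst.f.sf(Fi, df_int, df_err))
            pi_gg = float(sst.f.sf(Fi, df_int * eps, df_err * eps))
            rows.append({"effect": f"{between} * {name}", "F": float(Fi),
                         "df1": df_int, "df2": df_err, "p": pi, "eps": eps,
                         "mauchly_W": mW, "mauchly_p": mp, "p_gg": pi_gg,
                         "p_reported": pi_gg if use_gg else pi})

    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# nonparametric post-hocs
# ----------------------------------------------------------------------

def _check_not_all_tied(*samples) -> None:
    combined = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if np.ptp(combined) == 0:
        raise ValueError("all observations tied: rank test undefined")


def mann_whitney_u(x, y) -> StatResult:
    """Mann-Whitney U test (exact for small untied samples, else normal approx)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    _check_not_all_tied(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (max(x.size, y.size) <= 10) and not has_ties
    res = sst.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return StatResult(name="Mann-Whitney U", statistic=float(res.statistic),
                      df=(x.size, y.size), p=float(res.pvalue),
                      note="exact" if exact else "normal approximation (tie-corrected)")


def wilcoxon_signed_rank(x, y=None) -> StatResult:
    """Wilcoxon signed-rank test on paired data (or a difference vector)."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if np.ptp(d) == 0 and d.size and d[0] == 0:
        raise ValueError("all differences zero: Wilcoxon test undefined")
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all differences zero: Wilcoxon test undefined")
    has_ties = np.unique(np.abs(nz)).size < nz.size or (d == 0).any()
    exact = nz.size <= 10 and not has_ties
    res = sst.wilcoxon(d, alternative="two-sided",
                       method="exact" if exact else "approx")
    return StatResult(name="Wilcoxon signed-rank", statistic=float(res.statistic),
                      df=int(nz.size), p=float(res.pvalue),
                      note="exact" if exact else "normal approximation")


def _friedman_stat(R: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an (n, k) within-block rank matrix.

    Conover's form: T = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C) with
    A = sum of squared ranks and C = n k (k+1)^2 / 4; reduces to the textbook
    statistic when there are no ties.
    """
    n, k = R.shape
    Rj = R.sum(axis=0)
    ss = float(((Rj - n * (k + 1) / 2.0) ** 2).sum())
    A = float((R**2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    if A - C <= 0:
        raise ValueError("all observations tied within every block")
    return (k - 1) * ss / (A - C)


def friedman(*samples, exact_limit: int = 100_000) -> StatResult:
    """Friedman test across k related samples (columns = treatments).

    For small designs (k!^n below ``exact_limit``) the p-value is computed by
    exact enumeration over all within-block rank permutations; otherwise the
    chi-square approximation (with tie correction) is used.
    """
    X = np.column_stack([np.asarray(s, dtype=float) for s in samples])
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("Friedman test needs >= 2 treatments and >= 2 blocks")
    _check_not_all_tied(X)
    R = np.apply_along_axis(sst.rankdata, 1, X)
    obs = _friedman_stat(R)
    has_ties = any(np.unique(row).size < k for row in X)
    n_perm = math.factorial(k) ** n
    if n_perm <= exact_limit and not has_ties:
        perms = [np.array(p, dtype=float) for p in
                 itertools.permutations(range(1, k + 1))]
        count = total = 0
        for combo in itertools.product(range(len(perms)), repeat=n):
            Rp = np.stack([perms[i] for i in combo])
            if _friedman_stat(Rp) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        note = "exact enumeration"
    else:
        p = float(sst.chi2.sf(obs, k - 1))
        note = "chi-square approximation"
    return StatResult(name="Friedman", statistic=float(obs), df=k - 1, p=float(p),
                      note=note)
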