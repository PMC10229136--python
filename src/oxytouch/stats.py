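"""Inferential layer: one-way and mixed repeated-measures ANOVA with
partial eta-squared, Bonferroni-corrected pairwise comparisons, Spearman
correlation, bootstrap mediation, the noncentral-F sample-size solver,
chi-square independence, and exclusion accounting.

ANOVA tables are tidy DataFrames with columns
``effect, df1, df2, F, p, partial_eta_sq``.  All p-values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "one_way_anova",
    "mixed_anova",
    "bonferroni_adjust",
    "bonferroni_pairwise",
    "spearman_rho",
    "MediationResult",
    "mediate",
    "PowerSpec",
    "anova_power",
    "anova_sample_size",
    "chi_square_independence",
    "exclusion_accounting",
]

ANOVA_COLUMNS = ["effect", "df1", "df2", "F", "p", "partial_eta_sq"]


def _anova_row(effect: str, ss: float, df1: int, ss_err: float, df2: int, scale: float = 1.0) -> dict:
    # clamp floating-point dust so degenerate decompositions give F = 0
    tol = 1e-12 * max(scale, 1.0)
    ss = 0.0 if ss < tol else ss
    ss_err = 0.0 if ss_err < tol else ss_err
    ms, ms_err = ss / df1, ss_err / df2
    F = ms / ms_err if ms_err > 0 else (0.0 if ms == 0 else np.inf)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
    return {"effect": effect, "df1": df1, "df2": df2, "F": F, "p": p, "partial_eta_sq": eta}


def one_way_anova(values: Sequence[float], group_labels: Sequence[str]) -> pd.DataFrame:
    """Between-subjects one-way ANOVA with partial eta-squared.

    The returned table carries ``ms_error``, ``df_error``, group means and
    sizes in ``.attrs`` for post-hoc use.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if y.size != labels.size:
        raise ValueError("values and group_labels must have equal length")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = {g: int((labels == g).sum()) for g in groups}
    if min(ns.values()) < 2:
        raise ValueError("every group needs at least 2 observations")
    grand = y.mean()
    means = {g: float(y[labels == g].mean()) for g in groups}
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = sum(((y[labels == g] - means[g]) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, y.size - len(groups)
    table = pd.DataFrame([_anova_row("group", ss_between, df1, ss_within, df2)], columns=ANOVA_COLUMNS)
    table.attrs.update(
        ms_error=ss_within / df2, df_error=df2, group_means=means, group_sizes=ns
    )
    return table


# ---------------------------------------------------------------------------
# mixed (split-plot) repeated-measures ANOVA


def _check_balanced(data: pd.DataFrame, subject: str, within: list[str]) -> None:
    cells = data.groupby([subject, *within], observed=True).size()
    if (cells != 1).any():
        raise ValueError("each subject must have exactly one observation per within-cell")
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    per_subject = data.groupby(subject, observed=True).size()
    if (per_subject != n_cells).any():
        raise ValueError("missing within-cells for some subjects (unbalanced within design)")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str | Sequence[str],
) -> pd.DataFrame:
    """Split-plot ANOVA: one between-subject factor, one or two
    within-subject factors, subject as the error stratum.

    Sums of squares follow the classical totals decomposition (weighted
    means under unequal group sizes); each within effect is tested against
    its own factor-by-subject-within-group interaction.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise ValueError("supports one or two within factors")
    cols = [subject, between, *within_list, dv]
    df = data[cols].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in dv")
    _check_balanced(df, subject, within_list)

    grp_of = df.groupby(subject, observed=True)[between].agg(lambda s: s.iloc[0])
    if df.groupby(subject, observed=True)[between].nunique().gt(1).any():
        raise ValueError("a subject appears in more than one between-group")

    groups = sorted(df[between].unique().tolist())
    k = len(groups)
    N = df[subject].nunique()
    if N < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 groups")
    n_g = grp_of.value_counts().to_dict()
    A = within_list[0]
    p = df[A].nunique()
    B = within_list[1] if len(within_list) == 2 else None
    q = df[B].nunique() if B else 1

    y = df[dv].to_numpy(dtype=float)
    C = y.sum() ** 2 / y.size
    ss_total = (y**2).sum() - C

    def ss_of(by: list[str], divisor) -> float:
        sums = df.groupby(by, observed=True)[dv].sum()
        if callable(divisor):
            return float(sum(s**2 / divisor(idx) for idx, s in sums.items()))
        return float((sums**2 / divisor).sum())

    ng_of = lambda g: n_g[g]
    ss_g_tot = ss_of([between], lambda g: ng_of(g) * p * q)
    ss_G = ss_g_tot - C
    ss_subj_tot = ss_of([subject], p * q)
    ss_S = ss_subj_tot - ss_g_tot  # subjects within groups

    def row(effect, ss, df1, ss_err, df2):
        return _anova_row(effect, ss, df1, ss_err, df2, scale=ss_total)

    rows = [row(between, ss_G, k - 1, ss_S, N - k)]

    if p == 1 and not B:
        # single within level: the design degenerates to a between-subjects
        # one-way ANOVA; only the between effect is testable
        return pd.DataFrame(rows, columns=ANOVA_COLUMNS)

    ss_a_tot = ss_of([A], N * q)
    ss_A = ss_a_tot - C
    ss_ga_tot = ss_of([between, A], lambda ga: ng_of(ga[0]) * q)
    ss_GA = ss_ga_tot - C - ss_G - ss_A
    ss_sa_tot = ss_of([subject, A], q)
    ss_AS = ss_sa_tot - ss_subj_tot - ss_ga_tot + ss_g_tot
    df_AS = (p - 1) * (N - k)
    rows.append(row(A, ss_A, p - 1, ss_AS, df_AS))
    rows.append(row(f"{between}*{A}", ss_GA, (k - 1) * (p - 1), ss_AS, df_AS))

    if B:
        ss_b_tot = ss_of([B], N * p)
        ss_B = ss_b_tot - C
        ss_gb_tot = ss_of([between, B], lambda gb: ng_of(gb[0]) * p)
        ss_GB = ss_gb_tot - C - ss_G - ss_B
        ss_sb_tot = ss_of([subject, B], p)
        ss_BS = ss_sb_tot - ss_subj_tot - ss_gb_tot + ss_g_tot
        df_BS = (q - 1) * (N - k)
        rows.append(row(B, ss_B, q - 1, ss_BS, df_BS))
        rows.append(row(f"{between}*{B}", ss_GB, (k - 1) * (q - 1), ss_BS, df_BS))

        ss_ab_tot = ss_of([A, B], N)
        ss_AB = ss_ab_tot - C - ss_A - ss_B
        ss_gab_tot = ss_of([between, A, B], lambda gab: ng_of(gab[0]))
        ss_GAB = ss_gab_tot - C - ss_G - ss_A - ss_B - ss_GA - ss_GB - ss_AB
        ss_ABS = (
            ss_total - ss_S - ss_G - ss_A - ss_GA - ss_AS - ss_B - ss_GB - ss_BS - ss_AB - ss_GAB
        )
        df_ABS = (p - 1) * (q - 1) * (N - k)
        rows.append(row(f"{A}*{B}", ss_AB, (p - 1) * (q - 1), ss_ABS, df_ABS))
        rows.append(
            row(f"{between}*{A}*{B}", ss_GAB, (k - 1) * (p - 1) * (q - 1), ss_ABS, df_ABS)
        )

    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


# ---------------------------------------------------------------------------
# post-hoc comparisons


def bonferroni_adjust(p_raw: float | Sequence[float], m: Optional[int] = None) -> np.ndarray | float:
    """p_adjusted = min(1, m * p_raw)."""
    p = np.atleast_1d(np.asarray(p_raw, dtype=float))
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if np.isscalar(p_raw) else adj


def bonferroni_pairwise(
    means: dict[str, float],
    sizes: dict[str, int],
    ms_error: float,
    df_error: int,
    comparisons: Sequence[tuple[str, str]],
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Pairwise t-comparisons against a pooled error term, Bonferroni-adjusted."""
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    m = m if m is not None else len(comparisons)
    if m < 1:
        raise ValueError("need at least one comparison")
    rows = []
    for g1, g2 in comparisons:
        diff = means[g1] - means[g2]
        se = np.sqrt(ms_error * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        t = diff / se
        p_raw = 2 * float(sps.t.sf(abs(t), df_error))
        rows.append(
            {
                "comparison": f"{g1} - {g2}",
                "difference": diff,
                "t": t,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw),
            }
        )
    return pd.DataFrame(rows)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation (average ranks for ties) with large-sample p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * float(sps.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Three-regression mediation decomposition with bootstrap CI.

    ``a``: X->M; ``b``: M->Y adjusted for X; ``c``: total X->Y;
    ``c_prime``: direct effect; ``indirect`` = a*b.  The percentile CI and
    ``se_boot`` come from resampling subjects with replacement.
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    se_boot: float
    ci_95: tuple[float, float]
    n_boot: int
    seed: Optional[int]
    p_a: float = float("nan")
    p_b: float = float("nan")
    p_c: float = float("nan")
    p_c_prime: float = float("nan")


def _ols_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS path coefficients (with intercepts) for vectorised
    inputs; the last axis indexes observations."""
    n = x.shape[-1]
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc**2).sum(axis=-1)
    smm = (mc**2).sum(axis=-1)
    sxm = (xc * mc).sum(axis=-1)
    sxy = (xc * yc).sum(axis=-1)
    smy = (mc * yc).sum(axis=-1)
    a = sxm / sxx
    c = sxy / sxx
    det = sxx * smm - sxm**2
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return a, b, c, c_prime


def mediate(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    n_boot: int = 5000,
    seed: Optional[int] = None,
    ci_level: float = 95.0,
) -> MediationResult:
    """Bootstrap mediation of X -> M -> Y.

    Fits M~X (a), Y~X+M (c', b) and Y~X (c) by OLS; the indirect effect is
    a*b with a percentile bootstrap CI over subject resamples.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        vif = 1.0 / max(1e-12, 1 - r_xm**2)
        raise ValueError(f"M and X are collinear (variance inflation factor {vif:.1f})")

    a, b, c, c_prime = _ols_paths(x, m, y)

    # classical t-tests for the individual paths: a and c from the simple
    # regressions, b and c' from the two-predictor fit
    def simple_p(pred, resp, slope):
        pc = pred - pred.mean()
        resid = (resp - resp.mean()) - slope * pc
        dof = n - 2
        se = np.sqrt((resid**2).sum() / dof / (pc**2).sum())
        if se == 0:
            return 0.0 if slope != 0 else 1.0
        return 2 * float(sps.t.sf(abs(slope / se), dof))

    p_a = simple_p(x, m, a)
    p_c = simple_p(x, y, c)
    # b and c': two-predictor regression
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    resid = yc - c_prime * xc - b * mc
    dof = n - 3
    sigma2 = (resid**2).sum() / dof
    det = (xc**2).sum() * (mc**2).sum() - (xc * mc).sum() ** 2
    se_cp = np.sqrt(sigma2 * (mc**2).sum() / det)
    se_b = np.sqrt(sigma2 * (xc**2).sum() / det)

    def t_p(coef, se):
        if se == 0:
            return 0.0 if coef != 0 else 1.0
        return 2 * float(sps.t.sf(abs(coef / se), dof))

    p_c_prime = t_p(c_prime, se_cp)
    p_b = t_p(b, se_b)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab_boot = []
    chunk = 2000
    for start in range(0, n_boot, chunk):
        ii = idx[start : start + chunk]
        xa, ma, ya = x[ii], m[ii], y[ii]
        keep = np.ptp(xa, axis=-1) > 0
        a_b, b_b, _, _ = _ols_paths(xa[keep], ma[keep], ya[keep])
        ab_boot.append(a_b * b_b)
    ab = np.concatenate(ab_boot)
    lo, hi = np.percentile(ab, [(100 - ci_level) / 2, 100 - (100 - ci_level) / 2])
    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        c_prime=float(c_prime),
        indirect=float(a * b),
        se_boot=float(ab.std(ddof=1)),
        ci_95=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        p_a=p_a,
        p_b=p_b,
        p_c=p_c,
        p_c_prime=p_c_prime,
    )


# ---------------------------------------------------------------------------
# a-priori power


@dataclass(frozen=True)
class PowerSpec:
    k: int = 3  # number of groups
    f: float = 0.25  # Cohen's f
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.f <= 0:
            raise ValueError("f must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")


def anova_power(n_total: int, spec: PowerSpec) -> float:
    """Power of the one-way fixed-effects ANOVA at total sample size N,
    from the noncentral F distribution with ncp = f^2 * N."""
    df1, df2 = spec.k - 1, n_total - spec.k
    if df2 < 1:
        return 0.0
    fcrit = sps.f.isf(spec.alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, spec.f**2 * n_total))


def anova_sample_size(spec: PowerSpec | None = None, n_cap: int = 100000, **kwargs) -> int:
    """Smallest equally-allocated total N reaching the target power.

    Steps over N = k*m (equal group sizes, matching a priori allocation),
    returning the first N whose noncentral-F power meets the target.
    """
    spec = spec or PowerSpec(**kwargs)
    m = 2
    while spec.k * m <= n_cap:
        n_total = spec.k * m
        if anova_power(n_total, spec) >= spec.power:
            return n_total
        m += 1
    raise ValueError(f"target power {spec.power} unreachable below N = {n_cap}")


# ---------------------------------------------------------------------------
# counts


def chi_square_independence(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table of at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal total")
    expected = row @ col / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, dof, float(sps.chi2.sf(chi2, dof))


VALID_EXCLUSION_REASONS = ("incomplete", "technical")


def exclusion_accounting(roster: Iterable) -> dict:
    """Tally enrolled / excluded / analyzed counts from a subject roster.

    Accepts any iterable of objects (or mapping rows) exposing
    ``exclusion_reason`` (None for analyzed subjects).
    """
    enrolled = 0
    by_reason: dict[str, int] = {}
    for rec in roster:
        reason = rec.get("exclusion_reason") if isinstance(rec, dict) else rec.exclusion_reason
        enrolled += 1
        if reason is None or (isinstance(reason, float) and np.isnan(reason)) or reason == "none":
            continue
        if reason not in VALID_EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        by_reason[reason] = by_reason.get(reason, 0) + 1
    excluded = sum(by_reason.values())
    return {"enrolled": enrolled, "excluded": by_reason, "analyzed": enrolled - excluded}
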