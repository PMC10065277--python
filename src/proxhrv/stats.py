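"""Frequentist statistics battery with effect sizes.

Mixed-design (split-plot) ANOVA/ANCOVA with partial eta squared, Bonferroni
post hocs, Mann-Whitney U with rank-biserial correlation, chi-square,
Spearman correlations with Benjamini-Hochberg FDR, case-resampling bootstrap
regression, and simulation-based power.

All factors in the mixed design are two-level, so every effect has one
numerator degree of freedom and no sphericity machinery is needed; within
effects are tested against their own subject-by-factor error stratum via
per-subject normalised contrasts, the between effect against the
subject-means stratum.  Effect coding makes the within-effect tests
unweighted (Type III) under unequal group sizes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# effect-size identities

def partial_eta_squared(f: float, df1: float, df2: float) -> float:
    """partial eta^2 = F*df1 / (F*df1 + df2)."""
    return f * df1 / (f * df1 + df2)


def r_squared_from_f(f: float, df1: float, df2: float) -> float:
    """Model R^2 recovered from its overall F test; same identity."""
    return partial_eta_squared(f, df1, df2)


def rank_biserial_from_u(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n1*n2)."""
    if n1 < 1 or n2 < 1:
        raise DesignError("both samples must be non-empty")
    return 1.0 - 2.0 * u / (n1 * n2)


def group_mean_difference(mean_a: float, mean_b: float) -> float:
    """Difference of two group means (first minus second)."""
    return mean_a - mean_b


def summarize_groups(data: pd.DataFrame, dv: str, group: str) -> pd.DataFrame:
    """Per-group n/mean/sd plus the pairwise mean difference as an attr."""
    out = data.groupby(group)[dv].agg(n="count", mean="mean", sd="std").reset_index()
    if len(out) == 2:
        out.attrs["mean_difference"] = group_mean_difference(
            float(out["mean"].iloc[0]), float(out["mean"].iloc[1])
        )
    return out


# ---------------------------------------------------------------------------
# mixed-design ANOVA / ANCOVA

@dataclass(frozen=True)
class AnovaTable:
    """Per-effect F table with partial eta squared.

    Columns: effect, sum_sq, df1, df2, F, p, partial_eta_sq.  The eta
    identity ``partial_eta_sq == F*df1/(F*df1+df2)`` is asserted on
    construction.
    """

    table: pd.DataFrame
    dropped_subjects: tuple[str, ...] = ()

    def __post_init__(self):
        expected = partial_eta_squared(
            self.table["F"].to_numpy(),
            self.table["df1"].to_numpy(),
            self.table["df2"].to_numpy(),
        )
        if not np.allclose(self.table["partial_eta_sq"].to_numpy(), expected, atol=1e-10):
            raise AssertionError("partial eta squared identity violated")
        if ((self.table["p"] < 0) | (self.table["p"] > 1)).any():
            raise AssertionError("p values out of [0, 1]")

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def _two_levels(data: pd.DataFrame, col: str) -> list:
    levels = sorted(pd.unique(data[col].dropna()))
    if len(levels) != 2:
        raise DesignError(
            f"factor {col!r} has {len(levels)} levels; only two-level designs are supported"
        )
    return levels


def _ols_t(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Coefficient t statistics, residual SS and df of an OLS fit."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise DesignError("design matrix is rank deficient")
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = n - p
    if df <= 0:
        raise DesignError("not enough subjects for the requested model")
    mse = sse / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return t, sse, df


def _stratum_rows(
    names: Sequence[str], t: np.ndarray, sse: float, df: int, which: Mapping[str, int]
) -> list[dict]:
    mse = sse / df
    rows = []
    for name, j in which.items():
        F = float(t[j] ** 2)
        rows.append(
            {
                "effect": name,
                "sum_sq": F * mse,
                "df1": 1,
                "df2": df,
                "F": F,
                "p": float(sps.f.sf(F, 1, df)),
                "partial_eta_sq": partial_eta_squared(F, 1, df),
            }
        )
    return rows


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: Sequence[str] = (),
    covariates: Sequence[str] = (),
) -> AnovaTable:
    """Split-plot ANOVA: one two-level between factor, 0-2 two-level within
    factors, optional covariates in the between-subject stratum (ANCOVA).

    Expects long-format data with one row per subject x within-cell.
    Subjects with any missing cell (or missing covariate) are dropped
    listwise and recorded on the returned table.
    """
    blevels = _two_levels(data, between)
    wlevels = {w: _two_levels(data, w) for w in within}
    cells = list(itertools.product(*wlevels.values())) if within else [()]

    if within:
        wide = data.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells) if len(within) > 1 else
                            [c[0] for c in cells])
    else:
        wide = data.groupby(subject)[dv].mean().to_frame()

    subj_info = data.drop_duplicates(subject).set_index(subject)
    if subj_info.groupby(level=0).size().max() > 1:  # pragma: no cover - defensive
        raise DesignError("a subject maps to multiple metadata rows")
    group = subj_info[between].reindex(wide.index)
    cov = subj_info[list(covariates)].reindex(wide.index) if covariates else None

    complete = wide.notna().all(axis=1) & group.notna()
    if cov is not None:
        complete &= cov.notna().all(axis=1)
    dropped = tuple(str(s) for s in wide.index[~complete])
    if dropped:
        logger.info("mixed_anova: dropping %d incomplete subject(s): %s", len(dropped), dropped)
    wide, group = wide[complete], group[complete]
    if cov is not None:
        cov = cov[complete]

    counts = group.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise DesignError("need at least 2 complete subjects per group")

    Y = wide.to_numpy(dtype=float)
    n, C = Y.shape
    g_code = np.where(group.to_numpy() == blevels[0], 1.0, -1.0)

    rows: list[dict] = []
    # between-subject stratum: subject means (scaled back to cell units by C)
    m = Y.mean(axis=1) * math.sqrt(C)
    Xb = np.column_stack([np.ones(n), g_code])
    bnames = {between: 1}
    if cov is not None:
        cov_z = cov.to_numpy(dtype=float)
        cov_z = cov_z - cov_z.mean(axis=0)
        Xb = np.column_stack([Xb, cov_z])
        for j, c in enumerate(covariates):
            bnames[c] = 2 + j
    t, sse, dfb = _ols_t(m, Xb)
    rows += _stratum_rows([between], t, sse, dfb, bnames)

    # within strata: one normalised contrast per within-effect subset
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            signs = np.array(
                [
                    np.prod([1.0 if cell[within.index(w)] == wlevels[w][0] else -1.0
                             for w in combo])
                    for cell in cells
                ]
            )
            z = (Y @ signs) / math.sqrt(C)
            Xw = np.column_stack([np.ones(n), g_code])
            t, sse, dfw = _ols_t(z, Xw)
            base = " * ".join(combo)
            rows += _stratum_rows(
                [base], t, sse, dfw, {base: 0, f"{base} * {between}": 1}
            )

    return AnovaTable(table=pd.DataFrame(rows), dropped_subjects=dropped)


# ---------------------------------------------------------------------------
# post hoc comparisons

def bonferroni_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Multiply by family size and cap at 1; empty family is an error."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise DesignError("empty comparison family")
    return np.minimum(p * p.size, 1.0)


def bonferroni_posthoc(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str | None = None,
    by: str | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Pairwise t comparisons of ``factor``'s two levels, Bonferroni adjusted.

    Run within each level of ``by`` (e.g. per group) when given; the family
    is the full set of comparisons produced.  ``paired=True`` aligns the two
    levels on ``subject`` and uses a paired t test; otherwise a pooled
    two-sample t test is used.
    """
    levels = _two_levels(data, factor)
    strata = sorted(pd.unique(data[by].dropna())) if by else [None]
    rows = []
    for stratum in strata:
        sub = data if stratum is None else data[data[by] == stratum]
        if paired:
            if subject is None:
                raise DesignError("paired comparisons need a subject column")
            wide = sub.pivot_table(index=subject, columns=factor, values=dv).dropna()
            a, b = wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy()
            t, p = sps.ttest_rel(a, b)
            df = a.size - 1
        else:
            a = sub.loc[sub[factor] == levels[0], dv].dropna().to_numpy()
            b = sub.loc[sub[factor] == levels[1], dv].dropna().to_numpy()
            t, p = sps.ttest_ind(a, b, equal_var=True)
            df = a.size + b.size - 2
        rows.append(
            {
                "stratum": "all" if stratum is None else stratum,
                "contrast": f"{levels[0]} - {levels[1]}",
                "t": float(t),
                "df": df,
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni_adjust(out["p_raw"])
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney with rank-biserial effect size

@dataclass(frozen=True)
class EffectSizeResult:
    """Mann-Whitney U with rank-biserial r and a Fisher-z confidence interval.

    ``u`` counts pairs where the first sample is below the second (plus half
    of ties), so r > 0 means the first sample tends to be larger.  The CI
    method (Fisher z with se = sqrt((n1+n2+1)/(3 n1 n2))) is a documented
    convention, not a claim about the source analysis.
    """

    u: float
    rank_biserial_r: float
    ci_low: float
    ci_high: float
    p: float
    n1: int
    n2: int

    def __post_init__(self):
        expected = rank_biserial_from_u(self.u, self.n1, self.n2)
        if abs(self.rank_biserial_r - expected) > 1e-12:
            raise AssertionError("rank-biserial identity violated")


def mann_whitney_rb(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> EffectSizeResult:
    """Two-sided Mann-Whitney U test with rank-biserial correlation.

    Exact enumeration is used for tie-free samples of at most 20 per group,
    the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DesignError("both samples must be non-empty")
    n1, n2 = int(x.size), int(y.size)
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    method = "exact" if (not has_ties and max(n1, n2) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(y, x, alternative="two-sided", method=method)
    u = float(res.statistic)  # pairs with x below y (+ half ties)
    r = rank_biserial_from_u(u, n1, n2)
    z_crit = sps.norm.ppf(0.5 + ci_level / 2)
    se_z = math.sqrt((n1 + n2 + 1) / (3.0 * n1 * n2))
    r_clip = min(max(r, -1 + 1e-12), 1 - 1e-12)
    zr = math.atanh(r_clip)
    return EffectSizeResult(
        u=u,
        rank_biserial_r=r,
        ci_low=math.tanh(zr - z_crit * se_z),
        ci_high=math.tanh(zr + z_crit * se_z),
        p=float(res.pvalue),
        n1=n1,
        n2=n2,
    )


# ---------------------------------------------------------------------------
# chi-square

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    dof: int
    expected: np.ndarray


def chi_square(contingency, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a table of counts, no continuity correction by
    default (the convention consistent with the reported group comparison);
    pass ``correction=True`` for the Yates-corrected variant."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise DesignError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise DesignError("counts must be non-negative")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise DesignError("an expected cell count is zero; test undefined")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=correction)[:4]
    return ChiSquareResult(statistic=float(stat), p=float(p), dof=int(dof), expected=expected)


# ---------------------------------------------------------------------------
# Spearman matrix with BH-FDR

@dataclass(frozen=True)
class CorrelationReport:
    """Spearman rho/p/q matrices over a variable set.

    q values come from Benjamini-Hochberg step-up over the unique
    off-diagonal pairs with defined correlations; ``flagged`` lists
    variables whose correlations are undefined (constant input).
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    level: float
    flagged: tuple[str, ...] = ()


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, >= raw p)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def spearman_fdr(
    variables: pd.DataFrame, level: float = 0.05, min_n: int = 3
) -> CorrelationReport:
    """Pairwise-complete Spearman correlations with BH-FDR control.

    Pairs with fewer than ``min_n`` complete observations, or involving a
    constant variable, get NaN rho/p and are excluded from the FDR family.
    """
    cols = list(variables.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    np.fill_diagonal(rho, 1.0)
    flagged = set()
    for i, j in itertools.combinations(range(k), 2):
        pair = variables[[cols[i], cols[j]]].dropna()
        if len(pair) < min_n:
            continue
        a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            flagged.add(cols[i] if np.unique(a).size < 2 else cols[j])
            continue
        r, p = sps.spearmanr(a, b)
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
    iu = np.triu_indices(k, 1)
    family = ~np.isnan(pmat[iu])
    qmat = np.full((k, k), np.nan)
    if family.any():
        q_up = np.full(family.size, np.nan)
        q_up[family] = bh_qvalues(pmat[iu][family])
        qmat[iu] = q_up
        qmat[(iu[1], iu[0])] = q_up
    if flagged:
        logger.warning("constant variable(s), correlations undefined: %s", sorted(flagged))
    as_df = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationReport(
        rho=as_df(rho),
        p=as_df(pmat),
        q=as_df(qmat),
        significant=as_df(qmat <= level),
        level=level,
        flagged=tuple(sorted(flagged)),
    )


# ---------------------------------------------------------------------------
# bootstrap regression

@dataclass(frozen=True)
class RegressionResult:
    """OLS point fit with case-resampling bootstrap uncertainty.

    ``params`` columns: estimate, bootstrap_se, ci_low, ci_high, p (two-sided
    normal approximation from the bootstrap SE).  Model F/df/R^2 come from
    the point fit; the ``r_squared == F*df1/(F*df1+df2)`` identity is
    asserted on construction.
    """

    params: pd.DataFrame
    f: float
    df1: int
    df2: int
    r_squared: float
    n_boot: int
    seed: int | None

    def __post_init__(self):
        if self.df1 > 0 and np.isfinite(self.f):
            expected = r_squared_from_f(self.f, self.df1, self.df2)
            if abs(self.r_squared - expected) > 1e-10:
                raise AssertionError("R^2 identity violated")


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[j] for j in np.flatnonzero(diag < tol)]


def bootstrap_regression(
    y,
    X: pd.DataFrame,
    n_boot: int = 10000,
    seed: int | None = None,
    ci_level: float = 0.95,
    add_intercept: bool = True,
) -> RegressionResult:
    """OLS with case-resampling bootstrap SEs and percentile CIs.

    ``X`` is a named design matrix (an intercept column is prepended unless
    ``add_intercept=False``).  Rank-deficient designs are rejected with the
    offending columns named.  Deterministic under ``seed``.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = pd.concat([pd.Series(1.0, index=X.index, name="intercept"), X], axis=1)
    names = list(X.columns)
    Xm = X.to_numpy()
    n, p = Xm.shape
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(Xm) < p:
        bad = _collinear_columns(Xm, names)
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta = np.linalg.lstsq(Xm, y, rcond=None)[0]
    resid = y - Xm @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df1 = p - 1 if add_intercept else p
    df2 = n - p
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    if df1 > 0 and sse > 0:
        f = (sst - sse) / df1 / (sse / df2) if add_intercept else math.nan
    else:
        f = math.inf if sse == 0 else math.nan

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Xb = Xm[idx]                      # (B, n, p)
    yb = y[idx][..., None]            # (B, n, 1)
    boot = (np.linalg.pinv(Xb) @ yb)[..., 0]  # (B, p)
    se = boot.std(axis=0, ddof=1)
    alpha = 1.0 - ci_level
    ci = np.quantile(boot, [alpha / 2, 1 - alpha / 2], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.norm.sf(np.abs(zstat))
    params = pd.DataFrame(
        {
            "estimate": beta,
            "bootstrap_se": se,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": pvals,
        },
        index=names,
    )
    return RegressionResult(
        params=params, f=float(f), df1=df1, df2=df2,
        r_squared=float(r2), n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation-based power

@dataclass(frozen=True)
class PowerResult:
    rejection_rate: float
    mc_se: float
    n_reps: int
    alpha: float


def _pooled_t_p(x: np.ndarray, y: np.ndarray) -> float:
    return float(sps.ttest_ind(x, y, equal_var=True).pvalue)


def _welch_t_p(x: np.ndarray, y: np.ndarray) -> float:
    return float(sps.ttest_ind(x, y, equal_var=False).pvalue)


def _mw_p(x: np.ndarray, y: np.ndarray) -> float:
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


_POWER_TESTS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "pooled_t": _pooled_t_p,
    "welch_t": _welch_t_p,
    "mann_whitney": _mw_p,
}


def power_simulation(
    group_params: Sequence[tuple[float, float, int]],
    test: str | Callable[[np.ndarray, np.ndarray], float] = "pooled_t",
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PowerResult:
    """Monte-Carlo power of a two-group comparison.

    ``group_params`` is two (mean, sd, n) triples; cohorts are drawn from
    the corresponding normals, the test is run, and the rejection fraction
    is returned with its binomial MC standard error.
    """
    if n_reps < 100:
        raise DesignError("n_reps must be at least 100 for a usable estimate")
    if len(group_params) != 2:
        raise DesignError("exactly two groups are supported")
    p_of = _POWER_TESTS[test] if isinstance(test, str) else test
    (m1, s1, n1), (m2, s2, n2) = group_params
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(m1, s1, n1)
        y = rng.normal(m2, s2, n2)
        if p_of(x, y) < alpha:
            rejections += 1
    rate = rejections / n_reps
    return PowerResult(
        rejection_rate=rate,
        mc_se=math.sqrt(max(rate * (1 - rate), 1.0 / n_reps) / n_reps),
        n_reps=n_reps,
        alpha=alpha,
    )
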