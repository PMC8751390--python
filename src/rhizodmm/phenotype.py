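"""Plant-performance statistics for the microbiome-inoculation experiment.

Plants of four genotypes grown in substrate inoculated with microbiomes
conditioned by each of the four genotypes, in blocks: the questions are
whether the inoculum (the microbiome's previous host), the plant's own
genotype, and block shift biomass.  Analyses: fixed-effect three-way
ANOVA (main effects only: inoculum + genotype + block, sequential sums
of squares), residualization over genotype+block for display, Tukey HSD
on inoculum means using the full-model residual mean square, and
planned (unadjusted) pairwise contrasts of inoculum levels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range, t as t_dist

DEFAULT_FACTORS = ("inoculum", "genotype", "block")


def _clean(tbl: pd.DataFrame, response: str, factors) -> pd.DataFrame:
    missing = [c for c in (*factors, response) if c not in tbl.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    df = tbl.dropna(subset=[response]).copy()
    for f in factors:
        df[f] = df[f].astype(str)
    return df


def _fit_ols(df: pd.DataFrame, response: str, factors):
    formula = f"Q('{response}') ~ " + " + ".join(f"C({f})" for f in factors)
    return smf.ols(formula, data=df).fit()


def fit_anova3(tbl: pd.DataFrame, response: str,
               factors=DEFAULT_FACTORS, interaction: bool = False) -> pd.DataFrame:
    """Fixed-effect main-effects ANOVA with sequential (type I) SS.

    Term order is the order of ``factors`` (inoculum, genotype, block
    by default); on balanced data sequential and marginal sums of
    squares coincide.  ``interaction=True`` adds the genotype x
    inoculum interaction term.  Rows with a missing response are
    dropped listwise.
    """
    df = _clean(tbl, response, factors)
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    formula = f"Q('{response}') ~ " + " + ".join(f"C({f})" for f in factors)
    if interaction:
        formula += " + C(genotype):C(inoculum)"
    model = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design (aliased factor levels)")
    constant = np.allclose(df[response].var(ddof=1), 0.0)
    if constant:
        warnings.warn("constant response: all sums of squares are 0, F undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=1)
    if constant:
        table["sum_sq"] = 0.0
        table["mean_sq"] = 0.0
        table["F"] = np.nan
        table["PR(>F)"] = np.nan
    table = table.rename(
        index=lambda s: s.replace("C(", "").replace(")", "").replace("Q('", "").replace("'", "")
    )
    table.index.name = "term"
    table.attrs["model"] = model
    return table


def residualize(tbl: pd.DataFrame, response: str,
                remove=("genotype", "block")) -> pd.Series:
    """Residuals after removing nuisance factors by least squares.

    The display convention for inoculum effects: regress the response
    on genotype + block only and plot the residual means by inoculum.
    """
    df = _clean(tbl, response, remove)
    model = _fit_ols(df, response, remove)
    return pd.Series(model.resid, index=df.index, name=f"resid_{response}")


def residual_means_by_inoculum(tbl: pd.DataFrame, response: str,
                               remove=("genotype", "block")) -> pd.DataFrame:
    """Mean +/- SE of genotype/block-adjusted residuals per inoculum."""
    res = residualize(tbl, response, remove)
    df = tbl.loc[res.index].assign(resid=res)
    out = df.groupby("inoculum")["resid"].agg(["mean", "sem", "count"])
    out.columns = ["mean", "se", "n"]
    return out


def tukey_hsd(tbl: pd.DataFrame, response: str, factor: str = "inoculum",
              model_factors=DEFAULT_FACTORS, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD on factor level means.

    Uses the residual mean square and df of the full main-effects model
    (Tukey-Kramer form for unequal level sizes); adjusted p-values come
    from the studentized-range distribution.  A compact letter display
    is attached: levels sharing a letter do not differ at ``alpha``.
    """
    factors = tuple(dict.fromkeys((factor, *model_factors)))
    usable = [f for f in factors if f in tbl.columns and tbl[f].astype(str).nunique() > 1]
    if factor not in usable:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    df = _clean(tbl, response, usable)
    sizes = df.groupby(factor)[response].count()
    if (sizes < 2).any():
        raise ValueError(f"levels with <2 observations: {list(sizes.index[sizes < 2])}")
    model = _fit_ols(df, response, usable)
    mse = model.mse_resid
    dfres = model.df_resid
    means = df.groupby(factor)[response].mean()
    levels = list(means.index)
    k = len(levels)
    rows = []
    for a, b in [(levels[i], levels[j]) for i in range(k) for j in range(i + 1, k)]:
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2 * (1 / sizes[a] + 1 / sizes[b]))
        q = abs(diff) / se
        p_adj = float(studentized_range.sf(q, k, dfres))
        rows.append({"level_1": a, "level_2": b, "diff": diff, "se": se,
                     "q": q, "p_adj": p_adj, "reject": p_adj < alpha})
    table = pd.DataFrame(rows)
    table.attrs["letters"] = compact_letters(levels, table, alpha)
    table.attrs["mse"] = float(mse)
    table.attrs["df_resid"] = float(dfres)
    return table


def compact_letters(levels, pairwise: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Greedy compact letter display from a pairwise comparison table.

    Levels connected by non-significant comparisons (p_adj >= alpha)
    share a letter; each maximal connected set gets its own letter in
    level order.
    """
    levels = list(levels)
    nonsig = {frozenset((r.level_1, r.level_2)) for r in pairwise.itertuples()
              if r.p_adj >= alpha}

    def compatible(group, lvl):
        return all(frozenset((m, lvl)) in nonsig for m in group)

    groups = []
    for lvl in levels:
        placed = False
        for grp in groups:
            if compatible(grp, lvl):
                grp.append(lvl)
                placed = True
        if not placed:
            groups.append([lvl])
    letters = {lvl: "" for lvl in levels}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lvl in grp:
            letters[lvl] += letter
    return pd.Series(letters, name="letters")


def planned_contrast(tbl: pd.DataFrame, response: str, pair,
                     factor: str = "inoculum",
                     model_factors=DEFAULT_FACTORS):
    """Planned single-df contrast of two factor level means.

    Uses the full main-effects model residual variance; the p-value is
    unadjusted (a planned comparison, not post hoc).  Returns
    ``(estimate, t, p)`` with estimate = mean(level1) - mean(level2).
    """
    a, b = pair
    factors = tuple(dict.fromkeys((factor, *model_factors)))
    usable = [f for f in factors if f in tbl.columns and tbl[f].astype(str).nunique() > 1]
    df = _clean(tbl, response, usable)
    for lvl in (a, b):
        if lvl not in set(df[factor]):
            raise ValueError(f"level {lvl!r} not present in {factor!r}")
    model = _fit_ols(df, response, usable)
    means = df.groupby(factor)[response].mean()
    sizes = df.groupby(factor)[response].count()
    est = means[a] - means[b]
    se = np.sqrt(model.mse_resid * (1 / sizes[a] + 1 / sizes[b]))
    t_stat = est / se
    p = float(2 * t_dist.sf(abs(t_stat), model.df_resid))
    return float(est), float(t_stat), p
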