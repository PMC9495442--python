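"""Group-comparison statistics: gated parametric/nonparametric tests,
partial eta-squared effect sizes, and ANOSIM.

The univariate battery mirrors common soil-ecology practice: Shapiro-Wilk
per group and Levene's test gate the choice between the parametric branch
(t-test / one-way ANOVA) and the rank branch (Mann-Whitney rank-sum /
Kruskal-Wallis).  "Wilcoxon test" between independent plots is the
Mann-Whitney form.  Permutation p-values use the add-one estimator and
are therefore never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FunctionTable, SampleDesign, ValidationError


@dataclass
class TestResult:
    test: str  # one of t, ANOVA, Wilcoxon, Kruskal-Wallis
    statistic: float
    pvalue: float
    gate_passed: bool | None
    shapiro_p: dict[str, float] = field(default_factory=dict)
    levene_p: float | None = None
    warnings: list[str] = field(default_factory=list)


def auto_group_test(values, labels, alpha: float = 0.05) -> TestResult:
    """Choose and run the appropriate difference test for >=2 groups.

    Gate: all per-group Shapiro-Wilk p > alpha AND Levene p > alpha.
    Two groups -> t-test (gate passed) or Mann-Whitney rank-sum; more
    groups -> one-way ANOVA or Kruskal-Wallis.  Groups with fewer than 3
    observations skip the gate and fall back to the rank branch.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    group_names = [g for g in pd.unique(labels)]
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == g] for g in group_names]
    warns: list[str] = []

    gate: bool | None
    shapiro_p: dict[str, float] = {}
    levene_p: float | None = None
    if min(len(g) for g in groups) < 3:
        gate = None
        warns.append("a group has <3 samples: gate skipped, rank test used")
    else:
        ok = True
        for name, g in zip(group_names, groups):
            if np.ptp(g) == 0:
                shapiro_p[str(name)] = 0.0  # degenerate: treat as non-normal
                ok = False
                continue
            p = float(stats.shapiro(g).pvalue)
            shapiro_p[str(name)] = p
            ok = ok and p > alpha
        lev = stats.levene(*groups, center="mean")
        levene_p = float(lev.pvalue) if np.isfinite(lev.pvalue) else 1.0
        gate = ok and levene_p > alpha

    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # identical constant groups: nothing to test
        name = "Wilcoxon" if len(groups) == 2 else "Kruskal-Wallis"
        return TestResult(name, 0.0, 1.0, gate, shapiro_p, levene_p, warns)

    if gate:
        if len(groups) == 2:
            res = stats.ttest_ind(groups[0], groups[1], equal_var=True)
            return TestResult(
                "t", float(res.statistic), float(res.pvalue), gate, shapiro_p,
                levene_p, warns,
            )
        res = stats.f_oneway(*groups)
        return TestResult(
            "ANOVA", float(res.statistic), float(res.pvalue), gate, shapiro_p,
            levene_p, warns,
        )
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return TestResult(
            "Wilcoxon", float(res.statistic), float(res.pvalue), gate, shapiro_p,
            levene_p, warns,
        )
    try:
        res = stats.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    except ValueError:  # all observations identical
        stat, p = 0.0, 1.0
    return TestResult("Kruskal-Wallis", stat, p, gate, shapiro_p, levene_p, warns)


def partial_eta_squared(
    fn: FunctionTable | pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Two-way (plant x system) partial eta-squared per response.

    eta_p^2 = SS_effect / (SS_effect + SS_residual) from the two-way ANOVA
    decomposition with interaction (type II sums of squares; for the
    balanced design all types coincide).  Returns one row per function with
    columns ``plant``, ``system`` and ``interaction``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    values = fn.values if isinstance(fn, FunctionTable) else fn
    labels = design.frame.reindex(values.index)
    if labels[["plant", "system"]].isna().any().any():
        missing = labels.index[labels["plant"].isna()].tolist()
        raise ValidationError(f"samples absent from design: {missing}")
    cells = labels.groupby(["plant", "system"]).size()
    n_plants = labels["plant"].nunique()
    n_systems = labels["system"].nunique()
    if len(cells) < n_plants * n_systems:
        raise ValidationError("every plant x system cell needs observations")
    if len(values) - n_plants * n_systems <= 0:
        raise ValidationError("no residual degrees of freedom (need replicates)")

    rows = {}
    for col in values.columns:
        df = pd.DataFrame(
            {
                "y": values[col].to_numpy(),
                "plant": labels["plant"].to_numpy(),
                "system": labels["system"].to_numpy(),
            }
        )
        model = smf.ols("y ~ C(plant) * C(system)", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-residual fits warn in anova_lm
            table = sm.stats.anova_lm(model, typ=2)
        ss = table["sum_sq"]
        ss_res = float(ss["Residual"])
        # numerical floor: sums of squares below this fraction of the total
        # are treated as exactly zero (noise-free fits leave ~1e-30 residue)
        tol = 1e-10 * max(float(ss.sum()), np.finfo(float).tiny)
        if ss_res < tol:
            ss_res = 0.0
        out = {}
        for effect, key in (
            ("plant", "C(plant)"),
            ("system", "C(system)"),
            ("interaction", "C(plant):C(system)"),
        ):
            ss_eff = float(ss[key])
            out[effect] = 0.0 if ss_eff < tol else ss_eff / (ss_eff + ss_res)
        rows[col] = out
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class AnosimResult:
    R: float
    pvalue: float
    n_permutations: int


def anosim(
    dist, labels, n_permutations: int = 9999, seed: int | None = None
) -> AnosimResult:
    """Analysis of similarities on a square distance matrix.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2) with M = n(n-1)/2, ranks averaged over ties.  The
    p-value permutes group labels: p = (#{R_perm >= R_obs} + 1) /
    (n_permutations + 1).
    """
    if isinstance(dist, pd.DataFrame):
        dist = dist.to_numpy()
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels must match the distance matrix")
    if len(pd.unique(labels)) < 2:
        raise ValueError("ANOSIM needs at least two groups")

    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(D[iu])
    half_m = len(ranks) / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / half_m)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AnosimResult(R=r_obs, pvalue=p, n_permutations=n_permutations)
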