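"""Multifunctionality indices and the trade-off-intensity statistic.

Each measured function is z-scored across samples; an averaging-approach
multifunctionality index is the mean of a member set of standardized
functions (CCMF, NCMF, PCMF over the C/N/P-cycling members, AEMF over
all).  The trade-off intensity between two standardized properties is the
geometric distance of the sample's (x, y) point from the 1:1 line,
d = |x - y| / sqrt(2): zero means perfectly balanced functions, and the
statistic is symmetric and scales linearly with the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .tables import FunctionTable, SampleDesign, ValidationError

SQRT2 = np.sqrt(2.0)


def zscore_standardize(values: FunctionTable | pd.DataFrame) -> pd.DataFrame:
    """Standardize each function column to mean 0, sample SD 1 (ddof=1)."""
    if isinstance(values, FunctionTable):
        values = values.values
    sd = values.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        raise ValidationError(
            f"cannot z-score constant function column(s): {dead}"
        )
    return (values - values.mean(axis=0)) / sd


def multifunctionality(z: pd.DataFrame, members) -> pd.Series:
    """Row mean of the member z-columns for each sample."""
    members = list(members)
    if not members:
        raise ValueError("empty multifunctionality member list")
    missing = [m for m in members if m not in z.columns]
    if missing:
        raise KeyError(f"member function(s) not in table: {missing}")
    return z[members].mean(axis=1)


def multifunctionality_indices(
    fn: FunctionTable, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-sample CCMF/NCMF/PCMF/AEMF from one shared z-score table.

    Member functions missing from the table are silently dropped from the
    index (a table with only C-cycle columns still yields CCMF).
    """
    cfg = cfg or AnalysisConfig()
    z = zscore_standardize(fn)
    out = {}
    for name, members in cfg.function_groups.items():
        present = [m for m in members if m in z.columns]
        if present:
            out[name] = multifunctionality(z, present)
    return pd.DataFrame(out, index=fn.values.index)


def tradeoff_intensity(x, y):
    """Distance from (x, y) to the 1:1 line, |x - y| / sqrt(2); vectorized."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("trade-off intensity requires finite inputs")
    return np.abs(x - y) / SQRT2


def _pair_distance_matrix(z: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """All C(m,2) per-sample trade-off intensities, one row per pair."""
    cols = list(z.columns)
    pairs = list(itertools.combinations(range(len(cols)), 2))
    X = z.to_numpy()
    d = np.abs(X[:, [i for i, _ in pairs]] - X[:, [j for _, j in pairs]]) / SQRT2
    return d.T, [(cols[i], cols[j]) for i, j in pairs]


def mean_pairwise_tradeoff(z: pd.DataFrame) -> pd.Series:
    """Per-sample mean trade-off intensity over all function pairs."""
    d, _ = _pair_distance_matrix(z)
    if d.shape[0] == 0:
        raise ValueError("need at least two functions for trade-off analysis")
    return pd.Series(d.mean(axis=0), index=z.index, name="tradeoff")


@dataclass
class TradeoffResult:
    """Distribution of the k-pair mean trade-off intensity across draws."""

    k: int
    n_pairs_total: int
    draws: pd.DataFrame  # draws x samples
    exhaustive: bool

    @property
    def per_sample_mean(self) -> pd.Series:
        return self.draws.mean(axis=0)

    @property
    def per_sample_var(self) -> pd.Series:
        if self.exhaustive or len(self.draws) < 2:
            return pd.Series(0.0, index=self.draws.columns)
        return self.draws.var(axis=0, ddof=1)


def tradeoff_profile(
    z: pd.DataFrame,
    k: int,
    n_draws: int = 200,
    seed: int | None = None,
) -> TradeoffResult:
    """Sample k function pairs (uniform, without replacement) ``n_draws``
    times; per draw and sample, record the mean trade-off intensity.

    When k equals the total number of pairs the evaluation is exhaustive
    (a single draw with zero sampling variance).
    """
    d, pairs = _pair_distance_matrix(z)
    total = len(pairs)
    if not (1 <= k <= total):
        raise ValueError(f"k must be in [1, {total}], got {k}")
    if k == total:
        draws = pd.DataFrame(
            d.mean(axis=0)[None, :], columns=z.index, index=[0]
        )
        return TradeoffResult(k, total, draws, exhaustive=True)
    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, z.shape[0]))
    for i in range(n_draws):
        chosen = rng.choice(total, size=k, replace=False)
        out[i] = d[chosen].mean(axis=0)
    draws = pd.DataFrame(out, columns=z.index, index=range(n_draws))
    return TradeoffResult(k, total, draws, exhaustive=False)


def tradeoff_grid(
    z: pd.DataFrame,
    ks,
    n_draws: int = 200,
    seed: int | None = None,
) -> dict[int, TradeoffResult]:
    rng = np.random.default_rng(seed)
    return {
        int(k): tradeoff_profile(z, int(k), n_draws, seed=int(rng.integers(2**31)))
        for k in ks
    }


def compare_group_tradeoffs(
    results: TradeoffResult | dict[int, TradeoffResult],
    design: SampleDesign,
    group_pairs=None,
) -> pd.DataFrame:
    """Rank-sum (Mann-Whitney) comparison of per-sample trade-off means
    between groups, one row per (group pair, k)."""
    if isinstance(results, TradeoffResult):
        results = {results.k: results}
    groups = design.groups
    if group_pairs is None:
        group_pairs = list(itertools.combinations(groups, 2))
    rows = []
    for k, res in sorted(results.items()):
        values = res.per_sample_mean
        labels = design.group_labels(values.index)
        for g1, g2 in group_pairs:
            for g in (g1, g2):
                if g not in groups:
                    raise ValueError(f"group {g!r} absent from design")
            a = values[labels == g1].to_numpy()
            b = values[labels == g2].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"need >=2 samples per group for {g1} vs {g2}")
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "k": k,
                    "statistic": float(stat),
                    "pvalue": float(p),
                }
            )
    return pd.DataFrame(rows)
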