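"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity from first principles (full enumeration
or explicit sums of squares), deliberately sharing no code with the
implementation it checks.
"""

import math
from itertools import combinations, permutations

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist


def mantel_exhaustive(features, response, zscore=True):
    """Exact one-sided Mantel p by enumerating all n! sample orders."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if zscore:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    d1 = pdist(X)
    D2 = np.abs(y[:, None] - y[None, :])

    def sp(perm):
        d2 = D2[np.ix_(perm, perm)][np.triu_indices(n, 1)]
        return stats.spearmanr(d1, d2).statistic

    identity = tuple(range(n))
    r_obs = sp(identity)
    count = sum(sp(p) >= r_obs for p in permutations(range(n)))
    return r_obs, count / math.factorial(n)


def anosim_exhaustive(dist, labels):
    """Exact ANOSIM p over all label orderings (duplicates included)."""
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(D[iu])
    half_m = len(ranks) / 2.0
    labels = np.asarray(labels)

    def r_stat(lab):
        lab = np.asarray(lab)
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / half_m

    r_obs = r_stat(labels)
    rs = [r_stat(perm) for perm in permutations(labels)]
    p = sum(r >= r_obs for r in rs) / len(rs)
    return r_obs, p


def eta2_bruteforce(y, plant, system):
    """Partial eta-squared from explicit balanced two-way sums of squares."""
    y = np.asarray(y, dtype=float)
    plant = np.asarray(plant)
    system = np.asarray(system)
    grand = y.mean()
    plants = np.unique(plant)
    systems = np.unique(system)
    ss_plant = sum(
        (plant == p).sum() * (y[plant == p].mean() - grand) ** 2 for p in plants
    )
    ss_system = sum(
        (system == s).sum() * (y[system == s].mean() - grand) ** 2 for s in systems
    )
    ss_cells = 0.0
    ss_res = 0.0
    for p in plants:
        for s in systems:
            cell = y[(plant == p) & (system == s)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_res += ((cell - cell.mean()) ** 2).sum()
    ss_int = ss_cells - ss_plant - ss_system

    def eta(ss):
        return 0.0 if ss <= 1e-300 else ss / (ss + ss_res)

    return eta(ss_plant), eta(ss_system), eta(ss_int)


def network_bruteforce(matrix, r_threshold, q_threshold):
    """All-pairs Pearson + BH edge set from scipy/statsmodels primitives."""
    from statsmodels.stats.multitest import multipletests

    ids = list(matrix.index)
    pairs, rs, ps = [], [], []
    for i, j in combinations(range(len(ids)), 2):
        r, p = stats.pearsonr(matrix.iloc[i], matrix.iloc[j])
        pairs.append((ids[i], ids[j]))
        rs.append(r)
        ps.append(p)
    if not pairs:
        return set()
    q = multipletests(ps, method="fdr_bh")[1]
    return {
        pair
        for pair, r, qv in zip(pairs, rs, q)
        if abs(r) > r_threshold and qv < q_threshold
    }
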