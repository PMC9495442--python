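"""The selection-effect screen: Spearman + Kruskal-Wallis feature
selection, intersection, and Mantel ranking of subcommunities.

For every (organism x subcommunity level x feature kind x response) cell
the pipeline

1. selects features whose Spearman rank correlation with the response is
   significant (two-sided p < alpha),
2. selects features that differ significantly among the four groups
   (Kruskal-Wallis p < alpha),
3. intersects the two selections, and
4. runs a Mantel test (Spearman correlation of Euclidean distance
   matrices, one-sided permutation p) between the intersected feature
   matrix and the response.

The Mantel r of significant cells ranks the subcommunities: the larger
the r, the stronger the inferred selection effect of that subcommunity on
that response.  Screens use raw p < alpha without multiplicity
correction, mirroring the thousands-of-taxa screening practice this
pipeline reproduces; a BH option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .config import AnalysisConfig
from .multifunctionality import (
    mean_pairwise_tradeoff,
    multifunctionality_indices,
    zscore_standardize,
)
from .networks import fdr_bh
from .subcommunities import (
    diversity_profile,
    partition_local,
    partition_regional,
    relative_abundance,
)
from .tables import FunctionTable, OtuTable, SampleDesign

LEVELS = (
    "whole",
    "locally_abundant",
    "locally_rare",
    "regionally_abundant",
    "regionally_rare",
)
FEATURE_KINDS = ("species", "functions", "diversity")
RESPONSES_DEFAULT = ("CCMF", "NCMF", "PCMF", "AEMF", "ANPP", "TRADEOFF")


def _drop_constant(features: pd.DataFrame) -> pd.DataFrame:
    nun = features.nunique(axis=0)
    dead = nun.index[nun <= 1]
    if len(dead):
        warnings.warn(
            f"skipping {len(dead)} constant feature(s)", stacklevel=3
        )
    return features.loc[:, nun > 1]


def spearman_screen(
    features: pd.DataFrame,
    response: pd.Series,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature Spearman rho (average-rank ties) against the response.

    Returns a frame indexed by feature id with columns ``rho``, ``p`` and
    boolean ``selected`` (two-sided p < alpha; BH-adjusted first when
    ``adjust``).  Constant features are skipped with a warning.
    """
    n = len(features)
    if n < 5:
        raise ValueError("Spearman screen needs at least 5 samples")
    features = _drop_constant(features)
    X = features.to_numpy(dtype=float)
    y = response.reindex(features.index).to_numpy(dtype=float)
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=0) * (ryc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rxc * ryc[:, None]).sum(axis=0) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    padj = fdr_bh(p) if adjust else p
    return pd.DataFrame(
        {"rho": rho, "p": p, "selected": padj < alpha}, index=features.columns
    )


def kw_screen(
    features: pd.DataFrame,
    design: SampleDesign,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis H across groups with tie correction.

    All-tied features get p = 1 and are never selected.
    """
    labels = design.group_labels(features.index)
    groups = design.groups
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis screen needs at least 2 groups")
    masks = [np.asarray(labels == g) for g in groups]
    if min(m.sum() for m in masks) < 2:
        raise ValueError("each group needs at least 2 samples")
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    ranks = stats.rankdata(X, axis=0)
    # tie-corrected H, vectorized over features
    h = np.zeros(X.shape[1])
    for m in masks:
        h += ranks[m].sum(axis=0) ** 2 / m.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie_corr = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_corr[j] = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    all_tied = tie_corr <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_out = np.where(all_tied, 0.0, h / np.where(all_tied, 1.0, tie_corr))
    p_out = stats.chi2.sf(stats_out, df=len(groups) - 1)
    p_out[all_tied] = 1.0
    padj = fdr_bh(p_out) if adjust else p_out
    return pd.DataFrame(
        {"H": stats_out, "p": p_out, "selected": padj < alpha},
        index=features.columns,
    )


def intersect_selected(a, b) -> list:
    """Order-preserving intersection of two selected-feature id sets."""
    bset = set(b)
    return [x for x in a if x in bset]


@dataclass
class MantelResult:
    r: float
    pvalue: float
    n_permutations: int
    n_features: int


def _pair_index_matrix(n: int) -> np.ndarray:
    idx = np.zeros((n, n), dtype=np.intp)
    iu = np.triu_indices(n, 1)
    idx[iu] = np.arange(len(iu[0]))
    return idx + idx.T


def mantel(
    features: pd.DataFrame,
    response: pd.Series,
    n_permutations: int = 9999,
    seed: int | None = None,
    zscore: bool = True,
) -> MantelResult:
    """Mantel test between a feature matrix and a univariate response.

    D1 = Euclidean distances between samples on the (optionally z-scored)
    feature matrix, D2 = Euclidean distances on the response; r is the
    Spearman correlation of the condensed distance vectors.  The one-sided
    permutation p permutes one matrix's sample order:
    p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1).
    """
    if features.shape[1] < 1:
        raise ValueError("Mantel test needs at least one feature")
    n = len(features)
    if n < 5:
        raise ValueError("Mantel test needs at least 5 samples")
    y = response.reindex(features.index)
    if y.isna().any():
        raise ValueError("response does not cover all feature samples")
    X = features.to_numpy(dtype=float)
    if zscore:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot z-score constant feature column")
        X = (X - X.mean(axis=0)) / sd
    d1 = pdist(X)
    d2 = pdist(y.to_numpy(dtype=float)[:, None])
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        raise ValueError("zero-variance distance vector")
    r1 = stats.rankdata(d1)
    r2 = stats.rankdata(d2)
    r1c = r1 - r1.mean()
    r2c = r2 - r2.mean()
    norm1 = np.sqrt((r1c**2).sum())
    norm2 = np.sqrt((r2c**2).sum())
    r_obs = float((r1c * r2c).sum() / (norm1 * norm2))

    idx = _pair_index_matrix(n)
    iu = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)
    count = 0
    mean2 = r2.mean()
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        permuted_pairs = idx[perm][:, perm][iu]
        b = r2[permuted_pairs] - mean2
        r_perm = (r1c * b).sum() / (norm1 * norm2)
        if r_perm >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(
        r=r_obs, pvalue=p, n_permutations=n_permutations, n_features=features.shape[1]
    )


def compute_responses(
    functions: FunctionTable,
    cfg: AnalysisConfig | None = None,
    anpp: pd.Series | None = None,
    responses: Sequence[str] = RESPONSES_DEFAULT,
) -> pd.DataFrame:
    """Per-sample response vectors the screen ranks against.

    CCMF/NCMF/PCMF/AEMF are averaging-approach multifunctionality indices;
    TRADEOFF is the exhaustive mean pairwise trade-off intensity over all
    standardized function pairs (the stabilized regime of the
    pair-sampling analysis); ANPP must be supplied.
    """
    cfg = cfg or AnalysisConfig()
    mf = multifunctionality_indices(functions, cfg)
    out = {}
    for resp in responses:
        if resp in mf.columns:
            out[resp] = mf[resp]
        elif resp == "TRADEOFF":
            members = [
                f for f in cfg.function_groups.get("AEMF", ())
                if f in functions.values.columns
            ]
            z = zscore_standardize(functions.values[members or list(functions.values.columns)])
            out[resp] = mean_pairwise_tradeoff(z)
        elif resp == "ANPP":
            if anpp is None:
                continue  # response absent from the dataset
            out[resp] = anpp.reindex(functions.values.index)
        else:
            raise ValueError(f"unknown response {resp!r}")
    return pd.DataFrame(out, index=functions.values.index)


def _species_matrices(
    otu: OtuTable, cfg: AnalysisConfig
) -> dict[str, pd.DataFrame]:
    """Samples x taxa relative-abundance matrix per subcommunity level.

    Local levels zero the cells whose label does not match (membership is
    per sample); regional levels keep or drop whole taxa.  Fractions stay
    relative to the whole community so levels are comparable.
    """
    rel = relative_abundance(otu)
    local = partition_local(rel, cfg)
    regional = partition_regional(rel, cfg, otu=otu)
    out = {"whole": rel.T.copy()}
    for which in ("abundant", "rare"):
        mask = (local.labels == which).to_numpy()
        m = rel.where(mask, 0.0)
        m = m.loc[m.sum(axis=1) > 0]
        out[f"locally_{which}"] = m.T.copy()
        out[f"regionally_{which}"] = rel.loc[regional.labels == which].T.copy()
    return out


def _count_tables(otu: OtuTable, cfg: AnalysisConfig) -> dict[str, OtuTable]:
    from .networks import subcommunity_tables

    return subcommunity_tables(otu, cfg)


@dataclass
class ScreenCell:
    organism: str
    level: str
    kind: str
    response: str
    n_features: int
    spearman_selected: list[str]
    kw_selected: list[str]
    intersection: list[str]
    mantel: MantelResult | None
    note: str = ""


@dataclass
class ScreenResult:
    """Long-format screen table plus per-response rankings."""

    table: pd.DataFrame
    cells: list[ScreenCell]
    top_cells: dict[str, dict]
    summary: pd.DataFrame
    alpha: float

    def cell(self, organism: str, level: str, kind: str, response: str) -> ScreenCell:
        for c in self.cells:
            if (c.organism, c.level, c.kind, c.response) == (
                organism, level, kind, response,
            ):
                return c
        raise KeyError((organism, level, kind, response))


def run_screen(
    organisms: Mapping[str, OtuTable],
    functions: FunctionTable,
    design: SampleDesign,
    cfg: AnalysisConfig | None = None,
    responses: Sequence[str] = RESPONSES_DEFAULT,
    anpp: pd.Series | None = None,
    predicted_functions: Mapping | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> ScreenResult:
    """Run the full selection-effect screen and rank subcommunities.

    ``organisms`` maps organism names (e.g. ``bacteria``, ``fungi``) to
    OTU tables.  ``predicted_functions`` optionally supplies predicted
    functional-category matrices (samples x categories), keyed either by
    organism (used at the whole level) or by ``(organism, level)``.
    """
    cfg = cfg or AnalysisConfig()
    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    if seed is None:
        seed = cfg.rng_seed
    rng = np.random.default_rng(seed)

    resp_table = compute_responses(functions, cfg, anpp=anpp, responses=responses)
    sample_ids = list(functions.values.index)

    cells: list[ScreenCell] = []
    for organism, otu in organisms.items():
        species = _species_matrices(otu, cfg)
        count_tables = _count_tables(otu, cfg)
        for level in LEVELS:
            feats_by_kind: dict[str, pd.DataFrame] = {}
            sp = species[level].reindex(sample_ids)
            if sp.shape[1] > 0:
                feats_by_kind["species"] = sp
            pf = None
            if predicted_functions is not None:
                pf = predicted_functions.get((organism, level))
                if pf is None and level == "whole":
                    maybe = predicted_functions.get(organism)
                    pf = maybe if isinstance(maybe, pd.DataFrame) else None
            if pf is not None:
                feats_by_kind["functions"] = pf.reindex(sample_ids)
            div_parts = []
            if count_tables[level].n_taxa > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    div = diversity_profile(count_tables[level])
                div_parts.append(div.add_prefix("taxa_"))
            if pf is not None and (pf.to_numpy() >= 0).all():
                # function-category diversity needs non-negative abundances
                fdiv = diversity_profile(pf.T)
                div_parts.append(fdiv.add_prefix("functions_"))
            if div_parts:
                feats_by_kind["diversity"] = pd.concat(div_parts, axis=1).reindex(
                    sample_ids
                )
            for kind in FEATURE_KINDS:
                if kind not in feats_by_kind:
                    continue
                feats = feats_by_kind[kind]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kw = kw_screen(feats, design, cfg.alpha)
                kw_ids = list(kw.index[kw["selected"]])
                for response in resp_table.columns:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sp_screen = spearman_screen(
                            feats, resp_table[response], cfg.alpha
                        )
                    sp_ids = list(sp_screen.index[sp_screen["selected"]])
                    inter = intersect_selected(sp_ids, kw_ids)
                    note = ""
                    result = None
                    if inter:
                        try:
                            result = mantel(
                                feats[inter],
                                resp_table[response],
                                n_permutations=n_perm,
                                seed=int(rng.integers(2**31)),
                                zscore=cfg.mantel_zscore,
                            )
                        except ValueError as exc:
                            note = str(exc)
                    else:
                        note = "no features in intersection"
                    cells.append(
                        ScreenCell(
                            organism=organism,
                            level=level,
                            kind=kind,
                            response=response,
                            n_features=feats.shape[1],
                            spearman_selected=sp_ids,
                            kw_selected=kw_ids,
                            intersection=inter,
                            mantel=result,
                            note=note,
                        )
                    )

    rows = []
    for c in cells:
        rows.append(
            {
                "organism": c.organism,
                "level": c.level,
                "kind": c.kind,
                "response": c.response,
                "n_features": c.n_features,
                "n_selected_spearman": len(c.spearman_selected),
                "n_selected_kw": len(c.kw_selected),
                "n_intersection": len(c.intersection),
                "mantel_r": c.mantel.r if c.mantel else np.nan,
                "mantel_p": c.mantel.pvalue if c.mantel else np.nan,
                "note": c.note,
            }
        )
    table = pd.DataFrame(rows)

    top_cells: dict[str, dict] = {}
    for response in resp_table.columns:
        sub = table[
            (table["response"] == response) & (table["mantel_p"] < cfg.alpha)
        ]
        if sub.empty:
            top_cells[response] = {}
            continue
        best = sub.loc[sub["mantel_r"].idxmax()]
        top_cells[response] = {
            "organism": best["organism"],
            "level": best["level"],
            "kind": best["kind"],
            "mantel_r": float(best["mantel_r"]),
            "mantel_p": float(best["mantel_p"]),
        }

    # species/functions cells vs diversity cells: is the selection-effect
    # signal (identity of features) stronger than the diversity signal?
    summary_rows = []
    sig = table[table["mantel_p"] < cfg.alpha]
    for response in resp_table.columns:
        sub = sig[sig["response"] == response]
        ident = sub[sub["kind"].isin(["species", "functions"])]["mantel_r"]
        divr = sub[sub["kind"] == "diversity"]["mantel_r"]
        if len(ident) and len(divr):
            try:
                _, kw_p = stats.kruskal(ident, divr)
            except ValueError:
                kw_p = 1.0
        else:
            kw_p = np.nan
        summary_rows.append(
            {
                "response": response,
                "mean_r_identity": float(ident.mean()) if len(ident) else np.nan,
                "mean_r_diversity": float(divr.mean()) if len(divr) else np.nan,
                "kruskal_p": kw_p,
            }
        )
    summary = pd.DataFrame(summary_rows)

    return ScreenResult(
        table=table, cells=cells, top_cells=top_cells, summary=summary, alpha=cfg.alpha
    )
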