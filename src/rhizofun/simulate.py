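"""Synthetic studies with the statistical structure the pipeline assumes.

The generator emulates a 4-group x 5-replicate rhizosphere survey:

* a heavy-tailed (lognormal) rank-abundance profile of expected relative
  abundances, with per-sample counts drawn multinomially at a fixed
  library size;
* a standard-normal latent driver ``L`` per sample shared between the
  community and the functions — signal taxa multiply their expected
  abundance by ``exp(beta * L)`` and the target function gains
  ``coupling * L``, which is what induces the taxon-function association
  the Mantel screen is meant to detect;
* group-level effects: multiplicative fold changes on chosen taxa and
  additive shifts on chosen functions, so screened features can differ
  among groups;
* optional "decoy" taxa that receive group folds but no latent-driver
  coupling, optional conditional "bloomer" taxa, and (for planted signal
  taxa) driver-independent abundance excursions — blooms of conditionally
  rare taxa or crashes of abundant ones.

Signal-stratum membership is defined on the *expected* baseline relative
abundance; realized per-sample classification may differ, which
deliberately stresses the partitioner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig, default_function_tags
from .tables import FunctionTable, OtuTable, SampleDesign

STRATA = (
    "none",
    "locally_rare",
    "locally_abundant",
    "regionally_rare",
    "regionally_abundant",
)

#: Response name used when the planted signal drives productivity rather
#: than a measured rhizosphere function.
ANPP = "ANPP"


@dataclass
class PlantedSignal:
    """A latent-driver association planted into chosen taxa and a target."""

    target_level: str = "none"
    n_signal_taxa: int = 0
    beta: float = 0.0
    target_function: str | None = None
    coupling: float = 1.0  # slope of the target on the latent driver
    #: optional (lo, hi) band of baseline relative abundance restricting
    #: which stratum members may carry the signal.  Planting well inside
    #: the stratum keeps boosted cells from drifting across a threshold,
    #: so the planted level remains the true one.
    band: tuple[float, float] | None = None
    #: conditional-abundance excursions: with this probability per
    #: (taxon, sample) cell — a single float, or one probability per
    #: group — a signal taxon's expected abundance is *replaced* by
    #: baseline x lognormal(excursion_factor) (> 1 models blooms of
    #: conditionally rare taxa, < 1 crashes of abundant ones).  The
    #: excursion state is decoupled from the latent driver and the group
    #: folds: the taxon-function association holds only while the taxon
    #: occupies its home stratum, which is what makes the home-stratum
    #: restricted view more informative than the whole-community view.
    excursion_prob: float | tuple[float, ...] = 0.0
    excursion_factor: float = 30.0
    excursion_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.target_level not in STRATA:
            raise ValueError(f"unknown target_level {self.target_level!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class GroupEffects:
    """Group-level mean structure for taxa and functions.

    ``signal_folds``: multiplicative fold per group applied to every
    signal taxon.  ``decoy_folds``: fold vector for decoy taxa;
    ``decoy_mode`` controls how it is assigned: ``"paired"`` (default)
    alternates the vector and its reverse across decoys so total decoy
    mass stays balanced between groups (no compositional shadow on the
    rest of the community, and both orientations remain selectable by a
    two-sided screen), ``"aligned"`` applies it as-is, ``"permuted"``
    draws an independent random permutation per decoy.
    ``function_shifts``: additive per-group shift for named functions
    (the ``ANPP`` key shifts productivity).
    """

    signal_folds: tuple[float, ...] | None = None
    n_decoy_taxa: int = 0
    decoy_level: str | None = None
    decoy_folds: tuple[float, ...] | None = None
    decoy_band: tuple[float, float] | None = None
    decoy_mode: str = "paired"
    function_shifts: dict[str, tuple[float, ...]] = field(default_factory=dict)


@dataclass
class ConditionalBloomers:
    """Taxa whose association with the driver holds at moderate abundance
    but who undergo sporadic blooms unrelated to it.

    Bloomers are drawn from a (band-restricted) stratum, couple to the
    latent driver with ``beta`` and respond to the treatment with
    ``folds``; with ``bloom_prob`` per cell their expected abundance is
    multiplied by a lognormal factor centred on ``bloom_factor``.  The
    blooms are independent of the driver, so bloomer cells are
    informative only outside the bloom state.
    """

    n_taxa: int = 0
    level: str = "locally_intermediate"
    band: tuple[float, float] | None = None
    beta: float = 1.0
    folds: tuple[float, ...] | None = None
    bloom_prob: float = 0.25
    bloom_factor: float = 30.0
    bloom_sd: float = 0.5


@dataclass
class SimulationSpec:
    n_groups: int = 4
    reps: int = 5
    n_taxa: int = 600
    library_size: int = 30000
    mean_log: float = 0.0
    sd_log: float = 2.0
    signal: PlantedSignal = field(default_factory=PlantedSignal)
    effects: GroupEffects = field(default_factory=GroupEffects)
    bloomers: ConditionalBloomers = field(default_factory=ConditionalBloomers)
    noise_sd: float = 0.5
    min_expected_reads: float = 1.0  # signal/decoy taxa must be observable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.signal.n_signal_taxa > self.n_taxa:
            raise ValueError("n_signal_taxa cannot exceed n_taxa")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.reps


@dataclass
class SimulatedStudy:
    otu: OtuTable
    functions: FunctionTable
    anpp: pd.Series
    design: SampleDesign
    truth: dict

    def response_target(self) -> str | None:
        return self.truth.get("target_function")


def _stratum_mask(p0: np.ndarray, level: str, cfg: AnalysisConfig) -> np.ndarray:
    """Which taxa fall in the requested abundance stratum of the baseline.

    The baseline expectation is shared by all samples, so local and
    regional strata use their respective thresholds on the same vector.
    """
    if level == "locally_rare":
        return (p0 > 0) & (p0 <= cfg.local_rare)
    if level == "locally_abundant":
        return p0 >= cfg.local_abundant
    if level == "locally_intermediate":
        return (p0 > cfg.local_rare) & (p0 < cfg.local_abundant)
    if level == "regionally_rare":
        return (p0 > 0) & (p0 <= cfg.regional_rare)
    if level == "regionally_abundant":
        return p0 >= cfg.regional_abundant
    raise ValueError(f"unknown stratum {level!r}")


def _pick_stratum_taxa(
    p0: np.ndarray,
    level: str,
    n_pick: int,
    library_size: int,
    min_expected_reads: float,
    rng: np.random.Generator,
    cfg: AnalysisConfig,
    exclude: np.ndarray | None = None,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    mask = _stratum_mask(p0, level, cfg)
    mask &= p0 * library_size >= min_expected_reads
    if band is not None:
        mask &= (p0 >= band[0]) & (p0 <= band[1])
    if exclude is not None:
        mask[exclude] = False
    eligible = np.flatnonzero(mask)
    if len(eligible) < n_pick:
        raise ValueError(
            f"only {len(eligible)} observable taxa in stratum {level!r};"
            f" need {n_pick}. Increase n_taxa or library_size, or lower"
            f" min_expected_reads."
        )
    return np.sort(rng.choice(eligible, size=n_pick, replace=False))


def simulate_study(
    spec: SimulationSpec, cfg: AnalysisConfig | None = None
) -> SimulatedStudy:
    """Draw one complete synthetic study from a single RNG stream."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(spec.seed)
    design = SampleDesign.balanced(reps=spec.reps) if spec.n_groups == 4 else (
        SampleDesign.balanced(
            groups=tuple(f"G{i + 1}" for i in range(spec.n_groups)), reps=spec.reps
        )
    )
    sample_ids = design.sample_ids
    group_index = pd.Categorical(
        design.frame["group"], categories=design.groups
    ).codes

    # community baseline and strata
    baseline = rng.lognormal(spec.mean_log, spec.sd_log, spec.n_taxa)
    p0 = baseline / baseline.sum()
    latent = rng.standard_normal(spec.n_samples)

    signal_idx = np.empty(0, dtype=int)
    if spec.signal.n_signal_taxa > 0 and spec.signal.target_level != "none":
        signal_idx = _pick_stratum_taxa(
            p0, spec.signal.target_level, spec.signal.n_signal_taxa,
            spec.library_size, spec.min_expected_reads, rng, cfg,
            band=spec.signal.band,
        )
    decoy_idx = np.empty(0, dtype=int)
    eff = spec.effects
    if eff.n_decoy_taxa > 0 and eff.decoy_level is not None:
        exclude = signal_idx if len(signal_idx) else None
        decoy_idx = _pick_stratum_taxa(
            p0, eff.decoy_level, eff.n_decoy_taxa,
            spec.library_size, spec.min_expected_reads, rng, cfg,
            exclude=exclude, band=eff.decoy_band,
        )
    bloomer_idx = np.empty(0, dtype=int)
    blo = spec.bloomers
    if blo.n_taxa > 0:
        taken = np.concatenate([signal_idx, decoy_idx]).astype(int)
        bloomer_idx = _pick_stratum_taxa(
            p0, blo.level, blo.n_taxa,
            spec.library_size, spec.min_expected_reads, rng, cfg,
            exclude=taken if len(taken) else None, band=blo.band,
        )

    weights = np.tile(p0[:, None], (1, spec.n_samples))
    baseline_weights = weights.copy()
    if eff.signal_folds is not None and len(signal_idx):
        folds = np.asarray(eff.signal_folds, dtype=float)
        if len(folds) != spec.n_groups:
            raise ValueError("signal_folds must have one fold per group")
        weights[signal_idx] *= folds[group_index][None, :]
    if eff.decoy_folds is not None and len(decoy_idx):
        base = np.asarray(eff.decoy_folds, dtype=float)
        if len(base) != spec.n_groups:
            raise ValueError("decoy_folds must have one fold per group")
        for pos, t in enumerate(decoy_idx):
            if eff.decoy_mode == "permuted":
                folds_t = rng.permutation(base)
            elif eff.decoy_mode == "paired" and pos % 2 == 1:
                folds_t = base[::-1]
            else:
                folds_t = base
            weights[t] *= folds_t[group_index]
    if spec.signal.beta > 0 and len(signal_idx):
        weights[signal_idx] *= np.exp(spec.signal.beta * latent)[None, :]
    exc_prob = np.broadcast_to(
        np.asarray(spec.signal.excursion_prob, dtype=float)[
            group_index
        ] if np.ndim(spec.signal.excursion_prob) else spec.signal.excursion_prob,
        (spec.n_samples,),
    )
    if np.any(exc_prob > 0) and len(signal_idx):
        shape = (len(signal_idx), spec.n_samples)
        hit = rng.random(shape) < exc_prob[None, :]
        factors = np.exp(
            rng.normal(
                np.log(spec.signal.excursion_factor), spec.signal.excursion_sd, shape
            )
        )
        # excursion replaces the coupled expectation: the excursion state
        # is independent of the driver and the treatment
        weights[signal_idx] = np.where(
            hit, baseline_weights[signal_idx] * factors, weights[signal_idx]
        )
    if len(bloomer_idx):
        if blo.folds is not None:
            bfolds = np.asarray(blo.folds, dtype=float)
            if len(bfolds) != spec.n_groups:
                raise ValueError("bloomer folds must have one fold per group")
            weights[bloomer_idx] *= bfolds[group_index][None, :]
        if blo.beta > 0:
            weights[bloomer_idx] *= np.exp(blo.beta * latent)[None, :]
        if blo.bloom_prob > 0:
            # fixed bloom count per sample: which bloomers bloom is random,
            # how many is not, so stratum richness stays stable
            k = int(round(blo.bloom_prob * len(bloomer_idx)))
            shape = (len(bloomer_idx), spec.n_samples)
            hit = np.zeros(shape, dtype=bool)
            for s in range(spec.n_samples):
                hit[rng.choice(len(bloomer_idx), size=k, replace=False), s] = True
            factors = np.exp(
                rng.normal(np.log(blo.bloom_factor), blo.bloom_sd, shape)
            )
            weights[bloomer_idx] = np.where(
                hit, baseline_weights[bloomer_idx] * factors, weights[bloomer_idx]
            )

    probs = weights / weights.sum(axis=0)
    counts = np.empty((spec.n_taxa, spec.n_samples), dtype=np.int64)
    for s in range(spec.n_samples):
        counts[:, s] = rng.multinomial(spec.library_size, probs[:, s])

    width = len(str(spec.n_taxa))
    otu_ids = [f"OTU{i + 1:0{width}d}" for i in range(spec.n_taxa)]
    otu = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))

    # functions: shift + coupling to the latent driver + noise
    tags = default_function_tags()
    fn_ids = list(tags)
    values = np.zeros((spec.n_samples, len(fn_ids)))
    for j, fid in enumerate(fn_ids):
        col = rng.normal(0.0, spec.noise_sd, spec.n_samples)
        shifts = eff.function_shifts.get(fid)
        if shifts is not None:
            col = col + np.asarray(shifts, dtype=float)[group_index]
        if spec.signal.target_function == fid:
            col = col + spec.signal.coupling * latent
        values[:, j] = col
    functions = FunctionTable(
        pd.DataFrame(values, index=sample_ids, columns=fn_ids),
        tags=pd.Series(tags),
    )

    anpp = rng.normal(0.0, spec.noise_sd, spec.n_samples)
    shifts = eff.function_shifts.get(ANPP)
    if shifts is not None:
        anpp = anpp + np.asarray(shifts, dtype=float)[group_index]
    if spec.signal.target_function == ANPP:
        anpp = anpp + spec.signal.coupling * latent
    anpp = pd.Series(anpp, index=sample_ids, name=ANPP)

    truth = {
        "signal_taxa": [otu_ids[i] for i in signal_idx],
        "decoy_taxa": [otu_ids[i] for i in decoy_idx],
        "bloomer_taxa": [otu_ids[i] for i in bloomer_idx],
        "latent": {s: float(v) for s, v in zip(sample_ids, latent)},
        "beta": spec.signal.beta,
        "target_level": spec.signal.target_level,
        "target_function": spec.signal.target_function,
        "baseline_relative_abundance": {
            otu_ids[i]: float(p0[i]) for i in np.concatenate([signal_idx, decoy_idx])
        },
    }
    return SimulatedStudy(otu, functions, anpp, design, truth)


# Study conditions for the parameter-recovery experiments.
#
# * Signal taxa sit in a band of their stratum chosen so that (i) they are
#   observable at the simulated depth, (ii) the latent boost exp(beta * L)
#   and the group folds essentially never push a cell across the local
#   threshold (cells that do cross land in the excluded intermediate
#   class), and (iii) their mean relative abundance is regionally
#   *intermediate*, so no regional cell inherits the uncensored signal.
# * Decoy taxa are locally intermediate: excluded from all four
#   subcommunity cells, but present in the whole matrix, and regionally
#   abundant, so they dilute exactly the non-target cells.  Half carry the
#   fold vector and half its reverse, which balances decoy mass between
#   groups (no compositional shadow) while both orientations stay
#   selectable by the two-sided screens.
RECOVERY_SHIFTS = (0.0, 0.5, 1.0, 1.5)
DECOY_FOLDS = (1.0, 1.5, 2.2, 3.3)
# Rare signal taxa sit at the detection limit: group folds produce a
# natural detection gradient (Poisson zeros in the low groups), which is
# rank-coherent at every level, while the local-rare ceiling is never
# crossed by the latent boost itself.
_SIGNAL_FOLDS = {
    "locally_rare": (1.0, 2.2, 5.0, 12.0),
    "locally_abundant": (1.0, 2.0, 4.0, 8.0),
}
_SIGNAL_BANDS = {
    "locally_rare": (1.2e-7, 3e-7),
    "locally_abundant": (1e-3, 2.2e-3),
}
_DECOY_BAND = (1.5e-4, 6e-4)
_EXCURSIONS = {
    # (per-group probability, factor): blooms of the conditionally rare
    # signal taxa are concentrated in the low-response groups, where the
    # taxa are otherwise below the detection limit — so the home-stratum
    # view loses almost nothing while the whole-community view sees large
    # driver-independent spikes.  Abundant signal taxa do not bloom.
    "locally_rare": ((0.6, 0.45, 0.2, 0.05), 1000.0),
    "locally_abundant": (0.0, 1.0),
}


def recovery_scenario(
    target_level: str = "locally_rare",
    seed: int = 0,
    n_taxa: int = 5000,
    library_size: int = 20_000_000,
    beta: float = 1.5,
    n_signal_taxa: int = 10,
) -> SimulationSpec:
    """Spec for a planted-signal study whose truth the screen should find."""
    if target_level not in _SIGNAL_BANDS:
        raise ValueError(
            f"recovery scenarios are defined for {sorted(_SIGNAL_BANDS)}"
        )
    exc_prob, exc_factor = _EXCURSIONS[target_level]
    return SimulationSpec(
        n_taxa=n_taxa,
        library_size=library_size,
        signal=PlantedSignal(
            target_level=target_level,
            n_signal_taxa=n_signal_taxa,
            beta=beta,
            target_function=ANPP,
            coupling=1.0,
            band=_SIGNAL_BANDS[target_level],
            excursion_prob=exc_prob,
            excursion_factor=exc_factor,
        ),
        effects=GroupEffects(
            signal_folds=_SIGNAL_FOLDS[target_level],
            function_shifts={ANPP: RECOVERY_SHIFTS},
        ),
        noise_sd=0.25,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_taxa: int = 600, library_size: int = 30000) -> SimulationSpec:
    """No planted signal and no group structure anywhere."""
    return SimulationSpec(n_taxa=n_taxa, library_size=library_size, seed=seed)
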