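"""Analysis configuration and the canonical ecosystem-function groupings.

All abundance thresholds are stored as *fractions* of a sample's reads
(0.1% -> 1e-3), never as percentages, so that one unit convention holds
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

# Carbon-, nitrogen- and phosphorus-cycling surrogate measurements of the
# rhizosphere, as commonly assayed in cropping-system soil studies.
C_FUNCTIONS: tuple[str, ...] = ("OC", "MBC", "betaG")
N_FUNCTIONS: tuple[str, ...] = (
    "NH4_N", "NO3_N", "IN", "MBN", "NAG", "LAP", "Nitrogenase", "NOS", "GS",
)
P_FUNCTIONS: tuple[str, ...] = ("TP", "AP", "ACP")
OTHER_FUNCTIONS: tuple[str, ...] = ("WC",)

#: Default membership of the average ecosystem multifunctionality (AEMF)
#: index: every C/N/P-cycling function plus water content.  Soil pH is a
#: state variable rather than a function and is excluded by default (it can
#: be added back through ``AnalysisConfig.function_groups``).
AEMF_FUNCTIONS: tuple[str, ...] = (
    C_FUNCTIONS + N_FUNCTIONS + P_FUNCTIONS + OTHER_FUNCTIONS
)

VALID_TAGS = ("C", "N", "P", "other")


def default_function_tags() -> dict[str, str]:
    """Map each default function id to its element-cycle tag."""
    tags: dict[str, str] = {}
    for f in C_FUNCTIONS:
        tags[f] = "C"
    for f in N_FUNCTIONS:
        tags[f] = "N"
    for f in P_FUNCTIONS:
        tags[f] = "P"
    for f in OTHER_FUNCTIONS:
        tags[f] = "other"
    return tags


@dataclass
class AnalysisConfig:
    """Tunable knobs shared by every pipeline stage.

    Parameters
    ----------
    local_abundant, local_rare :
        Within-sample relative-abundance thresholds (fractions).  A taxon is
        locally abundant in a sample at >= ``local_abundant`` (default 0.1%)
        and locally rare at > 0 and <= ``local_rare`` (default 0.01%).
    regional_abundant, regional_rare :
        Thresholds applied to the mean relative abundance across all
        samples (defaults 0.01% and 0.001%).
    alpha :
        Significance level used by the normality/homoscedasticity gate, the
        Spearman and Kruskal-Wallis screens and the Mantel ranking.
    n_permutations :
        Permutation count for ANOSIM and the Mantel test.
    network_r_threshold, network_q_threshold :
        Co-occurrence edge rule: keep pairs with \\|Pearson r\\| >
        ``network_r_threshold`` and BH-adjusted p < ``network_q_threshold``.
    network_min_occupancy :
        A taxon enters a group network only if it is non-zero in at least
        this many of the group's samples.
    network_on_relative :
        Correlate relative abundances (default) instead of raw counts.
    regional_mode :
        ``"mean"`` (unweighted mean of per-sample fractions, default) or
        ``"pooled"`` (fraction of pooled counts).
    mantel_zscore :
        Standardize feature columns before Euclidean distances in the
        Mantel test.
    function_groups :
        Function-id membership of the CCMF/NCMF/PCMF/AEMF indices.
    """

    local_abundant: float = 1e-3
    local_rare: float = 1e-4
    regional_abundant: float = 1e-4
    regional_rare: float = 1e-5
    alpha: float = 0.05
    n_permutations: int = 9999
    network_r_threshold: float = 0.8
    network_q_threshold: float = 0.001
    network_min_occupancy: int = 3
    network_on_relative: bool = True
    regional_mode: str = "mean"
    mantel_zscore: bool = True
    rng_seed: int | None = None
    function_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "CCMF": C_FUNCTIONS,
            "NCMF": N_FUNCTIONS,
            "PCMF": P_FUNCTIONS,
            "AEMF": AEMF_FUNCTIONS,
        }
    )

    def __post_init__(self) -> None:
        for lo, hi, where in (
            (self.local_rare, self.local_abundant, "local"),
            (self.regional_rare, self.regional_abundant, "regional"),
        ):
            if not (0.0 < lo < hi < 1.0):
                raise ValueError(
                    f"{where} thresholds must satisfy 0 < rare < abundant < 1,"
                    f" got rare={lo}, abundant={hi}"
                )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.regional_mode not in ("mean", "pooled"):
            raise ValueError(f"unknown regional_mode {self.regional_mode!r}")
        if not (0.0 < self.network_r_threshold < 1.0):
            raise ValueError("network_r_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "function_groups" in d:
            d["function_groups"] = {
                k: tuple(v) for k, v in d["function_groups"].items()
            }
        return cls(**d)


def tags_from_groups(
    function_ids: Sequence[str],
    group_map: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Resolve a tag for every function id.

    Ids found in ``group_map`` use it; ids among the package defaults use
    the default tag; anything else is tagged ``"other"``.
    """
    defaults = default_function_tags()
    out: dict[str, str] = {}
    for fid in function_ids:
        if group_map is not None and fid in group_map:
            tag = group_map[fid]
            if tag not in VALID_TAGS:
                raise ValueError(
                    f"invalid tag {tag!r} for function {fid!r};"
                    f" expected one of {VALID_TAGS}"
                )
            out[fid] = tag
        else:
            out[fid] = defaults.get(fid, "other")
    return out
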