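"""Feedstock recipes -> community medium uptake bounds.

Converts grams-per-liter feedstock recipes (sewage sludge, food waste) into
per-compound medium availabilities in mmol gVS^-1 h^-1 using a local nutrient
table (food component -> mmol of each compound per gram of component), mixes
sludge and food-waste media by their volatile-solid loads, classifies samples
into the LFW/MFW/HFW food-waste groups, and folds measured VFA concentrations
into the medium as extra availabilities.

Daily feeds are converted to hourly fluxes by dividing by 24 (semi-continuous
feeding approximated as continuous).  VFA concentrations (mmol/L) become
fluxes through a configurable turnover factor defaulting to one reactor
turnover per hydraulic retention time (HRT = 21 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "NutrientTable",
    "FeedstockRecipe",
    "SampleFeed",
    "compute_medium",
    "mix_media",
    "classify_fw_group",
    "apply_vfa_constraints",
    "read_medium_tsv",
    "write_medium_tsv",
    "read_sample_sheet",
]

HOURS_PER_DAY = 24.0
#: default VFA concentration -> flux conversion, h^-1 (one turnover per HRT)
DEFAULT_VFA_TURNOVER = 1.0 / (21.0 * HOURS_PER_DAY)


@dataclass
class NutrientTable:
    """food component -> {compound -> mmol per gram of component}."""

    entries: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for food, comp in self.entries.items():
            for cpd, v in comp.items():
                if v < 0:
                    raise ValueError(f"nutrient table: {food}/{cpd} negative ({v})")

    @classmethod
    def from_tsv(cls, path) -> "NutrientTable":
        df = pd.read_csv(path, sep="\t")
        entries: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            entries.setdefault(row.food_component, {})[row.compound_id] = float(row.mmol_per_g)
        return cls(entries)

    def to_tsv(self, path) -> None:
        rows = [
            {"food_component": food, "compound_id": cpd, "mmol_per_g": v}
            for food in sorted(self.entries)
            for cpd, v in sorted(self.entries[food].items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class FeedstockRecipe:
    """Feedstock as (component, grams fresh mass per liter) with a VS fraction."""

    components: dict[str, float]
    vs_fraction: float
    label: str = "FW"  # "SS" or "FW"

    def __post_init__(self) -> None:
        if not 0 < self.vs_fraction <= 1:
            raise ValueError(f"vs_fraction {self.vs_fraction} outside (0, 1]")
        for comp, g in self.components.items():
            if g < 0:
                raise ValueError(f"recipe component {comp!r} has negative grams")


@dataclass
class SampleFeed:
    """One sample's feed: SS and FW loads (g VS L^-1 day^-1) and FW group."""

    sample_id: str
    day: int
    reactor: int
    ss_load: float
    fw_load: float
    g_fw_per_l_vs: float = field(default=0.0)
    fw_group: str = field(default="LFW")

    def __post_init__(self) -> None:
        if self.ss_load < 0 or self.fw_load < 0:
            raise ValueError("feed loads must be nonnegative")
        self.fw_group = classify_fw_group(self.g_fw_per_l_vs)


def compute_medium(recipe: FeedstockRecipe, table: NutrientTable) -> dict[str, float]:
    """Per-gVS hourly compound availability of one feedstock.

    flux(c) = sum_components grams * mmol_per_g(c) / (total g VS) / 24 h.
    Deterministic and order-independent; an empty recipe yields an empty
    medium.  Note the per-gVS normalization makes the result invariant to a
    common rescaling of all component grams.
    """
    unknown = sorted(set(recipe.components) - set(table.entries))
    if unknown:
        raise LookupError(f"recipe components missing from nutrient table: {unknown}")
    total_vs = sum(recipe.components.values()) * recipe.vs_fraction
    if total_vs == 0:
        return {}
    medium: dict[str, float] = {}
    for comp, grams in sorted(recipe.components.items()):
        for cpd, mmol_per_g in table.entries[comp].items():
            medium[cpd] = medium.get(cpd, 0.0) + grams * mmol_per_g
    return {cpd: v / total_vs / HOURS_PER_DAY for cpd, v in sorted(medium.items())}


def mix_media(ss_medium: dict[str, float], fw_medium: dict[str, float],
              ss_load: float, fw_load: float) -> dict[str, float]:
    """Convex combination of two per-gVS media weighted by VS loads."""
    if ss_load < 0 or fw_load < 0:
        raise ValueError("loads must be nonnegative")
    total = ss_load + fw_load
    if total == 0:
        raise ValueError("at least one load must be positive")
    out: dict[str, float] = {}
    for cpd in sorted(set(ss_medium) | set(fw_medium)):
        out[cpd] = (ss_load * ss_medium.get(cpd, 0.0) +
                    fw_load * fw_medium.get(cpd, 0.0)) / total
    return out


def classify_fw_group(g_fw_per_l_vs: float,
                      cutoffs: tuple[float, float] = (0.2, 0.6)) -> str:
    """LFW below the first cutoff, HFW above the second, MFW on [low, high]."""
    if g_fw_per_l_vs < 0:
        raise ValueError(f"FW ratio must be nonnegative, got {g_fw_per_l_vs}")
    low, high = cutoffs
    if g_fw_per_l_vs < low:
        return "LFW"
    if g_fw_per_l_vs <= high:
        return "MFW"
    return "HFW"


def apply_vfa_constraints(medium: dict[str, float], vfa: dict[str, float],
                          turnover: float = DEFAULT_VFA_TURNOVER,
                          vs_g_per_l: float = 1.0) -> dict[str, float]:
    """Add measured VFA pools to the medium as extra availability.

    Each concentration (mmol/L) contributes ``conc * turnover / vs_g_per_l``
    mmol gVS^-1 h^-1 on top of the feedstock-derived term; availabilities
    never drop below zero.  An empty ``vfa`` map leaves the medium unchanged.
    """
    out = dict(medium)
    for cpd, conc in sorted(vfa.items()):
        extra = conc * turnover / vs_g_per_l
        out[cpd] = max(0.0, out.get(cpd, 0.0) + extra)
    return out


def read_medium_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.compound_id): float(r.max_uptake_mmol_gVS_h)
            for r in df.itertuples(index=False)}


def write_medium_tsv(medium: dict[str, float], path) -> None:
    pd.DataFrame(
        [{"compound_id": c, "max_uptake_mmol_gVS_h": v} for c, v in sorted(medium.items())]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_sheet(path) -> list[SampleFeed]:
    """Load a sample sheet TSV (sample_id, day, reactor, ss_load, fw_load
    and optionally g_fw_per_l_vs; the FW group is derived)."""
    df = pd.read_csv(path, sep="\t")
    feeds = []
    for row in df.itertuples(index=False):
        ratio = getattr(row, "g_fw_per_l_vs", None)
        if ratio is None:
            total = row.ss_load + row.fw_load
            ratio = row.fw_load / total if total else 0.0
        feeds.append(SampleFeed(sample_id=str(row.sample_id), day=int(row.day),
                                reactor=int(row.reactor),
                                ss_load=float(row.ss_load),
                                fw_load=float(row.fw_load),
                                g_fw_per_l_vs=float(ratio)))
    return feeds
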