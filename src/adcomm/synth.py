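"""Synthetic anaerobic co-digestion datasets with known ground truth.

Generates everything the analysis pipeline consumes: small guild-structured
species models wired into the anaerobic-digestion trophic chain, a
49-sample feed series replaying a food-waste (FW) gradient over four
semi-continuous reactors (ramp-up, plateau, a two-week FW pulse, return),
relative-abundance time series with planted positive/negative couplings,
and noisy CH4/CO2/PTR measurement series derived from cooperative
trade-off FBA solutions at a known trade-off ``ct*``.

Guild roster (20 species by default)
------------------------------------
The five core guilds of the methanogenic food web, all coupled to one
latent abundance factor that also tracks the FW gradient:

* ``hydrolyzer`` — secretes an extracellular amylase (starch -> glucose, a
  community-public good) and ferments part of the glucose itself;
* ``fermenter`` — glucose -> acetate + CO2 + H2;
* ``sao`` — syntrophic acid oxidizer, propionate -> acetate + CO2 + H2;
* ``acetoclast`` — acetate -> CH4 + CO2;
* ``hydrogenotroph`` — 4 H2 + CO2 -> CH4.

Around them: a protein pair (extracellular protease feeding a glutamate
fermenter), a lipid pair (extracellular lipase feeding a glycerol
fermenter), five competitor clones planted with anti-correlated abundances
(for acetate, glutamate, glycerol, xylose and galactose), two dedicated
sugar-fermenter pairs hosting two of those competitions, and four neutral
filler species with independent abundances and private substrates.

Every planted mutualism is an actual export->import flux route above the
0.01 mmol gDW^-1 h^-1 evidence threshold when the communities are solved,
and every planted competition is a shared import of the same compound, so
the interaction-inference stage can be scored against exact ground truth.

Stoichiometries use whole-number textbook ratios (glucose -> 2 acetate +
2 CO2 + 4 H2; 4 H2 + CO2 -> CH4; acetate -> CH4 + CO2) so closed-form
oracles exist for the methane yields.  Growth couples to catabolism
through an ATP pseudo-metabolite consumed by the biomass reaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compounds as cpdlib
from .augment import EnzymeAnnotation, augment_model, builtin_template
from .fba import solve_ctfba
from .medium import (FeedstockRecipe, NutrientTable, SampleFeed,
                     apply_vfa_constraints, compute_medium, mix_media)
from .model import (AnalysisConfig, CommunityModel, FluxSolution, Metabolite,
                    Reaction, SpeciesModel, build_community, model_to_dict)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_guild_models",
    "generate_feed_series",
    "generate_abundance_series",
    "generate_measurements",
    "default_fw_recipe",
    "default_nutrient_table",
    "default_ss_medium",
    "run_pipeline",
    "write_dataset",
    "CORE_GUILDS",
    "ARCHAEA",
]

SAMPLING_DAYS = (8, 20, 30, 34, 69, 83, 114, 125, 128, 135, 140, 161)
PULSE_DAYS = range(125, 140)  # extra FW for two weeks from day 125

CORE_GUILDS = ("hydrolyzer", "fermenter", "sao", "acetoclast", "hydrogenotroph")
ARCHAEA = ("acetoclast", "acetoclast_b", "hydrogenotroph")

#: latent abundance factors: (positive members, negative members)
_FACTORS = (
    (("hydrolyzer", "fermenter", "sao", "acetoclast", "hydrogenotroph"), ("acetoclast_b",)),
    (("protein_degrader", "glutamate_fermenter"), ("glutamate_fermenter_b",)),
    (("lipid_degrader", "glycerol_fermenter"), ("glycerol_fermenter_b",)),
    (("xylose_fermenter",), ("xylose_fermenter_b",)),
    (("galactose_fermenter",), ("galactose_fermenter_b",)),
)

_FILLERS = ("filler_fru", "filler_man", "filler_ara", "filler_rib")

#: planted interactions: (type, species_a, species_b, compounds)
_TRUE_EDGES = (
    ("mutualism", "hydrolyzer", "fermenter", ("glc",)),
    ("mutualism", "hydrolyzer", "acetoclast", ("ac",)),
    ("mutualism", "hydrolyzer", "hydrogenotroph", ("h2",)),
    ("mutualism", "fermenter", "acetoclast", ("ac",)),
    ("mutualism", "fermenter", "hydrogenotroph", ("h2",)),
    ("mutualism", "sao", "acetoclast", ("ac",)),
    ("mutualism", "sao", "hydrogenotroph", ("h2",)),
    ("mutualism", "acetoclast", "hydrogenotroph", ("co2",)),
    ("mutualism", "protein_degrader", "glutamate_fermenter", ("glu",)),
    ("mutualism", "lipid_degrader", "glycerol_fermenter", ("glyc",)),
    ("competition", "acetoclast", "acetoclast_b", ("ac",)),
    ("competition", "glutamate_fermenter", "glutamate_fermenter_b", ("glu",)),
    ("competition", "glycerol_fermenter", "glycerol_fermenter_b", ("glyc",)),
    ("competition", "xylose_fermenter", "xylose_fermenter_b", ("xyl",)),
    ("competition", "galactose_fermenter", "galactose_fermenter_b", ("gal",)),
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults replay the study design: 49 samples over 4 reactors and 12
    sampling days (plus one extra mid-ramp sample), 20 species, 10 planted
    mutualisms and 5 planted competitions, measurements generated at
    ``true_tradeoff`` with Gaussian noise of sd ``noise_sd``
    (mmol gVS^-1 h^-1) truncated at zero.
    """

    n_samples: int = 49
    n_species: int = 20
    coupling: float = 0.97      # latent-factor loading of planted pairs
    log_sd: float = 0.35        # sd of species log-abundance fluctuations
    fw_factor_weight: float = 0.45  # how strongly factor 1 tracks the FW gradient
    noise_sd: float = 0.02
    ptr_slope: float = 3.0
    ptr_intercept: float = -0.5
    ptr_noise_sd: float = 0.1
    true_tradeoff: float = 0.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10 for correlation screening")
        if self.n_species != 20:
            raise ValueError("the guild roster is fixed at 20 species")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")


@dataclass
class GroundTruth:
    edges: list[tuple[str, str, str, tuple[str, ...]]]
    true_tradeoff: float
    true_ch4: dict[str, float] = field(default_factory=dict)
    true_co2: dict[str, float] = field(default_factory=dict)

    def edge_set(self, kind: str) -> set[frozenset]:
        return {frozenset((a, b)) for t, a, b, _ in self.edges if t == kind}


# ---------------------------------------------------------------------------
# Species models
# ---------------------------------------------------------------------------

def _species(sid: str, taxonomy: str,
             imports: dict[str, float],
             exports: tuple[str, ...],
             catabolism: dict[str, dict[str, float]],
             biomass_atp: float = 50.0,
             biomass_n: float = 0.01) -> SpeciesModel:
    """Assemble one guild model from compound-level shorthand.

    ``imports`` maps compound -> uptake Vmax (mmol gDW^-1 h^-1);
    ``catabolism`` maps reaction id -> stoichiometry over compound ids
    (plus ``atp``).  Water is freely exchangeable in both directions.
    """
    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}

    def ensure(cpd: str, comp: str) -> str:
        mid = f"{cpd}_{comp}"
        if mid not in mets:
            mets[mid] = Metabolite(id=mid, compartment=comp, name=cpd,
                                   formula=cpdlib.FORMULAS.get(cpd))
        return mid

    def ensure_exchange(cpd: str) -> None:
        ex = f"EX_{cpd}"
        if ex not in rxns:
            rxns[ex] = Reaction(ex, {ensure(cpd, "e"): -1.0, ensure(cpd, "m"): 1.0},
                                lower_bound=-100.0, upper_bound=100.0,
                                is_exchange=True)

    for cpd, vmax in imports.items():
        ensure_exchange(cpd)
        rxns[f"T_{cpd}_in"] = Reaction(
            f"T_{cpd}_in", {ensure(cpd, "e"): -1.0, ensure(cpd, "c"): 1.0},
            lower_bound=0.0, upper_bound=vmax)
    for cpd in exports:
        ensure_exchange(cpd)
        rid = f"T_{cpd}_out"
        if rid not in rxns:
            rxns[rid] = Reaction(rid, {ensure(cpd, "c"): -1.0, ensure(cpd, "e"): 1.0},
                                 lower_bound=0.0, upper_bound=100.0)
    # water moves freely
    ensure_exchange("h2o")
    rxns["T_h2o"] = Reaction("T_h2o", {ensure("h2o", "e"): -1.0, ensure("h2o", "c"): 1.0},
                             lower_bound=-100.0, upper_bound=100.0)
    for rid, stoich in catabolism.items():
        mapped = {}
        for cpd, coeff in stoich.items():
            mapped[ensure(cpd, "c")] = coeff
        rxns[rid] = Reaction(rid, mapped, lower_bound=0.0, upper_bound=100.0)
    # nitrogen for growth (omitted entirely when the requirement is zero)
    biomass_stoich = {ensure("atp", "c"): -biomass_atp}
    if biomass_n > 0:
        if "nh3" not in imports:
            ensure_exchange("nh3")
            rxns["T_nh3_in"] = Reaction(
                "T_nh3_in", {ensure("nh3", "e"): -1.0, ensure("nh3", "c"): 1.0},
                lower_bound=0.0, upper_bound=10.0)
        biomass_stoich[ensure("nh3", "c")] = -biomass_n
    rxns["BIOMASS"] = Reaction("BIOMASS", biomass_stoich,
                               lower_bound=0.0, upper_bound=100.0)
    return SpeciesModel(species_id=sid, taxonomy_label=taxonomy,
                        metabolites=mets, reactions=rxns,
                        biomass_reaction_id="BIOMASS")


_GLC_FERMENT = {"glc": -1.0, "h2o": -2.0, "ac": 2.0, "co2": 2.0, "h2": 4.0, "atp": 4.0}


def generate_guild_models(spec: SyntheticSpec | None = None) -> dict[str, SpeciesModel]:
    """Build the 20-species roster (order fixed, independent of the seed)."""
    template = builtin_template()
    models: dict[str, SpeciesModel] = {}

    def add(m: SpeciesModel) -> None:
        models[m.species_id] = m

    hydrolyzer = _species(
        "hydrolyzer", "Bacteroidales sp. (amylolytic)",
        imports={}, exports=("ac", "co2", "h2"),
        catabolism={"FERM_GLC": _GLC_FERMENT})
    hydrolyzer = augment_model(hydrolyzer, [template.entries["EC3.2.1.1"]])
    add(hydrolyzer)
    add(_species("fermenter", "Firmicutes sp. (saccharolytic)",
                 imports={"glc": 10.0}, exports=("ac", "co2", "h2"),
                 catabolism={"FERM_GLC": _GLC_FERMENT}))
    add(_species("sao", "Syntrophobacter sp. (propionate oxidizer)",
                 imports={"prop": 10.0}, exports=("ac", "co2", "h2"),
                 catabolism={"SAO_PROP": {"prop": -1.0, "h2o": -2.0, "ac": 1.0,
                                          "co2": 1.0, "h2": 3.0, "atp": 1.0}}))
    for sid, tax in (("acetoclast", "Methanothrix sp. 1"),
                     ("acetoclast_b", "Methanothrix sp. 2")):
        add(_species(sid, tax,
                     imports={"ac": 10.0}, exports=("ch4", "co2"),
                     catabolism={"ACM": {"ac": -1.0, "ch4": 1.0, "co2": 1.0, "atp": 1.0}},
                     biomass_atp=20.0))
    add(_species("hydrogenotroph", "Methanoculleus sp.",
                 imports={"h2": 40.0, "co2": 40.0}, exports=("ch4",),
                 catabolism={"HYM": {"h2": -4.0, "co2": -1.0, "ch4": 1.0,
                                     "h2o": 2.0, "atp": 1.5}},
                 biomass_atp=20.0))
    deaminate_ala = {"ala": -1.0, "h2o": -2.0, "ac": 1.0, "co2": 1.0,
                     "nh3": 1.0, "h2": 2.0, "atp": 1.0}
    protein_degrader = _species(
        "protein_degrader", "Proteiniphilum sp.",
        imports={"ala": 10.0}, exports=("ac", "co2", "h2", "nh3"),
        catabolism={"STICK_ALA": deaminate_ala})
    protein_degrader = augment_model(protein_degrader, [template.entries["EC3.4.21.x"]])
    add(protein_degrader)
    add(_species("glutamate_fermenter", "Acidaminococcus sp.",
                 imports={"glu": 10.0}, exports=("ac", "co2", "h2", "nh3"),
                 catabolism={"FERM_GLU": {"glu": -1.0, "h2o": -2.0, "ac": 2.0,
                                          "co2": 1.0, "nh3": 1.0, "h2": 1.0,
                                          "atp": 1.0}}))
    add(_species("glutamate_fermenter_b", "Peptoniphilus sp.",
                 imports={"glu": 10.0}, exports=("ac", "co2", "h2", "nh3"),
                 catabolism={"FERM_GLU": {"glu": -1.0, "h2o": -2.0, "ac": 2.0,
                                          "co2": 1.0, "nh3": 1.0, "h2": 1.0,
                                          "atp": 1.0}}))
    lipid_degrader = _species(
        "lipid_degrader", "Olb16 sp. (lipolytic)",
        imports={"oct": 5.0}, exports=("ac", "h2"),
        catabolism={"BOX_OCT": {"oct": -1.0, "h2o": -6.0, "ac": 4.0,
                                "h2": 6.0, "atp": 2.0}})
    lipid_degrader = augment_model(lipid_degrader, [template.entries["EC3.1.1.3"]])
    add(lipid_degrader)
    glyc_ferment = {"glyc": -1.0, "lac": 1.0, "h2": 1.0, "atp": 1.0}
    for sid, tax in (("glycerol_fermenter", "Kiritimatiellae sp. 1"),
                     ("glycerol_fermenter_b", "Kiritimatiellae sp. 2")):
        add(_species(sid, tax, imports={"glyc": 10.0}, exports=("lac", "h2"),
                     catabolism={"FERM_GLYC": glyc_ferment}))
    xyl_ferment = {"xyl": -3.0, "lac": 5.0, "atp": 5.0}
    for sid, tax in (("xylose_fermenter", "Bacteroides sp. X1"),
                     ("xylose_fermenter_b", "Bacteroides sp. X2")):
        add(_species(sid, tax, imports={"xyl": 10.0}, exports=("lac",),
                     catabolism={"FERM_XYL": xyl_ferment}))
    for sid, tax in (("galactose_fermenter", "Lactobacillus sp. G1"),
                     ("galactose_fermenter_b", "Lactobacillus sp. G2")):
        add(_species(sid, tax, imports={"gal": 10.0}, exports=("lac",),
                     catabolism={"FERM_GAL": {"gal": -1.0, "lac": 2.0, "atp": 2.0}}))
    for sid, sugar in (("filler_fru", "fru"), ("filler_man", "man"),
                       ("filler_ara", "ara"), ("filler_rib", "rib")):
        stoich = ({sugar: -1.0, "lac": 2.0, "atp": 2.0}
                  if cpdlib.FORMULAS[sugar] == "C6H12O6"
                  else {sugar: -3.0, "lac": 5.0, "atp": 5.0})
        add(_species(sid, f"Anaerolineaceae sp. ({sugar})",
                     imports={sugar: 10.0}, exports=("lac",),
                     catabolism={f"FERM_{sugar.upper()}": stoich}))
    return models


def guild_annotations() -> list[EnzymeAnnotation]:
    """The enzyme annotations the roster's hydrolyzers carry."""
    return [
        EnzymeAnnotation("hydrolyzer", "EC3.2.1.1", "extracellular"),
        EnzymeAnnotation("protein_degrader", "EC3.4.21.x", "extracellular"),
        EnzymeAnnotation("lipid_degrader", "EC3.1.1.3", "extracellular"),
    ]


# ---------------------------------------------------------------------------
# Feeds and media
# ---------------------------------------------------------------------------

def default_fw_recipe() -> FeedstockRecipe:
    """Food-waste recipe over the study's eight food components (g/L)."""
    return FeedstockRecipe(
        components={"apple": 15.0, "banana": 15.0, "bread": 20.0, "cabbage": 10.0,
                    "chicken": 10.0, "eggplant": 10.0, "mince": 10.0, "onion": 10.0},
        vs_fraction=0.2, label="FW")


def default_nutrient_table() -> NutrientTable:
    path = Path(__file__).parent / "data" / "nutrient_table.tsv"
    return NutrientTable.from_tsv(path)


def default_ss_medium() -> dict[str, float]:
    from .medium import read_medium_tsv

    return read_medium_tsv(Path(__file__).parent / "data" / "ss_medium.tsv")


def cmol_fractions(medium: dict[str, float]) -> dict[str, float]:
    """Carbon-mole share of each molecule class in a medium."""
    totals: dict[str, float] = {}
    for cpd, flux in medium.items():
        c = cpdlib.carbon_atoms(cpd)
        if c == 0:
            continue
        cls = cpdlib.CLASSES.get(cpd, "other")
        totals[cls] = totals.get(cls, 0.0) + flux * c
    grand = sum(totals.values())
    return {cls: v / grand for cls, v in totals.items()} if grand else {}


#: C-mol share of carbohydrates the default FW recipe + nutrient table aim for
FW_CARB_FRACTION = 0.72


def generate_feed_series(spec: SyntheticSpec) -> list[SampleFeed]:
    """Per-sample SS/FW loads replaying the reactor gradient.

    Four reactors fed 1.5 g VS L^-1 d^-1 of sludge; reactors 2-4 ramp food
    waste to +1.0/+2.0/+3.0 g VS L^-1 d^-1 over 30 days; all reactors get an
    extra 2 g VS L^-1 d^-1 FW pulse on days 125-139.  One extra mid-ramp
    sample (reactor 3, day 50) brings the default count to 49.
    """
    targets = {1: 0.0, 2: 1.0, 3: 2.0, 4: 3.0}
    points = [(r, d) for r in (1, 2, 3, 4) for d in SAMPLING_DAYS]
    points.append((3, 50))
    points.sort()
    feeds = []
    for reactor, day in points[: spec.n_samples]:
        ss = 1.5
        fw = targets[reactor] * min(1.0, day / 30.0)
        if day in PULSE_DAYS:
            fw += 2.0
        ratio = fw / (fw + ss)
        feeds.append(SampleFeed(sample_id=f"r{reactor}_d{day:03d}", day=day,
                                reactor=reactor, ss_load=ss, fw_load=fw,
                                g_fw_per_l_vs=ratio))
    return feeds


def sample_media(feeds: list[SampleFeed],
                 fw_recipe: FeedstockRecipe | None = None,
                 nutrient_table: NutrientTable | None = None,
                 ss_medium: dict[str, float] | None = None) -> dict[str, dict[str, float]]:
    fw_recipe = fw_recipe or default_fw_recipe()
    nutrient_table = nutrient_table or default_nutrient_table()
    ss_medium = ss_medium or default_ss_medium()
    fw_medium = compute_medium(fw_recipe, nutrient_table)
    return {
        f.sample_id: mix_media(ss_medium, fw_medium, f.ss_load, f.fw_load)
        for f in feeds
    }


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------

_BASE_ABUNDANCE = {"hydrolyzer": 0.09, "fermenter": 0.09, "sao": 0.06,
                   "acetoclast": 0.07, "hydrogenotroph": 0.06,
                   "acetoclast_b": 0.05}


def generate_abundance_series(
    spec: SyntheticSpec,
    feeds: list[SampleFeed] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Log-normal abundances with planted pairwise couplings.

    Each latent factor drives one interacting group; members load
    ``+coupling`` and planted competitors ``-coupling`` on their factor, on
    the log scale, with sd ``log_sd``.  Factor 1 (the methanogenic chain)
    additionally tracks the FW gradient.  Rows are renormalized to sum to 1.
    """
    rng = np.random.default_rng(spec.rng_seed)
    feeds = feeds if feeds is not None else generate_feed_series(spec)
    n = len(feeds)
    models_order = list(generate_guild_models(spec))
    fw = np.array([f.fw_load for f in feeds])
    z_fw = (fw - fw.mean()) / (fw.std() if fw.std() > 0 else 1.0)

    factors = rng.standard_normal((len(_FACTORS), n))
    w = spec.fw_factor_weight
    factors[0] = w * z_fw + np.sqrt(1 - w ** 2) * factors[0]

    lam = spec.coupling
    noise_scale = np.sqrt(max(0.0, 1 - lam ** 2))
    log_ab = np.empty((n, len(models_order)))
    for j, sid in enumerate(models_order):
        loading = 0.0
        for fi, (pos, neg) in enumerate(_FACTORS):
            if sid in pos:
                loading, fidx = lam, fi
            elif sid in neg:
                loading, fidx = -lam, fi
        base = np.log(_BASE_ABUNDANCE.get(sid, 0.04))
        eps = rng.standard_normal(n)
        if loading:
            signal = loading * factors[fidx] + noise_scale * eps
        else:
            signal = eps
        log_ab[:, j] = base + spec.log_sd * signal
    ab = np.exp(log_ab)
    ab /= ab.sum(axis=1, keepdims=True)
    df = pd.DataFrame(ab, index=[f.sample_id for f in feeds], columns=models_order)
    truth = GroundTruth(edges=[(t, a, b, c) for t, a, b, c in _TRUE_EDGES],
                        true_tradeoff=spec.true_tradeoff)
    return df, truth


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSeries:
    """Per-sample biochemical measurements.

    ``table`` is indexed by sample id with columns ``ch4_rate``, ``co2_rate``
    (mmol gVS^-1 h^-1), ``ph``, and VFA concentrations (mmol/L);
    ``log2_ptr`` is (sample x archaeon).
    """

    table: pd.DataFrame
    log2_ptr: pd.DataFrame

    @property
    def ch4(self) -> pd.Series:
        return self.table["ch4_rate"]

    @property
    def co2(self) -> pd.Series:
        return self.table["co2_rate"]


def generate_measurements(spec: SyntheticSpec,
                          solutions: dict[str, FluxSolution],
                          feeds: list[SampleFeed],
                          config: AnalysisConfig | None = None) -> MeasurementSeries:
    """Noisy measurement series consistent with the simulated fluxes."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(spec.rng_seed + 1)
    rows = []
    ptr_rows = {}
    feed_by_id = {f.sample_id: f for f in feeds}
    for sample_id in sorted(solutions):
        sol = solutions[sample_id]
        if not sol.optimal:
            raise ValueError(f"sample {sample_id}: solution is {sol.status}")
        ch4 = sol.community_exchange.get(config.ch4_id, 0.0)
        co2 = sol.community_exchange.get(config.co2_id, 0.0)
        f = feed_by_id[sample_id]
        rows.append({
            "sample_id": sample_id,
            "ch4_rate": max(0.0, ch4 + rng.normal(0.0, spec.noise_sd)),
            "co2_rate": max(0.0, co2 + rng.normal(0.0, spec.noise_sd)),
            "ph": round(7.3 - 0.2 * f.g_fw_per_l_vs + rng.normal(0.0, 0.05), 3),
            "vfa_ac": max(0.0, 10.0 + 8.0 * f.g_fw_per_l_vs + rng.normal(0.0, 1.0)),
            "vfa_prop": max(0.0, 4.0 + 3.0 * f.g_fw_per_l_vs + rng.normal(0.0, 0.5)),
            "vfa_but": max(0.0, 1.0 + rng.normal(0.0, 0.2)),
        })
        ptr_rows[sample_id] = {
            arch: spec.ptr_intercept + spec.ptr_slope * sol.growth_rates.get(arch, 0.0)
            + rng.normal(0.0, spec.ptr_noise_sd)
            for arch in ARCHAEA
        }
    table = pd.DataFrame(rows).set_index("sample_id")
    ptr = pd.DataFrame(ptr_rows).T.loc[table.index]
    return MeasurementSeries(table=table, log2_ptr=ptr)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    models: dict[str, SpeciesModel]
    feeds: list[SampleFeed]
    media: dict[str, dict[str, float]]
    abundances: pd.DataFrame
    ground_truth: GroundTruth
    communities: dict[str, CommunityModel]
    solutions: dict[str, FluxSolution]
    measurements: MeasurementSeries


def build_communities(models: dict[str, SpeciesModel],
                      abundances: pd.DataFrame,
                      media: dict[str, dict[str, float]],
                      measurements: MeasurementSeries | None = None,
                      config: AnalysisConfig | None = None,
                      tradeoff: float = 0.7,
                      reactor_vs_g_per_l: float = 20.0) -> dict[str, CommunityModel]:
    """One community model per sample; VFA measurements, when available,
    are folded into each sample's medium as extra availabilities."""
    config = config or AnalysisConfig()
    out = {}
    for sample_id, row in abundances.iterrows():
        medium = media[sample_id]
        if measurements is not None and sample_id in measurements.table.index:
            m = measurements.table.loc[sample_id]
            medium = apply_vfa_constraints(
                medium, {"ac": m["vfa_ac"], "prop": m["vfa_prop"], "but": m["vfa_but"]},
                turnover=config.vfa_turnover, vs_g_per_l=reactor_vs_g_per_l)
        out[sample_id] = build_community(models, row.to_dict(), medium,
                                         config=config, tradeoff=tradeoff)
    return out


def run_pipeline(spec: SyntheticSpec,
                 config: AnalysisConfig | None = None) -> SyntheticDataset:
    """Generate models, feeds, abundances, solve every sample at ``ct*``,
    and derive noisy measurements."""
    config = config or AnalysisConfig()
    models = generate_guild_models(spec)
    feeds = generate_feed_series(spec)
    media = sample_media(feeds)
    abundances, truth = generate_abundance_series(spec, feeds)
    communities = build_communities(models, abundances, media, config=config,
                                    tradeoff=spec.true_tradeoff)
    solutions = {sid: solve_ctfba(cm, spec.true_tradeoff)
                 for sid, cm in communities.items()}
    for sid, sol in solutions.items():
        truth.true_ch4[sid] = sol.community_exchange.get(config.ch4_id, 0.0)
        truth.true_co2[sid] = sol.community_exchange.get(config.co2_id, 0.0)
    measurements = generate_measurements(spec, solutions, feeds, config)
    return SyntheticDataset(spec=spec, models=models, feeds=feeds, media=media,
                            abundances=abundances, ground_truth=truth,
                            communities=communities, solutions=solutions,
                            measurements=measurements)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every pipeline input as plain-text TSV/JSON (deterministic bytes)."""
    out = Path(outdir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    for sid in sorted(ds.models):
        with open(out / "models" / f"{sid}.json", "w") as fh:
            json.dump(model_to_dict(ds.models[sid]), fh, indent=1, sort_keys=True)
            fh.write("\n")
    ds.abundances.round(10).to_csv(out / "abundance.tsv", sep="\t",
                                   index_label="sample_id")
    pd.DataFrame([{
        "sample_id": f.sample_id, "day": f.day, "reactor": f.reactor,
        "ss_load": f.ss_load, "fw_load": f.fw_load,
        "g_fw_per_l_vs": round(f.g_fw_per_l_vs, 10), "fw_group": f.fw_group,
    } for f in ds.feeds]).to_csv(out / "samples.tsv", sep="\t", index=False)
    media_rows = [
        {"sample_id": sid, "compound_id": cpd, "max_uptake_mmol_gVS_h": round(v, 12)}
        for sid in sorted(ds.media) for cpd, v in sorted(ds.media[sid].items())
    ]
    pd.DataFrame(media_rows).to_csv(out / "media.tsv", sep="\t", index=False)
    ds.measurements.table.round(10).to_csv(out / "measurements.tsv", sep="\t",
                                           index_label="sample_id")
    ds.measurements.log2_ptr.round(10).to_csv(out / "log2_ptr.tsv", sep="\t",
                                              index_label="sample_id")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "true_tradeoff": ds.ground_truth.true_tradeoff,
            "edges": [{"type": t, "a": a, "b": b, "compounds": list(c)}
                      for t, a, b, c in ds.ground_truth.edges],
            "true_ch4": {k: round(v, 12) for k, v in sorted(ds.ground_truth.true_ch4.items())},
            "true_co2": {k: round(v, 12) for k, v in sorted(ds.ground_truth.true_co2.items())},
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")
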