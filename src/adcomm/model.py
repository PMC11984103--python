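"""Stoichiometric model containers, JSON IO, validation, and community assembly.

A :class:`SpeciesModel` is one organism's metabolic network.  Metabolites live
in one of three compartments:

``c``
    cytosol (species-scoped),
``e``
    the species' own extracellular space (species-scoped; extracellular
    hydrolysis happens here),
``m``
    the shared medium.

Metabolite ids carry their compartment as a suffix (``glc_c``, ``glc_e``,
``glc_m``); the compound id is the prefix.  An *exchange* reaction moves a
compound between the species extracellular space and the medium
(``glc_e <-> glc_m``); positive flux is secretion into the medium, negative
flux is uptake.  Species-level fluxes are per gram dry weight of that species
(mmol gDW^-1 h^-1); community-level quantities are per gram volatile solids
(mmol gVS^-1 h^-1), linked by relative abundances and the single conversion
factor ``gdw_per_gvs``.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "SpeciesModel",
    "CommunityModel",
    "FluxSolution",
    "ValidationReport",
    "AnalysisConfig",
    "ModelError",
    "FormatError",
    "AssemblyError",
    "compound_of",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "validate_model",
    "build_community",
    "apply_bound_overrides",
]

COMPARTMENTS = ("c", "e", "m")

#: Standard atomic composition parser supports these elements only; enough for
#: the C/H/N/O/P/S chemistry of anaerobic digestion intermediates.
_ELEMENTS = ("C", "H", "N", "O", "P", "S")


class ModelError(ValueError):
    """A model violates a structural invariant."""


class FormatError(ValueError):
    """A file does not parse under the declared format."""


class AssemblyError(ValueError):
    """Community assembly cannot produce a valid community."""


def compound_of(metabolite_id: str) -> str:
    """Strip the compartment suffix from a metabolite id (``ac_m`` -> ``ac``)."""
    stem, _, comp = metabolite_id.rpartition("_")
    if not stem or comp not in COMPARTMENTS:
        raise ModelError(f"metabolite id {metabolite_id!r} lacks a _c/_e/_m compartment suffix")
    return stem


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r} "
                f"(expected one of {COMPARTMENTS})"
            )
        if compound_of(self.id) and not self.id.endswith("_" + self.compartment):
            raise ModelError(
                f"metabolite {self.id!r}: id suffix disagrees with compartment {self.compartment!r}"
            )

    def elements(self) -> dict[str, int] | None:
        """Parse the chemical formula into element counts (None if no formula)."""
        if not self.formula:
            return None
        counts: dict[str, int] = {}
        i, n = 0, len(self.formula)
        while i < n:
            el = self.formula[i]
            i += 1
            if i < n and self.formula[i].islower():
                el += self.formula[i]
                i += 1
            num = ""
            while i < n and self.formula[i].isdigit():
                num += self.formula[i]
                i += 1
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        return counts


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    is_extracellular: bool = False
    gene_rule: str | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class SpeciesModel:
    species_id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str
    taxonomy_label: str = ""
    extracellular_enzymes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_structure()

    def _check_structure(self) -> None:
        if not self.reactions:
            raise ModelError(f"model {self.species_id!r}: empty reaction list")
        if self.biomass_reaction_id not in self.reactions:
            raise ModelError(
                f"model {self.species_id!r}: biomass reaction "
                f"{self.biomass_reaction_id!r} not found"
            )
        for rxn in self.reactions.values():
            medium_mets = []
            for met_id in rxn.stoichiometry:
                met = self.metabolites.get(met_id)
                if met is None:
                    raise ModelError(
                        f"model {self.species_id!r}: reaction {rxn.id!r} references "
                        f"undeclared metabolite {met_id!r}"
                    )
                if met.compartment == "m":
                    medium_mets.append(met_id)
            if rxn.is_exchange:
                if len(medium_mets) != 1:
                    raise ModelError(
                        f"model {self.species_id!r}: exchange reaction {rxn.id!r} must "
                        f"touch exactly one medium metabolite, found {medium_mets}"
                    )
            elif medium_mets:
                raise ModelError(
                    f"model {self.species_id!r}: non-exchange reaction {rxn.id!r} "
                    f"touches medium metabolites {medium_mets}"
                )

    # -- convenience -------------------------------------------------------
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def exchanged_compound(self, rxn: Reaction) -> str:
        """The medium compound an exchange reaction moves."""
        for met_id in rxn.stoichiometry:
            if self.metabolites[met_id].compartment == "m":
                return compound_of(met_id)
        raise ModelError(f"reaction {rxn.id!r} exchanges no medium metabolite")

    def copy(self) -> "SpeciesModel":
        return copy.deepcopy(self)


@dataclass
class CommunityModel:
    """Abundance-weighted union of species models sharing one medium.

    ``medium`` maps compound id -> maximum community uptake flux
    (mmol gVS^-1 h^-1, >= 0).  Compounds absent from the medium cannot be
    taken up by the community but can always be secreted.
    """

    members: list[tuple[SpeciesModel, float]]
    medium: dict[str, float]
    tradeoff: float = 0.7
    gdw_per_gvs: float = 1.0

    def __post_init__(self) -> None:
        if not self.members:
            raise AssemblyError("community has no members")
        total = sum(a for _, a in self.members)
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise AssemblyError(f"member abundances sum to {total}, expected 1")
        for cpd, v in self.medium.items():
            if v < 0:
                raise AssemblyError(f"medium bound for {cpd!r} is negative ({v})")
        if not (0.0 < self.tradeoff <= 1.0):
            raise AssemblyError(f"tradeoff {self.tradeoff} outside (0, 1]")

    @property
    def species_ids(self) -> list[str]:
        return [m.species_id for m, _ in self.members]

    def abundance(self, species_id: str) -> float:
        for m, a in self.members:
            if m.species_id == species_id:
                return a
        raise KeyError(species_id)


@dataclass
class FluxSolution:
    """Result of one community solve.

    Species fluxes are per gDW of that species; ``community_exchange`` is per
    gVS of community (negative = net community uptake, positive = secretion).
    """

    status: str  # "optimal" | "infeasible" | "unbounded"
    per_species_fluxes: dict[tuple[str, str], float] = field(default_factory=dict)
    growth_rates: dict[str, float] = field(default_factory=dict)
    community_growth: float = float("nan")
    community_exchange: dict[str, float] = field(default_factory=dict)
    species_exchange: dict[tuple[str, str], float] = field(default_factory=dict)
    mu_c_star: float = float("nan")  # stage-1 optimum, set by solve_ctfba

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ValidationReport:
    species_id: str
    growth_rate: float
    grows: bool
    dead_end_metabolites: list[str] = field(default_factory=list)
    mass_imbalanced_reactions: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.grows and not self.dead_end_metabolites and not self.mass_imbalanced_reactions


@dataclass
class AnalysisConfig:
    """Analysis thresholds and conventions, with the study's printed defaults.

    ``abundance_inclusion``: species below this relative abundance are dropped
    per sample (0.1%).  ``corr_r_threshold``/``corr_p_threshold``: abundance
    correlation screen (|r| >= 0.65, p < 0.001).  ``flux_threshold``: minimum
    import/export flux (mmol gDW^-1 h^-1) counting as exchange evidence.
    ``tradeoff_grid``: cooperative trade-off values explored (0.4..1.0 by 0.05).
    ``fw_cutoffs``: food-waste group boundaries in g FW / L VS.
    ``vfa_turnover``: converts a VFA concentration (mmol/L) into an extra
    medium availability; defaults to one reactor turnover per hydraulic
    retention time (HRT = 21 days).
    """

    abundance_inclusion: float = 0.001
    corr_r_threshold: float = 0.65
    corr_p_threshold: float = 0.001
    flux_threshold: float = 0.01
    tradeoff_grid: tuple[float, ...] = tuple(round(0.4 + 0.05 * i, 2) for i in range(13))
    fw_cutoffs: tuple[float, float] = (0.2, 0.6)
    solver_tolerance: float = 1e-9
    rng_seed: int = 0
    min_samples: int = 1
    use_fdr: bool = False
    vfa_turnover: float = 1.0 / (21.0 * 24.0)
    gdw_per_gvs: float = 1.0
    ch4_id: str = "ch4"
    co2_id: str = "co2"
    tsne_perplexity: float = 20.0
    #: ubiquitous compounds excluded from interaction flux evidence — water
    #: is exchanged by essentially every organism and carries no niche signal
    currency_compounds: tuple[str, ...] = ("h2o",)

    def __post_init__(self) -> None:
        for name in ("abundance_inclusion", "corr_r_threshold", "corr_p_threshold", "flux_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(not 0 < t <= 1 for t in self.tradeoff_grid):
            raise ValueError("tradeoff_grid values must lie in (0, 1]")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(m: SpeciesModel) -> dict:
    return {
        "species_id": m.species_id,
        "taxonomy_label": m.taxonomy_label,
        "biomass_reaction_id": m.biomass_reaction_id,
        "extracellular_enzymes": [list(t) for t in m.extracellular_enzymes],
        "metabolites": [
            {
                "id": met.id,
                "name": met.name,
                "compartment": met.compartment,
                "formula": met.formula,
                "charge": met.charge,
            }
            for met in sorted(m.metabolites.values(), key=lambda x: x.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_extracellular": r.is_extracellular,
                "gene_rule": r.gene_rule,
            }
            for r in sorted(m.reactions.values(), key=lambda x: x.id)
        ],
    }


def model_from_dict(d: dict) -> SpeciesModel:
    try:
        mets = {
            e["id"]: Metabolite(
                id=e["id"],
                compartment=e["compartment"],
                name=e.get("name", ""),
                formula=e.get("formula"),
                charge=e.get("charge"),
            )
            for e in d["metabolites"]
        }
        rxns = {
            e["id"]: Reaction(
                id=e["id"],
                stoichiometry={k: float(v) for k, v in e["stoichiometry"].items()},
                name=e.get("name", ""),
                lower_bound=float(e.get("lower_bound", -1000.0)),
                upper_bound=float(e.get("upper_bound", 1000.0)),
                is_exchange=bool(e.get("is_exchange", False)),
                is_extracellular=bool(e.get("is_extracellular", False)),
                gene_rule=e.get("gene_rule"),
            )
            for e in d["reactions"]
        }
        return SpeciesModel(
            species_id=d["species_id"],
            taxonomy_label=d.get("taxonomy_label", ""),
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=d["biomass_reaction_id"],
            extracellular_enzymes=[tuple(t) for t in d.get("extracellular_enzymes", [])],
        )
    except KeyError as exc:
        raise FormatError(f"model JSON missing required field: {exc}") from exc


def read_model(path, format: str = "json") -> SpeciesModel:
    """Read a species model from ``path`` (``json`` dialect or ``sbml`` L3/FBC)."""
    if format == "json":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        return model_from_dict(d)
    if format == "sbml":
        from .sbml import read_sbml_model

        return read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(m: SpeciesModel, path, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(m), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format == "sbml":
        from .sbml import write_sbml_model

        write_sbml_model(m, path)
        return
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _mass_imbalance(m: SpeciesModel, rxn: Reaction) -> bool:
    """True if the formula-bearing participants do not balance elementally.

    Metabolites without a formula (accounting pseudo-compounds such as ATP
    proxies and biomass) are treated as massless, so energy- and
    growth-coupling terms do not mask a genuine elemental imbalance.
    """
    totals: dict[str, float] = {}
    for met_id, coeff in rxn.stoichiometry.items():
        elems = m.metabolites[met_id].elements()
        if elems is None:
            continue
        for el, n in elems.items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    return any(abs(v) > 1e-6 for v in totals.values())


def _dead_ends(m: SpeciesModel) -> list[str]:
    """Species-scoped metabolites that can only be produced or only consumed."""
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in m.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            if (coeff > 0 and fwd) or (coeff < 0 and rev):
                producible.add(met_id)
            if (coeff < 0 and fwd) or (coeff > 0 and rev):
                consumable.add(met_id)
    dead = []
    for met_id, met in m.metabolites.items():
        if met.compartment == "m":
            continue
        used = met_id in producible or met_id in consumable
        if used and not (met_id in producible and met_id in consumable):
            dead.append(met_id)
    return sorted(dead)


def validate_model(m: SpeciesModel, rich_medium: dict[str, float],
                   tolerance: float = 1e-9) -> ValidationReport:
    """Check structural soundness and FBA viability on ``rich_medium``."""
    from .fba import solve_fba  # deferred: avoid import cycle

    # biomass is exempt: it drains precursors into (massless) biomass by design
    imbalanced = sorted(r.id for r in m.reactions.values()
                        if r.id != m.biomass_reaction_id and _mass_imbalance(m, r))
    community = CommunityModel(members=[(m, 1.0)], medium=dict(rich_medium))
    sol = solve_fba(community)
    mu = sol.growth_rates.get(m.species_id, 0.0) if sol.optimal else 0.0
    return ValidationReport(
        species_id=m.species_id,
        growth_rate=mu,
        grows=mu > tolerance,
        dead_end_metabolites=_dead_ends(m),
        mass_imbalanced_reactions=imbalanced,
    )


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def build_community(
    models: dict[str, SpeciesModel] | list[SpeciesModel],
    abundances: dict[str, float],
    medium: dict[str, float],
    config: AnalysisConfig | None = None,
    tradeoff: float | None = None,
) -> CommunityModel:
    """Assemble a per-sample community model.

    Members with relative abundance below ``config.abundance_inclusion``
    (default 0.1%) are dropped and the survivors renormalized to sum to one,
    so abundances stay a valid weighting.
    """
    config = config or AnalysisConfig()
    if not isinstance(models, dict):
        models = {m.species_id: m for m in models}
    missing = [sid for sid in abundances if sid not in models]
    if missing:
        raise AssemblyError(f"abundances reference unknown models: {missing}")
    kept = {
        sid: a for sid, a in abundances.items()
        if a >= config.abundance_inclusion
    }
    if not kept:
        raise AssemblyError(
            f"no species passes the {config.abundance_inclusion:g} inclusion threshold"
        )
    total = sum(kept.values())
    members = [(models[sid], kept[sid] / total) for sid in sorted(kept)]
    return CommunityModel(
        members=members,
        medium=dict(medium),
        tradeoff=0.7 if tradeoff is None else tradeoff,
        gdw_per_gvs=config.gdw_per_gvs,
    )


def apply_bound_overrides(m: SpeciesModel, overrides) -> SpeciesModel:
    """Apply per-reaction flux-bound overrides from a table.

    ``overrides`` is a path to a TSV with columns ``species_id``,
    ``reaction_id``, ``lower_bound``, ``upper_bound`` (or an equivalent
    DataFrame).  This is the hook for per-model manual curation of exchange
    bounds from the literature on isolated organisms: rows for other species
    are ignored, unknown reaction ids raise, and the input model is left
    untouched.
    """
    import pandas as pd

    df = overrides if isinstance(overrides, pd.DataFrame) else \
        pd.read_csv(overrides, sep="\t")
    out = m.copy()
    for row in df.itertuples(index=False):
        if row.species_id != m.species_id:
            continue
        rxn = out.reactions.get(row.reaction_id)
        if rxn is None:
            raise ModelError(
                f"bound override: model {m.species_id!r} has no reaction "
                f"{row.reaction_id!r}")
        lo, hi = float(row.lower_bound), float(row.upper_bound)
        if lo > hi:
            raise ModelError(
                f"bound override for {row.reaction_id!r}: {lo} > {hi}")
        rxn.lower_bound, rxn.upper_bound = lo, hi
    return out
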