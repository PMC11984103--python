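"""Template-driven insertion of extracellular hydrolysis reactions.

Species whose genomes encode secreted hydrolases (amylases, pectinases,
proteases, lipases) act on polymers outside the cell; the degradation
products diffuse into the shared medium and are public goods for the whole
community.  This module maps enzyme annotations (EC/KO + predicted
localization) onto curated reaction templates and inserts the corresponding
reactions — flagged ``is_extracellular`` — into species models, together
with any product transporters the species needs to benefit from its own
hydrolysis.

Augmentation only ever adds reactions, so it cannot make a feasible model
infeasible, and it is idempotent: re-augmenting an already augmented model
changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import compounds as cpdlib
from .model import CommunityModel, FluxSolution, Metabolite, Reaction, SpeciesModel

__all__ = [
    "ReactionTemplate",
    "ExtracellularTemplate",
    "EnzymeAnnotation",
    "AugmentationError",
    "map_enzymes",
    "augment_model",
    "extracellular_flux_total",
    "builtin_template",
    "read_annotations_tsv",
]

logger = logging.getLogger(__name__)

LOCALIZATIONS = ("extracellular", "intracellular", "membrane")


class AugmentationError(ValueError):
    pass


@dataclass
class ReactionTemplate:
    """One extracellular reaction over compound ids (species ``e`` compartment).

    ``products`` lists compounds for which an import transporter
    (``cpd_e -> cpd_c``) is added so the hydrolyzing species can consume its
    own products; every product also gets a medium exchange reaction, making
    it available to the rest of the community.
    """

    id: str
    enzyme_id: str
    stoichiometry: dict[str, float]  # compound -> coefficient, negative = consumed
    reversible: bool = False
    products: tuple[str, ...] = ()
    name: str = ""


@dataclass
class ExtracellularTemplate:
    entries: dict[str, ReactionTemplate]  # enzyme id -> template

    @classmethod
    def from_tsv(cls, path) -> "ExtracellularTemplate":
        df = pd.read_csv(path, sep="\t")
        entries = {}
        for row in df.itertuples(index=False):
            stoich = {}
            for part in str(row.stoichiometry).split(";"):
                cpd, coeff = part.split(":")
                stoich[cpd.strip()] = float(coeff)
            entries[row.enzyme_id] = ReactionTemplate(
                id=row.reaction_id,
                enzyme_id=row.enzyme_id,
                stoichiometry=stoich,
                reversible=str(row.reversible).lower() == "true",
                products=tuple(p for p in str(row.products).split(",") if p and p != "nan"),
                name=getattr(row, "name_", "") or "",
            )
        return cls(entries)


@dataclass
class EnzymeAnnotation:
    species_id: str
    enzyme_id: str
    localization: str

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise ValueError(
                f"unknown localization {self.localization!r}; expected one of {LOCALIZATIONS}"
            )


@dataclass
class EnzymeMapping:
    mapped: list[tuple[str, ReactionTemplate]] = field(default_factory=list)
    unmapped: list[tuple[str, str]] = field(default_factory=list)  # (species, enzyme)
    skipped_localization: list[tuple[str, str]] = field(default_factory=list)


def map_enzymes(annotations: list[EnzymeAnnotation],
                template: ExtracellularTemplate) -> EnzymeMapping:
    """Match extracellular enzyme annotations to reaction templates.

    Only ``localization == "extracellular"`` annotations map; enzymes absent
    from the template table are reported under ``unmapped`` rather than
    silently dropped.
    """
    out = EnzymeMapping()
    for ann in annotations:
        if ann.localization != "extracellular":
            out.skipped_localization.append((ann.species_id, ann.enzyme_id))
            continue
        tpl = template.entries.get(ann.enzyme_id)
        if tpl is None:
            out.unmapped.append((ann.species_id, ann.enzyme_id))
        else:
            out.mapped.append((ann.species_id, tpl))
    return out


def _ensure_metabolite(m: SpeciesModel, cpd: str, comp: str) -> str:
    met_id = f"{cpd}_{comp}"
    if met_id not in m.metabolites:
        if cpd not in cpdlib.FORMULAS:
            raise AugmentationError(
                f"template compound {cpd!r} is not in the model namespace and "
                f"has no registered formula"
            )
        m.metabolites[met_id] = Metabolite(
            id=met_id, compartment=comp, name=cpd, formula=cpdlib.FORMULAS[cpd]
        )
    return met_id


def augment_model(m: SpeciesModel,
                  templates: list[ReactionTemplate]) -> SpeciesModel:
    """Return a copy of ``m`` with the extracellular reactions inserted.

    For each template: the reaction itself (over the species' ``e``
    compartment), a medium exchange for every participating compound that
    lacks one, and an import transporter for each listed product.  Existing
    reactions are never modified; repeating the augmentation is a no-op.
    """
    out = m.copy()
    for tpl in templates:
        rxn_id = f"XR_{tpl.id}"
        if rxn_id in out.reactions:
            continue
        stoich = {}
        for cpd, coeff in tpl.stoichiometry.items():
            stoich[_ensure_metabolite(out, cpd, "e")] = coeff
        out.reactions[rxn_id] = Reaction(
            id=rxn_id,
            name=tpl.name or tpl.id,
            stoichiometry=stoich,
            lower_bound=-1000.0 if tpl.reversible else 0.0,
            upper_bound=1000.0,
            is_extracellular=True,
        )
        # every participant compound must be able to reach the medium
        for cpd in tpl.stoichiometry:
            ex_id = f"EX_{cpd}"
            if ex_id not in out.reactions:
                e_id = _ensure_metabolite(out, cpd, "e")
                m_id = _ensure_metabolite(out, cpd, "m")
                out.reactions[ex_id] = Reaction(
                    id=ex_id, stoichiometry={e_id: -1.0, m_id: 1.0}, is_exchange=True
                )
        for cpd in tpl.products:
            t_id = f"T_{cpd}_in"
            if t_id not in out.reactions and f"T_{cpd}" not in out.reactions:
                e_id = _ensure_metabolite(out, cpd, "e")
                c_id = _ensure_metabolite(out, cpd, "c")
                out.reactions[t_id] = Reaction(
                    id=t_id, stoichiometry={e_id: -1.0, c_id: 1.0},
                    lower_bound=0.0, upper_bound=1000.0,
                )
        if (tpl.enzyme_id, rxn_id) not in [(e, r) for e, r in out.extracellular_enzymes]:
            out.extracellular_enzymes.append((rxn_id, tpl.enzyme_id))
    out._check_structure()
    return out


def extracellular_flux_total(
    sol: FluxSolution,
    cm: CommunityModel,
    class_map: dict[str, str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Abundance-weighted total |flux| through extracellular reactions.

    Returns ``(total, by_class)`` in mmol gVS^-1 h^-1.  Each reaction is
    assigned the molecule class of its most-consumed substrate compound
    (carbohydrate / protein / lipid / other); the breakdown sums to the
    total.
    """
    if not sol.optimal:
        raise ValueError(f"cannot summarize a {sol.status} solution")
    class_map = cpdlib.CLASSES if class_map is None else class_map
    g = cm.gdw_per_gvs
    total = 0.0
    by_class: dict[str, float] = {}
    for member, a in cm.members:
        for rxn in member.reactions.values():
            if not rxn.is_extracellular:
                continue
            v = abs(sol.per_species_fluxes.get((member.species_id, rxn.id), 0.0)) * a * g
            # the hydrolyzed polymer: most-consumed substrate, water aside
            substrates = {mid: c for mid, c in rxn.stoichiometry.items()
                          if c < 0 and not mid.startswith("h2o_")}
            substrate = min(substrates, key=substrates.get) if substrates else ""
            cls = class_map.get(substrate.rsplit("_", 1)[0], "other")
            total += v
            by_class[cls] = by_class.get(cls, 0.0) + v
    return total, by_class


def builtin_template() -> ExtracellularTemplate:
    """The packaged curated template set.

    Covers the four hydrolysis chemistries the anaerobic-digestion trophic
    chain starts from: starch amylolysis, pectate hydrolysis
    (exopolygalacturonase, EC 3.2.1.67), a generic protease releasing amino
    acids, and a generic lipase releasing glycerol and a fatty acid.
    """
    entries = {
        "EC3.2.1.1": ReactionTemplate(
            id="amylase", enzyme_id="EC3.2.1.1", name="extracellular amylase",
            stoichiometry={"starch": -1.0, "h2o": -2.0, "glc": 3.0},
            products=("glc",),
        ),
        "EC3.2.1.67": ReactionTemplate(
            id="exopolygalacturonase", enzyme_id="EC3.2.1.67",
            name="pectate hydrolysis",
            stoichiometry={"pectin": -1.0, "h2o": -2.0, "galur": 3.0},
            products=("galur",),
        ),
        "EC3.4.21.x": ReactionTemplate(
            id="protease", enzyme_id="EC3.4.21.x", name="generic protease",
            stoichiometry={"protein": -1.0, "h2o": -1.0, "ala": 1.0, "glu": 1.0},
            products=("ala",),
        ),
        "EC3.1.1.3": ReactionTemplate(
            id="lipase", enzyme_id="EC3.1.1.3", name="generic lipase",
            stoichiometry={"lipid": -1.0, "h2o": -3.0, "glyc": 1.0, "oct": 3.0},
            products=("oct",),
        ),
    }
    return ExtracellularTemplate(entries)


def read_annotations_tsv(path) -> list[EnzymeAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        EnzymeAnnotation(str(r.species_id), str(r.enzyme_id), str(r.localization))
        for r in df.itertuples(index=False)
    ]
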