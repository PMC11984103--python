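"""SBML Level 3 (FBC bounds) reading and writing, via COBRApy.

The three compartments map to SBML compartments ``c`` (cytosol), ``e``
(species extracellular), and ``m`` (shared medium).  The extracellular-
reaction flag survives round trips through reaction notes; extracellular
enzyme annotations through model notes.  Exchange status is structural
(a reaction touching exactly one medium metabolite) and is re-derived on
read rather than stored.
"""

from __future__ import annotations

from .model import FormatError, Metabolite, Reaction, SpeciesModel

__all__ = ["read_sbml_model", "write_sbml_model", "to_cobra", "from_cobra"]


def to_cobra(m: SpeciesModel):
    """Convert to a cobra.Model (also used for cross-checking FBA optima)."""
    import cobra

    out = cobra.Model(m.species_id)
    out.compartments = {"c": "cytosol", "e": "extracellular", "m": "medium"}
    mets = {}
    for met in m.metabolites.values():
        cm = cobra.Metabolite(met.id, name=met.name or met.id,
                              compartment=met.compartment,
                              formula=met.formula, charge=met.charge)
        mets[met.id] = cm
    out.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in m.reactions.values():
        cr = cobra.Reaction(rxn.id, name=rxn.name or rxn.id,
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        rxns.append(cr)
    out.add_reactions(rxns)
    for rxn in m.reactions.values():
        cr = out.reactions.get_by_id(rxn.id)
        cr.add_metabolites({mets[mid]: coeff for mid, coeff in rxn.stoichiometry.items()})
        if rxn.gene_rule:
            cr.gene_reaction_rule = rxn.gene_rule
        if rxn.is_extracellular:
            cr.notes["adcomm_extracellular"] = "true"
    out.notes["adcomm_taxonomy"] = m.taxonomy_label
    if m.extracellular_enzymes:
        out.notes["adcomm_enzymes"] = ";".join(f"{a},{b}" for a, b in m.extracellular_enzymes)
    out.objective = out.reactions.get_by_id(m.biomass_reaction_id)
    return out


def from_cobra(cm) -> SpeciesModel:
    mets = {}
    for met in cm.metabolites:
        if met.compartment not in ("c", "e", "m"):
            raise FormatError(
                f"metabolite {met.id!r}: unknown compartment {met.compartment!r}")
        mets[met.id] = Metabolite(id=met.id, compartment=met.compartment,
                                  name=met.name or "", formula=met.formula,
                                  charge=met.charge)
    rxns = {}
    biomass = None
    for rxn in cm.reactions:
        stoich = {met.id: coeff for met, coeff in rxn.metabolites.items()}
        medium_mets = [mid for mid in stoich if mets[mid].compartment == "m"]
        rxns[rxn.id] = Reaction(
            id=rxn.id, name=rxn.name or "", stoichiometry=stoich,
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            is_exchange=len(medium_mets) == 1,
            is_extracellular=str(rxn.notes.get("adcomm_extracellular", "")).lower() == "true",
            gene_rule=rxn.gene_reaction_rule or None,
        )
        if rxn.objective_coefficient:
            biomass = rxn.id
    if biomass is None:
        raise FormatError(f"model {cm.id!r}: no objective (biomass) reaction")
    enzymes = []
    raw = cm.notes.get("adcomm_enzymes", "")
    if raw:
        enzymes = [tuple(part.split(",", 1)) for part in raw.split(";") if part]
    return SpeciesModel(
        species_id=cm.id, taxonomy_label=str(cm.notes.get("adcomm_taxonomy", "")),
        metabolites=mets, reactions=rxns, biomass_reaction_id=biomass,
        extracellular_enzymes=enzymes,
    )


def read_sbml_model(path) -> SpeciesModel:
    from cobra.io import read_sbml_model as cobra_read

    try:
        cm = cobra_read(str(path))
    except Exception as exc:  # libsbml raises a zoo of error types
        raise FormatError(f"{path}: not a readable SBML L3/FBC file: {exc}") from exc
    return from_cobra(cm)


def write_sbml_model(m: SpeciesModel, path) -> None:
    from cobra.io import write_sbml_model as cobra_write

    cobra_write(to_cobra(m), str(path))
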