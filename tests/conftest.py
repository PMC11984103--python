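"""Shared fixtures: hand-built toy models with closed-form flux oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from adcomm.model import CommunityModel, Metabolite, Reaction, SpeciesModel
from adcomm.synth import _species


def toy_acetoclast() -> SpeciesModel:
    """Acetate -> CH4 + CO2 (1:1:1), growth coupled via 1 ATP per acetate."""
    return _species(
        "acetoclast_toy", "toy Methanothrix",
        imports={"ac": 50.0}, exports=("ch4", "co2"),
        catabolism={"ACM": {"ac": -1.0, "ch4": 1.0, "co2": 1.0, "atp": 1.0}},
        biomass_atp=10.0, biomass_n=0.0)


def toy_hydrogenotroph() -> SpeciesModel:
    """4 H2 + CO2 -> CH4 + 2 H2O, growth coupled via 1 ATP per CH4."""
    return _species(
        "hydrogenotroph_toy", "toy Methanoculleus",
        imports={"h2": 50.0, "co2": 50.0}, exports=("ch4",),
        catabolism={"HYM": {"h2": -4.0, "co2": -1.0, "ch4": 1.0, "h2o": 2.0,
                            "atp": 1.0}},
        biomass_atp=10.0, biomass_n=0.0)


def toy_fermenter(atp_yield: float = 4.0, product: str = "ac") -> SpeciesModel:
    """Glucose fermenter; ``product='ac'`` gives the acetate + H2 + CO2 route,
    ``product='lac'`` the homolactic route (no H2)."""
    if product == "ac":
        stoich = {"glc": -1.0, "h2o": -2.0, "ac": 2.0, "co2": 2.0, "h2": 4.0,
                  "atp": atp_yield}
        exports = ("ac", "co2", "h2")
    else:
        stoich = {"glc": -1.0, "lac": 2.0, "atp": atp_yield}
        exports = ("lac",)
    return _species(f"fermenter_{product}", "toy Firmicutes",
                    imports={"glc": 10.0}, exports=exports,
                    catabolism={"FERM": stoich}, biomass_atp=50.0)


@pytest.fixture
def acetoclast_community() -> CommunityModel:
    return CommunityModel(members=[(toy_acetoclast(), 1.0)],
                          medium={"ac": 5.0, "h2o": 1000.0})


@pytest.fixture
def hydrogenotroph_community() -> CommunityModel:
    return CommunityModel(members=[(toy_hydrogenotroph(), 1.0)],
                          medium={"h2": 8.0, "co2": 100.0, "h2o": 1000.0})


@pytest.fixture
def syntrophy_pair() -> CommunityModel:
    """Fermenter feeds H2 to a hydrogenotroph; the medium itself has no H2."""
    return CommunityModel(
        members=[(toy_fermenter(), 0.5), (toy_hydrogenotroph(), 0.5)],
        medium={"glc": 2.0, "co2": 100.0, "nh3": 1.0, "h2o": 1000.0})


@pytest.fixture
def chain_community() -> CommunityModel:
    """Three-member chain where plain FBA starves the low-yield fermenter.

    Two fermenters compete for scarce glucose; the acetate-route one has
    double the ATP yield, so growth maximization gives it all the sugar.
    The hydrogenotroph lives off fermentation H2.
    """
    return CommunityModel(
        members=[(toy_fermenter(4.0, "ac"), 0.4),
                 (toy_fermenter(2.0, "lac"), 0.4),
                 (toy_hydrogenotroph(), 0.2)],
        medium={"glc": 0.5, "co2": 100.0, "nh3": 1.0, "h2o": 1000.0})


@pytest.fixture
def rich_medium() -> dict[str, float]:
    """Generous availability of every substrate the guild roster uses."""
    return {c: 10.0 for c in ("glc", "ac", "prop", "h2", "co2", "glyc", "oct",
                              "ala", "glu", "xyl", "gal", "fru", "man", "ara",
                              "rib", "starch", "protein", "lipid", "nh3")} | {"h2o": 1000.0}


# ---------------------------------------------------------------------------
# Brute-force vertex-enumeration LP oracle (independent of the HiGHS path)
# ---------------------------------------------------------------------------

def lp_vertex_oracle(cm: CommunityModel, objective_coeffs) -> float:
    """Maximize c'v over the community polytope by enumerating basic points.

    Builds the steady-state system independently from the model definition,
    then walks all choices of active bounds/uptake rows that complete the
    equality system to full rank.  Exponential — only for tiny fixtures.
    """
    var_index = []
    rows = {}
    med_rows = {}
    lb, ub = [], []
    for member, a in cm.members:
        for rid in sorted(member.reactions):
            rxn = member.reactions[rid]
            col = len(var_index)
            var_index.append((member.species_id, rid))
            lb.append(rxn.lower_bound)
            ub.append(rxn.upper_bound)
            for met_id, coeff in rxn.stoichiometry.items():
                met = member.metabolites[met_id]
                if met.compartment == "m":
                    med_rows.setdefault(met_id[:-2], {})[col] = \
                        med_rows.get(met_id[:-2], {}).get(col, 0.0) - a * cm.gdw_per_gvs * coeff
                else:
                    rows.setdefault((member.species_id, met_id), {})[col] = \
                        rows.get((member.species_id, met_id), {}).get(col, 0.0) + coeff
    n = len(var_index)
    A_eq = np.zeros((len(rows), n))
    for i, key in enumerate(sorted(rows)):
        for col, coeff in rows[key].items():
            A_eq[i, col] = coeff
    ineqs = []  # (row, rhs) meaning row @ v <= rhs
    for cpd in sorted(med_rows):
        row = np.zeros(n)
        for col, coeff in med_rows[cpd].items():
            row[col] = coeff
        ineqs.append((row, cm.medium.get(cpd, 0.0)))
    for col in range(n):
        e = np.zeros(n)
        e[col] = 1.0
        ineqs.append((e, ub[col]))
        ineqs.append((-e, -lb[col]))
    rank = np.linalg.matrix_rank(A_eq)
    need = n - rank
    c = np.asarray(objective_coeffs, dtype=float)
    best = -np.inf
    for subset in combinations(range(len(ineqs)), need):
        A = np.vstack([A_eq] + [ineqs[i][0] for i in subset])
        b = np.concatenate([np.zeros(len(A_eq)), [ineqs[i][1] for i in subset]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > 1e-8:
            continue
        feasible = all(row @ v <= rhs + 1e-8 for row, rhs in ineqs)
        if feasible:
            best = max(best, float(c @ v))
    return best


def objective_for(cm: CommunityModel, species_id: str, reaction_id: str):
    coeffs = []
    for member, _ in cm.members:
        for rid in sorted(member.reactions):
            coeffs.append(1.0 if (member.species_id, rid) == (species_id, reaction_id)
                          else 0.0)
    return np.asarray(coeffs)
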