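"""Compound namespace shared by the packaged models, templates, and media.

Formulas use whole-number textbook stoichiometry so that elemental balance
checks are exact: the starch proxy is a glucose trimer (maltotriose), the
protein proxy an alanine-glutamate dipeptide, the lipid proxy a glycerol
trioctanoate, and pectin a digalacturonate chain unit.  ``atp`` and
``biomass`` are accounting pseudo-compounds and deliberately carry no formula.
"""

from __future__ import annotations

#: compound id -> chemical formula (None for pseudo-compounds)
FORMULAS: dict[str, str | None] = {
    "starch": "C18H32O16",     # maltotriose unit
    "mal": "C12H22O11",        # maltose
    "glc": "C6H12O6",          # glucose
    "fru": "C6H12O6",          # fructose
    "man": "C6H12O6",          # mannose
    "gal": "C6H12O6",          # galactose
    "xyl": "C5H10O5",          # xylose
    "ara": "C5H10O5",          # arabinose
    "rib": "C5H10O5",          # ribose
    "pectin": "C18H26O19",     # polygalacturonate trimer unit
    "galur": "C6H10O7",        # galacturonate
    "protein": "C8H14N2O5",    # Ala-Glu dipeptide proxy
    "ala": "C3H7NO2",          # L-alanine
    "glu": "C5H9NO4",          # L-glutamate
    "lipid": "C27H50O6",       # glyceryl trioctanoate proxy
    "glyc": "C3H8O3",          # glycerol
    "oct": "C8H16O2",          # octanoate (fatty-acid proxy)
    "ac": "C2H4O2",            # acetate
    "prop": "C3H6O2",          # propionate
    "but": "C4H8O2",           # butyrate
    "lac": "C3H6O3",           # lactate
    "ch4": "CH4",
    "co2": "CO2",
    "h2": "H2",
    "h2o": "H2O",
    "nh3": "H3N",
    "atp": None,
    "biomass": None,
}

#: molecule class used for extracellular-flux breakdowns
CLASSES: dict[str, str] = {
    "starch": "carbohydrate", "mal": "carbohydrate", "glc": "carbohydrate",
    "fru": "carbohydrate", "man": "carbohydrate", "gal": "carbohydrate",
    "xyl": "carbohydrate", "ara": "carbohydrate", "rib": "carbohydrate",
    "pectin": "carbohydrate", "galur": "carbohydrate",
    "protein": "protein", "ala": "protein", "glu": "protein",
    "lipid": "lipid", "glyc": "lipid", "oct": "lipid",
}

#: carbon atoms per compound (derived from FORMULAS; used for C-mol budgets)
def carbon_atoms(compound: str) -> int:
    formula = FORMULAS.get(compound)
    if not formula:
        return 0
    import re

    m = re.match(r"C(\d*)(?![a-z])", formula)
    if not m:
        return 0
    return int(m.group(1)) if m.group(1) else 1
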