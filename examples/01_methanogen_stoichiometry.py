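"""Closed-form methane yields of single-species toy methanogens.

Builds an acetoclastic methanogen (acetate -> CH4 + CO2) and a
hydrogenotrophic one (4 H2 + CO2 -> CH4), bounds their substrate supply, and
maximizes methane export with community FBA.  The printed yields follow the
catabolic stoichiometry exactly: 5 mmol/gVS/h of acetate supports 5 of CH4;
8 of H2 supports 2.
"""

from adcomm import CommunityModel, solve_fba
from adcomm.synth import SyntheticSpec, generate_guild_models

models = generate_guild_models(SyntheticSpec())

aceto = CommunityModel(members=[(models["acetoclast"], 1.0)],
                       medium={"ac": 5.0, "nh3": 1.0, "h2o": 1000.0})
sol = solve_fba(aceto, objective=("acetoclast", "EX_ch4"))
print(f"acetoclast:     acetate bound 5.0 -> max CH4 flux "
      f"{sol.per_species_fluxes[('acetoclast', 'EX_ch4')]:.6f} mmol/gVS/h")

hydro = CommunityModel(members=[(models["hydrogenotroph"], 1.0)],
                       medium={"h2": 8.0, "co2": 100.0, "nh3": 1.0, "h2o": 1000.0})
sol = solve_fba(hydro, objective=("hydrogenotroph", "EX_ch4"))
print(f"hydrogenotroph: H2 bound 8.0      -> max CH4 flux "
      f"{sol.per_species_fluxes[('hydrogenotroph', 'EX_ch4')]:.6f} mmol/gVS/h")
print("The 1:1 and 4:1 substrate:methane ratios are the textbook "
      "acetoclastic and hydrogenotrophic stoichiometries.")
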