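"""Community FBA and cooperative trade-off solves against independent oracles."""

import numpy as np
import pytest

from adcomm.fba import (GROWTH_FIX_RTOL, CommunityProblem, extract_exchanges,
                        methane_attribution, solve_ctfba, solve_fba,
                        _stage2_lp_fallback)
from adcomm.model import CommunityModel

from conftest import (lp_vertex_oracle, objective_for, toy_acetoclast,
                      toy_fermenter, toy_hydrogenotroph)

TRADEOFFS = tuple(round(0.4 + 0.1 * i, 2) for i in range(7))


def mass_balance_residual(cm: CommunityModel, sol) -> float:
    """Largest |S.v| over all species-scoped metabolites — computed directly
    from the model definition, independent of the solver's matrices."""
    worst = 0.0
    for member, _ in cm.members:
        totals = {}
        for rid, rxn in member.reactions.items():
            v = sol.per_species_fluxes[(member.species_id, rid)]
            for met_id, coeff in rxn.stoichiometry.items():
                if member.metabolites[met_id].compartment != "m":
                    totals[met_id] = totals.get(met_id, 0.0) + coeff * v
        if totals:
            worst = max(worst, max(abs(x) for x in totals.values()))
    return worst


def medium_violation(cm: CommunityModel, sol) -> float:
    worst = 0.0
    for cpd, bound in cm.medium.items():
        uptake = -sol.community_exchange.get(cpd, 0.0)
        worst = max(worst, uptake - bound)
    for cpd, net in sol.community_exchange.items():
        if cpd not in cm.medium and net < 0:
            worst = max(worst, -net)  # uptake of an unprovided compound
    return worst


class TestPlainFba:
    def test_acetoclast_methane_yield_closed_form(self, acetoclast_community):
        """Acetate bound 5 with 1:1 stoichiometry caps CH4 at exactly 5."""
        sol = solve_fba(acetoclast_community)
        assert sol.optimal
        assert sol.community_exchange["ch4"] == pytest.approx(5.0, abs=1e-6)

    def test_hydrogenotroph_four_to_one(self, hydrogenotroph_community):
        sol = solve_fba(hydrogenotroph_community)
        assert sol.community_exchange["ch4"] == pytest.approx(2.0, abs=1e-6)

    def test_no_carbon_no_growth(self):
        cm = CommunityModel(members=[(toy_fermenter(), 1.0)],
                            medium={"h2o": 1000.0, "nh3": 1.0})
        sol = solve_fba(cm)
        assert sol.community_growth == pytest.approx(0.0, abs=1e-9)

    def test_syntrophy_enables_hydrogenotroph(self, syntrophy_pair):
        alone = CommunityModel(members=[(toy_hydrogenotroph(), 1.0)],
                               medium={"co2": 100.0, "h2o": 1000.0})
        assert solve_fba(alone).community_growth == pytest.approx(0.0, abs=1e-9)
        paired = solve_fba(syntrophy_pair)
        assert paired.growth_rates["hydrogenotroph_toy"] > 1e-6

    @pytest.mark.parametrize("community_fixture,expected_ch4", [
        ("acetoclast_community", 5.0), ("hydrogenotroph_community", 2.0)])
    def test_matches_vertex_enumeration_oracle(self, community_fixture,
                                               expected_ch4, request):
        cm = request.getfixturevalue(community_fixture)
        sid = cm.members[0][0].species_id
        sol = solve_fba(cm, objective=(sid, "EX_ch4"))
        oracle = lp_vertex_oracle(cm, objective_for(cm, sid, "EX_ch4"))
        assert sol.per_species_fluxes[(sid, "EX_ch4")] == pytest.approx(
            oracle, abs=1e-6)
        assert oracle == pytest.approx(expected_ch4, abs=1e-6)

    def test_matches_cobra_glpk_optimum(self, acetoclast_community):
        """Cross-check the HiGHS path against COBRApy/GLPK on the same model.

        The shared-medium compartment is emulated in cobra by a bounded sink
        per medium metabolite: negative sink flux supplies the compound (up
        to the medium bound), positive flux vents it.
        """
        from adcomm.sbml import to_cobra

        m = acetoclast_community.members[0][0]
        cmod = to_cobra(m)
        for met in list(cmod.metabolites):
            if met.compartment == "m":
                supply = acetoclast_community.medium.get(met.id[:-2], 0.0)
                sink = cmod.add_boundary(met, type="sink")
                sink.bounds = (-supply, 1000.0)
        sol = cmod.optimize()
        ours = solve_fba(acetoclast_community)
        assert ours.community_growth == pytest.approx(sol.objective_value, abs=1e-6)

    def test_infeasible_reported_not_raised(self):
        m = toy_fermenter()
        m.reactions["BIOMASS"].lower_bound = 50.0  # impossible demand
        cm = CommunityModel(members=[(m, 1.0)], medium={"glc": 0.001, "h2o": 10.0,
                                                        "nh3": 1.0})
        sol = solve_fba(cm)
        assert sol.status == "infeasible"
        assert sol.per_species_fluxes == {}


class TestCooperativeTradeoff:
    def test_tradeoff_one_recovers_max_growth(self, syntrophy_pair):
        full = solve_fba(syntrophy_pair)
        ct1 = solve_ctfba(syntrophy_pair, 1.0)
        assert ct1.community_growth == pytest.approx(full.community_growth, abs=1e-6)

    def test_growth_contract_across_grid(self, chain_community):
        prob = CommunityProblem(chain_community)
        star = solve_fba(chain_community).community_growth
        for ct in TRADEOFFS:
            sol = solve_ctfba(chain_community, ct, problem=prob, mu_c_star=star)
            assert sol.community_growth >= ct * star - 1e-6

    def test_growth_monotone_in_tradeoff(self, chain_community):
        growths = [solve_ctfba(chain_community, ct).community_growth
                   for ct in TRADEOFFS]
        assert all(b >= a - 1e-9 for a, b in zip(growths, growths[1:]))

    def test_chain_fba_starves_weakest_but_ctfba_feeds_all(self, chain_community):
        plain = solve_fba(chain_community)
        assert min(plain.growth_rates.values()) == pytest.approx(0.0, abs=1e-9)
        coop = solve_ctfba(chain_community, 0.5)
        assert all(mu > 1e-6 for mu in coop.growth_rates.values())

    def test_identical_members_grow_identically(self):
        a, b = toy_fermenter(), toy_fermenter()
        b.species_id = "fermenter_twin"
        cm = CommunityModel(members=[(a, 0.5), (b, 0.5)],
                            medium={"glc": 1.0, "nh3": 1.0, "h2o": 1000.0})
        for ct in (0.4, 0.7, 1.0):
            sol = solve_ctfba(cm, ct)
            # twins may drift apart by at most the width of the parsimonious
            # growth-fixing band around the (symmetric) quadratic allocation
            mu = sol.growth_rates["fermenter_ac"]
            band = 2 * GROWTH_FIX_RTOL * abs(mu) + 1e-8
            assert sol.growth_rates["fermenter_twin"] == pytest.approx(mu, abs=band)

    def test_parsimony_reduces_total_flux(self, chain_community):
        coop = solve_ctfba(chain_community, 0.6, parsimonious=True)
        loose = solve_ctfba(chain_community, 0.6, parsimonious=False)
        total = sum(abs(v) for v in coop.per_species_fluxes.values())
        total_loose = sum(abs(v) for v in loose.per_species_fluxes.values())
        assert total <= total_loose + 1e-6
        assert coop.community_growth == pytest.approx(loose.community_growth,
                                                      rel=1e-4)

    def test_lp_fallback_meets_growth_target(self, chain_community):
        prob = CommunityProblem(chain_community)
        star = solve_fba(chain_community).community_growth
        x = _stage2_lp_fallback(prob, 0.6 * star)
        achieved = sum(prob.abundance[s] * x[c] for s, c in prob.biomass_cols.items())
        assert achieved >= 0.6 * star - 1e-8

    def test_invalid_tradeoff_rejected(self, chain_community):
        with pytest.raises(ValueError):
            solve_ctfba(chain_community, 0.0)

    def test_abundance_scale_invariance(self, chain_community):
        """Feeding uniformly scaled raw abundances through community assembly
        (which renormalizes) leaves every per-species flux unchanged."""
        from adcomm.model import build_community

        models = {m.species_id: m for m, _ in chain_community.members}
        raw = {m.species_id: a for m, a in chain_community.members}
        scaled = {sid: 7.5 * a for sid, a in raw.items()}
        cm2 = build_community(models, scaled, chain_community.medium, tradeoff=0.6)
        sol1 = solve_ctfba(chain_community, 0.6)
        sol2 = solve_ctfba(cm2, 0.6)
        for key, v in sol1.per_species_fluxes.items():
            assert sol2.per_species_fluxes[key] == pytest.approx(v, abs=1e-6)


class TestConservation:
    @pytest.mark.parametrize("ct", [0.4, 0.7, 1.0])
    def test_mass_balance_and_medium_compliance(self, chain_community, ct):
        sol = solve_ctfba(chain_community, ct)
        assert mass_balance_residual(chain_community, sol) <= 1e-6
        assert medium_violation(chain_community, sol) <= 1e-9

    def test_exchange_matrix_reconciles(self, syntrophy_pair):
        sol = solve_ctfba(syntrophy_pair, 0.7)
        ex = extract_exchanges(sol)
        g = syntrophy_pair.gdw_per_gvs
        for cpd, net in ex.net_community.items():
            recomputed = sum(
                (ex.exports.get((m.species_id, cpd), 0.0)
                 - ex.imports.get((m.species_id, cpd), 0.0)) * a * g
                for m, a in syntrophy_pair.members)
            assert recomputed == pytest.approx(net, abs=1e-6)

    def test_h2_transfer_balances_against_medium(self, syntrophy_pair):
        """The medium supplies no H2, so the hydrogenotroph's H2 import is
        covered entirely by the fermenter's export; any surplus is vented
        (never the reverse)."""
        sol = solve_ctfba(syntrophy_pair, 0.7)
        ex = extract_exchanges(sol)
        exp = ex.exports.get(("fermenter_ac", "h2"), 0.0)
        imp = ex.imports.get(("hydrogenotroph_toy", "h2"), 0.0)
        assert exp > 0.01 and imp > 0.01
        net = 0.5 * exp - 0.5 * imp
        assert net >= -1e-9
        assert ex.net_community.get("h2", 0.0) == pytest.approx(net, abs=1e-6)

    def test_import_export_mutually_exclusive(self, chain_community):
        sol = solve_ctfba(chain_community, 0.7)
        ex = extract_exchanges(sol)
        for key in ex.imports:
            assert key not in ex.exports


class TestExchangeExtraction:
    def test_secretion_recorded_as_export(self, acetoclast_community):
        sol = solve_ctfba(acetoclast_community, 0.7)
        ex = extract_exchanges(sol)
        assert ex.exports[("acetoclast_toy", "ch4")] > 0
        assert ("acetoclast_toy", "ch4") not in ex.imports
        assert ex.imports[("acetoclast_toy", "ac")] > 0

    def test_nonoptimal_solution_rejected(self):
        from adcomm.model import FluxSolution

        with pytest.raises(ValueError, match="infeasible"):
            extract_exchanges(FluxSolution(status="infeasible"))


class TestMethaneAttribution:
    def test_single_methanogen_gets_everything(self, acetoclast_community):
        sol = solve_ctfba(acetoclast_community, 0.7)
        att = methane_attribution(sol, ["acetoclast_toy"],
                                  abundances={"acetoclast_toy": 1.0})
        assert att["acetoclast_toy"] == pytest.approx(
            sol.community_exchange["ch4"], abs=1e-9)

    def test_empty_archaea_list(self, acetoclast_community):
        sol = solve_ctfba(acetoclast_community, 0.7)
        assert methane_attribution(sol, []) == {}

    def test_two_methanogens_sum_to_community_total(self):
        cm = CommunityModel(
            members=[(toy_fermenter(), 0.4), (toy_acetoclast(), 0.3),
                     (toy_hydrogenotroph(), 0.3)],
            medium={"glc": 1.0, "co2": 100.0, "nh3": 1.0, "h2o": 1000.0})
        sol = solve_ctfba(cm, 0.7)
        ab = {m.species_id: a for m, a in cm.members}
        att = methane_attribution(sol, ["acetoclast_toy", "hydrogenotroph_toy"],
                                  abundances=ab)
        assert sum(att.values()) == pytest.approx(
            sol.community_exchange["ch4"], abs=1e-9)
        assert all(v > 0 for v in att.values())

    def test_unknown_compound_is_config_error(self, acetoclast_community):
        sol = solve_ctfba(acetoclast_community, 0.7)
        with pytest.raises(KeyError):
            methane_attribution(sol, ["acetoclast_toy"], ch4_id="methane_typo")
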