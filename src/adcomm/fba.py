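"""Community steady-state flux solvers.

Implements plain community FBA, cooperative trade-off FBA (ctFBA), and a
parsimonious flux-minimization stage, over the abundance-weighted union of
species models sharing one medium compartment.

The ctFBA solve has three stages:

1. **LP** — maximize community growth ``mu_c = sum_i a_i mu_i`` subject to
   per-species steady state ``S v = 0``, reaction bounds, and shared medium
   uptake limits; this yields ``mu_c*``.
2. **QP** — minimize ``sum_i mu_i^2`` subject to the same constraints plus
   ``sum_i a_i mu_i >= tradeoff * mu_c*``.  For a fixed weighted community
   growth the L2 objective spreads growth across members instead of
   concentrating it on the single most efficient species: this is the
   cooperative trade-off.
3. **LP (pFBA)** — fix each ``mu_i`` within a small tolerance of its stage-2
   value and minimize total absolute flux ``sum_r |v_r|``, removing
   thermodynamically gratuitous cycles and taming degenerate optima.

Linear programs are solved with HiGHS (scipy.optimize.linprog); the convex QP
with OSQP.  If OSQP is unavailable an LP fallback replaces stage 2: minimize
the largest deviation of any ``mu_i`` from a free common growth level, which
also spreads growth but without the exact L2 geometry (a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import CommunityModel, FluxSolution

__all__ = [
    "CommunityProblem",
    "ExchangeMatrix",
    "solve_fba",
    "solve_ctfba",
    "extract_exchanges",
    "methane_attribution",
]

logger = logging.getLogger(__name__)

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}

#: fluxes below this magnitude are reported as exact zeros
FLUX_ZERO = 1e-9
#: HiGHS runs at its default tolerances: in practice its cleanup leaves
#: residuals far below the 1e-9 medium-compliance contract, and forcing
#: tighter tolerances makes vertex selection erratic across a trade-off grid
_HIGHS_OPTIONS: dict = {}
#: relative / absolute tolerance when fixing stage-2 growth rates in stage 3
GROWTH_FIX_RTOL = 1e-5
GROWTH_FIX_ATOL = 1e-9


class CommunityProblem:
    """Sparse LP skeleton for one community model.

    Variables are species reaction fluxes in a fixed deterministic order
    (members in community order, reactions sorted by id within a member).
    Rows: steady-state equalities for every species-scoped metabolite, and one
    inequality per medium compound limiting abundance-weighted community
    uptake to the medium bound.
    """

    def __init__(self, cm: CommunityModel):
        self.cm = cm
        self.var_index: list[tuple[str, str]] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.biomass_cols: dict[str, int] = {}
        self.abundance: dict[str, float] = {}
        # (species, compound) -> list of (col, medium-side stoich coeff)
        self.exchange_cols: dict[tuple[str, str], list[tuple[int, float]]] = {}

        eq_rows: list[tuple[int, int, float]] = []  # (row, col, coeff)
        met_row: dict[tuple[str, str], int] = {}
        n_eq = 0
        for member, a in cm.members:
            sid = member.species_id
            self.abundance[sid] = a
            for rid in sorted(member.reactions):
                rxn = member.reactions[rid]
                col = len(self.var_index)
                self.var_index.append((sid, rid))
                self.lb.append(rxn.lower_bound)
                self.ub.append(rxn.upper_bound)
                if rid == member.biomass_reaction_id:
                    self.biomass_cols[sid] = col
                for met_id, coeff in rxn.stoichiometry.items():
                    met = member.metabolites[met_id]
                    if met.compartment == "m":
                        cpd = met_id[:-2]
                        self.exchange_cols.setdefault((sid, cpd), []).append((col, coeff))
                        continue
                    key = (sid, met_id)
                    if key not in met_row:
                        met_row[key] = n_eq
                        n_eq += 1
                    eq_rows.append((met_row[key], col, coeff))

        n = len(self.var_index)
        rows, cols, vals = zip(*eq_rows) if eq_rows else ((), (), ())
        self.A_eq = sp.csr_matrix((vals, (rows, cols)), shape=(n_eq, n))
        self.b_eq = np.zeros(n_eq)

        # medium uptake rows:  sum_i a_i * gdw_per_gvs * (-secretion) <= bound
        g = cm.gdw_per_gvs
        compounds = sorted({cpd for (_, cpd) in self.exchange_cols})
        self.medium_compounds = compounds
        urows, ucols, uvals = [], [], []
        for ri, cpd in enumerate(compounds):
            for (sid, c2), entries in self.exchange_cols.items():
                if c2 != cpd:
                    continue
                for col, coeff in entries:
                    urows.append(ri)
                    ucols.append(col)
                    uvals.append(-self.abundance[sid] * g * coeff)
        self.A_ub = sp.csr_matrix((uvals, (urows, ucols)), shape=(len(compounds), n))
        self.b_ub = np.array([cm.medium.get(cpd, 0.0) for cpd in compounds])
        self.lb = np.asarray(self.lb)
        self.ub = np.asarray(self.ub)

    # ------------------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.var_index)

    def community_growth_objective(self) -> np.ndarray:
        c = np.zeros(self.n_vars)
        for sid, col in self.biomass_cols.items():
            c[col] = self.abundance[sid]
        return c

    def _solve_lp(self, c, A_ub=None, b_ub=None, lb=None, ub=None, extra_ub=None):
        A_ub = self.A_ub if A_ub is None else A_ub
        b_ub = self.b_ub if b_ub is None else b_ub
        if extra_ub is not None:
            A_extra, b_extra = extra_ub
            A_ub = sp.vstack([A_ub, A_extra], format="csr")
            b_ub = np.concatenate([b_ub, b_extra])
        bounds = np.column_stack([self.lb if lb is None else lb,
                                  self.ub if ub is None else ub])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=self.A_eq, b_eq=self.b_eq,
                      bounds=bounds, method="highs", options=_HIGHS_OPTIONS)
        return res

    def solution_from_x(self, x: np.ndarray) -> FluxSolution:
        g = self.cm.gdw_per_gvs
        fluxes = {}
        for col, (sid, rid) in enumerate(self.var_index):
            v = float(x[col])
            fluxes[(sid, rid)] = 0.0 if abs(v) < FLUX_ZERO else v
        growth = {sid: fluxes[(sid, self._biomass_rid(sid))] for sid in self.abundance}
        species_exchange: dict[tuple[str, str], float] = {}
        community_exchange: dict[str, float] = {}
        for (sid, cpd), entries in self.exchange_cols.items():
            net = float(sum(coeff * x[col] for col, coeff in entries))
            species_exchange[(sid, cpd)] = 0.0 if abs(net) < FLUX_ZERO else net
            # community totals sum the raw nets: zeroing first would bias the
            # total by up to FLUX_ZERO per member and can fake a bound breach
            community_exchange[cpd] = community_exchange.get(cpd, 0.0) + \
                self.abundance[sid] * g * net
        # project onto the medium box: LP primal residuals (<= ~1e-8 at the
        # solver's tolerances) may leave an apparent uptake a hair over the
        # bound; anything larger than 1e-6 is a real violation and is kept
        for cpd, v in community_exchange.items():
            bound = self.cm.medium.get(cpd, 0.0)
            if -bound - 1e-6 < v < -bound:
                community_exchange[cpd] = -bound
        community_exchange = {c: (0.0 if abs(v) < FLUX_ZERO else v)
                              for c, v in community_exchange.items()}
        return FluxSolution(
            status="optimal",
            per_species_fluxes=fluxes,
            growth_rates=growth,
            community_growth=float(sum(self.abundance[s] * mu for s, mu in growth.items())),
            community_exchange=community_exchange,
            species_exchange=species_exchange,
        )

    def _biomass_rid(self, sid: str) -> str:
        for member, _ in self.cm.members:
            if member.species_id == sid:
                return member.biomass_reaction_id
        raise KeyError(sid)


# ---------------------------------------------------------------------------
# Plain FBA
# ---------------------------------------------------------------------------

def solve_fba(cm: CommunityModel, objective="community_growth") -> FluxSolution:
    """Maximize community growth (or a named ``(species_id, reaction_id)``)."""
    prob = CommunityProblem(cm)
    if objective == "community_growth":
        c = prob.community_growth_objective()
    else:
        sid, rid = objective
        c = np.zeros(prob.n_vars)
        c[prob.var_index.index((sid, rid))] = 1.0
    res = prob._solve_lp(-c)
    if res.status != 0:
        return FluxSolution(status=_STATUS.get(res.status, "infeasible"))
    return prob.solution_from_x(res.x)


# ---------------------------------------------------------------------------
# Cooperative trade-off FBA
# ---------------------------------------------------------------------------

class _Stage2QP:
    """One OSQP instance per (problem, rho), reused across trade-off values.

    Only the lower bound of the community-growth row changes along a
    trade-off grid, so the factorization is kept and the solver warm-starts
    from the previous optimum.
    """

    def __init__(self, prob: CommunityProblem, extra_settings: dict | None = None):
        import osqp

        n = prob.n_vars
        bio_cols = [prob.biomass_cols[s] for s in sorted(prob.biomass_cols)]
        # a whisper of ridge on the non-growth fluxes makes the QP strongly
        # convex, which conditions the ADMM iterations without materially
        # moving the growth allocation (the parsimonious stage re-resolves
        # the flux degeneracy anyway)
        diag = np.full(n, 2.0e-8)
        diag[bio_cols] = 2.0
        P = sp.diags(diag, format="csc")
        growth_row = sp.csr_matrix(
            ([prob.abundance[s] for s in sorted(prob.biomass_cols)],
             (np.zeros(len(bio_cols), dtype=int), bio_cols)),
            shape=(1, n))
        A = sp.vstack([prob.A_eq, prob.A_ub, growth_row, sp.identity(n)],
                      format="csc")
        self._row = prob.A_eq.shape[0] + prob.A_ub.shape[0]
        self.l = np.concatenate([prob.b_eq, np.full(prob.A_ub.shape[0], -np.inf),
                                 [0.0], prob.lb])
        u = np.concatenate([prob.b_eq, prob.b_ub, [np.inf], prob.ub])
        settings = dict(verbose=False, eps_abs=1e-9, eps_rel=1e-9,
                        max_iter=50_000, polishing=True)
        settings.update(extra_settings or {})
        self.solver = osqp.OSQP()
        self.solver.setup(P=P, q=np.zeros(n), A=A, l=self.l, u=u, **settings)

    def solve(self, min_community_growth: float) -> np.ndarray | None:
        self.l[self._row] = min_community_growth
        self.solver.update(l=self.l)
        res = self.solver.solve(raise_error=False)
        if "solved" in res.info.status.lower():
            return np.asarray(res.x)
        return None


def _stage2_qp(prob: CommunityProblem, min_community_growth: float,
               tight: bool = False) -> np.ndarray | None:
    """Minimize sum of squared growth rates with OSQP; None if unavailable.

    ``tight`` requests full-accuracy ADMM (used when the result is returned
    directly, without the parsimonious stage to clean it up).
    """
    try:
        import osqp  # noqa: F401
    except ImportError:
        return None
    if not hasattr(prob, "_qp_cache"):
        prob._qp_cache = {}
        prob._qp_fail0 = 0  # rung-0 failures seen for this problem
    # the default ADMM parameters occasionally stall on these degenerate
    # community polytopes; a smaller step size (rho) with over-relaxation
    # disabled (alpha=1) converges on those, so retry down a short ladder.
    # Loose-eps rungs come first: the parsimonious stage re-imposes the
    # growth target exactly, so stage 2 only has to localize the allocation.
    # A problem that keeps failing the (fastest) first rung skips it.
    if tight:
        ladder = ({}, {"rho": 1e-2, "alpha": 1.0}, {"rho": 1e-3, "alpha": 1.0})
    else:
        ladder = ({"eps_abs": 1e-7, "eps_rel": 1e-7, "max_iter": 15_000},
                  {"eps_abs": 1e-7, "eps_rel": 1e-7, "rho": 1e-2, "alpha": 1.0},
                  {"rho": 1e-2, "alpha": 1.0},
                  {"rho": 1e-3, "alpha": 1.0})
    start = 1 if (prob._qp_fail0 >= 2 and not tight) else 0
    for i in range(start, len(ladder)):
        key = tuple(sorted(ladder[i].items()))
        solver = prob._qp_cache.get(key)
        if solver is None:
            solver = prob._qp_cache[key] = _Stage2QP(prob, ladder[i])
        x = solver.solve(min_community_growth)
        if x is not None:
            return x
        if i == 0:
            prob._qp_fail0 += 1
    logger.warning("OSQP stage-2 did not converge; falling back to LP spread")
    return None


def _stage2_lp_fallback(prob: CommunityProblem, min_community_growth: float) -> np.ndarray:
    """LP stand-in for the QP: minimize max_i |mu_i - m| over a free level m.

    Spreads growth toward a common level like the L2 objective does, but by
    Chebyshev rather than Euclidean geometry.
    """
    n = prob.n_vars
    # variables: [v (n), m, t]
    c = np.zeros(n + 2)
    c[-1] = 1.0
    bio = prob.biomass_cols
    rows = []
    for sid, col in bio.items():
        r1 = np.zeros(n + 2)  # mu - m - t <= 0
        r1[col], r1[-2], r1[-1] = 1.0, -1.0, -1.0
        r2 = np.zeros(n + 2)  # m - mu - t <= 0
        r2[col], r2[-2], r2[-1] = -1.0, 1.0, -1.0
        rows.extend([r1, r2])
    grow = np.zeros(n + 2)
    for sid, col in bio.items():
        grow[col] = -prob.abundance[sid]
    rows.append(grow)  # -sum a mu <= -min_growth
    A_extra = sp.csr_matrix(np.vstack(rows))
    b_extra = np.concatenate([np.zeros(2 * len(bio)), [-min_community_growth]])
    A_ub = sp.hstack([prob.A_ub, sp.csr_matrix((prob.A_ub.shape[0], 2))], format="csr")
    A_eq = sp.hstack([prob.A_eq, sp.csr_matrix((prob.A_eq.shape[0], 2))], format="csr")
    bounds = np.column_stack([
        np.concatenate([prob.lb, [-np.inf, 0.0]]),
        np.concatenate([prob.ub, [np.inf, np.inf]]),
    ])
    res = linprog(c, A_ub=sp.vstack([A_ub, A_extra], format="csr"),
                  b_ub=np.concatenate([prob.b_ub, b_extra]),
                  A_eq=A_eq, b_eq=prob.b_eq, bounds=bounds, method="highs",
                  options=_HIGHS_OPTIONS)
    if res.status != 0:
        raise RuntimeError(f"stage-2 LP fallback failed: {res.message}")
    return res.x[:n]


def _stage3_pfba(prob: CommunityProblem, mu_hat: dict[str, float],
                 min_community_growth: float | None = None,
                 rtol: float = GROWTH_FIX_RTOL) -> np.ndarray:
    """Fix growth rates near ``mu_hat`` and minimize total absolute flux.

    When ``min_community_growth`` is given, the community-growth constraint
    is re-imposed explicitly, so the trade-off contract holds to LP precision
    independent of any round-off in the quadratic stage.
    """
    n = prob.n_vars
    lb = prob.lb.copy()
    ub = prob.ub.copy()
    if np.isfinite(rtol):
        for sid, col in prob.biomass_cols.items():
            mu = mu_hat[sid]
            lo = mu - abs(mu) * rtol - GROWTH_FIX_ATOL
            hi = mu + abs(mu) * rtol + GROWTH_FIX_ATOL
            lb[col] = max(lb[col], lo)
            ub[col] = min(ub[col], hi)
    # split v = p - n with p, n >= 0 and unit costs: minimizes sum |v| without
    # extra constraint rows (at an optimum p and n are never both positive);
    # the split matrices are constant per problem, so cache them
    if not hasattr(prob, "_pfba_cache"):
        growth = np.zeros(n)
        for sid, col in prob.biomass_cols.items():
            growth[col] = -prob.abundance[sid]
        A_ub_grow = sp.vstack([prob.A_ub, sp.csr_matrix(growth)], format="csr")
        prob._pfba_cache = (
            sp.hstack([prob.A_eq, -prob.A_eq], format="csr"),
            sp.hstack([prob.A_ub, -prob.A_ub], format="csr"),
            sp.hstack([A_ub_grow, -A_ub_grow], format="csr"),
        )
    A_eq, A_ub_plain, A_ub_grow = prob._pfba_cache
    if min_community_growth is not None:
        A_ub = A_ub_grow
        b_ub = np.concatenate([prob.b_ub, [-min_community_growth]])
    else:
        A_ub = A_ub_plain
        b_ub = prob.b_ub
    c = np.ones(2 * n)
    bounds = np.column_stack([
        np.concatenate([np.maximum(0.0, lb), np.maximum(0.0, -ub)]),
        np.concatenate([np.maximum(0.0, ub), np.maximum(0.0, -lb)]),
    ])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=prob.b_eq,
                  bounds=bounds, method="highs", options=_HIGHS_OPTIONS)
    if res.status != 0:
        if rtol < 1e-2:  # stage-2 round-off can make a very tight band infeasible
            logger.debug("parsimonious stage infeasible at rtol=%g; widening", rtol)
            return _stage3_pfba(prob, mu_hat, min_community_growth, rtol=rtol * 100)
        if np.isfinite(rtol) and min_community_growth is not None:
            # the stage-2 point was unusable; keep only the growth target
            logger.warning("parsimonious stage: dropping growth band, "
                           "keeping community-growth target")
            return _stage3_pfba(prob, mu_hat, min_community_growth, rtol=np.inf)
        raise RuntimeError(f"parsimonious stage failed: {res.message}")
    return res.x[:n] - res.x[n:]


def solve_ctfba(cm: CommunityModel, tradeoff: float | None = None,
                parsimonious: bool = True,
                problem: CommunityProblem | None = None,
                mu_c_star: float | None = None) -> FluxSolution:
    """Cooperative trade-off FBA with a parsimonious final stage.

    ``problem`` and ``mu_c_star`` allow reuse across a trade-off grid (the
    stage-1 optimum does not depend on the trade-off value).
    """
    tradeoff = cm.tradeoff if tradeoff is None else tradeoff
    if not 0.0 < tradeoff <= 1.0:
        raise ValueError(f"tradeoff {tradeoff} outside (0, 1]")
    prob = problem if problem is not None else CommunityProblem(cm)
    if mu_c_star is None:
        res1 = prob._solve_lp(-prob.community_growth_objective())
        if res1.status != 0:
            return FluxSolution(status=_STATUS.get(res1.status, "infeasible"))
        mu_c_star = -res1.fun
    target = tradeoff * mu_c_star
    x2 = _stage2_qp(prob, target, tight=not parsimonious)
    if x2 is None:
        x2 = _stage2_lp_fallback(prob, target)
    mu_hat = {sid: float(np.clip(x2[col], max(0.0, prob.lb[col]), prob.ub[col]))
              for sid, col in prob.biomass_cols.items()}
    # lift: QP round-off may leave community growth a hair under the target;
    # rescale so the parsimonious band is centered on a contract-satisfying
    # allocation (the stage-3 LP then enforces the target exactly)
    achieved = sum(prob.abundance[s] * mu for s, mu in mu_hat.items())
    if 0 < achieved < target:
        lift = min(target / achieved, 1.01)
        mu_hat = {s: mu * lift for s, mu in mu_hat.items()}
    if parsimonious:
        x = _stage3_pfba(prob, mu_hat, min_community_growth=target)
    else:
        x = x2
    sol = prob.solution_from_x(x)
    sol.mu_c_star = mu_c_star  # achieved optimum of stage 1, for diagnostics
    return sol


# ---------------------------------------------------------------------------
# Exchange bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ExchangeMatrix:
    """Split of species net exchange fluxes into import/export magnitudes.

    Imports and exports are per gDW of the species (mmol gDW^-1 h^-1); at most
    one of the two is nonzero per (species, compound).  ``net_community`` is
    the abundance-weighted community total per compound (mmol gVS^-1 h^-1).
    """

    imports: dict[tuple[str, str], float] = field(default_factory=dict)
    exports: dict[tuple[str, str], float] = field(default_factory=dict)
    net_community: dict[str, float] = field(default_factory=dict)

    def importers(self, compound: str, threshold: float = 0.0) -> set[str]:
        return {s for (s, c), v in self.imports.items() if c == compound and v > threshold}

    def exporters(self, compound: str, threshold: float = 0.0) -> set[str]:
        return {s for (s, c), v in self.exports.items() if c == compound and v > threshold}

    def import_vector(self, species_id: str) -> dict[str, float]:
        return {c: v for (s, c), v in self.imports.items() if s == species_id and v > 0}


def extract_exchanges(sol: FluxSolution) -> ExchangeMatrix:
    """Split each species' net exchange into import and export magnitudes."""
    if not sol.optimal:
        raise ValueError(f"cannot extract exchanges from a {sol.status} solution")
    ex = ExchangeMatrix(net_community=dict(sol.community_exchange))
    for (sid, cpd), net in sol.species_exchange.items():
        if net > 0:
            ex.exports[(sid, cpd)] = net
        elif net < 0:
            ex.imports[(sid, cpd)] = -net
    return ex


def methane_attribution(sol: FluxSolution, archaea: list[str],
                        abundances: dict[str, float] | None = None,
                        gdw_per_gvs: float = 1.0,
                        ch4_id: str = "ch4") -> dict[str, float]:
    """Per-archaeon CH4 secretion in community units (mmol gVS^-1 h^-1).

    Requires the abundances used in the solved community so that per-gDW
    secretion can be weighted back to community scale; the attributed values
    sum to the community CH4 flux when the listed archaea are its only
    producers.
    """
    if not sol.optimal:
        raise ValueError(f"cannot attribute methane from a {sol.status} solution")
    known = {cpd for (_, cpd) in sol.species_exchange}
    if archaea and ch4_id not in known:
        raise KeyError(f"compound {ch4_id!r} not exchanged by any community member")
    out: dict[str, float] = {}
    for sid in archaea:
        net = sol.species_exchange.get((sid, ch4_id), 0.0)
        a = abundances[sid] if abundances is not None else 1.0
        out[sid] = max(0.0, net) * a * gdw_per_gvs
    return out
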