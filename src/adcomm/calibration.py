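"""Prediction-measurement comparison and trade-off calibration.

The cooperative trade-off ``ct`` controls how much community growth is
sacrificed for an even allocation across members.  It is calibrated by
solving every per-sample community over a grid of ``ct`` values and scoring
each value by the agreement between predicted and measured CH4 and CO2
production rates (mean of the two Pearson correlations), with a penalty for
trade-off values at which part of the archaeal community cannot grow —
predicted methanogenesis without methanogen growth is not a credible
equilibrium.  Predicted archaeal growth rates can additionally be compared
against replication-rate estimates from sequencing coverage (log2 PTR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fba import CommunityProblem, solve_ctfba
from .model import AnalysisConfig, CommunityModel, FluxSolution

__all__ = [
    "correlate_predictions",
    "calibrate_tradeoff",
    "compare_growth_ptr",
    "CalibrationResult",
]


def correlate_predictions(pred: dict[str, float] | pd.Series,
                          meas: dict[str, float] | pd.Series,
                          method: str = "pearson") -> tuple[float, float, int]:
    """Correlate predicted fluxes with measured rates over matched samples.

    Samples missing on either side are dropped pairwise; returns (r, p, n).
    A constant vector has no defined correlation and raises instead of
    propagating NaN.
    """
    pred = pd.Series(pred, dtype=float)
    meas = pd.Series(meas, dtype=float)
    common = pred.index.intersection(meas.index)
    x, y = pred.loc[common], meas.loc[common]
    mask = x.notna() & y.notna()
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    if np.isclose(x.std(ddof=0), 0.0) or np.isclose(y.std(ddof=0), 0.0):
        raise ValueError("correlation undefined: one of the series is constant")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


@dataclass
class CalibrationResult:
    best_tradeoff: float
    table: pd.DataFrame  # one row per grid point
    solutions: dict[float, dict[str, FluxSolution]]


def calibrate_tradeoff(communities: dict[str, CommunityModel],
                       measurements,
                       archaea: list[str],
                       config: AnalysisConfig | None = None,
                       grid: tuple[float, ...] | None = None,
                       penalty_weight: float = 1.0,
                       keep_solutions: bool = False,
                       problems: dict[str, CommunityProblem] | None = None) -> CalibrationResult:
    """Pick the trade-off maximizing prediction-measurement agreement.

    For each grid value: solve every sample by ctFBA, correlate predicted
    CH4 and CO2 community fluxes with the measured rates, and score
    ``mean(r_CH4, r_CO2) - penalty_weight * zero_archaea_fraction`` where the
    last term is the fraction of (sample, archaeon) pairs with no growth.
    Infeasible samples are recorded against their grid value, not fatal.
    Ties break toward the larger trade-off.
    """
    config = config or AnalysisConfig()
    grid = tuple(grid if grid is not None else config.tradeoff_grid)
    if not communities:
        raise ValueError("no communities to calibrate on")
    # stage-1 optimum is trade-off independent: compute once per sample;
    # callers sweeping several measurement sets over the same communities can
    # pass prebuilt problems to reuse solver state
    problems = {} if problems is None else problems
    mu_star: dict[str, float] = {}
    for sid, cm in communities.items():
        prob = problems.get(sid)
        if prob is None:
            prob = problems[sid] = CommunityProblem(cm)
        res = prob._solve_lp(-prob.community_growth_objective())
        mu_star[sid] = -res.fun if res.status == 0 else float("nan")
    rows = []
    all_solutions: dict[float, dict[str, FluxSolution]] = {}
    for ct in grid:
        pred_ch4, pred_co2 = {}, {}
        zero_archaea = 0
        n_archaea = 0
        failures = 0
        sols: dict[str, FluxSolution] = {}
        for sid, cm in communities.items():
            if np.isnan(mu_star[sid]):
                failures += 1
                continue
            sol = solve_ctfba(cm, ct, problem=problems[sid], mu_c_star=mu_star[sid])
            if not sol.optimal:
                failures += 1
                continue
            sols[sid] = sol
            pred_ch4[sid] = sol.community_exchange.get(config.ch4_id, 0.0)
            pred_co2[sid] = sol.community_exchange.get(config.co2_id, 0.0)
            present = [a for a in archaea if a in sol.growth_rates]
            n_archaea += len(present)
            zero_archaea += sum(
                1 for a in present if sol.growth_rates[a] <= config.solver_tolerance)
        if keep_solutions:
            all_solutions[ct] = sols
        try:
            r_ch4, _, _ = correlate_predictions(pred_ch4, measurements.ch4)
            r_co2, _, _ = correlate_predictions(pred_co2, measurements.co2)
        except ValueError:
            r_ch4 = r_co2 = float("nan")
        frac_zero = zero_archaea / n_archaea if n_archaea else 1.0
        score = np.nanmean([r_ch4, r_co2]) - penalty_weight * frac_zero
        rows.append({"tradeoff": ct, "r_ch4": r_ch4, "r_co2": r_co2,
                     "zero_archaea_fraction": frac_zero,
                     "n_infeasible": failures, "score": score})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["score"])]
    if finite.empty:
        raise ValueError("no trade-off value produced a defined score")
    best_score = finite["score"].max()
    # ties toward the larger trade-off
    best = finite.loc[np.isclose(finite["score"], best_score), "tradeoff"].max()
    return CalibrationResult(best_tradeoff=float(best), table=table,
                             solutions=all_solutions)


def compare_growth_ptr(pred_growth: pd.DataFrame | dict,
                       log2_ptr: pd.DataFrame | dict) -> tuple[float, float]:
    """Pooled Pearson correlation of predicted growth vs log2 PTR.

    Inputs are (sample x archaeon) tables or ``{(archaeon, sample): value}``
    maps; all matched pairs are pooled into one correlation.
    """
    def flatten(obj):
        if isinstance(obj, pd.DataFrame):
            return {(c, i): obj.loc[i, c] for i in obj.index for c in obj.columns
                    if pd.notna(obj.loc[i, c])}
        return dict(obj)

    g = flatten(pred_growth)
    ptr = flatten(log2_ptr)
    keys = sorted(set(g) & set(ptr))
    if len(keys) < 3:
        raise ValueError(f"need >= 3 matched (archaeon, sample) pairs, got {len(keys)}")
    x = np.array([g[k] for k in keys], dtype=float)
    y = np.array([ptr[k] for k in keys], dtype=float)
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined: constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
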