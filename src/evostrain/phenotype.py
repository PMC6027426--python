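"""Phenotype prediction: FBA, FVA, MiMBl, and yield-space computation.

All linear programs are solved with HiGHS via :func:`scipy.optimize.linprog`.
Substrate uptake follows the exchange-flux sign convention (negative flux =
uptake); reported uptake rates ``vS`` are magnitudes.

MiMBl (Minimization of Metabolite Balances) predicts a mutant flux
distribution by minimizing the L1 distance between mutant and reference
per-metabolite turnovers, ``t_i = 1/2 * sum_j |S_ij * v_j|``, subject to
steady state and the mutant's bounds. The absolute values are linearized by
splitting each flux into nonnegative forward/backward parts; at an optimum
with nonzero deviation costs the two parts are not used simultaneously, so
the linearized turnover coincides with the true one for irreversible
networks and is the standard relaxation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import DomainError, InfeasibleModelError
from .model import MetabolicModel

__all__ = [
    "RateSpec",
    "PhenotypePrediction",
    "ReferenceState",
    "YieldSpace",
    "fba",
    "fva",
    "predict_fba",
    "mimbl_predict",
    "yield_space",
]

STEADY_STATE_TOL = 1e-6
#: fluxes below this magnitude are treated as zero (solver noise floor)
FLUX_TOL = 1e-9


@dataclass(frozen=True)
class RateSpec:
    """Reaction ids from which growth, product, and substrate rates are read."""

    biomass: str
    product: str
    substrate: str


@dataclass
class PhenotypePrediction:
    """A (predicted) mutant flux distribution and its engineering rates."""

    v: np.ndarray
    mu: float
    vS: float
    vP: float
    feasible: bool
    objective_value: float = float("nan")

    @classmethod
    def infeasible_result(cls, n: int) -> "PhenotypePrediction":
        return cls(v=np.zeros(n), mu=0.0, vS=0.0, vP=0.0, feasible=False)


def _extract(model: MetabolicModel, v: np.ndarray, rates: RateSpec,
             objective_value: float = float("nan")) -> PhenotypePrediction:
    mu = float(v[model.rxn_index(rates.biomass)])
    vP = float(v[model.rxn_index(rates.product)])
    vS = float(abs(v[model.rxn_index(rates.substrate)]))
    return PhenotypePrediction(
        v=v, mu=max(mu, 0.0), vS=vS, vP=max(vP, 0.0), feasible=True,
        objective_value=objective_value,
    )


def _assert_steady_state(model: MetabolicModel, v: np.ndarray) -> None:
    resid = float(np.max(np.abs(model.S @ v))) if model.n_metabolites else 0.0
    if resid > STEADY_STATE_TOL * 10:
        raise InfeasibleModelError(f"LP solution violates steady state ({resid:.2e})")


def _solve(c: np.ndarray, A_eq: np.ndarray, b_eq: np.ndarray,
           bounds: Sequence[tuple[float, float]]):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return res


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    fixed: Optional[dict[str, float]] = None,
) -> tuple[np.ndarray, float, bool]:
    """Optimize the flux of one reaction subject to S v = 0 and bounds.

    Returns ``(v, objective_value, feasible)``; on infeasibility the flux
    vector is all zeros and the value 0.
    """
    rid = objective or model.objective_reaction
    if rid is None:
        raise DomainError("model has no objective reaction and none was given")
    j = model.rxn_index(rid)
    lb, ub = model.lb.copy(), model.ub.copy()
    if fixed:
        for r, val in fixed.items():
            k = model.rxn_index(r)
            lb[k] = ub[k] = val
    c = np.zeros(model.n_reactions)
    c[j] = -1.0 if sense == "max" else 1.0
    res = _solve(c, model.S, np.zeros(model.n_metabolites), list(zip(lb, ub)))
    if not res.success:
        return np.zeros(model.n_reactions), 0.0, False
    v = np.asarray(res.x)
    _assert_steady_state(model, v)
    return v, float(v[j]), True


def fva(
    model: MetabolicModel,
    reaction_ids: Optional[Iterable[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flux variability analysis: per-reaction min/max flux at steady state."""
    rids = list(reaction_ids) if reaction_ids is not None else list(model.reactions)
    vmin = np.empty(len(rids))
    vmax = np.empty(len(rids))
    bounds = list(zip(model.lb, model.ub))
    b_eq = np.zeros(model.n_metabolites)
    for i, rid in enumerate(rids):
        j = model.rxn_index(rid)
        c = np.zeros(model.n_reactions)
        c[j] = 1.0
        lo = _solve(c, model.S, b_eq, bounds)
        c[j] = -1.0
        hi = _solve(c, model.S, b_eq, bounds)
        if not (lo.success and hi.success):
            raise InfeasibleModelError(f"FVA subproblem infeasible at {rid!r}")
        vmin[i] = lo.x[j]
        vmax[i] = hi.x[j]
    return vmin, vmax


def predict_fba(
    model: MetabolicModel,
    rates: RateSpec,
    tie_break: str = "max",
    mu_tol: float = 1e-6,
) -> PhenotypePrediction:
    """FBA phenotype: maximal growth, product rate resolved by a second LP.

    The growth optimum is usually degenerate in the product flux, so with
    growth fixed at its maximum (within ``mu_tol``) the product rate is
    maximized (``tie_break='max'``, optimistic) or minimized (pessimistic).
    """
    if tie_break not in ("max", "min"):
        raise DomainError(f"tie_break must be 'max' or 'min', got {tie_break!r}")
    v, mu, ok = fba(model, objective=rates.biomass, sense="max")
    if not ok:
        return PhenotypePrediction.infeasible_result(model.n_reactions)
    jb = model.rxn_index(rates.biomass)
    sub = model.copy()
    sub.lb[jb] = mu - mu_tol * max(1.0, abs(mu))
    sub.ub[jb] = mu
    v2, _, ok2 = fba(sub, objective=rates.product, sense=tie_break)
    if not ok2:  # numerically tight growth fixing failed; fall back
        return _extract(model, v, rates, objective_value=mu)
    return _extract(model, v2, rates, objective_value=mu)


@dataclass
class ReferenceState:
    """Reference flux distribution and the turnovers MiMBl tracks.

    Fluxes are stored by reaction id so the state can be re-indexed onto a
    model extended with candidate insertion reactions (missing ids get zero
    flux).
    """

    fluxes: dict[str, float]

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes.get(r, 0.0) for r in model.reactions])

    def turnovers(self, model: MetabolicModel) -> np.ndarray:
        v = self.vector(model)
        return 0.5 * (np.abs(model.S) @ np.abs(v))

    def validate(self, model: MetabolicModel, tol: float = STEADY_STATE_TOL) -> None:
        resid = float(np.max(np.abs(model.S @ self.vector(model))))
        if resid > tol:
            raise DomainError(
                f"reference fluxes violate steady state (max residual {resid:.2e})"
            )

    @classmethod
    def from_model_fba(cls, model: MetabolicModel, rates: Optional[RateSpec] = None
                       ) -> "ReferenceState":
        """Wild-type FBA flux distribution as the reference state.

        When a :class:`RateSpec` is given the growth optimum is resolved with
        the optimistic product tie-break so the reference is deterministic.
        """
        if rates is not None:
            pred = predict_fba(model, rates)
            if not pred.feasible:
                raise InfeasibleModelError("wild-type model infeasible")
            v = pred.v
        else:
            v, _, ok = fba(model)
            if not ok:
                raise InfeasibleModelError("wild-type model infeasible")
        return cls(fluxes=dict(zip(model.reactions, map(float, v))))


def mimbl_predict(
    model: MetabolicModel,
    ref: ReferenceState,
    rates: RateSpec,
) -> PhenotypePrediction:
    """Minimization of Metabolite Balances phenotype prediction.

    Solves ``min sum_i |t_i(v) - t_ref_i|`` over steady-state flux vectors
    within the mutant's bounds, with turnovers linearized via forward /
    backward flux parts. The LP objective value is stored on the returned
    prediction (0 iff the mutant admits the reference turnover vector).
    """
    m, n = model.n_metabolites, model.n_reactions
    t_ref = ref.turnovers(model)
    absS = np.abs(model.S)

    # variables: [v+ (n), v- (n), d+ (m), d- (m)]
    nvar = 2 * n + 2 * m
    c = np.zeros(nvar)
    c[2 * n:] = 1.0

    A_eq = np.zeros((2 * m, nvar))
    b_eq = np.zeros(2 * m)
    # S (v+ - v-) = 0
    A_eq[:m, :n] = model.S
    A_eq[:m, n:2 * n] = -model.S
    # 0.5 |S| (v+ + v-) - d+ + d- = t_ref
    A_eq[m:, :n] = 0.5 * absS
    A_eq[m:, n:2 * n] = 0.5 * absS
    A_eq[m:, 2 * n:2 * n + m] = -np.eye(m)
    A_eq[m:, 2 * n + m:] = np.eye(m)
    b_eq[m:] = t_ref

    bounds = (
        [(max(lo, 0.0), max(hi, 0.0)) for lo, hi in zip(model.lb, model.ub)]
        + [(max(-hi, 0.0), max(-lo, 0.0)) for lo, hi in zip(model.lb, model.ub)]
        + [(0.0, None)] * (2 * m)
    )
    res = _solve(c, A_eq, b_eq, bounds)
    if not res.success:
        return PhenotypePrediction.infeasible_result(n)
    x = np.asarray(res.x)
    v = x[:n] - x[n:2 * n]
    _assert_steady_state(model, v)
    pred = _extract(model, v, rates, objective_value=float(res.fun))
    return pred


@dataclass
class YieldSpace:
    """Product-yield envelope over a growth-rate grid.

    ``y_min``/``y_max`` are product yields (mol per mol substrate) at each
    grid growth rate; infeasible grid points are masked out. Areas are
    trapezoidal integrals over the feasible growth range.
    """

    growth_grid: np.ndarray
    y_min: np.ndarray
    y_max: np.ndarray
    feasible: np.ndarray
    area_total: float = field(init=False)
    area_below_lower: float = field(init=False)

    def __post_init__(self) -> None:
        ok = self.feasible
        if ok.sum() >= 2:
            g = self.growth_grid[ok]
            self.area_total = float(np.trapezoid(self.y_max[ok], g))
            self.area_below_lower = float(np.trapezoid(self.y_min[ok], g))
        else:
            self.area_total = 0.0
            self.area_below_lower = 0.0


def yield_space(
    model: MetabolicModel,
    rates: RateSpec,
    n_points: int = 20,
    fix_substrate_uptake: bool = True,
    mu_tol: float = 1e-6,
) -> YieldSpace:
    """Compute the product yield envelope of a (mutant) model.

    At each of ``n_points`` growth rates between 0 and the FBA growth
    maximum, the product rate is minimized and maximized. By default the
    substrate exchange is pinned at its maximal uptake (the production-
    envelope convention), making yields well defined as vP/vS with a common
    vS; with ``fix_substrate_uptake=False`` each LP solution's own uptake is
    used instead.
    """
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    js = model.rxn_index(rates.substrate)
    work = model.copy()
    if fix_substrate_uptake:
        if work.lb[js] >= 0:
            raise DomainError(
                f"substrate exchange {rates.substrate!r} has no uptake capacity"
            )
        work.ub[js] = work.lb[js]

    _, mu_max, ok = fba(work, objective=rates.biomass, sense="max")
    grid = np.linspace(0.0, max(mu_max, 0.0), n_points)
    y_min = np.zeros(n_points)
    y_max = np.zeros(n_points)
    feas = np.zeros(n_points, dtype=bool)
    if not ok or mu_max <= FLUX_TOL:
        return YieldSpace(grid, y_min, y_max, feas)

    jb = work.rxn_index(rates.biomass)
    for k, mu in enumerate(grid):
        sub = work.copy()
        sub.lb[jb] = mu - mu_tol * max(1.0, mu)
        sub.ub[jb] = mu + mu_tol * max(1.0, mu)
        v_lo, p_lo, ok_lo = fba(sub, objective=rates.product, sense="min")
        v_hi, p_hi, ok_hi = fba(sub, objective=rates.product, sense="max")
        if not (ok_lo and ok_hi):
            continue
        vs_lo = abs(v_lo[js])
        vs_hi = abs(v_hi[js])
        y_min[k] = p_lo / vs_lo if vs_lo > FLUX_TOL else 0.0
        y_max[k] = p_hi / vs_hi if vs_hi > FLUX_TOL else 0.0
        if y_min[k] > y_max[k]:  # guard against quadrature-level noise
            y_min[k] = y_max[k] = 0.5 * (y_min[k] + y_max[k])
        feas[k] = True
    return YieldSpace(grid, y_min, y_max, feas)
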