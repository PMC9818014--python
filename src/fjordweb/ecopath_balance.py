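"""Steady-state mass balance of a food-web model.

Each living group i obeys the ecotrophic balance

    B_i (P/B)_i EE_i = sum_j B_j (Q/B)_j DC_ji + Y_i + BA_i

production used within the system equals predation plus catches plus
biomass accumulation.  Exactly one of {B_i, EE_i} may be unknown per
group.  All unknown biomasses are found by a single global linear solve
(predators of an unknown-biomass prey may themselves have unknown
biomass), after which the remaining EEs follow by substitution.

The detritus pool is balanced last: its inflow is the sum of
unassimilated consumption and non-predation mortality, its outflow is
detritivory plus a residual export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import CONSUMER, PRODUCER, FoodWebModel, ModelError


class UnbalancedModelError(ModelError):
    """The balance has no admissible solution (B <= 0 or EE outside [0, 1])."""


@dataclass
class BalancedModel:
    """A solved model with all per-group and pairwise flows.

    Flows are t km^-2 year^-1; ``predation`` is prey-by-predator with
    entry Q_j * DC_ji (consumption of prey i by predator j).
    """

    model: FoodWebModel
    biomass: pd.Series
    ee: pd.Series
    consumption: pd.Series  # Q_i = B_i (Q/B)_i
    production: pd.Series  # P_i = B_i (P/B)_i
    respiration: pd.Series  # R_i = (1 - GS_i) Q_i - P_i
    flow_to_detritus: pd.Series
    exports: pd.Series  # landings for living groups + detritus surplus
    predation: pd.DataFrame
    detritus_inflow: float = 0.0
    detritivory: float = 0.0
    detritus_export: float = 0.0

    @property
    def names(self) -> list[str]:
        return self.model.names

    def predation_on(self, name: str) -> float:
        return float(self.predation.loc[name].sum())


@dataclass
class PredationFractionMatrix:
    """FC[prey, predator]: share of predation on the prey by that predator."""

    fractions: pd.DataFrame  # prey x predator, rows sum to 1 or 0

    def loc(self, prey: str, predator: str) -> float:
        return float(self.fractions.loc[prey, predator])


def solve_mass_balance(model: FoodWebModel, rtol: float = 1e-8) -> BalancedModel:
    """Fill in the unknown biomasses and EEs and derive all flows.

    Raises :class:`UnbalancedModelError`, naming the offending group,
    when a solved biomass is non-positive or an EE falls outside
    [0, 1] (beyond ``rtol`` slack for rounded inputs).
    """
    names = model.names
    living = model.living
    pb = model.param_series("pb")
    qb = model.param_series("qb").fillna(0.0)
    ee = model.param_series("ee")
    bio = model.param_series("biomass")
    y = model.param_series("landings").fillna(0.0)
    ba = model.param_series("biomass_accumulation").fillna(0.0)
    diet = model.diet  # prey x predator fractions

    unknown_b = [n for n in living if np.isnan(bio[n])]
    for n in unknown_b:
        if np.isnan(ee[n]):
            raise UnbalancedModelError(f"{n}: both biomass and EE unknown")

    # Global linear system in the unknown biomasses.  For prey i with
    # unknown B (known EE):  EE_i PB_i B_i - sum_{j unknown} QB_j DC_ji B_j
    #   = sum_{j known} B_j QB_j DC_ji + Y_i + BA_i
    if unknown_b:
        k = len(unknown_b)
        pos = {n: idx for idx, n in enumerate(unknown_b)}
        A = np.zeros((k, k))
        rhs = np.zeros(k)
        for n in unknown_b:
            r = pos[n]
            A[r, r] += ee[n] * pb[n]
            rhs[r] += y[n] + ba[n]
            for j in model.consumers:
                dc = diet.loc[n, j]
                if dc == 0:
                    continue
                if j in pos:
                    A[r, pos[j]] -= qb[j] * dc
                else:
                    rhs[r] += bio[j] * qb[j] * dc
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise UnbalancedModelError(f"singular balance system: {exc}") from exc
        for n in unknown_b:
            b = sol[pos[n]]
            if not np.isfinite(b) or b <= 0:
                raise UnbalancedModelError(f"{n}: solved biomass {b:.4g} is not positive")
            bio[n] = b

    # EEs of the remaining groups by substitution.
    q_tot = bio.fillna(0.0) * qb  # per-predator total consumption
    predation = diet.mul(q_tot[diet.columns], axis=1)  # prey x predator flows
    for n in living:
        if np.isnan(ee[n]):
            prod = bio[n] * pb[n]
            demand = float(predation.loc[n].sum()) + y[n] + ba[n]
            if prod <= 0:
                raise UnbalancedModelError(f"{n}: zero production with nonzero demand")
            val = demand / prod
            if val < 0 or val > 1 + 1e-6:
                raise UnbalancedModelError(
                    f"{n}: solved EE {val:.4f} outside [0, 1] (unbalanced model)"
                )
            ee[n] = min(val, 1.0)

    balanced = BalancedModel(
        model=model,
        biomass=bio,
        ee=ee,
        consumption=pd.Series(0.0, index=names),
        production=pd.Series(0.0, index=names),
        respiration=pd.Series(0.0, index=names),
        flow_to_detritus=pd.Series(0.0, index=names),
        exports=pd.Series(0.0, index=names),
        predation=predation.reindex(index=names, columns=model.consumers).fillna(0.0),
    )
    return derive_flows(balanced)


def derive_flows(balanced: BalancedModel) -> BalancedModel:
    """Derive consumption, respiration, detrital and export flows.

    Respiration is what is left of assimilated consumption after
    production; a negative value means the input P/B, Q/B pair is
    physiologically impossible and raises.
    """
    m = balanced.model
    bio, ee = balanced.biomass, balanced.ee
    pb = m.param_series("pb").fillna(0.0)
    qb = m.param_series("qb").fillna(0.0)
    gs = m.param_series("unassimilated").fillna(0.0)
    y = m.param_series("landings").fillna(0.0)

    Q = bio.fillna(0.0) * qb
    P = bio.fillna(0.0) * pb
    R = pd.Series(0.0, index=m.names)
    FD = pd.Series(0.0, index=m.names)
    EX = pd.Series(0.0, index=m.names)
    for g in m.groups:
        n = g.name
        if g.role == CONSUMER:
            R[n] = (1.0 - gs[n]) * Q[n] - P[n]
            if R[n] < -1e-9 * max(Q[n], 1.0):
                raise UnbalancedModelError(
                    f"{n}: negative respiration ({R[n]:.4g}); P/B exceeds assimilation"
                )
            FD[n] = gs[n] * Q[n] + (1.0 - ee[n]) * P[n]
            EX[n] = y[n]
        elif g.role == PRODUCER:
            FD[n] = (1.0 - ee[n]) * P[n]
            EX[n] = y[n]

    inflow = float(FD.sum())
    detritivory = float(
        balanced.predation.loc[m.detritus_groups].to_numpy().sum()
    ) if m.detritus_groups else 0.0
    det_export = inflow - detritivory
    for n in m.detritus_groups:
        EX[n] = det_export

    balanced.consumption = Q
    balanced.production = P
    balanced.respiration = R
    balanced.flow_to_detritus = FD
    balanced.exports = EX
    balanced.detritus_inflow = inflow
    balanced.detritivory = detritivory
    balanced.detritus_export = det_export
    return balanced


def predation_fractions(balanced: BalancedModel) -> PredationFractionMatrix:
    """Share of each prey's predation mortality taken by each predator.

    Rows (prey) sum to 1 when the prey has predators and to 0 otherwise.
    """
    pred = balanced.predation
    totals = pred.sum(axis=1)
    fc = pred.div(totals.where(totals > 0, np.inf), axis=0)
    return PredationFractionMatrix(fractions=fc.fillna(0.0))


def balance_residuals(balanced: BalancedModel) -> pd.Series:
    """Per-living-group residual of the ecotrophic balance equation."""
    m = balanced.model
    y = m.param_series("landings").fillna(0.0)
    ba = m.param_series("biomass_accumulation").fillna(0.0)
    res = {}
    for n in m.living:
        res[n] = (
            balanced.production[n] * balanced.ee[n]
            - balanced.predation_on(n)
            - y[n]
            - ba[n]
        )
    return pd.Series(res)
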