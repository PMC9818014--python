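"""Fractional trophic levels and the discrete-level (Lindeman) spine.

The fractional trophic level of a consumer is one plus the diet-weighted
mean level of its prey,

    TL_j = 1 + sum_i DC_ji TL_i,

with producers and detritus fixed at level 1 and any diet import also
assigned level 1.  Cannibalistic and otherwise cyclic diets are handled
by solving the fixed point as a linear system.

The Lindeman decomposition distributes each group's flow over discrete
levels I, II, III, ...: a consumer acts at level k+1 in proportion to
the fraction of its diet acting at level k, with everything beyond the
cap level folded into the cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecopath_balance import BalancedModel
from .model_io import CONSUMER, FoodWebModel, ModelError


@dataclass
class TrophicDecomposition:
    tl: pd.Series  # fractional trophic level per group
    level_fractions: pd.DataFrame  # group x level (1..max_level), rows sum to 1
    aggregated_flows: pd.Series  # absolute throughflow per discrete level


def _as_model(model: BalancedModel | FoodWebModel) -> FoodWebModel:
    return model.model if isinstance(model, BalancedModel) else model


def trophic_levels(model: BalancedModel | FoodWebModel) -> pd.Series:
    """Solve the diet-weighted fixed point for fractional trophic levels."""
    m = _as_model(model)
    names = m.names
    consumers = m.consumers
    basal_level = pd.Series(1.0, index=names)

    k = len(consumers)
    pos = {n: i for i, n in enumerate(consumers)}
    A = np.eye(k)
    b = np.ones(k)
    for j in consumers:
        r = pos[j]
        b[r] += float(m.diet_import[j])  # import feeds at level 1
        for i in names:
            dc = float(m.diet.loc[i, j])
            if dc == 0:
                continue
            if i in pos:
                A[r, pos[i]] -= dc
            else:
                b[r] += dc * 1.0  # producers/detritus at level 1
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"trophic-level system is singular: {exc}") from exc
    tl = basal_level.copy()
    for n, i in pos.items():
        tl[n] = sol[i]
    return tl.rename("trophic_level")


def lindeman_decomposition(
    balanced: BalancedModel, max_level: int = 5
) -> TrophicDecomposition:
    """Distribute each group's flow over ``max_level`` discrete levels.

    Producers and detritus sit entirely at level I.  Consumer fractions
    follow the diet recursion; mass that cycles beyond the cap (e.g.
    through cannibalism) is folded into the cap level so each row sums
    to 1.
    """
    m = balanced.model
    names = m.names
    consumers = set(m.consumers)
    n = len(names)
    idx = {g: i for i, g in enumerate(names)}

    # Column-stochastic transition: consumer j receives from prey i.
    D = np.zeros((n, n))
    for j in m.consumers:
        for i in names:
            D[idx[i], idx[j]] = float(m.diet.loc[i, j])
    imp = np.array([float(m.diet_import[g]) if g in consumers else 0.0 for g in names])
    basal = np.array([0.0 if g in consumers else 1.0 for g in names])

    # frac(k+1) = D^T frac(k) + import entering one level above basal.
    frac = np.zeros((n, max_level))
    frac[:, 0] = basal
    cur = basal.copy()
    # Iterate well past the cap so slowly-converging cycles (cannibalism)
    # leave a negligible unassigned remainder, then fold into the cap.
    extra = 200
    for k in range(1, max_level + extra):
        cur = D.T @ cur
        if k == 1:
            cur = cur + imp
        col = min(k, max_level - 1)
        frac[:, col] += cur
        if cur.max() < 1e-14:
            break
    # Numerical guard: rows must sum to 1.
    frac[:, max_level - 1] += 1.0 - frac.sum(axis=1)

    level_fractions = pd.DataFrame(
        frac, index=names, columns=[i + 1 for i in range(max_level)]
    )

    # Throughflow per group: consumption for consumers, production for
    # producers, inflow for detritus.
    through = pd.Series(0.0, index=names)
    for g in m.groups:
        if g.role == CONSUMER:
            through[g.name] = balanced.consumption[g.name]
        elif g.role == "producer":
            through[g.name] = balanced.production[g.name]
        else:
            through[g.name] = balanced.detritus_inflow
    agg = level_fractions.mul(through, axis=0).sum(axis=0)
    tl = trophic_levels(balanced)
    return TrophicDecomposition(tl=tl, level_fractions=level_fractions, aggregated_flows=agg)


def mean_tl_catch(balanced: BalancedModel, tl: pd.Series | None = None) -> float:
    """Landings-weighted mean trophic level of the catch."""
    m = balanced.model
    y = m.param_series("landings").fillna(0.0)
    total = float(y.sum())
    if total <= 0:
        raise ModelError("no landings: mean trophic level of the catch undefined")
    if tl is None:
        tl = trophic_levels(balanced)
    return float((y * tl).sum() / total)
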