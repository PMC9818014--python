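"""Mixed trophic impacts: direct (diet minus predation share) and total.

The direct impact of group i on group j combines a bottom-up benefit
and a top-down cost:

    q_ij = DC_ij - FC_ij

where DC_ij is the fraction that i contributes to the diet of j (i as
prey supports j) and FC_ij is the share of j's total mortality
(predation plus catches) exerted by i (i as predator removes j).  The
detritus pool participates as a consumer whose "diet" is its inflow
shares and exerts no mortality; an optional fleet node has the landings
composition as its diet and its catch share of each group's total
mortality as its predation row.  The total (direct plus indirect)
impact matrix is the Neumann series of q,

    total = (I - q)^-1 - I,

which converges whenever the spectral radius of q is below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecopath_balance import BalancedModel
from .model_io import ModelError

FLEET = "Fleet"


@dataclass
class ImpactMatrix:
    """Pairwise impacts, impacting group (rows) by impacted group (cols)."""

    direct: pd.DataFrame
    total: pd.DataFrame


def direct_impacts(balanced: BalancedModel, include_fleet: bool = True) -> pd.DataFrame:
    """Direct-impact matrix (impacting rows, impacted columns)."""
    m = balanced.model
    names = list(m.names)
    y = m.param_series("landings").fillna(0.0)
    has_fleet = include_fleet and float(y.sum()) > 0
    nodes = names + [FLEET] if has_fleet else list(names)

    # Bottom-up term: DC[i, j] = contribution of i to the diet of j.
    dc = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for j in m.consumers:
        dc.loc[names, j] = balanced.model.diet[j].reindex(names).fillna(0.0).to_numpy()
    fd = balanced.flow_to_detritus
    inflow = float(fd.sum())
    for d in m.detritus_groups:
        if inflow > 0:
            dc.loc[names, d] = (fd / inflow).reindex(names).fillna(0.0).to_numpy()
    if has_fleet:
        dc.loc[names, FLEET] = (y / float(y.sum())).reindex(names).fillna(0.0).to_numpy()

    # Top-down term: FC[i, j] = share of j's mortality exerted by i.
    # With a fleet, catches count in each group's total mortality.
    pred = balanced.predation.reindex(index=names).fillna(0.0)
    totals = pred.sum(axis=1) + (y if has_fleet else 0.0)
    fc = pd.DataFrame(0.0, index=nodes, columns=nodes)
    denom = totals.where(totals > 0, np.inf)
    for i in m.consumers:
        fc.loc[i, names] = (pred[i] / denom).to_numpy()
    if has_fleet:
        fc.loc[FLEET, names] = (y / denom).to_numpy()

    return dc - fc


def total_impacts(direct: pd.DataFrame) -> pd.DataFrame:
    """Accumulate indirect effects: (I - q)^-1 - I.

    When the spectral radius of q is below 1 this equals the sum of the
    impact chains q + q^2 + q^3 + ...; the closed form remains defined
    (and is the conventional mixed-trophic-impact matrix) whenever
    I - q is invertible.  Raises :class:`ModelError` when it is not,
    which indicates a degenerate dependency structure worth inspecting.
    """
    q = direct.to_numpy()
    n = q.shape[0]
    A = np.eye(n) - q
    if np.linalg.cond(A) > 1e12:
        raise ModelError(
            "impact matrix is singular (a group's gains and losses are "
            "perfectly confounded); inspect the web"
        )
    total = np.linalg.inv(A) - np.eye(n)
    return pd.DataFrame(total, index=direct.index, columns=direct.columns)


def mixed_trophic_impacts(
    balanced: BalancedModel, include_fleet: bool = True
) -> ImpactMatrix:
    """Direct and total impact matrices for a balanced model."""
    direct = direct_impacts(balanced, include_fleet=include_fleet)
    return ImpactMatrix(direct=direct, total=total_impacts(direct))
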