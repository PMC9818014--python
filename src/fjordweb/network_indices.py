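"""Whole-system network indicators: flow sums, ratios, Finn's indices.

Total system throughput (TST) is the sum of four flow components —
consumption, respiration, flows to detritus and exports.  Finn's
cycling index is the percentage of TST that travels through cycles; it
is computed from the diagonal of the Leontief structure matrix of the
input-normalized flow network (Finn 1976 formulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecopath_balance import BalancedModel
from .model_io import CONSUMER, PRODUCER, ModelError
from .trophic_analysis import mean_tl_catch as _mean_tl_catch


@dataclass
class SystemIndicators:
    sum_consumption: float
    sum_respiration: float
    sum_flow_to_detritus: float
    sum_exports: float
    sum_production: float
    total_throughput: float
    total_biomass: float  # living groups only, t km^-2
    total_pp: float
    fci: float  # percent of TST recycled
    mean_path_length: float
    sp_ft: float  # production / throughput
    pp_bt: float  # primary production / biomass
    pp_rt: float  # primary production / respiration
    mean_tl_catch: float | None

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def _flow_matrix(balanced: BalancedModel) -> tuple[pd.DataFrame, pd.Series]:
    """Between-compartment flows and total compartment inflows.

    Flows are prey -> predator plus each group's flow to the detritus
    pool.  Inflows additionally count external inputs (primary
    production and diet imports), which close the throughflow balance.
    """
    m = balanced.model
    names = m.names
    F = pd.DataFrame(0.0, index=names, columns=names)
    for j in m.consumers:
        F[j] = balanced.predation[j].reindex(names).fillna(0.0)
    for d in m.detritus_groups:
        F[d] = F[d].add(balanced.flow_to_detritus, fill_value=0.0)

    external = pd.Series(0.0, index=names)
    for g in m.groups:
        if g.role == PRODUCER:
            external[g.name] = balanced.production[g.name]
        elif g.role == CONSUMER:
            external[g.name] = (
                float(m.diet_import[g.name]) * balanced.consumption[g.name]
            )
    inflow = F.sum(axis=0) + external
    return F, inflow


def finn_cycling_index(balanced: BalancedModel) -> tuple[float, float]:
    """Finn's cycling index (percent) and Finn's mean path length.

    The transfer matrix G has G[i, j] = flow(i -> j) / inflow(j); the
    structure matrix S = (I - G)^-1 gives the expected number of visits
    to each compartment, and the recycled throughput is
    sum_j (S_jj - 1)/S_jj * inflow_j.
    """
    F, inflow = _flow_matrix(balanced)
    names = list(F.index)
    n = len(names)
    T = inflow.to_numpy()
    G = F.to_numpy() / np.where(T > 0, T, np.inf)[None, :]
    try:
        S = np.linalg.inv(np.eye(n) - G)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"flow network has a lossless cycle: {exc}") from exc
    diag = np.diag(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        cyc = np.where(diag > 0, (diag - 1.0) / diag, 0.0)
    t_cyc = float((cyc * T).sum())

    ind = _flow_sums(balanced)
    tst = ind["total_throughput"]
    fci = 100.0 * t_cyc / tst if tst > 0 else 0.0

    m = balanced.model
    imports = sum(
        float(m.diet_import[c]) * balanced.consumption[c] for c in m.consumers
    )
    denom = ind["total_pp"] + imports
    mpl = tst / denom if denom > 0 else np.nan
    return fci, mpl


def _flow_sums(balanced: BalancedModel) -> dict[str, float]:
    m = balanced.model
    cons = sum(balanced.consumption[c] for c in m.consumers)
    resp = float(balanced.respiration.sum())
    fd = float(balanced.flow_to_detritus.sum())
    exports = float(balanced.exports.sum())
    prod = sum(balanced.production[g] for g in m.living)
    pp = sum(balanced.production[g] for g in m.producers)
    bt = sum(balanced.biomass[g] for g in m.living)
    return {
        "sum_consumption": float(cons),
        "sum_respiration": resp,
        "sum_flow_to_detritus": fd,
        "sum_exports": exports,
        "sum_production": float(prod),
        "total_throughput": float(cons + resp + fd + exports),
        "total_biomass": float(bt),
        "total_pp": float(pp),
    }


def system_indicators(balanced: BalancedModel) -> SystemIndicators:
    """All whole-system indicators for a balanced model."""
    s = _flow_sums(balanced)
    fci, mpl = finn_cycling_index(balanced)
    y = balanced.model.param_series("landings").fillna(0.0)
    mtlc = _mean_tl_catch(balanced) if float(y.sum()) > 0 else None
    return SystemIndicators(
        **s,
        fci=fci,
        mean_path_length=mpl,
        sp_ft=s["sum_production"] / s["total_throughput"],
        pp_bt=s["total_pp"] / s["total_biomass"],
        pp_rt=s["total_pp"] / s["sum_respiration"] if s["sum_respiration"] > 0 else np.inf,
        mean_tl_catch=mtlc,
    )
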