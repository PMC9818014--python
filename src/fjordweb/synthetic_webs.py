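"""Random exactly-balanced food webs for testing the pipeline.

Webs are built on a cascade topology: groups are ordered, producers
first, and every consumer feeds only on strictly lower-ranked groups
(plus, optionally, itself and a detritus pool).  Rates are drawn from
user ranges and biomasses are then assigned from the top of the web
downwards so that each preyed-upon group's ecotrophic efficiency lands
in a target interval — by construction the resulting model satisfies
the mass balance exactly, which makes it a ground truth for solver
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import (
    CONSUMER,
    DETRITUS,
    PRODUCER,
    FoodWebModel,
    FunctionalGroup,
    ModelError,
)


@dataclass
class GeneratorSpec:
    n_groups: int = 8  # living groups (detritus pool extra)
    n_producers: int = 2
    detritus: bool = True
    connectance: float = 0.35  # probability of each feasible link
    cannibalism: float = 0.0  # probability a consumer eats itself
    detritivory: float = 0.4  # probability a low consumer eats detritus
    pb_range: tuple[float, float] = (0.5, 5.0)
    qb_range: tuple[float, float] = (3.0, 30.0)
    target_ee_range: tuple[float, float] = (0.3, 0.95)
    top_biomass_range: tuple[float, float] = (0.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_producers < 1 or self.n_producers >= self.n_groups:
            raise ModelError("need at least one producer and one consumer")
        if not 0 < self.connectance <= 1:
            raise ModelError("connectance must be in (0, 1]")


@dataclass
class SyntheticWeb:
    full: FoodWebModel  # every B and EE specified
    masked: FoodWebModel  # a recoverable subset of biomasses hidden
    true_biomass: pd.Series
    hidden: list[str]


def generate(spec: GeneratorSpec) -> SyntheticWeb:
    """Sample a balanced web; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_groups
    names = [f"g{i + 1:02d}" for i in range(n)]
    roles = [PRODUCER] * spec.n_producers + [CONSUMER] * (n - spec.n_producers)
    det_name = "detritus"
    all_names = names + ([det_name] if spec.detritus else [])

    pb_draws = rng.uniform(*spec.pb_range, size=n)
    qb_draws = rng.uniform(*spec.qb_range, size=n)
    # Keep respiration positive: assimilated consumption must exceed
    # production.
    for i in range(spec.n_producers, n):
        qb_draws[i] = max(qb_draws[i], 1.3 * pb_draws[i] / 0.8)

    consumers = [names[i] for i in range(spec.n_producers, n)]
    diet = pd.DataFrame(0.0, index=all_names, columns=consumers)
    for ci, j in enumerate(consumers, start=spec.n_producers):
        candidates = names[:ci]
        chosen = [p for p in candidates if rng.random() < spec.connectance]
        if not chosen:
            chosen = [candidates[rng.integers(len(candidates))]]
        if spec.detritus and ci - spec.n_producers < 2 and rng.random() < spec.detritivory:
            chosen.append(det_name)
        if spec.cannibalism > 0 and rng.random() < spec.cannibalism:
            chosen.append(j)
        fracs = rng.dirichlet(np.ones(len(chosen)))
        for p, f in zip(chosen, fracs):
            diet.loc[p, j] += float(f)
        # Keep cannibalism mild so self-consumption can never outrun the
        # group's own production (q/b * DC_self must stay below p/b * EE).
        cap = 0.2 * pb_draws[ci] / qb_draws[ci]
        self_frac = float(diet.loc[j, j])
        if self_frac > cap:
            others = diet.loc[diet.index != j, j]
            diet.loc[j, j] = cap
            diet.loc[diet.index != j, j] = others * (1 - cap) / others.sum()

    pb, qb = pb_draws, qb_draws

    # Top-down biomass assignment: predators of group i all have higher
    # rank, so their consumption is known once we walk from the top.
    biomass = np.zeros(n)
    ee = np.zeros(n)
    externally_preyed = np.zeros(n, dtype=bool)
    for i in range(n - 1, -1, -1):
        name = names[i]
        demand = 0.0
        for cj, j in enumerate(consumers, start=spec.n_producers):
            dc = float(diet.loc[name, j])
            if dc > 0 and cj != i:
                demand += biomass[cj] * qb[cj] * dc
        self_dc = float(diet.loc[name, name]) if name in diet.columns else 0.0
        externally_preyed[i] = demand > 0
        if demand > 0:
            ee[i] = rng.uniform(*spec.target_ee_range)
            denom = pb[i] * ee[i] - qb[i] * self_dc
            if denom <= 0:
                raise ModelError(
                    f"infeasible spec: cannibalism of {name} exceeds its production"
                )
            biomass[i] = demand / denom
        else:
            ee[i] = 0.0
            biomass[i] = rng.uniform(*spec.top_biomass_range)
            if self_dc > 0:
                # pure self-feeding with no external demand: EE follows.
                ee[i] = qb[i] * self_dc / pb[i]

    groups = [
        FunctionalGroup(
            name=names[i],
            role=roles[i],
            biomass=float(biomass[i]),
            pb=float(pb[i]),
            qb=float(qb[i]) if roles[i] == CONSUMER else None,
            ee=float(ee[i]),
        )
        for i in range(n)
    ]
    if spec.detritus:
        groups.append(FunctionalGroup(name=det_name, role=DETRITUS))

    full = FoodWebModel(groups=groups, diet=diet)

    # Mask biomasses that the solver can recover: groups with external
    # predation demand have a non-degenerate balance row (a purely
    # cannibalistic EE makes the row singular and stays unmasked).
    maskable = [names[i] for i in range(n) if externally_preyed[i] and ee[i] > 0.05]
    hidden = [g for g in maskable if rng.random() < 0.5]
    if maskable and not hidden:
        hidden = [maskable[0]]
    masked = full.copy()
    for g in masked.groups:
        if g.name in hidden:
            g.biomass = None

    return SyntheticWeb(
        full=full,
        masked=masked,
        true_biomass=pd.Series(biomass, index=names),
        hidden=hidden,
    )


def perturb(model: FoodWebModel, noise: float, seed: int = 0) -> FoodWebModel:
    """Multiplicative lognormal noise on P/B and Q/B rates.

    Produces near-balanced models for validator and error-path tests;
    ``noise`` is the relative standard deviation (0 returns an identical
    copy).
    """
    out = model.copy()
    if noise == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise**2))
    for g in out.groups:
        if g.pb is not None:
            g.pb = float(g.pb * rng.lognormal(-sigma**2 / 2, sigma))
        if g.qb is not None:
            g.qb = float(g.qb * rng.lognormal(-sigma**2 / 2, sigma))
    return out
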