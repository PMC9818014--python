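"""Food-web model data structures and tabular I/O.

A model is stored as two delimiter-separated tables:

``groups``
    One row per functional group with columns ``name, role, biomass, pb,
    qb, ee, landings`` (and optionally ``unassimilated`` and
    ``biomass_accumulation``).  ``role`` is one of ``producer``,
    ``consumer`` or ``detritus``.  An empty biomass or EE cell marks the
    quantity as unknown, to be estimated by the mass-balance solver.

``diet``
    The predator-prey matrix: one row per prey (plus an optional
    ``Import`` row), one column per consumer.  Entries may be either
    diet fractions or absolute consumption rates (t km^-2 year^-1); in
    the latter case each consumer column is normalized by its own sum on
    read.  An optional ``flow_to_detritus`` column is kept aside for
    cross-checks and never normalized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

PRODUCER = "producer"
CONSUMER = "consumer"
DETRITUS = "detritus"
ROLES = (PRODUCER, CONSUMER, DETRITUS)

#: Default fraction of consumption that is not assimilated and is routed
#: to the detritus pool.  0.2 is the conventional value for consumers in
#: mass-balance trophic models.
DEFAULT_UNASSIMILATED = 0.2

IMPORT_ROW = "Import"
FLOW_TO_DETRITUS_COL = "flow_to_detritus"


class ModelError(ValueError):
    """Raised for structurally invalid food-web models."""


@dataclass
class FunctionalGroup:
    """One compartment of the food web (a species or species aggregate).

    Rates are annual and biomass is areal (t km^-2).  ``biomass`` or
    ``ee`` may be ``None`` (unknown, estimated by the balance solver);
    at most one of the two may be unknown for a living group.
    """

    name: str
    role: str = CONSUMER
    biomass: float | None = None
    pb: float | None = None  # production/biomass, year^-1
    qb: float | None = None  # consumption/biomass, year^-1
    ee: float | None = None  # ecotrophic efficiency, in [0, 1]
    landings: float = 0.0  # fishery yield, t km^-2 year^-1
    unassimilated: float | None = None  # fraction of Q egested
    biomass_accumulation: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelError(f"{self.name}: unknown role {self.role!r}")
        if self.unassimilated is None:
            self.unassimilated = (
                DEFAULT_UNASSIMILATED if self.role == CONSUMER else 0.0
            )

    @property
    def is_living(self) -> bool:
        return self.role != DETRITUS


@dataclass
class ModelDialect:
    """Serialization conventions for the two model tables."""

    delimiter: str = "\t"
    decimal: str = "."
    na_tokens: tuple[str, ...] = ("", "-", "NA")
    groups_file: str = "groups.tsv"
    diet_file: str = "diet.tsv"
    #: 'fraction', 'consumption', or 'auto' (consumption assumed when any
    #: consumer column sums to more than 1.5).
    diet_units: str = "auto"


@dataclass
class Diagnostic:
    level: str  # 'error' | 'warning'
    group: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.group}: {self.message}"


@dataclass
class FoodWebModel:
    """A parameterized food web: groups plus a normalized diet matrix.

    ``diet`` is prey-by-predator with dimensionless fractions; consumer
    columns sum to at most 1 (any shortfall is diet import, recorded in
    ``diet_import``).  Producer and detritus columns are absent or zero.
    """

    groups: list[FunctionalGroup]
    diet: pd.DataFrame
    diet_import: pd.Series | None = None
    #: Per-group flow-to-detritus column as printed in the source tables,
    #: when one was provided.  Used only for cross-checks.
    flow_to_detritus_reference: pd.Series | None = None
    #: Raw (pre-normalization) consumer column sums, when the diet matrix
    #: was supplied in consumption units.  Used only for cross-checks.
    consumption_column_sums: pd.Series | None = None

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ModelError("duplicate group names")
        self.diet = self.diet.reindex(
            index=names, columns=self.consumers
        ).fillna(0.0)
        if self.diet_import is None:
            self.diet_import = pd.Series(0.0, index=self.consumers)

    # -- views ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def consumers(self) -> list[str]:
        return [g.name for g in self.groups if g.role == CONSUMER]

    @property
    def producers(self) -> list[str]:
        return [g.name for g in self.groups if g.role == PRODUCER]

    @property
    def living(self) -> list[str]:
        return [g.name for g in self.groups if g.is_living]

    @property
    def detritus_groups(self) -> list[str]:
        return [g.name for g in self.groups if g.role == DETRITUS]

    def group(self, name: str) -> FunctionalGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def param_series(self, attr: str) -> pd.Series:
        """Per-group parameter vector (NaN where absent/unknown)."""
        vals = [getattr(g, attr) for g in self.groups]
        return pd.Series(
            [np.nan if v is None else float(v) for v in vals],
            index=self.names, name=attr,
        )

    def copy(self) -> "FoodWebModel":
        return FoodWebModel(
            groups=[dataclasses.replace(g) for g in self.groups],
            diet=self.diet.copy(),
            diet_import=None if self.diet_import is None else self.diet_import.copy(),
            flow_to_detritus_reference=(
                None
                if self.flow_to_detritus_reference is None
                else self.flow_to_detritus_reference.copy()
            ),
            consumption_column_sums=(
                None
                if self.consumption_column_sums is None
                else self.consumption_column_sums.copy()
            ),
        )


def normalize_diet(
    consumption: pd.DataFrame,
    consumers: Iterable[str] | None = None,
    import_row: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Convert a consumption matrix (t km^-2 year^-1) to diet fractions.

    Each consumer column is divided by its own total (including any
    import consumption).  Returns ``(fractions, import_fraction)``.

    Raises :class:`ModelError` for negative entries or a consumer column
    with zero total.
    """
    cols = list(consumers) if consumers is not None else list(consumption.columns)
    mat = consumption.loc[:, cols].astype(float).fillna(0.0)
    if (mat.to_numpy() < 0).any():
        raise ModelError("negative entries in consumption matrix")
    imp = (
        import_row.reindex(cols).fillna(0.0).astype(float)
        if import_row is not None
        else pd.Series(0.0, index=cols)
    )
    totals = mat.sum(axis=0) + imp
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ModelError(f"zero diet column sum for consumer(s): {zero}")
    return mat.div(totals, axis=1), imp / totals


def validate(
    model: FoodWebModel,
    consumption_rtol: float = 0.01,
    biomass: "pd.Series | None" = None,
) -> list[Diagnostic]:
    """Check model invariants; return diagnostics (never raises).

    Errors flag invariant violations (negative rates, EE outside [0, 1],
    both biomass and EE unknown, bad diet columns).  Warnings flag
    internal inconsistencies of the inputs, notably when the raw diet
    matrix implied a total consumption differing from biomass * Q/B by
    more than ``consumption_rtol``.  Pass solved biomasses via
    ``biomass`` to extend that cross-check to groups whose biomass was
    estimated by the balance.
    """
    out: list[Diagnostic] = []

    def err(g: str, msg: str) -> None:
        out.append(Diagnostic("error", g, msg))

    def warn(g: str, msg: str) -> None:
        out.append(Diagnostic("warning", g, msg))

    for g in model.groups:
        for attr in ("biomass", "pb", "qb", "ee", "landings"):
            v = getattr(g, attr)
            if v is not None and v < 0:
                err(g.name, f"negative {attr} ({v})")
        if g.ee is not None and g.ee > 1:
            err(g.name, f"EE above 1 ({g.ee})")
        if not 0 <= (g.unassimilated or 0.0) < 1:
            err(g.name, f"unassimilated fraction outside [0, 1)")
        if g.role == CONSUMER:
            if g.biomass is None and g.ee is None:
                err(g.name, "both biomass and EE unknown")
            if g.pb is None or g.qb is None:
                err(g.name, "consumer missing P/B or Q/B")
        elif g.role == PRODUCER:
            if g.qb not in (None,):
                err(g.name, "producer must not have Q/B")
            if g.biomass is None and g.ee is None:
                err(g.name, "both biomass and EE unknown")
        else:  # detritus
            if any(x is not None for x in (g.pb, g.qb, g.ee)):
                err(g.name, "detritus must not carry P/B, Q/B or EE")

    arr = model.diet.to_numpy()
    if (arr < 0).any() or (arr > 1 + 1e-9).any():
        err("<diet>", "diet fractions outside [0, 1]")
    colsum = model.diet.sum(axis=0) + model.diet_import
    for c in model.consumers:
        if not np.isclose(colsum[c], 1.0, atol=1e-6):
            err(c, f"diet column (incl. import) sums to {colsum[c]:.6f}, not 1")

    unknown = set(model.diet.index) - set(model.names)
    if unknown:
        err("<diet>", f"diet matrix references unknown groups: {sorted(unknown)}")

    if model.consumption_column_sums is not None:
        for c in model.consumers:
            g = model.group(c)
            b_val = g.biomass
            if b_val is None and biomass is not None and np.isfinite(biomass.get(c, np.nan)):
                b_val = float(biomass[c])
            if b_val is None or g.qb is None:
                continue
            implied = b_val * g.qb
            raw = model.consumption_column_sums.get(c, np.nan)
            if np.isfinite(raw) and implied > 0:
                rel = abs(raw - implied) / implied
                if rel > consumption_rtol:
                    warn(
                        c,
                        f"diet-matrix consumption {raw:.3f} disagrees with "
                        f"B*(Q/B) = {implied:.3f} by {100 * rel:.1f}%",
                    )
    return out


def _read_table(path: Path, dialect: ModelDialect) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        na_values=list(dialect.na_tokens),
        keep_default_na=False,
        index_col=0,
        float_precision="round_trip",
    )


def _groups_from_frame(df: pd.DataFrame) -> list[FunctionalGroup]:
    def opt(row: pd.Series, key: str) -> float | None:
        v = row.get(key, np.nan)
        return None if pd.isna(v) else float(v)

    groups = []
    for name, row in df.iterrows():
        groups.append(
            FunctionalGroup(
                name=str(name),
                role=str(row["role"]),
                biomass=opt(row, "biomass"),
                pb=opt(row, "pb"),
                qb=opt(row, "qb"),
                ee=opt(row, "ee"),
                landings=opt(row, "landings") or 0.0,
                unassimilated=opt(row, "unassimilated"),
                biomass_accumulation=opt(row, "biomass_accumulation") or 0.0,
            )
        )
    return groups


def read_model(path: str | Path, dialect: ModelDialect | None = None) -> FoodWebModel:
    """Read and validate a model from a directory of two tables.

    Raises :class:`ModelError` on structural errors; warnings from
    :func:`validate` are attached to the returned model as
    ``model.diagnostics``.
    """
    dialect = dialect or ModelDialect()
    path = Path(path)
    groups = _groups_from_frame(_read_table(path / dialect.groups_file, dialect))
    raw = _read_table(path / dialect.diet_file, dialect).astype(float)

    ftd = None
    if FLOW_TO_DETRITUS_COL in raw.columns:
        ftd = raw[FLOW_TO_DETRITUS_COL].drop(IMPORT_ROW, errors="ignore").fillna(0.0)
        raw = raw.drop(columns=[FLOW_TO_DETRITUS_COL])
    imp = None
    if IMPORT_ROW in raw.index:
        imp = raw.loc[IMPORT_ROW].fillna(0.0)
        raw = raw.drop(index=IMPORT_ROW)

    names = [g.name for g in groups]
    consumers = [g.name for g in groups if g.role == CONSUMER]
    unknown_rows = set(raw.index) - set(names)
    if unknown_rows:
        raise ModelError(f"diet matrix references unknown groups: {sorted(unknown_rows)}")
    unknown_cols = set(raw.columns) - set(names)
    if unknown_cols:
        raise ModelError(f"diet matrix has non-group predator columns: {sorted(unknown_cols)}")
    non_consumer = set(raw.columns) - set(consumers)
    if non_consumer:
        raise ModelError(f"diet columns for non-consumers: {sorted(non_consumer)}")

    mat = raw.reindex(index=names, columns=consumers).fillna(0.0)
    raw_sums = None
    colsum = mat.sum(axis=0) + (imp.reindex(consumers).fillna(0.0) if imp is not None else 0.0)
    units = dialect.diet_units
    if units == "auto":
        units = "consumption" if (colsum > 1.5).any() else "fraction"
    if units == "consumption":
        raw_sums = colsum.copy()
        diet, imp_frac = normalize_diet(mat, consumers, imp)
    else:
        diet = mat
        imp_frac = imp.reindex(consumers).fillna(0.0) if imp is not None else None

    model = FoodWebModel(
        groups=groups,
        diet=diet,
        diet_import=imp_frac,
        flow_to_detritus_reference=ftd,
        consumption_column_sums=raw_sums,
    )
    diags = validate(model)
    errors = [d for d in diags if d.level == "error"]
    if errors:
        raise ModelError("; ".join(map(str, errors)))
    model.diagnostics = [d for d in diags if d.level == "warning"]  # type: ignore[attr-defined]
    return model


def write_model(model: FoodWebModel, path: str | Path, dialect: ModelDialect | None = None) -> None:
    """Write a model back to the two-table directory format.

    The diet matrix is written in fractions, so read(write(m)) preserves
    every field of ``m`` (the raw-consumption bookkeeping columns are a
    property of the source tables, not of the model).
    """
    dialect = dialect or ModelDialect()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in model.groups:
        rows.append(
            {
                "name": g.name,
                "role": g.role,
                "biomass": g.biomass,
                "pb": g.pb,
                "qb": g.qb,
                "ee": g.ee,
                "landings": g.landings,
                "unassimilated": g.unassimilated,
                "biomass_accumulation": g.biomass_accumulation,
            }
        )
    gdf = pd.DataFrame(rows).set_index("name")
    gdf.to_csv(path / dialect.groups_file, sep=dialect.delimiter, float_format="%.17g")

    diet = model.diet.copy()
    if model.diet_import is not None and len(diet.columns):
        diet.loc[IMPORT_ROW] = model.diet_import
    if model.flow_to_detritus_reference is not None:
        diet[FLOW_TO_DETRITUS_COL] = model.flow_to_detritus_reference
    diet.index.name = "prey"
    diet.to_csv(path / dialect.diet_file, sep=dialect.delimiter, float_format="%.17g")


def load_coloane() -> FoodWebModel:
    """The bundled 21-group Francisco Coloane (Magellan Strait) model."""
    root = resources.files("fjordweb").joinpath("data/coloane")
    with resources.as_file(root) as p:
        return read_model(p)
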