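"""End-to-end analysis: balance -> flows -> levels -> indices -> impacts
-> centrality -> scenarios, with serializable result tables."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .centrality import centrality_table
from .ecopath_balance import BalancedModel, solve_mass_balance
from .ecosim import ScenarioReport, SimulationConfig, run_scenarios, standard_scenarios
from .impact_analysis import mixed_trophic_impacts
from .model_io import FoodWebModel, read_model
from .network_indices import system_indicators
from .trophic_analysis import lindeman_decomposition, trophic_levels


class StageError(RuntimeError):
    """An analysis stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class AnalysisReport:
    balanced: BalancedModel
    indicators: pd.Series
    group_table: pd.DataFrame  # TL + centrality per living group
    lindeman: pd.DataFrame
    mti_direct: pd.DataFrame
    mti_total: pd.DataFrame
    scenarios: ScenarioReport | None
    manifest: dict = field(default_factory=dict)


def run_all(
    model: FoodWebModel | str | Path,
    simulate_scenarios: bool = True,
    config: SimulationConfig | None = None,
) -> AnalysisReport:
    """Run the full pipeline on a model or model directory."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-tagged for the caller
            raise StageError(name, exc) from exc

    if not isinstance(model, FoodWebModel):
        model = stage("read", read_model, model)
    balanced = stage("balance", solve_mass_balance, model)
    tl = stage("trophic_levels", trophic_levels, balanced)
    lind = stage("lindeman", lindeman_decomposition, balanced)
    ind = stage("indicators", system_indicators, balanced)
    mti = stage("mti", mixed_trophic_impacts, balanced)
    cent = stage("centrality", centrality_table, balanced)

    group_table = cent.copy()
    group_table.insert(0, "trophic_level", tl.reindex(group_table.index))
    group_table.insert(1, "biomass", balanced.biomass.reindex(group_table.index))
    group_table.insert(2, "ee", balanced.ee.reindex(group_table.index))

    scen = None
    has_focal = {"Squat lobster", "Fuegian sprat"} <= set(model.names)
    if simulate_scenarios and has_focal:
        scen = stage(
            "scenarios", run_scenarios, balanced, standard_scenarios(balanced), config
        )

    return AnalysisReport(
        balanced=balanced,
        indicators=ind.as_series(),
        group_table=group_table,
        lindeman=lind.level_fractions,
        mti_direct=mti.direct,
        mti_total=mti.total,
        scenarios=scen,
        manifest={"fjordweb": __version__, "n_groups": len(model.groups)},
    )


def write_report(report: AnalysisReport, outdir: str | Path, decimals: int = 1) -> None:
    """Write the report tables; full precision in the machine-readable
    files, ``decimals`` places in the human summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.indicators.to_csv(out / "indicators.tsv", sep="\t", header=["value"])
    report.group_table.to_csv(out / "groups.tsv", sep="\t")
    report.lindeman.to_csv(out / "lindeman.tsv", sep="\t")
    report.mti_direct.to_csv(out / "mti_direct.tsv", sep="\t")
    report.mti_total.to_csv(out / "mti_total.tsv", sep="\t")
    if report.scenarios is not None:
        report.scenarios.summary.to_csv(out / "scenarios.tsv", sep="\t")
    summary = {
        "manifest": report.manifest,
        "indicators": {
            k: (round(v, decimals) if isinstance(v, float) else v)
            for k, v in report.indicators.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
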