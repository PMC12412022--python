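"""Case configurations, built-in worked cases, and the run orchestrator.

A :class:`CaseConfig` captures everything needed to reproduce a simulation:
column (plate count, dead time or dead volume, phase ratio), flow rate,
solutes (partition coefficient given directly or via the two phase
solubilities), an optional time grid, and the band-shape model.  Configs
round-trip losslessly through JSON or YAML.

Three classroom cases ship as presets: a single solute whose K = 3 follows
from its 0.6/0.2 g/L solubilities (case1), the same column with a second
K = 1.8 solute (case2), and a five-solute mixture with K = 1, 3, 5, 7, 9
(case3) whose peak times fall on the line tR = 3 + 1.5*K.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .chromatogram_sim import MODELS, default_grid, simulate_mixture
from .peak_regression import find_peak, fit_retention_vs_K
from .plate_model import (
    ColumnSpec,
    FlowSpec,
    SeparationMethod,
    Solute,
    TimeGrid,
    dead_time,
    k_from_solubilities,
)

__all__ = ["CaseConfig", "SoluteConfig", "preset", "PRESET_NAMES", "run_case"]

logger = logging.getLogger("platesim")

PRESET_NAMES = ("case1", "case2", "case3")


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"{field_name}: {message}")


@dataclass(frozen=True)
class SoluteConfig:
    """One solute entry: exactly one of K / the two solubilities."""

    name: str
    C0: float
    K: Optional[float] = None
    solubility_stationary_g_per_L: Optional[float] = None
    solubility_mobile_g_per_L: Optional[float] = None

    def __post_init__(self) -> None:
        _require(bool(self.name), "solutes[].name", "must be a non-empty label")
        _require(self.C0 > 0, f"solutes[{self.name}].C0", "must be > 0")
        has_k = self.K is not None
        has_sol = (
            self.solubility_stationary_g_per_L is not None
            or self.solubility_mobile_g_per_L is not None
        )
        _require(
            has_k != has_sol,
            f"solutes[{self.name}]",
            "give exactly one of K / solubilities",
        )
        if has_sol:
            _require(
                self.solubility_stationary_g_per_L is not None
                and self.solubility_mobile_g_per_L is not None,
                f"solutes[{self.name}].solubilities",
                "both stationary and mobile solubilities are required",
            )

    def resolve(self) -> Solute:
        """Resolve into a model solute, deriving K from solubilities if given."""
        if self.K is not None:
            return Solute(name=self.name, K=self.K, C0=self.C0)
        sol = Solute.from_solubilities(
            self.name,
            self.solubility_stationary_g_per_L,
            self.solubility_mobile_g_per_L,
            self.C0,
        )
        logger.info(
            "solute %s: K = %g/%g = %g (stationary/mobile solubility ratio)",
            self.name,
            self.solubility_stationary_g_per_L,
            self.solubility_mobile_g_per_L,
            sol.K,
        )
        return sol

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "C0": self.C0}
        if self.K is not None:
            d["K"] = self.K
        else:
            d["solubilities"] = {
                "stationary_g_per_L": self.solubility_stationary_g_per_L,
                "mobile_g_per_L": self.solubility_mobile_g_per_L,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SoluteConfig":
        _require(isinstance(d, dict), "solutes[]", "each solute must be a mapping")
        known = {"name", "C0", "K", "solubilities"}
        for key in d:
            _require(key in known, f"solutes[].{key}", "unknown field")
        sol = d.get("solubilities")
        kwargs = dict(name=d.get("name", ""), C0=d.get("C0", 0.0), K=d.get("K"))
        if sol is not None:
            _require(
                isinstance(sol, dict)
                and set(sol) == {"stationary_g_per_L", "mobile_g_per_L"},
                f"solutes[{d.get('name')}].solubilities",
                "must be a mapping with stationary_g_per_L and mobile_g_per_L",
            )
            kwargs["solubility_stationary_g_per_L"] = sol["stationary_g_per_L"]
            kwargs["solubility_mobile_g_per_L"] = sol["mobile_g_per_L"]
        return cls(**kwargs)


@dataclass(frozen=True)
class CaseConfig:
    """Full description of one simulation case."""

    name: str
    n_plates: int
    phase_ratio: float
    flow_mL_per_min: float
    solutes: Tuple[SoluteConfig, ...]
    dead_time_min: Optional[float] = None
    dead_volume_mL: Optional[float] = None
    grid: Optional[TimeGrid] = None
    model: str = "stirling"

    def __post_init__(self) -> None:
        _require(bool(self.name), "name", "must be a non-empty label")
        _require(
            isinstance(self.n_plates, int) and self.n_plates >= 1,
            "column.n_plates",
            "must be an integer >= 1",
        )
        _require(
            isinstance(self.phase_ratio, (int, float)) and self.phase_ratio > 0,
            "column.phase_ratio",
            "must be > 0",
        )
        _require(
            isinstance(self.flow_mL_per_min, (int, float))
            and self.flow_mL_per_min > 0,
            "flow.flow_mL_per_min",
            "must be > 0",
        )
        _require(
            (self.dead_time_min is None) != (self.dead_volume_mL is None),
            "column",
            "give exactly one of dead_time_min / dead_volume_mL",
        )
        _require(self.model in MODELS, "model", f"must be one of {MODELS}")
        _require(len(self.solutes) >= 1, "solutes", "need at least one solute")
        names = [s.name for s in self.solutes]
        _require(
            len(set(names)) == len(names), "solutes", f"duplicate names in {names}"
        )

    # -- resolution into model objects ------------------------------------

    def method(self) -> SeparationMethod:
        flow = FlowSpec(flow_mL_per_min=self.flow_mL_per_min)
        if self.dead_time_min is not None:
            tm = self.dead_time_min
        else:
            tm = dead_time(self.dead_volume_mL, flow)
            logger.info(
                "case %s: tm = %g mL / %g mL/min = %g min",
                self.name,
                self.dead_volume_mL,
                self.flow_mL_per_min,
                tm,
            )
        column = ColumnSpec(
            n_plates=self.n_plates, dead_time_min=tm, phase_ratio=self.phase_ratio
        )
        return SeparationMethod(column=column, flow=flow)

    def resolved_solutes(self) -> List[Solute]:
        return [s.resolve() for s in self.solutes]

    def resolved_grid(self, method: SeparationMethod) -> TimeGrid:
        if self.grid is not None:
            return self.grid
        return default_grid(method, self.resolved_solutes())

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        column: dict = {"n_plates": self.n_plates, "phase_ratio": self.phase_ratio}
        if self.dead_time_min is not None:
            column["dead_time_min"] = self.dead_time_min
        else:
            column["dead_volume_mL"] = self.dead_volume_mL
        d: dict = {
            "name": self.name,
            "column": column,
            "flow": {"flow_mL_per_min": self.flow_mL_per_min},
            "solutes": [s.to_dict() for s in self.solutes],
            "model": self.model,
        }
        if self.grid is not None:
            d["grid"] = {
                "t_start_min": self.grid.t_start_min,
                "t_stop_min": self.grid.t_stop_min,
                "n_points": self.grid.n_points,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        _require(isinstance(d, dict), "config", "must be a mapping")
        known = {"name", "column", "flow", "solutes", "grid", "model"}
        for key in d:
            _require(key in known, key, "unknown field")
        column = d.get("column")
        _require(isinstance(column, dict), "column", "must be a mapping")
        for key in column:
            _require(
                key in {"n_plates", "phase_ratio", "dead_time_min", "dead_volume_mL"},
                f"column.{key}",
                "unknown field",
            )
        flow = d.get("flow")
        _require(
            isinstance(flow, dict) and set(flow) == {"flow_mL_per_min"},
            "flow",
            "must be a mapping with flow_mL_per_min",
        )
        solutes = d.get("solutes")
        _require(isinstance(solutes, list), "solutes", "must be a list")
        grid_d = d.get("grid")
        grid = None
        if grid_d is not None:
            _require(
                isinstance(grid_d, dict)
                and set(grid_d) == {"t_start_min", "t_stop_min", "n_points"},
                "grid",
                "must be a mapping with t_start_min, t_stop_min, n_points",
            )
            grid = TimeGrid(**grid_d)
        return cls(
            name=d.get("name", ""),
            n_plates=column.get("n_plates"),
            phase_ratio=column.get("phase_ratio"),
            dead_time_min=column.get("dead_time_min"),
            dead_volume_mL=column.get("dead_volume_mL"),
            flow_mL_per_min=flow["flow_mL_per_min"],
            solutes=tuple(SoluteConfig.from_dict(s) for s in solutes),
            grid=grid,
            model=d.get("model", "stirling"),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "CaseConfig":
        """Load a config from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# built-in cases
# ---------------------------------------------------------------------------

_CASE1_COLUMN = dict(
    n_plates=100, dead_volume_mL=3.0, phase_ratio=2.0, flow_mL_per_min=1.0
)

_SOLUTE_A = SoluteConfig(
    name="A",
    C0=1.0,
    solubility_stationary_g_per_L=0.6,
    solubility_mobile_g_per_L=0.2,
)


def preset(name: str) -> CaseConfig:
    """One of the three built-in worked cases.

    * ``case1`` — single solute A on a C18 column (n=100, Vm=3 mL, beta=2,
      F=1 mL/min); K = 3 derived from 0.6/0.2 g/L phase solubilities.
    * ``case2`` — case1 plus solute B with K = 1.8: can A and B be separated?
    * ``case3`` — five solutes, K = 1, 3, 5, 7, 9, used to discover the
      linear retention-time law tR = tm + (tm/beta)*K.
    """
    if name == "case1":
        return CaseConfig(name="case1", solutes=(_SOLUTE_A,), **_CASE1_COLUMN)
    if name == "case2":
        return CaseConfig(
            name="case2",
            solutes=(_SOLUTE_A, SoluteConfig(name="B", C0=1.0, K=1.8)),
            **_CASE1_COLUMN,
        )
    if name == "case3":
        solutes = tuple(
            SoluteConfig(name=label, C0=1.0, K=float(k))
            for label, k in zip("ABCDE", (1, 3, 5, 7, 9))
        )
        return CaseConfig(name="case3", solutes=solutes, **_CASE1_COLUMN)
    raise ValueError(f"unknown preset {name!r}; available presets: {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_case(config: CaseConfig, out_dir, plot: bool = False) -> Dict[str, Path]:
    """Simulate a case and write its artifacts.

    Writes ``<case>_chromatogram.csv`` and ``<case>_peaks.csv`` always, a
    regression JSON when at least three solutes with distinct K are present,
    and optionally a PNG plot.  Fully deterministic: rerunning a config
    produces byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    method = config.method()
    solutes = config.resolved_solutes()
    grid = config.resolved_grid(method)
    logger.info(
        "case %s: n=%d, tm=%g min, beta=%g, F=%g mL/min, model=%s, "
        "grid [%g, %g] min x %d",
        config.name,
        method.column.n_plates,
        method.column.dead_time_min,
        method.column.phase_ratio,
        method.flow.flow_mL_per_min,
        config.model,
        grid.t_start_min,
        grid.t_stop_min,
        grid.n_points,
    )

    chrom = simulate_mixture(grid, method, solutes, model=config.model)
    written: Dict[str, Path] = {}

    chrom_path = out_dir / f"{config.name}_chromatogram.csv"
    chrom.to_csv(chrom_path)
    written["chromatogram"] = chrom_path

    peaks = [
        find_peak(chrom.traces[s.name], grid, solute_name=s.name) for s in solutes
    ]
    peaks_path = out_dir / f"{config.name}_peaks.csv"
    with open(peaks_path, "w") as fh:
        fh.write("solute,t_peak_min,height,area\n")
        for p in peaks:
            fh.write(
                f"{p.solute_name},{p.t_peak_min:.6f},"
                f"{p.height_mg_per_L:.6g},{p.area:.6g}\n"
            )
    written["peaks"] = peaks_path
    for p in peaks:
        logger.info(
            "peak %s: t = %.4f min, height = %.4g mg/L", p.solute_name,
            p.t_peak_min, p.height_mg_per_L,
        )

    ks = [s.K for s in solutes]
    if len(set(ks)) >= 3:
        fit = fit_retention_vs_K(
            [(s.K, p.t_peak_min) for s, p in zip(solutes, peaks)]
        )
        fit_path = out_dir / f"{config.name}_regression.json"
        fit_path.write_text(
            json.dumps(
                {"slope": fit.slope, "intercept": fit.intercept, "r": fit.r},
                indent=2,
            )
            + "\n"
        )
        written["regression"] = fit_path
        logger.info(
            "regression tR vs K: slope = %.6g min, intercept = %.6g min, r = %.8f",
            fit.slope, fit.intercept, fit.r,
        )
    else:
        logger.info(
            "case %s: fewer than 3 distinct K values — regression skipped",
            config.name,
        )

    if plot:
        plot_path = out_dir / f"{config.name}_chromatogram.png"
        chrom.plot(plot_path, title=f"{config.name} simulated chromatogram")
        written["plot"] = plot_path

    return written
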