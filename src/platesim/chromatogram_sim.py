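"""Elution-profile simulation: single solutes, mixtures, the Gaussian limit.

Composes the plate-model band shape with the time transformation
``v(t) = t*n/((1+K/beta)*tm)`` to produce concentration traces C(t) on a
uniform time grid, and bundles per-solute traces into a :class:`Chromatogram`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_model import (
    SeparationMethod,
    Solute,
    TimeGrid,
    concentration_exact,
    concentration_stirling,
    reduced_volume,
)

__all__ = [
    "MODELS",
    "Chromatogram",
    "elution_profile",
    "simulate_mixture",
    "gaussian_limit_profile",
    "profile_area",
    "default_grid",
]

MODELS = ("exact", "stirling")

_CONCENTRATION = {
    "exact": concentration_exact,
    "stirling": concentration_stirling,
}


@dataclass(frozen=True)
class Chromatogram:
    """Time grid plus per-solute concentration traces.

    ``traces`` preserves solute order (the overlaid per-component view);
    ``total`` is their pointwise sum (the physical detector view).
    """

    grid: TimeGrid
    traces: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("a chromatogram needs at least one trace")
        for name, trace in self.traces.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != (self.grid.n_points,):
                raise ValueError(
                    f"trace {name!r} has {trace.shape} values, "
                    f"grid has {self.grid.n_points} points"
                )
            if np.any(trace < 0):
                raise ValueError(f"trace {name!r} contains negative concentrations")

    @property
    def solute_names(self) -> tuple:
        return tuple(self.traces)

    @property
    def total(self) -> np.ndarray:
        """Summed detector trace, mg/L."""
        return np.sum(list(self.traces.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_min, one column per solute, total."""
        data = {"time_min": self.grid.times()}
        data.update({name: np.asarray(tr) for name, tr in self.traces.items()})
        data["total"] = self.total
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Chromatogram":
        """Read a chromatogram written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        if "time_min" not in df.columns:
            raise ValueError(f"{path}: missing 'time_min' column")
        t = df["time_min"].to_numpy(float)
        grid = TimeGrid(float(t[0]), float(t[-1]), len(t))
        names = [c for c in df.columns if c not in ("time_min", "total")]
        if not names:
            raise ValueError(f"{path}: no solute trace columns")
        traces = {name: df[name].to_numpy(float) for name in names}
        return cls(grid=grid, traces=traces)

    def plot(self, path, title: str = "Simulated chromatogram") -> None:
        """Overlaid per-solute curves (mirrors the classroom view); PNG/SVG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        t = self.grid.times()
        for name, trace in self.traces.items():
            ax.plot(t, trace, label=name)
        ax.set_xlabel("time / min")
        ax.set_ylabel("concentration / (mg/L)")
        ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def elution_profile(
    grid: TimeGrid,
    method: SeparationMethod,
    solute: Solute,
    model: str = "stirling",
) -> np.ndarray:
    """Concentration trace C(t) for one solute over the grid.

    Evaluates the chosen band-shape model at ``v(t)``; unimodal with its
    maximum at the retention time ``tm*(1 + K/beta)``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose one of {MODELS}")
    conc = _CONCENTRATION[model]
    v = reduced_volume(grid.times(), method, solute.K)
    return conc(v, method.column.n_plates, solute.K, solute.C0)


def simulate_mixture(
    grid: TimeGrid,
    method: SeparationMethod,
    solutes: Sequence[Solute],
    model: str = "stirling",
) -> Chromatogram:
    """Simulate several solutes under one method; traces do not interact.

    Each trace is exactly the corresponding single-solute profile (the
    plate model is linear in concentration), so the chromatogram's total
    is simply their sum.
    """
    if not solutes:
        raise ValueError("solute list must not be empty")
    names = [s.name for s in solutes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate solute names in {names}")
    traces: Dict[str, np.ndarray] = {
        s.name: elution_profile(grid, method, s, model=model) for s in solutes
    }
    return Chromatogram(grid=grid, traces=traces)


def gaussian_limit_profile(
    grid: TimeGrid, method: SeparationMethod, solute: Solute
) -> np.ndarray:
    """Large-n Gaussian approximation of the elution profile.

    The Poisson band has mean ``n`` and variance ``n`` in reduced volume;
    pushed through the linear map ``t = v*(1+K/beta)*tm/n`` this gives a
    Gaussian in time with mean ``tR = tm*(1+K/beta)`` and standard
    deviation ``tR/sqrt(n)``, scaled so its time integral equals the
    plate-model profile's closed-form area ``C0/(1+K) * tR/n``.
    """
    n = method.column.n_plates
    if n < 2:
        raise ValueError(f"Gaussian limit requires n >= 2, got n={n}")
    tr = method.column.dead_time_min * (
        1.0 + solute.K / method.column.phase_ratio
    )
    sigma = tr / math.sqrt(n)
    area = solute.C0 / (1.0 + solute.K) * tr / n
    t = grid.times()
    return (
        area
        / (sigma * math.sqrt(2.0 * math.pi))
        * np.exp(-0.5 * ((t - tr) / sigma) ** 2)
    )


def profile_area(trace: np.ndarray, grid: TimeGrid) -> float:
    """Trapezoidal time integral of a trace, mg*min/L."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape != (grid.n_points,):
        raise ValueError(
            f"trace has {trace.shape} values, grid has {grid.n_points} points"
        )
    return float(np.trapezoid(trace, grid.times()))


def default_grid(
    method: SeparationMethod, solutes: Iterable[Solute], n_points: int = 2000
) -> TimeGrid:
    """Grid spanning [0, 1.5 x slowest retention time]."""
    col = method.column
    tr_max = max(
        col.dead_time_min * (1.0 + s.K / col.phase_ratio) for s in solutes
    )
    return TimeGrid(0.0, 1.5 * tr_max, n_points)
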