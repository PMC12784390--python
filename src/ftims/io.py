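"""Configuration, CSV interchange, and bundled ion-mixture fixtures.

Run configuration is one YAML document with nested sections (ions, cell,
amplifier, noise, plan, reconstruct, analyze) plus a global ``seed`` and a
schema ``version``.  Unknown keys are rejected.  The effective configuration
is echoed into every output's metadata sidecar so a run is reproducible from
its artifacts alone.

CSV dialects (comma-separated, ``.`` decimal, mandatory header, UTF-8):

* interferograms  — ``frequency_hz,signal``
* mobility spectra — ``drift_time_ms,intensity``
* arrival traces  — ``time_ms,signal``
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .benchmark import benchmark_table, default_calibration_constant
from .core import Amplifier, DriftCell, IonSpecies, NoiseModel
from .reconstruct import MobilitySpectrum
from .schedule import (
    AcquisitionPlan,
    plan_single_gate,
    plan_stepped,
    plan_swept,
)
from .simulate import ArrivalTrace, Interferogram

__all__ = [
    "RunConfig",
    "load_config",
    "config_to_ions",
    "config_to_cell",
    "config_to_amplifier",
    "config_to_noise",
    "config_to_plan",
    "read_interferogram",
    "write_interferogram",
    "read_spectrum",
    "write_spectrum",
    "write_arrival_trace",
    "fixture_mixture",
]

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IonConfig(_Strict):
    name: str
    K0: float | None = None
    td: float | None = None
    abundance: float = 1.0
    sigma: float = 0.0


class CellConfig(_Strict):
    mode: Literal["calibration", "geometry"] = "calibration"
    C: float | None = None
    L: float | None = None
    E: float | None = None
    T: float = 298.15
    P: float = 760.0


class AmplifierConfig(_Strict):
    gain: float = 1.0e9
    rise_time: float = 100.0


class NoiseConfig(_Strict):
    white_rms: float = 0.0
    baseline: float = 0.0


class PlanConfig(_Strict):
    kind: Literal["stepped", "swept", "single_gate"] = "stepped"
    f_min: float | None = None
    f_step: float | None = None
    f_max: float | None = None
    n_avg: int = 1
    trigger_offset: float = 0.0005
    switch_overhead: float = 0.0
    sweep_duration: float | None = None
    scan_time: float = 50.0
    pulse_width: float = 0.2
    n_scans: int = 275


class ReconstructConfig(_Strict):
    window: str = "rectangular"
    zero_pad_factor: int = 8


class AnalyzeConfig(_Strict):
    min_prominence: float = 0.2
    noise_region: tuple[float, float] | None = None


class RunConfig(_Strict):
    """One experiment's complete, validated configuration."""

    version: int = SCHEMA_VERSION
    seed: int = 0
    ions: list[IonConfig] = Field(default_factory=list)
    cell: CellConfig = Field(default_factory=CellConfig)
    amplifier: AmplifierConfig = Field(default_factory=AmplifierConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    plan: PlanConfig = Field(default_factory=PlanConfig)
    reconstruct: ReconstructConfig = Field(default_factory=ReconstructConfig)
    analyze: AnalyzeConfig = Field(default_factory=AnalyzeConfig)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration (unknown keys rejected)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def config_to_ions(cfg: RunConfig) -> list[IonSpecies]:
    return [IonSpecies(name=i.name, K0=i.K0, td=i.td,
                       abundance=i.abundance, sigma=i.sigma)
            for i in cfg.ions]


def config_to_cell(cfg: RunConfig) -> DriftCell:
    c = cfg.cell
    if c.mode == "calibration":
        C = c.C if c.C is not None else default_calibration_constant()
        return DriftCell.from_calibration(C)
    return DriftCell.from_geometry(L=c.L, E=c.E, T=c.T, P=c.P)


def config_to_amplifier(cfg: RunConfig) -> Amplifier:
    return Amplifier(gain=cfg.amplifier.gain,
                     rise_time=cfg.amplifier.rise_time)


def config_to_noise(cfg: RunConfig) -> NoiseModel:
    return NoiseModel(white_rms=cfg.noise.white_rms,
                      baseline=cfg.noise.baseline, seed=cfg.seed)


def config_to_plan(cfg: RunConfig) -> AcquisitionPlan:
    p = cfg.plan
    if p.kind == "stepped":
        if p.f_min is None or p.f_step is None or p.f_max is None:
            raise ValueError("stepped plan requires f_min, f_step, f_max")
        return plan_stepped(p.f_min, p.f_step, p.f_max, p.n_avg,
                            trigger_offset=p.trigger_offset,
                            switch_overhead=p.switch_overhead)
    if p.kind == "swept":
        if p.f_min is None or p.f_max is None or p.sweep_duration is None:
            raise ValueError("swept plan requires f_min, f_max, sweep_duration")
        return plan_swept(p.f_min, p.f_max, p.sweep_duration, p.n_avg)
    return plan_single_gate(p.scan_time, p.pulse_width, p.n_scans)


# --------------------------------------------------------------------------
# CSV interchange


def _read_two_column_csv(path: str | Path, col_x: str,
                         col_y: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    for col in (col_x, col_y):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r} (found {list(df.columns)})"
            )
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return df[col_x].to_numpy(float), df[col_y].to_numpy(float)


def read_interferogram(path: str | Path) -> Interferogram:
    """Read ``frequency_hz,signal`` CSV; the grid must be strictly
    increasing and uniform (shuffled or resampled files are rejected)."""
    f, s = _read_two_column_csv(path, "frequency_hz", "signal")
    return Interferogram(frequencies=f, signal=s, meta={"source": str(path)})


def write_interferogram(ig: Interferogram, path: str | Path) -> None:
    """Write an interferogram; floats at full precision, so write -> read
    round-trips exactly."""
    pd.DataFrame({"frequency_hz": ig.frequencies,
                  "signal": ig.signal}).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> MobilitySpectrum:
    """Read ``drift_time_ms,intensity`` CSV into a MobilitySpectrum.

    Axis parameters are rebuilt from the grid: ``f_step`` from the bin width
    (the file must cover the full FFT half-axis for that to be exact).
    """
    x, y = _read_two_column_csv(path, "drift_time_ms", "intensity")
    if len(x) < 2:
        raise ValueError(f"{path}: need at least two rows")
    bin_ms = x[1] - x[0]
    n_fft = 2 * (len(x) - 1)
    f_step = 1.0e3 / (n_fft * bin_ms)
    return MobilitySpectrum(drift_times=x, intensity=y, f_step=f_step,
                            f_max=np.nan, meta={"source": str(path)})


def write_spectrum(spectrum: MobilitySpectrum, path: str | Path) -> None:
    pd.DataFrame({"drift_time_ms": spectrum.drift_times,
                  "intensity": spectrum.intensity}).to_csv(path, index=False)


def write_arrival_trace(trace: ArrivalTrace, path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.times,
                  "signal": trace.signal}).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Fixtures


def fixture_mixture(name: str) -> tuple[list[IonSpecies], DriftCell]:
    """Bundled ion mixtures with the default calibration cell.

    * ``rip`` — the reactant ion peak alone, drift time 20 ms.
    * ``txa4`` — the four tetraalkylammonium salts (benchmark SG drift
      times 30.11, 35.06, 40.33, 45.49 ms).
    * ``standards9`` — all nine benchmark compounds at their SG drift times.

    Intrinsic widths are set to 0.15 ms, a typical drift-tube arrival-time
    spread at these drift times.
    """
    cell = DriftCell.from_calibration(default_calibration_constant())
    sigma = 0.15
    table = benchmark_table()
    if name == "rip":
        ions = [IonSpecies(name="RIP", td=20.0, abundance=1.0, sigma=sigma)]
    elif name == "txa4":
        txa = table[table["name"].isin(("T3A", "T4A", "T5A", "T6A"))]
        ions = [IonSpecies(name=r["name"], td=float(r["td_sg"]),
                           abundance=1.0, sigma=sigma)
                for _, r in txa.iterrows()]
    elif name == "standards9":
        ions = [IonSpecies(name=r["name"], td=float(r["td_sg"]),
                           abundance=1.0, sigma=sigma)
                for _, r in table.iterrows()]
    else:
        raise ValueError(
            f"unknown fixture {name!r}; available: rip, txa4, standards9"
        )
    return ions, cell
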