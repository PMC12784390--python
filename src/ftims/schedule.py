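"""Acquisition planning for stepped, swept and single-gate experiments.

The stepped FT protocol steps the gate frequency from ``f_min`` to ``f_max``
in increments of ``f_step``.  Averaging is defined by *time*, not by pulse
count: every step dwells for ``n_avg / f_min`` seconds — the time needed to
see ``n_avg`` periods of the slowest frequency — so the averaging window is
identical at every frequency.  Data collection at each step is software
triggered a fixed offset (0.5 ms by default) after the new frequency is
established; the offset applies to the data window only, never to the gate
waveform phase, which is exactly the asynchrony the long-rise-time amplifier
makes harmless.

The swept alternative drives the gates with a linear chirp; the single-gate
mode is the classical pulsed experiment (one short gate pulse per scan,
signal-averaged over many scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyStep",
    "AcquisitionPlan",
    "plan_stepped",
    "plan_swept",
    "plan_single_gate",
    "plan_duration",
    "chirp_frequency",
    "gate_waveform",
    "single_gate_duty",
]


@dataclass(frozen=True)
class FrequencyStep:
    """One dwell of the stepped protocol.

    ``n_pulses = floor(dwell * f)`` is the number of full gate periods seen
    during the dwell; a valid plan has ``n_pulses >= 1`` at every step.
    """

    f: float
    dwell: float
    n_pulses: int
    trigger_offset: float = 0.0005

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be > 0")
        if self.dwell <= 0:
            raise ValueError("dwell must be > 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")


@dataclass
class AcquisitionPlan:
    """A fully specified acquisition: stepped, swept, or single-gate.

    Only the fields relevant to ``kind`` are populated.  Frequencies in Hz,
    dwell/overhead/sweep duration in s, single-gate scan time and pulse width
    in ms.
    """

    kind: str
    f_min: float | None = None
    f_step: float | None = None
    f_max: float | None = None
    n_avg: int | None = None
    steps: list[FrequencyStep] = field(default_factory=list)
    sweep_duration: float | None = None
    scan_time: float | None = None
    pulse_width: float | None = None
    n_scans: int | None = None
    switch_overhead: float = 0.0

    @property
    def frequencies(self) -> np.ndarray:
        """Step frequencies (Hz) of a stepped plan as an array."""
        if self.kind != "stepped":
            raise ValueError("only stepped plans have discrete frequencies")
        return np.array([s.f for s in self.steps], dtype=float)

    def to_dict(self) -> dict:
        """JSON-serialisable description (explicit step list included)."""
        out: dict = {"kind": self.kind, "switch_overhead": self.switch_overhead}
        for key in ("f_min", "f_step", "f_max", "n_avg", "sweep_duration",
                    "scan_time", "pulse_width", "n_scans"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        if self.kind == "stepped":
            out["steps"] = [
                {"f": s.f, "dwell": s.dwell, "n_pulses": s.n_pulses,
                 "trigger_offset": s.trigger_offset}
                for s in self.steps
            ]
        return out


def plan_stepped(
    f_min: float,
    f_step: float,
    f_max: float,
    n_avg: int,
    trigger_offset: float = 0.0005,
    switch_overhead: float = 0.0,
) -> AcquisitionPlan:
    """Build a stepped-frequency plan.

    Frequencies form the arithmetic grid ``f_min, f_min + f_step, ...`` up to
    the largest grid point <= ``f_max`` (the FFT axis requires a uniform
    grid, so the last step is never rounded up).  Every step dwells
    ``n_avg / f_min`` seconds.

    Example: stepping 4 Hz -> 4000 Hz by 5 Hz with 4 averages dwells
    4 / 4 Hz = 1 s at every step.
    """
    if f_min <= 0:
        raise ValueError("f_min must be > 0")
    if f_min > f_max:
        raise ValueError("invalid range: f_min > f_max")
    if f_step <= 0:
        raise ValueError("invalid step: f_step must be > 0")
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    n_steps = int(math.floor((f_max - f_min) / f_step + 1e-9)) + 1
    dwell = n_avg / f_min
    steps = [
        FrequencyStep(
            f=f_min + k * f_step,
            dwell=dwell,
            n_pulses=int(math.floor(dwell * (f_min + k * f_step) + 1e-9)),
            trigger_offset=trigger_offset,
        )
        for k in range(n_steps)
    ]
    return AcquisitionPlan(
        kind="stepped",
        f_min=f_min,
        f_step=f_step,
        f_max=f_max,
        n_avg=n_avg,
        steps=steps,
        switch_overhead=switch_overhead,
    )


def plan_swept(
    f_min: float,
    f_max: float,
    sweep_duration: float,
    n_avg: int = 1,
) -> AcquisitionPlan:
    """Linear-chirp plan: instantaneous frequency
    ``f(t) = f_min + (f_max - f_min) * t / sweep_duration``."""
    if f_min <= 0 or f_min >= f_max:
        raise ValueError("invalid range: require 0 < f_min < f_max")
    if sweep_duration <= 0:
        raise ValueError("sweep_duration must be > 0")
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    return AcquisitionPlan(
        kind="swept",
        f_min=f_min,
        f_max=f_max,
        sweep_duration=sweep_duration,
        n_avg=n_avg,
    )


def plan_single_gate(
    scan_time: float = 50.0,
    pulse_width: float = 0.2,
    n_scans: int = 275,
) -> AcquisitionPlan:
    """Classical pulsed single-gate plan (scan time and pulse width in ms)."""
    if scan_time <= 0 or pulse_width <= 0:
        raise ValueError("scan_time and pulse_width must be > 0")
    if pulse_width >= scan_time:
        raise ValueError("pulse_width must be < scan_time")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    return AcquisitionPlan(
        kind="single_gate",
        scan_time=scan_time,
        pulse_width=pulse_width,
        n_scans=n_scans,
    )


def plan_duration(plan: AcquisitionPlan) -> float:
    """Predicted wall-clock duration of a plan in seconds.

    Stepped: sum over steps of (dwell + switch_overhead).  Swept:
    n_avg * (sweep_duration + switch_overhead).  Single-gate:
    n_scans * scan_time.  Reported hardware run times additionally include
    per-step software overhead that varies by DAQ; expose it through
    ``switch_overhead`` rather than guessing a value.
    """
    if plan.kind == "stepped":
        return sum(s.dwell + plan.switch_overhead for s in plan.steps)
    if plan.kind == "swept":
        return plan.n_avg * (plan.sweep_duration + plan.switch_overhead)
    if plan.kind == "single_gate":
        return plan.n_scans * plan.scan_time * 1.0e-3
    raise ValueError(f"unknown plan kind {plan.kind!r}")


def chirp_frequency(plan: AcquisitionPlan, t) -> np.ndarray | float:
    """Instantaneous frequency (Hz) of a swept plan at time ``t`` (s)."""
    if plan.kind != "swept":
        raise ValueError("chirp_frequency requires a swept plan")
    rate = (plan.f_max - plan.f_min) / plan.sweep_duration
    return plan.f_min + rate * np.asarray(t, dtype=float)


def gate_waveform(step: FrequencyStep, sample_rate: float) -> np.ndarray:
    """Binary open/closed series for one step's 50%-duty square wave.

    Both gates are driven from the same output, so a single waveform serves
    the pair.  Raises on undersampling (< 10 samples per gate period).
    """
    if sample_rate < 10.0 * step.f:
        raise ValueError(
            f"sample_rate {sample_rate} Hz undersamples a {step.f} Hz gate; "
            "need >= 10 samples per period"
        )
    n = int(round(step.dwell * sample_rate))
    t = np.arange(n) / sample_rate
    return (np.mod(t * step.f, 1.0) < 0.5).astype(np.uint8)


def single_gate_duty(plan: AcquisitionPlan) -> float:
    """Duty cycle of a single-gate plan (pulse width / scan time)."""
    if plan.kind != "single_gate":
        raise ValueError("duty of a non single-gate plan is set by the waveform")
    return plan.pulse_width / plan.scan_time
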