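"""Synthetic detector records for single-gate, swept and stepped experiments.

Three levels of fidelity are provided:

* :func:`steady_state_signal` — the analytic model.  At each gate frequency
  the dual-gate cell transmits a steady DC level equal to the gate
  correlation averaged over each ion's Gaussian arrival-time distribution.
* :func:`time_domain_record` — the brute-force model for a single step:
  explicit gate trains, packet convolution, the exit gate, a first-order
  low-pass amplifier, sampled at an ADC rate.  Windowed means of this record
  must agree with the analytic model; that equivalence, and its insensitivity
  to the data-window start, is the quantitative form of the claim that
  asynchronous (software-timed) triggering costs nothing.
* :func:`single_gate_record` / :func:`swept_record` — the classical pulsed
  experiment and the linear-chirp FT variant.

All randomness flows from the :class:`~ftims.core.NoiseModel` seed; stepped
interferograms derive one substream per step index so that sub-plans and
full plans produce identical noise at shared steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .core import (
    Amplifier,
    DriftCell,
    IonSpecies,
    NoiseModel,
    gate_correlation,
    resolve_drift_time,
)
from .schedule import AcquisitionPlan, FrequencyStep, chirp_frequency

__all__ = [
    "NOISE_BANDWIDTH_HZ",
    "Interferogram",
    "ArrivalTrace",
    "ChirpRecord",
    "gaussian_gate_correlation",
    "steady_state_signal",
    "time_domain_record",
    "windowed_mean",
    "single_gate_record",
    "swept_record",
    "chirp_to_interferogram",
]

#: Equivalent raw-sampling bandwidth used to convert the per-sample white
#: noise of a NoiseModel into per-interferogram-point noise: averaging for
#: ``dwell`` seconds at an effective rate of NOISE_BANDWIDTH_HZ reduces the
#: white RMS by sqrt(dwell * NOISE_BANDWIDTH_HZ).  Held fixed so that noise
#: levels are comparable across plans and reproducible across runs.
NOISE_BANDWIDTH_HZ = 1000.0


@dataclass
class Interferogram:
    """Per-frequency averaged detector signal — the FT experiment's raw data.

    ``frequencies`` must be a strictly increasing, uniform grid (spacing
    constant to 1e-9 relative): the FFT axis mapping depends on it.
    """

    frequencies: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.frequencies.ndim != 1 or len(self.frequencies) < 2:
            raise ValueError("need at least two frequency points")
        if len(self.signal) != len(self.frequencies):
            raise ValueError("signal and frequencies lengths differ")
        df = np.diff(self.frequencies)
        if np.any(df <= 0):
            raise ValueError("frequencies must be strictly increasing")
        step = df[0]
        if np.any(np.abs(df - step) > 1e-9 * step):
            raise ValueError("frequency grid is not uniform; resample first")

    @property
    def f_step(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class ArrivalTrace:
    """Averaged single-gate arrival-time trace (times in ms from the pulse)."""

    times: np.ndarray
    signal: np.ndarray
    n_scans: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.times) != len(self.signal):
            raise ValueError("signal and times lengths differ")
        if self.times[0] != 0.0:
            raise ValueError("times must start at 0")


@dataclass
class ChirpRecord:
    """Sampled swept-frequency (linear chirp) detector record, times in s."""

    times: np.ndarray
    signal: np.ndarray
    plan: AcquisitionPlan


def gaussian_gate_correlation(f, td: float, sigma: float, duty: float = 0.5):
    """Gate correlation averaged over a Gaussian arrival distribution.

    ``td`` and ``sigma`` in ms.  For ``sigma = 0`` this is
    :func:`~ftims.core.gate_correlation` itself; otherwise the triangular
    correlation is integrated numerically against N(td, sigma^2) on a
    +/- 8 sigma grid fine enough that the kinks of the triangle contribute
    error well below simulation tolerances.
    """
    if sigma == 0.0:
        return gate_correlation(f, td, duty)
    z = np.linspace(-8.0, 8.0, 1601)
    t = td + sigma * z
    w = np.exp(-0.5 * z * z)
    w /= w.sum()
    f = np.atleast_1d(np.asarray(f, dtype=float))
    g = gate_correlation(f[:, None], t[None, :], duty) @ w
    return g if g.size > 1 else float(g[0])


def _noise_sd_per_step(noise: NoiseModel, dwell: float) -> float:
    return noise.white_rms / np.sqrt(dwell * NOISE_BANDWIDTH_HZ)


def steady_state_signal(
    plan: AcquisitionPlan,
    ions: list[IonSpecies],
    cell: DriftCell | None = None,
    noise: NoiseModel | None = None,
    duty: float = 0.5,
) -> Interferogram:
    """Analytic stepped-frequency interferogram.

    At each step frequency f the signal is::

        baseline + sum_i abundance_i * <g(f, t)>_{t ~ N(td_i, sigma_i^2)} + eps

    where g is the gate correlation and eps is white noise whose standard
    deviation is ``white_rms / sqrt(dwell * NOISE_BANDWIDTH_HZ)`` — the
    averaging gain of the dwell.  Each step draws its noise from a substream
    keyed by (seed, step index), so the stream is bit-reproducible and
    independent of how steps are batched.
    """
    if plan.kind != "stepped":
        raise ValueError("steady_state_signal requires a stepped plan")
    freqs = plan.frequencies
    signal = np.zeros_like(freqs)
    for ion in ions:
        td = resolve_drift_time(ion, cell)
        signal += ion.abundance * np.asarray(
            gaussian_gate_correlation(freqs, td, ion.sigma, duty)
        )
    meta = {"plan": plan.to_dict(), "duty": duty}
    if noise is not None:
        signal = signal + noise.baseline
        if noise.white_rms > 0:
            dwell = plan.steps[0].dwell
            sd = _noise_sd_per_step(noise, dwell)
            eps = np.array([
                np.random.default_rng([noise.seed, j]).standard_normal()
                for j in range(len(freqs))
            ])
            signal = signal + sd * eps
        meta["seed"] = noise.seed
        meta["white_rms"] = noise.white_rms
        meta["baseline"] = noise.baseline
    return Interferogram(frequencies=freqs, signal=signal, meta=meta)


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Delay a series by a (possibly fractional) number of samples via
    two-tap linear interpolation; the head is zero-filled."""
    i = int(np.floor(delay_samples))
    frac = delay_samples - i

    def shift(arr: np.ndarray, k: int) -> np.ndarray:
        if k == 0:
            return arr
        out = np.zeros_like(arr)
        out[k:] = arr[:-k]
        return out

    if frac == 0.0:
        return shift(x, i)
    return (1.0 - frac) * shift(x, i) + frac * shift(x, i + 1)


def time_domain_record(
    step: FrequencyStep,
    ions: list[IonSpecies],
    cell: DriftCell | None = None,
    amplifier: Amplifier | None = None,
    noise: NoiseModel | None = None,
    sample_rate: float | None = None,
    stream: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force amplifier output over one step's dwell.

    Both gates run the step's square wave continuously; the detector current
    is ``gate(t) * sum_i a_i (gate * N(td_i, sigma_i))(t)``, i.e. the packet
    train admitted by gate 1, spread by each ion's Gaussian arrival
    distribution and chopped by gate 2.  White noise (per-sample sd
    ``white_rms``) is added to the raw current, then a first-order low-pass
    with ``tau = rise_time / ln 9`` is applied and the settled portion
    starting at t = 0 (frequency establishment) is returned.

    Returns ``(times_s, signal)``; ``times_s[0] = 0``.  The record is long
    enough before t = 0 (drift times + 7 tau) that the filter transient has
    died away.
    """
    f = step.f
    if sample_rate is None:
        sample_rate = 50.0 * f
    if sample_rate < 20.0 * f:
        raise ValueError(
            f"sample_rate {sample_rate} Hz undersamples a {f} Hz gate; "
            "need >= 20 samples per period"
        )
    amplifier = amplifier if amplifier is not None else Amplifier(rise_time=0.0)
    dt = 1.0 / sample_rate
    tds = [resolve_drift_time(ion, cell) * 1e-3 for ion in ions]
    sigmas = [ion.sigma * 1e-3 for ion in ions]
    tau = amplifier.tau_ms * 1e-3
    pad = (max(tds, default=0.0) + 6.0 * max(sigmas, default=0.0)
           + 7.0 * tau + 2.0 / f)
    n_pad = int(np.ceil(pad * sample_rate))
    n = int(round(step.dwell * sample_rate))
    t = np.arange(-n_pad, n) * dt
    gate = (np.mod(t * f, 1.0) < 0.5).astype(float)

    current = np.zeros_like(gate)
    for ion, td_s, sig_s in zip(ions, tds, sigmas):
        packet = _fractional_delay(gate, td_s * sample_rate)
        if sig_s > 0:
            packet = gaussian_filter1d(packet, sig_s * sample_rate,
                                       mode="nearest")
        current += ion.abundance * packet
    detector = gate * current
    if noise is not None:
        detector = detector + noise.baseline
        if noise.white_rms > 0:
            rng = np.random.default_rng([noise.seed, stream])
            detector = detector + rng.normal(0.0, noise.white_rms,
                                             size=detector.shape)
    if tau > 0:
        alpha = 1.0 - np.exp(-dt / tau)
        zi = np.array([(1.0 - alpha) * detector[0]])
        out, _ = lfilter([alpha], [1.0, alpha - 1.0], detector, zi=zi)
    else:
        out = detector
    return t[n_pad:], out[n_pad:]


def windowed_mean(
    times: np.ndarray,
    signal: np.ndarray,
    start: float,
    duration: float | None = None,
) -> float:
    """Mean of ``signal`` over ``times`` in [start, start + duration)
    (to the end of the record if ``duration`` is None)."""
    stop = times[-1] + np.inf if duration is None else start + duration
    sel = (times >= start) & (times < stop)
    if not np.any(sel):
        raise ValueError("empty averaging window")
    return float(np.mean(signal[sel]))


def single_gate_record(
    plan: AcquisitionPlan,
    ions: list[IonSpecies],
    cell: DriftCell | None = None,
    amplifier: Amplifier | None = None,
    noise: NoiseModel | None = None,
    sample_rate: float = 20000.0,
) -> ArrivalTrace:
    """Averaged single-gate arrival trace.

    Each ion contributes a Gaussian of width
    ``sqrt(sigma^2 + (pulse_width / 2.3548)^2)`` (the finite gate pulse adds
    its own width in quadrature), convolved with the amplifier response.
    White noise is reduced by sqrt(n_scans) — the averaging gain of the
    pulsed experiment.
    """
    if plan.kind != "single_gate":
        raise ValueError("single_gate_record requires a single_gate plan")
    n = int(round(plan.scan_time * 1e-3 * sample_rate))
    times_ms = np.arange(n) / sample_rate * 1e3
    signal = np.zeros(n)
    pulse_sigma = plan.pulse_width / 2.3548
    for ion in ions:
        td = resolve_drift_time(ion, cell)
        s = np.sqrt(ion.sigma**2 + pulse_sigma**2)
        signal += ion.abundance * np.exp(-0.5 * ((times_ms - td) / s) ** 2)
    if amplifier is not None and amplifier.rise_time > 0:
        dt_ms = 1e3 / sample_rate
        alpha = 1.0 - np.exp(-dt_ms / amplifier.tau_ms)
        signal, _ = lfilter([alpha], [1.0, alpha - 1.0], signal,
                            zi=np.array([0.0]))
    if noise is not None:
        signal = signal + noise.baseline
        if noise.white_rms > 0:
            rng = np.random.default_rng(noise.seed)
            signal = signal + rng.normal(
                0.0, noise.white_rms / np.sqrt(plan.n_scans), size=n
            )
    return ArrivalTrace(times=times_ms, signal=signal, n_scans=plan.n_scans)


def swept_record(
    plan: AcquisitionPlan,
    ions: list[IonSpecies],
    cell: DriftCell | None = None,
    noise: NoiseModel | None = None,
    sample_rate: float = 1000.0,
    duty: float = 0.5,
) -> ChirpRecord:
    """Quasi-static swept-frequency record.

    The chirp is slow compared with the gate periods, so each sample carries
    the steady-state gate correlation evaluated at the instantaneous chirp
    frequency.  Averaging ``n_avg`` sweeps reduces white noise by
    sqrt(n_avg).
    """
    if plan.kind != "swept":
        raise ValueError("swept_record requires a swept plan")
    n = int(round(plan.sweep_duration * sample_rate))
    t = np.arange(n) / sample_rate
    f_inst = np.asarray(chirp_frequency(plan, t))
    signal = np.zeros(n)
    for ion in ions:
        td = resolve_drift_time(ion, cell)
        signal += ion.abundance * np.asarray(
            gaussian_gate_correlation(f_inst, td, ion.sigma, duty)
        )
    if noise is not None:
        signal = signal + noise.baseline
        if noise.white_rms > 0:
            rng = np.random.default_rng(noise.seed)
            signal = signal + rng.normal(
                0.0, noise.white_rms / np.sqrt(plan.n_avg), size=n
            )
    return ChirpRecord(times=t, signal=signal, plan=plan)


def chirp_to_interferogram(record: ChirpRecord) -> Interferogram:
    """Map a linear-chirp record onto its (uniform) frequency axis.

    Uniform time sampling of a linear chirp is uniform frequency sampling,
    so the record re-labels directly into an interferogram.
    """
    f = np.asarray(chirp_frequency(record.plan, record.times))
    return Interferogram(
        frequencies=f,
        signal=record.signal.copy(),
        meta={"plan": record.plan.to_dict()},
    )
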