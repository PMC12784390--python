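"""Bundled drift-tube benchmark: single-gate vs stepped-FT measurements.

Nine compounds commonly used to characterise drift-tube IMS instruments —
di-tert-butylpyridine (DtBP), the DMMP dimer, cocaine, the tetraalkylammonium
(TXA) calibration salts T3A/T4A/T5A/T6A, nitroglycerine (NG) and TNT —
measured on one cell in both single-gate (SG) and stepped-FT modes.
Columns: drift time (ms), reduced mobility K0 (cm^2 V^-1 s^-1), resolving
power and S/N per mode, plus literature K0 values.

This table anchors the comparison statistics (:mod:`ftims.compare`), the
mobility calibration constant of the default cell, and the bundled ion
mixtures (:func:`ftims.io.fixture_mixture`).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "benchmark_table",
    "default_calibration_constant",
    "TXA_NAMES",
]

#: Tetraalkylammonium calibration salts present in the benchmark.
TXA_NAMES = ("T3A", "T4A", "T5A", "T6A")

_ROWS = [
    # name, td_sg, k0_sg, rp_sg, snr_sg, td_ft, k0_ft, rp_ft, snr_ft, k0_lit
    ("DtBP",         30.34, 1.42, 38.35, 5.69, 30.27, 1.41, 80.55, 16.82, 1.42),
    ("DMMP (dimer)", 30.52, 1.41, 63.91, 3.16, 31.00, 1.39, 76.80,  6.60, 1.40),
    ("Cocaine",      36.71, 1.16, 64.55, 9.13, 36.67, 1.16, 83.90, 17.52, 1.16),
    ("T3A",          30.11, 1.43, 71.62, 4.72, 30.00, 1.44, 88.12,  9.20, 1.51),
    ("T4A",          35.06, 1.23, 77.89, 5.14, 35.09, 1.23, 78.96, 11.51, 1.28),
    ("T5A",          40.33, 1.07, 82.73, 6.16, 40.18, 1.07, 87.86,  8.08, 1.10),
    ("T6A",          45.49, 0.95, 84.61, 6.88, 45.53, 0.95, 86.85,  6.55, 0.97),
    ("NG",           24.93, 1.71, 54.00, 4.18, 24.70, 1.72, 48.07, 13.47, 1.83),
    ("TNT",          28.78, 1.48, 38.71, 3.52, 28.42, 1.50, 67.92,  8.73, 1.54),
]

_COLUMNS = ["name", "td_sg", "k0_sg", "rp_sg", "snr_sg",
            "td_ft", "k0_ft", "rp_ft", "snr_ft", "k0_lit"]


def benchmark_table() -> pd.DataFrame:
    """The benchmark as a DataFrame (one row per compound)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def default_calibration_constant() -> float:
    """Cell constant C = td * K0 (ms cm^2 V^-1 s^-1), fitted as the mean of
    the single-gate td * K0 products over the TXA salts.

    The TXA rows are used because the salts are the de facto mobility
    calibration standards; td * K0 is constant for one cell at fixed
    conditions, so its mean is a one-number calibration.
    """
    table = benchmark_table()
    txa = table[table["name"].isin(TXA_NAMES)]
    return float((txa["td_sg"] * txa["k0_sg"]).mean())
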