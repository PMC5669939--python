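"""EV biophysics: nanoplasmonic aggregation index and weighted mean diameter.

Two closed-form computations accompany the sequencing pipeline.  The
aggregation index (AI) of a gold-nanoparticle/EV mixture is the ratio of
UV-Vis absorbance at the localized surface plasmon resonance peak (519 nm)
to the aggregation shoulder (650 nm): AI = A519/A650.  The weighted mean EV
diameter is the particle-count-weighted average of an AFM size histogram,
excluding objects below 30 nm (sub-vesicle debris).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "aggregation_index",
    "weighted_mean_diameter",
    "read_spectrum_tsv",
    "read_size_histogram_tsv",
]

AI_PEAK_NM = 519.0
AI_SHOULDER_NM = 650.0
DEFAULT_MIN_DIAMETER_NM = 30.0


def aggregation_index(wavelengths, absorbance) -> float:
    """AI = A(519 nm) / A(650 nm), linearly interpolating off-grid wavelengths.

    Wavelengths must be strictly ascending and cover both 519 and 650 nm;
    absorbance must be non-negative and A(650) nonzero.
    """
    wl = np.asarray(wavelengths, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if wl.ndim != 1 or wl.shape != ab.shape:
        raise ValueError("wavelengths and absorbance must be equal-length 1-D arrays")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly ascending")
    if (ab < 0).any():
        raise ValueError("absorbance must be non-negative")
    if wl[0] > AI_PEAK_NM or wl[-1] < AI_SHOULDER_NM:
        raise ValueError(
            f"spectrum must cover {AI_PEAK_NM:.0f}-{AI_SHOULDER_NM:.0f} nm "
            f"(got {wl[0]:.0f}-{wl[-1]:.0f} nm)"
        )
    a519 = float(np.interp(AI_PEAK_NM, wl, ab))
    a650 = float(np.interp(AI_SHOULDER_NM, wl, ab))
    if a650 == 0:
        raise ValueError("absorbance at 650 nm is zero; AI undefined")
    return a519 / a650


def weighted_mean_diameter(
    diameters, counts, min_diameter: float = DEFAULT_MIN_DIAMETER_NM
) -> float:
    """Count-weighted mean diameter over bins with diameter >= min_diameter.

    sum(d_i * n_i) / sum(n_i) restricted to qualifying bins; raises if no bin
    with positive count qualifies.
    """
    d = np.asarray(diameters, dtype=float)
    n = np.asarray(counts, dtype=float)
    if d.ndim != 1 or d.shape != n.shape:
        raise ValueError("diameters and counts must be equal-length 1-D arrays")
    if (d <= 0).any():
        raise ValueError("diameters must be positive")
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    keep = d >= min_diameter
    total = n[keep].sum()
    if total == 0:
        raise ValueError(f"no particles with diameter >= {min_diameter} nm")
    return float((d[keep] * n[keep]).sum() / total)


def read_spectrum_tsv(path: str | Path) -> pd.DataFrame:
    """Read a two-column spectrum TSV (wavelength_nm, absorbance)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("wavelength_nm", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"spectrum file {path} is missing column {col!r}")
    return df[["wavelength_nm", "absorbance"]].astype(float)


def read_size_histogram_tsv(path: str | Path) -> pd.DataFrame:
    """Read a two-column size histogram TSV (diameter_nm, count)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("diameter_nm", "count"):
        if col not in df.columns:
            raise ValueError(f"size histogram file {path} is missing column {col!r}")
    return df[["diameter_nm", "count"]].astype(float)
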