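"""ATR-FTIR spectral preprocessing and band reporting.

Spectra live on a uniform wavenumber grid (default 600–4000 cm^-1, step 1,
3401 points).  Preprocessing follows standard chemometric practice: a
per-spectrum standard normal variate (SNV) transform removes additive
offset and multiplicative scatter, and a Savitzky–Golay second derivative
resolves overlapping bands in the sugar fingerprint region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

#: Default acquisition grid: 600–4000 cm^-1 inclusive, 1 cm^-1 step.
DEFAULT_GRID = np.arange(600.0, 4001.0, 1.0)


def _check_uniform(grid: np.ndarray) -> float:
    steps = np.diff(grid)
    if grid.ndim != 1 or len(grid) < 3:
        raise ValueError("wavenumber grid must be 1-D with >= 3 points")
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-8) or steps[0] == 0:
        raise ValueError("wavenumber grid must be uniform")
    return float(steps[0])


@dataclass
class Spectrum:
    """A single absorbance spectrum on a uniform wavenumber grid."""

    wavenumber: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.wavenumber.shape != self.absorbance.shape:
            raise ValueError("wavenumber and absorbance lengths differ")
        _check_uniform(self.wavenumber)


@dataclass
class SpectraSet:
    """Matrix of spectra sharing one grid, with stage/sample metadata."""

    wavenumber: np.ndarray
    absorbance: np.ndarray  # observations x wavenumbers
    stage: np.ndarray
    sample_id: np.ndarray
    replicate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, float))
        _check_uniform(self.wavenumber)
        if self.absorbance.shape[1] != len(self.wavenumber):
            raise ValueError("spectra and grid lengths differ")
        n = self.absorbance.shape[0]
        self.stage = np.asarray(self.stage)
        self.sample_id = np.asarray(self.sample_id)
        if self.replicate is None:
            self.replicate = np.arange(1, n + 1)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.stage) == len(self.sample_id) == len(self.replicate) == n):
            raise ValueError("metadata length must match number of spectra")

    @property
    def n_obs(self) -> int:
        return self.absorbance.shape[0]


def snv(x):
    """Standard normal variate transform: (x - mean(x)) / sd(x) per spectrum.

    The sample (n-1) standard deviation convention is used.  Accepts a
    :class:`Spectrum`, a 1-D array, or a 2-D array (rows transformed
    independently); returns the same kind.  Raises on a constant spectrum.
    """
    if isinstance(x, Spectrum):
        return Spectrum(x.wavenumber, snv(x.absorbance))
    if isinstance(x, SpectraSet):
        return SpectraSet(x.wavenumber, snv(x.absorbance), x.stage, x.sample_id, x.replicate)
    arr = np.asarray(x, float)
    if arr.ndim == 1:
        if np.ptp(arr) == 0:
            raise ValueError("SNV undefined for a constant spectrum (sd = 0)")
        return (arr - arr.mean()) / arr.std(ddof=1)
    if np.any(np.ptp(arr, axis=1) == 0):
        raise ValueError("SNV undefined for a constant spectrum (sd = 0)")
    return (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, ddof=1, keepdims=True)


def second_derivative(
    spectrum: Spectrum, window_points: int = 15, poly_order: int = 3
) -> Spectrum:
    """Savitzky–Golay second derivative of a spectrum.

    ``window_points`` must be odd and exceed ``poly_order`` (>= 2).  Edge
    points are handled by the fitted polynomial of the first/last window.
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if poly_order < 2 or window_points <= poly_order:
        raise ValueError("require window_points > poly_order >= 2")
    if window_points > len(spectrum.wavenumber):
        raise ValueError("window larger than spectrum")
    step = _check_uniform(spectrum.wavenumber)
    d2 = savgol_filter(
        spectrum.absorbance,
        window_length=window_points,
        polyorder=poly_order,
        deriv=2,
        delta=abs(step),
        mode="interp",
    )
    return Spectrum(spectrum.wavenumber, d2)


def band_report(
    loading: np.ndarray,
    grid: np.ndarray,
    top_k: int = 6,
    rel_prominence: float = 0.05,
    smooth_points: int = 61,
) -> list[tuple[float, int]]:
    """Dominant bands of a loading vector: top-k local extrema by |value|.

    The loading is first smoothed with a short Savitzky–Golay filter
    (``smooth_points`` window, cubic), because on a broad band's flat top
    the raw extremum position is dominated by noise; a quadratic-preserving
    smoother leaves band-centre positions unbiased.  Local maxima of the
    smoothed loading and of its negation are then picked with a prominence
    of ``rel_prominence`` times the peak-to-peak range, so noise wiggles
    riding on a band do not yield duplicate reports.  Returns
    ``[(band_center_cm-1, sign), ...]`` sorted by decreasing absolute
    loading; sign (+1/-1) is the direction of association with the
    component.  A flat loading yields an empty report.
    """
    from scipy.signal import find_peaks, savgol_filter

    loading = np.asarray(loading, float)
    grid = np.asarray(grid, float)
    if loading.shape != grid.shape:
        raise ValueError("loading and grid must have the same length")
    if np.allclose(loading, loading[0]):
        return []
    if smooth_points and smooth_points >= 5 and smooth_points <= len(loading):
        w = smooth_points if smooth_points % 2 else smooth_points - 1
        loading = savgol_filter(loading, window_length=w, polyorder=3)
    prom = rel_prominence * float(np.ptp(loading))
    idx: list[int] = []
    for sgn in (1.0, -1.0):
        peaks, _ = find_peaks(sgn * loading, prominence=prom)
        idx.extend(int(i) for i in peaks)
    # endpoints can carry a band centre truncated by the grid
    for i in (0, len(loading) - 1):
        inner = loading[1:-1]
        if inner.size and abs(loading[i]) > np.max(np.abs(inner)):
            idx.append(i)
    idx = sorted(set(idx), key=lambda i: -abs(loading[i]))
    return [
        (float(grid[i]), 1 if loading[i] >= 0 else -1)
        for i in idx[: max(0, int(top_k))]
    ]


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read spectra from CSV; wide and long dialects both accepted.

    Wide: first column ``wavenumber_cm-1``, one column per observation,
    column names ``stage|sample|replicate``.  Long: columns
    ``wavenumber_cm-1, stage, sample_id, replicate, absorbance``.
    """
    df = pd.read_csv(path)
    if "wavenumber_cm-1" not in df.columns:
        raise ValueError(f"{path}: expected a wavenumber_cm-1 column")
    if "absorbance" in df.columns:  # long dialect
        grid = np.sort(df["wavenumber_cm-1"].unique())
        obs_keys = df[["stage", "sample_id", "replicate"]].drop_duplicates()
        mats, stages, samples, reps = [], [], [], []
        for _, key in obs_keys.iterrows():
            sub = df[
                (df["stage"] == key["stage"])
                & (df["sample_id"] == key["sample_id"])
                & (df["replicate"] == key["replicate"])
            ].sort_values("wavenumber_cm-1")
            mats.append(sub["absorbance"].to_numpy(float))
            stages.append(key["stage"])
            samples.append(key["sample_id"])
            reps.append(key["replicate"])
        return SpectraSet(grid, np.vstack(mats), np.array(stages), np.array(samples), np.array(reps))
    grid = df["wavenumber_cm-1"].to_numpy(float)
    cols = [c for c in df.columns if c != "wavenumber_cm-1"]
    meta = [c.split("|") for c in cols]
    if not all(len(m) == 3 for m in meta):
        raise ValueError("wide spectra columns must be named stage|sample|replicate")
    mat = df[cols].to_numpy(float).T
    return SpectraSet(
        grid,
        mat,
        np.array([m[0] for m in meta]),
        np.array([m[1] for m in meta]),
        np.array([m[2] for m in meta]),
    )


def write_spectra_csv(path: str | Path, spectra: SpectraSet) -> None:
    """Write spectra in the wide dialect."""
    out = pd.DataFrame({"wavenumber_cm-1": spectra.wavenumber})
    for i in range(spectra.n_obs):
        name = f"{spectra.stage[i]}|{spectra.sample_id[i]}|{spectra.replicate[i]}"
        out[name] = spectra.absorbance[i]
    out.to_csv(path, index=False)
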