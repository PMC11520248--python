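"""Spectral table I/O, smoothing and scalar-probe extraction.

The denaturation experiments record three kinds of wavelength-resolved
spectra at each urea concentration: tryptophan fluorescence emission
(300-450 nm), far-UV CD (190-250 nm) and a scattering scan around 300 nm
(second-order Rayleigh scattering of 600 nm excitation).  From each spectrum
a scalar probe is extracted after a +/-5 nm moving average:

* ``I335``     - fluorescence intensity at 335 nm (tertiary-structure probe)
* ``lmax``     - wavelength of the emission maximum (red-shifts on unfolding)
* ``scatter300`` - mean signal over 300 +/- 5 nm (oligomer-size probe)
* ``CD222`` / ``CD208`` - ellipticity at 222 / 208 nm (helix content)
* ``ratio``    - 222/208 ellipticity ratio (> 1 indicates coiled-coil)

Per-concentration replicates are averaged into a ``DenaturationSeries`` and
normalized between native and unfolded plateaus before model fitting.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PROBES",
    "Spectrum",
    "DenaturationSeries",
    "KineticTrace",
    "read_spectrum_table",
    "moving_average",
    "extract_signal",
    "lambda_max",
    "rayleigh_scatter",
    "cd_ratio_222_208",
    "build_denaturation_series",
    "normalize_series",
    "normalize_kinetics",
    "flag_high_urea",
    "molar_ellipticity",
    "series_to_frame",
    "write_series_csv",
    "read_series_csv",
]

PROBES = ("fluorescence", "cd", "scattering")

#: CD 222/208 ratios above this urea concentration are flagged unusable by
#: default: urea absorbs strongly in the far UV and the 208 nm signal drowns
#: in noise at high denaturant.
CD_RATIO_UREA_CUTOFF = 4.5


@dataclass(frozen=True)
class Spectrum:
    """One wavelength-resolved measurement at a single urea concentration.

    ``values`` are in probe-native units: counts/s for fluorescence and
    scattering, (molar) ellipticity for CD.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    probe: str
    urea: float
    replicate: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D array")
        if wl.shape != vals.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.probe not in PROBES:
            raise ValueError(f"probe must be one of {PROBES}, got {self.probe!r}")
        if self.urea < 0:
            raise ValueError("urea concentration must be >= 0")

    def _grid_step(self) -> float:
        steps = np.diff(self.wavelengths)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("wavelength grid is not uniform")
        return float(steps[0]) if steps.size else 0.0


@dataclass(frozen=True)
class DenaturationSeries:
    """Extracted scalar signal versus urea with replicate statistics."""

    urea: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_rep: np.ndarray
    probe_label: str
    #: True where the point should not enter a fit (e.g. noisy high-urea
    #: 222/208 ratios, or normalized values escaping [0, 1]).
    flagged: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        urea = np.asarray(self.urea, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        n_rep = np.asarray(self.n_rep, dtype=int)
        flagged = (
            np.zeros(urea.shape, dtype=bool)
            if self.flagged is None
            else np.asarray(self.flagged, dtype=bool)
        )
        for name, arr in (("mean", mean), ("sd", sd), ("n_rep", n_rep), ("flagged", flagged)):
            if arr.shape != urea.shape:
                raise ValueError(f"{name} must match urea in length")
        if np.any(np.diff(urea) <= 0):
            raise ValueError("urea grid must be sorted ascending and unique")
        if np.any(sd < 0):
            raise ValueError("standard deviations must be >= 0")
        for name, arr in (
            ("urea", urea), ("mean", mean), ("sd", sd), ("n_rep", n_rep), ("flagged", flagged)
        ):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.urea.size)


@dataclass(frozen=True)
class KineticTrace:
    """Stopped-flow style time course at a single final urea concentration."""

    time: np.ndarray
    values: np.ndarray
    probe: str
    urea_final: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("time must be strictly increasing and positive")
        if self.probe not in PROBES:
            raise ValueError(f"probe must be one of {PROBES}")


def read_spectrum_table(
    path, probe: str, urea: float, *, replicate: int = 0, dialect: str | None = None
) -> Spectrum:
    """Read a two-column (wavelength, value) delimited text table.

    Header/comment lines are tolerated; rows are sorted by wavelength.
    Duplicate wavelengths are a hard parse error (they would silently skew
    the moving average) and the error names the offending line.
    """
    if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
        raise FileNotFoundError(path)
    text = (
        path.read_text() if hasattr(path, "read_text")
        else open(path).read() if isinstance(path, (str, os.PathLike))
        else path.read()
    )
    rows: list[tuple[float, float]] = []
    lines_of: list[int] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(dialect) if dialect else stripped.replace(",", " ").split()
        if dialect:
            parts = [p.strip() for p in parts if p.strip()]
        try:
            wl, val = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if rows:  # numeric section already started -> corrupt row
                raise ValueError(f"{path}: non-numeric data row at line {lineno}: {stripped!r}")
            continue  # header line
        rows.append((wl, val))
        lines_of.append(lineno)
    if not rows:
        raise ValueError(f"{path}: no numeric (wavelength, value) rows found")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    dup = np.flatnonzero(np.diff(arr[:, 0]) == 0)
    if dup.size:
        lineno = lines_of[order[dup[0] + 1]]
        raise ValueError(
            f"{path}: duplicate wavelength {arr[dup[0], 0]:g} nm at line {lineno}"
        )
    return Spectrum(arr[:, 0], arr[:, 1], probe=probe, urea=urea, replicate=replicate)


def moving_average(s: Spectrum, halfwidth: float = 5.0) -> Spectrum:
    """Smooth with a boxcar of +/-``halfwidth`` nm, truncated at the edges.

    Each value becomes the arithmetic mean of all grid points within
    +/-halfwidth nm.  Near the ends the window shrinks to the available
    points rather than padding, so endpoints are preserved without
    fabricating data.  Requires a uniform grid.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    step = s._grid_step()
    if halfwidth == 0 or step == 0:
        return s
    k = int(np.floor(halfwidth / step + 1e-9))
    if k == 0:
        return s
    n = s.values.size
    csum = np.concatenate(([0.0], np.cumsum(s.values)))
    idx = np.arange(n)
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return replace(s, values=smoothed)


def extract_signal(s: Spectrum, wavelength: float) -> float:
    """Value at the grid point nearest the requested wavelength.

    The instruments record on 1 nm grids, so nearest-point lookup (not
    interpolation) reproduces the reported on-grid probes exactly.
    """
    wl = s.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside measured range [{wl[0]}, {wl[-1]}] nm"
        )
    return float(s.values[np.argmin(np.abs(wl - wavelength))])


def lambda_max(s: Spectrum) -> float:
    """Wavelength of the global maximum; ties broken toward lower wavelength."""
    return float(s.wavelengths[int(np.argmax(s.values))])


def rayleigh_scatter(s: Spectrum, center: float = 300.0, halfwidth: float = 5.0) -> float:
    """Mean signal over ``center`` +/- ``halfwidth`` nm (default 300 +/- 5 nm).

    This is the second-order Rayleigh scattering readout used as the
    oligomer-assembly probe.
    """
    lo, hi = center - halfwidth, center + halfwidth
    if s.wavelengths[0] > lo or s.wavelengths[-1] < hi:
        raise ValueError(f"spectrum does not cover the [{lo}, {hi}] nm window")
    mask = (s.wavelengths >= lo - 1e-9) & (s.wavelengths <= hi + 1e-9)
    return float(np.mean(s.values[mask]))


def cd_ratio_222_208(s: Spectrum) -> float:
    """Ellipticity ratio theta(222)/theta(208); > 1 indicates coiled-coil helices.

    Raises if theta(208) vanishes - such points are unusable (the 208 nm
    signal drowns in urea absorbance at high denaturant).
    """
    v208 = extract_signal(s, 208.0)
    if v208 == 0:
        raise ZeroDivisionError(
            f"theta(208) = 0 at {s.urea:g} M urea: 222/208 ratio unusable"
        )
    return extract_signal(s, 222.0) / v208


def build_denaturation_series(points, probe_label: str) -> DenaturationSeries:
    """Average replicate scalar signals per urea concentration.

    Parameters
    ----------
    points : iterable of (urea, values)
        ``values`` is the collection of replicate signals at that
        concentration (>= 1 each).  Sample SD (ddof=1) is recorded; a single
        replicate records sd = 0.
    """
    points = list(points)
    if not points:
        raise ValueError("no data points supplied")
    by_urea: dict[float, list[float]] = {}
    for urea, vals in points:
        by_urea.setdefault(float(urea), []).extend(np.atleast_1d(vals).tolist())
    ureas = np.array(sorted(by_urea))
    means, sds, n_rep = [], [], []
    for u in ureas:
        v = np.asarray(by_urea[u], dtype=float)
        means.append(v.mean())
        sds.append(v.std(ddof=1) if v.size > 1 else 0.0)
        n_rep.append(v.size)
    return DenaturationSeries(
        urea=ureas, mean=np.array(means), sd=np.array(sds),
        n_rep=np.array(n_rep), probe_label=probe_label,
    )


def flag_high_urea(series: DenaturationSeries, cutoff: float = CD_RATIO_UREA_CUTOFF) -> DenaturationSeries:
    """Flag points above a urea cutoff as unusable.

    Applied by default to 222/208 ratio series: above ~4.5 M urea the
    208 nm CD signal is buried in urea absorbance noise, so those ratios are
    excluded from interpretation.
    """
    return DenaturationSeries(
        urea=series.urea, mean=series.mean, sd=series.sd, n_rep=series.n_rep,
        probe_label=series.probe_label, flagged=series.flagged | (series.urea > cutoff),
    )


def _plateau_mean(series: DenaturationSeries, interval) -> float:
    lo, hi = interval
    mask = (series.urea >= lo - 1e-9) & (series.urea <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"no measured concentration inside plateau [{lo}, {hi}] M")
    return float(series.mean[mask].mean())


def normalize_series(
    series: DenaturationSeries,
    native_range=(0.0, 0.5),
    unfolded_range=(6.5, 7.0),
) -> DenaturationSeries:
    """Map the series onto [0, 1] between native and unfolded plateau means.

    normalized = (x - unfolded_mean) / (native_mean - unfolded_mean), so the
    native plateau maps to ~1 and the unfolded plateau to ~0 regardless of
    signal polarity.  Values escaping [0, 1] (replicate noise) are kept but
    flagged.  SDs are scaled by the same factor.
    """
    native = _plateau_mean(series, native_range)
    unfolded = _plateau_mean(series, unfolded_range)
    span = native - unfolded
    if span == 0:
        raise ValueError("native and unfolded plateau means are equal; cannot normalize")
    mean = (series.mean - unfolded) / span
    sd = series.sd / abs(span)
    flagged = series.flagged | (mean < -1e-12) | (mean > 1 + 1e-12)
    return DenaturationSeries(
        urea=series.urea, mean=mean, sd=sd, n_rep=series.n_rep,
        probe_label=series.probe_label + "_norm", flagged=flagged,
    )


def normalize_kinetics(trace: KineticTrace, t_start: float = 0.006, t_end: float = 100.0) -> KineticTrace:
    """Affine rescaling of a kinetic trace to 1 at ``t_start`` and 0 at ``t_end``.

    The default anchors (6 ms, 100 s) skip the mixing artifact at the start
    and stop before photobleaching becomes visible.  Anchor values are taken
    at the nearest recorded time points.
    """
    if trace.time[0] > t_start or trace.time[-1] < t_end:
        raise ValueError("trace does not cover the [t_start, t_end] anchor window")
    v0 = trace.values[np.argmin(np.abs(trace.time - t_start))]
    v1 = trace.values[np.argmin(np.abs(trace.time - t_end))]
    if v0 == v1:
        raise ValueError("anchor values are equal; trace cannot be normalized")
    return replace(trace, values=(trace.values - v1) / (v0 - v1))


def molar_ellipticity(
    theta_mdeg, concentration_molar: float, pathlength_cm: float, n_residues: int
) -> np.ndarray:
    """Mean-residue molar ellipticity from raw ellipticity in millidegrees.

    [theta]_MRW = theta_mdeg / (10 * c * l * n_res) in deg cm^2 dmol^-1 per
    residue.  Optional helper; all model fitting operates on normalized
    signals, so this conversion never enters the fits.
    """
    if concentration_molar <= 0 or pathlength_cm <= 0 or n_residues < 1:
        raise ValueError("concentration, pathlength and residue count must be positive")
    return np.asarray(theta_mdeg, dtype=float) / (
        10.0 * concentration_molar * pathlength_cm * n_residues
    )


def series_to_frame(series: DenaturationSeries) -> pd.DataFrame:
    """DenaturationSeries as a tidy DataFrame (urea_M, mean, sd, n_rep, ...)."""
    return pd.DataFrame(
        {
            "urea_M": series.urea,
            "mean": series.mean,
            "sd": series.sd,
            "n_rep": series.n_rep,
            "probe_label": series.probe_label,
            "flagged": series.flagged,
        }
    )


def write_series_csv(series: DenaturationSeries, path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series_csv(path) -> DenaturationSeries:
    df = pd.read_csv(path)
    return DenaturationSeries(
        urea=df["urea_M"].to_numpy(),
        mean=df["mean"].to_numpy(),
        sd=df["sd"].to_numpy(),
        n_rep=df["n_rep"].to_numpy(),
        probe_label=str(df["probe_label"].iloc[0]),
        flagged=df["flagged"].to_numpy() if "flagged" in df else None,
    )
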