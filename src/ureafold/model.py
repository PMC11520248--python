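"""Three-state chemical denaturation equilibrium under the linear extrapolation model.

The system is an oligomeric native state N (a large barrel/rod assembly), a
folded-core intermediate I (monomer or small oligomer) and the unfolded
monomer U.  Disassembly N -> I is not modelled thermodynamically: the
fraction of protein still in the native assembly, ``fN``, is read directly
from the normalized static light-scattering signal.  The remaining protein,
``1 - fN``, partitions between I and U according to an equilibrium constant

    K(urea) = [U]/[I] = exp(-(c50 - urea) / d)

which is the linear extrapolation model (LEM) re-parameterized with the
transition midpoint ``c50`` (urea concentration where K = 1) and the width
``d = R*T / m``, where ``m`` is the LEM slope of the unfolding free energy
versus denaturant concentration.  This (c50, d) parameterization keeps the
fitted parameters nearly uncorrelated; :func:`delta_g_water` converts back
to (m, dG_H2O).

Normalized probe signals are linear in the species fractions:

    F_norm = fN + a * fI          (tryptophan fluorescence; 1 = native)
    D_norm = b * fI + fU          (CD ellipticity; 0 = native, 1 = unfolded)

with contrast ratios a = (F_I - F_U)/(F_N - F_U) and
b = (D_I - D_N)/(D_U - D_N), both expected in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "LEMParams",
    "ThreeStateParams",
    "SpeciesFractions",
    "ThermoContext",
    "equilibrium_K",
    "log_equilibrium_K",
    "delta_g_water",
    "fractions_three_state",
    "predict_three_state",
    "predict_two_state",
]

#: Molar gas constant in J mol^-1 K^-1.
GAS_CONSTANT = 8.31446261815324


@dataclass(frozen=True)
class LEMParams:
    """Linear-extrapolation-model equilibrium, midpoint/width form.

    Parameters
    ----------
    c50 : float
        Urea concentration (mol/L) at which K = [U]/[I] = 1.
    d : float
        Transition width d = R*T/m in mol/L; must be positive.
    """

    c50: float
    d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.c50) or self.c50 < 0:
            raise ValueError(f"c50 must be finite and >= 0, got {self.c50}")
        if not np.isfinite(self.d) or self.d <= 0:
            raise ValueError(f"d must be finite and > 0, got {self.d}")


@dataclass(frozen=True)
class ThreeStateParams:
    """Full parameter set of the three-state model.

    ``a`` and ``b`` are the fluorescence and CD contrast ratios of the
    intermediate relative to the bracketing states (see module docstring).
    Fitting constrains both to [0, 1] by default; the dataclass itself only
    requires finiteness so that synthetic sweeps may step outside.
    """

    lem: LEMParams
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("a and b must be finite")


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of total protein in the native, intermediate and unfolded states."""

    fN: np.ndarray
    fI: np.ndarray
    fU: np.ndarray

    def __post_init__(self) -> None:
        fN, fI, fU = (np.asarray(x, dtype=float) for x in (self.fN, self.fI, self.fU))
        total = fN + fI + fU
        if np.any(fN < -1e-12) or np.any(fI < -1e-12) or np.any(fU < -1e-12):
            raise ValueError("species fractions must be non-negative")
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("species fractions must sum to 1 within 1e-9")


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and gas constant used to convert (c50, d) to (m, dG_H2O).

    Default temperature is 293.15 K (20 degC, the measurement temperature of
    the scattering/fluorescence/CD experiments).
    """

    temperature: float = 293.15
    R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def log_equilibrium_K(lem: LEMParams, urea) -> np.ndarray:
    """ln K(urea) = -(c50 - urea)/d, safe at any urea (no overflow)."""
    urea = np.asarray(urea, dtype=float)
    if np.any(urea < 0):
        raise ValueError("urea concentrations must be >= 0")
    return (urea - lem.c50) / lem.d


def equilibrium_K(lem: LEMParams, urea) -> np.ndarray:
    """Equilibrium constant K = [U]/[I] at the given urea concentration(s).

    Strictly increasing in urea, K(c50) = 1.  Prefer
    :func:`log_equilibrium_K` plus stable logistic forms when urea is far
    above the midpoint.
    """
    return np.exp(log_equilibrium_K(lem, urea))


def delta_g_water(lem: LEMParams, ctx: ThermoContext = ThermoContext()) -> tuple[float, float]:
    """Convert (c50, d) to the LEM slope m and the zero-denaturant free energy.

    Returns
    -------
    (m, dG_H2O) : tuple of float
        m in J mol^-1 (mol/L)^-1 and dG_H2O = m * c50 in J mol^-1.
    """
    m = ctx.R * ctx.temperature / lem.d
    return m, m * lem.c50


def _logistic(x) -> np.ndarray:
    """1/(1+e^-x) evaluated stably for large |x| (works on scalars and arrays)."""
    x = np.asarray(x, dtype=float)
    ex = np.exp(-np.abs(x))  # always <= 1, never overflows
    return np.where(x >= 0, 1.0 / (1.0 + ex), ex / (1.0 + ex))


def fractions_three_state(params: ThreeStateParams, fN, urea) -> SpeciesFractions:
    """Species fractions given the native fraction and the urea concentration.

    The non-native pool 1 - fN splits as fI = (1-fN)/(1+K), fU = K*fI.
    ``fN`` must already be a valid fraction; noisy scattering values are
    clipped upstream (see :func:`ureafold.fitting.interpolate_fraction_native`).
    """
    fN = np.asarray(fN, dtype=float)
    if np.any((fN < 0) | (fN > 1)):
        raise ValueError("fN must lie in [0, 1]; clip noisy values upstream")
    logK = log_equilibrium_K(params.lem, urea)
    logK, fN = np.broadcast_arrays(logK, fN)
    # fU/(fI+fU) = K/(1+K) = logistic(ln K); stable for urea >> c50
    w_u = _logistic(logK)
    rest = 1.0 - fN
    fU = rest * w_u
    fI = rest - fU
    return SpeciesFractions(fN=fN, fI=fI, fU=fU)


def predict_three_state(params: ThreeStateParams, fN, urea) -> tuple[np.ndarray, np.ndarray]:
    """Normalized fluorescence and CD signals of the three-state model.

    F_norm = fN + a*fI (native anchor 1) and D_norm = b*fI + fU
    (native anchor 0, unfolded anchor 1).
    """
    fr = fractions_three_state(params, fN, urea)
    f_norm = fr.fN + params.a * fr.fI
    d_norm = params.b * fr.fI + fr.fU
    return f_norm, d_norm


def predict_two_state(lem: LEMParams, urea) -> tuple[np.ndarray, np.ndarray]:
    """Two-state (N' <-> U) normalized signals for non-assembling constructs.

    F_norm = 1/(1+K) and D_norm = K/(1+K); evaluated via the stable logistic
    so urea far above c50 cannot overflow.
    """
    d_norm = _logistic(log_equilibrium_K(lem, urea))
    return 1.0 - d_norm, d_norm
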