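"""Global least-squares fitting of multi-probe denaturation curves.

The three-state fit ties the normalized fluorescence and CD series together
with a single shared parameter set (c50, d, a, b), exactly as a
shared-parameter Levenberg-Marquardt global fit: the native fraction at each
concentration is pinned to the normalized scattering signal (linearly
interpolated and clipped to [0, 1]), and the joint residual vector
concatenates both probes.  Non-assembling constructs, whose scattering is
flat, are fitted with the two-state logistic instead.

A vectorized exhaustive grid search over (c50, d) - with the closed-form
optimum over (a, b) snapped to a 0.01 grid, which is exact because the
objective is quadratic in (a, b) at fixed (c50, d) - serves as a brute-force
reference path for validating the Levenberg-Marquardt optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .model import LEMParams, ThreeStateParams, fractions_three_state, predict_three_state, predict_two_state
from .spectra import DenaturationSeries

__all__ = [
    "FitResult",
    "interpolate_fraction_native",
    "fit_three_state",
    "fit_two_state",
    "species_fraction_curves",
    "grid_search_three_state",
]


@dataclass
class FitResult:
    """Converged (or not) global-fit state plus uncertainty estimates.

    Standard errors come from the Jacobian-based covariance at the optimum,
    scaled by reduced chi-square (standard Levenberg-Marquardt practice).
    """

    params: ThreeStateParams | LEMParams
    standard_errors: dict
    covariance: np.ndarray | None
    residual_ss: float
    n_obs: int
    converged: bool
    fixed_b_zero: bool = False
    n_free: int = 0
    message: str = ""
    warnings: list = field(default_factory=list)

    def param_dict(self) -> dict:
        if isinstance(self.params, ThreeStateParams):
            return {
                "c50": self.params.lem.c50, "d": self.params.lem.d,
                "a": self.params.a, "b": self.params.b,
            }
        return {"c50": self.params.c50, "d": self.params.d}

    def to_json(self, path=None) -> str:
        """Serialize the fit report (parameters, errors, covariance) to JSON."""
        payload = {
            "model": "three_state" if isinstance(self.params, ThreeStateParams) else "two_state",
            "params": self.param_dict(),
            "standard_errors": self.standard_errors,
            "covariance": None if self.covariance is None else np.asarray(self.covariance).tolist(),
            "residual_ss": self.residual_ss,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "converged": self.converged,
            "fixed_b_zero": self.fixed_b_zero,
            "message": self.message,
            "warnings": list(self.warnings),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def interpolate_fraction_native(scatter: DenaturationSeries, urea_points) -> np.ndarray:
    """Native (assembled) fraction fN at arbitrary urea points.

    Linear interpolation of the normalized scattering series, clipped to
    [0, 1] so replicate noise (e.g. a normalized value of 1.04) cannot
    produce an invalid fraction.  Extrapolation is refused.
    """
    urea_points = np.atleast_1d(np.asarray(urea_points, dtype=float))
    if urea_points.min() < scatter.urea[0] - 1e-9 or urea_points.max() > scatter.urea[-1] + 1e-9:
        raise ValueError(
            "requested urea outside the measured scattering range "
            f"[{scatter.urea[0]:g}, {scatter.urea[-1]:g}] M"
        )
    fn = np.interp(urea_points, scatter.urea, scatter.mean)
    return np.clip(fn, 0.0, 1.0)


def _check_transition(series: DenaturationSeries, what: str) -> None:
    span = float(series.mean.max() - series.mean.min())
    if span < 1e-8:
        raise ValueError(f"{what} curve is flat (span {span:.2e}); nothing to fit")


def _init_c50_from_curve(urea, signal) -> float:
    """Urea at half-amplitude of a (roughly monotone) normalized curve."""
    lo, hi = float(np.min(signal)), float(np.max(signal))
    half = 0.5 * (lo + hi)
    dist = np.abs(np.asarray(signal) - half)
    return float(urea[int(np.argmin(dist))])


def _stderr_and_cov(mini_result, names):
    errs = {}
    cov = mini_result.covar
    for name in names:
        par = mini_result.params[name]
        errs[name] = float(par.stderr) if par.stderr is not None else float("nan")
    return errs, cov


def fit_three_state(
    F: DenaturationSeries,
    D: DenaturationSeries,
    S: DenaturationSeries,
    init: ThreeStateParams | None = None,
    fix_b_zero: bool = False,
    weights: str = "none",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Globally fit (c50, d, a, b) to normalized fluorescence + CD curves.

    The native fraction at every observation is interpolated from the
    normalized scattering series ``S``; fluorescence and CD residuals are
    concatenated with equal weight (``weights="inverse_sd"`` divides each
    residual by its replicate SD instead).  Five jittered starts (seeded)
    guard against local minima; the best-residual solution is kept.

    With ``fix_b_zero`` the CD contrast of the intermediate is pinned to 0,
    i.e. the intermediate is assumed spectroscopically identical to the
    native monomer - the nested model used to test whether barrel
    disassembly alone changes the CD signal.
    """
    if weights not in ("none", "inverse_sd"):
        raise ValueError("weights must be 'none' or 'inverse_sd'")
    if len(F) < 6 or len(D) < 6:
        raise ValueError("need at least 6 concentrations per probe for a 4-parameter fit")
    _check_transition(F, "fluorescence")
    _check_transition(D, "CD")

    fn_f = interpolate_fraction_native(S, F.urea)
    fn_d = interpolate_fraction_native(S, D.urea)

    def make_weights(series):
        if weights == "none":
            return np.ones(len(series))
        sd = np.where(series.sd > 0, series.sd, np.nanmin(series.sd[series.sd > 0]) if (series.sd > 0).any() else 1.0)
        return 1.0 / sd

    f_w, d_w = make_weights(F), make_weights(D)

    if init is None:
        init = ThreeStateParams(LEMParams(_init_c50_from_curve(D.urea, D.mean), 0.5), 0.8, 0.2)

    rng = np.random.default_rng(seed)
    best = None
    urea_all_f, urea_all_d = F.urea, D.urea
    for start in range(max(1, n_starts)):
        p = lmfit.Parameters()
        jitter = (lambda s: 1.0) if start == 0 else (lambda s: float(np.exp(rng.normal(0, s))))
        p.add("c50", value=np.clip(init.lem.c50 * jitter(0.1), 0.1, 10.0), min=0.0, max=12.0)
        p.add("d", value=np.clip(init.lem.d * jitter(0.3), 0.05, 3.0), min=1e-3, max=5.0)
        p.add("a", value=float(np.clip(init.a * jitter(0.2), 0.05, 0.95)), min=0.0, max=1.0)
        if fix_b_zero:
            p.add("b", value=0.0, vary=False)
        else:
            p.add("b", value=float(np.clip(init.b * jitter(0.2), 0.05, 0.95)), min=0.0, max=1.0)
        # fn/urea pairs are bound via closure so the two probes may sit on
        # different urea grids
        def resid(pars):
            params = ThreeStateParams(
                LEMParams(pars["c50"].value, pars["d"].value), pars["a"].value, pars["b"].value
            )
            f_pred, _ = predict_three_state(params, fn_f, urea_all_f)
            _, d_pred = predict_three_state(params, fn_d, urea_all_d)
            return np.concatenate([(f_pred - F.mean) * f_w, (d_pred - D.mean) * d_w])

        mini = lmfit.Minimizer(resid, p)
        try:
            out = mini.minimize(method="leastsq")
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        ss = float(np.sum(out.residual**2))
        if best is None or ss < best[1]:
            best = (out, ss)

    if best is None:
        return FitResult(
            params=init, standard_errors={}, covariance=None, residual_ss=np.inf,
            n_obs=len(F) + len(D), converged=False, fixed_b_zero=fix_b_zero,
            message="all optimizer starts failed",
        )
    out, ss = best
    names = ["c50", "d", "a"] + ([] if fix_b_zero else ["b"])
    errs, cov = _stderr_and_cov(out, names)
    params = ThreeStateParams(
        LEMParams(out.params["c50"].value, out.params["d"].value),
        out.params["a"].value, out.params["b"].value,
    )
    warnings_ = []
    if not (F.urea.min() <= params.lem.c50 <= F.urea.max()):
        warnings_.append("fitted c50 lies outside the measured urea range")
    return FitResult(
        params=params, standard_errors=errs, covariance=cov, residual_ss=ss,
        n_obs=len(F) + len(D), converged=bool(out.success), fixed_b_zero=fix_b_zero,
        n_free=len(names), message=str(out.message), warnings=warnings_,
    )


def fit_two_state(
    curve: DenaturationSeries,
    direction: str = "native_referenced",
    init: LEMParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit the two-state logistic to a single normalized curve.

    ``direction="native_referenced"`` fits F_norm = 1/(1+K) (signal 1 at zero
    urea, e.g. normalized I335); ``"unfolded_referenced"`` fits
    D_norm = K/(1+K).
    """
    if direction not in ("native_referenced", "unfolded_referenced"):
        raise ValueError("direction must be 'native_referenced' or 'unfolded_referenced'")
    if len(curve) < 4:
        raise ValueError("need at least 4 concentrations spanning the transition")
    _check_transition(curve, "two-state")

    if init is None:
        init = LEMParams(_init_c50_from_curve(curve.urea, curve.mean), 0.5)

    def resid(pars):
        f_pred, d_pred = predict_two_state(LEMParams(pars["c50"].value, pars["d"].value), curve.urea)
        pred = f_pred if direction == "native_referenced" else d_pred
        return pred - curve.mean

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        p = lmfit.Parameters()
        jitter = (lambda s: 1.0) if start == 0 else (lambda s: float(np.exp(rng.normal(0, s))))
        p.add("c50", value=np.clip(init.c50 * jitter(0.1), 0.1, 10.0), min=0.0, max=12.0)
        p.add("d", value=np.clip(init.d * jitter(0.3), 0.05, 3.0), min=1e-3, max=5.0)
        try:
            out = lmfit.Minimizer(resid, p).minimize(method="leastsq")
        except Exception:  # noqa: BLE001
            continue
        ss = float(np.sum(out.residual**2))
        if best is None or ss < best[1]:
            best = (out, ss)
    if best is None:
        return FitResult(
            params=init, standard_errors={}, covariance=None, residual_ss=np.inf,
            n_obs=len(curve), converged=False, message="all optimizer starts failed",
        )
    out, ss = best
    errs, cov = _stderr_and_cov(out, ["c50", "d"])
    params = LEMParams(out.params["c50"].value, out.params["d"].value)
    warnings_ = []
    converged = bool(out.success)
    if not (curve.urea.min() <= params.c50 <= curve.urea.max()):
        warnings_.append("fitted c50 lies outside the measured urea range; midpoint not identified")
    return FitResult(
        params=params, standard_errors=errs, covariance=cov, residual_ss=ss,
        n_obs=len(curve), converged=converged, n_free=2,
        message=str(out.message), warnings=warnings_,
    )


def species_fraction_curves(
    result: FitResult, S: DenaturationSeries, urea_grid
) -> pd.DataFrame:
    """Tabulate (urea, fN, fI, fU) from a converged three-state fit.

    fN is the interpolated normalized scattering; I/U partition the rest via
    the fitted equilibrium.  Rows sum to 1 by construction.
    """
    if not result.converged:
        raise ValueError("fit did not converge; species curves would be meaningless")
    if not isinstance(result.params, ThreeStateParams):
        raise TypeError("species_fraction_curves requires a three-state FitResult")
    urea_grid = np.atleast_1d(np.asarray(urea_grid, dtype=float))
    fn = interpolate_fraction_native(S, urea_grid)
    fr = fractions_three_state(result.params, fn, urea_grid)
    return pd.DataFrame({"urea_M": urea_grid, "fN": fr.fN, "fI": fr.fI, "fU": fr.fU})


def grid_search_three_state(
    F: DenaturationSeries,
    D: DenaturationSeries,
    S: DenaturationSeries,
    c50_grid=None,
    d_grid=None,
    ab_step: float = 0.01,
) -> tuple[ThreeStateParams, float]:
    """Exhaustive-grid reference optimum for the three-state objective.

    Scans (c50, d) over dense grids; at each node the unweighted objective is
    quadratic in a and in b separately, so the constrained optimum over the
    0.01-step (a, b) grid is found exactly by rounding the clipped
    closed-form minimizer to its two neighbouring grid values and keeping the
    better one.  Equivalent to (but vastly cheaper than) the full 4-D scan.
    Intended as a brute-force cross-check of the Levenberg-Marquardt path.
    """
    c50_grid = np.arange(1.0, 5.0 + 1e-9, 0.01) if c50_grid is None else np.asarray(c50_grid)
    d_grid = np.arange(0.10, 1.50 + 1e-9, 0.01) if d_grid is None else np.asarray(d_grid)
    fn_f = interpolate_fraction_native(S, F.urea)
    fn_d = interpolate_fraction_native(S, D.urea)

    # shapes: (nc, nd, nu)
    uf = F.urea[None, None, :]
    ud = D.urea[None, None, :]
    c = c50_grid[:, None, None]
    d = d_grid[None, :, None]
    wU_f = 1.0 / (1.0 + np.exp(-np.clip((uf - c) / d, -500, 500)))
    wU_d = 1.0 / (1.0 + np.exp(-np.clip((ud - c) / d, -500, 500)))
    fI_f = (1.0 - fn_f) * (1.0 - wU_f)
    fI_d = (1.0 - fn_d) * (1.0 - wU_d)
    fU_d = (1.0 - fn_d) * wU_d

    ab_grid = np.round(np.arange(0.0, 1.0 + 1e-9, ab_step), 10)

    def best_linear(x, target):
        """min over gridded t of sum((t*x - target)^2), vectorized over (nc, nd)."""
        xx = np.sum(x * x, axis=-1)
        xt = np.sum(x * target, axis=-1)
        t_star = np.where(xx > 0, xt / np.where(xx > 0, xx, 1.0), 0.0)
        t_star = np.clip(t_star, ab_grid[0], ab_grid[-1])
        lo = np.clip(np.floor(t_star / ab_step) * ab_step, ab_grid[0], ab_grid[-1])
        hi = np.clip(lo + ab_step, ab_grid[0], ab_grid[-1])
        tt = np.sum(target * target, axis=-1)
        ss_lo = tt - 2 * lo * xt + lo**2 * xx
        ss_hi = tt - 2 * hi * xt + hi**2 * xx
        t_best = np.where(ss_lo <= ss_hi, lo, hi)
        return t_best, np.minimum(ss_lo, ss_hi)

    a_best, ss_f = best_linear(fI_f, F.mean[None, None, :] - fn_f[None, None, :])
    b_best, ss_d = best_linear(fI_d, D.mean[None, None, :] - fU_d)
    ss = ss_f + ss_d
    i, j = np.unravel_index(int(np.argmin(ss)), ss.shape)
    params = ThreeStateParams(
        LEMParams(float(c50_grid[i]), float(d_grid[j])),
        float(a_best[i, j]), float(b_best[i, j]),
    )
    return params, float(ss[i, j])
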