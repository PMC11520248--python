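"""Synthetic denaturation datasets with the statistical structure the analysis assumes.

No raw spectroscopic data are deposited for the urea titrations this package
analyzes, so every downstream stage is exercised on forward-simulated data:

* a scattering profile that decays linearly from its 0 M level to a 6-fold
  lower plateau at 3.5 M urea (continuous disassembly of a heterogeneous
  barrel/stack population; no single sigmoidal transition);
* fluorescence and CD titration curves generated by the three-state model,
  with the native fraction taken from the noiseless scattering profile and a
  sigmoidal I <-> U transition near 3 M urea;
* full emission and CD spectra whose scalar probes (I335, lambda_max,
  theta_222...) reproduce those curves: emission is a population-weighted
  mixture of Gaussian bands at 335 nm (folded) and 344 nm (unfolded), CD a
  mixture of a helix-like basis (minima at 208 and 222 nm) and a coil-like
  basis (single negative band near 200 nm);
* additive Gaussian replicate noise, three replicates, fully seeded.

Default truth (c50 = 3.0 M, a = 0.81, b = 0.24) mirrors the fitted values
reported for the wild-type oligomer; d defaults to 0.45 M, which places the
visible I -> U transition between roughly 2.5 and 4.5 M urea.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import LEMParams, ThreeStateParams, predict_three_state
from .spectra import DenaturationSeries, KineticTrace, Spectrum, build_denaturation_series

__all__ = [
    "SpeciesSignals",
    "GeneratorConfig",
    "generate_scattering_profile",
    "generate_denaturation_dataset",
    "generate_spectra_set",
    "exponential_trace",
    "default_config",
]


@dataclass(frozen=True)
class SpeciesSignals:
    """Specific (per-state) raw signal levels used to de-normalize the model.

    Fluorescence drops on unfolding (F_N > F_U); the intermediate and
    unfolded states scatter identically (S_IU), about six-fold below the
    assembled oligomer (S_N).  The implied contrast ratios
    a = (F_I-F_U)/(F_N-F_U) and b = (D_I-D_N)/(D_U-D_N) must be finite.
    """

    F_N: float = 1.0e6
    F_I: float = 0.848e6
    F_U: float = 0.2e6
    D_N: float = -22.0
    D_I: float = -17.9
    D_U: float = -5.0
    S_N: float = 6.0e5
    S_IU: float = 1.0e5

    def __post_init__(self) -> None:
        if not self.F_N > self.F_U:
            raise ValueError("fluorescence must drop on unfolding (F_N > F_U)")
        if not self.S_N > self.S_IU:
            raise ValueError("the assembled oligomer must scatter more (S_N > S_IU)")

    @property
    def a(self) -> float:
        return (self.F_I - self.F_U) / (self.F_N - self.F_U)

    @property
    def b(self) -> float:
        return (self.D_I - self.D_N) / (self.D_U - self.D_N)

    @classmethod
    def from_contrasts(cls, a: float, b: float, **kwargs) -> "SpeciesSignals":
        """Build signal levels whose implied contrast ratios are exactly (a, b)."""
        base = cls(**kwargs)
        F_I = base.F_U + a * (base.F_N - base.F_U)
        D_I = base.D_N + b * (base.D_U - base.D_N)
        return replace(base, F_I=F_I, D_I=D_I)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a simulated titration (grid, truth, noise, seed)."""

    truth: ThreeStateParams
    signals: SpeciesSignals
    urea_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 7.0 + 1e-9, 0.5))
    scatter_breakpoint: float = 3.5
    #: relative (fraction of the signal span) SD of the additive Gaussian
    #: replicate noise, per probe
    noise_sd: dict = field(default_factory=lambda: {"scattering": 0.05, "fluorescence": 0.03, "cd": 0.04})
    n_rep: int = 3
    seed: int = 0
    lambda_native: float = 335.0
    lambda_unfolded: float = 344.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.urea_grid, dtype=float)
        object.__setattr__(self, "urea_grid", grid)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("urea grid must be sorted ascending, unique")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")


def default_config(seed: int = 0, noise: bool = True, **overrides) -> GeneratorConfig:
    """Default study conditions: truth (c50=3.0, d=0.45, a=0.81, b=0.24),
    0-7 M in 0.5 M steps, 3 replicates, per-probe noise (or none)."""
    truth = ThreeStateParams(LEMParams(3.0, 0.45), 0.81, 0.24)
    signals = SpeciesSignals.from_contrasts(truth.a, truth.b)
    cfg = dict(
        truth=truth,
        signals=signals,
        noise_sd={"scattering": 0.05, "fluorescence": 0.03, "cd": 0.04}
        if noise else {"scattering": 0.0, "fluorescence": 0.0, "cd": 0.0},
        seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def _fraction_native_noiseless(cfg: GeneratorConfig, urea: np.ndarray) -> np.ndarray:
    """Piecewise-linear native fraction: 1 at 0 M, 0 at/after the breakpoint."""
    return np.clip(1.0 - urea / cfg.scatter_breakpoint, 0.0, 1.0)


def _scatter_mean(cfg: GeneratorConfig, urea: np.ndarray) -> np.ndarray:
    fn = _fraction_native_noiseless(cfg, urea)
    return cfg.signals.S_IU + (cfg.signals.S_N - cfg.signals.S_IU) * fn


def generate_scattering_profile(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> DenaturationSeries:
    """Raw scattering titration: linear decay to a ~6-fold lower plateau.

    The noiseless mean falls linearly from S_N at 0 M urea to S_IU at the
    breakpoint (default 3.5 M) and stays constant beyond; Gaussian replicate
    noise is added per replicate, scaled to the S_N - S_IU span.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    mean = _scatter_mean(cfg, cfg.urea_grid)
    sd = cfg.noise_sd["scattering"] * (cfg.signals.S_N - cfg.signals.S_IU)
    points = [
        (u, m + rng.normal(0.0, sd, size=cfg.n_rep) if sd > 0 else np.full(cfg.n_rep, m))
        for u, m in zip(cfg.urea_grid, mean)
    ]
    return build_denaturation_series(points, "scatter300")


def generate_denaturation_dataset(cfg: GeneratorConfig):
    """Forward-simulate the full (S, F, D) triplet plus the truth record.

    The native fraction is the *noiseless* normalized scattering; normalized
    model predictions are rescaled into raw units via the per-state signal
    levels, then noised and replicated.  Returns
    ``(scatter, fluorescence, cd, truth)`` where ``truth`` records every
    generating parameter.
    """
    rng = np.random.default_rng(cfg.seed)
    scatter = generate_scattering_profile(cfg, rng)

    fn = _fraction_native_noiseless(cfg, cfg.urea_grid)
    f_norm, d_norm = predict_three_state(cfg.truth, fn, cfg.urea_grid)
    sig = cfg.signals
    f_raw = sig.F_U + f_norm * (sig.F_N - sig.F_U)
    d_raw = sig.D_N + d_norm * (sig.D_U - sig.D_N)

    f_sd = cfg.noise_sd["fluorescence"] * (sig.F_N - sig.F_U)
    d_sd = cfg.noise_sd["cd"] * abs(sig.D_U - sig.D_N)
    f_points = [
        (u, m + rng.normal(0.0, f_sd, size=cfg.n_rep) if f_sd > 0 else np.full(cfg.n_rep, m))
        for u, m in zip(cfg.urea_grid, f_raw)
    ]
    d_points = [
        (u, m + rng.normal(0.0, d_sd, size=cfg.n_rep) if d_sd > 0 else np.full(cfg.n_rep, m))
        for u, m in zip(cfg.urea_grid, d_raw)
    ]
    F = build_denaturation_series(f_points, "I335")
    D = build_denaturation_series(d_points, "CD222")
    truth = {
        "c50": cfg.truth.lem.c50, "d": cfg.truth.lem.d,
        "a": cfg.truth.a, "b": cfg.truth.b,
        "signals": sig, "scatter_breakpoint": cfg.scatter_breakpoint,
        "noise_sd": dict(cfg.noise_sd), "n_rep": cfg.n_rep, "seed": cfg.seed,
        "fraction_native": fn, "urea_grid": cfg.urea_grid,
        "f_norm": f_norm, "d_norm": d_norm,
    }
    return scatter, F, D, truth


def generate_normalized_dataset(cfg: GeneratorConfig):
    """Forward-simulate the (S, F, D) triplet directly in normalized units.

    The noiseless means are exactly the model curves (fN from the piecewise
    scattering profile, F_norm/D_norm from the three-state prediction), so a
    zero-noise dataset round-trips through the global fit to the generating
    parameters at optimizer precision.  ``noise_sd`` entries are absolute
    SDs here, since every normalized span is 1.  Returns
    ``(S, F, D, truth)`` like :func:`generate_denaturation_dataset`.
    """
    rng = np.random.default_rng(cfg.seed)
    fn = _fraction_native_noiseless(cfg, cfg.urea_grid)
    f_norm, d_norm = predict_three_state(cfg.truth, fn, cfg.urea_grid)

    def noised(mean, sd, label):
        points = [
            (u, m + rng.normal(0.0, sd, size=cfg.n_rep) if sd > 0 else np.full(cfg.n_rep, m))
            for u, m in zip(cfg.urea_grid, mean)
        ]
        return build_denaturation_series(points, label)

    S = noised(fn, cfg.noise_sd["scattering"], "scatter300_norm")
    F = noised(f_norm, cfg.noise_sd["fluorescence"], "I335_norm")
    D = noised(d_norm, cfg.noise_sd["cd"], "Dnorm")
    truth = {
        "c50": cfg.truth.lem.c50, "d": cfg.truth.lem.d,
        "a": cfg.truth.a, "b": cfg.truth.b,
        "scatter_breakpoint": cfg.scatter_breakpoint,
        "noise_sd": dict(cfg.noise_sd), "n_rep": cfg.n_rep, "seed": cfg.seed,
        "fraction_native": fn, "urea_grid": cfg.urea_grid,
        "f_norm": f_norm, "d_norm": d_norm,
    }
    return S, F, D, truth


def _emission_band(wl: np.ndarray, center: float, width: float = 18.0) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _cd_helix_basis(wl: np.ndarray) -> np.ndarray:
    """Helix-like CD shape: comparable negative bands at 208 and 222 nm on a
    positive short-wavelength lobe (the familiar alpha-helix double minimum)."""
    return (
        -1.0 * np.exp(-0.5 * ((wl - 208.0) / 4.5) ** 2)
        - 1.0 * np.exp(-0.5 * ((wl - 222.0) / 5.0) ** 2)
        + 1.2 * np.exp(-0.5 * ((wl - 192.0) / 5.0) ** 2)
    )


def _cd_coil_basis(wl: np.ndarray) -> np.ndarray:
    """Coil-like CD shape: one deep negative band near 200 nm with a weak
    negative tail through 222 nm."""
    return -1.0 * np.exp(-0.5 * ((wl - 200.0) / 9.0) ** 2) - 0.05 * np.exp(
        -0.5 * ((wl - 222.0) / 15.0) ** 2
    )


def _smoothed_at(wl: np.ndarray, shape: np.ndarray, target: float, halfwidth: float = 5.0) -> float:
    mask = np.abs(wl - target) <= halfwidth + 1e-9
    return float(shape[mask].mean())


def generate_spectra_set(cfg: GeneratorConfig, smooth_halfwidth: float = 5.0):
    """Full per-urea, per-replicate emission and CD spectra.

    Emission (300-450 nm, 1 nm) is a linear mixture of pure-folded and
    pure-unfolded Gaussian bands at ``lambda_native`` / ``lambda_unfolded``.
    Each pure-state band is scaled so that a +/-5 nm moving average followed
    by extraction at 335 nm returns exactly F_N (pure folded) or F_U (pure
    unfolded); since smoothing and extraction are linear, the preprocessed
    I335 of any mixture reproduces the scalar fluorescence curve exactly at
    zero noise.  CD spectra (190-250 nm, 1 nm) mix a helix-like basis
    (minima at 208 and 222 nm) and a coil-like basis (single negative band
    near 200 nm), scaled the same way against theta(222), so the
    preprocessed CD222 curve matches the scalar series.  Returns
    ``(emission, cd)`` lists of :class:`Spectrum`.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    fn = _fraction_native_noiseless(cfg, cfg.urea_grid)
    f_norm, d_norm = predict_three_state(cfg.truth, fn, cfg.urea_grid)
    sig = cfg.signals

    wl_em = np.arange(300.0, 450.0 + 1e-9, 1.0)
    wl_cd = np.arange(190.0, 250.0 + 1e-9, 1.0)
    band_n = _emission_band(wl_em, cfg.lambda_native)
    band_u = _emission_band(wl_em, cfg.lambda_unfolded)
    em_native = sig.F_N / _smoothed_at(wl_em, band_n, 335.0, smooth_halfwidth) * band_n
    em_unfolded = sig.F_U / _smoothed_at(wl_em, band_u, 335.0, smooth_halfwidth) * band_u

    helix = _cd_helix_basis(wl_cd)
    coil = _cd_coil_basis(wl_cd)
    cd_native = sig.D_N / _smoothed_at(wl_cd, helix, 222.0, smooth_halfwidth) * helix
    cd_unfolded = sig.D_U / _smoothed_at(wl_cd, coil, 222.0, smooth_halfwidth) * coil

    f_sd = cfg.noise_sd["fluorescence"] * (sig.F_N - sig.F_U)
    d_sd = cfg.noise_sd["cd"] * abs(sig.D_U - sig.D_N)

    emission, cd = [], []
    for i, u in enumerate(cfg.urea_grid):
        # mixture weight of the folded emission band: by linearity the
        # smoothed I335 then equals F_U + f_norm*(F_N - F_U)
        em_mean = f_norm[i] * em_native + (1.0 - f_norm[i]) * em_unfolded
        helix_w = 1.0 - d_norm[i]  # 1 = fully helical (native), 0 = coil
        cd_mean = helix_w * cd_native + (1.0 - helix_w) * cd_unfolded
        for rep in range(cfg.n_rep):
            em = em_mean + (rng.normal(0.0, f_sd, size=wl_em.size) if f_sd > 0 else 0.0)
            cdv = cd_mean + (rng.normal(0.0, d_sd, size=wl_cd.size) if d_sd > 0 else 0.0)
            emission.append(Spectrum(wl_em, em, probe="fluorescence", urea=u, replicate=rep))
            cd.append(Spectrum(wl_cd, cdv, probe="cd", urea=u, replicate=rep))
    return emission, cd


def exponential_trace(
    urea_final: float,
    rate: float = 0.5,
    amplitude: float = 40.0,
    baseline: float = 10.0,
    t_min: float = 0.002,
    t_max: float = 200.0,
    n: int = 400,
    probe: str = "fluorescence",
) -> KineticTrace:
    """Single-exponential decay helper for exercising kinetic normalization.

    Not a physical model of the disassembly kinetics (none is fitted here);
    simply value(t) = baseline + amplitude * exp(-rate * t) on a log time grid.
    """
    t = np.geomspace(t_min, t_max, n)
    return KineticTrace(
        time=t, values=baseline + amplitude * np.exp(-rate * t),
        probe=probe, urea_final=urea_final,
    )
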