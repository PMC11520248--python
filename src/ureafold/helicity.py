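"""Dihedral-window secondary-structure statistics for coarse-grained trajectories.

A residue is in *helical form* in a frame when its backbone dihedrals fall in
the open windows -160 deg < phi < -20 deg and -120 deg < psi < 50 deg.  It is
part of an *alpha-helix* when it and both sequence neighbours are in helical
form (so chain termini are never alpha-helical).  The *helical propensity* of
a residue is the fraction of frames in which it is part of an alpha-helix;
frames with missing dihedrals count as non-helical rather than being dropped,
keeping the denominator equal to the total frame count.

Also provided: the backbone hydrogen-bond potential of the coarse-grained
force field used for in-silico denaturation,

    V(r, thN, thC) = lambda * eps_hb * (5 (s/r)^12 - 6 (s/r)^10)
                     * cos^2(thN) * cos^2(thC)        for |thN|, |thC| < 90 deg

and zero outside that angular domain.  The prefactor lambda <= 1 scales the
hydrogen-bond strength to mimic urea; at r = s and aligned angles the well
depth is -lambda * eps_hb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PHI_WINDOW",
    "PSI_WINDOW",
    "DihedralSeries",
    "HelicityProfile",
    "HBondParams",
    "dihedral_angle",
    "compute_dihedrals",
    "is_helical_form",
    "assign_alpha_helix",
    "helical_propensity_profile",
    "region_helicity",
    "hbond_potential",
    "ideal_helix_backbone",
    "read_dihedral_table",
]

#: Open (phi, psi) windows in degrees defining "helical form".
PHI_WINDOW = (-160.0, -20.0)
PSI_WINDOW = (-120.0, 50.0)


def _wrap_degrees(angle: np.ndarray) -> np.ndarray:
    """Normalize angles to (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(a == -180.0, 180.0, a)


@dataclass(frozen=True)
class DihedralSeries:
    """Per-frame, per-residue backbone dihedrals in degrees.

    Undefined angles (chain termini, missing atoms, degenerate geometry) are
    NaN.  Angles are wrapped to (-180, 180] on construction.
    """

    phi: np.ndarray
    psi: np.ndarray
    residue_ids: np.ndarray = None

    def __post_init__(self) -> None:
        phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if phi.shape != psi.shape:
            raise ValueError("phi and psi must have identical (frames, residues) shapes")
        object.__setattr__(self, "phi", _wrap_degrees(phi))
        object.__setattr__(self, "psi", _wrap_degrees(psi))
        rid = (
            np.arange(1, phi.shape[1] + 1)
            if self.residue_ids is None
            else np.asarray(self.residue_ids, dtype=int)
        )
        if rid.size != phi.shape[1]:
            raise ValueError("residue_ids length must equal the residue dimension")
        object.__setattr__(self, "residue_ids", rid)

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


@dataclass(frozen=True)
class HelicityProfile:
    """Per-residue fraction of frames spent in an alpha-helix."""

    propensity: np.ndarray
    n_frames: int
    residue_ids: np.ndarray = None

    def __post_init__(self) -> None:
        p = np.asarray(self.propensity, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("propensities must lie in [0, 1]")
        object.__setattr__(self, "propensity", p)
        rid = (
            np.arange(1, p.size + 1) if self.residue_ids is None
            else np.asarray(self.residue_ids, dtype=int)
        )
        object.__setattr__(self, "residue_ids", rid)


@dataclass(frozen=True)
class HBondParams:
    """Backbone H-bond potential parameters (lambda is the denaturation prefactor)."""

    lam: float = 1.0
    epsilon_hb: float = 1.0
    sigma_hb: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.lam <= 1):
            raise ValueError("lambda prefactor must lie in (0, 1]")
        if self.epsilon_hb <= 0 or self.sigma_hb <= 0:
            raise ValueError("epsilon_hb and sigma_hb must be positive")


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees) of four points; NaN for degenerate geometry.

    Vectorized over leading axes (inputs broadcast as (..., 3) arrays).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b1, axis=-1) / np.where(b1n > 0, b1n, 1.0)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    bad = (norm1 < 1e-10) | (norm2 < 1e-10) | (b1n < 1e-10)
    return np.where(bad, np.nan, ang)


def compute_dihedrals(backbone_coords) -> DihedralSeries:
    """Backbone phi/psi from (frames, residues, 3 atoms [N, CA, C'], xyz).

    phi(i) is the C'(i-1)-N(i)-CA(i)-C'(i) torsion, psi(i) the
    N(i)-CA(i)-C'(i)-N(i+1) torsion; both are NaN at the respective chain
    terminus.  Residues with missing (NaN) atoms yield NaN dihedrals - they
    are marked missing, never silently dropped.
    """
    xyz = np.asarray(backbone_coords, dtype=float)
    if xyz.ndim == 3:
        xyz = xyz[None]
    if xyz.ndim != 4 or xyz.shape[2] != 3 or xyz.shape[3] != 3:
        raise ValueError("expected coordinates shaped (frames, residues, 3 atoms, xyz)")
    n_res = xyz.shape[1]
    if n_res < 3:
        raise ValueError("need at least 3 consecutive residues")
    N, CA, C = xyz[:, :, 0], xyz[:, :, 1], xyz[:, :, 2]
    phi = np.full(xyz.shape[:2], np.nan)
    psi = np.full(xyz.shape[:2], np.nan)
    phi[:, 1:] = dihedral_angle(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
    psi[:, :-1] = dihedral_angle(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    return DihedralSeries(phi=phi, psi=psi)


def is_helical_form(phi, psi) -> np.ndarray:
    """True where both dihedrals fall inside the open helical windows.

    Missing (NaN) angles are never helical.  Window boundaries are open; the
    choice is measure-zero but fixed for reproducibility.
    """
    phi = _wrap_degrees(phi)
    psi = _wrap_degrees(psi)
    ok_phi = (phi > PHI_WINDOW[0]) & (phi < PHI_WINDOW[1])
    ok_psi = (psi > PSI_WINDOW[0]) & (psi < PSI_WINDOW[1])
    return np.asarray(ok_phi & ok_psi)


def assign_alpha_helix(form_flags) -> np.ndarray:
    """Triplet rule: residue i is alpha-helical iff i-1, i, i+1 are all in
    helical form.  Works on a single frame (1-D) or a (frames, residues)
    stack; terminal residues are never alpha-helical.
    """
    flags = np.asarray(form_flags, dtype=bool)
    squeeze = flags.ndim == 1
    flags = np.atleast_2d(flags)
    out = np.zeros_like(flags)
    if flags.shape[1] >= 3:
        out[:, 1:-1] = flags[:, :-2] & flags[:, 1:-1] & flags[:, 2:]
    return out[0] if squeeze else out


def helical_propensity_profile(series: DihedralSeries) -> HelicityProfile:
    """Fraction of frames each residue spends in an alpha-helix.

    The denominator is the total frame count: frames where a residue's
    dihedrals are missing count as non-helical.
    """
    if series.n_frames < 1:
        raise ValueError("need at least one frame")
    form = is_helical_form(series.phi, series.psi)
    helix = assign_alpha_helix(form)
    return HelicityProfile(
        propensity=helix.mean(axis=0), n_frames=series.n_frames,
        residue_ids=series.residue_ids,
    )


def region_helicity(profile: HelicityProfile, regions: dict) -> dict:
    """Unweighted mean propensity per named residue-range region.

    ``regions`` maps names to inclusive 1-based (start, stop) residue-id
    ranges, e.g. ``{"a0_3": (1, 156), "a4_6": (157, 267)}``.
    """
    out = {}
    rid = profile.residue_ids
    for name, (start, stop) in regions.items():
        mask = (rid >= start) & (rid <= stop)
        if not mask.any():
            raise ValueError(f"region {name!r} ({start}-{stop}) matches no residues")
        if start < rid.min() or stop > rid.max():
            raise ValueError(f"region {name!r} ({start}-{stop}) extends beyond the chain")
        out[name] = float(profile.propensity[mask].mean())
    return out


def hbond_potential(r, params: HBondParams, theta_N=0.0, theta_C=0.0) -> np.ndarray:
    """Backbone H-bond potential V(r, theta_N, theta_C); zero outside |theta| < 90 deg.

    The radial 12-10 term equals -1 at r = sigma_hb, so the well depth at
    aligned angles is -lambda * epsilon_hb.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    theta_N = np.asarray(theta_N, dtype=float)
    theta_C = np.asarray(theta_C, dtype=float)
    sr = params.sigma_hb / r
    radial = 5.0 * sr**12 - 6.0 * sr**10
    angular = np.cos(np.radians(theta_N)) ** 2 * np.cos(np.radians(theta_C)) ** 2
    inside = (np.abs(theta_N) < 90.0) & (np.abs(theta_C) < 90.0)
    v = params.lam * params.epsilon_hb * radial * angular
    return np.where(inside, v, 0.0)


# -- ideal helix generator (synthetic trajectory input) ----------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d given three predecessors and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_helix_backbone(
    n_residues: int, phi: float = -57.0, psi: float = -47.0, omega: float = 180.0
) -> np.ndarray:
    """Backbone N/CA/C coordinates of an ideal helix, shape (n_residues, 3, 3).

    Built atom-by-atom from canonical bond lengths/angles with the requested
    (phi, psi, omega) torsions, so :func:`compute_dihedrals` on the result
    round-trips to the requested angles exactly (interior residues).
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    atoms = [
        np.array([0.0, 0.0, 0.0]),
        np.array([_BOND_N_CA, 0.0, 0.0]),
    ]
    # first C via the N-CA-C angle in the z=0 plane
    ang = np.radians(180.0 - _ANG_N_CA_C)
    atoms.append(atoms[1] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]))
    # torsion sequence from here on: psi (places next N), omega (next CA),
    # phi (next C), repeating
    seq = [
        (_BOND_C_N, _ANG_CA_C_N, psi),
        (_BOND_N_CA, _ANG_C_N_CA, omega),
        (_BOND_CA_C, _ANG_N_CA_C, phi),
    ]
    while len(atoms) < 3 * n_residues:
        bond, angle, torsion = seq[(len(atoms)) % 3]
        atoms.append(_place_atom(atoms[-3], atoms[-2], atoms[-1], bond, angle, torsion))
    return np.asarray(atoms).reshape(n_residues, 3, 3)


def read_dihedral_table(path) -> DihedralSeries:
    """Read a long-format delimited table with columns frame, residue, phi, psi.

    Accepts CSV or whitespace-delimited text with a header line.  Missing
    (frame, residue) combinations become NaN dihedrals.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"frame", "residue", "phi", "psi"}
    if not required <= set(df.columns):
        raise ValueError(f"dihedral table must have columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    residues = np.sort(df["residue"].unique())
    fidx = {f: i for i, f in enumerate(frames)}
    ridx = {r: j for j, r in enumerate(residues)}
    phi = np.full((frames.size, residues.size), np.nan)
    psi = np.full((frames.size, residues.size), np.nan)
    for row in df.itertuples(index=False):
        i, j = fidx[row.frame], ridx[row.residue]
        phi[i, j] = row.phi
        psi[i, j] = row.psi
    return DihedralSeries(phi=phi, psi=psi, residue_ids=residues.astype(int))
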