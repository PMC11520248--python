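"""Shrake-Rupley solvent-accessible surface area and the Trp-indole burial comparison.

The tertiary-structure probe of the denaturation experiments is a single
tryptophan sitting inside the coiled-coil hairpin of each protomer; in the
assembled barrel it is additionally buried in a pocket formed by neighbouring
protomers.  Comparing the SASA of the Trp indole ring in three nested atomic
contexts - the full assembly, one chain's coiled-coil hairpin, and the
Trp-bearing helix alone - quantifies how much solvent exposure the residue
gains at each disassembly/unfolding step, which is what links the observed
fluorescence red-shift to coiled-coil unwinding rather than barrel
disassembly.

SASA is computed with the Shrake-Rupley algorithm: a deterministic
golden-spiral point set on each atom's solvent-expanded sphere, points
removed if inside any neighbour's expanded sphere, area proportional to the
surviving fraction.  Defaults: probe 1.4 Angstrom, 960 points/atom, standard
heavy-atom van der Waals radii (hydrogens are typically absent from cryo-EM
models and are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "INDOLE_ATOMS",
    "AtomSet",
    "shrake_rupley",
    "trp_indole_sasa",
    "reference_indole_sasa",
    "build_synthetic_trp_pocket",
]

#: Standard heavy-atom van der Waals radii in Angstrom (Bondi-type set).
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20,
}
DEFAULT_RADIUS = 1.70

#: The nine atoms of the tryptophan indole ring.
INDOLE_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass(frozen=True)
class AtomSet:
    """Flat atom table: coordinates plus the identifiers needed for selection."""

    coords: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        for name in ("elements", "atom_names", "res_names", "chain_ids"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype="U6"))
        object.__setattr__(self, "res_ids", np.asarray(self.res_ids, dtype=int))
        n = coords.shape[0]
        for name in ("elements", "atom_names", "res_ids", "res_names", "chain_ids"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} must have one entry per atom")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in self.elements])

    def select(self, mask) -> "AtomSet":
        return AtomSet(
            self.coords[mask], self.elements[mask], self.atom_names[mask],
            self.res_ids[mask], self.res_names[mask], self.chain_ids[mask],
        )

    @classmethod
    def from_atom_array(cls, arr) -> "AtomSet":
        """Build from a biotite AtomArray (hydrogens dropped)."""
        mask = ~np.isin(np.char.upper(arr.element.astype("U2")), ("H", "D"))
        arr = arr[mask]
        return cls(
            coords=arr.coord, elements=arr.element, atom_names=arr.atom_name,
            res_ids=arr.res_id, res_names=arr.res_name, chain_ids=arr.chain_id,
        )

    @classmethod
    def from_pdb(cls, path, model: int = 1) -> "AtomSet":
        """Read a (multi-chain, single-model) PDB file via biotite."""
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        return cls.from_atom_array(pdb.get_structure(model=model))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) point set on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley(
    atoms: AtomSet, probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Angstrom^2.

    Each atom's expanded sphere (vdW + probe) is sampled with ``n_points``
    golden-spiral points; a point survives if it lies outside every
    neighbour's expanded sphere (strictly inside, with a 1e-9 tolerance,
    removes it - so exactly coincident identical atoms each keep their full
    sphere).  Area = 4 pi (r+w)^2 * surviving fraction.
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    if probe_radius < 0 or n_points < 1:
        raise ValueError("probe_radius must be >= 0 and n_points >= 1")
    radii = atoms.radii() + probe_radius
    coords = atoms.coords
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            buried = (d2 < (radii[neigh][None, :] - 1e-9) ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas


_CONTEXTS = ("full_assembly", "coiled_coil_chain", "single_helix")


def trp_indole_sasa(
    structure: AtomSet,
    chain: str,
    residue: int,
    context: str = "full_assembly",
    coiled_coil_range: tuple = (26, 156),
    helix_range: tuple = (26, 92),
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Summed SASA (Angstrom^2) of the nine indole-ring atoms of one Trp.

    ``context`` selects the occluding atom set:

    * ``full_assembly``     - every atom in the structure (the barrel);
    * ``coiled_coil_chain`` - the target chain's residues in
      ``coiled_coil_range`` (default 26-156, the helical-hairpin construct);
    * ``single_helix``      - the target chain's residues in ``helix_range``
      (default 26-92, the Trp-bearing helix alone).

    The exact residue windows of each helix are structure-specific and
    therefore configurable.
    """
    if context not in _CONTEXTS:
        raise ValueError(f"context must be one of {_CONTEXTS}")
    in_chain = structure.chain_ids == str(chain)
    res_mask = in_chain & (structure.res_ids == int(residue))
    if not res_mask.any():
        raise ValueError(f"residue {residue} not found in chain {chain}")
    res_name = structure.res_names[res_mask][0]
    if res_name.upper() != "TRP":
        raise ValueError(f"residue {residue}/{chain} is {res_name}, not TRP")
    present = set(structure.atom_names[res_mask])
    missing = [a for a in INDOLE_ATOMS if a not in present]
    if missing:
        raise ValueError(f"Trp {residue}/{chain} is missing indole atoms: {missing}")

    if context == "full_assembly":
        ctx_mask = np.ones(len(structure), dtype=bool)
    else:
        lo, hi = coiled_coil_range if context == "coiled_coil_chain" else helix_range
        ctx_mask = in_chain & (structure.res_ids >= lo) & (structure.res_ids <= hi)
    if not (ctx_mask & res_mask).any():
        raise ValueError("the target Trp lies outside the selected context range")
    ctx = structure.select(ctx_mask)
    areas = shrake_rupley(ctx, probe_radius=probe_radius, n_points=n_points)
    indole = (
        (ctx.chain_ids == str(chain))
        & (ctx.res_ids == int(residue))
        & np.isin(ctx.atom_names, INDOLE_ATOMS)
    )
    return float(areas[indole].sum())


_REF_CACHE: dict = {}


def reference_indole_sasa(probe_radius: float = 1.4, n_points: int = 960) -> float:
    """Maximal indole SASA: a free Trp side chain with no neighbours (cached)."""
    key = (probe_radius, n_points)
    if key not in _REF_CACHE:
        trp = _ideal_trp()
        indole_only = trp.select(np.isin(trp.atom_names, INDOLE_ATOMS))
        areas = shrake_rupley(indole_only, probe_radius=probe_radius, n_points=n_points)
        _REF_CACHE[key] = float(areas.sum())
    return _REF_CACHE[key]


# -- synthetic Trp-pocket stand-in -------------------------------------------


def _ideal_trp() -> AtomSet:
    """Idealized TRP residue coordinates from the chemical component dictionary."""
    import biotite.structure.info as info

    arr = info.residue("TRP")
    arr = arr[~np.isin(np.char.upper(arr.element.astype("U2")), ("H", "D"))]
    return AtomSet(
        coords=arr.coord, elements=arr.element, atom_names=arr.atom_name,
        res_ids=np.full(arr.array_length(), 1), res_names=arr.res_name,
        chain_ids=np.full(arr.array_length(), "A", dtype="U6"),
    )


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R@mobile + t - target||."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, tc - R @ mc


def _helix_chain(
    n_res: int, chain_id: str, res_start: int = 1, trp_at: int | None = None
) -> AtomSet:
    """Poly-Ala ideal helix (N, CA, C, CB per residue), optionally with one
    full Trp side chain grafted at ``trp_at`` (1-based position in the helix)."""
    from .helicity import ideal_helix_backbone

    bb = ideal_helix_backbone(n_res)  # (n_res, 3 [N,CA,C], 3)
    coords, elements, names, rids, rnames = [], [], [], [], []
    for i in range(n_res):
        N, CA, C = bb[i]
        b1 = N - CA
        b2 = C - CA
        b1 /= np.linalg.norm(b1)
        b2 /= np.linalg.norm(b2)
        d1 = b1 + b2
        d1 /= np.linalg.norm(d1)
        d2 = np.cross(b1, b2)
        d2 /= np.linalg.norm(d2)
        CB = CA + 1.53 * ((-d1 * np.sin(np.radians(54.0)) + d2 * np.cos(np.radians(54.0))))
        res_atoms = [("N", "N", N), ("CA", "C", CA), ("C", "C", C), ("CB", "C", CB)]
        rname = "ALA"
        if trp_at is not None and i == trp_at - 1:
            rname = "TRP"
            trp = _ideal_trp()
            tsel = {a: trp.coords[list(trp.atom_names).index(a)] for a in trp.atom_names}
            R, t = _kabsch(
                np.array([tsel["N"], tsel["CA"], tsel["CB"]]),
                np.array([N, CA, CB]),
            )
            for aname in ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"):
                pos = R @ tsel[aname] + t
                res_atoms.append((aname, "N" if aname == "NE1" else "C", pos))
        for aname, elem, pos in res_atoms:
            coords.append(pos)
            elements.append(elem)
            names.append(aname)
            rids.append(res_start + i)
            rnames.append(rname)
    return AtomSet(
        coords=np.array(coords), elements=np.array(elements), atom_names=np.array(names),
        res_ids=np.array(rids), res_names=np.array(rnames),
        chain_ids=np.full(len(coords), chain_id, dtype="U6"),
    )


def _transform(atoms: AtomSet, R: np.ndarray, t: np.ndarray) -> AtomSet:
    return replace(atoms, coords=atoms.coords @ R.T + t)


def _rot(axis: str, deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _concat(sets) -> AtomSet:
    return AtomSet(
        coords=np.vstack([s.coords for s in sets]),
        elements=np.concatenate([s.elements for s in sets]),
        atom_names=np.concatenate([s.atom_names for s in sets]),
        res_ids=np.concatenate([s.res_ids for s in sets]),
        res_names=np.concatenate([s.res_names for s in sets]),
        chain_ids=np.concatenate([s.chain_ids for s in sets]),
    )


def _centred_helix(chain_id: str, res_start: int, n_res: int, trp_at: int | None = None) -> AtomSet:
    """Ideal helix aligned to the z axis and centred on its own helical axis.

    Centring uses the CA centroid in x/y (a point on the axis, to within a
    fraction of the helical radius) rather than the endpoint midpoint, which
    can sit a full helix radius off-axis.
    """
    h = _helix_chain(n_res, chain_id, res_start=res_start, trp_at=trp_at)
    ca = h.coords[h.atom_names == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, zhat)
    if np.linalg.norm(v) > 1e-12:
        angle = np.degrees(np.arccos(np.clip(axis @ zhat, -1, 1)))
        v /= np.linalg.norm(v)
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = (
            np.eye(3)
            + np.sin(np.radians(angle)) * K
            + (1 - np.cos(np.radians(angle))) * K @ K
        )
        h = _transform(h, R, np.zeros(3))
    ca = h.coords[h.atom_names == "CA"]
    centre = np.array([ca[:, 0].mean(), ca[:, 1].mean(), (ca[0, 2] + ca[-1, 2]) / 2.0])
    return _transform(h, np.eye(3), -centre)


def build_synthetic_trp_pocket(
    helix_len: int = 26,
    pair_distance: float = 13.5,
    stack_distance: float = 9.0,
    partner_z_shift: float = 2.5,
):
    """SYNTHETIC stand-in assembly for the Trp-pocket burial comparison.

    Not a real structure: an idealized Trp-bearing helix (chain A, residues
    26-51, Trp at 38, indole facing the partner) paired with an antiparallel
    poly-Ala helix (chain A, residues 57-82) into a coiled-coil-like
    hairpin, flanked by two identical poly-Ala hairpins (chains B and C) at
    hexagonal-packing offsets, standing in for the adjacent protomer stacks
    that close the Trp pocket in an assembled barrel.  The placement
    constants are chosen for plausible clash-free packing (no interatomic
    contact below ~3.5 Angstrom) with the indole occluded from three sides;
    no quantitative agreement with any real assembly is implied.

    Returns (structure, selection) where ``selection`` holds the chain,
    residue id and context residue ranges to feed :func:`trp_indole_sasa`.
    """
    trp_pos = helix_len // 2
    trp_res_id = 26 + trp_pos - 1
    helix_a = _centred_helix("A", 26, helix_len, trp_at=trp_pos)
    # spin chain A about its axis so the indole points at the partner (+x)
    trp_mask = helix_a.res_ids == trp_res_id
    indole_dir = helix_a.coords[trp_mask & (helix_a.atom_names == "CZ2")][0]
    spin = -np.degrees(np.arctan2(indole_dir[1], indole_dir[0]))
    helix_a = _transform(helix_a, _rot("z", spin), np.zeros(3))

    def partner_helix(chain_id, res_start):
        p = _centred_helix(chain_id, res_start, helix_len)
        p = _transform(p, _rot("x", 180.0), np.zeros(3))  # antiparallel
        return _transform(p, np.eye(3), np.array([pair_distance, 0.0, partner_z_shift]))

    chain_a = _concat([helix_a, partner_helix("A", 57)])

    neighbors = []
    for chain_id, sy in (("B", +stack_distance), ("C", -stack_distance)):
        hairpin = _concat([_centred_helix(chain_id, 1, helix_len), partner_helix(chain_id, 31)])
        neighbors.append(
            _transform(hairpin, np.eye(3), np.array([pair_distance / 2.0, sy, 0.0]))
        )
    structure = _concat([chain_a] + neighbors)
    selection = {
        "chain": "A",
        "residue": int(trp_res_id),
        "coiled_coil_range": (26, 26 + 2 * helix_len + 4),
        "helix_range": (26, 26 + helix_len - 1),
    }
    return structure, selection
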