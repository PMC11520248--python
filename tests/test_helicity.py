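"""Dihedral helicity statistics and the backbone H-bond potential."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ureafold.helicity import (
    DihedralSeries,
    HBondParams,
    assign_alpha_helix,
    compute_dihedrals,
    dihedral_angle,
    hbond_potential,
    helical_propensity_profile,
    ideal_helix_backbone,
    is_helical_form,
    read_dihedral_table,
    region_helicity,
)


class TestComputeDihedrals:
    def test_ideal_helix_round_trip(self):
        bb = ideal_helix_backbone(10, phi=-57.0, psi=-47.0)
        ds = compute_dihedrals(bb[None])
        np.testing.assert_allclose(ds.phi[0, 1:], -57.0, atol=1e-8)
        np.testing.assert_allclose(ds.psi[0, :-1], -47.0, atol=1e-8)

    def test_termini_marked_missing(self):
        ds = compute_dihedrals(ideal_helix_backbone(5)[None])
        assert np.isnan(ds.phi[0, 0])
        assert np.isnan(ds.psi[0, -1])

    def test_colinear_atoms_flagged_not_dropped(self):
        bb = ideal_helix_backbone(4).copy()
        # collapse residue 2's backbone onto a line through residues 1-3
        bb[1, :, :] = np.linspace(bb[0, 2], bb[2, 0], 5)[1:4]
        ds = compute_dihedrals(bb[None])
        assert ds.phi.shape == (1, 4)
        assert np.isnan(ds.phi[0, 1]) or np.isnan(ds.psi[0, 1])

    def test_cross_check_against_independent_dihedral(self):
        """Our vectorized dihedral agrees with biotite's implementation on
        random four-point geometries."""
        import biotite.structure as struc

        rng = np.random.default_rng(7)
        pts = rng.normal(0, 5, size=(50, 4, 3))
        mine = dihedral_angle(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        theirs = np.degrees(
            [struc.dihedral(p[0], p[1], p[2], p[3]) for p in pts]
        )
        # same angle modulo 360
        diff = np.abs((mine - theirs + 180) % 360 - 180)
        np.testing.assert_allclose(diff, 0, atol=1e-3)  # biotite runs in float32

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError, match="3"):
            compute_dihedrals(ideal_helix_backbone(2)[None])


class TestHelicalForm:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (-60.0, -45.0, True),   # canonical helix
            (-170.0, -45.0, False),  # phi outside
            (-60.0, 60.0, False),    # psi outside
            (-160.0, -45.0, False),  # open boundary
            (-20.0, -45.0, False),   # open boundary
            (-60.0, 50.0, False),    # open boundary
            (np.nan, -45.0, False),  # missing angle
            (-57.0, -47.0, True),
        ],
    )
    def test_window_membership(self, phi, psi, expected):
        assert bool(is_helical_form(phi, psi)) is expected

    def test_wraparound_normalization(self):
        # -60 deg expressed as 300 deg must still be helical
        assert bool(is_helical_form(300.0, -45.0))


class TestAssignAlphaHelix:
    def test_triplet_rule_example(self):
        flags = np.array([False, True, True, True, False])
        np.testing.assert_array_equal(
            assign_alpha_helix(flags), [False, False, True, False, False]
        )

    def test_termini_excluded(self):
        np.testing.assert_array_equal(
            assign_alpha_helix(np.ones(5, dtype=bool)),
            [False, True, True, True, False],
        )

    def test_short_chain_all_false(self):
        np.testing.assert_array_equal(assign_alpha_helix([True, True]), [False, False])

    def test_matches_brute_force_on_random_strings(self, rng):
        """Vectorized triplet assignment equals the literal per-residue rule."""
        for _ in range(300):
            n = int(rng.integers(1, 21))
            flags = rng.random(n) < 0.5
            got = assign_alpha_helix(flags)
            expected = np.zeros(n, dtype=bool)
            for i in range(1, n - 1):
                expected[i] = flags[i - 1] and flags[i] and flags[i + 1]
            np.testing.assert_array_equal(got, expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=30))
    def test_assignment_never_adds_helicity(self, flags):
        flags = np.asarray(flags, dtype=bool)
        assert not np.any(assign_alpha_helix(flags) & ~flags)


class TestPropensity:
    def test_ideal_helix_interior_propensity_one(self):
        bb = ideal_helix_backbone(12)
        traj = np.repeat(bb[None], 5, axis=0)
        profile = helical_propensity_profile(compute_dihedrals(traj))
        # residues 1 and n lack a dihedral; residues 2 and n-1 lack a helical
        # neighbour on one side
        np.testing.assert_allclose(profile.propensity[2:-2], 1.0)
        assert profile.propensity[0] == 0.0
        assert profile.propensity[-1] == 0.0

    def test_half_frames_helical(self):
        helical = np.full((1, 7), -57.0), np.full((1, 7), -47.0)
        coil = np.full((1, 7), 120.0), np.full((1, 7), 120.0)
        phi = np.vstack([helical[0], coil[0]])
        psi = np.vstack([helical[1], coil[1]])
        profile = helical_propensity_profile(DihedralSeries(phi=phi, psi=psi))
        np.testing.assert_allclose(profile.propensity[1:-1], 0.5)

    def test_frame_order_invariance(self, rng):
        phi = rng.uniform(-180, 180, size=(40, 9))
        psi = rng.uniform(-180, 180, size=(40, 9))
        p1 = helical_propensity_profile(DihedralSeries(phi=phi, psi=psi)).propensity
        order = rng.permutation(40)
        p2 = helical_propensity_profile(DihedralSeries(phi=phi[order], psi=psi[order])).propensity
        np.testing.assert_array_equal(p1, p2)

    def test_random_coil_matches_window_probability_cube(self, rng):
        """For i.i.d. uniform dihedrals the triplet rule makes an interior
        residue helical with probability p^3, p the (phi,psi)-window area
        fraction - checked against direct simulation."""
        p_window = (140.0 / 360.0) * (170.0 / 360.0)
        n_frames, n_res = 4000, 30
        phi = rng.uniform(-180, 180, size=(n_frames, n_res))
        psi = rng.uniform(-180, 180, size=(n_frames, n_res))
        profile = helical_propensity_profile(DihedralSeries(phi=phi, psi=psi))
        interior = profile.propensity[1:-1].mean()
        expected = p_window**3
        se = np.sqrt(expected * (1 - expected) / (n_frames * (n_res - 2)))
        assert abs(interior - expected) < 6 * se  # generous band, correlated cols


class TestRegionHelicity:
    def test_uniform_profile(self):
        from ureafold.helicity import HelicityProfile

        prof = HelicityProfile(propensity=np.full(20, 0.6), n_frames=10)
        out = region_helicity(prof, {"a": (1, 10), "b": (11, 20)})
        assert out == {"a": pytest.approx(0.6), "b": pytest.approx(0.6)}

    def test_two_residue_mean(self):
        from ureafold.helicity import HelicityProfile

        prof = HelicityProfile(propensity=np.array([0.2, 0.8, 0.5]), n_frames=10)
        assert region_helicity(prof, {"r": (1, 2)})["r"] == pytest.approx(0.5)

    def test_region_beyond_chain_rejected(self):
        from ureafold.helicity import HelicityProfile

        prof = HelicityProfile(propensity=np.full(5, 0.5), n_frames=1)
        with pytest.raises(ValueError, match="beyond"):
            region_helicity(prof, {"r": (3, 9)})

    def test_region_mean_bounded_by_max(self, rng):
        from ureafold.helicity import HelicityProfile

        prof = HelicityProfile(propensity=rng.random(30), n_frames=1)
        out = region_helicity(prof, {"r": (5, 25)})
        assert out["r"] <= prof.propensity[4:25].max() + 1e-12


class TestHBondPotential:
    def test_well_depth_at_sigma(self):
        p = HBondParams(lam=1.0, epsilon_hb=2.0, sigma_hb=3.0)
        assert hbond_potential(3.0, p) == pytest.approx(-2.0)

    def test_lambda_scales_linearly(self):
        p = HBondParams(lam=0.75, epsilon_hb=1.0, sigma_hb=1.0)
        assert hbond_potential(1.0, p) == pytest.approx(-0.75)

    def test_zero_outside_angular_domain(self):
        p = HBondParams()
        assert hbond_potential(1.0, p, theta_N=95.0) == 0.0
        assert hbond_potential(1.0, p, theta_C=-90.5) == 0.0

    def test_minimum_location_and_value_on_fine_grid(self):
        p = HBondParams(lam=0.6, epsilon_hb=1.7, sigma_hb=2.2)
        r = np.linspace(0.8 * 2.2, 3.0 * 2.2, 200001)
        v = hbond_potential(r, p)
        i = np.argmin(v)
        assert abs(r[i] - 2.2) < 1e-4 * 2.2
        assert abs(v[i] - (-0.6 * 1.7)) < 1e-6
        # angular factor scales the well depth
        v45 = hbond_potential(2.2, p, theta_N=45.0, theta_C=45.0)
        assert v45 == pytest.approx(-0.6 * 1.7 * 0.25)

    def test_vanishes_at_infinity_and_monotone_in_lambda(self):
        assert abs(hbond_potential(1e3, HBondParams())) < 1e-20
        r = np.linspace(0.95, 3.0, 50)
        v1 = hbond_potential(r, HBondParams(lam=1.0))
        v2 = hbond_potential(r, HBondParams(lam=0.5))
        assert np.all(np.abs(v2) <= np.abs(v1) + 1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hbond_potential(0.0, HBondParams())
        with pytest.raises(ValueError):
            HBondParams(lam=0.0)
        with pytest.raises(ValueError):
            HBondParams(lam=1.2)


def test_read_dihedral_table_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    phi = rng.uniform(-180, 180, size=(3, 4))
    psi = rng.uniform(-180, 180, size=(3, 4))
    lines = ["frame,residue,phi,psi"]
    for f in range(3):
        for r in range(4):
            lines.append(f"{f},{r + 1},{phi[f, r]},{psi[f, r]}")
    path = tmp_path / "dihedrals.csv"
    path.write_text("\n".join(lines))
    ds = read_dihedral_table(path)
    np.testing.assert_allclose(ds.phi, phi)
    np.testing.assert_allclose(ds.psi, psi)
    np.testing.assert_array_equal(ds.residue_ids, [1, 2, 3, 4])
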