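"""Potential sources: OpenDX grids, PQR charge sets, and PD matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brass.electrostatics import (
    ChargeSet,
    PotentialGrid,
    coulomb_potential,
    pd_from_potentials,
    pd_matrix,
    read_dx,
    read_pqr,
    sample_grid,
    upper_pairs,
    write_dx,
    write_pqr,
)
from brass.errors import OutOfGridError, ParseError, SingularityError, UnsupportedFormatError

CONSTANT_DX = """\
object 1 class gridpositions counts 2 2 2
origin 0.0 0.0 0.0
delta 1.0 0.0 0.0
delta 0.0 1.0 0.0
delta 0.0 0.0 1.0
object 2 class gridconnections counts 2 2 2
object 3 class array type double rank 0 items 8 data follows
5.0 5.0 5.0
5.0 5.0 5.0
5.0 5.0
"""


class TestDX:
    def test_constant_grid(self):
        grid = read_dx(CONSTANT_DX)
        assert grid.counts == (2, 2, 2)
        np.testing.assert_array_equal(grid.values, np.full((2, 2, 2), 5.0))

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        grid = PotentialGrid(
            origin=[-3.0, 1.5, 0.25],
            spacing=[0.5, 0.75, 1.0],
            counts=(4, 3, 5),
            values=rng.normal(size=(4, 3, 5)),
        )
        back = read_dx(write_dx(grid, comment="roundtrip"))
        np.testing.assert_allclose(back.origin, grid.origin)
        np.testing.assert_allclose(back.spacing, grid.spacing)
        np.testing.assert_allclose(back.values, grid.values, rtol=1e-6)

    def test_truncated_stream_rejected(self):
        truncated = "\n".join(CONSTANT_DX.splitlines()[:-1]) + "\n"
        with pytest.raises(ParseError, match="mismatch"):
            read_dx(truncated)

    def test_non_orthogonal_deltas_rejected(self):
        skewed = CONSTANT_DX.replace("delta 0.0 1.0 0.0", "delta 0.3 1.0 0.0")
        with pytest.raises(UnsupportedFormatError):
            read_dx(skewed)


class TestPQR:
    def test_single_atom(self):
        cs = read_pqr("ATOM 1 O HOH A 1 1.0 2.0 3.0 -1.0 1.4\n")
        assert cs.charges.tolist() == [-1.0]
        assert cs.radii.tolist() == [1.4]
        np.testing.assert_array_equal(cs.positions, [[1.0, 2.0, 3.0]])

    def test_total_charge_bookkeeping(self):
        rng = np.random.default_rng(3)
        charges = rng.uniform(-1, 1, size=10)
        lines = [
            f"ATOM {i+1} C RES A {i+1} {i:.3f} 0.000 0.000 {q:.4f} 1.5000"
            for i, q in enumerate(charges)
        ]
        cs = read_pqr("\n".join(lines))
        assert cs.total_charge == pytest.approx(charges.sum(), abs=1e-3)

    def test_roundtrip_through_writer(self):
        cs = ChargeSet(positions=[[0, 0, 0], [1, 2, 3]], charges=[0.5, -0.25],
                       radii=[1.2, 1.6])
        back = read_pqr(write_pqr(cs))
        np.testing.assert_allclose(back.positions, cs.positions)
        np.testing.assert_allclose(back.charges, cs.charges)

    def test_errors(self):
        with pytest.raises(ParseError):
            read_pqr("")
        with pytest.raises(ParseError, match="line 1"):
            read_pqr("ATOM 1 O HOH A 1 1.0 2.0 3.0 XX 1.4\n")


class TestSampleGrid:
    @pytest.fixture
    def random_grid(self):
        rng = np.random.default_rng(7)
        return PotentialGrid(origin=[0, 0, 0], spacing=[1, 1, 1], counts=(4, 4, 4),
                             values=rng.normal(scale=10, size=(4, 4, 4)))

    def test_exact_on_nodes(self, random_grid):
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            point = random_grid.origin + random_grid.spacing * np.array(idx)
            assert sample_grid(random_grid, point) == pytest.approx(
                random_grid.values[idx], abs=1e-12
            )

    def test_cell_center_is_corner_mean(self, random_grid):
        corners = random_grid.values[1:3, 1:3, 1:3]
        assert sample_grid(random_grid, (1.5, 1.5, 1.5)) == pytest.approx(
            corners.mean(), abs=1e-12
        )

    def test_matches_independent_trilinear_oracle(self, random_grid):
        def oracle(grid, p):
            # nearest-lower-node trilinear blend, coded independently
            f = (np.asarray(p) - grid.origin) / grid.spacing
            i0 = np.minimum(np.floor(f).astype(int), np.array(grid.counts) - 2)
            t = f - i0
            total = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((t[0] if dx else 1 - t[0])
                             * (t[1] if dy else 1 - t[1])
                             * (t[2] if dz else 1 - t[2]))
                        total += w * grid.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
            return total

        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(0, 3, size=3)
            assert sample_grid(random_grid, p) == pytest.approx(
                oracle(random_grid, p), abs=1e-9
            )

    def test_refuses_extrapolation(self, random_grid):
        with pytest.raises(OutOfGridError):
            sample_grid(random_grid, (5.0, 1.0, 1.0))


class TestCoulomb:
    def test_opposite_charges_cancel_at_midplane(self):
        cs = ChargeSet(positions=[[-1, 0, 0], [1, 0, 0]], charges=[1.0, -1.0],
                       radii=[1.0, 1.0])
        assert coulomb_potential(cs, (0, 5, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_unscreened_inverse_distance(self):
        cs = ChargeSet(positions=[[0, 0, 0]], charges=[1.0], radii=[1.0], kappa=0.0)
        phi_r = coulomb_potential(cs, (2.0, 0, 0))
        phi_2r = coulomb_potential(cs, (4.0, 0, 0))
        assert phi_2r == pytest.approx(phi_r / 2, rel=1e-12)
        # sanity on magnitude: Bjerrum-length prefactor ~7.1 A in water at 298 K
        assert phi_r * 2.0 == pytest.approx(7.14, abs=0.05)

    def test_brute_force_term_sum(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-5, 5, size=(5, 3))
        q = rng.uniform(-1, 1, size=5)
        cs = ChargeSet(positions=pos, charges=q, radii=np.ones(5))
        point = np.array([8.0, 1.0, -2.0])
        from scipy import constants

        pref = (constants.elementary_charge**2
                / (4 * np.pi * constants.epsilon_0 * constants.Boltzmann * 298.0)
                * 1e10 / 78.5)
        expected = sum(
            pref * qi * np.exp(-0.09 * np.linalg.norm(point - pi)) / np.linalg.norm(point - pi)
            for pi, qi in zip(pos, q)
        )
        assert coulomb_potential(cs, point) == pytest.approx(expected, rel=1e-12)

    def test_singularity_refused(self):
        cs = ChargeSet(positions=[[0, 0, 0]], charges=[1.0], radii=[1.0])
        with pytest.raises(SingularityError):
            coulomb_potential(cs, (0.05, 0, 0))

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(9)
        pos = rng.uniform(-3, 3, size=(4, 3))
        q = rng.uniform(-1, 1, size=4)
        cs = ChargeSet(positions=pos, charges=q, radii=np.ones(4))
        point = np.array([6.0, 0.0, 0.0])
        phi0 = coulomb_potential(cs, point)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        shift = np.array([10.0, -4.0, 2.5])
        moved = ChargeSet(positions=pos @ rot.T + shift, charges=q, radii=np.ones(4))
        assert coulomb_potential(moved, rot @ point + shift) == pytest.approx(phi0, rel=1e-10)


class TestPDMatrix:
    def test_constant_field_gives_zero(self, triad_structure, triad_motif):
        from brass.fixtures import generate_potential
        from brass.structure import functional_atom

        grid = generate_potential(triad_structure, "constant", constant_value=3.0)
        atoms = [functional_atom(r) for r in triad_motif.residues]
        np.testing.assert_allclose(pd_matrix(atoms, grid), np.zeros((3, 3)), atol=1e-12)

    def test_pairwise_differences_in_table_order(self):
        pd = pd_from_potentials([10.0, 2.0, 6.0])
        np.testing.assert_allclose(upper_pairs(pd), [8.0, 4.0, -4.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-500, 500), min_size=3, max_size=5))
    def test_antisymmetry_and_telescoping(self, phis):
        pd = pd_from_potentials(phis)
        np.testing.assert_allclose(pd, -pd.T, atol=1e-9)
        assert np.all(np.diag(pd) == 0)
        n = len(phis)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert pd[i, j] == pytest.approx(pd[i, k] + pd[k, j], abs=1e-6)
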