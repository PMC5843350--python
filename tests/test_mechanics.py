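"""Subcellular-element forces: pair laws, assembly, integration."""

import numpy as np
import pytest

from epistrat.mechanics import (
    MechanicsParams,
    NeighborIndex,
    assemble_forces,
    external_force,
    inter_pair_force,
    inter_pair_potential,
    intra_pair_force,
    step_positions,
    total_potential,
)
from epistrat.tissue import Cell, Tissue

from conftest import make_tissue


def brute_force_assembly(tissue, params):
    """Independent all-pairs O(n^2) force oracle (no neighbor lists)."""
    pos, cell_start, cell_class, adherent, basal = tissue.flatten()
    n = pos.shape[0]
    cell_of = np.empty(n, dtype=int)
    elem_class = np.empty(n, dtype=int)
    for i in range(len(cell_start) - 1):
        cell_of[cell_start[i]:cell_start[i + 1]] = i
        elem_class[cell_start[i]:cell_start[i + 1]] = cell_class[i]
    lx, ly, _ = tissue.box
    forces = np.zeros_like(pos)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            if tissue.periodic_xy:
                d[0] -= lx * np.rint(d[0] / lx)
                d[1] -= ly * np.rint(d[1] / ly)
            r = np.linalg.norm(d)
            if cell_of[i] == cell_of[j]:
                f = -params.mu_spring * (r - params.r0) * d / r
            else:
                if r > params.inter_cutoff or r == 0.0:
                    continue
                r_eff = max(r, params.rmin_frac * params.sigma)
                fmult = params.Fa if elem_class[i] == elem_class[j] else params.Fb
                s6 = (params.sigma / r_eff) ** 6
                f = fmult * params.eps * (12 * s6 * s6 - 6 * s6) / r_eff**2 * d
            forces[i] += f
            forces[j] -= f
    for i in range(n):
        z = pos[i, 2]
        if adherent[i] and basal[i] and abs(z) <= params.membrane_cutoff and z != 0:
            forces[i, 2] -= params.eps_external * np.sign(z)
        if z < 0:
            forces[i, 2] += params.wall_k * (-z)
    return forces


class TestPairForces:
    def test_spring_zero_at_rest_length(self, mech_params):
        ri = np.array([0.0, 0.0, 0.0])
        rj = np.array([mech_params.r0, 0.0, 0.0])
        np.testing.assert_allclose(intra_pair_force(ri, rj, mech_params), 0.0, atol=1e-14)

    def test_spring_unit_extension_gives_mu(self, mech_params):
        ri = np.array([0.0, 0.0, 0.0])
        rj = np.array([mech_params.r0 + 1.0, 0.0, 0.0])
        f = intra_pair_force(ri, rj, mech_params)
        # stretched spring pulls i toward j with magnitude mu
        assert f[0] == pytest.approx(mech_params.mu_spring)
        assert np.linalg.norm(f) == pytest.approx(mech_params.mu_spring)

    def test_spring_antisymmetric(self, mech_params, rng):
        ri, rj = rng.normal(size=3), rng.normal(size=3) + 4.0
        np.testing.assert_allclose(
            intra_pair_force(ri, rj, mech_params),
            -intra_pair_force(rj, ri, mech_params),
        )

    def test_lj_potential_zero_at_sigma(self, mech_params):
        assert inter_pair_potential(mech_params.sigma, True, mech_params) == 0.0

    def test_lj_force_zero_at_minimum(self, mech_params):
        r = 2.0 ** (1.0 / 6.0) * mech_params.sigma
        f = inter_pair_force(np.zeros(3), np.array([r, 0, 0]), True, mech_params)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_lj_exactly_zero_beyond_cutoff(self, mech_params):
        r = mech_params.inter_cutoff + 1e-9
        f = inter_pair_force(np.zeros(3), np.array([r, 0, 0]), True, mech_params)
        assert np.all(f == 0.0)

    def test_selective_strength_scales_linearly(self):
        p = MechanicsParams(Fa=4.0, Fb=1.0)
        ri, rj = np.zeros(3), np.array([5.0, 0.0, 0.0])
        same = inter_pair_force(ri, rj, True, p)
        cross = inter_pair_force(ri, rj, False, p)
        np.testing.assert_allclose(same, 4.0 * cross)

    @pytest.mark.parametrize("same", [True, False])
    def test_force_matches_potential_gradient(self, mech_params, same, rng):
        """Analytic force equals the central difference of the pair potential."""
        h = 1e-6
        for _ in range(10):
            r = rng.uniform(0.6, 1.9) * mech_params.sigma
            f = inter_pair_force(np.zeros(3), np.array([-r, 0, 0]), same, mech_params)
            num = -(
                inter_pair_potential(r + h, same, mech_params)
                - inter_pair_potential(r - h, same, mech_params)
            ) / (2 * h)
            assert f[0] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_spring_force_matches_gradient(self, mech_params, rng):
        h = 1e-6
        for _ in range(10):
            r = rng.uniform(0.5, 2.5) * mech_params.r0
            f = intra_pair_force(np.array([r, 0, 0]), np.zeros(3), mech_params)
            v = lambda rr: 0.5 * mech_params.mu_spring * (rr - mech_params.r0) ** 2
            num = -(v(r + h) - v(r - h)) / (2 * h)
            assert f[0] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestExternalForce:
    def test_adherent_basal_pulled_down(self, mech_params):
        pos = np.array([0.0, 0.0, 0.5 * mech_params.membrane_cutoff])
        f = external_force(pos, adherent=True, basal=True, params=mech_params)
        assert f[2] == pytest.approx(-mech_params.eps_external)

    def test_out_of_range_feels_nothing(self, mech_params):
        pos = np.array([0.0, 0.0, mech_params.membrane_cutoff + 0.1])
        f = external_force(pos, adherent=True, basal=True, params=mech_params)
        assert np.all(f == 0.0)

    def test_suprabasal_detached(self, mech_params):
        pos = np.array([0.0, 0.0, 0.5])
        assert np.all(external_force(pos, True, False, mech_params) == 0.0)
        assert np.all(external_force(pos, False, True, mech_params) == 0.0)


class TestAssembly:
    def test_matches_brute_force_oracle(self, rng):
        """Neighbor-list assembly equals the all-pairs oracle exactly."""
        params = MechanicsParams()
        centers = [(rng.uniform(10, 60), rng.uniform(10, 60), rng.uniform(0, 25))
                   for _ in range(12)]
        stages = rng.integers(0, 4, size=12)
        tissue = make_tissue(list(zip(centers, stages)), box=(70.0, 70.0, 40.0),
                             periodic=True, k=6, rng=rng)
        tissue.relabel_adherent()
        index = NeighborIndex(tissue, params)
        forces, _ = assemble_forces(tissue, index, params)
        expected = brute_force_assembly(tissue, params)
        np.testing.assert_allclose(forces, expected, rtol=1e-10, atol=1e-10)

    def test_internal_forces_sum_to_zero(self, rng):
        params = MechanicsParams(eps_external=0.0, wall_k=0.0)
        centers = [(rng.uniform(20, 50), rng.uniform(20, 50), rng.uniform(5, 20))
                   for _ in range(8)]
        tissue = make_tissue([(c, int(i % 4)) for i, c in enumerate(centers)],
                             box=(70.0, 70.0, 40.0), periodic=True, rng=rng)
        index = NeighborIndex(tissue, params)
        forces, _ = assemble_forces(tissue, index, params)
        np.testing.assert_allclose(forces.sum(axis=0), 0.0, atol=1e-9)

    def test_isolated_cells_independent(self, rng):
        """Cells beyond the cutoff feel exactly their own internal forces."""
        params = MechanicsParams()
        pair = make_tissue([((20.0, 20, 20), 1), ((60.0, 60, 20), 2)],
                           box=(100.0, 100.0, 60.0), rng=np.random.default_rng(3))
        solo = make_tissue([((20.0, 20, 20), 1)], box=(100.0, 100.0, 60.0),
                           rng=np.random.default_rng(3))
        f_pair, _ = assemble_forces(pair, NeighborIndex(pair, params), params)
        f_solo, _ = assemble_forces(solo, NeighborIndex(solo, params), params)
        np.testing.assert_allclose(f_pair[: len(f_solo)], f_solo, atol=1e-12)


class TestStepping:
    def test_zero_force_no_noise_is_static(self, mech_params):
        pos = np.zeros((5, 3))
        new, capped = step_positions(pos, np.zeros_like(pos), mech_params, rng=None)
        np.testing.assert_array_equal(new, pos)
        assert capped == 0

    def test_attractive_pair_converges_to_lj_minimum(self):
        params = MechanicsParams(noise_amp=0.0)
        t = Tissue(box=(100.0, 100.0, 100.0), periodic_xy=False)
        for i, x in enumerate((50.0, 50.0 + 1.5 * params.sigma)):
            t.cells.append(Cell(i, 1, np.array([[x, 50.0, 50.0]]),
                                np.zeros(1, dtype=bool)))
        index = NeighborIndex(t, params)
        pos, *_ = t.flatten()
        seps = []
        for _ in range(4000):
            f, _ = assemble_forces(t, index, params, pos=pos)
            pos, _ = step_positions(pos, f, params, rng=None)
            seps.append(pos[1, 0] - pos[0, 0])
        seps = np.array(seps)
        assert np.all(np.diff(seps) <= 1e-12)  # monotone approach
        assert seps[-1] == pytest.approx(2 ** (1 / 6) * params.sigma, rel=1e-3)

    def test_gradient_flow_energy_nonincreasing(self, rng):
        params = MechanicsParams(noise_amp=0.0, eps_external=0.0)
        t = make_tissue([((50.0, 50.0, 50.0), 1)], k=6, rng=rng)
        index = NeighborIndex(t, params)
        pos, *_ = t.flatten()
        energies = []
        for _ in range(60):
            f, _ = assemble_forces(t, index, params, pos=pos)
            pos, _ = step_positions(pos, f, params, rng=None)
            t.scatter(pos)
            energies.append(total_potential(t, params))
        assert np.all(np.diff(energies) <= 1e-9)

    def test_relaxed_cell_roughly_spherical(self, rng):
        """An isolated cell relaxes to a near-spherical element cluster."""
        params = MechanicsParams(noise_amp=0.0, eps_external=0.0)
        t = make_tissue([((50.0, 50.0, 50.0), 1)], k=6, rng=rng)
        index = NeighborIndex(t, params)
        pos, *_ = t.flatten()
        for _ in range(3000):
            f, _ = assemble_forces(t, index, params, pos=pos)
            pos, _ = step_positions(pos, f, params, rng=None)
        t.scatter(pos)
        c = t.cells[0]
        radii = np.linalg.norm(c.elements - c.centroid(), axis=1)
        # asphericity: relative spread of element radii
        assert radii.std() / radii.mean() < 0.1

    def test_displacement_capped(self, mech_params):
        pos = np.zeros((2, 3))
        forces = np.array([[1e9, 0.0, 0.0], [0.0, 0.0, 0.0]])
        new, capped = step_positions(pos, forces, mech_params, rng=None)
        assert capped == 1
        assert np.linalg.norm(new[0]) == pytest.approx(
            mech_params.max_disp_frac * mech_params.sigma
        )
        np.testing.assert_array_equal(new[1], 0.0)

    def test_noise_reproducible(self, mech_params):
        pos = np.zeros((4, 3))
        f = np.zeros_like(pos)
        a, _ = step_positions(pos, f, mech_params, rng=np.random.default_rng(7))
        b, _ = step_positions(pos, f, mech_params, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
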