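"""Potential identities and the vectorised evaluator vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phaseslab.constants import COULOMB, debye_length_angstrom
from phaseslab.energy import (
    ElectrostaticsSpec,
    EnergyModel,
    debye_huckel_energy,
    debye_length,
    system_energy,
    wang_frenkel_dudr,
    wang_frenkel_energy,
)
from phaseslab.md import SimulationFrame
from phaseslab.synth import random_bead_frame


def brute_force_energy(coords, box, topo, spec, table):
    """Independent O(N^2) pure-Python pair-sum (no pair lists, no masks)."""
    wf = dh = 0.0
    t_idx = [table.index[name] for name in topo.type_names]
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[i] - coords[j]
            d = d - box * np.round(d / box)
            r = float(np.sqrt((d * d).sum()))
            ti, tj = t_idx[i], t_idx[j]
            wf += wang_frenkel_energy(r, table.eps[ti, tj],
                                      table.sigma[ti, tj],
                                      table.mu[ti, tj], table.nu[ti, tj])
            dh += debye_huckel_energy(r, topo.charges[i], topo.charges[j], spec)
    return wf, dh


class TestWangFrenkel:
    @given(st.floats(min_value=3.0, max_value=9.0),
           st.floats(min_value=0.05, max_value=2.0))
    def test_zero_at_contact_and_cutoff(self, sigma, eps):
        assert wang_frenkel_energy(sigma, eps, sigma) == pytest.approx(0.0)
        assert wang_frenkel_energy(3 * sigma, eps, sigma) == 0.0
        assert wang_frenkel_energy(3 * sigma + 1e-9, eps, sigma) == 0.0
        assert wang_frenkel_energy(10 * sigma, eps, sigma) == 0.0

    @pytest.mark.parametrize("sigma,eps,mu,nu", [
        (6.0, 0.5, 2.0, 1.0), (4.5, 0.2, 1.0, 1.0), (7.0, 0.8, 3.0, 1.0),
    ])
    def test_minimum_depth_equals_minus_eps(self, sigma, eps, mu, nu):
        r = np.linspace(0.8 * sigma, 3 * sigma, 400000)
        u = wang_frenkel_energy(r, eps, sigma, mu, nu)
        assert u.min() == pytest.approx(-eps, rel=1e-6)

    def test_gradient_matches_finite_differences(self):
        for r0 in (5.0, 6.63, 9.0, 14.0):
            h = 1e-6
            fd = (wang_frenkel_energy(r0 + h, 0.5, 6.0)
                  - wang_frenkel_energy(r0 - h, 0.5, 6.0)) / (2 * h)
            assert wang_frenkel_dudr(r0, 0.5, 6.0) == pytest.approx(fd, abs=1e-7)


class TestDebyeHuckel:
    def test_null_charge(self, electrostatics):
        r = np.linspace(1.0, 30.0, 50)
        assert np.allclose(debye_huckel_energy(r, 0.0, 1.0, electrostatics), 0.0)

    def test_unscreened_coulomb_limit(self):
        # huge Debye length (via vanishing ionic strength): exp factor -> 1
        spec = ElectrostaticsSpec(ionic_strength=1e-16, cutoff=1e6)
        r = 10.0
        expected = COULOMB * 1.0 * (-1.0) / (spec.epsilon_r * r)
        got = debye_huckel_energy(r, 1.0, -1.0, spec, shifted=False)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_debye_length_constant_evaluation(self, electrostatics):
        # independent closed-form evaluation at 150 mM, 300 K, eps_r 80
        lam = debye_length(electrostatics)
        assert lam == pytest.approx(
            debye_length_angstrom(0.150, 300.0, 80.0), rel=1e-12)
        assert lam == pytest.approx(7.95, abs=0.02)

    def test_debye_length_scaling(self):
        lam1 = debye_length(ElectrostaticsSpec(ionic_strength=0.1))
        lam4 = debye_length(ElectrostaticsSpec(ionic_strength=0.4))
        assert lam4 == pytest.approx(lam1 / 2.0, rel=1e-9)
        grid = [debye_length(ElectrostaticsSpec(ionic_strength=i))
                for i in (0.01, 0.05, 0.15, 0.5, 1.0)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_inconsistent_stored_length_rejected(self):
        with pytest.raises(ValueError):
            ElectrostaticsSpec(debye_length_A=5.0)


class TestSystemEnergy:
    def test_neutral_beads_beyond_cutoff(self, electrostatics):
        from phaseslab.topology import BeadTopology
        topo = BeadTopology(
            type_names=["ALA", "ALA"], charges=np.zeros(2),
            sigmas=np.full(2, 5.04), masses=np.full(2, 71.08),
            bonds=np.zeros((0, 2), int), bond_r0=np.zeros(0),
            bond_k=np.zeros(0), chain_id=np.arange(2),
            chain_kinds=["protein"] * 2, chain_rigid=[False] * 2)
        frame = SimulationFrame(
            coordinates=np.array([[10.0, 50.0, 50.0], [40.0, 50.0, 50.0]]),
            box=np.array([100.0] * 3))
        terms = system_energy(frame, topo, electrostatics)
        assert terms["total"] == 0.0

    def test_bonded_dimer_at_rest_length(self, electrostatics):
        from phaseslab.sequences import ProteinSequence
        from phaseslab.topology import build_protein_topology
        topo = build_protein_topology(ProteinSequence("gg", "GG"))
        frame = SimulationFrame(
            coordinates=np.array([[10.0, 10.0, 10.0], [13.81, 10.0, 10.0]]),
            box=np.array([60.0] * 3))
        terms = system_energy(frame, topo, electrostatics)
        assert terms["bond"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, electrostatics, pair_table):
        for seed in range(5):
            frame, topo = random_bead_frame(10 + 4 * seed, box=38.0, seed=seed)
            terms = system_energy(frame, topo, electrostatics)
            wf, dh = brute_force_energy(frame.coordinates, frame.box, topo,
                                        electrostatics, pair_table)
            assert abs(terms["wf"] - wf) < 1e-9 * max(1.0, abs(wf))
            assert abs(terms["dh"] - dh) < 1e-9 * max(1.0, abs(dh))

    def test_translation_and_wrap_invariance(self, electrostatics):
        frame, topo = random_bead_frame(20, box=40.0, seed=11)
        model = EnergyModel(topo, electrostatics)
        e0 = model.energy_forces(frame.coordinates, frame.box)[1]["total"]
        shifted = frame.coordinates + np.array([13.0, -80.0, 41.5])
        e1 = model.energy_forces(shifted, frame.box)[1]["total"]
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_forces_match_finite_differences(self, electrostatics):
        frame, topo = random_bead_frame(12, box=30.0, seed=4)
        model = EnergyModel(topo, electrostatics)
        forces = model.energy_forces(frame.coordinates, frame.box)[0]
        h = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(6):
            i = int(rng.integers(12))
            k = int(rng.integers(3))
            c = frame.coordinates.copy()
            c[i, k] += h
            ep = model.energy_forces(c, frame.box)[1]["total"]
            c[i, k] -= 2 * h
            em = model.energy_forces(c, frame.box)[1]["total"]
            fd = -(ep - em) / (2 * h)
            assert forces[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_mismatched_bead_count_errors(self, electrostatics):
        frame, topo = random_bead_frame(8, seed=0)
        bad = SimulationFrame(coordinates=frame.coordinates[:5],
                              box=frame.box)
        with pytest.raises(ValueError):
            system_energy(bad, topo, electrostatics)
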