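"""Integrator physics: conservation, thermostat, barostat, determinism."""

import numpy as np
import pytest

from phaseslab.constants import KB, PRESS2BAR
from phaseslab.energy import ElectrostaticsSpec
from phaseslab.md import (
    ProtocolConfig,
    SimulationFrame,
    Simulator,
    initialize_system,
    langevin_step,
)
from phaseslab.sequences import ProteinSequence
from phaseslab.topology import BeadTopology, build_protein_topology
from phaseslab.synth import polyampholyte_dna_system


def free_beads(n, mass=71.0, sigma=5.0, box=500.0, seed=0):
    topo = BeadTopology(
        type_names=["ALA"] * n, charges=np.zeros(n),
        sigmas=np.full(n, sigma), masses=np.full(n, mass),
        bonds=np.zeros((0, 2), int), bond_r0=np.zeros(0), bond_k=np.zeros(0),
        chain_id=np.arange(n), chain_kinds=["protein"] * n,
        chain_rigid=[False] * n)
    coords = np.random.default_rng(seed).uniform(size=(n, 3)) * box
    return topo, coords, np.array([box] * 3)


def harmonic_dimer(spec, dt=1.0, friction=0.0, seed=1):
    topo = build_protein_topology(ProteinSequence("gg", "GG"))
    coords = np.array([[10.0, 10.0, 10.0], [13.5, 10.0, 10.0]])
    cfg = ProtocolConfig(temperature=300.0, timestep=dt, friction=friction,
                         seed=seed)
    return Simulator(topo, spec, cfg, coords, np.array([50.0] * 3))


class TestIntegrator:
    def test_free_flight_is_linear(self, electrostatics):
        topo, coords, box = free_beads(4, box=1000.0)
        cfg = ProtocolConfig(temperature=300.0, timestep=5.0, friction=0.0,
                             seed=3)
        sim = Simulator(topo, electrostatics, cfg, coords, box)
        x0 = sim.coords.copy()
        v0 = sim.vel.copy()
        for _ in range(100):
            sim.step()
        assert np.allclose(sim.coords, x0 + v0 * 500.0, atol=1e-9)

    def test_harmonic_dimer_energy_conservation(self, electrostatics):
        """Symplectic limit: < 0.1% drift over 1e4 frictionless 1 fs steps."""
        sim = harmonic_dimer(electrostatics)
        e0 = sim.energies["total"] + sim.kinetic_energy()
        for _ in range(10000):
            sim.step()
        e1 = sim.energies["total"] + sim.kinetic_energy()
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_momentum_conserved_without_thermostat(self, electrostatics):
        sim = harmonic_dimer(electrostatics)
        p0 = sim.total_momentum()
        for _ in range(100):
            sim.step()
        assert np.abs(sim.total_momentum() - p0).max() < 1e-10

    def test_thermostat_equipartition(self, electrostatics):
        """Ideal-gas kinetic energy within 2% of (3/2) N kT."""
        topo, coords, box = free_beads(64)
        cfg = ProtocolConfig(temperature=300.0, timestep=10.0, friction=0.01,
                             seed=5)
        sim = Simulator(topo, electrostatics, cfg, coords, box)
        samples = []
        for i in range(30000):
            sim.step()
            if i >= 3000:
                samples.append(sim.kinetic_energy())
        target = 1.5 * 64 * KB * 300.0
        assert np.mean(samples) == pytest.approx(target, rel=0.02)

    def test_kinetic_temperature_unbiased_across_seeds(self, electrostatics):
        """Thermostatted harmonic dimers: seed-averaged T within 2%."""
        temps = []
        for seed in range(5):
            sim = harmonic_dimer(electrostatics, dt=5.0, friction=0.01,
                                 seed=seed)
            acc = []
            for i in range(6000):
                sim.step()
                if i >= 1000:
                    acc.append(sim.instantaneous_temperature())
            temps.append(np.mean(acc))
        assert np.mean(temps) == pytest.approx(300.0, rel=0.02)

    def test_langevin_step_requires_positive_dt(self, electrostatics):
        topo, coords, box = free_beads(2)
        frame = SimulationFrame(coordinates=coords, box=box)
        with pytest.raises(ValueError):
            langevin_step(frame, topo, electrostatics, dt=0.0, friction=0.0,
                          temperature=300.0, rng=np.random.default_rng(0))


class TestDeterminism:
    def test_same_seed_identical_trajectory(self, electrostatics):
        results = []
        for _ in range(2):
            topo = polyampholyte_dna_system()
            frame = initialize_system(topo, 80.0, seed=9)
            cfg = ProtocolConfig(temperature=200.0, timestep=10.0,
                                 friction=0.01, seed=9)
            sim = Simulator(topo, electrostatics, cfg, frame.coordinates,
                            frame.box)
            for _ in range(50):
                sim.step()
            results.append(sim.coords.copy())
        assert np.array_equal(results[0], results[1])

    def test_initialize_system_seeded(self, electrostatics):
        topo = polyampholyte_dna_system()
        a = initialize_system(topo, 80.0, seed=4)
        b = initialize_system(topo, 80.0, seed=4)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_initialize_counts_and_overlaps(self):
        topo = polyampholyte_dna_system(n_chains=4, n_strands=2)
        frame = initialize_system(topo, 70.0, seed=0)
        assert frame.coordinates.shape == (4 * 20 + 2 * 8, 3)
        # no catastrophic overlap between different chains
        from phaseslab.contacts import _distance_matrix
        r = _distance_matrix(frame.coordinates, frame.box)
        inter = topo.chain_id[:, None] != topo.chain_id[None, :]
        assert r[inter].min() > 0.8 * 0.5 * (4.5 + 4.5)

    def test_placement_failure_suggests_larger_box(self):
        topo = polyampholyte_dna_system(n_chains=8, n_strands=3)
        with pytest.raises(RuntimeError, match="larger box"):
            initialize_system(topo, 18.0, seed=0, max_tries_per_chain=5)


class TestBarostat:
    def test_volume_shrinks_below_target_pressure(self, electrostatics):
        topo, coords, box = free_beads(32, box=200.0)
        cfg = ProtocolConfig(temperature=300.0, timestep=10.0, friction=0.01,
                             pressure_target=100.0, seed=1)
        sim = Simulator(topo, electrostatics, cfg, coords, box)
        v0 = np.prod(sim.box)
        sim.run(400, npt=True)
        assert np.prod(sim.box) < v0

    def test_infinite_coupling_time_is_nvt(self, electrostatics):
        topo, coords, box = free_beads(16, box=150.0)
        cfg = ProtocolConfig(temperature=300.0, timestep=10.0, friction=0.01,
                             pressure_target=100.0, barostat_tau_fs=1e18,
                             seed=1)
        sim = Simulator(topo, electrostatics, cfg, coords, box)
        v0 = np.prod(sim.box)
        sim.run(100, npt=True)
        assert np.prod(sim.box) == pytest.approx(v0, rel=1e-12)

    def test_ideal_gas_pressure_converges_to_target(self, electrostatics):
        """Free beads have exact P = N kT / V; Berendsen must reach it."""
        n, box = 48, 300.0
        topo, coords, _ = free_beads(n, box=box)
        target = 20.0  # bar
        cfg = ProtocolConfig(temperature=300.0, timestep=10.0, friction=0.01,
                             pressure_target=target, seed=2)
        sim = Simulator(topo, electrostatics, cfg, coords,
                        np.array([box] * 3))
        sim.run(9000, npt=True)
        vols = []
        for _ in range(2500):
            sim.step()
            sim.berendsen_barostat(10.0, target, cfg.barostat_tau_fs)
            vols.append(np.prod(sim.box))
        p_mean = n * KB * 300.0 / np.mean(vols) * PRESS2BAR
        assert p_mean == pytest.approx(target, rel=0.10)


class TestEnergyBookkeeping:
    def test_monitor_potential_matches_recomputation(self, electrostatics):
        from phaseslab.energy import system_energy
        topo = polyampholyte_dna_system(n_chains=3, n_strands=1)
        frame0 = initialize_system(topo, 60.0, seed=2)
        cfg = ProtocolConfig(temperature=250.0, timestep=10.0, friction=0.01,
                             seed=2)
        sim = Simulator(topo, electrostatics, cfg, frame0.coordinates,
                        frame0.box)
        series, frames = sim.run(200, record_every=50, collect_frames=True)
        for e_mon, frame in zip(series.potential_kcal, frames):
            recomputed = system_energy(frame, topo, electrostatics)["total"]
            assert e_mon == pytest.approx(recomputed, rel=1e-6)

    def test_elongation_geometry(self, electrostatics):
        topo = polyampholyte_dna_system(n_chains=2, n_strands=1)
        frame0 = initialize_system(topo, 50.0, seed=1)
        cfg = ProtocolConfig(temperature=200.0, seed=1)
        sim = Simulator(topo, electrostatics, cfg, frame0.coordinates,
                        frame0.box)
        box0 = sim.box.copy()
        sim.elongate(3.0, axis=2)
        assert sim.box[2] == pytest.approx(3.0 * box0[2])
        assert np.allclose(sim.box[:2], box0[:2])
        assert sim.coords.shape[0] == topo.n_beads  # particle conservation
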