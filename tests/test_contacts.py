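"""Contact criterion, map aggregation, valency rule, per-contact energies."""

import numpy as np
import pytest

from phaseslab.constants import KB
from phaseslab.contacts import (
    aggregate_contact_map,
    contact_matrix,
    dna_valency,
    mean_contact_energy,
)
from phaseslab.md import SimulationFrame, Trajectory
from phaseslab.synth import random_bead_frame
from phaseslab.topology import BeadTopology


def bead_system(sigmas, coords, box=200.0, kinds=None, chain_of=None):
    n = len(sigmas)
    chain_of = np.arange(n) if chain_of is None else np.asarray(chain_of)
    n_chains = chain_of.max() + 1
    kinds = ["protein"] * n_chains if kinds is None else kinds
    topo = BeadTopology(
        type_names=["ALA"] * n, charges=np.zeros(n),
        sigmas=np.asarray(sigmas, dtype=float), masses=np.full(n, 100.0),
        bonds=np.zeros((0, 2), int), bond_r0=np.zeros(0), bond_k=np.zeros(0),
        chain_id=chain_of, chain_kinds=list(kinds),
        chain_rigid=[False] * n_chains)
    frame = SimulationFrame(coordinates=np.asarray(coords, dtype=float),
                            box=np.array([box] * 3))
    return frame, topo


class TestContactCriterion:
    def test_boundary_arithmetic_of_113_rule(self):
        # sigma 5 and 7: threshold 1.13 * 6 = 6.78 A
        for dist, expected in ((6.5, True), (6.9, False)):
            frame, topo = bead_system(
                [5.0, 7.0], [[10.0, 10.0, 10.0], [10.0 + dist, 10.0, 10.0]])
            cm = contact_matrix(frame, topo)
            assert bool(cm[0, 1]) is expected

    def test_matches_brute_force_oracle_on_random_frames(self):
        """Standing property: 100 random frames vs pure-Python O(N^2) loop."""
        for trial in range(100):
            n = 10 + trial % 30
            frame, topo = random_bead_frame(n, box=30.0, seed=trial)
            cm = contact_matrix(frame, topo)
            coords, box = frame.coordinates, frame.box
            for i in range(n):
                for j in range(i + 1, n):
                    d = coords[i] - coords[j]
                    d = d - box * np.round(d / box)
                    r = np.sqrt((d * d).sum())
                    expected = r < 1.13 * 0.5 * (topo.sigmas[i] + topo.sigmas[j])
                    assert cm[i, j] == expected

    def test_bonded_neighbours_excluded(self):
        from phaseslab.sequences import ProteinSequence
        from phaseslab.topology import build_protein_topology
        topo = build_protein_topology(ProteinSequence("x", "GGGGG"))
        coords = np.column_stack([np.arange(5) * 3.81, np.zeros(5), np.zeros(5)])
        frame = SimulationFrame(coordinates=coords + 50.0,
                                box=np.array([120.0] * 3))
        cm = contact_matrix(frame, topo)
        assert not cm[0, 1] and not cm[0, 2]   # <= 2 bonds apart
        # 3 bonds apart is eligible (distance 11.43 > threshold so still False,
        # but the mask itself must allow it at short distance)
        coords2 = coords.copy()
        coords2[3] = coords[0] + np.array([4.0, 0.0, 0.0])
        frame2 = SimulationFrame(coordinates=coords2 + 50.0,
                                 box=np.array([120.0] * 3))
        assert contact_matrix(frame2, topo)[0, 3]


class TestAggregateMap:
    def _two_chain_system(self, separation):
        coords = [[10.0, 10.0, 10.0], [16.0, 10.0, 10.0],
                  [10.0 + separation, 10.0, 16.0],
                  [16.0 + separation, 10.0, 16.0]]
        return bead_system([6.0] * 4, coords, chain_of=[0, 0, 1, 1])

    def test_single_frame_single_pair_identity(self):
        frame, topo = self._two_chain_system(3.0)
        traj = Trajectory([frame], topo, 300.0)
        cmap = aggregate_contact_map(traj, topo, "protein-protein")
        cm = contact_matrix(frame, topo)
        block = cm[np.ix_([0, 1], [2, 3])].astype(float)
        assert np.allclose(cmap.frequency, 0.5 * (block + block.T))

    def test_idempotent_under_frame_duplication(self):
        frame, topo = self._two_chain_system(3.0)
        t1 = Trajectory([frame], topo, 300.0)
        t2 = Trajectory([frame, frame], topo, 300.0)
        a = aggregate_contact_map(t1, topo, "protein-protein").frequency
        b = aggregate_contact_map(t2, topo, "protein-protein").frequency
        assert np.allclose(a, b)

    def test_half_frequency_construction(self):
        """Residue touching a bp in half the frames -> entry 0.5."""
        near, topo = bead_system(
            [6.0, 10.0], [[10.0, 10.0, 10.0], [10.0, 10.0, 16.0]],
            kinds=["protein", "dna"], chain_of=[0, 1])
        far = SimulationFrame(
            coordinates=np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 60.0]]),
            box=near.box)
        traj = Trajectory([near, far], topo, 300.0)
        cmap = aggregate_contact_map(traj, topo, "protein-dna")
        assert cmap.frequency[0, 0] == pytest.approx(0.5)

    def test_entries_bounded_by_one(self):
        frame, topo = self._two_chain_system(0.5)
        traj = Trajectory([frame] * 3, topo, 300.0)
        freq = aggregate_contact_map(traj, topo, "protein-protein").frequency
        assert ((freq >= 0) & (freq <= 1)).all()

    def test_missing_selection_errors(self):
        frame, topo = self._two_chain_system(3.0)
        with pytest.raises(ValueError):
            aggregate_contact_map(Trajectory([frame], topo, 300.0), topo,
                                  "protein-dna")


def valency_fixture(contact_counts):
    """One 12-bead strand plus protein chains making given contact counts."""
    strand_sig, prot_sig = 10.0, 6.0
    coords = [[50.0, 50.0, 50.0 + 3.4 * k] for k in range(12)]
    sigmas = [strand_sig] * 12
    chain_of = [0] * 12
    kinds = ["dna"]
    cid = 1
    for count in contact_counts:
        for k in range(5):
            if k < count:
                # threshold is 1.13*(10+6)/2 = 9.04 A; an 8.9 A lateral
                # offset touches bp k only (diagonal to bp k+1 is 9.53 A)
                coords.append([50.0 + 8.9, 50.0, 50.0 + 3.4 * k])
            else:           # far away
                coords.append([150.0 + 10.0 * cid, 150.0, 20.0 * k])
            sigmas.append(prot_sig)
            chain_of.append(cid)
        kinds.append("protein")
        cid += 1
    frame, topo = bead_system(sigmas, coords, box=400.0,
                              kinds=kinds, chain_of=chain_of)
    # mark strand rigid as in real topologies
    topo.chain_rigid[0] = True
    return Trajectory([frame], topo, 300.0), topo


class TestValency:
    def test_exactly_three_contacts_counts_once(self):
        traj, topo = valency_fixture([3])
        res = dna_valency(traj, topo)
        assert res.per_strand.tolist() == [1.0]

    def test_two_contacts_below_threshold(self):
        traj, topo = valency_fixture([2])
        assert dna_valency(traj, topo).per_strand.tolist() == [0.0]

    def test_two_qualifying_chains(self):
        traj, topo = valency_fixture([5, 3])
        res = dna_valency(traj, topo)
        assert res.per_strand.tolist() == [2.0]
        assert res.mean_valency == 2.0

    def test_monotone_in_min_contacts(self):
        traj, topo = valency_fixture([5, 3, 2, 1])
        vals = [dna_valency(traj, topo, min_contacts=k).mean_valency
                for k in (1, 2, 3, 4, 5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_no_dna_errors(self):
        frame, topo = bead_system([6.0, 6.0],
                                  [[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            dna_valency(Trajectory([frame], topo, 300.0), topo)


class TestContactEnergy:
    def test_single_pair_identity(self, electrostatics, pair_table):
        from phaseslab.energy import debye_huckel_energy, wang_frenkel_energy
        frame, topo = bead_system(
            [6.0, 10.0], [[10.0, 10.0, 10.0], [10.0, 10.0, 17.0]],
            kinds=["protein", "dna"], chain_of=[0, 1])
        topo.charges[:] = [1.0, -2.0]
        traj = Trajectory([frame], topo, 300.0)
        res = mean_contact_energy(traj, topo, electrostatics, "protein-dna")
        i = pair_table.index["ALA"]
        expected = wang_frenkel_energy(7.0, pair_table.eps[i, i],
                                       pair_table.sigma[i, i],
                                       pair_table.mu[i, i],
                                       pair_table.nu[i, i])
        expected += debye_huckel_energy(7.0, 1.0, -2.0, electrostatics)
        assert res.mean_kT == pytest.approx(expected / (KB * 300.0))
        assert res.n_contacts == 1

    def test_temperature_scaling_of_kT_units(self, electrostatics):
        frame, topo = bead_system(
            [6.0, 10.0], [[10.0, 10.0, 10.0], [10.0, 10.0, 17.0]],
            kinds=["protein", "dna"], chain_of=[0, 1])
        traj = Trajectory([frame], topo, 300.0)
        e300 = mean_contact_energy(traj, topo, electrostatics, "protein-dna",
                                   temperature=300.0)
        e600 = mean_contact_energy(traj, topo, electrostatics, "protein-dna",
                                   temperature=600.0)
        assert e600.magnitude_kT == pytest.approx(e300.magnitude_kT / 2.0)

    def test_zero_contacts_errors(self, electrostatics):
        frame, topo = bead_system(
            [6.0, 10.0], [[10.0, 10.0, 10.0], [10.0, 10.0, 90.0]],
            kinds=["protein", "dna"], chain_of=[0, 1])
        with pytest.raises(ValueError):
            mean_contact_energy(Trajectory([frame], topo, 300.0), topo,
                                electrostatics, "protein-dna")
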