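"""Langevin dynamics and the Direct Coexistence protocol.

The integrator is BAOAB Langevin: with friction zero (and hence no noise) it
reduces exactly to velocity Verlet, which the energy-conservation tests
exploit. Protein chains are fully flexible; DNA duplexes are propagated as
rigid bodies (translation of the center of mass plus rotation about it, with
matching rotational friction and noise). Inertia tensors include each bead's
own spherical inertia so rotation about a duplex axis stays well defined.

The Direct Coexistence protocol mirrors the standard slab construction:
random insertion in a cubic box, Berendsen NPT compression at a few tens of
bars to a dense liquid, elongation of the z axis by a fixed factor, then NVT
production during which frames, energies and densities are recorded. The
liquid-liquid phase separation flag is read from the time-averaged density
profile of the final third of production (interface criterion in
:mod:`phaseslab.phase`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import DA_PER_A3_TO_G_CM3, FTM2V, KB, MV2E, PRESS2BAR
from .energy import ElectrostaticsSpec, EnergyModel
from .topology import BeadTopology

#: Berendsen effective-compressibility parameter, 1/bar. Coarse-grained
#: protein fluids are far softer than water; this value gives useful
#: compression rates at a 1 ps coupling time without destabilising the box
#: (per-step volume changes are clamped regardless).
BERENDSEN_KAPPA = 4.5e-3


class SimulationUnstableError(RuntimeError):
    """Raised on non-finite coordinates; carries the last stable frame."""

    def __init__(self, message: str, last_frame: "SimulationFrame | None" = None):
        super().__init__(message)
        self.last_frame = last_frame


@dataclass
class SimulationFrame:
    coordinates: np.ndarray            # (N, 3) A, wrapped into the box
    box: np.ndarray                    # 3 edge lengths, A (orthorhombic)
    time: float = 0.0                  # ns
    velocities: np.ndarray | None = None   # (N, 3) A/fs
    energies: dict | None = None       # per-term potential, kcal/mol
    temperature: float | None = None   # instantaneous kinetic temperature, K


@dataclass
class Trajectory:
    frames: list
    topology: BeadTopology
    temperature: float                 # thermostat setpoint, K
    stride_ns: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MonitorSeries:
    """Convergence monitors sampled alongside stored frames."""

    time_ns: np.ndarray
    potential_kcal: np.ndarray
    kinetic_kcal: np.ndarray
    temperature_K: np.ndarray
    density_g_cm3: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_ns)
        for arr in (self.potential_kcal, self.kinetic_kcal,
                    self.temperature_K, self.density_g_cm3):
            if len(arr) != n:
                raise ValueError("monitor channels must share one length")


@dataclass
class ProtocolConfig:
    """Direct Coexistence run parameters (desk-scale defaults)."""

    temperature: float = 300.0         # K
    pressure_target: float = 25.0      # bar, NPT stage
    elongation_factor: float = 3.0
    timestep: float = 10.0             # fs
    friction: float = 0.01             # 1/fs (= 10/ps)
    npt_friction: float | None = None  # heavier damping during compression
    npt_duration_ns: float = 0.05
    production_duration_ns: float = 0.2
    stride_ns: float = 0.01            # frame/monitor stride in production
    seed: int = 0
    n_protein: int = 48
    n_dna: int = 12
    initial_box: float | None = None   # cubic edge, A; None -> from density
    initial_density_g_cm3: float = 0.03
    barostat_tau_fs: float = 1000.0
    tc_wildtype_K: float = 160.0       # conversion constant for reduced T
    #: per-bead speed cap, A/fs. Thermal speeds here are ~2e-3 A/fs, so the
    #: cap only engages in pathological close-contact events (e.g. a barostat
    #: step landing two beads inside the repulsive core) and dissipates them
    #: instead of letting them run away.
    velocity_cap: float = 0.05
    #: interface-criterion dials used for the llps flag (see
    #: phaseslab.phase.coexistence_densities); desk-scale condensates are
    #: only a few interface widths thick, so small systems may need the
    #: plateau requirement relaxed (0 disables it) and the contrast raised.
    llps_contrast_ratio: float = 10.0
    llps_min_plateau_widths: float = 3.0
    #: additionally require the mass to be localized along the slab axis
    #: (phase.mass_localization <= this fraction of the box; 1.0 disables).
    #: A spreading supercritical cloud keeps near-empty box edges for a
    #: while, which fools contrast-based detection; localization does not.
    llps_max_localization: float = 1.0


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return coords - box * np.floor(coords / box)


class _RigidBody:
    def __init__(self, idx: np.ndarray, coords: np.ndarray, masses: np.ndarray,
                 sigmas: np.ndarray):
        self.idx = idx
        m = masses[idx]
        self.mass = float(m.sum())
        com = (coords[idx] * m[:, None]).sum(axis=0) / self.mass
        self.com = com
        self.ref = coords[idx] - com           # body frame at R = identity
        # inertia: point masses + per-bead solid-sphere term (regularises
        # rotation about the axis of a linear duplex)
        ib = np.zeros((3, 3))
        for k in range(len(idx)):
            r = self.ref[k]
            ib += m[k] * ((r @ r) * np.eye(3) - np.outer(r, r))
            ib += (2.0 / 5.0) * m[k] * (0.5 * sigmas[idx[k]]) ** 2 * np.eye(3)
        self.i_body = ib
        self.rot = np.eye(3)
        self.vcom = np.zeros(3)
        self.omega = np.zeros(3)               # lab frame, rad/fs

    def i_world(self) -> np.ndarray:
        return self.rot @ self.i_body @ self.rot.T

    def bead_coords(self) -> np.ndarray:
        return self.com + self.ref @ self.rot.T


class Simulator:
    """Owns coordinates, velocities, rigid-body states and the RNG."""

    def __init__(self, topo: BeadTopology, spec: ElectrostaticsSpec,
                 config: ProtocolConfig, coords: np.ndarray, box: np.ndarray,
                 rng: np.random.Generator | None = None):
        self.topo = topo
        self.spec = spec
        self.config = config
        self.model = EnergyModel(topo, spec)
        self.box = np.asarray(box, dtype=float).copy()
        self.coords = np.asarray(coords, dtype=float).copy()
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.time_fs = 0.0

        rigid_chains = [c for c in range(topo.n_chains) if topo.chain_rigid[c]]
        self.bodies = [
            _RigidBody(topo.chain_beads(c), self.coords, topo.masses, topo.sigmas)
            for c in rigid_chains
        ]
        flex_mask = np.ones(topo.n_beads, dtype=bool)
        for b in self.bodies:
            flex_mask[b.idx] = False
        self.flex = np.flatnonzero(flex_mask)
        self.masses_flex = topo.masses[self.flex]
        self.dof = 3 * len(self.flex) + 6 * len(self.bodies)
        self.vel = np.zeros((topo.n_beads, 3))
        self.init_velocities(config.temperature)
        self.forces, self.energies, self.virial = self.model.energy_forces(
            self.coords, self.box)

    # -- state ------------------------------------------------------------

    def init_velocities(self, temperature: float) -> None:
        sig = np.sqrt(KB * temperature / (self.topo.masses * MV2E))
        self.vel = self.rng.normal(size=(self.topo.n_beads, 3)) * sig[:, None]
        for b in self.bodies:
            b.vcom = self.rng.normal(size=3) * np.sqrt(
                KB * temperature / (b.mass * MV2E))
            iw = b.i_world()
            evals, evecs = np.linalg.eigh(iw)
            w_p = self.rng.normal(size=3) * np.sqrt(KB * temperature / (evals * MV2E))
            b.omega = evecs @ w_p
        # remove net linear momentum (flexible beads + body COMs)
        ptot = (self.vel[self.flex] * self.masses_flex[:, None]).sum(axis=0)
        mtot = self.masses_flex.sum()
        for b in self.bodies:
            ptot += b.vcom * b.mass
            mtot += b.mass
        vdrift = ptot / mtot
        self.vel[self.flex] -= vdrift
        for b in self.bodies:
            b.vcom -= vdrift

    def kinetic_energy(self) -> float:
        ke = 0.5 * MV2E * float(
            (self.masses_flex[:, None] * self.vel[self.flex] ** 2).sum())
        for b in self.bodies:
            ke += 0.5 * MV2E * b.mass * float(b.vcom @ b.vcom)
            ke += 0.5 * MV2E * float(b.omega @ b.i_world() @ b.omega)
        return ke

    def instantaneous_temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (self.dof * KB)

    def total_momentum(self) -> np.ndarray:
        p = (self.vel[self.flex] * self.masses_flex[:, None]).sum(axis=0)
        for b in self.bodies:
            p = p + b.vcom * b.mass
        return p

    def density(self) -> float:
        return float(self.topo.masses.sum() / np.prod(self.box)) * DA_PER_A3_TO_G_CM3

    def pressure_bar(self) -> float:
        """Instantaneous virial pressure from the last force evaluation."""
        ke_trans = 0.5 * MV2E * float(
            (self.masses_flex[:, None] * self.vel[self.flex] ** 2).sum())
        for b in self.bodies:
            ke_trans += 0.5 * MV2E * b.mass * float(b.vcom @ b.vcom)
        vol = float(np.prod(self.box))
        p = (2.0 * ke_trans + self.virial) / (3.0 * vol)
        return p * PRESS2BAR

    def frame(self) -> SimulationFrame:
        return SimulationFrame(
            coordinates=_wrap(self.coords.copy(), self.box),
            box=self.box.copy(),
            time=self.time_fs * 1e-6,
            velocities=self.vel.copy(),
            energies=dict(self.energies),
            temperature=self.instantaneous_temperature(),
        )

    # -- integration -------------------------------------------------------

    def _sync_rigid_coords(self) -> None:
        for b in self.bodies:
            self.coords[b.idx] = b.bead_coords()

    def _kick(self, half_dt: float) -> None:
        acc = self.forces[self.flex] / self.masses_flex[:, None] * FTM2V
        self.vel[self.flex] += half_dt * acc
        for b in self.bodies:
            f_tot = self.forces[b.idx].sum(axis=0)
            arm = b.bead_coords() - b.com
            torque = np.cross(arm, self.forces[b.idx]).sum(axis=0)
            b.vcom += half_dt * f_tot / b.mass * FTM2V
            b.omega += half_dt * (np.linalg.solve(b.i_world(), torque)) * FTM2V
        self._cap_velocities()

    def _cap_velocities(self) -> None:
        vmax = self.config.velocity_cap
        if vmax <= 0:
            return
        speed = np.sqrt((self.vel[self.flex] ** 2).sum(axis=1))
        over = speed > vmax
        if over.any():
            idx = self.flex[over]
            self.vel[idx] *= (vmax / speed[over])[:, None]
        for b in self.bodies:
            s = float(np.linalg.norm(b.vcom))
            if s > vmax:
                b.vcom *= vmax / s
            # cap tip speed of the rotating body
            arm = max(float(np.linalg.norm(b.ref, axis=1).max()), 1.0)
            w = float(np.linalg.norm(b.omega))
            if w * arm > vmax:
                b.omega *= vmax / (w * arm)

    def _drift(self, half_dt: float) -> None:
        self.coords[self.flex] += half_dt * self.vel[self.flex]
        for b in self.bodies:
            b.com = b.com + half_dt * b.vcom
            w = b.omega * half_dt
            if (w @ w) > 0:
                b.rot = Rotation.from_rotvec(w).as_matrix() @ b.rot
        self._sync_rigid_coords()

    def _thermostat(self, dt: float, temperature: float, friction: float) -> None:
        if friction <= 0.0:
            return
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        sig = np.sqrt(KB * temperature / (self.masses_flex * MV2E))
        self.vel[self.flex] = (c1 * self.vel[self.flex]
                               + c2 * sig[:, None]
                               * self.rng.normal(size=(len(self.flex), 3)))
        for b in self.bodies:
            sv = np.sqrt(KB * temperature / (b.mass * MV2E))
            b.vcom = c1 * b.vcom + c2 * sv * self.rng.normal(size=3)
            evals, evecs = np.linalg.eigh(b.i_world())
            w_p = evecs.T @ b.omega
            sw = np.sqrt(KB * temperature / (evals * MV2E))
            w_p = c1 * w_p + c2 * sw * self.rng.normal(size=3)
            b.omega = evecs @ w_p

    def step(self, dt: float | None = None, temperature: float | None = None,
             friction: float | None = None) -> None:
        """One BAOAB step (reduces to velocity Verlet at zero friction)."""
        cfg = self.config
        dt = cfg.timestep if dt is None else dt
        temperature = cfg.temperature if temperature is None else temperature
        friction = cfg.friction if friction is None else friction
        self._kick(0.5 * dt)
        self._drift(0.5 * dt)
        self._thermostat(dt, temperature, friction)
        self._drift(0.5 * dt)
        if not np.isfinite(self.coords).all():
            raise SimulationUnstableError(
                "non-finite coordinates: reduce the timestep", None)
        if self.config.friction > 0 and \
                self.instantaneous_temperature() > \
                50.0 * max(self.config.temperature, 1.0):
            raise SimulationUnstableError(
                "kinetic temperature ran away: reduce the timestep", None)
        self.forces, self.energies, self.virial = self.model.energy_forces(
            self.coords, self.box)
        self._kick(0.5 * dt)
        self.time_fs += dt

    def _scale_molecules(self, factor: float) -> None:
        """Isotropic molecular (per-chain COM) coordinate scaling.

        Chains are first translated so their COM lies inside the box
        (a pure PBC shift), which bounds the per-step displacement to
        |factor - 1| * box — scaling unwrapped coordinates about the origin
        can otherwise slam distant chains into each other.
        """
        topo = self.topo
        for c in range(topo.n_chains):
            idx = topo.chain_beads(c)
            m = topo.masses[idx]
            com = (self.coords[idx] * m[:, None]).sum(axis=0) / m.sum()
            wrapped = com - self.box * np.floor(com / self.box)
            self.coords[idx] += (wrapped - com) + (factor - 1.0) * wrapped
        for b in self.bodies:
            wrapped = b.com - self.box * np.floor(b.com / self.box)
            b.com = wrapped * factor
        self._sync_rigid_coords()
        self.box *= factor

    def berendsen_barostat(self, dt: float, pressure_target_bar: float,
                           tau_fs: float) -> None:
        p = self.pressure_bar()
        mu3 = 1.0 - BERENDSEN_KAPPA * dt / tau_fs * (pressure_target_bar - p)
        mu = float(np.clip(mu3, 0.99, 1.01)) ** (1.0 / 3.0)
        if mu != 1.0:
            self._scale_molecules(mu)
            self.forces, self.energies, self.virial = self.model.energy_forces(
                self.coords, self.box)

    # -- stages ------------------------------------------------------------

    def run(self, n_steps: int, record_every: int = 0, npt: bool = False,
            collect_frames: bool = False, friction: float | None = None):
        """Advance ``n_steps``; optionally record monitors / frames."""
        monitors = {k: [] for k in ("time_ns", "potential_kcal", "kinetic_kcal",
                                    "temperature_K", "density_g_cm3")}
        frames: list[SimulationFrame] = []
        for i in range(n_steps):
            self.step(friction=friction)
            if npt:
                self.berendsen_barostat(self.config.timestep,
                                        self.config.pressure_target,
                                        self.config.barostat_tau_fs)
            if record_every and (i + 1) % record_every == 0:
                monitors["time_ns"].append(self.time_fs * 1e-6)
                monitors["potential_kcal"].append(self.energies["total"])
                monitors["kinetic_kcal"].append(self.kinetic_energy())
                monitors["temperature_K"].append(self.instantaneous_temperature())
                monitors["density_g_cm3"].append(self.density())
                if collect_frames:
                    frames.append(self.frame())
        series = MonitorSeries(**{k: np.array(v) for k, v in monitors.items()})
        return series, frames

    def _make_chains_whole(self) -> None:
        """Rebuild every flexible chain contiguously and put COMs in the box.

        Walking bead-to-bead with minimum-image displacements removes any
        boundary straddling, and a whole-chain shift by box multiples then
        places the COM inside the box. Pure periodic-boundary operations —
        minimum-image geometry is unchanged — but absolute coordinates end
        up compact, which is required before the box dimensions change
        (a straddling bond would otherwise unfold under the new box).
        """
        topo = self.topo
        rigid_chains = {topo.chain_id[b.idx[0]] for b in self.bodies}
        for c in range(topo.n_chains):
            if c in rigid_chains:
                continue
            idx = topo.chain_beads(c)
            p = self.coords[idx]
            if len(idx) > 1:
                d = np.diff(p, axis=0)
                d -= self.box * np.round(d / self.box)
                p = np.vstack([p[0], p[0] + np.cumsum(d, axis=0)])
            m = topo.masses[idx]
            com = (p * m[:, None]).sum(axis=0) / m.sum()
            self.coords[idx] = p - self.box * np.floor(com / self.box)
        for b in self.bodies:
            b.com = b.com - self.box * np.floor(b.com / self.box)
        self._sync_rigid_coords()

    def elongate(self, factor: float, axis: int = 2) -> None:
        """Stretch one box edge, keeping the dense configuration centered.

        Chains are wrapped into the current box first: elongating with
        far-unwrapped coordinates would reassign minimum images under the
        new box length and teleport chains onto each other.
        """
        if factor < 1.0:
            raise ValueError("elongation factor must be >= 1")
        self._make_chains_whole()
        old = self.box[axis]
        self.coords[:, axis] += 0.5 * (factor - 1.0) * old
        for b in self.bodies:
            b.com[axis] += 0.5 * (factor - 1.0) * old
        self.box[axis] = old * factor
        self._sync_rigid_coords()
        self.forces, self.energies, self.virial = self.model.energy_forces(
            self.coords, self.box)


# ---------------------------------------------------------------------------
# protocol operations
# ---------------------------------------------------------------------------

def initialize_system(topo: BeadTopology, box: float | np.ndarray, seed: int = 0,
                      min_separation_factor: float = 0.8,
                      max_tries_per_chain: int = 200) -> SimulationFrame:
    """Place all chains with random positions/orientations, overlap-free.

    Protein chains get a persistent-random-walk conformation at the backbone
    bond length; rigid chains keep their straight reference geometry. Two
    beads may not come closer than ``min_separation_factor`` times the mean
    of their diameters. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray([box] * 3, dtype=float) if np.isscalar(box) else \
        np.asarray(box, dtype=float)
    placed = np.zeros((0, 3))
    placed_sig = np.zeros(0)
    coords = np.zeros((topo.n_beads, 3))
    for c in range(topo.n_chains):
        idx = topo.chain_beads(c)
        ref = _chain_conformation(topo, c, rng)
        ref = ref - ref.mean(axis=0)
        sig_c = topo.sigmas[idx]
        ok = False
        for _ in range(max_tries_per_chain):
            rot = Rotation.random(rng=rng).as_matrix()
            com = rng.uniform(0.0, 1.0, size=3) * box
            trial = ref @ rot.T + com
            if len(placed):
                d = trial[:, None, :] - placed[None, :, :]
                d -= box * np.round(d / box)
                r = np.sqrt((d * d).sum(axis=2))
                thresh = min_separation_factor * 0.5 * (
                    sig_c[:, None] + placed_sig[None, :])
                if (r < thresh).any():
                    continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place chain {c} without overlap after "
                f"{max_tries_per_chain} tries; use a larger box")
        coords[idx] = trial
        placed = np.vstack([placed, trial])
        placed_sig = np.concatenate([placed_sig, sig_c])
    return SimulationFrame(coordinates=_wrap(coords, box), box=box)


def _chain_conformation(topo: BeadTopology, chain: int,
                        rng: np.random.Generator) -> np.ndarray:
    idx = topo.chain_beads(chain)
    n = len(idx)
    if topo.chain_rigid[chain] or topo.chain_kinds[chain] == "dna":
        # straight duplex along z at the helical rise
        rise = topo.bond_r0[0] if len(topo.bond_r0) else 3.4
        bond_idx = [k for k, (a, b) in enumerate(topo.bonds)
                    if topo.chain_id[a] == chain]
        if bond_idx:
            rise = float(topo.bond_r0[bond_idx[0]])
        return np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * rise])
    # persistent random walk at the backbone bond length
    r0 = 3.81
    bond_idx = [k for k, (a, b) in enumerate(topo.bonds)
                if topo.chain_id[a] == chain]
    if bond_idx:
        r0 = float(topo.bond_r0[bond_idx[0]])
    pts = [np.zeros(3)]
    direction = _random_unit(rng)
    for _ in range(n - 1):
        for _try in range(50):
            perturb = _random_unit(rng)
            new_dir = direction + 0.8 * perturb
            new_dir /= np.linalg.norm(new_dir)
            cand = pts[-1] + r0 * new_dir
            if len(pts) < 3 or (np.linalg.norm(
                    np.array(pts[:-1]) - cand, axis=1) > 0.9 * r0).all():
                break
        pts.append(cand)
        direction = new_dir
    return np.array(pts)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def langevin_step(frame: SimulationFrame, topo: BeadTopology,
                  spec: ElectrostaticsSpec, dt: float, friction: float,
                  temperature: float,
                  rng: np.random.Generator) -> SimulationFrame:
    """Single BAOAB update of a frame (convenience wrapper over Simulator)."""
    if dt <= 0:
        raise ValueError("timestep must be positive")
    cfg = ProtocolConfig(temperature=temperature, timestep=dt, friction=friction)
    sim = Simulator(topo, spec, cfg, frame.coordinates, frame.box, rng=rng)
    if frame.velocities is not None:
        sim.vel = np.asarray(frame.velocities, dtype=float).copy()
    sim.step()
    return sim.frame()


def equilibrate_npt(frame: SimulationFrame, topo: BeadTopology,
                    spec: ElectrostaticsSpec,
                    config: ProtocolConfig) -> tuple[SimulationFrame, MonitorSeries]:
    """Berendsen NPT compression toward ``config.pressure_target``."""
    sim = Simulator(topo, spec, config, frame.coordinates, frame.box,
                    rng=np.random.default_rng(config.seed))
    n_steps = max(1, int(round(config.npt_duration_ns * 1e6 / config.timestep)))
    record = max(1, n_steps // 200)
    series, _ = sim.run(n_steps, record_every=record, npt=True)
    if not np.isfinite(sim.box).all() or (sim.box <= 0).any():
        raise SimulationUnstableError("box volume diverged during NPT", None)
    return sim.frame(), series


def run_direct_coexistence(topo: BeadTopology, spec: ElectrostaticsSpec,
                           config: ProtocolConfig):
    """Compress -> elongate (z) -> NVT production; returns
    (Trajectory, MonitorSeries, llps_flag)."""
    from .phase import (  # no cycle
        coexistence_densities,
        density_profile,
        mass_localization,
    )

    if config.initial_box is not None:
        edge = float(config.initial_box)
    else:
        vol = topo.masses.sum() * DA_PER_A3_TO_G_CM3 / config.initial_density_g_cm3
        edge = vol ** (1.0 / 3.0)
    frame0 = initialize_system(topo, edge, seed=config.seed)
    sim = Simulator(topo, spec, config, frame0.coordinates, frame0.box,
                    rng=np.random.default_rng(config.seed))

    # compression benefits from heavier damping (suppresses the rare close
    # approaches a shrinking box can generate); production uses the
    # configured friction so transport is not artificially drag-limited
    npt_fric = config.npt_friction if config.npt_friction is not None \
        else max(config.friction, 0.01)
    npt_steps = max(1, int(round(config.npt_duration_ns * 1e6 / config.timestep)))
    sim.run(npt_steps, npt=True, friction=npt_fric)

    sim.elongate(config.elongation_factor, axis=2)

    prod_steps = max(1, int(round(
        config.production_duration_ns * 1e6 / config.timestep)))
    stride_steps = max(1, int(round(config.stride_ns * 1e6 / config.timestep)))
    series, frames = sim.run(prod_steps, record_every=stride_steps,
                             collect_frames=True)
    traj = Trajectory(frames=frames, topology=topo,
                      temperature=config.temperature,
                      stride_ns=config.stride_ns,
                      metadata={"elongation_factor": config.elongation_factor,
                                "seed": config.seed})
    # flag from the time-averaged profile of the final third of production
    # (early production can retain the compressed blob while it relaxes)
    tail = max(0, (2 * len(frames)) // 3)
    profile = density_profile(traj, axis="z", n_bins=40,
                              frame_range=(tail, len(frames)))
    _, _, llps_flag = coexistence_densities(
        profile, contrast_ratio=config.llps_contrast_ratio,
        min_plateau_widths=config.llps_min_plateau_widths)
    if llps_flag and mass_localization(profile) > config.llps_max_localization:
        llps_flag = False
    return traj, series, llps_flag
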