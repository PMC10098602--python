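"""Energy model: Wang-Frenkel short-range term, Debye-Huckel electrostatics,
harmonic bonds, and a vectorised all-pairs evaluator with analytic forces.

The Wang-Frenkel potential

    U(r) = eps * alpha * ((sigma/r)^(2 mu) - 1) * ((rc/r)^(2 mu) - 1)^(2 nu)

with ``alpha`` chosen so the minimum depth is exactly ``-eps``, is zero at
``r = sigma`` and identically zero at and beyond its cutoff ``rc = 3 sigma``,
so no truncation shift is needed. Screened electrostatics use the
Debye-Huckel form truncated and shifted at a fixed cutoff (35 A default).
Bonds are harmonic, ``U = k (r - r0)^2``.

Nonbonded exclusions: directly bonded (1-2) pairs, and all intra-chain pairs
of rigid chains (their internal energy is constant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import COULOMB, debye_length_angstrom
from .params import PairTable
from .topology import BeadTopology

WF_CUTOFF_FACTOR = 3.0
DH_CUTOFF_DEFAULT = 35.0
#: below this fraction of sigma the Wang-Frenkel core is continued
#: linearly (constant force). U(0.6 sigma) is already hundreds of kcal/mol
#: — never visited in equilibrium — but the unmodified core reaches ~1e6,
#: enough for a single overlap (e.g. from a barostat move) to launch a
#: heating cascade; the linear core keeps such events integrable.
WF_CORE_FRACTION = 0.6


@dataclass(frozen=True)
class ElectrostaticsSpec:
    """Debye-Huckel parameters; the screening length is derived.

    ``ionic_strength`` in mol/L, ``temperature`` in K, ``cutoff`` in A.
    """

    ionic_strength: float = 0.150
    temperature: float = 300.0
    epsilon_r: float = 80.0
    cutoff: float = DH_CUTOFF_DEFAULT
    debye_length_A: float | None = None

    def __post_init__(self) -> None:
        lam = debye_length_angstrom(self.ionic_strength, self.temperature,
                                    self.epsilon_r)
        if self.debye_length_A is None:
            object.__setattr__(self, "debye_length_A", lam)
        elif abs(self.debye_length_A - lam) > 1e-6 * lam:
            raise ValueError(
                f"stored Debye length {self.debye_length_A} inconsistent with "
                f"recomputed {lam}")


def debye_length(spec: ElectrostaticsSpec) -> float:
    """Screening length (A); strictly decreasing in ionic strength."""
    return debye_length_angstrom(spec.ionic_strength, spec.temperature,
                                 spec.epsilon_r)


def wf_alpha(rc_over_sigma, mu, nu):
    rcs = np.asarray(rc_over_sigma, dtype=float) ** (2.0 * mu)
    return (2.0 * nu * rcs
            * ((1.0 + 2.0 * nu) / (2.0 * nu * (rcs - 1.0))) ** (2.0 * nu + 1.0))


def _wf_smooth_energy(r, eps, sigma, mu, nu, rc, alpha):
    with np.errstate(divide="ignore"):
        x = (sigma / r) ** (2.0 * mu)
        y = (rc / r) ** (2.0 * mu)
    return eps * alpha * (x - 1.0) * (y - 1.0) ** (2.0 * nu)


def _wf_smooth_dudr(r, eps, sigma, mu, nu, rc, alpha):
    x = (sigma / r) ** (2.0 * mu)
    y = (rc / r) ** (2.0 * mu)
    return -(2.0 * mu * eps * alpha / r) * (
        x * (y - 1.0) ** (2.0 * nu)
        + 2.0 * nu * y * (x - 1.0) * (y - 1.0) ** (2.0 * nu - 1.0))


def wang_frenkel_energy(r, eps, sigma, mu=2.0, nu=1.0, rc=None):
    """Wang-Frenkel pair energy (kcal/mol); exactly zero at and beyond rc.

    Below ``WF_CORE_FRACTION * sigma`` the repulsive core continues
    linearly (C1, constant force) so accidental deep overlaps carry large
    but bounded energies.
    """
    r = np.asarray(r, dtype=float)
    rc = WF_CUTOFF_FACTOR * sigma if rc is None else rc
    alpha = wf_alpha(rc / sigma, mu, nu)
    r_core = WF_CORE_FRACTION * sigma
    r_eff = np.maximum(r, r_core)
    u = _wf_smooth_energy(r_eff, eps, sigma, mu, nu, rc, alpha)
    core = r < r_core
    if np.any(core):
        u_core = _wf_smooth_energy(r_core, eps, sigma, mu, nu, rc, alpha)
        g_core = _wf_smooth_dudr(r_core, eps, sigma, mu, nu, rc, alpha)
        u = np.where(core, u_core + g_core * (r - r_core), u)
    u = np.where(r < rc, u, 0.0)
    return float(u) if u.ndim == 0 else u


def wang_frenkel_dudr(r, eps, sigma, mu=2.0, nu=1.0, rc=None):
    """Radial derivative dU/dr of the (core-linearised) Wang-Frenkel form."""
    r = np.asarray(r, dtype=float)
    rc = WF_CUTOFF_FACTOR * sigma if rc is None else rc
    alpha = wf_alpha(rc / sigma, mu, nu)
    r_core = WF_CORE_FRACTION * sigma
    r_eff = np.maximum(r, r_core)
    grad = _wf_smooth_dudr(r_eff, eps, sigma, mu, nu, rc, alpha)
    grad = np.where(r < rc, grad, 0.0)
    return float(grad) if grad.ndim == 0 else grad


def debye_huckel_energy(r, q_i, q_j, spec: ElectrostaticsSpec,
                        shifted: bool = True):
    """Screened Coulomb pair energy (kcal/mol), truncated-and-shifted at the
    spec cutoff. With ``shifted=False`` the bare screened form is returned
    (useful for analytic-limit checks)."""
    r = np.asarray(r, dtype=float)
    pref = COULOMB * q_i * q_j / spec.epsilon_r
    lam = spec.debye_length_A
    u = pref / r * np.exp(-r / lam)
    if shifted:
        u_rc = pref / spec.cutoff * np.exp(-spec.cutoff / lam)
        u = np.where(r < spec.cutoff, u - u_rc, 0.0)
    return float(u) if u.ndim == 0 else u


class EnergyModel:
    """Precomputed all-pairs evaluator for a fixed topology.

    Builds static per-pair parameter arrays once (indices, Wang-Frenkel
    eps/sigma/mu/nu, charge products, exclusion mask) so each call to
    :meth:`energy_forces` is a handful of vectorised operations. Exact —
    every non-excluded pair is evaluated with minimum-image distances.
    """

    def __init__(self, topo: BeadTopology, spec: ElectrostaticsSpec,
                 pair_table: PairTable | None = None):
        self.topo = topo
        self.spec = spec
        table = pair_table if pair_table is not None else PairTable.from_table()
        n = topo.n_beads
        iu, ju = np.triu_indices(n, 1)
        chain = topo.chain_id
        same = chain[iu] == chain[ju]
        rigid = np.array([topo.chain_rigid[c] for c in chain])
        pos = topo.bead_position_in_chain()
        sep = np.where(same, np.abs(pos[iu] - pos[ju]), 10 ** 9)
        excluded = (same & rigid[iu]) | (sep <= 1)
        keep = ~excluded
        self.iu, self.ju = iu[keep], ju[keep]

        t_idx = np.array([table.index[name] for name in topo.type_names])
        ti, tj = t_idx[self.iu], t_idx[self.ju]
        self.eps = table.eps[ti, tj]
        self.sig = table.sigma[ti, tj]
        self.mu = table.mu[ti, tj]
        self.nu = table.nu[ti, tj]
        self.rc_wf = WF_CUTOFF_FACTOR * self.sig
        self.alpha = wf_alpha(WF_CUTOFF_FACTOR, self.mu, self.nu)
        q = topo.charges
        self.qq = COULOMB * q[self.iu] * q[self.ju] / spec.epsilon_r
        self.has_q = self.qq != 0.0
        lam = spec.debye_length_A
        self.dh_shift = self.qq / spec.cutoff * np.exp(-spec.cutoff / lam)
        self.n_beads = n

    def energy_forces(self, coords: np.ndarray, box: np.ndarray):
        """Return (forces, per-term energies dict, scalar virial W = sum r.f)."""
        box = np.asarray(box, dtype=float)
        d = coords[self.iu] - coords[self.ju]
        d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(axis=1))
        # floor keeps an accidental exact overlap finite (enormous repulsion
        # still triggers the integrator's instability detection cleanly)
        r = np.maximum(r, 1e-3)
        n_pairs = len(r)
        dudr = np.zeros(n_pairs)

        # Wang-Frenkel
        in_wf = r < self.rc_wf
        e_wf = 0.0
        if in_wf.any():
            rs, eps, sig = r[in_wf], self.eps[in_wf], self.sig[in_wf]
            mu, nu, alpha = self.mu[in_wf], self.nu[in_wf], self.alpha[in_wf]
            rc = self.rc_wf[in_wf]
            r_core = WF_CORE_FRACTION * sig
            r_eff = np.maximum(rs, r_core)
            u = _wf_smooth_energy(r_eff, eps, sig, mu, nu, rc, alpha)
            g = _wf_smooth_dudr(r_eff, eps, sig, mu, nu, rc, alpha)
            core = rs < r_core
            if core.any():
                # linear continuation below the core radius (constant force)
                u = np.where(core, u + g * (rs - r_core), u)
            e_wf = float(u.sum())
            dudr[in_wf] += g

        # Debye-Huckel (truncated and shifted)
        lam = self.spec.debye_length_A
        in_dh = self.has_q & (r < self.spec.cutoff)
        e_dh = 0.0
        if in_dh.any():
            rs, qq = r[in_dh], self.qq[in_dh]
            expf = np.exp(-rs / lam)
            e_dh = float((qq / rs * expf - self.dh_shift[in_dh]).sum())
            dudr[in_dh] += -qq * expf * (1.0 / rs ** 2 + 1.0 / (rs * lam))

        forces = np.zeros((self.n_beads, 3))
        active = dudr != 0.0
        virial = 0.0
        if active.any():
            fmag = -dudr[active] / r[active]          # force on iu along +d
            fvec = fmag[:, None] * d[active]
            for k in range(3):
                forces[:, k] += np.bincount(self.iu[active], weights=fvec[:, k],
                                            minlength=self.n_beads)
                forces[:, k] -= np.bincount(self.ju[active], weights=fvec[:, k],
                                            minlength=self.n_beads)
            virial += float((-dudr[active] * r[active]).sum())

        # bonds (skipped inside rigid chains: geometry is fixed)
        e_bond = 0.0
        topo = self.topo
        if len(topo.bonds):
            a, b = topo.bonds[:, 0], topo.bonds[:, 1]
            rigid_bond = np.array([topo.chain_rigid[topo.chain_id[i]] for i in a])
            flex = ~rigid_bond
            if flex.any():
                af, bf = a[flex], b[flex]
                db = coords[af] - coords[bf]
                db -= box * np.round(db / box)
                rb = np.maximum(np.sqrt((db * db).sum(axis=1)), 1e-3)
                dr = rb - topo.bond_r0[flex]
                k_ = topo.bond_k[flex]
                e_bond = float((k_ * dr ** 2).sum())
                dudr_b = 2.0 * k_ * dr
                fvec = (-dudr_b / rb)[:, None] * db
                for k in range(3):
                    forces[:, k] += np.bincount(af, weights=fvec[:, k],
                                                minlength=self.n_beads)
                    forces[:, k] -= np.bincount(bf, weights=fvec[:, k],
                                                minlength=self.n_beads)
                virial += float((-dudr_b * rb).sum())

        terms = {"wf": e_wf, "dh": e_dh, "bond": e_bond,
                 "total": e_wf + e_dh + e_bond}
        return forces, terms, virial


def system_energy(frame, topo: BeadTopology, spec: ElectrostaticsSpec,
                  pair_table: PairTable | None = None) -> dict[str, float]:
    """Total and per-term potential energy (kcal/mol) of a frame.

    ``frame`` needs ``coordinates`` (N x 3, A) and ``box`` (3 edge lengths).
    """
    coords = np.asarray(frame.coordinates, dtype=float)
    if coords.shape[0] != topo.n_beads:
        raise ValueError(
            f"frame has {coords.shape[0]} beads, topology {topo.n_beads}")
    model = EnergyModel(topo, spec, pair_table)
    _, terms, _ = model.energy_forces(coords, np.asarray(frame.box, dtype=float))
    return terms
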