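"""Slab-trajectory phase analysis: density profiles, coexistence densities,
binodals and critical points.

The coexistence densities of a slab are read from the time-averaged mass
density profile along the long axis by fitting the symmetric interface form

    rho(z) = (rho_l + rho_v)/2 - (rho_l - rho_v)/2 * tanh((|z - z0| - w) / d)

where ``w`` is the slab half-width and ``d`` the interface width. A
"well-defined interface" — the LLPS indicator — is operationalised as a
fitted dense/dilute contrast of at least ``contrast_ratio`` (default 10)
together with a dense plateau at least three interface widths wide.

Critical points come from the standard simultaneous fit of the law of
rectilinear diameters, (rho_l + rho_v)/2 = rho_c + A (T_c - T), and the
scaling relation rho_l - rho_v = B (1 - T/T_c)^beta with the 3-D Ising
exponent beta = 0.325 held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import DA_PER_A3_TO_G_CM3

ISING_BETA = 0.325
AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class DensityProfile:
    bin_centers: np.ndarray          # A, along the chosen axis
    density: np.ndarray              # g/cm^3, total
    species: dict[str, np.ndarray]   # per chain kind, same units
    axis: str
    box: np.ndarray
    n_frames: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def total_mass_g_mol(self) -> float:
        """Mass implied by the profile (integral x cross-section), in Da."""
        ax = AXES[self.axis]
        cross = np.prod(self.box) / self.box[ax]
        return float(self.density.sum() * self.bin_width * cross
                     / DA_PER_A3_TO_G_CM3)


@dataclass(frozen=True)
class BinodalPoint:
    temperature: float               # K
    rho_v: float                     # dilute, g/cm^3
    rho_l: float                     # dense, g/cm^3
    drho_v: float = 0.0
    drho_l: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rho_l >= self.rho_v >= 0.0):
            raise ValueError("require rho_l >= rho_v >= 0")


@dataclass
class Binodal:
    points: list[BinodalPoint]
    tc_wildtype: float | None = None   # K; enables reduced-temperature output
    shape_warnings: list[str] = field(default_factory=list)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p.temperature for p in self.points])

    @property
    def reduced_temperatures(self) -> np.ndarray:
        if self.tc_wildtype is None:
            raise ValueError("no wildtype critical temperature configured")
        return self.temperatures / self.tc_wildtype

    @property
    def rho_v(self) -> np.ndarray:
        return np.array([p.rho_v for p in self.points])

    @property
    def rho_l(self) -> np.ndarray:
        return np.array([p.rho_l for p in self.points])


@dataclass
class CriticalPoint:
    t_c: float                       # K
    rho_c: float                     # g/cm^3
    slope_A: float
    amplitude_B: float
    beta: float
    residual_norm: float
    n_points: int


def _frame_masses_kinds(topo):
    kinds = np.array([topo.chain_kinds[c] for c in topo.chain_id])
    return topo.masses, kinds


def density_profile(traj, axis: str = "z", n_bins: int = 100,
                    frame_range: tuple[int, int] | None = None) -> DensityProfile:
    """Time-averaged, slab-recentred mass density profile along one axis.

    Each frame is recentred so the mass-weighted circular mean along the
    axis sits at the box center (centres the dense slab before averaging);
    per-species channels (chain kinds) sum to the total.
    """
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    frames = traj.frames
    if frame_range is not None:
        frames = frames[frame_range[0]:frame_range[1]]
    if not frames:
        raise ValueError("empty frame range")
    ax = AXES[axis]
    box = np.asarray(frames[0].box, dtype=float)
    for f in frames:
        if not np.allclose(f.box, box):
            raise ValueError("frames must share box dimensions")
    masses, kinds = _frame_masses_kinds(traj.topology)
    length = box[ax]
    cross = np.prod(box) / length
    edges = np.linspace(0.0, length, n_bins + 1)
    kind_names = sorted(set(kinds))
    hist = {k: np.zeros(n_bins) for k in kind_names}
    for f in frames:
        z = np.asarray(f.coordinates)[:, ax]
        theta = 2.0 * np.pi * z / length
        zc = length / (2.0 * np.pi) * np.arctan2(
            (masses * np.sin(theta)).sum(), (masses * np.cos(theta)).sum())
        z = np.mod(z - zc + 0.5 * length, length)
        for k in kind_names:
            sel = kinds == k
            h, _ = np.histogram(z[sel], bins=edges, weights=masses[sel])
            hist[k] += h
    width = length / n_bins
    norm = DA_PER_A3_TO_G_CM3 / (len(frames) * width * cross)
    species = {k: hist[k] * norm for k in kind_names}
    total = sum(species.values())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, total, species, axis, box, len(frames))


def _tanh_model(z, rho_v, rho_l, z0, w, d):
    return (0.5 * (rho_l + rho_v)
            - 0.5 * (rho_l - rho_v) * np.tanh((np.abs(z - z0) - w) / d))


def fit_tanh_profile(profile: DensityProfile) -> dict:
    """Least-squares fit of the symmetric tanh interface form.

    Initial guesses come from a lightly smoothed profile (half-maximum
    width of the dense region); several interface-width starting values are
    tried and the lowest-residual solution kept, which stabilises the fit
    on noisy few-frame profiles. Returns a dict with the fitted parameters,
    success flag and residual norm; never raises on non-convergence.
    """
    z, rho = profile.bin_centers, profile.density
    length = profile.box[AXES[profile.axis]]
    width = profile.bin_width
    smooth = np.convolve(rho, np.ones(3) / 3.0, mode="same")
    lo, hi = float(smooth.min()), float(smooth.max())
    dense = smooth > lo + 0.5 * (hi - lo) if hi > lo else \
        np.ones_like(smooth, dtype=bool)
    w0 = max(0.5 * dense.sum() * width, width)
    z0_guess = float((z[dense] * smooth[dense]).sum() / smooth[dense].sum()) \
        if dense.any() else 0.5 * length
    bounds = ([0.0, 0.0, 0.0, width * 0.1, width * 0.05],
              [np.inf, np.inf, length, 0.5 * length, 0.25 * length])

    def resid(p):
        return _tanh_model(z, *p) - rho

    best = None
    for d0 in (0.5 * width, 1.5 * width, 4.0 * width, w0 / 2.0):
        p0 = np.array([max(lo, 1e-6), max(hi, 1e-5), z0_guess, w0,
                       float(np.clip(d0, width * 0.1, 0.2 * length))])
        try:
            sol = least_squares(resid, p0, bounds=bounds, max_nfev=2000)
        except Exception:
            continue
        res = float(np.linalg.norm(sol.fun))
        if best is None or res < best[1]:
            best = (sol, res)
    if best is None:
        mean = float(rho.mean())
        return {"rho_v": mean, "rho_l": mean, "z0": 0.5 * length, "w": 0.0,
                "d": 1.0, "success": False, "residual_norm": float("nan")}
    sol, res = best
    rho_v, rho_l, z0, w, d = sol.x
    if rho_l < rho_v:
        rho_v, rho_l = rho_l, rho_v
    return {"rho_v": float(rho_v), "rho_l": float(rho_l), "z0": float(z0),
            "w": float(w), "d": float(d), "success": bool(sol.success),
            "residual_norm": res}


def coexistence_densities(profile: DensityProfile,
                          contrast_ratio: float = 10.0,
                          min_plateau_widths: float = 3.0
                          ) -> tuple[float, float, bool]:
    """(rho_v, rho_l, interface_present) from the tanh interface fit.

    The interface is called present only if the fit converged, the dense/
    dilute contrast reaches ``contrast_ratio`` and the dense plateau spans at
    least ``min_plateau_widths`` interface widths. On non-convergence the
    profile mean is returned for both phases with the flag false.
    """
    fit = fit_tanh_profile(profile)
    if not fit["success"]:
        mean = float(profile.density.mean())
        return mean, mean, False
    rho_v, rho_l = fit["rho_v"], fit["rho_l"]
    floor = max(rho_v, 1e-9 * max(rho_l, 1.0))
    contrast = rho_l / floor
    present = (contrast >= contrast_ratio
               and fit["w"] >= min_plateau_widths * fit["d"])
    return rho_v, rho_l, bool(present)


def mass_localization(profile: DensityProfile) -> float:
    """Mass-weighted standard deviation along the axis, as a fraction of
    the box length.

    A condensed slab or droplet concentrates its mass (values around
    0.05-0.12); a uniform or spreading fluid approaches the uniform limit
    1/sqrt(12) ~ 0.29. Robust to the shape degeneracies that afflict
    interface fits on small systems.
    """
    z, rho = profile.bin_centers, profile.density
    length = profile.box[AXES[profile.axis]]
    total = rho.sum()
    if total <= 0:
        return 1.0 / np.sqrt(12.0)
    mean = (z * rho).sum() / total
    var = ((z - mean) ** 2 * rho).sum() / total
    return float(np.sqrt(var) / length)


def assemble_binodal(points: list[BinodalPoint],
                     tc_wildtype: float | None = None) -> Binodal:
    """Sort subcritical points by temperature; flag unphysical branch shapes."""
    if len(points) < 2:
        raise ValueError("need at least 2 binodal points")
    temps = [p.temperature for p in points]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in binodal")
    ordered = sorted(points, key=lambda p: p.temperature)
    warnings = []
    rl = np.array([p.rho_l for p in ordered])
    rv = np.array([p.rho_v for p in ordered])
    if np.any(np.diff(rl) > 0):
        warnings.append("dense branch not non-increasing with T")
    if np.any(np.diff(rv) < 0):
        warnings.append("dilute branch not non-decreasing with T")
    return Binodal(ordered, tc_wildtype=tc_wildtype, shape_warnings=warnings)


def fit_critical_point(binodal: Binodal | list[BinodalPoint],
                       beta: float = ISING_BETA) -> CriticalPoint:
    """Simultaneous rectilinear-diameter + scaling fit of (T_c, rho_c)."""
    points = binodal.points if isinstance(binodal, Binodal) else \
        sorted(binodal, key=lambda p: p.temperature)
    if len(points) < 3:
        raise ValueError("critical-point fit needs at least 3 binodal points")
    T = np.array([p.temperature for p in points])
    rv = np.array([p.rho_v for p in points])
    rl = np.array([p.rho_l for p in points])
    t_max = T.max()

    # initial guesses: linearise the scaling law, then the diameter law
    drho = np.maximum(rl - rv, 1e-12)
    c1, c0 = np.polyfit(T, drho ** (1.0 / beta), 1)
    tc0 = -c0 / c1 if c1 < 0 else t_max * 1.1
    if not np.isfinite(tc0) or tc0 <= t_max:
        tc0 = t_max * 1.05
    b0 = max((-c1 * tc0), 1e-12) ** beta
    mid = 0.5 * (rl + rv)
    a0, rc_at_tc = np.polyfit(tc0 - T, mid, 1)
    rc0 = max(rc_at_tc, 1e-9)

    def resid(p):
        tc, rc, a, b = p
        red = np.maximum(1.0 - T / tc, 1e-12)
        r1 = 0.5 * (rl + rv) - (rc + a * (tc - T))
        r2 = (rl - rv) - b * red ** beta
        return np.concatenate([r1, r2])

    sol = least_squares(
        resid, x0=[tc0, rc0, a0, max(b0, 1e-9)],
        bounds=([t_max * (1.0 + 1e-9), 0.0, -np.inf, 0.0],
                [np.inf, np.inf, np.inf, np.inf]),
        max_nfev=5000)
    if not sol.success:
        raise RuntimeError(
            f"critical-point fit did not converge (residuals {sol.fun})")
    tc, rc, a, b = sol.x
    return CriticalPoint(float(tc), float(rc), float(a), float(b), beta,
                         float(np.linalg.norm(sol.fun)), len(points))
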