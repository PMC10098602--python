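"""Plain-text trajectory and monitor I/O.

Trajectories are written as extended XYZ: one block per frame with the bead
count, a comment line carrying the orthorhombic lattice, frame time and
per-term energies, then one ``type x y z`` line per bead. Monitors go to
CSV. Both formats round-trip through :func:`read_xyz` /
``MonitorSeries``-from-CSV for analysis after the fact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .md import MonitorSeries, SimulationFrame, Trajectory


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    lines: list[str] = []
    names = traj.topology.type_names
    for frame in traj.frames:
        box = np.asarray(frame.box, dtype=float)
        lattice = f"{box[0]:.6f} 0 0 0 {box[1]:.6f} 0 0 0 {box[2]:.6f}"
        energy = (frame.energies or {}).get("total", float("nan"))
        lines.append(str(len(names)))
        lines.append(
            f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 '
            f"time_ns={frame.time:.6f} potential_kcal={energy:.6f}")
        for name, (x, y, z) in zip(names, frame.coordinates):
            lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[SimulationFrame]:
    """Read frames (coordinates, box, time) back from extended XYZ."""
    lines = Path(path).read_text().splitlines()
    frames: list[SimulationFrame] = []
    i = 0
    while i < len(lines):
        n = int(lines[i])
        header = lines[i + 1]
        lat = header.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
        time_ns = 0.0
        for token in header.split():
            if token.startswith("time_ns="):
                time_ns = float(token.split("=")[1])
        coords = np.array([
            [float(v) for v in lines[i + 2 + k].split()[1:4]]
            for k in range(n)
        ])
        frames.append(SimulationFrame(coordinates=coords, box=box, time=time_ns))
        i += 2 + n
    return frames


def write_monitors(series: MonitorSeries, path: str | Path) -> None:
    pd.DataFrame({
        "time_ns": series.time_ns,
        "potential_kcal": series.potential_kcal,
        "kinetic_kcal": series.kinetic_kcal,
        "temperature_K": series.temperature_K,
        "density_g_cm3": series.density_g_cm3,
    }).to_csv(path, index=False)


def read_monitors(path: str | Path) -> MonitorSeries:
    df = pd.read_csv(path)
    return MonitorSeries(
        time_ns=df["time_ns"].to_numpy(),
        potential_kcal=df["potential_kcal"].to_numpy(),
        kinetic_kcal=df["kinetic_kcal"].to_numpy(),
        temperature_K=df["temperature_K"].to_numpy(),
        density_g_cm3=df["density_g_cm3"].to_numpy(),
    )
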