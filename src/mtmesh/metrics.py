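"""Contraction and constraint-fidelity readouts for trajectories.

Filament midpoints (not endpoints or heads) define the radius of gyration and
pair gaps: the midpoint is insensitive to the filament spinning or sliding
about its own axis, and matches the visual reading of asters being pulled
closer together.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .dynamics import Trajectory, CONSTRAINT_CLASSES


def _midpoints(positions: np.ndarray, filament_particles: Dict) -> np.ndarray:
    """(n_filaments, 3) midpoints for one frame's particle positions."""
    mids = [
        0.5 * (positions[im] + positions[ip])
        for im, ip in filament_particles.values()
    ]
    return np.asarray(mids)


def radius_of_gyration(positions: np.ndarray, filament_particles: Dict) -> float:
    """RMS distance of filament midpoints from their centroid."""
    mids = _midpoints(positions, filament_particles)
    if len(mids) < 1:
        raise ValueError("radius_of_gyration needs at least one filament")
    centroid = mids.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((mids - centroid) ** 2, axis=1))))


def rg_series(trajectory: Trajectory) -> np.ndarray:
    """Radius of gyration at every recorded frame."""
    return np.array(
        [
            radius_of_gyration(trajectory.positions[f], trajectory.filament_particles)
            for f in range(trajectory.n_frames + 1)
        ]
    )


def pair_gap(trajectory: Trajectory, filament_a: str, filament_b: str) -> np.ndarray:
    """Per-frame distance between two filament midpoints."""
    for fid in (filament_a, filament_b):
        if fid not in trajectory.filament_particles:
            raise KeyError(f"unknown filament id {fid!r}")
    ia = trajectory.filament_particles[filament_a]
    ib = trajectory.filament_particles[filament_b]
    ma = 0.5 * (trajectory.positions[:, ia[0]] + trajectory.positions[:, ia[1]])
    mb = 0.5 * (trajectory.positions[:, ib[0]] + trajectory.positions[:, ib[1]])
    return np.linalg.norm(ma - mb, axis=1)


def contraction_ratio(trajectory: Trajectory) -> float:
    """Rg(final) / Rg(initial); < 1 indicates net contraction."""
    rg0 = radius_of_gyration(trajectory.positions[0], trajectory.filament_particles)
    rg1 = radius_of_gyration(trajectory.positions[-1], trajectory.filament_particles)
    if rg0 == 0:
        raise ValueError("initial radius of gyration is zero")
    return float(rg1 / rg0)


def constraint_report(
    trajectory: Trajectory, tolerance: Optional[float] = None
) -> pd.DataFrame:
    """Residual maxima per constraint class per frame, with violation flags.

    Residuals come straight from the trajectory's recorded per-frame maxima
    (themselves recomputed from positions, not from solver internals).  Frames
    within the declared startup window are not flagged.
    """
    tol = tolerance if tolerance is not None else trajectory.config.constraint_tolerance
    rep = trajectory.residuals.copy()
    structural = [c for c in ("rod", "piston", "hub", "joint") if c in rep.columns]
    exceeded = rep[structural].max(axis=1) > tol
    startup = rep.index < trajectory.startup_frames
    rep["flagged"] = exceeded & ~startup
    return rep


def metrics_table(trajectory: Trajectory) -> pd.DataFrame:
    """Per-frame metric series: Rg plus every filament-pair midpoint gap."""
    out = pd.DataFrame({"frame": np.arange(trajectory.n_frames + 1)})
    out["rg"] = rg_series(trajectory)
    ids = list(trajectory.filament_particles)
    for i, fa in enumerate(ids):
        for fb in ids[i + 1 :]:
            out[f"gap_{fa}_{fb}"] = pair_gap(trajectory, fa, fb)
    return out


def summary(trajectory: Trajectory) -> dict:
    """JSON-ready summary: contraction ratio, simulated time, flagged frames."""
    rep = constraint_report(trajectory)
    return {
        "contraction_ratio": contraction_ratio(trajectory),
        "simulated_duration_s": trajectory.config.duration,
        "n_frames": trajectory.n_frames,
        "flagged_frames": int(rep["flagged"].sum()),
        "max_rod_residual": float(rep["rod"].max()),
        "max_piston_residual": float(rep["piston"].max()),
    }
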