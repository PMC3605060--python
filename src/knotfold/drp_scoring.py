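"""A-posteriori path probability under unbiased overdamped Langevin dynamics.

A discrete trajectory is scored by its Onsager-Machlup weight (Ito
convention, force at the step's starting frame):

    log W = - sum_steps sum_beads |dx - (D dt / kT) F|^2 / (4 D dt)

up to a path-independent additive constant.  Only the *unbiased* physical
force enters, so scoring a set of ratchet-biased trial trajectories and
keeping the maximum lessens the steering bias a posteriori.  Weights are
comparable only between trajectories recorded at the same frame stride
(enforced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from knotfold.chain_core import Trajectory
from knotfold.cg_forcefield import ForceFieldSpec, force

__all__ = ["PathWeight", "path_log_weight", "select_dominant"]


@dataclass(frozen=True)
class PathWeight:
    """Log-weight of one trajectory under free (unbiased) Langevin dynamics."""

    log_weight: float
    n_steps_scored: int
    diffusion: float
    temperature: float
    dt: float


def path_log_weight(traj: Trajectory, ff: ForceFieldSpec,
                    diffusion: float = 1.0, temperature: float = 1.0,
                    dt: float | None = None) -> PathWeight:
    """Onsager-Machlup log-weight of a trajectory (larger = more probable).

    ``dt`` defaults to the trajectory's own frame interval: weights are
    computed on saved frames, an explicit coarse-graining of the underlying
    integrator steps.
    """
    if len(traj.frames) < 2:
        raise ValueError("need at least 2 frames to score a path")
    dt = dt if dt is not None else traj.dt
    if dt is None or dt <= 0:
        raise ValueError("trajectory has no usable frame interval dt")
    coords = traj.coords_array()
    mob = diffusion * dt / temperature
    lw = 0.0
    for k in range(coords.shape[0] - 1):
        drift = mob * force(coords[k], ff)
        dev = coords[k + 1] - coords[k] - drift
        lw -= float((dev ** 2).sum()) / (4.0 * diffusion * dt)
    return PathWeight(log_weight=lw, n_steps_scored=coords.shape[0] - 1,
                      diffusion=diffusion, temperature=temperature, dt=dt)


def select_dominant(paths, ff: ForceFieldSpec, diffusion: float = 1.0,
                    temperature: float = 1.0,
                    start_tolerance: float = 1e-6) -> Trajectory:
    """Highest-weight trajectory among trials sharing one initial condition.

    All paths must start from the same frame (within ``start_tolerance``
    RMSD-free coordinate deviation) and share the same frame interval.  Ties
    are broken deterministically by the lowest trajectory seed.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("empty path set")
    x0 = paths[0].frames[0].coords
    dt0 = paths[0].dt
    for t in paths[1:]:
        if np.abs(t.frames[0].coords - x0).max() > start_tolerance:
            raise ValueError("paths do not share an initial condition")
        if not np.isclose(t.dt, dt0):
            raise ValueError("cannot compare paths with different frame strides")
    scored = [(path_log_weight(t, ff, diffusion, temperature).log_weight,
               -(t.seed if t.seed is not None else np.inf), i)
              for i, t in enumerate(paths)]
    best = max(scored, key=lambda s: (s[0], s[1]))
    return paths[best[2]]
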