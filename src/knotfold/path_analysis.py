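"""Pathway statistics and knotting-mechanism classification.

A folding mechanism is encoded as the order in which native contacts first
form.  For a trajectory with formation frames ``r_i`` the binary order
matrix has ``M_ij = 1`` iff contact ``i`` formed no later than contact ``j``
(ties set both entries); the similarity of two mechanisms is

    sigma(a, b) = 1 - sum_{i != j} |M^a_ij - M^b_ij| / (Nc (Nc - 1)),

which is 1 for identical orders, 0 for exactly reversed strict orders, and
depends only on the order (not the timing) of events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from knotfold.chain_core import (Conformation, NativeStructure, Trajectory,
                                 kabsch_rmsd)
from knotfold.contact_maps import formation_times, native_overlap
from knotfold.knot_topology import (ClosureSpec, classify_conformation,
                                    first_knotting_event)

__all__ = [
    "PathRecord",
    "MechanismCall",
    "MechanismConfig",
    "DensityProjection",
    "order_matrix",
    "path_record",
    "path_similarity",
    "sigma_distribution",
    "overlap_at_first_knot",
    "density_projection",
    "classify_mechanism",
]


@dataclass
class PathRecord:
    """Per-trajectory contact-formation record and derived order matrix."""

    trajectory_id: str
    contacts: tuple                 # sorted native contact pairs
    formation_frames: np.ndarray    # float; +inf for never-formed
    order_matrix: np.ndarray        # (Nc, Nc) binary


@dataclass(frozen=True)
class MechanismCall:
    """Knotting-mechanism verdict with its supporting evidence."""

    label: str                      # threading | slipknot | mousetrap | unresolved
    first_knot_frame: Optional[int]
    slipknot_prior: bool
    tail_displacement: float
    loop_displacement: float


@dataclass(frozen=True)
class MechanismConfig:
    """Operational thresholds for the mechanism rules.

    ``lookback_frames``: window before the first knotting frame inspected for
    slipknotted intermediates and displacement scores (default: 5 % of the
    trajectory, at least 3 frames).  ``displacement_threshold``: Angstrom
    scale separating "stationary" from "moving" regions (default twice the
    bead spacing).
    """

    lookback_frames: Optional[int] = None
    lookback_fraction: float = 0.05
    displacement_threshold: float = 7.6
    scan_closures: int = 15
    every: int = 1


@dataclass
class DensityProjection:
    """Log-density of visited (total RMSD, region RMSD) pairs."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    log_counts: np.ndarray
    knot_markers: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# order matrices and sigma
# ---------------------------------------------------------------------------

def order_matrix(formation_frames: Sequence) -> np.ndarray:
    """Binary order matrix from first-formation frames.

    ``None``/NaN entries (never formed) are treated as ``+inf``: they rank
    after every formed contact and tie among themselves.  Requires at least
    two defined frames.
    """
    r = np.array([np.inf if f is None else float(f) for f in formation_frames])
    r = np.where(np.isnan(r), np.inf, r)
    if np.sum(np.isfinite(r)) < 2:
        raise ValueError("need at least 2 formed contacts")
    # inf <= inf is True, so never-formed contacts tie among themselves
    return (r[:, None] <= r[None, :]).astype(np.uint8)


def path_record(traj: Trajectory, native: NativeStructure,
                trajectory_id: str = "", tol_factor: float = 1.2) -> PathRecord:
    """Measure contact formation times along a trajectory and build the record."""
    events = formation_times(traj, native, tol_factor=tol_factor)
    frames = [e.formation_frame for e in events]
    return PathRecord(
        trajectory_id=trajectory_id or f"seed{traj.seed}",
        contacts=tuple(e.contact for e in events),
        formation_frames=np.array(
            [np.inf if f is None else float(f) for f in frames]),
        order_matrix=order_matrix(frames))


def path_similarity(a: PathRecord, b: PathRecord) -> float:
    """Order-of-contact-formation similarity in [0, 1]."""
    if a.contacts != b.contacts:
        raise ValueError("path records refer to different native contact sets")
    nc = len(a.contacts)
    off = ~np.eye(nc, dtype=bool)
    diff = np.abs(a.order_matrix.astype(int) - b.order_matrix.astype(int))[off]
    return 1.0 - float(diff.sum()) / (nc * (nc - 1))


def sigma_distribution(paths: Sequence[PathRecord], bins=20):
    """Histogram of sigma over all unordered path pairs, normalised to 1.

    Returns ``(sigma_values, hist, bin_edges)``.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 paths")
    sigmas = np.array([path_similarity(paths[i], paths[j])
                       for i in range(len(paths))
                       for j in range(i + 1, len(paths))])
    hist, edges = np.histogram(sigmas, bins=bins, range=(0.0, 1.0))
    total = hist.sum()
    return sigmas, hist / total if total else hist.astype(float), edges


# ---------------------------------------------------------------------------
# knotting-event statistics
# ---------------------------------------------------------------------------

def overlap_at_first_knot(traj: Trajectory, native: NativeStructure,
                          closure: ClosureSpec, seed=None, every: int = 1,
                          tol_factor: float = 1.2) -> Optional[float]:
    """Native overlap at the first knotting frame; ``None`` if never knotted."""
    k = first_knotting_event(traj, closure, seed=seed, every=every)
    if k is None:
        return None
    return native_overlap(traj.frames[k], native, tol_factor=tol_factor)


def density_projection(paths: Sequence[Trajectory], native: NativeStructure,
                       region: Sequence[int] | None = None, bins: int = 40,
                       closure: ClosureSpec | None = None, seed=None,
                       every: int = 1) -> DensityProjection:
    """Per-frame (total RMSD, region RMSD) log-density over an ensemble.

    ``region`` defaults to the annotated ``sheet_a``+``sheet_b`` beads.  When
    a closure spec is given, first-knotting frames are located and marked.
    """
    if not paths:
        raise ValueError("empty path set")
    if region is None:
        regs = native.annotated_regions
        region = [i for name in ("sheet_a", "sheet_b") if name in regs
                  for i in range(regs[name][0], regs[name][1] + 1)]
    region = sorted(region)
    if len(region) < 3:
        raise ValueError("region must contain at least 3 beads")
    ref = native.reference
    xs, ys = [], []
    markers = []
    for t_i, traj in enumerate(paths):
        for frame in traj.frames:
            xs.append(kabsch_rmsd(frame, ref))
            ys.append(kabsch_rmsd(frame, ref, subset=region))
        if closure is not None:
            k = first_knotting_event(
                traj, closure, seed=None if seed is None else seed + t_i,
                every=every)
            if k is not None:
                markers.append((kabsch_rmsd(traj.frames[k], ref),
                                kabsch_rmsd(traj.frames[k], ref, subset=region)))
    counts, xe, ye = np.histogram2d(xs, ys, bins=bins)
    return DensityProjection(x_edges=xe, y_edges=ye,
                             log_counts=np.log1p(counts),
                             knot_markers=markers)


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------

def _region_indices(native: NativeStructure, name: str) -> np.ndarray:
    if name not in native.annotated_regions:
        raise ValueError(f"native structure lacks region {name!r}")
    a, b = native.annotated_regions[name]
    return np.arange(a, b + 1)


def _mean_displacement(traj: Trajectory, idx: np.ndarray,
                       f0: int, f1: int) -> float:
    d = traj.frames[f1].coords[idx] - traj.frames[f0].coords[idx]
    return float(np.linalg.norm(d, axis=1).mean())


def classify_mechanism(traj: Trajectory, native: NativeStructure,
                       closure: ClosureSpec,
                       config: MechanismConfig = MechanismConfig(),
                       seed=None) -> MechanismCall:
    """Call the knotting mechanism of one trajectory.

    Rules, applied at the first globally-knotted frame with a lookback
    window ``w``:

    1. *slipknot* if any frame in the window is classified slipknotted
       (knotted subchain inside a globally unknotted chain);
    2. else *mousetrap* if over the window the tail region stayed below the
       displacement threshold while the threading-loop region exceeded it;
    3. else *threading*.

    Trajectories with no knotting event are *unresolved*.
    """
    first = first_knotting_event(traj, closure, seed=seed, every=config.every)
    if first is None:
        return MechanismCall(label="unresolved", first_knot_frame=None,
                             slipknot_prior=False, tail_displacement=0.0,
                             loop_displacement=0.0)
    w = config.lookback_frames or max(
        3, int(round(config.lookback_fraction * len(traj.frames))))
    f0 = max(0, first - w)
    slip = False
    rng_seed = seed
    for k in range(f0, first):
        verdict = classify_conformation(
            traj.frames[k], closure, seed=rng_seed, do_scan=True,
            scan_closures=config.scan_closures)
        if verdict.classification == "slipknotted":
            slip = True
            break
    tail_idx = _region_indices(native, "tail")
    loop_idx = _region_indices(native, "threading_loop")
    tail_disp = _mean_displacement(traj, tail_idx, f0, first)
    loop_disp = _mean_displacement(traj, loop_idx, f0, first)
    if slip:
        label = "slipknot"
    elif (tail_disp < config.displacement_threshold
          and loop_disp > config.displacement_threshold):
        label = "mousetrap"
    else:
        label = "threading"
    return MechanismCall(label=label, first_knot_frame=first,
                         slipknot_prior=slip, tail_displacement=tail_disp,
                         loop_displacement=loop_disp)
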