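"""Generators for every input the pipeline needs, with no downloads.

Provides parametric closed knots (test oracles for the topology module), an
open-chain "shallow trefoil" toy native with annotated sheet/loop/tail
motifs, self-avoiding random-coil ensembles, and scripted kinematic
trajectories that realise the three knotting mechanisms (threading,
slipknot, mousetrap) by piecewise-rigid motion.  Everything is deterministic
under its seed and re-verified topologically at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from knotfold.chain_core import Conformation, NativeStructure, Trajectory
from knotfold.contact_maps import ContactMapParams, build_native_structure
from knotfold.knot_topology import (ClosureSpec, alexander_determinant,
                                    classify_conformation)

__all__ = [
    "ToyNativeSpec",
    "parametric_knot",
    "build_toy_native",
    "coil_ensemble",
    "kinematic_fixture",
]


class GenerationError(RuntimeError):
    """A generator could not satisfy its post-conditions within its retry cap."""


# ---------------------------------------------------------------------------
# parametric closed curves
# ---------------------------------------------------------------------------

_MIN_VERTICES = {"unknot": 3, "trefoil": 30, "figure_eight": 30}


def _curve(kind: str, t: np.ndarray) -> np.ndarray:
    if kind == "unknot":
        return np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    if kind == "trefoil":
        return np.column_stack([np.sin(t) + 2 * np.sin(2 * t),
                                np.cos(t) - 2 * np.cos(2 * t),
                                -np.sin(3 * t)])
    if kind == "figure_eight":
        return np.column_stack([(2 + np.cos(2 * t)) * np.cos(3 * t),
                                (2 + np.cos(2 * t)) * np.sin(3 * t),
                                np.sin(4 * t)])
    raise ValueError(f"unknown knot kind {kind!r}")


def parametric_knot(kind: str, n_vertices: int = 60, scale: float = 1.0) -> np.ndarray:
    """Closed polygonal curve of the requested knot type.

    ``kind`` is one of ``"unknot"``, ``"trefoil"``, ``"figure_eight"``.
    Vertices are placed at uniform parameter values; the minimum vertex count
    (3 / 30 / 30) keeps the polygonal type faithful to the smooth curve.
    """
    if kind not in _MIN_VERTICES:
        raise ValueError(f"unknown knot kind {kind!r}")
    if n_vertices < _MIN_VERTICES[kind]:
        raise ValueError(
            f"{kind} needs at least {_MIN_VERTICES[kind]} vertices")
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return scale * _curve(kind, t)


def _resample_arclength(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at constant spacing along its arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = int(s[-1] // spacing) + 1
    targets = np.arange(n_out) * spacing
    out = np.empty((n_out, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, points[:, d])
    return out


# ---------------------------------------------------------------------------
# toy shallow-trefoil native
# ---------------------------------------------------------------------------

@dataclass
class ToyNativeSpec:
    """Recipe for the open-chain shallow-trefoil toy native.

    The chain traces (almost) a full circuit of a parametric trefoil at
    constant bead spacing, then continues with a ``knot_depth``-bead straight
    tail pointing away from the body, which makes the knot shallow (the
    knotted core ends ``knot_depth`` beads before the C terminus).
    ``sheet_pair`` / ``loop_range`` default to auto-detected motifs: the pair
    of distant-in-sequence windows in closest spatial contact, and the open
    region the tail passes by.
    """

    n_beads: int = 48
    bead_spacing: float = 3.8
    knot_depth: int = 6
    sheet_pair: Optional[tuple] = None
    loop_range: Optional[tuple] = None
    seed: int = 0
    gap_fraction: float = 0.04     # parameter gap left open in the circuit
    jitter: float = 0.12           # Angstrom, breaks exact symmetries

    def __post_init__(self):
        if self.knot_depth < 1:
            raise GenerationError("knot_depth must be >= 1 (no tail to thread)")
        if self.n_beads - self.knot_depth < 30:
            raise GenerationError("too few core beads to hold a trefoil")


def _auto_sheet_pair(coords: np.ndarray, forbidden: set, min_sep: int = 15,
                     width: int = 4):
    """Two disjoint windows with large sequence separation in closest contact,
    avoiding bead indices in ``forbidden``."""
    n = coords.shape[0]
    best, best_d = None, np.inf
    for a in range(0, n - width):
        if any(i in forbidden for i in range(a, a + width)):
            continue
        for b in range(a + min_sep, n - width):
            if any(i in forbidden for i in range(b, b + width)):
                continue
            d = np.linalg.norm(coords[a:a + width, None, :]
                               - coords[None, b:b + width, :], axis=-1).min()
            if d < best_d:
                best_d = d
                best = ((a, a + width - 1), (b, b + width - 1))
    if best is None:
        raise GenerationError("no sheet-like window pair found")
    return best


def build_toy_native(spec: ToyNativeSpec | None = None,
                     params: ContactMapParams | None = None,
                     closure: ClosureSpec | None = None) -> NativeStructure:
    """Build and verify the toy shallow-trefoil native structure.

    Post-conditions (verified, with retries over the derived rng stream):
    globally knotted with modal determinant 3; the core without the tail is
    still knotted (the tail is a free threading segment); annotated regions
    ``sheet_a`` / ``sheet_b`` / ``threading_loop`` / ``tail`` are disjoint.
    """
    spec = spec or ToyNativeSpec()
    closure = closure or ClosureSpec(n_closures=30)
    rng = np.random.default_rng(spec.seed)
    n_core = spec.n_beads - spec.knot_depth

    # open the circuit at the point of maximal radius (an outer lobe) so the
    # free ends sit on the outside of the knot body and closures are unambiguous
    tt = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    t_star = float(tt[np.argmax(np.linalg.norm(_curve("trefoil", tt), axis=1))])

    for attempt in range(8):
        gap = 2 * np.pi * spec.gap_fraction
        t = np.linspace(t_star + gap / 2, t_star + 2 * np.pi - gap / 2, 4096)
        raw = _curve("trefoil", t)
        # scale so that n_core beads at bead_spacing cover the open circuit
        seg = np.linalg.norm(np.diff(raw, axis=0), axis=1).sum()
        s = (n_core - 1) * spec.bead_spacing / seg
        core = _resample_arclength(raw * s, spec.bead_spacing)[:n_core]
        # straight tail from the C-end of the core, pointing away from the body
        center = core.mean(axis=0)
        out_dir = core[-1] - center
        out_dir /= np.linalg.norm(out_dir)
        tail = core[-1] + out_dir * spec.bead_spacing * np.arange(
            1, spec.knot_depth + 1)[:, None]
        coords = np.vstack([core, tail])
        coords = coords + spec.jitter * rng.standard_normal(coords.shape)

        conf = Conformation(coords)
        verdict = classify_conformation(conf, closure, seed=rng, do_scan=False)
        core_verdict = classify_conformation(coords[:n_core], closure,
                                             seed=rng, do_scan=False)
        if (verdict.classification == "globally_knotted"
                and verdict.knot_determinant == 3
                and verdict.vote_fraction >= 0.9
                and core_verdict.global_state == "knotted"):
            break
    else:
        raise GenerationError("could not build a verified shallow trefoil")

    loop = spec.loop_range
    if loop is None:
        # open region the terminal segment passes by: the window of the core
        # closest to the first tail bead, excluding the core's own C-end
        tail_tip = coords[n_core]
        d = np.linalg.norm(coords[:n_core - 8] - tail_tip, axis=1)
        c = int(np.argmin(d))
        loop = (max(0, c - 4), min(n_core - 9, c + 4))
    forbidden = set(range(loop[0], loop[1] + 1)) | set(range(n_core, spec.n_beads))
    sheet = spec.sheet_pair or _auto_sheet_pair(coords, forbidden)
    regions = {"sheet_a": tuple(sheet[0]), "sheet_b": tuple(sheet[1]),
               "threading_loop": tuple(loop),
               "tail": (spec.n_beads - spec.knot_depth, spec.n_beads - 1)}
    native = build_native_structure(conf, params=params,
                                    annotated_regions=regions)
    if not native.native_contacts:
        raise GenerationError("toy native has no contacts")
    return native


# ---------------------------------------------------------------------------
# denatured coil ensembles
# ---------------------------------------------------------------------------

def _self_avoiding_walk(n_beads: int, spacing: float, rng,
                        min_dist: float, max_bend_cos: float = -0.4,
                        max_tries: int = 60) -> Optional[np.ndarray]:
    coords = np.zeros((n_beads, 3))
    coords[1] = [spacing, 0.0, 0.0]
    for k in range(2, n_beads):
        prev_dir = coords[k - 1] - coords[k - 2]
        prev_dir /= np.linalg.norm(prev_dir)
        for _ in range(max_tries):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if float(v @ prev_dir) < max_bend_cos:  # forbid immediate backfold
                continue
            cand = coords[k - 1] + spacing * v
            if k >= 2:
                d = np.linalg.norm(coords[:k - 1] - cand, axis=1)
                if d.min() < min_dist:
                    continue
            coords[k] = cand
            break
        else:
            return None
    return coords


def coil_ensemble(n_chains: int, n_beads: int = 48, bead_spacing: float = 3.8,
                  seed: int = 0, min_dist: float = 3.5,
                  verify_unknotted: bool = True,
                  closure: ClosureSpec | None = None) -> list:
    """Self-avoiding random coils, each verified globally unknotted."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    closure = closure or ClosureSpec(n_closures=20)
    rng = np.random.default_rng(seed)
    chains = []
    attempts = 0
    while len(chains) < n_chains:
        attempts += 1
        if attempts > 50 * n_chains:
            raise GenerationError("self-avoidance failure rate too high")
        coords = _self_avoiding_walk(n_beads, bead_spacing, rng, min_dist)
        if coords is None:
            continue
        conf = Conformation(coords)
        if verify_unknotted:
            verdict = classify_conformation(conf, closure, seed=rng,
                                            do_scan=False)
            if verdict.global_state != "unknot":
                continue
        chains.append(conf)
    return chains


# ---------------------------------------------------------------------------
# kinematic mechanism fixtures
# ---------------------------------------------------------------------------

def _find_thread_length(coords: np.ndarray, closure: ClosureSpec, rng,
                        lo: int = 2, hi: int | None = None) -> int:
    """Smallest k such that dropping the last k beads unknots the chain."""
    n = coords.shape[0]
    hi = hi or n - closure.anchor_seq_dist - 5
    for k in range(lo, hi):
        verdict = classify_conformation(coords[:n - k], closure, seed=rng,
                                        do_scan=False)
        if verdict.global_state == "unknot":
            return k
    raise GenerationError("could not find an unknotting truncation")


def _interp(a: np.ndarray, b: np.ndarray, n_frames: int) -> list:
    return [a + (b - a) * s for s in np.linspace(0.0, 1.0, n_frames)]


def kinematic_fixture(kind: str, n_frames: int = 16,
                      spec: ToyNativeSpec | None = None,
                      closure: ClosureSpec | None = None,
                      seed: int = 0) -> Trajectory:
    """Scripted rigid-piece trajectory realising one knotting mechanism.

    ``threading``: the terminal segment translates straight through the
    stationary loop into its native place.  ``slipknot``: the terminal
    segment first overshoots along the native thread line (the chain minus
    its very end is then knotted while the full chain can still withdraw:
    slipknotted intermediates), then settles back to native.  ``mousetrap``:
    the terminal segment is parked at its native position from the start and
    the loop side of the chain swings over it (hinge rotation) into place.

    All fixtures end globally knotted; they are verified at generation time.
    """
    if kind not in ("threading", "slipknot", "mousetrap"):
        raise ValueError(f"unknown mechanism kind {kind!r}")
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    spec = spec or ToyNativeSpec()
    closure = closure or ClosureSpec(n_closures=30)
    rng = np.random.default_rng(seed + 7)
    native = build_toy_native(spec)
    xn = native.reference.coords.copy()
    n = xn.shape[0]
    k_thread = _find_thread_length(xn, closure, rng)
    move = min(n - 5, k_thread + spec.knot_depth)  # moving terminal piece
    exit_dir = xn[-1] - xn[n - move]
    exit_dir /= np.linalg.norm(exit_dir)
    retract = exit_dir * spec.bead_spacing * (move + 4)

    if kind == "threading":
        # the straight terminal piece translates through the stationary loop
        start = xn.copy()
        start[n - move:] += retract
        frames = _interp(start, xn, n_frames)
    elif kind == "slipknot":
        # mid-state: chain minus its last h beads is exactly native (knotted
        # subchain) while those h beads retrace the thread path backwards out
        # of the loop -- globally unknotted, i.e. a slipknot
        lateral = np.array([1.8, 1.2, 0.9])
        mid = None
        for h in range(max(2, k_thread - 5), k_thread + 3):
            cand = xn.copy()
            for i in range(1, h + 1):
                cand[n - h - 1 + i] = xn[n - h - 1 - i] + lateral
            verdicts = [classify_conformation(cand, closure, seed=rng,
                                              do_scan=True, scan_closures=15)
                        for _ in range(2)]
            if all(v.classification == "slipknotted" for v in verdicts):
                mid = cand
                break
        if mid is None:
            raise GenerationError("no slipknotted mid-state found")
        start = mid.copy()
        start[n - move:] += retract
        n_out = max(3, n_frames // 4)  # short final unfolding phase
        frames = (_interp(start, mid, n_frames - n_out + 1)
                  + _interp(mid, xn, n_out)[1:])
    else:  # mousetrap
        # the loop side of the chain hinge-rotates over the stationary,
        # already-docked terminal piece
        from scipy.spatial.transform import Rotation
        hinge = n - move
        pivot = xn[hinge]
        found = None
        for ax_seed in range(12):
            axis = np.random.default_rng(ax_seed).normal(size=3)
            axis /= np.linalg.norm(axis)
            for ang in (90.0, 120.0, -90.0, -120.0, 150.0, -150.0):
                start = xn.copy()
                start[:hinge] = Rotation.from_rotvec(
                    np.radians(ang) * axis).apply(xn[:hinge] - pivot) + pivot
                v0 = classify_conformation(start, closure, seed=rng,
                                           do_scan=True, scan_closures=12)
                if v0.classification == "unknotted":
                    found = (axis, ang)
                    break
            if found:
                break
        if not found:
            raise GenerationError("no unknotted mousetrap start found")
        axis, ang = found
        frames = []
        for s in np.linspace(0.0, 1.0, n_frames):
            f = xn.copy()
            f[:hinge] = Rotation.from_rotvec(
                np.radians(ang * (1 - s)) * axis).apply(xn[:hinge] - pivot) + pivot
            frames.append(f)

    traj = Trajectory([Conformation(f, frame_index=i)
                       for i, f in enumerate(frames)], seed=seed)
    _verify_fixture(traj, kind, closure, rng)
    traj.meta["mechanism"] = kind
    traj.meta["native_spec"] = spec
    return traj


def _verify_fixture(traj: Trajectory, kind: str, closure: ClosureSpec,
                    rng) -> None:
    """Topological post-conditions of a mechanism fixture."""
    first = classify_conformation(traj.frames[0], closure, seed=rng,
                                  do_scan=False)
    last = classify_conformation(traj.frames[-1], closure, seed=rng,
                                 do_scan=False)
    if last.global_state != "knotted" or first.global_state != "unknot":
        raise GenerationError(f"{kind} fixture failed topological verification")
    if kind == "slipknot":
        # a slipknotted frame must precede the first globally knotted frame
        first_knot = None
        for k, frame in enumerate(traj.frames):
            v = classify_conformation(frame, closure, seed=rng, do_scan=False)
            if v.global_state == "knotted":
                first_knot = k
                break
        if first_knot is None or first_knot == 0:
            raise GenerationError("slipknot fixture knots too early")
        ok = any(
            classify_conformation(traj.frames[k], closure, seed=rng,
                                  do_scan=True, scan_closures=15
                                  ).classification == "slipknotted"
            for k in range(max(0, first_knot - 3), first_knot))
        if not ok:
            raise GenerationError(
                "slipknot fixture lacks slipknotted intermediates")
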