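"""Topological classification of open chains.

An open chain has no well-defined knot type; it acquires one after closure
into a ring.  Here each terminus is prolonged far outside the chain along a
stochastically chosen outward direction and the prolonged ends are joined by
an arc on a sphere much larger than the chain, so the closing geometry cannot
entangle with the chain itself.  Repeating this for many random closures and
taking the majority verdict of the Alexander determinant ``|Delta(-1)|``
yields a robust open-chain topology call; scanning subchains detects
slipknots (knotted portion inside a globally unknotted chain) and the minimal
knotted portion.

The determinant is computed exactly over the integers: project the ring onto
a generic plane, enumerate crossings, build the underpass relation matrix at
``t = -1`` and evaluate its minor determinant with fraction-free Bareiss
elimination.  At ``t = -1`` the two crossing handedness classes contribute
identical rows, so only the over/under assignment matters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from knotfold.chain_core import Conformation, Trajectory

__all__ = [
    "ClosureSpec",
    "KnotAssignment",
    "alexander_determinant",
    "stochastic_closure",
    "classify_conformation",
    "first_knotting_event",
]


class ProjectionError(RuntimeError):
    """No generic projection found after the retry cap."""


@dataclass(frozen=True)
class ClosureSpec:
    """Stochastic-closure protocol parameters.

    ``min_angle_deg``: sampled exit directions must form more than this angle
    with the oriented segment from the terminus to the bead ``anchor_seq_dist``
    positions inward.  ``extension_factor`` multiplies the chain's bounding
    sphere radius to set how far the termini are prolonged.
    """

    n_closures: int = 100
    min_angle_deg: float = 90.0
    anchor_seq_dist: int = 10
    extension_factor: float = 3.0
    majority_threshold: float = 0.6

    def __post_init__(self):
        if self.n_closures < 1:
            raise ValueError("n_closures must be >= 1")
        if not (0.0 < self.min_angle_deg < 180.0):
            raise ValueError("min_angle_deg must be in (0, 180)")


@dataclass(frozen=True)
class KnotAssignment:
    """Per-conformation topology verdict."""

    global_state: str            # "unknot" | "knotted" | "ambiguous"
    knot_determinant: int        # modal |Delta(-1)| over closures
    vote_fraction: float
    knotted_span: Optional[tuple]  # 0-based inclusive (start, stop) or None
    classification: str          # "unknotted" | "globally_knotted" | "slipknotted"


# ---------------------------------------------------------------------------
# Alexander determinant
# ---------------------------------------------------------------------------

def _bareiss_det(m: list) -> int:
    """Exact determinant of a square integer matrix (fraction-free Bareiss)."""
    a = [row[:] for row in m]
    n = len(a)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            for s in range(k + 1, n):
                if a[s][k] != 0:
                    a[k], a[s] = a[s], a[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
        prev = a[k][k]
    return sign * a[-1][-1]


def _find_crossings(xy: np.ndarray, z: np.ndarray, eps: float):
    """All transversal crossings of the projected closed polygon.

    Returns ``(pos_under, pos_over)`` arrays of curve parameters (segment
    index + fraction), or ``None`` if the projection is degenerate.
    """
    n = xy.shape[0]
    p1 = xy
    p2 = xy[(np.arange(n) + 1) % n]
    d = p2 - p1
    seg_len = np.linalg.norm(d, axis=1)
    if np.any(seg_len < eps):
        return None

    ii, jj = np.triu_indices(n, k=2)
    # exclude the wrap-around adjacency (segment 0 with segment n-1)
    keep = ~((ii == 0) & (jj == n - 1))
    ii, jj = ii[keep], jj[keep]

    di, dj = d[ii], d[jj]
    denom = di[:, 0] * dj[:, 1] - di[:, 1] * dj[:, 0]
    rel = p1[jj] - p1[ii]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (rel[:, 0] * dj[:, 1] - rel[:, 1] * dj[:, 0]) / denom
        t = (rel[:, 0] * di[:, 1] - rel[:, 1] * di[:, 0]) / denom
    parallel = np.abs(denom) < eps * np.maximum(seg_len[ii] * seg_len[jj], eps)
    s = np.where(parallel | ~np.isfinite(s), -1.0, s)
    t = np.where(parallel | ~np.isfinite(t), -1.0, t)
    tol = 1e-7
    inside = (~parallel) & (s > tol) & (s < 1 - tol) & (t > tol) & (t < 1 - tol)
    # an intersection grazing a vertex makes the diagram non-generic: re-project
    grazing = (~parallel) & ~inside \
        & (s > -tol) & (s < 1 + tol) & (t > -tol) & (t < 1 + tol)
    if np.any(grazing):
        return None
    zi = z[ii] + s * (z[(ii + 1) % n] - z[ii])
    zj = z[jj] + t * (z[(jj + 1) % n] - z[jj])
    if np.any(inside & (np.abs(zi - zj) < eps)):
        return None
    sel = inside
    pos_i = ii[sel] + s[sel]
    pos_j = jj[sel] + t[sel]
    under_is_i = zi[sel] < zj[sel]
    pos_under = np.where(under_is_i, pos_i, pos_j)
    pos_over = np.where(under_is_i, pos_j, pos_i)
    return pos_under, pos_over


def alexander_determinant(ring: np.ndarray, rng=None, max_retries: int = 25) -> int:
    """``|Delta(-1)|`` of a closed polygonal curve (odd positive integer).

    The curve is projected along random directions until a generic diagram is
    found (no tangencies, no crossings at vertices, distinct crossing
    depths); the underpass relation matrix is then evaluated exactly at
    ``t = -1``.  Unknot -> 1, trefoil -> 3, figure-eight -> 5.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 3 or ring.shape[0] < 3:
        raise ValueError("ring must be an (M, 3) array with M >= 3")
    rng = np.random.default_rng(rng)
    scale = max(np.ptp(ring, axis=0).max(), 1.0)
    eps = 1e-10 * scale
    rot = np.eye(3)
    for attempt in range(max_retries):
        pts = ring @ rot.T
        res = _find_crossings(pts[:, :2], pts[:, 2], eps)
        if res is not None:
            return _determinant_from_crossings(*res, n_seg=ring.shape[0])
        rot = Rotation.random(rng=rng).as_matrix()
    raise ProjectionError("no generic projection found; curve may be degenerate")


def _determinant_from_crossings(pos_under: np.ndarray, pos_over: np.ndarray,
                                n_seg: int) -> int:
    n = pos_under.shape[0]
    if n <= 1:
        return 1
    order = np.argsort(pos_under)
    pos_under = pos_under[order]
    pos_over = pos_over[order]
    # arc k (0-based) runs from underpass k-1 to underpass k (cyclically);
    # the overpass of underpass k lies on arc ov(k)
    ov = np.searchsorted(pos_under, pos_over) % n
    rows = []
    for k in range(n):
        row = [0] * n
        k1 = (k + 1) % n
        i = int(ov[k])
        if i == k or i == k1:
            row[k] += -1
            row[k1] += 1
        else:
            # at t = -1 both crossing handedness types give the same row
            row[k] += 1
            row[k1] += 1
            row[i] += -2
        rows.append(row)
    minor = [row[:-1] for row in rows[:-1]]
    return abs(_bareiss_det(minor))


# ---------------------------------------------------------------------------
# stochastic closure
# ---------------------------------------------------------------------------

def _sample_exit_direction(terminus: np.ndarray, anchor: np.ndarray,
                           min_angle_deg: float, rng) -> np.ndarray:
    """Uniform unit vector forming more than ``min_angle_deg`` with the
    oriented segment terminus -> anchor."""
    ref = anchor - terminus
    nref = np.linalg.norm(ref)
    ref = ref / nref if nref > 0 else np.array([1.0, 0.0, 0.0])
    cos_max = np.cos(np.radians(min_angle_deg))
    while True:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if float(v @ ref) < cos_max:
            return v


def stochastic_closure(x: Conformation | np.ndarray, spec: ClosureSpec,
                       rng=None) -> np.ndarray:
    """Close an open chain into a ring through an arc far outside the chain.

    Each terminus is prolonged by ``extension_factor`` bounding-sphere radii
    along a random outward direction; the prolonged ends are pushed onto a
    sphere of 10 bounding radii and joined by a short great-circle arc, so
    the closing geometry stays outside the chain's bounding sphere.
    """
    coords = x.coords if isinstance(x, Conformation) else np.asarray(x, dtype=float)
    n = coords.shape[0]
    if n <= spec.anchor_seq_dist:
        raise ValueError("chain shorter than anchor_seq_dist")
    rng = np.random.default_rng(rng)
    center = coords.mean(axis=0)
    radius = float(np.linalg.norm(coords - center, axis=1).max())
    radius = max(radius, 1.0)
    ext = spec.extension_factor * radius

    d0 = _sample_exit_direction(coords[0], coords[spec.anchor_seq_dist],
                                spec.min_angle_deg, rng)
    d1 = _sample_exit_direction(coords[-1], coords[-1 - spec.anchor_seq_dist],
                                spec.min_angle_deg, rng)
    e0 = coords[0] + ext * d0
    e1 = coords[-1] + ext * d1

    far = 10.0 * radius
    u0 = (e0 - center) / np.linalg.norm(e0 - center)
    u1 = (e1 - center) / np.linalg.norm(e1 - center)
    q0 = center + far * u0
    q1 = center + far * u1
    # great-circle arc q1 -> q0 (ring runs ... chain ... e1 q1 arc q0 e0 ...)
    dot = float(np.clip(u0 @ u1, -1.0, 1.0))
    if dot < -0.999:  # near-antipodal: route via a perpendicular waypoint
        perp = np.cross(u0, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        mids = [center + far * perp]
    else:
        omega = np.arccos(dot)
        k = max(2, int(np.ceil(omega / (np.pi / 4))))
        mids = []
        if omega > 1e-6:
            for s in np.linspace(0, 1, k + 1)[1:-1]:
                v = (np.sin((1 - s) * omega) * u1 + np.sin(s * omega) * u0) \
                    / np.sin(omega)
                mids.append(center + far * v / np.linalg.norm(v))
        else:
            mids = []
    ring = np.vstack([coords, e1[None, :], q1[None, :]] +
                     [m[None, :] for m in mids] + [q0[None, :], e0[None, :]])
    return ring


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _closure_vote(coords: np.ndarray, spec: ClosureSpec, rng) -> tuple:
    """(state, modal determinant, vote fraction) over ``spec.n_closures``."""
    dets = []
    for _ in range(spec.n_closures):
        ring = stochastic_closure(coords, spec, rng)
        dets.append(alexander_determinant(ring, rng=rng))
    values, counts = np.unique(dets, return_counts=True)
    top = int(np.argmax(counts))
    mode, frac = int(values[top]), float(counts[top] / len(dets))
    if frac < spec.majority_threshold:
        # a split between several nontrivial determinants still means knotted
        nt_mask = values != 1
        nontrivial = float(counts[nt_mask].sum() / len(dets))
        if nontrivial >= spec.majority_threshold:
            nt_mode = int(values[nt_mask][np.argmax(counts[nt_mask])])
            return "knotted", nt_mode, nontrivial
        return "ambiguous", mode, frac
    return ("unknot" if mode == 1 else "knotted"), mode, frac


def _scan_schedule(n: int, lengths: Sequence[int] | None) -> list:
    if lengths is not None:
        return [l for l in lengths if l <= n]
    return [l for l in range(20, n + 1, 10)]


def classify_conformation(x: Conformation | np.ndarray, spec: ClosureSpec,
                          scan_lengths: Sequence[int] | None = None,
                          seed=None, do_scan: bool = True,
                          scan_closures: int | None = None,
                          offset_stride: int = 1) -> KnotAssignment:
    """Full topology verdict for one open chain.

    Global state by closure vote; if a subchain scan is requested, windows of
    the schedule lengths (default 20, 30, 40, ... up to N) at all start
    offsets are tested shortest-first and the first knotted window gives
    ``knotted_span`` (a slipknot when the global state is unknot).
    """
    coords = x.coords if isinstance(x, Conformation) else np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    state, mode, frac = _closure_vote(coords, spec, rng)
    span = None
    if do_scan:
        n = coords.shape[0]
        sub_spec = spec if scan_closures is None else replace(
            spec, n_closures=scan_closures)
        for length in _scan_schedule(n, scan_lengths):
            if length <= sub_spec.anchor_seq_dist:
                continue
            found = None
            for start in range(0, n - length + 1, offset_stride):
                sub = coords[start:start + length]
                s_state, s_mode, _ = _closure_vote(sub, sub_spec, rng)
                if s_state == "knotted":
                    found = (start, start + length - 1)
                    break
            if found is not None:
                span = found
                break
    if state == "knotted":
        classification = "globally_knotted"
    elif state == "unknot" and span is not None:
        classification = "slipknotted"
    else:
        classification = "unknotted"
    return KnotAssignment(global_state=state, knot_determinant=mode,
                          vote_fraction=frac, knotted_span=span,
                          classification=classification)


def first_knotting_event(traj: Trajectory, spec: ClosureSpec, seed=None,
                         every: int = 1) -> Optional[int]:
    """Smallest frame index classified globally knotted, or ``None``.

    Frames are tested every ``every`` frames (global vote only; no subchain
    scan is needed to call the event).
    """
    rng = np.random.default_rng(seed)
    for k in range(0, len(traj.frames), every):
        state, _, _ = _closure_vote(traj.frames[k].coords, spec, rng)
        if state == "knotted":
            return k
    return None
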