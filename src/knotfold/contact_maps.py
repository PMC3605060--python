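"""Smooth contact maps and the contact-map collective coordinate.

The smooth contact function is the rational switching form

    C(r) = [1 - (r/r0)^p] / [1 - (r/r0)^q],   p < q,

evaluated through its factored polynomial representation so the removable
singularity at ``r = r0`` (value ``p/q``) never appears numerically.

The collective coordinate is the squared Frobenius-type distance between the
instantaneous and reference contact maps, summed over an included pair set
(by default the support of the reference map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Optional

import numpy as np

from knotfold import _kernels
from knotfold.chain_core import Conformation, NativeStructure, Trajectory

__all__ = [
    "ContactMapParams",
    "ContactEvent",
    "contact_value",
    "contact_value_deriv",
    "contact_matrix",
    "build_native_structure",
    "collective_coordinate",
    "cc_and_gradient",
    "native_overlap",
    "formation_times",
]


@dataclass(frozen=True)
class ContactMapParams:
    """Parameters of the smooth contact map and pair-inclusion rules.

    ``cutoff`` defines the native contact set (reference distance below it,
    ``|i - j| >= min_seq_sep``); ``support_threshold`` defines the sparse
    support of the map sum; ``include_mode`` selects whether the collective
    coordinate sums over the native-map support only (``"native"``) or over
    the union of native and instantaneous supports (``"union"``).
    """

    r0: float = 7.5
    cutoff: float = 7.5
    min_seq_sep: int = 3
    exponents: tuple = (6, 10)
    support_threshold: float = 0.01
    include_mode: str = "native"

    def __post_init__(self):
        if self.r0 <= 0 or self.cutoff <= 0:
            raise ValueError("r0 and cutoff must be positive")
        if self.min_seq_sep < 1:
            raise ValueError("min_seq_sep must be >= 1")
        p, q = self.exponents
        if not (0 < p < q):
            raise ValueError("exponents must satisfy 0 < p < q")
        if self.include_mode not in ("native", "union"):
            raise ValueError("include_mode must be 'native' or 'union'")


@dataclass(frozen=True)
class ContactEvent:
    """First formation of one native contact along a trajectory."""

    contact: tuple
    formation_frame: Optional[int]


def _poly_ratio(params: ContactMapParams, u: np.ndarray):
    """Evaluate C and dC/du at u = r/r0 via the factored rational form.

    (1 - u^p)/(1 - u^q) = P(u^g)/Q(u^g) with g = gcd(p, q),
    P(x) = sum_{k<p/g} x^k, Q(x) = sum_{k<q/g} x^k; Q > 0 for all u >= 0.
    """
    p, q = params.exponents
    g = gcd(p, q)
    mp, mq = p // g, q // g
    x = u ** g
    powers = x[..., None] ** np.arange(mq)
    P = powers[..., :mp].sum(axis=-1)
    Q = powers.sum(axis=-1)
    C = P / Q
    # dP/dx, dQ/dx
    kp = np.arange(1, mp)
    kq = np.arange(1, mq)
    dP = (kp * x[..., None] ** (kp - 1)).sum(axis=-1) if mp > 1 else np.zeros_like(x)
    dQ = (kq * x[..., None] ** (kq - 1)).sum(axis=-1) if mq > 1 else np.zeros_like(x)
    dC_dx = (dP * Q - P * dQ) / Q ** 2
    dx_du = g * u ** (g - 1)
    return C, dC_dx * dx_du


def contact_value(r, params: ContactMapParams = ContactMapParams()):
    """Smooth contact function C(r) in [0, 1]; vectorised over ``r``."""
    u = np.asarray(r, dtype=float) / params.r0
    C, _ = _poly_ratio(params, u)
    return C if C.ndim else float(C)


def contact_value_deriv(r, params: ContactMapParams = ContactMapParams()):
    """dC/dr at ``r``; vectorised."""
    u = np.asarray(r, dtype=float) / params.r0
    _, dC_du = _poly_ratio(params, u)
    d = dC_du / params.r0
    return d if d.ndim else float(d)


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def contact_matrix(x: Conformation, params: ContactMapParams) -> np.ndarray:
    """Symmetric N x N smooth contact map with the near-diagonal band zeroed."""
    coords = x.coords
    n = coords.shape[0]
    r = _pair_distances(coords)
    np.fill_diagonal(r, 1.0)
    C = contact_value(r, params)
    i, j = np.indices((n, n))
    C[np.abs(i - j) < params.min_seq_sep] = 0.0
    return C


def build_native_structure(reference: Conformation,
                           params: ContactMapParams | None = None,
                           annotated_regions: dict | None = None
                           ) -> NativeStructure:
    """Derive the native contact set and native map from a reference chain.

    Native contacts: reference bead-bead distance <= ``params.cutoff`` and
    sequence separation >= ``params.min_seq_sep``.
    """
    params = params or ContactMapParams()
    coords = reference.coords
    n = coords.shape[0]
    r = _pair_distances(coords)
    contacts = set()
    for i in range(n):
        for j in range(i + params.min_seq_sep, n):
            if r[i, j] <= params.cutoff:
                contacts.add((i, j))
    native_map = contact_matrix(reference, params)
    return NativeStructure(reference=reference,
                           native_contacts=frozenset(contacts),
                           native_map=native_map,
                           annotated_regions=dict(annotated_regions or {}),
                           params=params)


def _support_pairs(native: NativeStructure, params: ContactMapParams) -> np.ndarray:
    """Index pairs (i < j) in the native-map support (cached on the native)."""
    key = (params.min_seq_sep, params.support_threshold)
    cache = getattr(native, "_support_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    nm = native.native_map
    iu = np.triu_indices(nm.shape[0], k=params.min_seq_sep)
    mask = nm[iu] > params.support_threshold
    pairs = np.column_stack([iu[0][mask], iu[1][mask]])
    native._support_cache = (key, pairs)
    return pairs


def collective_coordinate(x: Conformation, native: NativeStructure,
                          params: ContactMapParams | None = None) -> float:
    """Squared distance between instantaneous and native contact maps."""
    params = params or native.params or ContactMapParams()
    if x.n_beads != native.n_beads:
        raise ValueError("conformation / native size mismatch")
    if params.include_mode == "union":
        Ci = contact_matrix(x, params)
        Cn = native.native_map
        thr = params.support_threshold
        mask = (Ci > thr) | (Cn > thr)
        iu = np.triu_indices(Cn.shape[0], k=params.min_seq_sep)
        m = mask[iu]
        return float(((Ci[iu][m] - Cn[iu][m]) ** 2).sum())
    z, _ = cc_and_gradient(x, native, params)
    return z


def cc_and_gradient(x: Conformation, native: NativeStructure,
                    params: ContactMapParams | None = None):
    """Collective coordinate and its gradient w.r.t. bead coordinates.

    Native-support mode only (the support set is fixed, so the coordinate is
    differentiable).  Returns ``(z, grad)`` with grad of shape ``(N, 3)``.
    """
    params = params or native.params or ContactMapParams()
    coords = x.coords if isinstance(x, Conformation) else np.asarray(x, float)
    pairs = _support_pairs(native, params)
    grad = np.zeros_like(coords)
    if pairs.size == 0:
        return 0.0, grad
    if _kernels.HAVE_NUMBA:
        p_exp, q_exp = params.exponents
        g = gcd(p_exp, q_exp)
        z, grad = _kernels.cc_value_grad(
            np.ascontiguousarray(coords), pairs,
            native.native_map[pairs[:, 0], pairs[:, 1]],
            params.r0, g, p_exp // g, q_exp // g)
        return float(z), grad
    i, j = pairs[:, 0], pairs[:, 1]
    d = coords[i] - coords[j]
    r = np.linalg.norm(d, axis=1)
    Ci = contact_value(r, params)
    Cn = native.native_map[i, j]
    diff = Ci - Cn
    z = float((diff ** 2).sum())
    w = 2.0 * diff * contact_value_deriv(r, params) / r  # dz/dr * 1/r
    np.add.at(grad, i, (w[:, None] * d))
    np.add.at(grad, j, -(w[:, None] * d))
    return z, grad


def native_overlap(x: Conformation, native: NativeStructure,
                   tol_factor: float = 1.2) -> float:
    """Fraction of native contacts formed in ``x``.

    A contact counts as formed when its instantaneous distance is at most
    ``tol_factor`` times its reference distance.
    """
    if tol_factor < 1.0:
        raise ValueError("tol_factor must be >= 1")
    pairs = native.contact_pairs()
    if pairs.shape[0] == 0:
        raise ValueError("native structure has no contacts")
    if x.n_beads != native.n_beads:
        raise ValueError("conformation / native size mismatch")
    d = np.linalg.norm(x.coords[pairs[:, 0]] - x.coords[pairs[:, 1]], axis=1)
    dn = native.contact_distances()
    return float(np.mean(d <= tol_factor * dn))


def formation_times(traj: Trajectory, native: NativeStructure,
                    tol_factor: float = 1.2) -> list:
    """First-formation frame of every native contact along a trajectory.

    Returns one :class:`ContactEvent` per native contact (sorted pair order);
    ``formation_frame`` is ``None`` for contacts never formed.
    """
    pairs = native.contact_pairs()
    dn = native.contact_distances()
    first = np.full(pairs.shape[0], -1, dtype=int)
    for k, frame in enumerate(traj.frames):
        todo = first < 0
        if not todo.any():
            break
        p = pairs[todo]
        d = np.linalg.norm(frame.coords[p[:, 0]] - frame.coords[p[:, 1]], axis=1)
        formed = d <= tol_factor * dn[todo]
        idx = np.flatnonzero(todo)[formed]
        first[idx] = k
    return [ContactEvent(contact=(int(i), int(j)),
                         formation_frame=(int(f) if f >= 0 else None))
            for (i, j), f in zip(pairs, first)]
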