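"""Coarse-grained Cα-bead energy and force models.

Two variants share the bonded and native-centric terms:

* ``native_only`` -- harmonic bonds/angles, a cosine dihedral series fit to
  the reference dihedrals, 12-10 wells on the native contacts and a capped
  excluded-volume repulsion elsewhere;
* ``with_nonnative`` -- additionally a quasi-chemical pair term (a smooth
  short-range well scaled by a statistical amino-acid contact-propensity
  matrix, shipped as an editable TSV) and Debye-screened electrostatics on
  charged residues (D, E = -1; K, R = +1).

Energies are in kT at the reference temperature; forces are exact analytic
gradients (finite-difference-validated in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from knotfold.chain_core import Conformation, NativeStructure
from knotfold import _kernels

__all__ = [
    "ForceFieldParams",
    "ForceFieldSpec",
    "EnergyBreakdown",
    "load_quasichemical_matrix",
    "build_forcefield",
    "energy",
    "force",
    "energy_and_force",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


@dataclass(frozen=True)
class ForceFieldParams:
    """Tunable constants (kT / Angstrom units)."""

    k_bond: float = 100.0
    k_angle: float = 20.0
    k_dihedral_1: float = 1.0
    k_dihedral_3: float = 0.5
    native_eps: float = 1.0          # native-contact well depth
    ev_sigma: float = 4.0            # excluded-volume bead diameter
    ev_eps: float = 1.0
    ev_cap: float = 100.0            # hard-core energy cap (keeps MC ergodic)
    qc_scale: float = 1.0            # multiplies the propensity matrix
    qc_range: float = 6.5            # centre of the quasi-chemical well
    qc_width: float = 0.75
    debye_length: float = 10.0
    coulomb_prefactor: float = 7.0   # kT*A at unit charges (approx. 25C water)
    min_seq_sep: int = 3


@dataclass
class ForceFieldSpec:
    """Assembled per-system force field (all arrays index into the chain)."""

    n_beads: int
    mode: str                        # "native_only" | "with_nonnative"
    params: ForceFieldParams
    bond_r0: np.ndarray              # (N-1,)
    angle_t0: np.ndarray             # (N-2,) radians
    dihedral_p0: np.ndarray          # (N-3,) radians
    native_pairs: np.ndarray         # (Nc, 2)
    native_sigma: np.ndarray         # (Nc,) native distances
    nonnative_pairs: np.ndarray      # (Nn, 2) pairs with |i-j|>=min_seq_sep
    qc_eps: np.ndarray               # (Nn,) propensity, zero when native_only
    charge_product: np.ndarray       # (Nn,) q_i*q_j, zero when native_only
    sequence: str = ""


@dataclass(frozen=True)
class EnergyBreakdown:
    bonded: float
    native: float
    quasichemical: float
    electrostatic: float
    excluded_volume: float

    @property
    def total(self) -> float:
        return (self.bonded + self.native + self.quasichemical
                + self.electrostatic + self.excluded_volume)


def load_quasichemical_matrix(path=None) -> pd.DataFrame:
    """20x20 symmetric contact-propensity matrix (kT), amino-acid lettered."""
    if path is None:
        path = resources.files("knotfold.data") / "quasichemical.tsv"
    m = pd.read_csv(path, sep="\t", index_col=0)
    if not np.allclose(m.values, m.values.T):
        raise ValueError("quasichemical matrix must be symmetric")
    return m


def _dihedral_angles(x: np.ndarray) -> np.ndarray:
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    yy = (m1 * n2).sum(1)
    xx = (n1 * n2).sum(1)
    return np.arctan2(yy, xx)


def _angles(x: np.ndarray) -> np.ndarray:
    u = x[:-2] - x[1:-1]
    v = x[2:] - x[1:-1]
    cu = np.linalg.norm(u, axis=1)
    cv = np.linalg.norm(v, axis=1)
    cos = np.clip((u * v).sum(1) / (cu * cv), -1.0, 1.0)
    return np.arccos(cos)


def build_forcefield(native: NativeStructure, sequence: str | None = None,
                     mode: str = "native_only",
                     params: ForceFieldParams = ForceFieldParams(),
                     qc_matrix: pd.DataFrame | None = None) -> ForceFieldSpec:
    """Assemble a force field from a native structure and a sequence.

    ``sequence`` defaults to poly-alanine (which carries no charge and a mild
    uniform propensity).  In ``native_only`` mode the quasi-chemical and
    electrostatic couplings are identically zero.
    """
    if mode not in ("native_only", "with_nonnative"):
        raise ValueError(f"unknown mode {mode!r}")
    n = native.n_beads
    sequence = sequence or "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length does not match bead count")
    bad = set(sequence) - set(_AA)
    if bad:
        raise ValueError(f"unknown amino-acid code(s): {sorted(bad)}")

    x0 = native.reference.coords
    bond_r0 = np.linalg.norm(np.diff(x0, axis=0), axis=1)
    angle_t0 = _angles(x0)
    dihedral_p0 = _dihedral_angles(x0)

    native_pairs = native.contact_pairs()
    native_sigma = native.contact_distances()
    native_set = set(map(tuple, native_pairs))

    iu = np.triu_indices(n, k=params.min_seq_sep)
    nn_mask = np.array([(i, j) not in native_set
                        for i, j in zip(iu[0], iu[1])], dtype=bool)
    nonnative_pairs = np.column_stack([iu[0][nn_mask], iu[1][nn_mask]])

    if mode == "with_nonnative":
        qc = qc_matrix if qc_matrix is not None else load_quasichemical_matrix()
        eps_aa = qc.loc[list(sequence), list(sequence)].values
        qc_eps = params.qc_scale * eps_aa[nonnative_pairs[:, 0],
                                          nonnative_pairs[:, 1]]
        q = np.array([_CHARGE.get(a, 0.0) for a in sequence])
        charge_product = q[nonnative_pairs[:, 0]] * q[nonnative_pairs[:, 1]]
    else:
        qc_eps = np.zeros(nonnative_pairs.shape[0])
        charge_product = np.zeros(nonnative_pairs.shape[0])

    return ForceFieldSpec(n_beads=n, mode=mode, params=params,
                          bond_r0=bond_r0, angle_t0=angle_t0,
                          dihedral_p0=dihedral_p0,
                          native_pairs=native_pairs, native_sigma=native_sigma,
                          nonnative_pairs=nonnative_pairs, qc_eps=qc_eps,
                          charge_product=charge_product, sequence=sequence)


# ---------------------------------------------------------------------------
# energy / force evaluation
# ---------------------------------------------------------------------------

def _ev_energy_force(r: np.ndarray, p: ForceFieldParams):
    """Capped 1/r^12 repulsion: value and dV/dr (C1 at the cap)."""
    sig = p.ev_sigma
    if p.ev_eps <= 0.0:
        return np.zeros_like(r), np.zeros_like(r)
    v = p.ev_eps * (sig / r) ** 12
    dv = -12.0 * v / r
    # linearise below the radius where v reaches the cap
    r_cap = sig * (p.ev_eps / p.ev_cap) ** (1.0 / 12.0)
    slope = -12.0 * p.ev_cap / r_cap
    capped = r < r_cap
    v = np.where(capped, p.ev_cap + slope * (r - r_cap), v)
    dv = np.where(capped, slope, dv)
    return v, dv


def _pair_terms(x: np.ndarray, ff: ForceFieldSpec):
    """Energies and per-pair radial derivatives of all non-bonded terms."""
    p = ff.params
    out = {}

    i, j = ff.native_pairs[:, 0], ff.native_pairs[:, 1]
    d = x[i] - x[j]
    r = np.linalg.norm(d, axis=1)
    # linearise the 12-10 repulsive core below 0.8 sigma (same cap rationale
    # as the excluded volume: bounded forces keep the integrators stable)
    r_lin = 0.8 * ff.native_sigma
    rc = np.maximum(r, r_lin)
    s = ff.native_sigma / rc
    v = p.native_eps * (5.0 * s ** 12 - 6.0 * s ** 10)
    dv = p.native_eps * (-60.0 * s ** 12 + 60.0 * s ** 10) / rc
    below = r < r_lin
    v = np.where(below, v + dv * (r - r_lin), v)
    out["native"] = (ff.native_pairs, d, r, v, dv)

    i, j = ff.nonnative_pairs[:, 0], ff.nonnative_pairs[:, 1]
    d = x[i] - x[j]
    r = np.linalg.norm(d, axis=1)
    v_ev, dv_ev = _ev_energy_force(r, p)
    out["excluded_volume"] = (ff.nonnative_pairs, d, r, v_ev, dv_ev)

    sig = 1.0 / (1.0 + np.exp(np.minimum((r - p.qc_range) / p.qc_width, 50.0)))
    v_qc = ff.qc_eps * sig
    dv_qc = ff.qc_eps * (-sig * (1.0 - sig) / p.qc_width)
    out["quasichemical"] = (ff.nonnative_pairs, d, r, v_qc, dv_qc)

    screen = np.exp(-r / p.debye_length)
    v_el = p.coulomb_prefactor * ff.charge_product * screen / r
    dv_el = -v_el * (1.0 / r + 1.0 / p.debye_length)
    out["electrostatic"] = (ff.nonnative_pairs, d, r, v_el, dv_el)
    return out


def _kernel_args(coords: np.ndarray, ff: ForceFieldSpec) -> tuple:
    p = ff.params
    return (coords, ff.bond_r0, ff.angle_t0, ff.dihedral_p0,
            ff.native_pairs, ff.native_sigma, ff.nonnative_pairs,
            ff.qc_eps, ff.charge_product,
            p.k_bond, p.k_angle, p.k_dihedral_1, p.k_dihedral_3,
            p.native_eps, p.ev_sigma, p.ev_eps, p.ev_cap,
            p.qc_range, p.qc_width, p.debye_length, p.coulomb_prefactor)


def energy_and_force(x: Conformation | np.ndarray,
                     ff: ForceFieldSpec) -> tuple:
    """(EnergyBreakdown, force array) in one fused compiled evaluation."""
    coords = x.coords if isinstance(x, Conformation) else np.asarray(x, float)
    if coords.shape[0] != ff.n_beads:
        raise ValueError("conformation / force field size mismatch")
    f, e_bond, e_nat, e_qc, e_el, e_ev = _kernels.ff_energy_force(
        *_kernel_args(np.ascontiguousarray(coords), ff))
    return EnergyBreakdown(bonded=e_bond, native=e_nat, quasichemical=e_qc,
                           electrostatic=e_el, excluded_volume=e_ev), f


def energy(x: Conformation | np.ndarray, ff: ForceFieldSpec,
           use_kernel: bool = True) -> EnergyBreakdown:
    """Energy breakdown (kT) of a conformation under a force field."""
    if use_kernel and _kernels.HAVE_NUMBA:
        return energy_and_force(x, ff)[0]
    coords = x.coords if isinstance(x, Conformation) else np.asarray(x, float)
    if coords.shape[0] != ff.n_beads:
        raise ValueError("conformation / force field size mismatch")
    p = ff.params

    bond_r = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    e_bond = float(p.k_bond * ((bond_r - ff.bond_r0) ** 2).sum())
    e_angle = float(p.k_angle * ((_angles(coords) - ff.angle_t0) ** 2).sum())
    dphi = _dihedral_angles(coords) - ff.dihedral_p0
    e_dih = float(p.k_dihedral_1 * (1.0 - np.cos(dphi)).sum()
                  + p.k_dihedral_3 * (1.0 - np.cos(3.0 * dphi)).sum())

    terms = _pair_terms(coords, ff)
    return EnergyBreakdown(
        bonded=e_bond + e_angle + e_dih,
        native=float(terms["native"][3].sum()),
        quasichemical=float(terms["quasichemical"][3].sum()),
        electrostatic=float(terms["electrostatic"][3].sum()),
        excluded_volume=float(terms["excluded_volume"][3].sum()))


def force(x: Conformation | np.ndarray, ff: ForceFieldSpec,
          use_kernel: bool = True) -> np.ndarray:
    """Force field gradient: F = -dE/dx, shape (N, 3), in kT/Angstrom."""
    if use_kernel and _kernels.HAVE_NUMBA:
        return energy_and_force(x, ff)[1]
    coords = x.coords if isinstance(x, Conformation) else np.asarray(x, float)
    if coords.shape[0] != ff.n_beads:
        raise ValueError("conformation / force field size mismatch")
    p = ff.params
    f = np.zeros_like(coords)

    # bonds
    dvec = np.diff(coords, axis=0)
    r = np.linalg.norm(dvec, axis=1)
    dv = 2.0 * p.k_bond * (r - ff.bond_r0)
    g = (dv / r)[:, None] * dvec       # dE/dx of the second bead
    f[1:] -= g
    f[:-1] += g

    # angles: E = k (theta - t0)^2
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.clip((u * v).sum(1) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos)
    sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
    dE = 2.0 * p.k_angle * (theta - ff.angle_t0)
    # d(theta)/du = -1/sin * d(cos)/du
    dcos_du = v / (nu * nv)[:, None] - (cos / nu ** 2)[:, None] * u
    dcos_dv = u / (nu * nv)[:, None] - (cos / nv ** 2)[:, None] * v
    gu = (-dE / sin)[:, None] * dcos_du
    gv = (-dE / sin)[:, None] * dcos_dv
    f[:-2] -= gu
    f[1:-1] += gu + gv
    f[2:] -= gv

    # dihedrals (Blondel-Karplus gradients)
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2((m1 * n2).sum(1), (n1 * n2).sum(1))
    dphi = phi - ff.dihedral_p0
    dE = (p.k_dihedral_1 * np.sin(dphi)
          + 3.0 * p.k_dihedral_3 * np.sin(3.0 * dphi))
    # clamp the colinear singularity (n -> 0): bounded torque, energy exact
    n1sq = np.maximum((n1 ** 2).sum(1), 1e-2)
    n2sq = np.maximum((n2 ** 2).sum(1), 1e-2)
    # signs fixed to this module's atan2 angle convention
    dphi_dx1 = (nb2 / n1sq)[:, None] * n1
    dphi_dx4 = -(nb2 / n2sq)[:, None] * n2
    c12 = ((b1 * b2).sum(1) / nb2 ** 2)[:, None]
    c32 = ((b3 * b2).sum(1) / nb2 ** 2)[:, None]
    dphi_dx2 = -(1.0 + c12) * dphi_dx1 + c32 * dphi_dx4
    dphi_dx3 = c12 * dphi_dx1 - (1.0 + c32) * dphi_dx4
    f[:-3] -= dE[:, None] * dphi_dx1
    f[1:-2] -= dE[:, None] * dphi_dx2
    f[2:-1] -= dE[:, None] * dphi_dx3
    f[3:] -= dE[:, None] * dphi_dx4

    # non-bonded pair terms
    n = ff.n_beads
    for pairs, d, r, _, dv in _pair_terms(coords, ff).values():
        if pairs.shape[0] == 0:
            continue
        g = (dv / r)[:, None] * d      # dE/dx_i
        for c in range(3):
            f[:, c] -= np.bincount(pairs[:, 0], weights=g[:, c], minlength=n)
            f[:, c] += np.bincount(pairs[:, 1], weights=g[:, c], minlength=n)
    return f
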