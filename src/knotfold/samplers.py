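"""Dynamics engines: ratcheted overdamped Langevin and Metropolis MC.

The ratchet-and-pawl bias acts on the contact-map collective coordinate z:
no force while the chain spontaneously lowers z below its running reference
``z_m``; a harmonic penalty ``(k_R/2)(z - z_m)^2`` otherwise.  ``z_m`` always
follows z downward; upward (backtracking) updates are accepted with
probability ``exp(-beta_tilde * (z - z_m))`` (Metropolis), which weakens the
bias and lets the chain escape topological traps.  ``beta_tilde = inf``
recovers the strictly monotone ratchet.

The MC engine combines local crankshaft and single-bead Cartesian moves
(dynamics-mimicking) with optional global pivot moves (equilibrium
sampling); move boldness is auto-tuned during burn-in towards a target
acceptance rate, then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from knotfold.chain_core import Conformation, NativeStructure, Trajectory
from knotfold.contact_maps import (ContactMapParams, cc_and_gradient,
                                   native_overlap)
from knotfold.cg_forcefield import ForceFieldSpec, energy, force

__all__ = [
    "RatchetState",
    "MoveSet",
    "bias_potential",
    "update_zm",
    "run_rmd",
    "run_mc",
    "denature",
]


class SamplerError(RuntimeError):
    """Numerical blow-up or a dead sampler."""


@dataclass
class RatchetState:
    """Running state of the ratchet bias.

    ``beta_tilde`` is the artificial inverse thermal energy of the
    backtracking rule; 0 disables the ratchet memory entirely (every upward
    move accepted), ``inf`` forbids backtracking.  ``quadratic_backtrack``
    switches the Metropolis exponent from ``(z - z_m)`` to the bias-energy
    difference ``(k_R/2)(z - z_m)^2``.
    """

    k_R: float = 0.02
    beta_tilde: float = 50.0
    z_m: Optional[float] = None
    quadratic_backtrack: bool = False

    def __post_init__(self):
        if self.k_R < 0 or self.beta_tilde < 0:
            raise ValueError("k_R and beta_tilde must be >= 0")


@dataclass
class MoveSet:
    """MC move parameters; boldness fields are tuned in place during burn-in."""

    crankshaft_angle: float = 0.8        # max rotation (radians)
    cartesian_step: float = 0.5          # max bead displacement (Angstrom)
    pivot_enabled: bool = False
    pivot_angle: float = 1.5
    target_acceptance: float = 0.5
    crankshaft_gap: int = 6              # max sequence gap of the rotated piece
    p_crankshaft: float = 0.5            # remainder split between cartesian/pivot
    # end-regrowth: resample a terminal segment with uniform random bond
    # directions (symmetric proposal); efficient at changing end topology
    p_regrow: float = 0.0
    regrow_max: int = 12
    regrow_min: int = 4
    # fraction of pivot moves whose hinge is drawn near a terminus (the
    # short side is rotated): cheap bonded cost, efficient end threading
    pivot_end_bias: float = 0.0
    pivot_end_window: int = 15

    def __post_init__(self):
        if self.crankshaft_angle <= 0 or self.cartesian_step <= 0:
            raise ValueError("move boldness must be positive")
        if not (0.0 < self.target_acceptance < 1.0):
            raise ValueError("target_acceptance must be in (0, 1)")


def bias_potential(z: float, s: RatchetState) -> float:
    """Ratchet potential: 0 at or below the reference, harmonic above it."""
    if s.z_m is None or z <= s.z_m:
        return 0.0
    return 0.5 * s.k_R * (z - s.z_m) ** 2


def update_zm(z_t: float, s: RatchetState, u: float) -> float:
    """Metropolis update of the running reference ``z_m``; returns the new value.

    Downward moves are always taken; an upward move is taken iff
    ``exp(-beta_tilde * dz) >= u`` (or the quadratic variant).
    """
    if s.z_m is None or z_t <= s.z_m:
        s.z_m = z_t
        return s.z_m
    if s.quadratic_backtrack:
        arg = 0.5 * s.k_R * (z_t - s.z_m) ** 2
    else:
        arg = z_t - s.z_m
    with np.errstate(over="ignore"):
        if np.exp(-s.beta_tilde * arg) >= u:
            s.z_m = z_t
    return s.z_m


# ---------------------------------------------------------------------------
# ratcheted overdamped Langevin
# ---------------------------------------------------------------------------

def run_rmd(start: Conformation, native: NativeStructure, ff: ForceFieldSpec,
            ratchet: Optional[RatchetState], n_steps: int, dt: float = 1e-3,
            temperature: float = 1.0, seed: int = 0, diffusion: float = 1.0,
            save_every: int = 100, cm_params: ContactMapParams | None = None,
            record_energy: bool = False, debug: bool = False,
            max_step: float = 2.0) -> Trajectory:
    """Overdamped Langevin dynamics with the optional ratchet bias.

    ``x += (D dt / kT) F + sqrt(2 D dt) xi`` with ``F`` the physical force
    minus the gradient of the bias potential.  Noise and Metropolis draws use
    independent seeded streams, so ``ratchet=None`` and ``k_R = 0`` produce
    bitwise-identical trajectories.  Per-frame cc, bias energy and the
    running ``z_m`` are recorded; ``debug`` additionally stores per-step
    ``(z, z_m, |bias force|)`` for contract checking.
    """
    if n_steps < 1 or dt <= 0:
        raise ValueError("need n_steps >= 1 and dt > 0")
    rng_noise = np.random.default_rng(seed)
    rng_metro = np.random.default_rng(seed + 987654321)
    cm_params = cm_params or native.params
    x = start.coords.copy()
    mob = diffusion * dt / temperature
    sig = np.sqrt(2.0 * diffusion * dt)

    frames, ccs, ebias, epots, zms = [], [], [], [], []
    dbg = {"z": [], "z_m": [], "bias_force_norm": []} if debug else None

    def snapshot(step, z, vb):
        frames.append(Conformation(x.copy(), frame_index=step))
        ccs.append(z)
        ebias.append(vb)
        zms.append(ratchet.z_m if ratchet is not None else np.nan)
        if record_energy:
            epots.append(energy(x, ff).total)

    for step in range(n_steps + 1):
        z, gz = cc_and_gradient(x, native, cm_params)
        f_total = force(x, ff)
        vb = 0.0
        bias_norm = 0.0
        if ratchet is not None:
            vb = bias_potential(z, ratchet)
            if ratchet.z_m is not None and z > ratchet.z_m and ratchet.k_R > 0:
                fb = -ratchet.k_R * (z - ratchet.z_m) * gz
                f_total = f_total + fb
                bias_norm = float(np.linalg.norm(fb))
            update_zm(z, ratchet, float(rng_metro.random()))
        if debug:
            dbg["z"].append(z)
            dbg["z_m"].append(ratchet.z_m if ratchet is not None else np.nan)
            dbg["bias_force_norm"].append(bias_norm)
        if step % save_every == 0:
            snapshot(step, z, vb)
        if step == n_steps:
            break
        disp = mob * f_total + sig * rng_noise.standard_normal(x.shape)
        step_size = np.abs(disp).max()
        if not np.isfinite(step_size) or step_size > max_step:
            raise SamplerError(
                f"integration blow-up at step {step}: max displacement "
                f"{step_size:.3g} A (reduce dt)")
        x = x + disp

    traj = Trajectory(frames, dt=dt * save_every, seed=seed,
                      cc_value=np.array(ccs), bias_energy=np.array(ebias),
                      potential_energy=np.array(epots) if record_energy else None)
    traj.meta["z_m"] = np.array(zms)
    traj.meta["save_every"] = save_every
    if debug:
        traj.meta["debug"] = {k: np.array(v) for k, v in dbg.items()}
    return traj


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

def _propose(x: np.ndarray, moves: MoveSet, rng) -> tuple:
    """One trial move; returns (new coords, move kind)."""
    n = x.shape[0]
    r = rng.random()
    if moves.p_regrow > 0.0 and r < moves.p_regrow:
        kind = "regrow"
    else:
        r = (r - moves.p_regrow) / max(1e-12, 1.0 - moves.p_regrow)
        if moves.pivot_enabled:
            kind = ("crankshaft" if r < moves.p_crankshaft
                    else "cartesian" if r < moves.p_crankshaft
                    + (1 - moves.p_crankshaft) / 2 else "pivot")
        else:
            kind = ("crankshaft" if r < moves.p_crankshaft else "cartesian")
    y = x.copy()
    if kind == "regrow":
        length = int(rng.integers(moves.regrow_min,
                                  min(moves.regrow_max, n - 3) + 1))
        bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
        dirs = rng.normal(size=(length, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        if rng.random() < 0.5:  # C-terminal segment
            for m, i in enumerate(range(n - length, n)):
                y[i] = y[i - 1] + bonds[i - 1] * dirs[m]
        else:                   # N-terminal segment
            for m, i in enumerate(range(length - 1, -1, -1)):
                y[i] = y[i + 1] + bonds[i] * dirs[m]
        return y, kind
    if kind == "crankshaft":
        i = int(rng.integers(0, n - 2))
        j = int(rng.integers(i + 2, min(n, i + 2 + moves.crankshaft_gap)))
        axis = x[j] - x[i]
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            return y, kind  # degenerate axis: null move
        angle = rng.uniform(-moves.crankshaft_angle, moves.crankshaft_angle)
        rot = Rotation.from_rotvec(axis / nrm * angle)
        y[i + 1:j] = rot.apply(x[i + 1:j] - x[i]) + x[i]
    elif kind == "cartesian":
        i = int(rng.integers(0, n))
        y[i] = x[i] + rng.uniform(-moves.cartesian_step,
                                  moves.cartesian_step, size=3)
    else:  # pivot
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-moves.pivot_angle, moves.pivot_angle)
        rot = Rotation.from_rotvec(axis * angle)
        tail_side = rng.random() < 0.5
        if rng.random() < moves.pivot_end_bias:
            w = min(moves.pivot_end_window, n - 3)
            k = int(rng.integers(n - 1 - w, n - 1)) if tail_side \
                else int(rng.integers(1, 1 + w))
        else:
            k = int(rng.integers(1, n - 1))
        if tail_side:
            y[k + 1:] = rot.apply(x[k + 1:] - x[k]) + x[k]
        else:
            y[:k] = rot.apply(x[:k] - x[k]) + x[k]
    return y, kind


def run_mc(start: Conformation, ff: ForceFieldSpec, moves: MoveSet,
           n_moves: int, temperature: float = 1.0, seed: int = 0,
           bias: Optional[RatchetState] = None,
           native: Optional[NativeStructure] = None,
           n_saved: int = 100, burn_in: int = 2000, tune_every: int = 100,
           tune: bool = True) -> Trajectory:
    """Metropolis Monte Carlo with auto-tuned move boldness.

    During the first ``burn_in`` moves the crankshaft angle and Cartesian
    step are rescaled every ``tune_every`` moves towards
    ``moves.target_acceptance`` and then frozen.  With a ``bias`` (requires
    ``native``) the ratchet potential on z enters the Metropolis criterion
    and ``z_m`` is updated after every accepted move.
    """
    if n_moves < 1:
        raise ValueError("n_moves must be >= 1")
    if bias is not None and native is None:
        raise ValueError("a ratchet bias requires the native structure")
    rng = np.random.default_rng(seed)
    x = start.coords.copy()
    e = energy(x, ff).total
    z = None
    if bias is not None:
        z, _ = cc_and_gradient(x, native)
        update_zm(z, bias, float(rng.random()))

    save_stride = max(1, n_moves // n_saved)
    frames, ccs, epots = [Conformation(x.copy(), frame_index=0)], [
        np.nan if z is None else z], [e]
    acc_window, n_acc, n_try = [], 0, 0
    moves_live = moves

    for m in range(1, n_moves + 1):
        y, kind = _propose(x, moves_live, rng)
        e_new = energy(y, ff).total
        delta = e_new - e
        z_new = None
        if bias is not None:
            z_new, _ = cc_and_gradient(y, native)
            delta += bias_potential(z_new, bias) - bias_potential(z, bias)
        accept = delta <= 0 or rng.random() < np.exp(-delta / temperature)
        n_try += 1
        if accept:
            x, e = y, e_new
            n_acc += 1
            if bias is not None:
                z = z_new
                update_zm(z, bias, float(rng.random()))
        acc_window.append(accept)
        if tune and m <= burn_in and m % tune_every == 0:
            rate = np.mean(acc_window[-tune_every:])
            factor = 1.15 if rate > moves.target_acceptance + 0.05 else \
                0.85 if rate < moves.target_acceptance - 0.05 else 1.0
            moves_live.crankshaft_angle = min(
                np.pi, moves_live.crankshaft_angle * factor)
            moves_live.cartesian_step *= factor
        if m % save_stride == 0:
            frames.append(Conformation(x.copy(), frame_index=m))
            ccs.append(np.nan if z is None else z)
            epots.append(e)

    post = acc_window[burn_in:] if n_moves > burn_in else acc_window
    rate = float(np.mean(post)) if post else 0.0
    if n_moves > burn_in + 1000 and rate == 0.0:
        raise SamplerError("zero acceptance after tuning")
    traj = Trajectory(frames, dt=float(save_stride), seed=seed,
                      cc_value=np.array(ccs),
                      potential_energy=np.array(epots))
    traj.meta["acceptance_rate"] = rate
    traj.meta["moveset"] = moves_live
    return traj


# ---------------------------------------------------------------------------
# denaturation protocol
# ---------------------------------------------------------------------------

def denature(native: NativeStructure, ff: ForceFieldSpec,
             t_high: float = 6.0, t_eq: float = 1.0,
             n_high_steps: int = 20000, n_eq_steps: int = 5000,
             seed: int = 0, max_retries: int = 10,
             overlap_max: float = 0.3, closure=None) -> Conformation:
    """High-temperature unfolding followed by thermalization.

    Returns a conformation verified globally unknotted with native overlap
    below ``overlap_max``; retries with derived seeds up to ``max_retries``.
    """
    from knotfold.knot_topology import ClosureSpec, classify_conformation

    if t_high <= t_eq:
        raise ValueError("t_high must exceed t_eq")
    if n_high_steps < 1:
        raise SamplerError("n_high_steps = 0 cannot denature anything")
    closure = closure or ClosureSpec(n_closures=20)
    for attempt in range(max_retries):
        s = seed + 1000003 * attempt
        hot = MoveSet(pivot_enabled=True, crankshaft_angle=1.2,
                      cartesian_step=1.0)
        t1 = run_mc(native.reference, ff, hot, n_high_steps,
                    temperature=t_high, seed=s, n_saved=2)
        cool = MoveSet(pivot_enabled=False)
        t2 = run_mc(t1.frames[-1], ff, cool, n_eq_steps,
                    temperature=t_eq, seed=s + 1, n_saved=2)
        out = t2.frames[-1]
        if native_overlap(out, native) >= overlap_max:
            continue
        verdict = classify_conformation(out, closure, seed=s, do_scan=False)
        if verdict.global_state == "unknot":
            return Conformation(out.coords, frame_index=None)
    raise SamplerError(f"denaturation failed after {max_retries} attempts")
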