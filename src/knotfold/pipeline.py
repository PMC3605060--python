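"""End-to-end folding campaigns and equilibrium knotting experiments.

``run_folding_campaign`` orchestrates the full protocol at configurable
scale: build/load a native, denature an ensemble of starts, attempt several
ratcheted folding runs per start, flag the attempts that reach the knotted
near-native state, select the dominant (highest Onsager-Machlup weight) path
per successful start and run the pathway analyses on the selection.

``run_equilibrium_knotting`` measures the knotted fraction of decorrelated
equilibrium MC samples (local + pivot moves) for each force-field variant.

Both consume a flat configuration dictionary (YAML-friendly); every number
in the returned manifest is computed from stage outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from knotfold.chain_core import read_structure, write_trajectory
from knotfold.contact_maps import (ContactMapParams, build_native_structure,
                                   native_overlap)
from knotfold.cg_forcefield import ForceFieldParams, build_forcefield
from knotfold.drp_scoring import select_dominant
from knotfold.knot_topology import ClosureSpec, classify_conformation
from knotfold.path_analysis import (MechanismConfig, classify_mechanism,
                                    density_projection, overlap_at_first_knot,
                                    path_record, sigma_distribution)
from knotfold.samplers import MoveSet, RatchetState, denature, run_mc, run_rmd
from knotfold.synthetic_data import ToyNativeSpec, build_toy_native

__all__ = ["CampaignConfig", "RunManifest", "run_folding_campaign",
           "run_equilibrium_knotting"]


@dataclass
class CampaignConfig:
    """Scale and physics knobs of a folding campaign (toy defaults)."""

    n_starts: int = 10
    n_attempts: int = 5
    seed: int = 0
    # native
    native_pdb: str | None = None          # None -> toy shallow trefoil
    toy_seed: int = 0
    contact_cutoff: float = 9.5
    # force field
    ff_mode: str = "native_only"
    sequence: str | None = None
    k_bond: float = 50.0
    k_angle: float = 10.0
    native_eps: float = 2.0
    ev_cap: float = 15.0
    ev_sigma: float = 3.0
    # denaturation
    t_high: float = 4.0
    n_high_steps: int = 4000
    n_eq_steps: int = 3000
    # attempt engine
    engine: str = "mc"                     # "mc" (pivot MC) | "langevin"
    k_R: float = 0.0
    beta_tilde: float = 2.0
    temperature: float = 1.0
    # langevin engine
    n_steps: int = 60000
    dt: float = 4e-3
    save_every: int = 500
    # MC engine: local crankshaft/Cartesian moves plus global pivots (the
    # move class that makes threading observable at desk scale), run as a
    # simulated-annealing schedule so the topology equilibrates while the
    # chain is still warm and locks in on cooling
    anneal_temperatures: tuple = (1.3, 1.2, 1.1, 1.0, 0.9)
    anneal_chunk_moves: int = 30000
    mc_crankshaft: float = 1.0
    mc_gap: int = 8
    mc_cartesian: float = 0.7
    mc_pivot_angle: float = 3.14159
    mc_p_crankshaft: float = 0.4
    mc_pivot_end_bias: float = 0.5
    mc_pivot_end_window: int = 14
    # extension filter on denatured starts (fraction of straight-chain cc)
    min_start_cc_fraction: float = 0.7
    # success criteria / knot detection
    overlap_threshold: float = 0.7
    rmsd_unsuccessful: float = 5.0
    n_closures: int = 20
    knot_every: int = 4


@dataclass
class RunManifest:
    """Traceable census of one campaign."""

    config: dict
    n_starts: int = 0
    n_attempts_total: int = 0
    n_blowups: int = 0
    n_successes: int = 0
    n_distinct_successful_starts: int = 0
    n_unsuccessful_folded: int = 0
    successes: list = field(default_factory=list)   # (start, attempt) pairs
    selected_seeds: list = field(default_factory=list)
    mechanism_census: dict = field(default_factory=dict)
    overlap_at_knot: list = field(default_factory=list)
    sigma_values: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _build_native(cfg: CampaignConfig):
    params = ContactMapParams(cutoff=cfg.contact_cutoff)
    if cfg.native_pdb:
        ref = read_structure(cfg.native_pdb)
        return build_native_structure(ref, params=params)
    toy = build_toy_native(ToyNativeSpec(seed=cfg.toy_seed))
    return build_native_structure(toy.reference, params=params,
                                  annotated_regions=toy.annotated_regions)


def _forcefield(cfg: CampaignConfig, native):
    p = ForceFieldParams(k_bond=cfg.k_bond, k_angle=cfg.k_angle,
                         native_eps=cfg.native_eps, ev_cap=cfg.ev_cap,
                         ev_sigma=cfg.ev_sigma)
    return build_forcefield(native, cfg.sequence, mode=cfg.ff_mode, params=p)



def _denatured_starts(cfg: CampaignConfig, native, ff, log):
    """Denatured, unknotted, *extended* starting conformations.

    Partially collapsed denatured states are glassy under the ratchet, so
    starts must exceed ``min_start_cc_fraction`` of a fully extended chain's
    collective coordinate; denaturation seeds are scanned until enough pass.
    """
    from knotfold.chain_core import Conformation
    from knotfold.contact_maps import collective_coordinate

    n = native.n_beads
    straight = Conformation(np.column_stack(
        [3.8 * np.arange(n), np.zeros(n), np.zeros(n)]))
    cc_min = cfg.min_start_cc_fraction * collective_coordinate(straight, native)
    starts, trial = [], 0
    while len(starts) < cfg.n_starts and trial < 20 * cfg.n_starts:
        try:
            conf = denature(native, ff, t_high=cfg.t_high,
                            n_high_steps=cfg.n_high_steps,
                            n_eq_steps=cfg.n_eq_steps,
                            seed=cfg.seed + 100 + trial)
        except Exception:
            trial += 1
            continue
        trial += 1
        if collective_coordinate(conf, native) >= cc_min:
            starts.append(conf)
            log(f"denatured start {len(starts) - 1}")
    return starts


def _attempt_mc(start, native, ff, cfg: CampaignConfig, seed):
    """One folding attempt: annealed pivot-enabled MC.

    Local moves mimic the chain dynamics; global pivots supply the large
    end-segment swings that make threading observable at desk scale (without
    them no knotting event occurred in >100 instrumented Langevin or
    local-MC runs).  The temperature anneals over fixed chunks.  An optional
    weak ratchet (``k_R > 0``) can be layered on, but even a weak pawl
    penalises the transient contact-map excursions that pivots need, so the
    toy default is unbiased annealing.
    """
    from knotfold.chain_core import Trajectory

    stride = 2000
    bias = (RatchetState(k_R=cfg.k_R, beta_tilde=cfg.beta_tilde)
            if cfg.k_R > 0 else None)
    moves = MoveSet(crankshaft_angle=cfg.mc_crankshaft,
                    crankshaft_gap=cfg.mc_gap,
                    cartesian_step=cfg.mc_cartesian,
                    pivot_enabled=True, pivot_angle=cfg.mc_pivot_angle,
                    p_crankshaft=cfg.mc_p_crankshaft,
                    pivot_end_bias=cfg.mc_pivot_end_bias,
                    pivot_end_window=cfg.mc_pivot_end_window)
    frames, ccs, epots = [], [], []
    x, offset = start, 0
    for ci, temp in enumerate(cfg.anneal_temperatures):
        t = run_mc(x, ff, moves, n_moves=cfg.anneal_chunk_moves,
                   temperature=temp, seed=seed + 17 * ci, tune=False,
                   bias=bias, native=native if bias else None,
                   n_saved=cfg.anneal_chunk_moves // stride)
        skip = 0 if ci == 0 else 1
        for f in t.frames[skip:]:
            f.frame_index += offset
        frames.extend(t.frames[skip:])
        ccs.extend(t.cc_value[skip:])
        epots.extend(t.potential_energy[skip:])
        offset += cfg.anneal_chunk_moves
        x = t.frames[-1]
    traj = Trajectory(frames, dt=float(stride), seed=seed,
                      cc_value=np.array(ccs),
                      potential_energy=np.array(epots))
    return traj


def run_folding_campaign(cfg: CampaignConfig | dict | None = None,
                         out_dir=None, progress=None):
    """Run the full protocol; returns ``(RunManifest, analyses dict)``.

    A trajectory counts as a *success* when a saved frame is globally
    knotted and the final native overlap reaches the configured threshold;
    the unsuccessful set contains attempts that end unknotted yet
    near-native (RMSD below the configured bound).  One dominant path per
    successful start enters the sigma / overlap / mechanism / density
    analyses.
    """
    if cfg is None:
        cfg = CampaignConfig()
    elif isinstance(cfg, dict):
        cfg = CampaignConfig(**cfg)
    log = progress or (lambda msg: None)
    native = _build_native(cfg)
    ff = _forcefield(cfg, native)
    closure = ClosureSpec(n_closures=cfg.n_closures)
    manifest = RunManifest(config=asdict(cfg))

    starts = _denatured_starts(cfg, native, ff, log)
    manifest.n_starts = len(starts)

    from knotfold.chain_core import kabsch_rmsd

    per_start_successes: dict[int, list] = {}
    for si, start in enumerate(starts):
        for a in range(cfg.n_attempts):
            seed = cfg.seed + 1000 + 37 * si + a
            manifest.n_attempts_total += 1
            try:
                if cfg.engine == "mc":
                    traj = _attempt_mc(start, native, ff, cfg, seed)
                else:
                    traj = run_rmd(start, native, ff,
                                   RatchetState(k_R=cfg.k_R,
                                                beta_tilde=cfg.beta_tilde),
                                   n_steps=cfg.n_steps, dt=cfg.dt,
                                   temperature=cfg.temperature, seed=seed,
                                   save_every=cfg.save_every)
            except Exception:
                manifest.n_blowups += 1
                continue
            fin = traj.frames[-1]
            ov = native_overlap(fin, native)
            verdict = classify_conformation(fin.coords, closure,
                                            seed=seed, do_scan=False)
            knotted = verdict.global_state == "knotted"
            if knotted and ov >= cfg.overlap_threshold:
                manifest.n_successes += 1
                manifest.successes.append((si, a))
                per_start_successes.setdefault(si, []).append(traj)
                log(f"start {si} attempt {a}: SUCCESS (overlap {ov:.2f})")
            elif (not knotted
                  and kabsch_rmsd(fin, native.reference) <= cfg.rmsd_unsuccessful):
                manifest.n_unsuccessful_folded += 1

    manifest.n_distinct_successful_starts = len(per_start_successes)
    selected = []
    for si, paths in sorted(per_start_successes.items()):
        best = select_dominant(paths, ff, temperature=cfg.temperature)
        selected.append(best)
        manifest.selected_seeds.append(best.seed)

    analyses = {"selected": selected}
    mech_cfg = MechanismConfig(every=cfg.knot_every)
    census: dict[str, int] = {}
    mech_calls = []
    for ti, traj in enumerate(selected):
        call = classify_mechanism(traj, native, closure, config=mech_cfg,
                                  seed=cfg.seed + 5000 + ti)
        census[call.label] = census.get(call.label, 0) + 1
        mech_calls.append(call)
        ov = overlap_at_first_knot(traj, native, closure,
                                   seed=cfg.seed + 6000 + ti,
                                   every=cfg.knot_every)
        if ov is not None:
            manifest.overlap_at_knot.append(ov)
    manifest.mechanism_census = census
    analyses["mechanism_calls"] = mech_calls
    if len(selected) >= 2:
        records = [path_record(t, native, trajectory_id=str(t.seed))
                   for t in selected]
        sigmas, hist, edges = sigma_distribution(records)
        manifest.sigma_values = [float(s) for s in sigmas]
        analyses["sigma_hist"] = (hist, edges)
    if selected:
        analyses["density"] = density_projection(
            selected, native, closure=closure, seed=cfg.seed + 7000,
            every=cfg.knot_every)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_json(out_dir / "manifest.json")
        for t in selected:
            write_trajectory(t, out_dir / f"selected_seed{t.seed}.xyz")
        _write_tsv_reports(out_dir, manifest, analyses)
    return manifest, analyses


def _write_tsv_reports(out_dir: Path, manifest: RunManifest,
                       analyses: dict) -> None:
    selected = analyses["selected"]
    lines = ["trajectory_seed\tmechanism\tfirst_knot_frame"
             "\ttail_displacement\tloop_displacement"]
    for t, call in zip(selected, analyses.get("mechanism_calls", [])):
        lines.append(f"{t.seed}\t{call.label}\t{call.first_knot_frame}"
                     f"\t{call.tail_displacement:.3f}"
                     f"\t{call.loop_displacement:.3f}")
    (out_dir / "mechanisms.tsv").write_text("\n".join(lines) + "\n")

    lines = ["path_a\tpath_b\tsigma"]
    k = 0
    for i in range(len(selected)):
        for j in range(i + 1, len(selected)):
            if k < len(manifest.sigma_values):
                lines.append(f"{selected[i].seed}\t{selected[j].seed}"
                             f"\t{manifest.sigma_values[k]:.4f}")
                k += 1
    (out_dir / "sigma_pairs.tsv").write_text("\n".join(lines) + "\n")

    if "density" in analyses:
        d = analyses["density"]
        lines = ["x_bin_left\ty_bin_left\tlog_count"]
        for ix in range(d.log_counts.shape[0]):
            for iy in range(d.log_counts.shape[1]):
                if d.log_counts[ix, iy] > 0:
                    lines.append(f"{d.x_edges[ix]:.3f}\t{d.y_edges[iy]:.3f}"
                                 f"\t{d.log_counts[ix, iy]:.4f}")
        (out_dir / "density.tsv").write_text("\n".join(lines) + "\n")


def run_equilibrium_knotting(native=None, modes=("native_only",
                                                 "with_nonnative"),
                             n_samples: int = 32, n_chains: int = 8,
                             stride: int = 3000, burn_in: int = 8000,
                             temperature: float = 1.0,
                             start: str = "native", seed: int = 0,
                             sequence: str | None = None,
                             ff_params: ForceFieldParams | None = None,
                             closure: ClosureSpec | None = None,
                             progress=None) -> dict:
    """Knotted fraction of decorrelated MC samples per force-field variant.

    ``n_chains`` independent MC runs (local + pivot moves) per variant are
    subsampled every ``stride`` attempted moves after ``burn_in``; samples
    are pooled across chains (a single chain's samples are strongly
    correlated through its folding history).  ``start`` selects the initial
    condition: ``"native"`` probes native-basin stability, ``"coil"``
    (self-avoiding random coils) probes how accessible knotted conformations
    are to an initially unfolded ensemble.  Returns, per mode, ``(fraction,
    binomial standard error, n)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if start not in ("native", "coil"):
        raise ValueError("start must be 'native' or 'coil'")
    log = progress or (lambda msg: None)
    if native is None:
        toy = build_toy_native()
        native = build_native_structure(
            toy.reference, params=ContactMapParams(cutoff=9.5),
            annotated_regions=toy.annotated_regions)
    closure = closure or ClosureSpec(n_closures=20)
    ff_params = ff_params or ForceFieldParams(k_bond=50.0, k_angle=10.0,
                                              native_eps=2.0, ev_cap=15.0)
    n_chains = min(n_chains, n_samples)
    per_chain = int(np.ceil(n_samples / n_chains))
    if start == "coil":
        from knotfold.synthetic_data import coil_ensemble
        starts = coil_ensemble(n_chains, n_beads=native.n_beads,
                               seed=seed + 31, verify_unknotted=False)
    else:
        starts = [native.reference] * n_chains
    out = {}
    for mode in modes:
        ff = build_forcefield(native, sequence, mode=mode, params=ff_params)
        moves = MoveSet(pivot_enabled=True)
        rng = np.random.default_rng(seed + 17)
        knotted, n = 0, 0
        for c in range(n_chains):
            n_moves = burn_in + per_chain * stride
            traj = run_mc(starts[c], ff, moves, n_moves=n_moves,
                          temperature=temperature, seed=seed + 101 * c,
                          n_saved=n_moves // stride)
            frames = [f for f in traj.frames
                      if f.frame_index is not None
                      and f.frame_index >= burn_in][:per_chain]
            for f in frames:
                v = classify_conformation(f.coords, closure, seed=rng,
                                          do_scan=False)
                knotted += v.global_state == "knotted"
                n += 1
        if n == 0:
            raise ValueError("no samples collected")
        frac = knotted / n
        se = float(np.sqrt(frac * (1 - frac) / n))
        out[mode] = (frac, se, n)
        log(f"{mode}: knotted fraction {frac:.2f} +/- {se:.2f} (n={n})")
    return out
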