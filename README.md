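# knotfold

Simulation and analysis toolkit for studying how a protein chain folds into
a natively-knotted state, exercised end-to-end on synthetic knotted toy
chains (no downloads required).

It provides, as importable modules and a CLI:

- **Topology** (`knotfold.knot_topology`): exact Alexander-determinant
  evaluation (`|Δ(-1)|`, integer arithmetic) of closed polygonal curves;
  stochastic chain closure (termini prolonged along random outward
  directions, closed by an arc far outside the chain) with majority voting;
  subchain scanning for slipknots and the minimal knotted portion;
  first-knotting-event detection on trajectories.
- **Contact maps** (`knotfold.contact_maps`): smooth rational switching
  contact function, native contact sets, the contact-map collective
  coordinate z(X) and its analytic gradient, native overlap, per-contact
  formation times.
- **Coarse-grained force fields** (`knotfold.cg_forcefield`): Cα-bead
  native-centric model (harmonic bonds/angles, cosine dihedrals, 12-10
  native wells, capped excluded volume) with optional non-native terms
  (quasi-chemical propensity well from an editable 20×20 TSV, Debye-screened
  electrostatics). Forces are exact analytic gradients; hot loops are
  numba-compiled with a vectorised numpy reference implementation kept for
  cross-validation.
- **Samplers** (`knotfold.samplers`): overdamped Langevin dynamics with the
  ratchet-and-pawl bias on z (zero force while z decreases past its running
  minimum, harmonic penalty above it, Metropolis backtracking of the
  reference); Metropolis MC with crankshaft, Cartesian, pivot and
  end-regrowth moves and acceptance auto-tuning; a high-temperature
  denaturation protocol that returns verified-unknotted expanded states.
- **Path scoring** (`knotfold.drp_scoring`): a-posteriori Onsager-Machlup
  log-weights of trajectories under the unbiased overdamped dynamics and
  dominant-path selection among trials sharing an initial condition.
- **Pathway analysis** (`knotfold.path_analysis`): contact-formation order
  matrices and the σ pathway-similarity statistic, overlap at the first
  knotting event, RMSD-plane log-density projections with knot markers, and
  threading / slipknot / mousetrap mechanism classification.
- **Synthetic data** (`knotfold.synthetic_data`): parametric
  unknot/trefoil/figure-eight curves, a 48-bead open-chain "shallow
  trefoil" toy native with annotated sheet/loop/tail motifs, self-avoiding
  coil ensembles, and scripted kinematic fixtures realising the three
  knotting mechanisms (all re-verified topologically at generation time).
- **Pipeline** (`knotfold.pipeline`): the full campaign — denature an
  ensemble of starts, run many folding attempts per start, flag attempts
  that reach the knotted near-native state, select the dominant path per
  start and run all analyses — plus the equilibrium knotted-fraction
  comparison between the native-only and with-non-native models.

## CLI

```sh
knotfold make-fixtures --out fixtures/ --seed 0   # toy native, knots, fixtures
knotfold mc --moves 100000 --pivot --seed 1 --out run.xyz
knotfold rmd --steps 60000 --seed 1 --out rmd.xyz # ratcheted Langevin
knotfold denature --seed 2 --out start.pdb
knotfold knotscan --traj run.xyz --closures 100 --seed 3
knotfold run-campaign --seed 0 --out campaign/    # full protocol + TSV reports
knotfold run-equilibrium --samples 24 --temperature 3.5
```

All commands accept `--config config.yaml` with flat keys mirroring the
library dataclasses (`CampaignConfig`, `ForceFieldParams`, ...), and every
stochastic stage takes `--seed`.

## Units and conventions

Coordinates in Å; energies and temperatures in reduced units (kT at T = 1);
time in integrator steps / attempted MC moves. Residue indices are 0-based
in the API and 1-based in CLI tables. Default contact function:
`C(r) = [1-(r/7.5 Å)^6]/[1-(r/7.5 Å)^10]`.
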