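"""Core geometric types and structure/trajectory I/O.

Coordinates are in Angstrom throughout.  Residue indices are 0-based in all
public APIs; user-facing reports (CLI tables) convert to 1-based labels.
Energies and temperatures are in reduced units (kT at the reference
temperature T = 1).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Conformation",
    "NativeStructure",
    "Trajectory",
    "read_structure",
    "write_structure",
    "kabsch_rmsd",
    "superpose",
    "read_trajectory",
    "write_trajectory",
]


class StructureError(ValueError):
    """Raised on malformed structural input (missing atoms, bad frames...)."""


@dataclass
class Conformation:
    """One chain snapshot: ordered bead coordinates.

    Parameters
    ----------
    coords
        ``(N, 3)`` float array of bead positions in Angstrom, ordered by
        residue index.
    chain_id
        Chain label (single character for PDB output).
    frame_index
        Optional non-negative frame index when the conformation belongs to a
        trajectory.
    """

    coords: np.ndarray
    chain_id: str = "A"
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise StructureError("a chain needs at least 3 beads")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        bond = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any(bond <= 0.0):
            raise StructureError("coincident consecutive beads")
        if self.frame_index is not None and self.frame_index < 0:
            raise StructureError("frame_index must be >= 0")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def translated(self, shift: Sequence[float]) -> "Conformation":
        return Conformation(self.coords + np.asarray(shift, dtype=float),
                            chain_id=self.chain_id, frame_index=self.frame_index)

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), chain_id=self.chain_id,
                            frame_index=self.frame_index)


@dataclass
class NativeStructure:
    """Reference conformation plus its derived native-contact data.

    ``native_contacts`` holds ``(i, j)`` with ``i < j``; ``native_map`` is the
    symmetric matrix of smooth contact-function values with the near-diagonal
    band (``|i - j| < min_seq_sep``) zeroed.  ``annotated_regions`` maps names
    such as ``"beta_sheet"`` or ``"threading_loop"`` to inclusive 0-based
    ``(start, stop)`` index ranges; they are user/builder supplied, never
    inferred from residue numbering.
    """

    reference: Conformation
    native_contacts: frozenset
    native_map: np.ndarray
    annotated_regions: dict = field(default_factory=dict)
    params: object | None = None  # ContactMapParams; kept loose to avoid cycle

    def __post_init__(self) -> None:
        n = self.reference.n_beads
        self.native_map = np.asarray(self.native_map, dtype=float)
        if self.native_map.shape != (n, n):
            raise StructureError("native_map shape mismatch")
        if self.native_map.min() < 0.0 or self.native_map.max() > 1.0 + 1e-12:
            raise StructureError("native_map values must lie in [0, 1]")
        for i, j in self.native_contacts:
            if not (0 <= i < j < n):
                raise StructureError(f"bad native contact ({i}, {j})")
        for name, (a, b) in self.annotated_regions.items():
            if not (0 <= a <= b < n):
                raise StructureError(f"region {name!r} out of range")

    @property
    def n_beads(self) -> int:
        return self.reference.n_beads

    def contact_pairs(self) -> np.ndarray:
        """Native contacts as a sorted ``(Nc, 2)`` integer array."""
        if not self.native_contacts:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.native_contacts), dtype=int)

    def contact_distances(self) -> np.ndarray:
        """Reference-structure distances of the native contacts (sorted order)."""
        pairs = self.contact_pairs()
        x = self.reference.coords
        return np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)

    @classmethod
    def from_reference(cls, reference: Conformation, params=None,
                       annotated_regions: dict | None = None) -> "NativeStructure":
        """Build the native contact set and map from a reference conformation.

        Delegates to :func:`knotfold.contact_maps.build_native_structure`.
        """
        from knotfold import contact_maps

        return contact_maps.build_native_structure(
            reference, params=params, annotated_regions=annotated_regions)


@dataclass
class Trajectory:
    """Time-ordered conformations with optional per-frame scalars."""

    frames: list
    dt: float = 1.0
    seed: int | None = None
    cc_value: np.ndarray | None = None
    bias_energy: np.ndarray | None = None
    potential_energy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise StructureError("empty trajectory")
        n = self.frames[0].n_beads
        if any(f.n_beads != n for f in self.frames):
            raise StructureError("inconsistent bead count across frames")
        idx = [f.frame_index for f in self.frames]
        if all(i is not None for i in idx):
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise StructureError("frame_index must be strictly increasing")
        else:
            for k, f in enumerate(self.frames):
                f.frame_index = k
        for name in ("cc_value", "bias_energy", "potential_energy"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.frames),):
                    raise StructureError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames[0].n_beads

    def coords_array(self) -> np.ndarray:
        """All frame coordinates stacked as ``(n_frames, N, 3)``."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def read_structure(path, bead_rule: str = "CA", chain_id: str | None = None,
                   model: int = 0) -> Conformation:
    """Read a PDB or XYZ file into a one-bead-per-residue :class:`Conformation`.

    ``bead_rule`` names the atom selected per residue (default ``"CA"``).
    Only ATOM records of the first model are used; the chain defaults to the
    first one encountered unless ``chain_id`` is given.  XYZ files (suffix
    ``.xyz``) are read verbatim, first frame only.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        traj = read_trajectory(path)
        return traj.frames[0]

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"no models in {path}")
    mdl = models[model]
    chains = [c for c in mdl if any(True for _ in c)]
    if chain_id is None:
        if len(chains) > 1:
            raise StructureError(
                f"{path} has {len(chains)} chains; pass chain_id explicitly")
        chain = chains[0]
    else:
        match = [c for c in chains if c.id == chain_id]
        if not match:
            raise StructureError(f"chain {chain_id!r} not found in {path}")
        chain = match[0]

    coords = []
    for residue in chain:
        if residue.id[0].strip():  # skip HETATM / waters
            continue
        if bead_rule not in residue:
            raise StructureError(
                f"residue {residue.id[1]} lacks atom {bead_rule!r}")
        coords.append(residue[bead_rule].coord)
    if len(coords) < 3:
        raise StructureError("bead rule selected fewer than 3 atoms")
    return Conformation(np.asarray(coords, dtype=float), chain_id=str(chain.id))


def write_structure(conf: Conformation, path, bead_name: str = "CA",
                    res_name: str = "GLY") -> None:
    """Write a Cα-bead conformation as a minimal single-chain PDB file."""
    path = Path(path)
    lines = []
    cid = (conf.chain_id or "A")[0]
    for i, (x, y, z) in enumerate(conf.coords):
        lines.append(
            f"ATOM  {i + 1:5d}  {bead_name:<3s}{res_name:>4s} {cid}{i + 1:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: Conformation | np.ndarray, b: Conformation | np.ndarray,
                subset: Iterable[int] | None = None) -> float:
    """Minimum RMSD (Angstrom) between two equal-length bead sets over rigid
    rotations and translations (Kabsch superposition).
    """
    xa = a.coords if isinstance(a, Conformation) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, Conformation) else np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise StructureError("conformations differ in size")
    if subset is not None:
        idx = np.asarray(sorted(subset), dtype=int)
        if idx.size < 3:
            raise StructureError("subset must contain at least 3 beads")
        xa, xb = xa[idx], xb[idx]
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    # align_vectors minimises sqrt(sum |Ra - b|^2) and reports it as rssd
    _, rssd = Rotation.align_vectors(xb, xa)
    return float(rssd / np.sqrt(xa.shape[0]))


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` optimally superposed onto ``target`` (same shape)."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    return rot.apply(mobile - cm) + ct


# ---------------------------------------------------------------------------
# trajectory I/O (extended XYZ, plain text)
# ---------------------------------------------------------------------------

_SCALARS = ("cc_value", "bias_energy", "potential_energy")
_SCALAR_KEYS = {"cc_value": "cc", "bias_energy": "ebias",
                "potential_energy": "epot"}


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame extended XYZ (lossless to 1e-6 A).

    The comment line of each frame carries ``key=value`` metadata: frame
    index, dt, seed and any of the per-frame scalars that are present.
    """
    path = Path(path)
    buf = io.StringIO()
    n = traj.n_beads
    for k, frame in enumerate(traj.frames):
        fields = [f"frame={frame.frame_index}", f"dt={traj.dt:.9g}"]
        if traj.seed is not None:
            fields.append(f"seed={traj.seed}")
        for name in _SCALARS:
            v = getattr(traj, name)
            if v is not None:
                fields.append(f"{_SCALAR_KEYS[name]}={v[k]:.9g}")
        buf.write(f"{n}\n{' '.join(fields)}\n")
        for x, y, z in frame.coords:
            buf.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")
    path.write_text(buf.getvalue())


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Conformation] = []
    scalars: dict[str, list] = {k: [] for k in _SCALAR_KEYS.values()}
    seen: set[str] = set()
    dt, seed = 1.0, None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise StructureError(f"malformed frame header at line {pos + 1}") from exc
        meta = dict(tok.split("=", 1) for tok in lines[pos + 1].split()
                    if "=" in tok)
        coords = np.array(
            [list(map(float, lines[pos + 2 + i].split()[1:4])) for i in range(n)])
        frame_index = int(meta.get("frame", len(frames)))
        frames.append(Conformation(coords, frame_index=frame_index))
        dt = float(meta.get("dt", dt))
        if "seed" in meta:
            seed = int(meta["seed"])
        for key in _SCALAR_KEYS.values():
            if key in meta:
                scalars[key].append(float(meta[key]))
                seen.add(key)
        pos += 2 + n
    if not frames:
        raise StructureError(f"no frames in {path}")
    if any(f.n_beads != frames[0].n_beads for f in frames):
        raise StructureError("inconsistent bead count across frames")
    kwargs = {}
    for name, key in _SCALAR_KEYS.items():
        if key in seen:
            if len(scalars[key]) != len(frames):
                raise StructureError(f"scalar {key} missing on some frames")
            kwargs[name] = np.array(scalars[key])
    return Trajectory(frames, dt=dt, seed=seed, **kwargs)
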