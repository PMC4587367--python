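"""Trajectory container, structure I/O, and artificial-trajectory construction.

The central protocol here is chunk-random sub-sampling: a trajectory is divided
into equal time chunks of one stride each, one frame is drawn at random per
chunk, and frames falling within a boundary-exclusion zone (10% of the stride
on either side of each chunk edge) are ineligible.  Sub-sampled frames from
several systems are then concatenated — in a fixed canonical system order, the
long run of each system first, its restart runs after — into an "artificial
trajectory" whose per-frame provenance (system, source, original time) is kept
throughout the downstream analysis.

Units: coordinates in Å, times in ps, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem
from .errors import FormatError, ProtocolError, ShapeError, UsageError
from .selection import select_atoms  # noqa: F401  (public re-export)
from .topology import Atom, ToyTopology

__all__ = [
    "Trajectory",
    "SystemTrajectories",
    "SamplingProtocol",
    "ArtificialTrajectory",
    "select_atoms",
    "read_trajectory",
    "write_trajectory",
    "sample_frames",
    "build_artificial_trajectory",
]


@dataclass(eq=False)
class Trajectory:
    """Ordered frames of coordinates with times and a topology.

    ``source`` tags where the frames came from: ``"long"`` for the main run or
    ``"restart<k>"`` for short re-seeded runs.  ``basin_ids`` carries the
    generator's ground-truth basin label per frame when available.
    """

    topology: ToyTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray  # (n_frames,) ps, strictly increasing
    label: str = ""
    source: str = "long"
    basin_ids: np.ndarray | None = None
    box: np.ndarray | None = None  # (3,) orthorhombic box lengths Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"coords have {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise ShapeError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ShapeError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def interval_ps(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration_ps(self) -> float:
        """Sampled duration under the half-open convention: the last frame
        represents one full interval."""
        return float(self.times[-1] - self.times[0] + self.interval_ps)

    def slice_frames(self, indices) -> "Trajectory":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            coords=self.coords[indices],
            times=self.times[indices],
            basin_ids=None if self.basin_ids is None else self.basin_ids[indices],
        )


@dataclass(eq=False)
class SystemTrajectories:
    """One simulated system: a long run plus its restart runs."""

    label: str
    long: Trajectory
    restarts: tuple[Trajectory, ...] = ()

    def all_sources(self) -> list[Trajectory]:
        return [self.long, *self.restarts]


@dataclass(frozen=True)
class SamplingProtocol:
    """Chunk-random sampling parameters.

    stride_ps: chunk length; one frame is drawn per chunk.
    exclusion: fraction of the stride excluded at each chunk boundary (0.10
        means frames within 4 ps of a boundary are ineligible at 40 ps stride).
    discard_ns: initial prefix removed from *long* trajectories only, to drop
        the relaxation transient.
    """

    stride_ps: float
    exclusion: float = 0.10
    discard_ns: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.stride_ps <= 0:
            raise UsageError("stride must be positive")
        if not 0 <= self.exclusion < 0.5:
            raise UsageError("exclusion fraction must be in [0, 0.5)")


@dataclass(eq=False)
class ArtificialTrajectory:
    """Concatenated sampled frames with complete per-frame provenance."""

    topology: ToyTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    provenance: pd.DataFrame  # columns: system, source, time_ps[, basin]
    protocol: SamplingProtocol
    system_order: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.provenance) != self.coords.shape[0]:
            raise ShapeError("provenance length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def write_provenance(self, path) -> None:
        df = self.provenance.copy()
        df.insert(0, "frame_index", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chunk-random sampling
# ---------------------------------------------------------------------------


def sample_frames(
    trajectory: Trajectory,
    protocol: SamplingProtocol,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one random frame per stride-length chunk.

    Long trajectories first have their initial ``discard_ns`` removed.  Chunk
    boundaries are measured in time from the start of the retained window; a
    frame is eligible if its timestamp lies strictly inside the chunk with a
    margin of ``exclusion × stride`` from either boundary.  The number of
    chunks is ``floor(retained duration / stride)`` — a partial trailing chunk
    is dropped.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    discard_ps = protocol.discard_ns * 1000.0 if trajectory.source == "long" else 0.0
    t0 = trajectory.times[0] + discard_ps
    retained = trajectory.times[-1] - t0 + trajectory.interval_ps
    if retained < protocol.stride_ps:
        raise ProtocolError(
            f"retained duration {retained} ps shorter than one stride"
        )
    n_chunks = int(np.floor(retained / protocol.stride_ps + 1e-9))
    margin = protocol.exclusion * protocol.stride_ps
    chosen = np.empty(n_chunks, dtype=int)
    times = trajectory.times
    for j in range(n_chunks):
        lo = t0 + j * protocol.stride_ps
        hi = lo + protocol.stride_ps
        eligible = np.flatnonzero((times > lo + margin) & (times < hi - margin))
        if eligible.size == 0:
            raise ProtocolError(
                f"chunk {j} ({lo:.1f}-{hi:.1f} ps) has no eligible frame after "
                f"boundary exclusion"
            )
        chosen[j] = eligible[rng.integers(eligible.size)]
    return chosen


def build_artificial_trajectory(
    systems: list[SystemTrajectories],
    protocol: SamplingProtocol,
) -> ArtificialTrajectory:
    """Sample every source of every system and concatenate in the given order.

    Per system the long-run frames (post-discard) come first, then each restart
    in order; systems follow the declared canonical order of the input list.
    """
    if not systems:
        raise UsageError("need at least one system")
    labels = [s.label for s in systems]
    if len(set(labels)) != len(labels):
        raise UsageError(f"duplicate system labels in {labels}")
    rng = np.random.default_rng(protocol.seed)
    topology = systems[0].long.topology
    parts, records = [], []
    for system in systems:
        for traj in system.all_sources():
            if traj.n_atoms != topology.n_atoms:
                raise ShapeError("atom count differs between systems")
            idx = sample_frames(traj, protocol, rng=rng)
            parts.append(traj.coords[idx])
            rec = pd.DataFrame(
                {
                    "system": system.label,
                    "source": traj.source,
                    "time_ps": traj.times[idx],
                }
            )
            if traj.basin_ids is not None:
                rec["basin"] = traj.basin_ids[idx]
            records.append(rec)
    provenance = pd.concat(records, ignore_index=True)
    return ArtificialTrajectory(
        topology=topology,
        coords=np.concatenate(parts, axis=0),
        provenance=provenance,
        protocol=protocol,
        system_order=tuple(labels),
    )


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------


def _topology_from_annotations(names, res_names, res_ids, elements, first_frame):
    """Rebuild a ToyTopology from file annotations.

    Roles that PDB/XYZ cannot carry are re-inferred: each hydrogen within
    1.2 Å of a nitrogen or oxygen in the first frame becomes a donor triplet,
    oxygens become acceptors, the first sulfur becomes the start atom.
    """
    atoms = tuple(
        Atom(str(n), str(rn), int(ri), str(el), chem.vdw_radius(str(el)))
        for n, rn, ri, el in zip(names, res_names, res_ids, elements)
    )
    elements = np.asarray(elements)
    donors = []
    h_idx = np.flatnonzero(np.char.upper(elements.astype(str)) == "H")
    da_idx = np.flatnonzero(np.isin(np.char.upper(elements.astype(str)), ["N", "O"]))
    for h in h_idx:
        if da_idx.size == 0:
            break
        d = np.linalg.norm(first_frame[da_idx] - first_frame[h], axis=1)
        j = int(np.argmin(d))
        if d[j] < 1.2:
            donors.append((int(da_idx[j]), int(h)))
    acceptors = tuple(
        int(i) for i in np.flatnonzero(np.char.upper(elements.astype(str)) == "O")
    )
    s_idx = np.flatnonzero(np.char.upper(elements.astype(str)) == "S")
    return ToyTopology(
        atoms=atoms,
        donor_triplets=tuple(donors),
        acceptors=acceptors,
        start_atom=int(s_idx[0]) if s_idx.size else None,
        reference_coords=np.array(first_frame, dtype=float),
    )


def write_trajectory(trajectory: Trajectory, path, fmt: str | None = None) -> None:
    """Write a multi-model PDB or extended XYZ file."""
    path = str(path)
    if fmt is None:
        fmt = "pdb" if path.lower().endswith(".pdb") else "xyz"
    if fmt == "pdb":
        _write_pdb(trajectory, path)
    elif fmt == "xyz":
        _write_xyz(trajectory, path)
    else:
        raise UsageError(f"unknown trajectory format {fmt!r}")


def read_trajectory(
    path, fmt: str | None = None, interval_ps: float = 1.0
) -> Trajectory:
    """Read a multi-model PDB or extended XYZ file.

    Missing times default to ``frame_index × interval_ps``.
    """
    path = str(path)
    if fmt is None:
        fmt = "pdb" if path.lower().endswith(".pdb") else "xyz"
    if fmt == "pdb":
        return _read_pdb(path, interval_ps)
    if fmt == "xyz":
        return _read_xyz(path, interval_ps)
    raise UsageError(f"unknown trajectory format {fmt!r}")


def _write_pdb(trajectory: Trajectory, path: str) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = trajectory.topology
    stack = struc.AtomArrayStack(trajectory.n_frames, top.n_atoms)
    stack.coord[:] = trajectory.coords
    stack.atom_name = top.names
    stack.res_name = top.res_names
    stack.res_id = top.res_ids
    stack.element = top.elements
    stack.chain_id = np.full(top.n_atoms, "A")
    stack.hetero = np.zeros(top.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def _read_pdb(path: str, interval_ps: float) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    topology = _topology_from_annotations(
        stack.atom_name, stack.res_name, stack.res_id, stack.element, coords[0]
    )
    times = np.arange(coords.shape[0]) * interval_ps
    return Trajectory(topology=topology, coords=coords, times=times)


def _write_xyz(trajectory: Trajectory, path: str) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"time_ps={trajectory.times[f]:.6g}\n")
            for el, xyz in zip(top.elements, trajectory.coords[f]):
                fh.write(f"{el:<3s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


def _read_xyz(path: str, interval_ps: float) -> Trajectory:
    frames, times = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    n_atoms = None
    elements = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise FormatError(f"bad atom count line {pos + 1} in {path}") from exc
        if n_atoms is None:
            n_atoms = n
        elif n != n_atoms:
            raise FormatError(
                f"model {len(frames) + 1} has {n} atoms instead of {n_atoms}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t = None
        for tokenpair in comment.split():
            if tokenpair.startswith("time_ps="):
                t = float(tokenpair.split("=", 1)[1])
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise FormatError(f"truncated model at line {pos + 1} in {path}")
        els, xyz = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"bad coordinate line in {path}: {ln!r}")
            els.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements is None:
            elements = els
        frames.append(xyz)
        times.append(t)
        pos += 2 + n
    if not frames:
        raise FormatError(f"no models in {path}")
    coords = np.asarray(frames, dtype=float)
    if any(t is None for t in times):
        times = np.arange(coords.shape[0]) * interval_ps
    else:
        times = np.asarray(times, dtype=float)
    names = [f"{el}{i + 1}" for i, el in enumerate(elements)]
    topology = _topology_from_annotations(
        names, ["MOL"] * len(elements), [1] * len(elements), elements, coords[0]
    )
    return Trajectory(topology=topology, coords=coords, times=times)
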