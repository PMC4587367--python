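"""Ground-truth-labelled synthetic data.

This module is a statistical emulator, not an MD engine: it produces
conformational ensembles with a controlled multi-basin structure, sphere-packed
bodies containing channels of known bottleneck radius, Poisson solvent clouds
with optional excess/depletion shells, and hydrogen-bond series with scheduled
occupancies.  Every output carries its generating truth (basin labels, channel
geometry, target occupancies) so each downstream analysis stage can be tested
against a known answer.

The default ensemble layout emulates a five-system study: one wild-type-like
system and one bulky-hydrophobic mutant each occupying their own conformational
basin, and three further mutants sharing a common basin — with one long run of
150 ns plus two 10 ns restart runs per system, frames every 20 ps.

All coordinates are in Å, times in ps, and identical (spec, seed) pairs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError, ShapeError
from .topology import Atom, ToyTopology
from .trajectory import SystemTrajectories, Trajectory
from . import chem

__all__ = [
    "generate_topology",
    "BasinSpec",
    "SystemSpec",
    "EnsembleSpec",
    "generate_ensemble",
    "make_basin_references",
    "five_system_spec",
    "ChannelDef",
    "ChannelSpec",
    "generate_channel_system",
    "SolventShellSpec",
    "SolvatedFrames",
    "generate_solvated_frames",
    "HBondPairSpec",
    "HBondSeriesSpec",
    "generate_hbond_series",
]


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def generate_topology(n_residues: int, seed: int) -> ToyTopology:
    """Build a toy peptide-like topology with all analysis roles populated.

    Each residue carries N (donor), H (bonded to N), CA, CB and O (acceptor).
    The middle residue gets a Cys-like SG start-point atom, the first residue a
    positively charged side-chain nitrogen, and the last a negatively charged
    side-chain oxygen.  Reference coordinates trace an irregular helix.
    """
    if n_residues < 3:
        raise InvalidSpecError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    donor_triplets: list[tuple[int, int]] = []
    acceptors: list[int] = []
    charges: dict[int, int] = {}
    start_atom = None
    mid = n_residues // 2 + 1

    def _unit(v):
        return v / np.linalg.norm(v)

    for r in range(1, n_residues + 1):
        theta = np.deg2rad(100.0) * r
        ca = np.array(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * r]
        ) + rng.normal(scale=0.15, size=3)
        res_name = "CYS" if r == mid else ("LYS" if r == 1 else ("GLU" if r == n_residues else "ALA"))
        u_n = _unit(rng.normal(size=3))
        u_h = _unit(rng.normal(size=3))
        u_b = _unit(rng.normal(size=3))
        u_o = _unit(rng.normal(size=3))
        n_pos = ca + 1.45 * u_n
        h_pos = n_pos + 1.00 * u_h
        cb_pos = ca + 1.53 * u_b
        o_pos = ca + 2.40 * u_o

        base = len(atoms)
        atoms.append(Atom("N", res_name, r, "N", chem.vdw_radius("N")))
        coords.append(n_pos)
        atoms.append(Atom("H", res_name, r, "H", chem.vdw_radius("H")))
        coords.append(h_pos)
        atoms.append(Atom("CA", res_name, r, "C", chem.vdw_radius("C")))
        coords.append(ca)
        atoms.append(Atom("CB", res_name, r, "C", chem.vdw_radius("C")))
        coords.append(cb_pos)
        atoms.append(Atom("O", res_name, r, "O", chem.vdw_radius("O")))
        coords.append(o_pos)
        donor_triplets.append((base, base + 1))
        acceptors.append(base + 4)
        if r == mid:
            atoms.append(Atom("SG", res_name, r, "S", chem.vdw_radius("S")))
            coords.append(ca + 2.0 * _unit(rng.normal(size=3)))
            start_atom = len(atoms) - 1
        if r == 1:
            atoms.append(Atom("NZ", res_name, r, "N", chem.vdw_radius("N")))
            coords.append(ca + 3.0 * _unit(rng.normal(size=3)))
            charges[len(atoms) - 1] = +1
        if r == n_residues:
            atoms.append(Atom("OE1", res_name, r, "O", chem.vdw_radius("O")))
            coords.append(ca + 2.8 * _unit(rng.normal(size=3)))
            charges[len(atoms) - 1] = -1

    return ToyTopology(
        atoms=tuple(atoms),
        donor_triplets=tuple(donor_triplets),
        acceptors=tuple(acceptors),
        start_atom=start_atom,
        charges=charges,
        reference_coords=np.array(coords),
    )


# ---------------------------------------------------------------------------
# multi-basin conformational ensembles
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class BasinSpec:
    """One conformational basin: a reference geometry plus isotropic width."""

    reference: np.ndarray  # (n_atoms, 3) Å
    sigma: float  # Å, per coordinate

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        if self.sigma < 0:
            raise InvalidSpecError("basin width must be non-negative")


@dataclass(eq=False)
class SystemSpec:
    """A system's basins and its occupancy schedule.

    ``schedule`` is a list of ``(t_start_ps, t_end_ps, basin_id)`` half-open
    windows that must partition ``[0, long duration)``.
    """

    label: str
    basins: dict[int, BasinSpec]
    schedule: tuple[tuple[float, float, int], ...]

    def active_basin(self, t_ps: float) -> int:
        for t0, t1, b in self.schedule:
            if t0 <= t_ps < t1:
                return b
        # the very last instant belongs to the final window
        return self.schedule[-1][2]


@dataclass(eq=False)
class EnsembleSpec:
    systems: tuple[SystemSpec, ...]
    long_ns: float = 150.0
    restart_ns: tuple[float, ...] = (10.0, 10.0)
    restart_branch_ns: tuple[float, ...] = (60.0, 130.0)
    interval_ps: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.long_ns <= 0 or any(r <= 0 for r in self.restart_ns):
            raise InvalidSpecError("durations must be positive")
        if len(self.restart_ns) != len(self.restart_branch_ns):
            raise InvalidSpecError("restart durations and branch times mismatch")
        for dur in (self.long_ns * 1000.0, *(r * 1000.0 for r in self.restart_ns)):
            if abs(dur / self.interval_ps - round(dur / self.interval_ps)) > 1e-9:
                raise InvalidSpecError("frame interval must divide all durations")
        for sys_spec in self.systems:
            if not sys_spec.basins:
                raise InvalidSpecError(f"system {sys_spec.label} has no basins")
            self._check_schedule(sys_spec)

    def _check_schedule(self, sys_spec: SystemSpec) -> None:
        sched = sorted(sys_spec.schedule)
        long_ps = self.long_ns * 1000.0
        if not sched:
            raise InvalidSpecError(f"system {sys_spec.label} has empty schedule")
        if sched[0][0] != 0 or abs(sched[-1][1] - long_ps) > 1e-6:
            raise InvalidSpecError(
                f"schedule of {sys_spec.label} must span [0, {long_ps}) ps"
            )
        for (a0, a1, _), (b0, _, _) in zip(sched, sched[1:]):
            if abs(a1 - b0) > 1e-6:
                raise InvalidSpecError(
                    f"schedule windows of {sys_spec.label} must be contiguous"
                )
        for _, _, b in sched:
            if b not in sys_spec.basins:
                raise InvalidSpecError(f"unknown basin id {b} in schedule")


def _displace(reference, sigma, n_frames, topology, rng):
    """Gaussian displacements, with each hydrogen riding rigidly on its donor
    so donor-H bonds stay intact."""
    disp = rng.normal(scale=sigma, size=(n_frames, reference.shape[0], 3)) if sigma > 0 else np.zeros((n_frames, reference.shape[0], 3))
    for d, h in topology.donor_triplets:
        disp[:, h, :] = disp[:, d, :]
    return reference[None] + disp


def generate_ensemble(
    topology: ToyTopology, spec: EnsembleSpec
) -> list[SystemTrajectories]:
    """Generate one long + restart trajectories per system.

    Each frame is the scheduled basin's reference plus i.i.d. Gaussian
    displacement of the basin width per coordinate (hydrogens ride on their
    donors).  Restart runs reuse the basin active at their branch time with a
    fresh random stream.
    """
    out = []
    root = np.random.SeedSequence(spec.seed)
    sys_seeds = root.spawn(len(spec.systems))
    for sys_spec, sys_seed in zip(spec.systems, sys_seeds):
        for b in sys_spec.basins.values():
            if b.reference.shape != (topology.n_atoms, 3):
                raise ShapeError(
                    f"basin reference for {sys_spec.label} has shape "
                    f"{b.reference.shape}, expected ({topology.n_atoms}, 3)"
                )
        src_seeds = sys_seed.spawn(1 + len(spec.restart_ns))
        long_ps = spec.long_ns * 1000.0
        times = np.arange(0.0, long_ps, spec.interval_ps)
        basin_ids = np.array([sys_spec.active_basin(t) for t in times])
        rng = np.random.default_rng(src_seeds[0])
        coords = np.empty((times.size, topology.n_atoms, 3))
        for b_id in np.unique(basin_ids):
            mask = basin_ids == b_id
            basin = sys_spec.basins[int(b_id)]
            coords[mask] = _displace(
                basin.reference, basin.sigma, int(mask.sum()), topology, rng
            )
        long_traj = Trajectory(
            topology=topology,
            coords=coords,
            times=times,
            label=sys_spec.label,
            source="long",
            basin_ids=basin_ids,
        )
        restarts = []
        for k, (dur_ns, branch_ns) in enumerate(
            zip(spec.restart_ns, spec.restart_branch_ns), start=1
        ):
            b_id = sys_spec.active_basin(branch_ns * 1000.0)
            basin = sys_spec.basins[b_id]
            r_times = np.arange(0.0, dur_ns * 1000.0, spec.interval_ps)
            r_rng = np.random.default_rng(src_seeds[k])
            r_coords = _displace(
                basin.reference, basin.sigma, r_times.size, topology, r_rng
            )
            restarts.append(
                Trajectory(
                    topology=topology,
                    coords=r_coords,
                    times=r_times,
                    label=sys_spec.label,
                    source=f"restart{k}",
                    basin_ids=np.full(r_times.size, b_id),
                )
            )
        out.append(
            SystemTrajectories(
                label=sys_spec.label, long=long_traj, restarts=tuple(restarts)
            )
        )
    return out


def make_basin_references(
    topology: ToyTopology, n_basins: int, separation: float, seed: int
) -> list[np.ndarray]:
    """Distinct reference conformations at a controlled mutual RMSD.

    Basin 0 is the topology reference; each further basin displaces every atom
    along a smooth random field, rescaled (a few fixed-point iterations) so the
    superposition RMSD to the base reference equals ``separation`` Å.
    References are pairwise roughly equidistant because the fields are
    independent.
    """
    from .superpose import kabsch_rmsd

    base = topology.reference_coords
    rng = np.random.default_rng(seed)
    if n_basins == 1:
        return [base.copy()]
    # orthonormal random displacement fields (flattened), hydrogens riding donors
    fields = []
    for _ in range(n_basins - 1):
        f = rng.normal(size=(topology.n_atoms, 3))
        for d, h in topology.donor_triplets:
            f[h] = f[d]
        v = f.ravel()
        for u in fields:
            v = v - (v @ u) * u
        fields.append(v / np.linalg.norm(v))
    # regular simplex with one vertex at the origin (the base reference)
    m = n_basins - 1
    verts = [np.zeros(m)]
    for j in range(1, n_basins):
        c = np.mean(verts, axis=0)
        r = np.linalg.norm(verts[0] - c)
        x = c.copy()
        x[j - 1] += np.sqrt(max(1.0 - r**2, 0.0))
        verts.append(x)

    def _refs(scale):
        out = []
        for v in verts:
            disp = sum(
                coef * u for coef, u in zip(v, fields)
            ) if m else np.zeros(base.size)
            out.append(base + scale * np.asarray(disp).reshape(base.shape))
        return out

    # calibrate one global scale so the mean pairwise superposition RMSD
    # between references equals the requested separation
    scale = separation * np.sqrt(topology.n_atoms)
    for _ in range(4):
        refs = _refs(scale)
        dists = [
            kabsch_rmsd(refs[i], refs[j])[0]
            for i in range(n_basins)
            for j in range(i + 1, n_basins)
        ]
        mean_d = float(np.mean(dists))
        if mean_d == 0:
            break
        scale *= separation / mean_d
    return _refs(scale)


def five_system_spec(
    topology: ToyTopology,
    seed: int = 0,
    sigma: float = 0.7,
    separation: float = 2.9,
    long_ns: float = 150.0,
    restart_ns: tuple[float, ...] = (10.0, 10.0),
    restart_branch_ns: tuple[float, ...] = (60.0, 130.0),
    interval_ps: float = 20.0,
) -> EnsembleSpec:
    """The canonical five-system study design.

    Systems, in canonical order: WT (own basin), F429A / F429E / F429H
    (shared basin), F429L (own basin).  The default width (σ = 0.7 Å per
    coordinate) and basin separation (2.9 Å) place the intra-basin pairwise
    RMSD mode near 0.17 nm (≈ σ√6) and the inter-basin mode near 0.29 nm,
    matching the two modes of the RMSD-distance histograms the cutoff scan is
    calibrated against.
    """
    refs = make_basin_references(topology, 3, separation, seed)
    basin_wt = {0: BasinSpec(refs[0], sigma)}
    basin_shared = {1: BasinSpec(refs[1], sigma)}
    basin_l = {2: BasinSpec(refs[2], sigma)}
    long_ps = long_ns * 1000.0
    systems = (
        SystemSpec("WT", basin_wt, ((0.0, long_ps, 0),)),
        SystemSpec("F429A", basin_shared, ((0.0, long_ps, 1),)),
        SystemSpec("F429E", basin_shared, ((0.0, long_ps, 1),)),
        SystemSpec("F429H", basin_shared, ((0.0, long_ps, 1),)),
        SystemSpec("F429L", basin_l, ((0.0, long_ps, 2),)),
    )
    return EnsembleSpec(
        systems=systems,
        long_ns=long_ns,
        restart_ns=restart_ns,
        restart_branch_ns=restart_branch_ns,
        interval_ps=interval_ps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# channel bodies for tunnel analysis
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ChannelDef:
    """One channel: unit axis from the body centre plus a radius profile given
    as breakpoints ``(arc length s Å, radius Å)``; linear interpolation in
    between."""

    axis: tuple[float, float, float]
    profile: tuple[tuple[float, float], ...]

    def radius_at(self, s: float | np.ndarray) -> np.ndarray:
        pts = np.asarray(self.profile, dtype=float)
        return np.interp(s, pts[:, 0], pts[:, 1])


@dataclass(eq=False)
class ChannelSpec:
    body_radius: float
    channels: tuple[ChannelDef, ...]
    lattice_pitch: float = 2.0
    jitter: float = 0.15
    sphere_radius: float = 1.5
    start_clearance: float = 3.0  # free radius of the walled start cavity, Å

    def __post_init__(self):
        if self.body_radius <= 0:
            raise InvalidSpecError("body radius must be positive")
        for ch in self.channels:
            pts = np.asarray(ch.profile, dtype=float)
            if pts[:, 1].min() < 0.5:
                raise InvalidSpecError("channel radius must be ≥ 0.5 Å everywhere")
            if pts[:, 0].max() < self.body_radius:
                raise InvalidSpecError(
                    "channel profile does not reach the body surface"
                )


def _orthobasis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def generate_channel_system(spec: ChannelSpec, seed: int):
    """Sphere-packed spherical body with empty channels of known geometry.

    Spheres of 1.5 Å radius on a jittered cubic lattice fill a ball.  Each
    channel tube (plus a spherical start cavity at the centre) is carved out
    and then *lined* with explicit wall-sphere rings at the profile radius, so
    the free radius along the axis equals the profile within the lattice
    jitter rather than being quantised by the lattice.  Returns a single-frame
    :class:`Trajectory` plus a truth record per channel with bottleneck radius
    = min of the profile over ``[0, body radius]``, length = body radius, and
    a tolerance equal to the lattice jitter.
    """
    rng = np.random.default_rng(seed)
    R = spec.body_radius
    sr = spec.sphere_radius
    pitch = spec.lattice_pitch
    cavity_r = spec.start_clearance + sr
    grid = np.arange(-R - pitch, R + pitch + 1e-9, pitch)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    pts = pts + rng.uniform(-spec.jitter, spec.jitter, size=pts.shape)
    pts = pts[np.linalg.norm(pts, axis=1) <= R]
    keep = np.linalg.norm(pts, axis=1) >= cavity_r

    axes, truths = [], []
    for ch in spec.channels:
        axis = np.asarray(ch.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        axes.append(axis)
        s = pts @ axis
        perp = np.linalg.norm(pts - s[:, None] * axis[None], axis=1)
        tube_r = ch.radius_at(np.clip(s, 0.0, R))
        keep &= ~((s >= 0.0) & (s <= R) & (perp < tube_r + sr))
        # piecewise-linear min occurs at a breakpoint or an interval end
        s_eval = np.clip(
            np.array([p[0] for p in ch.profile] + [0.0, R]), 0.0, R
        )
        truths.append(
            {
                "bottleneck_radius": float(np.min(ch.radius_at(s_eval))),
                "length": float(R),
                "axis": tuple(axis),
                "tolerance": spec.jitter,
            }
        )
    pts = pts[keep]

    def _in_any_tube(p: np.ndarray, skip: int | None = None) -> bool:
        for ci, (ch, axis) in enumerate(zip(spec.channels, axes)):
            if ci == skip:
                continue
            s = float(p @ axis)
            if 0.0 < s <= R:
                perp = float(np.linalg.norm(p - s * axis))
                if perp < float(ch.radius_at(min(s, R))) + sr - 1e-6:
                    return True
        return False

    wall: list[np.ndarray] = []
    ring_step = 1.0
    for ci, (ch, axis) in enumerate(zip(spec.channels, axes)):
        u, v = _orthobasis(axis)
        for s in np.arange(0.0, R + 1e-9, ring_step):
            rw = float(ch.radius_at(min(s, R))) + sr
            n_ring = max(8, int(np.ceil(2.0 * np.pi * rw / 1.4)))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            radial = rw + rng.uniform(0.0, spec.jitter, size=n_ring)
            for t in range(n_ring):
                th = phase + 2.0 * np.pi * t / n_ring
                p = s * axis + radial[t] * (np.cos(th) * u + np.sin(th) * v)
                if np.linalg.norm(p) < cavity_r:
                    continue
                if _in_any_tube(p, skip=ci):
                    continue
                wall.append(p)
    # walled start cavity: Fibonacci-sphere shell, open where channels leave
    n_shell = int(np.ceil(4.0 * np.pi * cavity_r**2 / 1.4**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_shell):
        zfrac = 1.0 - 2.0 * (i + 0.5) / n_shell
        rad = np.sqrt(max(1.0 - zfrac**2, 0.0))
        th = golden * i
        direction = np.array([rad * np.cos(th), rad * np.sin(th), zfrac])
        p = (cavity_r + rng.uniform(0.0, spec.jitter)) * direction
        if _in_any_tube(p):
            continue
        wall.append(p)
    pts = np.concatenate([pts, np.array(wall).reshape(-1, 3)], axis=0)
    atoms = tuple(
        Atom("SPH", "BDY", i + 1, "C", spec.sphere_radius)
        for i in range(len(pts))
    )
    topology = ToyTopology(atoms=atoms, reference_coords=pts)
    traj = Trajectory(
        topology=topology,
        coords=pts[None],
        times=np.array([0.0]),
        label="channel-body",
    )
    return traj, truths


# ---------------------------------------------------------------------------
# solvent point clouds
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class SolventShellSpec:
    """Homogeneous Poisson solvent modulated by radial shells around a target.

    ``shells`` are ``(r_lo, r_hi, multiplier)`` density factors relative to the
    bulk number density; multiplier 0 carves a depletion shell.
    """

    bulk_density: float  # Å^-3
    box: tuple[float, float, float]
    shells: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if self.bulk_density < 0:
            raise InvalidSpecError("density must be non-negative")
        if any(m < 0 for _, _, m in self.shells):
            raise InvalidSpecError("shell multipliers must be non-negative")
        half = min(self.box) / 2.0
        if any(r_hi > half for _, r_hi, _ in self.shells):
            raise InvalidSpecError("box too small to hold the shells")


@dataclass(eq=False)
class SolvatedFrames:
    """Static protein coordinates plus per-frame solvent point clouds.

    Solvent counts vary per frame (Poisson), so solvent lives in a list of
    arrays rather than a fixed-shape Trajectory.
    """

    topology: ToyTopology
    protein_coords: np.ndarray  # (n_atoms, 3)
    solvent: list[np.ndarray]  # per frame (m_f, 3)
    box: np.ndarray  # (3,)
    target_index: int

    @property
    def n_frames(self) -> int:
        return len(self.solvent)

    @property
    def target_point(self) -> np.ndarray:
        return self.protein_coords[self.target_index]


def generate_solvated_frames(
    topology: ToyTopology,
    spec: SolventShellSpec,
    n_frames: int,
    seed: int,
    target_atom: int | None = None,
) -> SolvatedFrames:
    """Draw solvent centres as a modulated spatial Poisson process.

    Homogeneous points at ``bulk_density × max multiplier`` are thinned per
    point by the local multiplier, the standard exact construction for an
    inhomogeneous Poisson process.  The box is centred on the target atom and
    the box is periodic for the downstream g(r) machinery.
    """
    if target_atom is None:
        target_atom = topology.start_atom
    if target_atom is None:
        raise InvalidSpecError("no target atom available")
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)
    coords = topology.reference_coords
    center = coords[target_atom]
    origin = center - box / 2.0
    vol = float(np.prod(box))
    mults = [m for _, _, m in spec.shells]
    rho_max = spec.bulk_density * max([1.0, *mults]) if spec.bulk_density > 0 else 0.0
    frames = []
    for _ in range(n_frames):
        if rho_max == 0.0:
            frames.append(np.empty((0, 3)))
            continue
        n = rng.poisson(rho_max * vol)
        pts = origin + rng.uniform(size=(n, 3)) * box
        d = np.linalg.norm(pts - center, axis=1)
        mult = np.ones(n)
        for r_lo, r_hi, m in spec.shells:
            mult[(d >= r_lo) & (d < r_hi)] = m
        accept = rng.uniform(size=n) < mult * spec.bulk_density / rho_max
        frames.append(pts[accept])
    return SolvatedFrames(
        topology=topology,
        protein_coords=coords,
        solvent=frames,
        box=box,
        target_index=int(target_atom),
    )


# ---------------------------------------------------------------------------
# scheduled hydrogen-bond series
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class HBondPairSpec:
    donor_triplet: int  # index into topology.donor_triplets
    acceptor: int  # atom index (must be a tagged acceptor)
    occupancy: float
    formed_distance: float = 2.9  # d(D,A) Å when formed
    formed_angle: float = 10.0  # deviation-from-linear (deg) when formed
    broken_distance: float = 5.5
    broken_angle: float = 60.0


@dataclass(eq=False)
class HBondSeriesSpec:
    pairs: tuple[HBondPairSpec, ...]
    n_frames: int
    seed: int = 0
    interval_ps: float = 20.0

    def __post_init__(self):
        for p in self.pairs:
            if not 0.0 <= p.occupancy <= 1.0:
                raise InvalidSpecError("target occupancy must be in [0, 1]")


def generate_hbond_series(
    topology: ToyTopology, spec: HBondSeriesSpec
) -> Trajectory:
    """Trajectory in which each specified pair is formed in a Bernoulli(target)
    fraction of frames.

    The acceptor atom of each pair is repositioned per frame relative to the
    frozen donor-H geometry: on the D→H ray, tilted by the formed (or broken)
    deviation angle, at the formed (or broken) distance.  Each acceptor may be
    scheduled by at most one pair.
    """
    n_d = len(topology.donor_triplets)
    seen_acceptors = set()
    for p in spec.pairs:
        if not 0 <= p.donor_triplet < n_d:
            raise InvalidSpecError(f"unknown donor triplet id {p.donor_triplet}")
        if p.acceptor not in topology.acceptors:
            raise InvalidSpecError(f"atom {p.acceptor} is not a tagged acceptor")
        if p.acceptor in seen_acceptors:
            raise InvalidSpecError("each acceptor may appear in one pair only")
        seen_acceptors.add(p.acceptor)
        d_idx, _ = topology.donor_triplets[p.donor_triplet]
        if topology.atoms[d_idx].res_id == topology.atoms[p.acceptor].res_id:
            raise InvalidSpecError("donor and acceptor must be in different residues")
    rng = np.random.default_rng(spec.seed)
    ref = topology.reference_coords
    coords = np.repeat(ref[None], spec.n_frames, axis=0)
    formed_record = {}
    for p in spec.pairs:
        d_idx, h_idx = topology.donor_triplets[p.donor_triplet]
        u = ref[h_idx] - ref[d_idx]
        u = u / np.linalg.norm(u)
        # any unit vector perpendicular to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        w = np.cross(u, helper)
        w /= np.linalg.norm(w)
        formed = rng.uniform(size=spec.n_frames) < p.occupancy
        for f in range(spec.n_frames):
            dist, ang = (
                (p.formed_distance, p.formed_angle)
                if formed[f]
                else (p.broken_distance, p.broken_angle)
            )
            a = np.deg2rad(ang)
            direction = np.cos(a) * u + np.sin(a) * w
            coords[f, p.acceptor] = ref[d_idx] + dist * direction
        formed_record[(p.donor_triplet, p.acceptor)] = formed
    times = np.arange(spec.n_frames) * spec.interval_ps
    traj = Trajectory(
        topology=topology, coords=coords, times=times, label="hbond-series"
    )
    traj.hbond_truth = formed_record  # ground-truth schedule rides along
    return traj
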