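"""Geometric hydrogen-bond and salt-bridge detection with occupancy statistics.

A donor-acceptor pair is hydrogen bonded in a frame when the donor-acceptor
distance is strictly below the cutoff (default 3.5 Å) and the deviation angle
is at most the angle cutoff (default 30°, inclusive).  The default angle
convention ("hda") measures the angle at the donor between the D→H and D→A
directions — the deviation of the acceptor from the donor-hydrogen axis; the
alternative "dha_deviation" convention measures 180° minus the literal
D-H···A angle.  Intra-residue pairs are always excluded.

Occupancy is the fraction of analysed frames in which a pair is detected
(resolving multiple hydrogens on one donor to the best, i.e. minimum-angle,
hydrogen per frame).  Lifetime filtering keeps bonds whose occupancy is
strictly greater than the threshold; network differencing compares the
surviving bond sets of two systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TopologyError, UsageError
from .topology import ToyTopology
from .trajectory import Trajectory

__all__ = [
    "HBondCriteria",
    "detect_hbonds",
    "OccupancyTable",
    "hbond_occupancy",
    "filter_by_lifetime",
    "NetworkDiff",
    "network_difference",
    "detect_salt_bridges",
]


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 3.5  # Å, strict <
    angle_cutoff: float = 30.0  # degrees, inclusive ≤
    convention: str = "hda"  # or "dha_deviation"

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise UsageError("cutoffs must be positive")
        if self.convention not in ("hda", "dha_deviation"):
            raise UsageError(f"unknown angle convention {self.convention!r}")


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(
    frame: np.ndarray,
    topology: ToyTopology,
    criteria: HBondCriteria = HBondCriteria(),
    donors=None,
    acceptors=None,
) -> list[tuple[int, int, int, float, float]]:
    """Hydrogen bonds present in one frame.

    Returns ``(donor, hydrogen, acceptor, distance, angle)`` tuples.  Donors
    default to all donor triplets in the topology, acceptors to all tagged
    acceptors.  A donor listed without a bonded hydrogen is a topology error.
    """
    frame = np.asarray(frame, dtype=float)
    triplets = (
        topology.donor_triplets
        if donors is None
        else tuple(topology.donor_triplets[i] for i in donors)
    )
    acc = topology.acceptors if acceptors is None else tuple(acceptors)
    for d, h in triplets:
        if np.linalg.norm(frame[h] - frame[d]) >= 1.2:
            raise TopologyError(
                f"donor {topology.atom_label(d)} has no bonded hydrogen"
            )
    res_ids = topology.res_ids
    found = []
    for d, h in triplets:
        for a in acc:
            if res_ids[a] == res_ids[d]:
                continue
            dist = float(np.linalg.norm(frame[a] - frame[d]))
            if dist >= criteria.distance_cutoff:
                continue
            if criteria.convention == "hda":
                ang = _angle_deg(frame[h] - frame[d], frame[a] - frame[d])
            else:
                ang = 180.0 - _angle_deg(frame[d] - frame[h], frame[a] - frame[h])
            if ang <= criteria.angle_cutoff:
                found.append((d, h, a, dist, ang))
    return found


@dataclass(eq=False)
class OccupancyTable:
    """Per-pair hydrogen-bond occupancy over a trajectory."""

    df: pd.DataFrame  # donor, acceptor, donor_label, acceptor_label,
    #                   frames_present, fraction, equivalent_ns
    total_frames: int
    total_time_ns: float
    system: str = ""
    labeling: tuple[str, ...] = ()

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "system", self.system)
        out.to_csv(path, sep="\t", index=False)


def hbond_occupancy(
    trajectory: Trajectory, criteria: HBondCriteria = HBondCriteria()
) -> OccupancyTable:
    """Fraction of frames each donor-acceptor pair is bonded.

    When a donor has several hydrogens the minimum-angle hydrogen represents
    the pair in each frame, so a pair never counts twice per frame.
    """
    if trajectory.n_frames < 1:
        raise UsageError("empty trajectory")
    top = trajectory.topology
    counts: dict[tuple[int, int], int] = {}
    for f in range(trajectory.n_frames):
        best: dict[tuple[int, int], float] = {}
        for d, h, a, dist, ang in detect_hbonds(trajectory.coords[f], top, criteria):
            key = (d, a)
            if key not in best or ang < best[key]:
                best[key] = ang
        for key in best:
            counts[key] = counts.get(key, 0) + 1
    total_time_ns = trajectory.duration_ps / 1000.0
    rows = []
    for (d, a), n in sorted(counts.items()):
        frac = n / trajectory.n_frames
        rows.append(
            {
                "donor": d,
                "acceptor": a,
                "donor_label": top.atom_label(d),
                "acceptor_label": top.atom_label(a),
                "frames_present": n,
                "fraction": frac,
                "equivalent_ns": frac * total_time_ns,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "donor",
            "acceptor",
            "donor_label",
            "acceptor_label",
            "frames_present",
            "fraction",
            "equivalent_ns",
        ],
    )
    return OccupancyTable(
        df=df,
        total_frames=trajectory.n_frames,
        total_time_ns=total_time_ns,
        system=trajectory.label,
        labeling=top.labeling_key(),
    )


def filter_by_lifetime(table: OccupancyTable, min_fraction: float) -> OccupancyTable:
    """Keep bonds with occupancy strictly greater than ``min_fraction``."""
    if not 0.0 <= min_fraction <= 1.0:
        raise UsageError("min_fraction must be in [0, 1]")
    df = table.df[table.df["fraction"] > min_fraction].reset_index(drop=True)
    return OccupancyTable(
        df=df,
        total_frames=table.total_frames,
        total_time_ns=table.total_time_ns,
        system=table.system,
        labeling=table.labeling,
    )


@dataclass(eq=False)
class NetworkDiff:
    unique_to_a: pd.DataFrame
    unique_to_b: pd.DataFrame
    shared: pd.DataFrame  # with fraction_a, fraction_b, delta_fraction
    threshold: float


def network_difference(
    table_a: OccupancyTable, table_b: OccupancyTable, threshold: float = 0.5
) -> NetworkDiff:
    """Set difference of above-threshold bonds between two systems.

    Bonds are keyed by (donor label, acceptor label); shared bonds report the
    occupancy change Δ = fraction_a − fraction_b.
    """
    if table_a.labeling != table_b.labeling:
        raise UsageError("occupancy tables use incompatible residue labelings")

    def _above(t: OccupancyTable) -> pd.DataFrame:
        df = t.df[t.df["fraction"] > threshold]
        return df.set_index(["donor_label", "acceptor_label"])

    a, b = _above(table_a), _above(table_b)
    only_a = a.loc[~a.index.isin(b.index)].reset_index()
    only_b = b.loc[~b.index.isin(a.index)].reset_index()
    common = a.index.intersection(b.index)
    shared = pd.DataFrame(
        {
            "donor_label": [i[0] for i in common],
            "acceptor_label": [i[1] for i in common],
            "fraction_a": a.loc[common, "fraction"].to_numpy(),
            "fraction_b": b.loc[common, "fraction"].to_numpy(),
        }
    )
    shared["delta_fraction"] = shared["fraction_a"] - shared["fraction_b"]
    return NetworkDiff(
        unique_to_a=only_a, unique_to_b=only_b, shared=shared, threshold=threshold
    )


def detect_salt_bridges(
    frame: np.ndarray,
    topology: ToyTopology,
    distance_cutoff: float = 4.0,
) -> list[tuple[int, int]]:
    """Residue pairs whose opposite-charge tagged atoms come within the cutoff.

    Returns sorted (res_i, res_j) pairs with res_i < res_j.  If the topology
    tags no charged groups an empty list is returned with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    pos = [i for i, q in topology.charges.items() if q > 0]
    neg = [i for i, q in topology.charges.items() if q < 0]
    if not pos or not neg:
        warnings.warn("no charged groups tagged in topology", stacklevel=2)
        return []
    res_ids = topology.res_ids
    pairs = set()
    for p in pos:
        for n in neg:
            if res_ids[p] == res_ids[n]:
                continue
            if np.linalg.norm(frame[p] - frame[n]) <= distance_cutoff:
                pairs.add(tuple(sorted((int(res_ids[p]), int(res_ids[n])))))
    return sorted(pairs)
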