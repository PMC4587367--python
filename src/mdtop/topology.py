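"""Minimal topology container for toy protein systems.

A :class:`ToyTopology` lists atoms (name, residue, element, vdW radius) plus the
functional roles the analysis needs: backbone markers (Cα-like), side-chain
markers (Cβ-like), donor–hydrogen pairs and acceptors for hydrogen-bond
detection, a buried start-point atom (Sγ-like) for tunnel searches, and formal
charge tags for salt bridges.  It deliberately knows nothing about chemistry
beyond these tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .errors import TopologyError


@dataclass(frozen=True)
class Atom:
    name: str
    res_name: str
    res_id: int
    element: str
    vdw_radius: float


@dataclass(eq=False)
class ToyTopology:
    """Atom table plus role annotations.

    Parameters
    ----------
    atoms:
        Ordered atom records; residue ids must be contiguous starting at 1.
    donor_triplets:
        ``(donor_index, hydrogen_index)`` pairs; the hydrogen must stay bonded
        (< 1.2 Å) to its donor in generated frames.
    acceptors:
        Indices of hydrogen-bond acceptor atoms.
    start_atom:
        Index of the buried start-point atom for tunnel searches (may be None).
    charges:
        Formal charge tag per atom index (+1 / -1) for salt-bridge detection.
    reference_coords:
        Canonical reference geometry (n_atoms, 3) in Å.
    """

    atoms: tuple[Atom, ...]
    donor_triplets: tuple[tuple[int, int], ...] = ()
    acceptors: tuple[int, ...] = ()
    start_atom: int | None = None
    charges: dict[int, int] = field(default_factory=dict)
    reference_coords: np.ndarray | None = None
    solvent_element: str = "O"

    def __post_init__(self):
        res_ids = [a.res_id for a in self.atoms]
        if res_ids:
            uniq = sorted(set(res_ids))
            if uniq != list(range(1, len(uniq) + 1)):
                raise TopologyError("residue indices must be contiguous from 1")
        if any(a.vdw_radius <= 0 for a in self.atoms):
            raise TopologyError("vdW radii must be positive")
        for d, h in self.donor_triplets:
            for idx in (d, h):
                if not 0 <= idx < len(self.atoms):
                    raise TopologyError(f"donor triplet index {idx} out of range")
        if self.reference_coords is not None:
            ref = np.asarray(self.reference_coords, dtype=float)
            if ref.shape != (len(self.atoms), 3):
                raise TopologyError("reference_coords shape mismatch")
            object.__setattr__(self, "reference_coords", ref)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return max((a.res_id for a in self.atoms), default=0)

    @cached_property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @cached_property
    def res_ids(self) -> np.ndarray:
        return np.array([a.res_id for a in self.atoms])

    @cached_property
    def res_names(self) -> np.ndarray:
        return np.array([a.res_name for a in self.atoms])

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @cached_property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def atom_label(self, i: int) -> str:
        a = self.atoms[i]
        return f"{a.res_name}{a.res_id}:{a.name}"

    def residue_label(self, res_id: int) -> str:
        for a in self.atoms:
            if a.res_id == res_id:
                return f"{a.res_name}{res_id}"
        raise TopologyError(f"no residue {res_id}")

    def labeling_key(self) -> tuple[str, ...]:
        """Hashable identity of the residue labelling, used to check that two
        occupancy tables are comparable."""
        return tuple(f"{a.res_name}{a.res_id}:{a.name}" for a in self.atoms)
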