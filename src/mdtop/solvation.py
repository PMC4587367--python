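"""Radial distribution functions and coordination numbers.

The g(r) normalisation follows the sphere-local convention: the shell density
of species B around centres A is divided by the *mean* density of B within the
sphere of radius ``r_max`` around A (not the global box density), averaged over
frames and centres.  This keeps g(r) well defined for non-periodic fixtures
where only the solvated neighbourhood of the target is meaningful; for
periodic boxes the minimum-image convention is applied and ``r_max`` may not
exceed half the smallest box edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .synthetic import SolvatedFrames

__all__ = ["RDFProfile", "rdf", "coordination_number"]


@dataclass(eq=False)
class RDFProfile:
    bin_edges: np.ndarray  # Å
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin
    rho_local: float  # Å^-3
    r_max: float

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"r_mid_A": self.r_mid, "g": self.g, "raw_count": self.counts}
        ).to_csv(path, sep="\t", index=False)


def _min_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def _iter_frames(frames, centers, targets):
    """Yield (center points (c,3), target points (m,3)) per frame."""
    if isinstance(frames, SolvatedFrames):
        if centers is None:
            centers_pts = frames.protein_coords[[frames.target_index]]
        else:
            centers_pts = frames.protein_coords[np.atleast_1d(np.asarray(centers, int))]
        for sol in frames.solvent:
            yield centers_pts, sol
    else:
        # generic: list of (centers, targets) tuples
        for c, t in frames:
            yield np.atleast_2d(c), np.atleast_2d(t)


def rdf(
    frames,
    centers=None,
    targets=None,
    bin_width: float = 0.1,
    r_max: float = 12.0,
    box: np.ndarray | None = None,
) -> RDFProfile:
    """Radial distribution function of targets B around centres A.

    ``frames`` is either a :class:`~mdtop.synthetic.SolvatedFrames` (centres
    are protein atom indices, targets the solvent cloud) or an iterable of
    ``(center_points, target_points)`` pairs.  ``g(r)`` is the shell density
    divided by the mean density inside the ``r_max`` sphere.
    """
    if bin_width <= 0:
        raise UsageError("bin width must be positive")
    if isinstance(frames, SolvatedFrames) and box is None:
        box = frames.box
    if box is not None and r_max > min(box) / 2.0 + 1e-9:
        raise UsageError("r_max must not exceed half the smallest box edge")
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_sphere_samples = 0  # (frame, center) pairs
    total_within = 0
    for centers_pts, targets_pts in _iter_frames(frames, centers, targets):
        n_sphere_samples += len(centers_pts)
        if len(targets_pts) == 0:
            continue
        for c in centers_pts:
            d = np.linalg.norm(_min_image(targets_pts - c, box), axis=1)
            d = d[d <= r_max]
            total_within += d.size
            hist, _ = np.histogram(d, bins=edges)
            counts += hist
    if total_within == 0:
        raise UsageError(
            "no target particles within r_max in any frame; g(r) normalisation undefined"
        )
    v_sphere = 4.0 / 3.0 * np.pi * r_max**3
    rho_local = total_within / (n_sphere_samples * v_sphere)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    shell_density = counts / (n_sphere_samples * shell_vol)
    g = shell_density / rho_local
    return RDFProfile(
        bin_edges=edges, g=g, counts=counts, rho_local=float(rho_local), r_max=r_max
    )


def coordination_number(
    frames,
    center=None,
    cutoff: float = 7.0,
    box: np.ndarray | None = None,
) -> float:
    """Mean number of target particles within ``cutoff`` of the centre.

    Published tables often report ``round()`` of this value; the raw mean
    is returned so callers choose the rounding convention.
    """
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    if isinstance(frames, SolvatedFrames) and box is None:
        box = frames.box
    total, n_samples = 0, 0
    for centers_pts, targets_pts in _iter_frames(frames, center, None):
        for c in centers_pts:
            n_samples += 1
            if len(targets_pts) == 0:
                continue
            d = np.linalg.norm(_min_image(targets_pts - c, box), axis=1)
            total += int((d <= cutoff).sum())
    if n_samples == 0:
        raise UsageError("no frames")
    return total / n_samples
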