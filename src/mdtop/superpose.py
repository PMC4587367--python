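"""Optimal superposition, RMSD matrices, RMSF profiles and similarity centroids.

RMSD between two conformations is the least-squares residual after optimal
rigid-body superposition (Kabsch), with a proper rotation enforced.  Pairwise
matrices are computed with a batched SVD so whole frame sets stay in numpy.

The similarity-score centroid of a frame set is the frame maximising
``Σ_j exp(-rms_ij / σ)``, with σ the population standard deviation of the
off-diagonal upper triangle of the RMSD matrix.  Internally everything is Å;
the nm views exist only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, SelectionError, UsageError
from .selection import resolve_selection
from .topology import ToyTopology

__all__ = [
    "kabsch_rmsd",
    "superpose_onto",
    "iterative_mean",
    "DistanceMatrix",
    "pairwise_rmsd_matrix",
    "FluctuationProfile",
    "rmsf",
    "rmsf_difference",
    "similarity_centroid",
]


def _check_coords(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise UsageError(f"{name} must have shape (n_atoms, 3)")
    if X.shape[0] < 3:
        raise DegenerateInputError("need at least 3 atoms for superposition")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateInputError(f"{name} is collinear (rank < 2)")
    return X


def kabsch_rmsd(X, Y, weights=None):
    """Minimal RMSD between conformations and the optimal rigid transform.

    Returns ``(rmsd, R, t)`` such that ``Y @ R.T + t`` superposes Y onto X;
    R is a proper rotation (det = +1).
    """
    X = _check_coords(X, "X")
    Y = _check_coords(Y, "Y")
    if X.shape != Y.shape:
        raise UsageError("coordinate sets must have equal atom counts")
    if weights is None:
        w = np.ones(X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    x_mean = (w[:, None] * X).sum(axis=0) / wsum
    y_mean = (w[:, None] * Y).sum(axis=0) / wsum
    Xc, Yc = X - x_mean, Y - y_mean
    rot, rssd = Rotation.align_vectors(Xc, Yc, weights=w)
    R = rot.as_matrix()
    t = x_mean - y_mean @ R.T
    rmsd = rssd / np.sqrt(wsum)
    return float(rmsd), R, t


def superpose_onto(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``coords`` (F, n, 3) onto ``ref`` (n, 3)."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        _, R, t = kabsch_rmsd(ref, coords[f])
        out[f] = coords[f] @ R.T + t
    return out


def iterative_mean(coords: np.ndarray, passes: int = 2):
    """Mean structure by iterative superposition onto the running mean.

    Pass 1 aligns to the first frame and averages; each further pass aligns to
    the previous mean.  Returns ``(mean, aligned_frames)``.  Two passes are the
    package-wide convention, shared by RMSF and PCA.
    """
    ref = coords[0]
    for _ in range(passes):
        aligned = superpose_onto(coords, ref)
        ref = aligned.mean(axis=0)
    # final alignment onto the converged mean, so any later superposition onto
    # this mean (e.g. PCA projection) reproduces the same aligned frames
    aligned = superpose_onto(coords, ref)
    return ref, aligned


@dataclass(eq=False)
class DistanceMatrix:
    """Symmetric pairwise RMSD matrix (Å internally)."""

    values: np.ndarray  # (n, n) Å
    selection: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise UsageError("distance matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def values_nm(self) -> np.ndarray:
        return self.values / 10.0

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6f")


def pairwise_rmsd_matrix(
    coords: np.ndarray,
    topology: ToyTopology | None = None,
    selection=None,
) -> DistanceMatrix:
    """All-pairs minimal RMSD over a selection, computed once per pair.

    Uses the closed-form Kabsch residual: for centred selections X_i, X_j with
    cross-covariance H = X_iᵀX_j and singular values σ (sign-corrected for
    proper rotations), rmsd² = (|X_i|² + |X_j|² − 2Σσ) / n.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise UsageError("need at least 2 frames")
    if selection is not None:
        if topology is None and isinstance(selection, str):
            raise UsageError("selection expressions require a topology")
        idx = resolve_selection(topology, selection) if topology is not None else np.asarray(selection, int)
        X = coords[:, idx, :]
    else:
        idx = None
        X = coords
    if X.shape[1] == 0:
        raise SelectionError("empty selection")
    F, n, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    sq = (Xc**2).sum(axis=(1, 2))
    D = np.zeros((F, F))
    for i in range(F - 1):
        H = np.einsum("na,mnb->mab", Xc[i], Xc[i + 1 :])
        U, S, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
        trace = S[:, 0] + S[:, 1] + sign * S[:, 2]
        msd = (sq[i] + sq[i + 1 :] - 2.0 * trace) / n
        D[i, i + 1 :] = np.sqrt(np.clip(msd, 0.0, None))
    D = D + D.T
    return DistanceMatrix(values=D, selection=idx)


@dataclass(eq=False)
class FluctuationProfile:
    """Per-atom RMSF (nm) over a frame set, for a fixed selection."""

    values_nm: np.ndarray
    selection: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if np.any(self.values_nm < 0):
            raise UsageError("RMSF values must be non-negative")

    @property
    def values_angstrom(self) -> np.ndarray:
        return self.values_nm * 10.0

    def to_tsv(self, path, topology: ToyTopology | None = None) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {"atom_index": self.selection, "rmsf_nm": self.values_nm}
        )
        if topology is not None:
            df.insert(1, "residue", topology.res_ids[self.selection])
        df.to_csv(path, sep="\t", index=False)


def rmsf(
    coords: np.ndarray,
    topology: ToyTopology | None = None,
    selection=None,
    superpose: bool = True,
    label: str = "",
) -> FluctuationProfile:
    """Root mean square fluctuation about the iterative mean structure.

    RMSF_i = sqrt(⟨|x_i − ⟨x_i⟩|²⟩) over frames, after two superposition
    passes onto the running mean (disable with ``superpose=False`` for raw
    per-atom statistics).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise UsageError("RMSF needs at least 2 frames")
    if selection is not None:
        idx = resolve_selection(topology, selection) if topology is not None else np.asarray(selection, int)
        X = coords[:, idx, :]
    else:
        idx = np.arange(coords.shape[1])
        X = coords
    if superpose:
        mean, aligned = iterative_mean(X)
    else:
        aligned = X
        mean = X.mean(axis=0)
    dev = aligned - mean
    vals = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    return FluctuationProfile(values_nm=vals / 10.0, selection=idx, label=label)


def rmsf_difference(
    profile_mutant: FluctuationProfile, profile_reference: FluctuationProfile
) -> np.ndarray:
    """Elementwise mutant − reference RMSF (nm); selections must match."""
    if profile_mutant.selection.shape != profile_reference.selection.shape or np.any(
        profile_mutant.selection != profile_reference.selection
    ):
        raise UsageError("RMSF profiles use different selections")
    return profile_mutant.values_nm - profile_reference.values_nm


def rmsd_matrix_sigma(matrix: DistanceMatrix) -> float:
    """σ of the similarity score: population standard deviation of the
    off-diagonal upper-triangle entries."""
    iu = np.triu_indices(matrix.n, k=1)
    if iu[0].size == 0:
        return 0.0
    return float(np.std(matrix.values[iu]))


def similarity_centroid(matrix: DistanceMatrix) -> int:
    """Frame maximising the summed similarity score Σ_j exp(−rms_ij/σ).

    With σ = 0 (all frames identical) any frame is equivalent and index 0 is
    returned; ties break to the lowest index.
    """
    if matrix.n < 1:
        raise UsageError("empty matrix")
    sigma = rmsd_matrix_sigma(matrix)
    if sigma == 0.0:
        return 0
    scores = np.exp(-matrix.values / sigma).sum(axis=1)
    return int(np.argmax(scores))
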