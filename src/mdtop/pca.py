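"""Principal component analysis of coordinate covariance.

The covariance is taken over the 3n Cartesian coordinates of a selection after
all frames are superposed onto the two-pass iterative mean (the same routine
RMSF uses), mass-unweighted.  Eigenvalues are stored in Å² internally and
exposed in nm² at the reporting boundary; eigenvector signs follow the
convention that each vector's largest-magnitude component is positive, for
deterministic output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .selection import resolve_selection
from .superpose import iterative_mean, kabsch_rmsd
from .topology import ToyTopology

__all__ = ["PCAModel", "fit_pca", "project", "cumulative_variance"]

_EIG_TOL = 1e-10


@dataclass(eq=False)
class PCAModel:
    mean: np.ndarray  # (n_sel, 3) Å
    eigenvalues: np.ndarray  # (3n,) Å², descending
    eigenvectors: np.ndarray  # (3n, 3n), columns
    selection: np.ndarray
    n_frames: int

    @property
    def eigenvalues_nm2(self) -> np.ndarray:
        return self.eigenvalues / 100.0

    @property
    def rank(self) -> int:
        if self.eigenvalues.size == 0 or self.eigenvalues[0] <= 0:
            return 0
        return int(np.sum(self.eigenvalues > _EIG_TOL * self.eigenvalues[0]))

    @property
    def degenerate(self) -> bool:
        """All-zero spectrum (identical input frames)."""
        return self.rank == 0


def fit_pca(
    coords: np.ndarray,
    topology: ToyTopology | None = None,
    selection=None,
) -> PCAModel:
    """Eigendecomposition of the 3n×3n covariance of superposed coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise UsageError("PCA needs at least 2 frames")
    if selection is not None:
        idx = (
            resolve_selection(topology, selection)
            if topology is not None
            else np.asarray(selection, int)
        )
        X = coords[:, idx, :]
    else:
        idx = np.arange(coords.shape[1])
        X = coords
    mean, aligned = iterative_mean(X)
    F = aligned.shape[0]
    dev = (aligned - mean).reshape(F, -1)
    cov = dev.T @ dev / F
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(evals > -_EIG_TOL * max(abs(evals[0]), 1.0), np.clip(evals, 0.0, None), evals)
    if np.any(evals < 0):
        raise UsageError("covariance produced significantly negative eigenvalues")
    # identical frames leave only superposition round-off (~eps^2 of the
    # coordinate scale); flush that to an exactly zero spectrum
    scale2 = max(float((mean**2).mean()), 1.0)
    if evals[0] < 1e-16 * scale2:
        evals = np.zeros_like(evals)
    # deterministic sign: largest-|component| of each eigenvector positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    return PCAModel(
        mean=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        selection=idx,
        n_frames=F,
    )


def project(
    coords: np.ndarray, model: PCAModel, n_components: int
) -> np.ndarray:
    """Per-frame scores on the leading components (Å units).

    Frames are superposed onto the model mean before projecting the flattened
    deviation onto the eigenvectors.
    """
    if n_components < 1 or n_components > max(model.rank, 1):
        raise UsageError(
            f"n_components={n_components} exceeds model rank {model.rank}"
        )
    coords = np.asarray(coords, dtype=float)
    X = coords[:, model.selection, :] if coords.shape[1] != model.mean.shape[0] else coords
    scores = np.empty((X.shape[0], n_components))
    vecs = model.eigenvectors[:, :n_components]
    for f in range(X.shape[0]):
        _, R, t = kabsch_rmsd(model.mean, X[f])
        aligned = X[f] @ R.T + t
        scores[f] = (aligned - model.mean).ravel() @ vecs
    return scores


def cumulative_variance(model: PCAModel) -> np.ndarray:
    """Non-decreasing cumulative variance fractions per component count."""
    total = model.eigenvalues.sum()
    if total <= 0:
        return np.zeros_like(model.eigenvalues)
    return np.cumsum(model.eigenvalues) / total
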