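"""Lossless Gram-Schmidt compression of voxel beta-series.

The trial patterns of one subject span an (at most) n-trial-dimensional
subspace of voxel space. Modified Gram-Schmidt with re-orthogonalisation
builds an orthonormal basis of that span in chronological trial order;
projecting the patterns onto it yields an exactly n_trials-dimensional
coordinate system that preserves all inner products (and hence any linear
classifier's geometry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lss import BetaSeries

__all__ = ["GSBasis", "gs_fit_project", "gs_reconstruct", "RankDeficiencyError"]


class RankDeficiencyError(np.linalg.LinAlgError):
    """A trial pattern is (numerically) linearly dependent on earlier ones."""


@dataclass
class GSBasis:
    """Orthonormal basis of the trial-pattern span.

    ``matrix`` is features x n_trials; columns follow the construction
    (chronological trial) order.
    """

    matrix: np.ndarray
    order: np.ndarray
    rank_tol: float

    def __post_init__(self) -> None:
        q = self.matrix
        gram = q.T @ q
        if np.max(np.abs(gram - np.eye(q.shape[1]))) > 1e-8:
            raise ValueError("basis columns are not orthonormal")


def gs_fit_project(betas: BetaSeries, rank_tol: float = 1e-10
                   ) -> tuple[GSBasis, BetaSeries]:
    """Build the orthonormal basis and project the betas onto it.

    Raises :class:`RankDeficiencyError`, naming the offending trial, when a
    pattern's residual after projection onto the earlier patterns is below
    ``rank_tol`` times its original norm.
    """
    x = betas.data
    n_trials, n_feat = x.shape
    if n_feat < n_trials:
        raise ValueError("feature count must be >= trial count")
    q = np.empty((n_feat, n_trials))
    for t in range(n_trials):
        v = x[t].copy()
        orig = np.linalg.norm(v)
        for _ in range(2):  # re-orthogonalise for numerical stability
            v -= q[:, :t] @ (q[:, :t].T @ v)
        norm = np.linalg.norm(v)
        if orig == 0 or norm < rank_tol * orig:
            raise RankDeficiencyError(
                f"trial {t} (stimulus {betas.stimulus_ids[t]!r}) is linearly "
                "dependent on earlier trials within tolerance")
        q[:, t] = v / norm
    basis = GSBasis(matrix=q, order=np.arange(n_trials), rank_tol=rank_tol)
    coords = BetaSeries(data=x @ q, modality="GS",
                        stimulus_ids=betas.stimulus_ids, subject=betas.subject)
    return basis, coords


def gs_reconstruct(coords: BetaSeries, basis: GSBasis) -> BetaSeries:
    """Map coordinates back to voxel space (exact on the span)."""
    if coords.data.shape[1] != basis.matrix.shape[1]:
        raise ValueError("coordinate dimension does not match basis")
    return BetaSeries(data=coords.data @ basis.matrix.T, modality="GM",
                      stimulus_ids=coords.stimulus_ids, subject=coords.subject)
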