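"""Principal coordinate analysis (classical Torgerson scaling) and axis scaling.

PCoA embeds a dissimilarity matrix D by eigendecomposing
B = -1/2 * J * D^(2) * J (J the centering projector, D^(2) elementwise
squares). Coordinates on axis m are eigenvector_m * sqrt(lambda_m) for the
largest positive eigenvalues. Log-DTW dissimilarities are non-Euclidean, so
negative eigenvalues are expected; they are dropped without correction and the
full spectrum is kept on the result so the distortion can be inspected.

Eigenvector sign is arbitrary, which would flip downstream city contrasts
between runs; each axis is therefore oriented so its largest-magnitude
coordinate is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = ["Ordination", "pcoa", "standardize"]


@dataclass(frozen=True)
class Ordination:
    """Per-call coordinates on the retained principal axes.

    ``eigenvalues`` holds the retained (positive) eigenvalues in non-increasing
    order; ``proportion_explained`` is each retained eigenvalue over the sum of
    all positive eigenvalues; ``spectrum`` is the full eigenvalue spectrum,
    including any negative part, for diagnostics.
    """

    ids: tuple
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    proportion_explained: np.ndarray  # (k,)
    spectrum: np.ndarray  # (n,) non-increasing

    def axis(self, m: int) -> np.ndarray:
        """Coordinates on axis ``m`` (0-based: axis(0) is PC1)."""
        return self.coordinates[:, m]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pc{m + 1}": self.coordinates[:, m] for m in range(self.coordinates.shape[1])}
        return pd.DataFrame({"call_id": list(self.ids), **cols})

    def eigenvalue_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": np.arange(1, len(self.spectrum) + 1),
                "eigenvalue": self.spectrum,
            }
        )


def pcoa(dm: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical metric multidimensional scaling of ``dm`` onto ``k`` axes.

    Raises ``ValueError`` (reporting the spectrum) if fewer than ``k``
    eigenvalues are positive.
    """
    d = dm.values
    n = d.shape[0]
    if n < 3:
        raise ValueError("pcoa requires at least 3 objects")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2  # enforce exact symmetry before eigh
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    n_pos = int((eigval > tol).sum())
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive eigenvalues, cannot extract {k} axes; spectrum: {eigval}"
        )
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    # deterministic orientation: largest-magnitude coordinate positive per axis
    for m in range(k):
        col = coords[:, m]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, m] = -col
    pos_sum = eigval[eigval > tol].sum()
    return Ordination(
        ids=tuple(dm.ids),
        coordinates=coords,
        eigenvalues=eigval[:k].copy(),
        proportion_explained=eigval[:k] / pos_sum,
        spectrum=eigval.copy(),
    )


def standardize(values) -> np.ndarray:
    """Center and scale to sample mean 0, sample SD 1 (denominator n - 1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("standardize requires a 1-D array of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("standardize requires nonzero, finite sample SD")
    return (x - x.mean()) / sd
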