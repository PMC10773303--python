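"""Pairwise dynamic-time-warping distances between conditioned f0 traces.

DTW aligns two frequency contours by a monotone warping path and returns the
minimal cumulative |a_i - b_j| cost. The default step pattern is the standard
symmetric one with a diagonal weight of 2 (``symmetric2``):

    D[i, j] = min( D[i-1, j-1] + 2*d(i, j),
                   D[i-1, j]   +   d(i, j),
                   D[i, j-1]   +   d(i, j) ),   D[0, 0] = d(0, 0)

whose total weight along any path is len(a) + len(b); the normalized distance
divides by that, making traces of different lengths comparable.

Distances are computed on raw Hz — absolute frequency differences are the
dialect signal — and the full matrix is then log-transformed (after adding a
small epsilon so exact duplicates do not produce log 0) and shifted to be
nonnegative, which the downstream principal-coordinate embedding requires.

Note DTW is not a metric (the triangle inequality can fail), so the distance
matrix is generally non-Euclidean; the ordination step tolerates this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError

__all__ = [
    "DtwConfig",
    "DistanceMatrix",
    "dtw_distance",
    "pairwise_distances",
    "normalize_log",
    "read_distance_matrix",
]


@dataclass(frozen=True)
class DtwConfig:
    """DTW settings.

    step_pattern : only ``symmetric2`` is implemented (the common default).
    window : optional Sakoe-Chiba band half-width in samples (None = no
        constraint).
    normalize : divide the cumulative cost by len(a) + len(b).
    log_eps : offset added before the log transform; None means
        (smallest positive off-diagonal distance) * 1e-3, chosen per matrix.
    """

    step_pattern: str = "symmetric2"
    window: int | None = None
    normalize: bool = True
    log_eps: float | None = None

    def __post_init__(self):
        if self.step_pattern != "symmetric2":
            raise ConfigurationError(f"unsupported step pattern {self.step_pattern!r}")
        if self.window is not None and self.window < 1:
            raise ConfigurationError("window must be >= 1 sample or None")
        if self.log_eps is not None and self.log_eps <= 0:
            raise ConfigurationError("log_eps must be > 0")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities keyed by call id."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"distance matrix shape {vals.shape} does not match {n} ids")
        if not np.all(np.isfinite(vals)):
            raise ValueError("distance matrix has non-finite entries")
        if np.max(np.abs(vals - vals.T)) > 1e-9:
            raise ValueError("distance matrix is not symmetric within 1e-9")
        if np.any(np.abs(np.diag(vals)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="call_id")

    def to_long(self) -> pd.DataFrame:
        """Long format (call_a, call_b, distance) over unordered pairs."""
        iu, ju = np.triu_indices(len(self.ids), k=1)
        return pd.DataFrame(
            {
                "call_a": [self.ids[i] for i in iu],
                "call_b": [self.ids[j] for j in ju],
                "distance": self.values[iu, ju],
            }
        )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(str(c) for c in df.columns), df.to_numpy(float))


@njit(cache=True)
def _dtw_cost(a, b, window):  # pragma: no cover - numba kernel
    n, m = len(a), len(b)
    big = 1e300
    prev = np.full(m, big)
    curr = np.full(m, big)
    for i in range(n):
        lo, hi = 0, m
        if window >= 0:
            lo = max(0, i - window)
            hi = min(m, i + window + 1)
        curr[:] = big
        for j in range(lo, hi):
            d = abs(a[i] - b[j])
            if i == 0 and j == 0:
                curr[j] = d
                continue
            best = big
            if i > 0 and j > 0 and prev[j - 1] < big:
                c = prev[j - 1] + 2.0 * d
                if c < best:
                    best = c
            if i > 0 and prev[j] < big:
                c = prev[j] + d
                if c < best:
                    best = c
            if j > lo and curr[j - 1] < big:
                c = curr[j - 1] + d
                if c < best:
                    best = c
            curr[j] = best
        prev, curr = curr, prev
    return prev[m - 1]


def dtw_distance(a, b, cfg: DtwConfig | None = None) -> float:
    """DTW distance between two f0 sequences (Hz) under ``cfg``."""
    cfg = cfg or DtwConfig()
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("dtw_distance requires sequences of length >= 2")
    window = -1 if cfg.window is None else max(cfg.window, abs(len(a) - len(b)))
    cost = _dtw_cost(a, b, window)
    if not np.isfinite(cost):
        raise ValueError("no admissible warping path (window too narrow)")
    if cfg.normalize:
        cost /= len(a) + len(b)
    return float(cost)


def pairwise_distances(traces, cfg: DtwConfig | None = None) -> DistanceMatrix:
    """All n(n-1)/2 DTW distances between traces, in input order."""
    cfg = cfg or DtwConfig()
    traces = list(traces)
    if len(traces) < 3:
        raise ValueError("pairwise_distances requires >= 3 traces")
    ids = tuple(t.call_id for t in traces)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate call ids in trace set")
    n = len(traces)
    out = np.zeros((n, n))
    seqs = [np.ascontiguousarray(t.f0, dtype=float) for t in traces]
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = dtw_distance(seqs[i], seqs[j], cfg)
            except Exception as exc:
                raise ValueError(f"DTW failed for pair ({ids[i]!r}, {ids[j]!r}): {exc}") from exc
    return DistanceMatrix(ids, out)


def normalize_log(dm: DistanceMatrix, cfg: DtwConfig | None = None) -> DistanceMatrix:
    """Log-transform off-diagonal distances, then shift to nonnegativity.

    Off-diagonal entries become log(d + eps); if the minimum transformed value
    is negative (log of distances < 1), that minimum is subtracted from every
    off-diagonal entry so the matrix is a valid dissimilarity input for
    principal coordinate analysis. The diagonal stays 0 and monotone order of
    entries is preserved.
    """
    cfg = cfg or DtwConfig()
    vals = dm.values
    if np.any(vals < 0):
        raise ValueError("normalize_log requires nonnegative distances")
    n = len(dm.ids)
    off = ~np.eye(n, dtype=bool)
    eps = cfg.log_eps
    if eps is None:
        positive = vals[off & (vals > 0)]
        if positive.size == 0:
            raise ValueError("all off-diagonal distances are zero; set log_eps explicitly")
        eps = float(positive.min()) * 1e-3
    out = np.zeros_like(vals)
    out[off] = np.log(vals[off] + eps)
    shift = out[off].min()
    if shift < 0:
        out[off] -= shift
    return DistanceMatrix(dm.ids, out)
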