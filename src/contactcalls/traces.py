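"""Fundamental-frequency trace conditioning.

Field recordings yield per-call fundamental-frequency (f0) traces in which the
tracker occasionally loses the harmonic: those samples arrive with an empty f0
field. Conditioning happens in two steps, in this order:

1. :func:`fill_gaps` — detection gaps are bridged with a straight line between
   the flanking detected points, on a uniform time grid (default 1 ms).
   Undetected leading/trailing regions are dropped, never extrapolated.
2. :func:`smooth_trace` — a cubic smoothing spline removes single-sample
   tracking outliers. The smoothing penalty is parameterized by ``spar``
   (default 0.4) using the classical mapping lambda = r * 256**(3*spar - 1)
   with r = tr(X'X)/tr(Omega) computed on the time axis rescaled to [0, 1],
   so the same ``spar`` means a comparable amount of smoothing regardless of
   trace length or duration.

Outlier handling is done solely by the spline; there is no explicit point
rejection. :func:`qc_report` exposes per-trace residual RMS so unusually noisy
traces can be screened by thresholding instead of by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import ConfigurationError, TraceError

__all__ = [
    "CallTrace",
    "SmoothingConfig",
    "read_traces",
    "write_traces",
    "fill_gaps",
    "smooth_trace",
    "qc_report",
]


@dataclass(frozen=True)
class CallTrace:
    """One call's f0 contour: strictly increasing times (s), f0 (Hz).

    ``gap_mask`` flags samples that were created by interpolation (or, before
    gap filling, samples whose f0 the tracker failed to detect, stored as NaN).
    """

    call_id: str
    times: np.ndarray
    f0: np.ndarray
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        f0 = np.asarray(self.f0, dtype=float)
        if times.ndim != 1 or f0.ndim != 1 or len(times) != len(f0):
            raise TraceError(f"trace {self.call_id!r}: times and f0 must be 1-D and equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise TraceError(f"trace {self.call_id!r}: times must be strictly increasing")
        gap = self.gap_mask
        if gap is None:
            gap = np.isnan(f0)
        gap = np.asarray(gap, dtype=bool)
        if len(gap) != len(times):
            raise TraceError(f"trace {self.call_id!r}: gap_mask length mismatch")
        gap = gap | np.isnan(f0)  # undetected samples are gaps regardless of the mask
        detected = f0[~gap]
        if np.any(~np.isfinite(detected)) or np.any(detected <= 0):
            raise TraceError(f"trace {self.call_id!r}: detected f0 values must be finite and > 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "gap_mask", gap)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of samples the tracker actually detected."""
        return ~self.gap_mask & np.isfinite(self.f0)


@dataclass(frozen=True)
class SmoothingConfig:
    """Spline smoothing parameters.

    spar : smoothing parameter in (0, 1]; larger is smoother. 0.4 is the
        conventional setting for f0 traces of this kind.
    step : uniform resampling step in seconds used by gap filling.
    """

    spar: float = 0.4
    step: float = 0.001

    def __post_init__(self):
        if not (0 < self.spar <= 1):
            raise ConfigurationError(f"spar must be in (0, 1], got {self.spar}")
        if self.step <= 0:
            raise ConfigurationError(f"step must be > 0, got {self.step}")


def read_traces(path) -> list[CallTrace]:
    """Read a trace CSV (``call_id,time_s,f0_hz``; empty f0 marks a gap).

    Rows may arrive in any order; each call's samples are sorted by time.
    Duplicate (call_id, time) pairs and empty files are errors.
    """
    df = pd.read_csv(path, dtype={"call_id": str})
    required = {"call_id", "time_s", "f0_hz"}
    if not required.issubset(df.columns):
        raise TraceError(f"trace file {path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        raise TraceError(f"trace file {path} contains no samples")
    dup = df.duplicated(subset=["call_id", "time_s"])
    if dup.any():
        bad = df.loc[dup, "call_id"].unique()
        raise TraceError(f"duplicate (call_id, time) pairs for call(s): {', '.join(map(str, bad))}")
    traces = []
    for call_id, grp in df.groupby("call_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            CallTrace(
                call_id=str(call_id),
                times=grp["time_s"].to_numpy(float),
                f0=grp["f0_hz"].to_numpy(float),
            )
        )
    return traces


def write_traces(traces, path) -> None:
    """Write traces in the same CSV dialect ``read_traces`` accepts."""
    frames = [
        pd.DataFrame({"call_id": t.call_id, "time_s": t.times, "f0_hz": t.f0})
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _infer_step(times: np.ndarray) -> float:
    d = np.diff(times)
    if len(d) == 0:
        raise TraceError("cannot infer sampling step from a single sample")
    return float(np.median(d))


def fill_gaps(trace: CallTrace, step: float | None = None) -> CallTrace:
    """Bridge detection gaps with straight lines on a uniform time grid.

    The output grid runs from the first to the last *detected* sample at
    ``step`` seconds (default: the median spacing of the input rows), so
    leading/trailing undetected regions are dropped rather than extrapolated.
    Grid samples farther than step/2 from any detected input sample are marked
    in ``gap_mask``. Idempotent: gap-filling a gap-filled trace is a no-op.
    """
    det = trace.detected
    if det.sum() < 2:
        raise TraceError(f"trace {trace.call_id!r}: need >=2 detected samples to fill gaps")
    t_det = trace.times[det]
    f_det = trace.f0[det]
    if step is None:
        step = _infer_step(trace.times)
    n = int(round((t_det[-1] - t_det[0]) / step))
    grid = t_det[0] + step * np.arange(n + 1)
    f_grid = np.interp(grid, t_det, f_det)
    # a grid point counts as detected if a detected input sample lies within
    # half a step of it
    idx = np.searchsorted(t_det, grid)
    idx_lo = np.clip(idx - 1, 0, len(t_det) - 1)
    idx_hi = np.clip(idx, 0, len(t_det) - 1)
    nearest = np.minimum(np.abs(grid - t_det[idx_lo]), np.abs(t_det[idx_hi] - grid))
    gap_mask = nearest > step / 2 + 1e-12
    return CallTrace(trace.call_id, grid, f_grid, gap_mask=gap_mask)


def _penalty_matrix(knots: np.ndarray, m: int) -> np.ndarray:
    """Omega_ij = integral of B_i'' B_j'' over the knot span.

    B'' of a cubic B-spline is piecewise linear, so 2-point Gauss-Legendre per
    knot interval integrates the products exactly.
    """
    spl = BSpline(knots, np.eye(m), 3, extrapolate=False)
    d2 = spl.derivative(2)
    uniq = np.unique(knots)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    omega = np.zeros((m, m))
    for a, b in zip(uniq[:-1], uniq[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gauss
        vals = d2(pts)  # (2, m)
        vals = np.nan_to_num(vals)
        omega += half * (vals.T @ vals)  # both Gauss weights are 1
    return omega


def _smoothing_spline(x: np.ndarray, y: np.ndarray, spar: float) -> np.ndarray:
    """Penalized cubic B-spline fit evaluated at x; knots at the data sites."""
    t0, t1 = x[0], x[-1]
    xs = (x - t0) / (t1 - t0)  # scale to [0, 1] so spar is length-invariant
    n = len(xs)
    knots = np.concatenate([[xs[0]] * 4, xs[1:-1], [xs[-1]] * 4])
    m = n + 2
    design = BSpline.design_matrix(xs, knots, 3).toarray()
    omega = _penalty_matrix(knots, m)
    xtx = design.T @ design
    r = np.trace(xtx) / np.trace(omega)
    lam = r * 256.0 ** (3.0 * spar - 1.0)
    coef = np.linalg.solve(xtx + lam * omega, design.T @ y)
    return design @ coef


def smooth_trace(trace: CallTrace, cfg: SmoothingConfig | None = None) -> CallTrace:
    """Replace f0 by a cubic smoothing-spline fit at the original sample times.

    Requires a gap-filled trace (no NaN f0) with at least 4 samples. The time
    grid and gap_mask are preserved exactly.
    """
    cfg = cfg or SmoothingConfig()
    if len(trace) < 4:
        raise TraceError(f"trace {trace.call_id!r}: need >=4 samples to smooth, got {len(trace)}")
    if np.any(~np.isfinite(trace.f0)):
        raise TraceError(f"trace {trace.call_id!r}: fill gaps before smoothing (NaN f0 present)")
    fitted = _smoothing_spline(trace.times, trace.f0, cfg.spar)
    return replace(trace, f0=fitted)


def qc_report(raw, smoothed) -> pd.DataFrame:
    """Per-trace residual RMS between raw (gap-filled) and smoothed f0.

    Large residuals indicate traces the spline had to correct heavily; users
    can threshold this column instead of visual inspection.
    """
    rows = []
    for a, b in zip(raw, smoothed):
        if a.call_id != b.call_id or len(a) != len(b):
            raise TraceError("qc_report expects matching raw/smoothed trace lists")
        rows.append(
            {
                "call_id": a.call_id,
                "n_samples": len(a),
                "n_gap_samples": int(a.gap_mask.sum()),
                "residual_rms_hz": float(np.sqrt(np.mean((a.f0 - b.f0) ** 2))),
            }
        )
    return pd.DataFrame(rows)
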