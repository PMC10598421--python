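"""Sprint-speed extraction from frame-by-frame tracking coordinates.

A trial is a series of (frame, x, y) pixel coordinates of a running spider,
tracked at 100-500 fps. The processing chain is

1. per-interval velocities: pixel displacement -> cm (via the pixels-per-cm
   scale in the video) -> cm/s (via the frame rate);
2. a cubic smoothing spline over the velocity series with K = floor(N/2) + 1
   knots (N = number of frames), penalty chosen by generalized
   cross-validation — this removes the gait oscillation of the body centre
   so that the maximum reflects whole-animal translation;
3. per-trial mean and sprint (= maximum of the smoothed series) speed, both
   absolute (cm/s) and relative (body lengths per second);
4. aggregation: per individual the maximum sprint over its trials, per
   species the mean over its individuals.

Trials where the animal did not run in a roughly constant direction are
dropped by a straightness filter (net displacement / path length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

__all__ = [
    "Trajectory",
    "SpeedSeries",
    "SpeedSummary",
    "frame_velocities",
    "smooth_speed",
    "trial_summary",
    "aggregate",
    "straightness_filter",
    "process_trial",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

MIN_FRAMES = 10
FPS_RANGE = (100.0, 750.0)


@dataclass
class Trajectory:
    """Raw tracking data for one trial plus the metadata needed for scaling."""

    frame: np.ndarray          # strictly increasing frame indices
    x_px: np.ndarray
    y_px: np.ndarray
    fps: float
    px_per_cm: float
    body_length_cm: float
    species: str = ""
    individual: str = ""
    trial: str = ""

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if len(self.frame) != len(self.x_px) or len(self.frame) != len(self.y_px):
            raise ValueError("frame/x/y lengths differ")
        d = np.diff(self.frame)
        if np.any(d == 0):
            raise ValueError("duplicate frame index in trajectory")
        if np.any(d < 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.px_per_cm <= 0 or self.body_length_cm <= 0 or self.fps <= 0:
            raise ValueError("fps, px_per_cm and body_length_cm must be positive")
        if len(self.frame) < MIN_FRAMES:
            raise ValueError(f"need at least {MIN_FRAMES} frames, got {len(self.frame)}")
        if not FPS_RANGE[0] <= self.fps <= FPS_RANGE[1]:
            import warnings
            warnings.warn(f"fps={self.fps} outside the typical range {FPS_RANGE}")

    @property
    def n_frames(self) -> int:
        return len(self.frame)


@dataclass
class SpeedSeries:
    """Per-interval velocities (cm/s) at frame-midpoint times, raw and smoothed."""

    times: np.ndarray           # midpoint times, s
    raw: np.ndarray             # cm/s, length N-1
    smoothed: np.ndarray | None = None
    knots: int = 0


@dataclass
class SpeedSummary:
    species: str
    individual: str
    trial: str
    mean_abs: float             # cm/s, mean of smoothed series
    sprint_abs: float           # cm/s, max of smoothed series
    mean_rel: float             # bl/s
    sprint_rel: float           # bl/s
    mean_abs_raw: float = np.nan
    straightness: float = np.nan


def frame_velocities(traj: Trajectory) -> SpeedSeries:
    """Velocity between consecutive tracked frames, gap-aware: a k-frame gap
    divides the displacement by k/fps."""
    dt = np.diff(traj.frame) / traj.fps
    disp_px = np.hypot(np.diff(traj.x_px), np.diff(traj.y_px))
    v = disp_px / traj.px_per_cm / dt
    t = (traj.frame[:-1] + traj.frame[1:]) / 2.0 / traj.fps
    return SpeedSeries(times=t, raw=v)


def n_knots(n_frames: int) -> int:
    """The study's knot rule: N/2 + 1 (floor for odd N)."""
    return n_frames // 2 + 1


# -- penalized regression spline with GCV --------------------------------

def _second_deriv_penalty(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Exact Gram matrix of second derivatives of the B-spline basis.

    B'' of a cubic B-spline is piecewise linear, so 2-point Gauss-Legendre
    per knot interval integrates the products exactly.
    """
    nb = len(knots) - degree - 1
    spans = np.unique(knots)
    lo, hi = spans[:-1], spans[1:]
    half = (hi - lo) / 2.0
    mid = (lo + hi) / 2.0
    g = 1.0 / np.sqrt(3.0)
    pts = np.concatenate([mid - half * g, mid + half * g])
    w = np.concatenate([half, half])
    D2 = BSpline(knots, np.eye(nb), degree).derivative(2)(pts)
    return (D2 * w[:, None]).T @ D2


def smooth_speed(series: SpeedSeries, n_frames: int | None = None,
                 knots: int | None = None) -> SpeedSeries:
    """Cubic smoothing spline over the raw velocity series.

    Knots are placed at quantiles of the observation times; the roughness
    penalty (integrated squared second derivative) is weighted by a factor
    chosen by minimizing the GCV score. Negative fitted speeds are clipped
    to 0 (speed is a magnitude). Returns a new SpeedSeries with
    ``smoothed`` filled in.
    """
    x, y = series.times, series.raw
    m = len(x)
    if m < 4:
        raise ValueError("too few velocity points to smooth; drop this trial")
    if knots is None:
        knots = n_knots(m + 1 if n_frames is None else n_frames)
    k = min(max(knots, 4), len(np.unique(x)))
    qs = np.quantile(np.unique(x), np.linspace(0, 1, k))
    qs = np.unique(qs)
    t = np.concatenate([[qs[0]] * 3, qs, [qs[-1]] * 3])   # cubic, clamped
    B = BSpline.design_matrix(x, t, 3, extrapolate=False).toarray()
    BtB = B.T @ B
    Bty = B.T @ y
    P = _second_deriv_penalty(t)
    scale = np.trace(BtB) / max(np.trace(P), 1e-300)

    def gcv(loglam: float) -> float:
        lam = 10.0 ** loglam * scale
        A = BtB + lam * P
        try:
            fac = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        coef = cho_solve(fac, Bty)
        fitted = B @ coef
        edf = float(np.trace(cho_solve(fac, BtB)))
        rss = float(np.sum((y - fitted) ** 2))
        denom = (1.0 - edf / m) ** 2
        if denom <= 0:
            return np.inf
        return rss / m / denom

    grid = np.linspace(-9, 5, 29)
    scores = [gcv(g) for g in grid]
    g0 = grid[int(np.argmin(scores))]
    res = minimize_scalar(gcv, bounds=(g0 - 1.0, g0 + 1.0), method="bounded")
    lam = 10.0 ** float(res.x) * scale
    coef = np.linalg.solve(BtB + lam * P, Bty)
    sm = np.clip(B @ coef, 0.0, None)
    return SpeedSeries(times=x, raw=y, smoothed=sm, knots=k)


def trial_summary(traj: Trajectory, smoothed: SpeedSeries) -> SpeedSummary:
    """Mean and sprint (max of smoothed) speed, absolute and in body lengths/s."""
    if smoothed.smoothed is None:
        raise ValueError("run smooth_speed first")
    sm = smoothed.smoothed
    mean_abs = float(np.mean(sm))
    sprint_abs = float(np.max(sm))
    bl = traj.body_length_cm
    return SpeedSummary(
        species=traj.species, individual=traj.individual, trial=traj.trial,
        mean_abs=mean_abs, sprint_abs=sprint_abs,
        mean_rel=mean_abs / bl, sprint_rel=sprint_abs / bl,
        mean_abs_raw=float(np.mean(smoothed.raw)),
    )


def straightness_filter(traj: Trajectory, threshold: float = 0.9) -> tuple[bool, float]:
    """Keep trials where the spider ran in a roughly constant direction.

    Straightness = net displacement / total path length in [0, 1]; 1 is a
    perfectly straight run, 0 a closed loop or out-and-back path.
    """
    # coarsen to ~20 segments so the index measures direction constancy,
    # not frame-scale tracking jitter or gait wiggle
    step = max(1, traj.n_frames // 20)
    xs = np.append(traj.x_px[::step], traj.x_px[-1])
    ys = np.append(traj.y_px[::step], traj.y_px[-1])
    dx = np.diff(xs)
    dy = np.diff(ys)
    path = float(np.sum(np.hypot(dx, dy)))
    net = float(np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
    if path == 0:
        return False, 0.0
    s = net / path
    return s >= threshold, s


def process_trial(traj: Trajectory, straightness_threshold: float = 0.9,
                  apply_filter: bool = True) -> SpeedSummary | None:
    """Full single-trial chain; returns None when the straightness filter drops
    the trial."""
    keep, s = straightness_filter(traj, straightness_threshold)
    if apply_filter and not keep:
        return None
    series = frame_velocities(traj)
    sm = smooth_speed(series, n_frames=traj.n_frames)
    out = trial_summary(traj, sm)
    out.straightness = s
    return out


def aggregate(summaries: list[SpeedSummary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual table (max sprint over trials) and species table (mean over
    individuals). Raises on summaries lacking individual/species ids."""
    if not summaries:
        raise ValueError("no trial summaries to aggregate")
    rows = pd.DataFrame([vars(s) for s in summaries])
    if rows["individual"].eq("").any() or rows["species"].eq("").any():
        raise ValueError("trial summary with missing species/individual id")
    ind = (rows.groupby(["species", "individual"])
               .agg(sprint_rel=("sprint_rel", "max"),
                    sprint_abs=("sprint_abs", "max"),
                    mean_rel=("mean_rel", "mean"),
                    n_trials=("trial", "count"))
               .reset_index())
    sp = (ind.groupby("species")
             .agg(sprint_rel=("sprint_rel", "mean"),
                  sprint_abs=("sprint_abs", "mean"),
                  mean_rel=("mean_rel", "mean"),
                  n_individuals=("individual", "count"))
             .reset_index())
    return ind, sp


# -- CSV interface -------------------------------------------------------

_META_KEYS = ("fps", "px_per_cm", "body_length_cm", "species", "individual", "trial")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """CSV with '# key = value' metadata header then frame,x_px,y_px rows."""
    with open(path, "w") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key} = {getattr(traj, key)}\n")
        fh.write("frame,x_px,y_px\n")
        for f, x, y in zip(traj.frame, traj.x_px, traj.y_px):
            fh.write(f"{int(f)},{x:.4f},{y:.4f}\n")


def read_trajectory_csv(path) -> Trajectory:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip)
    missing = [k for k in ("fps", "px_per_cm", "body_length_cm") if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing metadata {missing}")
    return Trajectory(
        frame=df["frame"].to_numpy(), x_px=df["x_px"].to_numpy(),
        y_px=df["y_px"].to_numpy(),
        fps=float(meta["fps"]), px_per_cm=float(meta["px_per_cm"]),
        body_length_cm=float(meta["body_length_cm"]),
        species=meta.get("species", ""), individual=meta.get("individual", ""),
        trial=meta.get("trial", ""),
    )
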