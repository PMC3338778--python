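"""Mean-square-displacement curves and randomness diagnostics.

Two curve modes are supported: the standard squared net displacement per lag
(``displacement``), and the squared cumulative path length from the start of
the recording (``path_squared``).  A linear regression of the curve gives an
x-intercept diagnostic — a line through the origin is consistent with an
uncorrelated random walk — and a persistent-random-walk closed form
``MSD(tau) = 2 S^2 P [tau - P (1 - exp(-tau/P))]`` can be fitted to extract a
speed S and persistence time P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .track_metrics import Track

__all__ = [
    "MsdCurve",
    "RegressionFit",
    "PrwFit",
    "displacement_msd",
    "path_squared_curve",
    "linear_fit",
    "fit_persistent_walk",
    "prw_msd",
    "randomness_diagnostic",
    "CONSISTENT_WITH_RANDOM",
    "NOT_CONSISTENT",
    "default_lags",
]

CONSISTENT_WITH_RANDOM = "consistent_with_random"
NOT_CONSISTENT = "not_consistent"


def default_lags() -> list[float]:
    """Lag grid used throughout: every 20 min up to 120 min."""
    return [20.0, 40.0, 60.0, 80.0, 100.0, 120.0]


@dataclass(frozen=True)
class MsdCurve:
    mode: str  # "displacement" | "path_squared"
    lags_min: np.ndarray
    mean_squares_um2: np.ndarray
    n_tracks: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_min, dtype=float)
        vals = np.asarray(self.mean_squares_um2, dtype=float)
        if lags.size != vals.size:
            raise ValueError("lags and values must have equal length")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(vals < -1e-12):
            raise ValueError("mean squares must be non-negative")
        object.__setattr__(self, "lags_min", lags)
        object.__setattr__(self, "mean_squares_um2", vals)


@dataclass(frozen=True)
class RegressionFit:
    slope: float  # um^2 / min
    intercept: float  # um^2
    x_intercept: float  # min; nan when slope == 0
    r_squared: float


@dataclass(frozen=True)
class PrwFit:
    S: float  # um/min
    P: float  # min
    rss: float
    ballistic: bool = False


def _lag_steps(track: Track, lags_min: Sequence[float]) -> list[int]:
    steps = []
    for lag in lags_min:
        k = lag / track.dt_min
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"lag {lag} min is not a multiple of dt = {track.dt_min} min"
            )
        k = int(round(k))
        if k < 1 or k > track.n_points - 1:
            raise ValueError(
                f"lag {lag} min out of range for a track of "
                f"{track.n_points} points at dt = {track.dt_min} min"
            )
        steps.append(k)
    return steps


def displacement_msd(
    tracks: Sequence[Track],
    lags_min: Sequence[float] | None = None,
    time_average: bool = True,
) -> MsdCurve:
    """Mean squared net displacement per lag.

    With ``time_average`` (default) all overlapping start times within each
    track contribute; otherwise only the displacement from t = 0.
    """
    if not tracks:
        raise ValueError("tracks must be nonempty")
    if lags_min is None:
        lags_min = default_lags()
    steps = _lag_steps(tracks[0], lags_min)
    values = []
    for k in steps:
        per_track = []
        for tr in tracks:
            pos = tr.positions
            if time_average:
                d = pos[k:] - pos[:-k]
            else:
                d = pos[k : k + 1] - pos[0:1]
            per_track.append(np.mean(np.sum(d * d, axis=1)))
        values.append(float(np.mean(per_track)))
    return MsdCurve(
        mode="displacement",
        lags_min=np.asarray(lags_min, float),
        mean_squares_um2=np.asarray(values),
        n_tracks=len(tracks),
    )


def path_squared_curve(
    tracks: Sequence[Track], lags_min: Sequence[float] | None = None
) -> MsdCurve:
    """Mean squared cumulative path length from t = 0 up to each lag."""
    if not tracks:
        raise ValueError("tracks must be nonempty")
    if lags_min is None:
        lags_min = default_lags()
    steps = _lag_steps(tracks[0], lags_min)
    values = []
    for k in steps:
        per_track = []
        for tr in tracks:
            cum = float(tr.step_lengths()[:k].sum())
            per_track.append(cum * cum)
        values.append(float(np.mean(per_track)))
    return MsdCurve(
        mode="path_squared",
        lags_min=np.asarray(lags_min, float),
        mean_squares_um2=np.asarray(values),
        n_tracks=len(tracks),
    )


def linear_fit(curve: MsdCurve) -> RegressionFit:
    """Ordinary least squares of mean square on lag; x-intercept = -b/m."""
    lags = curve.lags_min
    if lags.size < 2:
        raise ValueError("need at least 2 lags for a linear fit")
    res = stats.linregress(lags, curve.mean_squares_um2)
    slope, intercept = float(res.slope), float(res.intercept)
    x_int = -intercept / slope if slope != 0 else float("nan")
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        x_intercept=x_int,
        r_squared=float(res.rvalue**2),
    )


def prw_msd(tau: np.ndarray, S: float, P: float) -> np.ndarray:
    """Persistent-random-walk closed form, linear-through-origin as P -> 0."""
    tau = np.asarray(tau, dtype=float)
    if P <= 0:
        return np.zeros_like(tau)
    return 2.0 * S * S * P * (tau - P * (1.0 - np.exp(-tau / P)))


def fit_persistent_walk(curve: MsdCurve) -> PrwFit:
    """Least-squares (S, P) fit of the persistent-random-walk form.

    Bounded derivative-free minimization from 8 deterministic multi-starts;
    ties broken by lowest residual, then lowest P.  A fit with P at or above
    the largest lag is flagged ballistic (the data cannot distinguish
    persistence times beyond the observation window).
    """
    if curve.mode != "displacement":
        raise ValueError(
            f"persistent-walk fit requires a displacement-mode curve, "
            f"got mode {curve.mode!r}"
        )
    lags = curve.lags_min
    if lags.size < 3:
        raise ValueError("need at least 3 lags to fit (S, P)")
    y = curve.mean_squares_um2
    max_lag = float(lags.max())

    scale = float(np.sqrt(max(y.max(), 1e-30)) / max_lag)  # crude speed scale
    s_hi = max(100.0 * scale, 1.0)
    p_hi = 10.0 * max_lag
    bounds = [(1e-9, s_hi), (1e-6, p_hi)]

    def objective(theta: np.ndarray) -> float:
        resid = prw_msd(lags, theta[0], theta[1]) - y
        return float(resid @ resid)

    starts = [
        (scale * fs, max_lag * fp)
        for fs in (0.5, 2.0)
        for fp in (0.05, 0.25, 1.0, 4.0)
    ]
    best: tuple[float, float, float] | None = None
    for s0, p0 in starts:
        res = optimize.minimize(
            objective,
            x0=np.array([s0, p0]),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        cand = (float(res.fun), float(res.x[1]), float(res.x[0]))
        if best is None or cand < best:
            best = cand
    rss, P, S = best
    return PrwFit(S=S, P=P, rss=rss, ballistic=P >= max_lag)


def randomness_diagnostic(fit: RegressionFit, tol_min: float = 10.0) -> str:
    """Consistent with a simple random walk iff |x-intercept| <= tol_min."""
    if np.isnan(fit.x_intercept):
        import warnings

        warnings.warn(
            "x-intercept undefined (zero slope); reporting not_consistent",
            stacklevel=2,
        )
        return NOT_CONSISTENT
    return (
        CONSISTENT_WITH_RANDOM
        if abs(fit.x_intercept) <= tol_min
        else NOT_CONSISTENT
    )
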