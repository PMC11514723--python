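"""First-order hydrolysis-rate fitting from lipid mole-fraction time courses.

Phospholipase digestion of the accessible POPE pool follows first-order
kinetics toward a plateau, so the normalized decay

    dx(t) = (x_PE(t) - x_inf) / (x0 - x_inf)

is exponential and ln dx(t) = -k t is a straight line.  Late in the
experiment secondary processes (overall compositional change, lipid
flip-flop) slow the decay, so only the initial linear regime of ln dx is
fitted: the window rule keeps the largest prefix of the series whose
ordinary-least-squares fit reaches R^2 >= 0.98 (configurable) with at least
four points.  Rates from different samples are made comparable by rescaling
to a common reference lipid concentration and protein copy number, and the
asymmetric/symmetric comparison is summarized by the ratio
r = k_asym / k_sym.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HydrolysisTimeCourse",
    "RateFit",
    "NormalizationRecord",
    "KineticsError",
    "delta_x",
    "estimate_plateau",
    "select_initial_window",
    "fit_rate",
    "normalize_rate",
    "rate_ratio",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "DEFAULT_R2_THRESHOLD",
    "DEFAULT_PLATEAU_POINTS",
    "TARGET_LIPID",
]

DEFAULT_R2_THRESHOLD = 0.98
DEFAULT_PLATEAU_POINTS = 3
MIN_WINDOW_POINTS = 4
TARGET_LIPID = "POPE"
_CLOSURE_TOL = 1e-6

_TIME_UNIT_S = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "min": 60.0, "minutes": 60.0}


class KineticsError(ValueError):
    """Raised on invalid time courses or failed rate fits."""


@dataclass(frozen=True)
class HydrolysisTimeCourse:
    """Time-stamped lipid-class mole fractions for one sample.

    ``fractions`` has one row per time point and one column per lipid class;
    every row must satisfy compositional closure (sum to 1).  Times are in
    seconds and strictly increasing.
    """

    times_s: np.ndarray
    fractions: pd.DataFrame
    label: str = ""
    ion: str = "none"
    concentration_mM: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if t.ndim != 1 or len(t) != len(self.fractions):
            raise KineticsError("times and fraction rows must align")
        if len(t) < MIN_WINDOW_POINTS:
            raise KineticsError(
                f"need >= {MIN_WINDOW_POINTS} time points, got {len(t)}"
            )
        if np.any(np.diff(t) <= 0):
            raise KineticsError("times must be strictly increasing")
        row_sums = self.fractions.to_numpy(dtype=float).sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > _CLOSURE_TOL)[0]
        if bad.size:
            raise KineticsError(
                f"fraction rows must sum to 1 (closure violated at row(s) "
                f"{bad.tolist()}, sums {row_sums[bad].round(6).tolist()})"
            )

    def series(self, lipid: str = TARGET_LIPID) -> np.ndarray:
        if lipid not in self.fractions.columns:
            raise KineticsError(f"no column for lipid class {lipid!r}")
        return self.fractions[lipid].to_numpy(dtype=float)


@dataclass(frozen=True)
class RateFit:
    """A fitted hydrolysis rate and its provenance."""

    k: float  # 1/s; slope magnitude of ln(dx) vs t on the selected window
    stderr_k: float
    window: tuple[int, int]  # [start, stop) indices into the valid log-series
    r_squared: float
    x0: float
    x_inf: float
    n_points_used: int
    intercept: float = 0.0
    negative_rate: bool = False  # fitted slope was positive (flag, not error)
    zero_decay: bool = False  # series showed no decay; k pinned to 0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.zero_decay and self.x_inf >= self.x0:
            raise KineticsError("plateau x_inf must lie below initial x0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise KineticsError("r_squared must be within [0, 1]")


@dataclass(frozen=True)
class NormalizationRecord:
    """Sample and reference lipid concentration / protein copy number.

    Normalization is ratio-to-reference, so normalized rates keep units of
    1/s: a sample with twice the reference lipid concentration has its rate
    halved, one with half the reference protein copies has it doubled.
    """

    lipid_concentration_mM: float
    protein_copies: float
    reference_lipid_concentration_mM: float = 1.0
    reference_protein_copies: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "lipid_concentration_mM",
            "protein_copies",
            "reference_lipid_concentration_mM",
            "reference_protein_copies",
        ):
            if getattr(self, name) <= 0:
                raise KineticsError(f"{name} must be strictly positive")


def delta_x(
    series: Sequence[float] | np.ndarray, x0: float, x_inf: float
) -> np.ndarray:
    """Normalized decay dx = (x(t) - x_inf) / (x0 - x_inf).

    dx equals 1 where x(t) = x0 and 0 at the plateau.  Values <= 0 (at or
    below the plateau) are returned as-is; callers exclude them from the log
    transform via ``dx > 0``.
    """
    if x0 <= x_inf:
        raise KineticsError(f"x0 ({x0:g}) must exceed the plateau x_inf ({x_inf:g})")
    dx = (np.asarray(series, dtype=float) - x_inf) / (x0 - x_inf)
    if not np.any(dx > 0):
        raise KineticsError("all points are at or below the plateau")
    return dx


def estimate_plateau(
    series: Sequence[float] | np.ndarray,
    m: int = DEFAULT_PLATEAU_POINTS,
    override: float | None = None,
) -> float:
    """Plateau x_inf as the mean of the final ``m`` points, or an override."""
    if override is not None:
        return float(override)
    series = np.asarray(series, dtype=float)
    if len(series) < m:
        raise KineticsError(f"series too short for a {m}-point plateau estimate")
    return float(series[-m:].mean())


def _ols(t: np.ndarray, y: np.ndarray):
    """OLS with free intercept; degenerate zero-variance response gets R^2=1."""
    res = stats.linregress(t, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else float(res.rvalue**2)
    return res.slope, res.intercept, res.stderr, r2


def select_initial_window(
    times_s: np.ndarray,
    log_dx: np.ndarray,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    min_points: int = MIN_WINDOW_POINTS,
) -> tuple[int, int]:
    """Largest prefix window over which ln(dx) vs t is acceptably linear.

    Starting from the full series, trailing points are trimmed one at a time
    until the prefix OLS fit reaches the R^2 threshold; the window always
    starts at the first point.  Returns [start, stop) indices.
    """
    n = len(log_dx)
    if n < min_points:
        raise KineticsError(
            f"need >= {min_points} valid points for window selection, got {n}"
        )
    for stop in range(n, min_points - 1, -1):
        _, _, _, r2 = _ols(times_s[:stop], log_dx[:stop])
        if r2 >= r2_threshold:
            return (0, stop)
    raise KineticsError(
        f"no linear initial regime: no prefix of >= {min_points} points "
        f"reaches R^2 >= {r2_threshold}"
    )


def fit_rate(
    tc: HydrolysisTimeCourse,
    lipid: str = TARGET_LIPID,
    x0: float | None = None,
    x_inf: float | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    plateau_points: int = DEFAULT_PLATEAU_POINTS,
) -> RateFit:
    """Fit the hydrolysis rate k from ln(dx) = -k t by windowed OLS.

    ``x0`` defaults to the first observed fraction and ``x_inf`` to the
    trailing-mean plateau estimate; both can be overridden (e.g. with the
    known end-state composition).  The OLS intercept is left free so that a
    mis-specified x0 biases the intercept, not the slope.  A positive fitted
    slope (negative rate) is flagged, not rejected, so basal near-zero
    activity samples survive the pipeline.
    """
    series = tc.series(lipid)
    x0_val = float(series[0]) if x0 is None else float(x0)
    xinf_val = estimate_plateau(series, m=plateau_points, override=x_inf)
    if x0_val - xinf_val <= 1e-12:
        # no measurable decay: pin the rate to zero rather than failing
        return RateFit(
            k=0.0,
            stderr_k=0.0,
            window=(0, len(series)),
            r_squared=1.0,
            x0=x0_val,
            x_inf=xinf_val,
            n_points_used=len(series),
            zero_decay=True,
            label=tc.label,
        )
    dx = delta_x(series, x0_val, xinf_val)
    valid = dx > 0
    t_valid = tc.times_s[valid]
    log_dx = np.log(dx[valid])
    window = select_initial_window(t_valid, log_dx, r2_threshold=r2_threshold)
    start, stop = window
    slope, intercept, stderr, r2 = _ols(t_valid[start:stop], log_dx[start:stop])
    return RateFit(
        k=-float(slope),
        stderr_k=float(stderr) if np.isfinite(stderr) else 0.0,
        window=window,
        r_squared=min(r2, 1.0),
        x0=x0_val,
        x_inf=xinf_val,
        n_points_used=stop - start,
        intercept=float(intercept),
        negative_rate=bool(slope > 0),
        label=tc.label,
    )


def normalize_rate(fit: RateFit, norm: NormalizationRecord) -> RateFit:
    """Rescale a fitted rate to the reference lipid and protein amounts."""
    factor = (
        norm.reference_lipid_concentration_mM / norm.lipid_concentration_mM
    ) * (norm.reference_protein_copies / norm.protein_copies)
    return replace(fit, k=fit.k * factor, stderr_k=fit.stderr_k * factor)


def rate_ratio(asym: RateFit, sym: RateFit) -> tuple[float, float]:
    """r = k_asym / k_sym with first-order (delta-method) error propagation."""
    if sym.k <= 0:
        raise KineticsError("ratio undefined: symmetric rate must be positive")
    r = asym.k / sym.k
    rel_a = asym.stderr_k / asym.k if asym.k != 0 else 0.0
    rel_s = sym.stderr_k / sym.k
    stderr_r = abs(r) * float(np.hypot(rel_a, rel_s))
    return r, stderr_r


def read_timecourse_csv(
    path: str,
    label: str = "",
    ion: str = "none",
    concentration_mM: float = 0.0,
    time_unit: str | None = None,
) -> HydrolysisTimeCourse:
    """Read a time-course CSV: a time column plus one column per lipid class.

    The time column may be named ``time``, ``time_s`` or ``time_min``; a
    unit suffix in the header (or an explicit ``time_unit``) converts to
    seconds on ingest.
    """
    df = pd.read_csv(path)
    time_col = next(
        (c for c in ("time_s", "time_min", "time") if c in df.columns), None
    )
    if time_col is None:
        raise KineticsError(f"{path}: no time column (time, time_s or time_min)")
    unit = time_unit or ("min" if time_col == "time_min" else "s")
    if unit not in _TIME_UNIT_S:
        raise KineticsError(f"unknown time unit {unit!r}")
    times = df[time_col].to_numpy(dtype=float) * _TIME_UNIT_S[unit]
    fractions = df.drop(columns=[time_col])
    return HydrolysisTimeCourse(
        times_s=times,
        fractions=fractions,
        label=label or path,
        ion=ion,
        concentration_mM=concentration_mM,
    )


def write_timecourse_csv(tc: HydrolysisTimeCourse, path: str) -> None:
    out = tc.fractions.copy()
    out.insert(0, "time_s", tc.times_s)
    out.to_csv(path, index=False)
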