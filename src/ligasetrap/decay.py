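"""Protein-stability estimation from cycloheximide-chase densitometry.

A chase time course (band intensity over hours after translation
shutoff) is normalized to its loading control and to the t = 0 band,
then fitted as first-order decay by least squares on the log scale:
ln I(t) = -k t + c over a stated window (the screen's convention is the
linear 0-2 h part of the time course).  Half-life is ln 2 / k; a rate
indistinguishable from zero is flagged stable.  Stabilization between a
treated and a reference chase is classified from the half-life ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "DecayTimecourse",
    "DecayFit",
    "FitError",
    "normalize_timecourse",
    "fit_halflife",
    "stabilization_ratio",
    "translation_recovery_ratio",
    "STABLE_CLASS",
]

#: rate (per hour) at or below which a protein is reported as stable
K_MIN = 1e-6
#: normalized intensity below which points are dropped from the log fit
INTENSITY_FLOOR = 0.01

STABLE_CLASS = "stable"


class FitError(RuntimeError):
    """Raised when a decay fit has too few usable points."""


@dataclass(frozen=True)
class DecayTimecourse:
    """One chase: times (hours, strictly increasing, t=0 present),
    band intensities, optional loading-control intensities."""

    protein: str
    condition: str
    times: tuple[float, ...]
    intensity: tuple[float, ...]
    loading: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.size < 2:
            raise ValueError("a time course needs at least 2 points")
        if y.size != t.size:
            raise ValueError("times and intensity must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("time 0 must be present (first point)")
        if (y < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.loading is not None:
            l = np.asarray(self.loading, dtype=float)
            if l.size != t.size:
                raise ValueError("loading must match times in length")
            if (l <= 0).any():
                raise ValueError("loading-control intensities must be positive")
        object.__setattr__(self, "times", tuple(float(v) for v in t))
        object.__setattr__(self, "intensity", tuple(float(v) for v in y))
        if self.loading is not None:
            object.__setattr__(self, "loading", tuple(float(v) for v in self.loading))


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: rate k (per hour), half-life (hours),
    r-squared of the log-linear regression, fit window, points used."""

    protein: str
    condition: str
    k: float
    half_life: float  # math.inf when flagged stable
    r_squared: float
    window: tuple[float, float]
    n_points: int

    @property
    def is_stable(self) -> bool:
        return self.k <= K_MIN


def normalize_timecourse(tc: DecayTimecourse) -> DecayTimecourse:
    """Divide by loading control (when present) and scale so t=0 is 1.0."""
    y = np.asarray(tc.intensity, dtype=float)
    if tc.loading is not None:
        y = y / np.asarray(tc.loading, dtype=float)
    if y[0] <= 0:
        raise ValueError("t=0 intensity must be positive after loading division")
    return replace(tc, intensity=tuple(y / y[0]), loading=None)


def fit_halflife(
    tc: DecayTimecourse,
    window: tuple[float, float] = (0.0, 2.0),
    floor: float = INTENSITY_FLOOR,
) -> DecayFit:
    """Fit ln(intensity) vs time by least squares inside ``window``.

    Expects a normalized time course (t=0 intensity 1.0).  Points with
    intensity at or below ``floor`` are excluded with a warning; fewer
    than 2 usable points is a :class:`FitError`.  The fitted slope is
    clipped at zero, so an increasing signal reports as stable.
    """
    t = np.asarray(tc.times, dtype=float)
    y = np.asarray(tc.intensity, dtype=float)
    in_window = (t >= window[0]) & (t <= window[1])
    usable = in_window & (y > floor)
    n_floored = int(in_window.sum() - usable.sum())
    if n_floored:
        warnings.warn(
            f"{tc.protein}/{tc.condition}: {n_floored} point(s) at or below "
            f"intensity floor {floor} excluded from the fit",
            stacklevel=2,
        )
    if usable.sum() < 2:
        raise FitError(
            f"{tc.protein}/{tc.condition}: fewer than 2 usable points in window {window}"
        )
    res = stats.linregress(t[usable], np.log(y[usable]))
    k = max(-res.slope, 0.0)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    half_life = math.inf if k <= K_MIN else math.log(2) / k
    return DecayFit(
        protein=tc.protein,
        condition=tc.condition,
        k=float(k),
        half_life=half_life,
        r_squared=r2,
        window=(float(window[0]), float(window[1])),
        n_points=int(usable.sum()),
    )


def stabilization_ratio(
    fit_treated: DecayFit,
    fit_reference: DecayFit,
    full_threshold: float = 2.0,
    partial_threshold: float = 1.3,
) -> tuple[float, str]:
    """Half-life fold change (treated / reference) and its class.

    Classes map fold changes onto the screen's yes/partial/no
    vocabulary: ``yes`` at or above ``full_threshold``, ``partial`` at
    or above ``partial_threshold``.  A reference that is itself stable
    yields class ``stable`` (degradation cannot be slowed further); a
    treated fit flagged stable over an unstable reference is ``yes``.
    """
    if fit_reference.is_stable and fit_treated.is_stable:
        return math.inf, STABLE_CLASS
    if fit_reference.is_stable:
        return fit_treated.half_life / fit_reference.half_life, STABLE_CLASS
    if fit_treated.is_stable:
        return math.inf, "yes"
    ratio = fit_treated.half_life / fit_reference.half_life
    if ratio >= full_threshold:
        cls = "yes"
    elif ratio >= partial_threshold:
        cls = "partial"
    else:
        cls = "no"
    return ratio, cls


def translation_recovery_ratio(
    signal: dict[str, float], reference: str = "untreated"
) -> dict[str, float]:
    """Total-lane densitometry per condition relative to ``reference``
    (puromycin-incorporation readout of bulk translation rate)."""
    if reference not in signal:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = signal[reference]
    if ref <= 0:
        raise ValueError("reference densitometry must be positive")
    return {cond: v / ref for cond, v in signal.items()}
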