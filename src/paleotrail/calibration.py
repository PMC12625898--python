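"""Radiocarbon calibration and highest-posterior-density intervals.

A conventional radiocarbon determination ``age +/- sigma`` (14C yr BP) is
calibrated against a curve giving the expected radiocarbon age mu(t) and
curve uncertainty sigma_c(t) on a calendar (cal BP) axis. With a uniform
prior over calendar time the posterior on a 1-yr grid is

    p(t)  propto  exp( -(age - mu(t))^2 / (2 (sigma^2 + sigma_c(t)^2)) )

i.e. measurement and curve error combined in quadrature. Highest-
posterior-density (HPD) regions are the smallest sets of grid years
containing the requested mass; they may be unions of disjoint intervals
when the curve folds the posterior into several modes. Interval endpoints
are rounded outward to the nearest 10 cal yr by default, the convention
used when reporting multi-decade uncertainties.

Curves are read in the IntCal text dialect: comment/header lines starting
with ``#``, then comma- or whitespace-separated columns whose first three
are cal BP, 14C age, and curve error. The published IntCal20 file parses
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import CurveFormatError, OutOfCurveError

__all__ = [
    "RadiocarbonDate",
    "CalibrationCurve",
    "CalibratedDensity",
    "HPDIntervalSet",
    "load_curve",
    "write_curve",
    "calibrate_date",
    "hpd_intervals",
]


@dataclass(frozen=True)
class RadiocarbonDate:
    """A conventional radiocarbon determination in 14C yr BP."""

    age: float
    sigma: float
    lab_code: str = ""
    pretreatment: str = ""

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class CalibrationCurve:
    """mu(t) and curve error sigma_c(t) on a strictly increasing cal BP grid."""

    t: np.ndarray
    mu: np.ndarray
    sig_c: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sig_c = np.asarray(self.sig_c, dtype=float)
        if not (t.size == mu.size == sig_c.size):
            raise CurveFormatError("curve columns have unequal lengths")
        if t.size < 2:
            raise CurveFormatError("curve needs at least two knots")
        if np.any(np.diff(t) <= 0):
            raise CurveFormatError("cal BP axis must be strictly monotone")
        if np.any(sig_c < 0):
            raise CurveFormatError("curve error must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sig_c", sig_c)

    def mu_at(self, t):
        """Linear interpolation of the 14C age at calendar year(s) t."""
        return np.interp(t, self.t, self.mu)

    def sig_at(self, t):
        return np.interp(t, self.t, self.sig_c)

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalized posterior mass per 1-yr step of the cal BP grid."""

    t: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if t.size != p.size:
            raise ValueError("t and p must have equal lengths")
        if np.any(p < 0):
            raise ValueError("probability mass must be non-negative")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probability mass must sum to 1, got {total}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)

    @property
    def mode(self) -> float:
        return float(self.t[int(np.argmax(self.p))])


@dataclass(frozen=True)
class HPDIntervalSet:
    """HPD region at one probability level, as (older, younger) cal BP pairs."""

    level: float
    intervals: tuple[tuple[float, float], ...]

    @property
    def older(self) -> float:
        """Oldest endpoint across all intervals."""
        return max(o for o, _ in self.intervals)

    @property
    def younger(self) -> float:
        return min(y for _, y in self.intervals)


def load_curve(path) -> CalibrationCurve:
    """Read a calibration curve in the IntCal text dialect.

    Lines starting with ``#`` are comments; remaining lines are comma- or
    whitespace-separated with first three columns cal BP, 14C age, error.
    A curve stored oldest-first (as IntCal20 is) is reversed to ascending.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                rows.append([float(x) for x in parts[:3]])
            except (ValueError, IndexError) as exc:
                raise CurveFormatError(
                    f"{path}: malformed row at line {lineno}: {text!r}"
                ) from exc
            if len(parts) < 3:
                raise CurveFormatError(
                    f"{path}: expected >=3 columns at line {lineno}"
                )
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    t, mu, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    dt = np.diff(t)
    if np.all(dt < 0):  # stored oldest-first
        t, mu, sig = t[::-1], mu[::-1], sig[::-1]
    elif not np.all(dt > 0):
        raise CurveFormatError(f"{path}: cal BP column is not monotone")
    return CalibrationCurve(t, mu, sig)


def write_curve(curve: CalibrationCurve, path, comment: str = "") -> None:
    """Write a curve in the IntCal text dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# CAL BP, 14C age, error\n")
        for t, mu, sig in zip(curve.t, curve.mu, curve.sig_c):
            fh.write(f"{t:.17g},{mu:.17g},{sig:.17g}\n")


def calibrate_date(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    grid_step: float = 1.0,
) -> CalibratedDensity:
    """Calibrate a determination; posterior on a 1-yr cal BP grid.

    Warns when the determination lies outside the curve's 14C range;
    raises :class:`OutOfCurveError` when it is so far outside that the
    likelihood is zero everywhere to machine precision.
    """
    lo, hi = curve.t_span
    t = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    mu = curve.mu_at(t)
    sig = np.sqrt(date.sigma**2 + curve.sig_at(t) ** 2)
    if not (curve.mu.min() <= date.age <= curve.mu.max()):
        warnings.warn(
            f"14C age {date.age} outside curve range "
            f"[{curve.mu.min():.0f}, {curve.mu.max():.0f}]",
            stacklevel=2,
        )
    z2 = ((date.age - mu) / sig) ** 2
    logp = -0.5 * z2
    raw = np.exp(logp)
    if not np.any(raw > 0):
        raise OutOfCurveError(
            f"posterior numerically zero everywhere for {date.age} +/- {date.sigma}"
        )
    p = np.exp(logp - logp.max())
    return CalibratedDensity(t, p / p.sum())


def _round_outward(older: float, younger: float, step: float):
    if not step:
        return older, younger
    return (
        float(np.ceil(older / step) * step),
        float(np.floor(younger / step) * step),
    )


def hpd_intervals(
    density: CalibratedDensity,
    level: float,
    round_to: float = 10.0,
) -> HPDIntervalSet:
    """Smallest set of calendar years holding at least ``level`` mass.

    Grid years are admitted in order of descending posterior mass until
    the level is reached; years tied with the last admitted mass are also
    included, so enclosed mass is >= level. Contiguous runs of admitted
    grid years become intervals, reported as (older, younger) pairs sorted
    oldest-first and rounded outward to the nearest ``round_to`` cal yr
    (pass 0 to disable rounding). By construction the region at a lower
    level is nested inside the region at a higher one.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    p = density.p
    order = np.argsort(p, kind="stable")[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, level)) + 1
    threshold = p[order[min(k - 1, p.size - 1)]]
    selected = p >= threshold
    # merge contiguous runs of selected grid indices
    idx = np.flatnonzero(selected)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    step = float(density.t[1] - density.t[0]) if density.t.size > 1 else 1.0
    grid_tol = 0.5 * step
    raw = [
        (float(density.t[idx[e]]), float(density.t[idx[s]]))
        for s, e in zip(starts, ends)
    ]
    intervals = [_round_outward(o, y, round_to) for o, y in raw]
    # rounding can make neighbours touch; merge overlaps
    intervals.sort(key=lambda oy: -oy[0])
    merged: list[tuple[float, float]] = []
    for o, y in intervals:
        if merged and y <= merged[-1][0] and o >= merged[-1][1] - grid_tol:
            po, py = merged[-1]
            merged[-1] = (max(po, o), min(py, y))
        else:
            merged.append((o, y))
    return HPDIntervalSet(level=level, intervals=tuple(merged))
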