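"""Monte Carlo Mahalanobis-distance habitat suitability modelling.

The model estimates a climatic envelope for a set of dated fossil
occurrences and projects it over a gridded paleoclimate reconstruction.
Because the occurrences are unevenly distributed over a few regions and
carry wide, uneven age uncertainties, the envelope is not fitted once: an
ensemble of members is drawn, each member taking an equal number k of
records from every region box (balanced spatial representation) and, for
every chosen record, a calendar age drawn uniformly within its age
bounds. Each member's records are mapped to the nearest grid cell and
time slice of the climate field, the (T, P) conditions are stacked into a
matrix C, and the member's envelope is the column mean C-bar with the
inverse of the unbiased sample covariance, Sigma^-1. Suitability of every
grid cell and slice is the exponential decay of the Mahalanobis distance
to that envelope,

    d_M = (c - C-bar)^T Sigma^-1 (c - C-bar),      s = exp(-d_M),

so s is in (0, 1] and equals 1 exactly where the climate matches the
envelope mean. The default uses the quadratic form above;
``distance_mode="root"`` takes its square root first, the conventional
Mahalanobis distance. The ensemble mean of s and per-region-box mean time
series summarize the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import (
    EnsembleRunError,
    GridDomainError,
    InsufficientSampleError,
    SamplingError,
)

__all__ = [
    "RegionBox",
    "ClimateField",
    "EnsembleMember",
    "SuitabilityEnsemble",
    "BoxSeries",
    "load_occurrences",
    "normalize_lon",
    "extract_climate",
    "sample_ensemble_member",
    "fit_envelope",
    "suitability_map",
    "run_monte_carlo",
    "box_timeseries",
]

#: Condition-number threshold above which the covariance is regularized.
COND_LIMIT = 1e12

OCCURRENCE_COLUMNS = [
    "specimen",
    "latitude",
    "longitude",
    "min_age",
    "max_age",
    "location",
    "method",
]


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class RegionBox:
    """A lon/lat rectangle used for balanced spatial sampling."""

    label: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    name: str = ""

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError(f"degenerate box {self.label!r}: min must be < max")

    def contains(self, lat, lon):
        """Vectorized membership test for cell centers (lon wrap-aware)."""
        lat = np.asarray(lat, dtype=float)
        lon = normalize_lon(lon)
        lo = normalize_lon(self.lon_min)
        # measure longitudes as offsets east of lon_min so boxes that
        # straddle the dateline (or end exactly at 180E) work uniformly
        width = (self.lon_max - self.lon_min) % 360.0 or 360.0
        offset = (lon - lo) % 360.0
        in_lon = offset <= width
        return in_lon & (lat >= self.lat_min) & (lat <= self.lat_max)


@dataclass
class ClimateField:
    """Gridded annual-mean temperature and precipitation through time.

    ``T`` and ``P`` have shape (time, lat, lon); ``time`` is in calendar
    years BP (stored oldest-first for a window running into the past),
    ``lon`` are cell centers in [-180, 180), ``lat`` in [-90, 90].
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    T: np.ndarray
    P: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        shape = (self.time.size, self.lat.size, self.lon.size)
        for name in ("T", "P"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        dt = np.diff(self.time)
        if self.time.size > 1 and not (np.all(dt > 0) or np.all(dt < 0)):
            raise ValueError("time axis must be strictly ordered")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.time.size, self.lat.size, self.lon.size)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "T": (("time", "lat", "lon"), self.T, {"units": "degC"}),
                "P": (("time", "lat", "lon"), self.P, {"units": "mm/yr"}),
            },
            coords={
                "time": ("time", self.time, {"units": "years BP"}),
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
            },
            attrs=self.attrs,
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateField":
        return cls(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            time=ds["time"].values,
            T=ds["T"].values,
            P=ds["P"].values,
            attrs=dict(ds.attrs),
        )

    @classmethod
    def from_netcdf(cls, path) -> "ClimateField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def load_occurrences(source) -> pd.DataFrame:
    """Load and normalize a fossil occurrence table.

    ``source`` is a CSV path or a DataFrame in the occurrence schema
    (specimen, latitude, longitude, min_age, max_age, location, method).
    Longitudes are mapped to [-180, 180); age bounds are normalized to
    explicit ``older``/``younger`` columns with older >= younger, emitting
    a warning for rows whose printed bounds had to be swapped relative to
    min <= max semantics.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in OCCURRENCE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if (np.abs(df["latitude"]) > 90).any():
        raise ValueError("latitudes must be within [-90, 90]")
    if ((df["min_age"] <= 0) | (df["max_age"] <= 0)).any():
        raise ValueError("age bounds must be positive")
    df["longitude"] = normalize_lon(df["longitude"])
    swapped = df["min_age"] > df["max_age"]
    if swapped.any():
        warnings.warn(
            f"{int(swapped.sum())} row(s) list min_age > max_age; "
            "bounds normalized to (older, younger)",
            stacklevel=2,
        )
    df["older"] = df[["min_age", "max_age"]].max(axis=1)
    df["younger"] = df[["min_age", "max_age"]].min(axis=1)
    return df


def extract_climate(lat, lon, age_bp, field: ClimateField):
    """(T, P) at the nearest cell center and time slice.

    Nearest on each axis independently; longitude distance is wrap-aware
    (179.9E is adjacent to -180). Ages outside the field's time span are
    clamped to the nearest slice with a warning. Scalar or array inputs.
    """
    lat = np.asarray(lat, dtype=float)
    lon = normalize_lon(lon)
    age = np.asarray(age_bp, dtype=float)
    scalar = lat.ndim == 0
    lat, lon, age = np.atleast_1d(lat), np.atleast_1d(lon), np.atleast_1d(age)

    if np.any(np.abs(lat) > 90):
        raise GridDomainError("latitude outside [-90, 90]")
    lat_pad = 0.75 * _axis_step(field.lat)
    if np.any(lat < field.lat.min() - lat_pad) or np.any(
        lat > field.lat.max() + lat_pad
    ):
        raise GridDomainError("point outside the grid's latitude extent")

    i_lat = np.abs(lat[:, None] - field.lat[None, :]).argmin(axis=1)
    dlon = np.abs(lon[:, None] - field.lon[None, :])
    dlon = np.minimum(dlon, 360.0 - dlon)
    i_lon = dlon.argmin(axis=1)

    t_lo, t_hi = field.time.min(), field.time.max()
    if np.any((age < t_lo) | (age > t_hi)):
        warnings.warn(
            "age(s) outside the climate field's time span; clamped to the "
            "nearest slice",
            stacklevel=2,
        )
    i_t = np.abs(age[:, None] - field.time[None, :]).argmin(axis=1)

    T = field.T[i_t, i_lat, i_lon]
    P = field.P[i_t, i_lat, i_lon]
    if scalar:
        return float(T[0]), float(P[0])
    return T, P


def _axis_step(axis: np.ndarray) -> float:
    return float(np.abs(np.diff(axis)).max()) if axis.size > 1 else 1.0


@dataclass
class EnsembleMember:
    """One balanced draw of records with sampled ages (climate optional)."""

    records: pd.DataFrame  # sampled rows, plus a drawn_age column
    conditions: np.ndarray | None = None  # n x 2 matrix of (T, P)
    mean: np.ndarray | None = None
    inv_cov: np.ndarray | None = None


def sample_ensemble_member(
    records: pd.DataFrame,
    boxes,
    k_per_box: int,
    rng: np.random.Generator,
) -> EnsembleMember:
    """Draw k records per region box, each with a uniform age in its bounds.

    Records are drawn uniformly without replacement within a box, so a box
    holding exactly k records contributes all of them every time. The
    drawn calendar age is Uniform[younger, older] per record.
    """
    boxes = list(boxes.values()) if isinstance(boxes, dict) else list(boxes)
    parts = []
    for box in boxes:
        pool = records[records["location"] == box.label]
        if len(pool) < k_per_box:
            raise SamplingError(
                f"box {box.label!r} holds {len(pool)} records, need {k_per_box}"
            )
        take = rng.choice(len(pool), size=k_per_box, replace=False)
        parts.append(pool.iloc[np.sort(take)])
    sampled = pd.concat(parts, ignore_index=True)
    lo = sampled["younger"].to_numpy(dtype=float)
    hi = sampled["older"].to_numpy(dtype=float)
    sampled["drawn_age"] = rng.uniform(lo, hi)
    return EnsembleMember(records=sampled)


def fit_envelope(C: np.ndarray, cond_limit: float = COND_LIMIT):
    """Column mean and inverse covariance of an n x 2 conditions matrix.

    Uses the unbiased (n-1) covariance estimator. An ill-conditioned or
    singular covariance (condition number above ``cond_limit``) is
    regularized as Sigma + eps*I with eps = 1e-6 * trace(Sigma)/2 (or an
    absolute floor when the trace itself vanishes), with a warning.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] != 2:
        raise ValueError(f"conditions matrix must be n x 2, got {C.shape}")
    n = C.shape[0]
    if n < 3:
        raise InsufficientSampleError(
            f"need >= 3 samples to estimate a 2-D envelope, got {n}"
        )
    mean = C.mean(axis=0)
    cov = np.cov(C, rowvar=False, ddof=1)
    if not np.all(np.isfinite(cov)) or np.linalg.cond(cov) > cond_limit:
        eps = 1e-6 * np.trace(cov) / 2.0
        if not eps > 0:
            eps = 1e-12
        warnings.warn(
            f"ill-conditioned covariance; regularized with eps={eps:.3g}",
            stacklevel=2,
        )
        cov = cov + eps * np.eye(2)
    return mean, np.linalg.inv(cov)


def suitability_map(
    envelope,
    field: ClimateField,
    distance_mode: str = "quadratic",
) -> np.ndarray:
    """Suitability s = exp(-d_M) over the whole grid and every time slice.

    ``envelope`` is a (mean, inv_cov) pair. ``distance_mode`` selects the
    quadratic form (default) or its square root (``"root"``). Non-finite
    climate values propagate to NaN suitability with a warning.
    """
    mean, inv_cov = envelope
    mean = np.asarray(mean, dtype=float)
    inv_cov = np.asarray(inv_cov, dtype=float)
    if distance_mode not in ("quadratic", "root"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    dT = field.T - mean[0]
    dP = field.P - mean[1]
    d = (
        inv_cov[0, 0] * dT * dT
        + (inv_cov[0, 1] + inv_cov[1, 0]) * dT * dP
        + inv_cov[1, 1] * dP * dP
    )
    if distance_mode == "root":
        d = np.sqrt(np.maximum(d, 0.0))
    s = np.exp(-d)
    n_bad = int(np.count_nonzero(~np.isfinite(s)))
    if n_bad:
        warnings.warn(
            f"{n_bad} grid values are non-finite; flagged as missing (NaN)",
            stacklevel=2,
        )
        s = np.where(np.isfinite(s), s, np.nan)
    return s


@dataclass
class BoxSeries:
    """Per-member and ensemble-mean suitability series over one box."""

    box_label: str
    time: np.ndarray
    members: np.ndarray | None  # (n_members, n_time) or None if not stored
    mean: np.ndarray  # (n_time,)


@dataclass
class SuitabilityEnsemble:
    """Ensemble-average suitability plus per-box member time series."""

    field: ClimateField
    mean_grid: np.ndarray  # (time, lat, lon) arithmetic mean over members
    box_series: dict  # label -> BoxSeries
    n_members: int
    seed: int
    distance_mode: str
    member_grids: list | None = None  # only kept when store_members=True
    n_failed: int = 0
    members_meta: list | None = None  # per-member EnsembleMember (no grids)

    def mean_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"suitability": (("time", "lat", "lon"), self.mean_grid)},
            coords={
                "time": self.field.time,
                "lat": self.field.lat,
                "lon": self.field.lon,
            },
            attrs={
                "n_members": self.n_members,
                "seed": self.seed,
                "distance_mode": self.distance_mode,
            },
        )


def _box_mask(field: ClimateField, box: RegionBox) -> np.ndarray:
    lat2d, lon2d = np.meshgrid(field.lat, field.lon, indexing="ij")
    mask = box.contains(lat2d, lon2d)
    if not mask.any():
        raise GridDomainError(f"box {box.label!r} contains no grid cell centers")
    return mask


def run_monte_carlo(
    records: pd.DataFrame,
    boxes,
    k_per_box: int,
    field: ClimateField,
    n_members: int,
    seed: int,
    distance_mode: str = "quadratic",
    store_members: bool = False,
    max_failure_frac: float = 0.1,
) -> SuitabilityEnsemble:
    """Run the full Monte Carlo suitability ensemble.

    Member m draws its random stream from ``default_rng([seed, m])``, so
    every member is reproducible independently of scheduling order. A
    member whose envelope cannot be fitted is skipped with a warning; the
    run aborts if more than ``max_failure_frac`` of members fail. The
    ensemble-average grid is a running arithmetic mean (per-member grids
    are only retained with ``store_members=True``; at the study's grid
    size 5,000 stored members would not fit in memory).
    """
    box_list = list(boxes.values()) if isinstance(boxes, dict) else list(boxes)
    masks = {box.label: _box_mask(field, box) for box in box_list}
    mean_grid = np.zeros(field.shape)
    series = {box.label: np.full((n_members, field.time.size), np.nan)
              for box in box_list}
    member_grids = [] if store_members else None
    members_meta = []
    n_ok = 0
    n_failed = 0
    for m in range(n_members):
        rng = np.random.default_rng([seed, m])
        member = sample_ensemble_member(records, box_list, k_per_box, rng)
        T, P = extract_climate(
            member.records["latitude"].to_numpy(),
            member.records["longitude"].to_numpy(),
            member.records["drawn_age"].to_numpy(),
            field,
        )
        member.conditions = np.column_stack([T, P])
        try:
            member.mean, member.inv_cov = fit_envelope(member.conditions)
        except InsufficientSampleError as exc:
            n_failed += 1
            warnings.warn(f"member {m} skipped: {exc}", stacklevel=2)
            continue
        s = suitability_map((member.mean, member.inv_cov), field, distance_mode)
        mean_grid += s
        for label, mask in masks.items():
            series[label][m] = s[:, mask].mean(axis=1)
        if store_members:
            member_grids.append(s)
        members_meta.append(member)
        n_ok += 1
    if n_members and n_failed > max_failure_frac * n_members:
        raise EnsembleRunError(
            f"{n_failed}/{n_members} ensemble members failed the envelope fit"
        )
    if n_ok:
        mean_grid /= n_ok
    box_series = {
        label: BoxSeries(
            box_label=label,
            time=field.time,
            members=series[label],
            mean=np.nanmean(series[label], axis=0),
        )
        for label in series
    }
    return SuitabilityEnsemble(
        field=field,
        mean_grid=mean_grid,
        box_series=box_series,
        n_members=n_members,
        seed=seed,
        distance_mode=distance_mode,
        member_grids=member_grids,
        n_failed=n_failed,
        members_meta=members_meta,
    )


def box_timeseries(ensemble: SuitabilityEnsemble, box: RegionBox) -> BoxSeries:
    """Mean suitability over a box's cell centers, per slice.

    For the boxes passed to :func:`run_monte_carlo` the per-member series
    were recorded during the run and are returned directly. For any other
    box the ensemble-mean series is always computable from the average
    grid; per-member series additionally require ``store_members=True``.
    """
    if box.label in ensemble.box_series:
        return ensemble.box_series[box.label]
    mask = _box_mask(ensemble.field, box)
    mean = ensemble.mean_grid[:, mask].mean(axis=1)
    members = None
    if ensemble.member_grids is not None:
        members = np.stack(
            [g[:, mask].mean(axis=1) for g in ensemble.member_grids]
        )
    return BoxSeries(
        box_label=box.label, time=ensemble.field.time, members=members, mean=mean
    )
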