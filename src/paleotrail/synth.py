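"""Synthetic inputs with known ground truth.

The real study consumed instrument output (MALDI spectra), sequencing data
and a multi-million-year climate simulation, none of which can ship with a
desk-scale package. This module generates structurally faithful stand-ins
with known ground truth so every downstream stage can be tested for exact
recovery:

* a gridded climate field with a latitudinal temperature gradient and a
  sinusoidal glacial-interglacial cycle (a deliberate simplification of an
  orbital-scale climate reconstruction — it creates warm "interglacial
  windows" without any pretence of simulation physics);
* fossil occurrence tables drawn from a known bivariate (T, P) climate
  envelope inside given region boxes, with the true age stored alongside
  the uncertainty bounds the pipeline is allowed to see;
* MALDI peak lists built from a reference marker table plus mass jitter,
  marker dropout and uniform noise peaks;
* calibration curves (identity plus seeded smooth wiggles) in the IntCal
  text dialect;
* sequence alignments with disjoint planted substitutions and N-masking,
  so pairwise difference counts are known by construction.

Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, GenerationError
from .calibration import CalibrationCurve
from .mtdna import SequenceAlignment
from .niche import ClimateField, RegionBox
from .zooms import MarkerTable, PeakList

__all__ = [
    "ClimateConfig",
    "EnvelopeTruth",
    "make_climate",
    "make_occurrences",
    "make_peaklist",
    "make_calcurve",
    "make_alignment",
]

#: Calendar year BP of the reference interglacial peak: the warm phase of
#: the sinusoidal cycle is centred here (Last Interglacial).
INTERGLACIAL_PEAK_BP = 125_000.0


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the synthetic climate field.

    The grid emulates a coarse global climate-model grid (5.75 x 3.75
    degrees) carrying 1,000-y averages over the MIS6-MIS3 window, 150 to
    30 ka BP. Temperature is baseline + linear latitudinal gradient +
    sinusoidal glacial cycle + seeded noise; precipitation is analogous
    with its own baseline, gradient and cycle amplitude, in phase with
    temperature (interglacials are warm and wet).
    """

    lon_step: float = 5.75
    lat_step: float = 3.75
    time_start_ka: float = 150.0
    time_end_ka: float = 30.0
    time_step: float = 1000.0  # years
    T_base: float = 10.0  # degC global reference
    lat_gradient_T: float = -0.6  # degC per degree latitude
    cycle_amplitude_T: float = 8.0  # degC half-amplitude of the glacial cycle
    cycle_period: float = 100_000.0  # years
    P_base: float = 600.0  # mm/yr
    lat_gradient_P: float = -3.0  # mm/yr per degree latitude
    cycle_amplitude_P: float = 150.0  # mm/yr half-amplitude
    noise_sd: float = 0.5  # degC; precipitation noise is noise_sd_P
    noise_sd_P: float | None = None  # defaults to 40 x noise_sd (mm/yr)
    seed: int = 0

    def __post_init__(self):
        if self.lon_step <= 0 or self.lat_step <= 0 or self.time_step <= 0:
            raise ConfigurationError("grid and time steps must be positive")
        if not self.time_start_ka > self.time_end_ka:
            raise ConfigurationError(
                "time_start_ka must exceed time_end_ka (BP axis runs into the past)"
            )

    @property
    def p_noise_sd(self) -> float:
        return 40.0 * self.noise_sd if self.noise_sd_P is None else self.noise_sd_P


@dataclass(frozen=True)
class EnvelopeTruth:
    """Ground-truth bivariate (T, P) climate envelope for recovery tests."""

    mean_T: float
    mean_P: float
    cov: np.ndarray  # 2x2, units degC^2 / degC*mm/yr / (mm/yr)^2

    def __post_init__(self):
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ConfigurationError("cov must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ConfigurationError("cov must be positive definite")
        object.__setattr__(self, "cov", cov)

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_T, self.mean_P])

    def mahalanobis_sq(self, T, P) -> np.ndarray:
        """Squared Mahalanobis distance of (T, P) points from the truth."""
        inv = np.linalg.inv(self.cov)
        dT = np.asarray(T, dtype=float) - self.mean_T
        dP = np.asarray(P, dtype=float) - self.mean_P
        return inv[0, 0] * dT**2 + 2 * inv[0, 1] * dT * dP + inv[1, 1] * dP**2


def make_climate(config: ClimateConfig = ClimateConfig()) -> ClimateField:
    """Generate the synthetic climate field described by ``config``."""
    lon = np.arange(-180.0, 180.0, config.lon_step)
    lat = np.arange(-90.0, 90.0 + 0.5 * config.lat_step, config.lat_step)
    time = np.arange(
        config.time_start_ka * 1000.0,
        config.time_end_ka * 1000.0 - 0.5 * config.time_step,
        -config.time_step,
    )
    phase = np.cos(2 * np.pi * (time - INTERGLACIAL_PEAK_BP) / config.cycle_period)
    cycle_T = config.cycle_amplitude_T * phase
    cycle_P = config.cycle_amplitude_P * phase

    lat3 = lat[None, :, None]
    T = config.T_base + config.lat_gradient_T * lat3 + cycle_T[:, None, None]
    P = config.P_base + config.lat_gradient_P * lat3 + cycle_P[:, None, None]
    shape = (time.size, lat.size, lon.size)
    T = np.broadcast_to(T, shape).copy()
    P = np.broadcast_to(P, shape).copy()
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        T += rng.normal(0.0, config.noise_sd, size=shape)
    if config.p_noise_sd > 0:
        P += rng.normal(0.0, config.p_noise_sd, size=shape)
    P = np.maximum(P, 0.0)  # precipitation cannot be negative
    return ClimateField(
        lon=lon,
        lat=lat,
        time=time,
        T=T,
        P=P,
        attrs={
            "title": "synthetic glacial-cycle climate field",
            "seed": config.seed,
        },
    )


def make_occurrences(
    climate: ClimateField,
    truth: EnvelopeTruth,
    boxes,
    n_per_box: int,
    age_uncertainty: float,
    seed: int,
) -> pd.DataFrame:
    """Draw fossil records whose true climates follow ``truth``.

    For each record a target climate is drawn from the truth envelope's
    bivariate normal and the record is placed at the (cell, time-slice)
    inside its region box whose climate is nearest the target in the
    truth's Mahalanobis metric — so, where the box's grid covers the
    envelope, the records' true climates are distributed as the envelope
    itself. Each record's published age bounds bracket its true age by
    +/- age_uncertainty/2 (clipped at the field's time span); the true
    age and true climate are stored in extra columns for recovery tests
    and are not part of the occurrence schema the pipeline reads.
    """
    if n_per_box < 0:
        raise GenerationError("n_per_box must be >= 0")
    box_list = list(boxes.values()) if isinstance(boxes, dict) else list(boxes)
    rng = np.random.default_rng(seed)
    chi2_999 = stats.chi2.ppf(0.999, df=2)
    rows = []
    for box in box_list:
        lat2d, lon2d = np.meshgrid(climate.lat, climate.lon, indexing="ij")
        mask = box.contains(lat2d, lon2d)
        if not mask.any():
            raise GenerationError(f"box {box.label!r} covers no grid cells")
        if n_per_box == 0:
            continue
        lat_cells = lat2d[mask]
        lon_cells = lon2d[mask]
        T_cells = climate.T[:, mask]  # (n_time, n_cells)
        P_cells = climate.P[:, mask]
        d2 = truth.mahalanobis_sq(T_cells, P_cells)
        if d2.min() > chi2_999:
            raise GenerationError(
                f"no cell in box {box.label!r} satisfies the climate envelope "
                f"(min Mahalanobis^2 = {d2.min():.1f})"
            )
        targets = rng.multivariate_normal(truth.mean, truth.cov,
                                          size=n_per_box)
        inv = np.linalg.inv(truth.cov)
        dT = T_cells.ravel()[None, :] - targets[:, 0, None]
        dP = P_cells.ravel()[None, :] - targets[:, 1, None]
        dist = (inv[0, 0] * dT**2 + 2 * inv[0, 1] * dT * dP
                + inv[1, 1] * dP**2)
        picks = dist.argmin(axis=1)
        i_t, i_c = np.unravel_index(picks, d2.shape)
        for j, (it, ic) in enumerate(zip(i_t, i_c)):
            true_age = float(climate.time[it])
            half = age_uncertainty / 2.0
            older = min(true_age + half, float(climate.time.max()))
            younger = max(true_age - half, float(climate.time.min()))
            rows.append(
                {
                    "specimen": f"{box.label}-{j:03d}",
                    "latitude": float(lat_cells[ic]),
                    "longitude": float(lon_cells[ic]),
                    "min_age": older,
                    "max_age": younger,
                    "location": box.label,
                    "method": "synthetic draw from truth envelope",
                    "true_age": true_age,
                    "true_T": float(T_cells[it, ic]),
                    "true_P": float(P_cells[it, ic]),
                }
            )
    columns = [
        "specimen", "latitude", "longitude", "min_age", "max_age",
        "location", "method", "true_age", "true_T", "true_P",
    ]
    return pd.DataFrame(rows, columns=columns)


def make_peaklist(
    taxon: str,
    markers: MarkerTable,
    jitter_sd: float = 0.05,
    dropout=frozenset(),
    n_noise_peaks: int = 0,
    seed: int = 0,
    noise_range: tuple[float, float] = (800.0, 3200.0),
) -> PeakList:
    """Synthesize a MALDI peak list for one taxon.

    One peak per non-dropped marker (reference mass + Gaussian jitter of
    ``jitter_sd`` Da) plus ``n_noise_peaks`` uniform noise peaks over
    ``noise_range``. Marker peaks get high intensities, noise peaks low.
    """
    taxon_markers = markers[taxon]  # raises TaxonLookupError if unknown
    rng = np.random.default_rng(seed)
    kept = [name for name in taxon_markers if name not in set(dropout)]
    mz = np.array([taxon_markers[m] for m in kept], dtype=float)
    if jitter_sd > 0 and mz.size:
        mz = mz + rng.normal(0.0, jitter_sd, size=mz.size)
    inten = rng.uniform(0.5, 1.0, size=mz.size)
    if n_noise_peaks > 0:
        noise_mz = rng.uniform(*noise_range, size=n_noise_peaks)
        noise_inten = rng.uniform(0.01, 0.2, size=n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_inten])
    return PeakList(mz, inten)


def make_calcurve(
    t_min: float,
    t_max: float,
    wiggle_amplitude: float = 0.0,
    curve_error: float = 20.0,
    seed: int = 0,
    knot_step: float = 5.0,
) -> CalibrationCurve:
    """Identity-plus-wiggles calibration curve on [t_min, t_max].

    mu(t) = t plus a seeded sum of smooth sinusoids with total standard
    deviation ~``wiggle_amplitude`` (14C yr); sigma_c(t) = ``curve_error``
    everywhere. mu is monotone on average (slope 1) but can wiggle locally
    like a real curve.
    """
    if not t_min < t_max:
        raise ConfigurationError("t_min must be < t_max")
    t = np.arange(float(t_min), float(t_max) + 0.5 * knot_step, knot_step)
    mu = t.astype(float).copy()
    if wiggle_amplitude > 0:
        rng = np.random.default_rng(seed)
        n_modes = 6
        wavelengths = rng.uniform(500.0, 5000.0, size=n_modes)
        phases = rng.uniform(0.0, 2 * np.pi, size=n_modes)
        amps = rng.uniform(0.5, 1.0, size=n_modes)
        amps *= wiggle_amplitude / np.sqrt(0.5 * np.sum(amps**2))
        for lam, phi, a in zip(wavelengths, phases, amps):
            mu = mu + a * np.sin(2 * np.pi * t / lam + phi)
    sig_c = np.full_like(t, float(curve_error))
    return CalibrationCurve(t, mu, sig_c)


def make_alignment(
    n_seqs: int,
    length: int,
    planted_diffs,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> tuple[SequenceAlignment, dict[str, int]]:
    """Reference plus sequences carrying disjoint planted substitutions.

    ``planted_diffs`` is either a mapping name -> substitution count vs
    the reference, or a sequence of counts (named ``seq01`` ...); the
    number of non-reference sequences is ``n_seqs - 1`` and must match.
    Substituted sites are disjoint across sequences, so for any two
    non-reference rows the pairwise difference count is the sum of their
    planted counts (with no masking). ``missing_frac`` of sites per
    non-reference sequence are then masked to N (the reference itself is
    never masked, keeping it usable as coordinate backbone).

    Returns the alignment and the realized ``{name: planted count}`` map.
    """
    if n_seqs < 1:
        raise GenerationError("need at least the reference sequence")
    if not 0.0 <= missing_frac <= 1.0:
        raise GenerationError("missing_frac must be in [0, 1]")
    if isinstance(planted_diffs, dict):
        counts = dict(planted_diffs)
    else:
        counts = {f"seq{i + 1:02d}": int(c) for i, c in enumerate(planted_diffs)}
    if len(counts) != n_seqs - 1:
        raise GenerationError(
            f"planted_diffs gives {len(counts)} sequences, expected {n_seqs - 1}"
        )
    total = sum(counts.values())
    if total > length:
        raise GenerationError(
            f"cannot plant {total} disjoint substitutions in length {length}"
        )
    if any(c < 0 for c in counts.values()):
        raise GenerationError("planted counts must be non-negative")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=length)
    site_pool = rng.permutation(length)
    names = ["ref"]
    rows = ["".join(ref)]
    cursor = 0
    for name, c in counts.items():
        seq = ref.copy()
        sites = site_pool[cursor : cursor + c]
        cursor += c
        for s in sites:
            alternatives = bases[bases != ref[s]]
            seq[s] = rng.choice(alternatives)
        n_mask = int(round(missing_frac * length))
        if n_mask:
            masked = rng.choice(length, size=n_mask, replace=False)
            seq[masked] = "N"
        names.append(name)
        rows.append("".join(seq))
    return SequenceAlignment(names, rows), counts
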