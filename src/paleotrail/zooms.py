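"""Collagen peptide mass fingerprinting (ZooMS) taxon screening.

Bone-collagen MALDI-TOF spectra are reduced to peak lists; each taxon in a
reference library is characterized by up to seven named tryptic-peptide
markers (A-G) with known monoisotopic [M+H]+ masses. A spectrum is
assigned to the taxon whose markers it matches best within a mass
tolerance, and assemblages are summarized as per-context taxon
percentages plus an overall identification success rate.

Matching deliberately does not enforce peak exclusivity: a single peak may
satisfy markers of several taxa, because collagen peptides are genuinely
shared across related clades. Post-translational mass shifts (deamidation,
oxidation) are not modelled; matching is against the reference masses.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, TaxonLookupError

__all__ = [
    "MarkerTable",
    "PeakList",
    "TaxonAssignment",
    "AssemblageSummary",
    "match_markers",
    "classify_spectrum",
    "summarize_assemblage",
    "UNIDENTIFIED",
]

#: Label used for spectra matching no taxon at the required marker count.
UNIDENTIFIED = "unidentified"

#: Default mass tolerance (Da) for marker matching.
DEFAULT_TOL = 0.2

#: Default minimum number of matched markers for a confident assignment.
DEFAULT_MIN_MARKERS = 4


@dataclass(frozen=True)
class MarkerTable:
    """Reference library: taxon -> marker name (A-G) -> m/z in Daltons.

    Composite taxa (e.g. ``"Cervidae/Bovidae"``) are permitted as labels.
    """

    markers: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        for taxon, mm in self.markers.items():
            for name, mz in mm.items():
                if not mz > 0:
                    raise ConfigurationError(
                        f"non-positive m/z {mz} for {taxon} marker {name}"
                    )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerTable":
        """Build from a long-format frame with columns taxon, marker, mz."""
        table: dict[str, dict[str, float]] = {}
        for row in frame.itertuples(index=False):
            table.setdefault(str(row.taxon), {})[str(row.marker)] = float(row.mz)
        return cls(table)

    @classmethod
    def from_csv(cls, path) -> "MarkerTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (taxon, name, mz)
            for taxon, mm in self.markers.items()
            for name, mz in sorted(mm.items())
        ]
        return pd.DataFrame(rows, columns=["taxon", "marker", "mz"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def taxa(self) -> list[str]:
        return list(self.markers)

    def __getitem__(self, taxon: str) -> Mapping[str, float]:
        try:
            return self.markers[taxon]
        except KeyError:
            raise TaxonLookupError(f"taxon {taxon!r} not in marker table") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.markers


@dataclass(frozen=True)
class PeakList:
    """An observed MALDI peak list: m/z (Da, ascending) and optional intensity."""

    mz: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        if mz.size and not np.all(mz > 0):
            raise ConfigurationError("peak m/z must be strictly positive")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=float)
            if inten.shape != mz.shape:
                raise ConfigurationError("intensity length must match m/z length")
            object.__setattr__(self, "intensity", inten[order])

    @classmethod
    def from_mz(cls, mz: Iterable[float]) -> "PeakList":
        return cls(np.asarray(list(mz), dtype=float))

    @classmethod
    def from_csv(cls, path) -> "PeakList":
        """Read a two-column (mz, intensity) or single-column CSV/whitespace file."""
        try:
            frame = pd.read_csv(path)
            if frame.shape[1] == 1 or "mz" not in frame.columns:
                frame = pd.read_csv(path, header=None, sep=None, engine="python")
                frame.columns = ["mz", "intensity"][: frame.shape[1]]
        except pd.errors.EmptyDataError:
            return cls(np.empty(0))
        inten = frame["intensity"].to_numpy() if "intensity" in frame else None
        return cls(frame["mz"].to_numpy(), inten)

    def to_csv(self, path) -> None:
        inten = (
            self.intensity
            if self.intensity is not None
            else np.ones_like(self.mz)
        )
        pd.DataFrame({"mz": self.mz, "intensity": inten}).to_csv(path, index=False)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class TaxonAssignment:
    """Outcome of classifying one spectrum."""

    taxon: str
    matched_markers: frozenset[str] = frozenset()
    matched_mz: tuple[float, ...] = ()

    @property
    def n_matched(self) -> int:
        return len(self.matched_markers)

    @property
    def identified(self) -> bool:
        return self.taxon != UNIDENTIFIED


def match_markers(
    peaks: PeakList,
    taxon_markers: Mapping[str, float],
    tol: float = DEFAULT_TOL,
) -> dict[str, float]:
    """Match one taxon's markers against a peak list.

    A marker matches iff some peak lies within ``tol`` Daltons (inclusive)
    of its reference mass. Returns ``{marker name: closest peak m/z}`` for
    the matched markers; the matched set is monotone non-decreasing in
    ``tol``.
    """
    if not tol > 0:
        raise ConfigurationError(f"tolerance must be positive, got {tol}")
    if not taxon_markers:
        raise ConfigurationError("empty marker map")
    matched: dict[str, float] = {}
    if len(peaks) == 0:
        return matched
    for name, ref in taxon_markers.items():
        delta = np.abs(peaks.mz - ref)
        i = int(np.argmin(delta))
        if delta[i] <= tol:
            matched[name] = float(peaks.mz[i])
    return matched


def classify_spectrum(
    peaks: PeakList,
    table: MarkerTable,
    tol: float = DEFAULT_TOL,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> TaxonAssignment:
    """Assign a spectrum to the taxon with the most matched markers.

    A spectrum is ``unidentified`` when no taxon reaches ``min_markers``
    matches. A tie between taxa is reported as the composite label joining
    the tied names with ``/`` (mirroring composite categories like
    Cervidae/Bovidae); the matched markers reported are those of the
    alphabetically first tied taxon.
    """
    if min_markers < 1:
        raise ConfigurationError("min_markers must be >= 1")
    best: list[tuple[str, dict[str, float]]] = []
    best_n = 0
    for taxon in table.taxa:
        matched = match_markers(peaks, table[taxon], tol=tol)
        if len(matched) > best_n:
            best, best_n = [(taxon, matched)], len(matched)
        elif len(matched) == best_n and best_n > 0:
            best.append((taxon, matched))
    if best_n < min_markers:
        return TaxonAssignment(UNIDENTIFIED)
    best.sort(key=lambda tm: tm[0])
    label = "/".join(t for t, _ in best)
    markers = best[0][1]
    return TaxonAssignment(
        taxon=label,
        matched_markers=frozenset(markers),
        matched_mz=tuple(markers[m] for m in sorted(markers)),
    )


@dataclass
class AssemblageSummary:
    """Per-context taxon percentages and the overall identification rate."""

    by_context: pd.DataFrame  # index context, columns taxa, values % of identified
    counts: pd.DataFrame  # same shape, raw counts
    n_analyzed: int
    n_identified: int

    @property
    def success_rate(self) -> float:
        """Identified / analyzed, in percent."""
        return 100.0 * self.n_identified / self.n_analyzed

    success_rate_pct = success_rate  # legible alias

    def to_csv(self, path) -> None:
        self.by_context.to_csv(path)


def summarize_assemblage(
    assignments: Sequence[tuple[str, TaxonAssignment]],
) -> AssemblageSummary:
    """Summarize (context label, assignment) pairs by stratigraphic context.

    Percentages use identified specimens as the denominator within each
    context (so each context row sums to 100); the success rate uses all
    analyzed specimens as denominator.
    """
    if not assignments:
        raise ConfigurationError("no assignments to summarize")
    rows = [
        {"context": ctx, "taxon": a.taxon, "identified": a.identified}
        for ctx, a in assignments
    ]
    frame = pd.DataFrame(rows)
    ident = frame[frame.identified]
    counts = (
        ident.groupby(["context", "taxon"]).size().unstack(fill_value=0)
        if len(ident)
        else pd.DataFrame()
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0 if len(counts) else counts
    return AssemblageSummary(
        by_context=pct,
        counts=counts,
        n_analyzed=len(frame),
        n_identified=int(frame.identified.sum()),
    )
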