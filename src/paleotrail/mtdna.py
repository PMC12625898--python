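"""Pairwise-difference statistics on mitochondrial sequence alignments.

Operates on a multiple sequence alignment of complete (or partial)
mitochondrial genomes. For a pair of rows, the comparable sites are the
positions where both carry an unambiguous base (A, C, G or T); gaps, N and
other ambiguity codes are treated as missing data and excluded from both
the numerator and the denominator. The pairwise-difference count is the
number of comparable sites at which the bases differ. Ranking all rows by
their distance to a focal sequence orders relatives from most to least
dissimilar, the desk-scale equivalent of a distance panel next to a
phylogeny.

Also provided: tallying of read support at diagnostic positions — sites
where a derived allele separates one lineage (e.g. Neanderthals) from
another — as (reads matching the derived allele, reads covering the site).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import AlignmentLookupError

__all__ = [
    "SequenceAlignment",
    "PairwiseDifferenceResult",
    "DiagnosticSite",
    "pairwise_differences",
    "rank_dissimilarity",
    "diagnostic_allele_fraction",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass
class SequenceAlignment:
    """Named equal-length rows over {A, C, G, T, N, -}, case-insensitive."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal lengths")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sequence names must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @classmethod
    def from_fasta(cls, path) -> "SequenceAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=name, description="")
            for name, row in zip(self.names, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise AlignmentLookupError(f"sequence {name!r} not in alignment") from None


@dataclass(frozen=True)
class PairwiseDifferenceResult:
    """Differences between two rows over their mutually comparable sites."""

    seq_a: str
    seq_b: str
    n_diff: int
    n_comparable: int

    def __post_init__(self):
        if not 0 <= self.n_diff <= self.n_comparable:
            raise ValueError("need 0 <= n_diff <= n_comparable")


def _as_bytes(row: str) -> np.ndarray:
    return np.frombuffer(row.encode("ascii"), dtype="S1")


def pairwise_differences(
    aln: SequenceAlignment, a: str, b: str
) -> PairwiseDifferenceResult:
    """Count differing and comparable sites between rows ``a`` and ``b``.

    Comparable sites are positions where both rows have a base in
    {A, C, G, T}; everything else (N, -, IUPAC ambiguity) is missing data.
    Symmetric in (a, b).
    """
    ra, rb = _as_bytes(aln.row(a)), _as_bytes(aln.row(b))
    ok = np.isin(ra, _BASES) & np.isin(rb, _BASES)
    n_comparable = int(ok.sum())
    n_diff = int((ra[ok] != rb[ok]).sum())
    return PairwiseDifferenceResult(a, b, n_diff, n_comparable)


def rank_dissimilarity(
    aln: SequenceAlignment, focal: str
) -> list[PairwiseDifferenceResult]:
    """All non-focal rows vs ``focal``, most dissimilar first.

    Ties in the difference count are broken lexicographically by sequence
    name so output is deterministic.
    """
    aln.row(focal)  # raises for unknown focal
    results = [
        pairwise_differences(aln, focal, name)
        for name in aln.names
        if name != focal
    ]
    results.sort(key=lambda r: (-r.n_diff, r.seq_b))
    return results


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic position with the bases observed in overlapping reads."""

    position: int  # 1-based alignment coordinate
    derived_allele: str
    reads: tuple[str, ...]

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        allowed = set("ACGTN")
        bases = {self.derived_allele.upper(), *(r.upper() for r in self.reads)}
        if not bases <= allowed:
            raise ValueError(f"bases must be in ACGTN, got {bases - allowed}")


def diagnostic_allele_fraction(
    table: Iterable[DiagnosticSite] | Sequence[DiagnosticSite],
) -> tuple[int, int]:
    """Tally derived-allele support over diagnostic positions.

    Returns ``(n_matching, n_covered)``: covered = reads overlapping any
    diagnostic position with a called base other than N; matching = those
    equal to the site's derived allele. Empty input gives (0, 0).
    """
    n_matching = n_covered = 0
    for site in table:
        derived = site.derived_allele.upper()
        for base in site.reads:
            base = base.upper()
            if base == "N":
                continue
            n_covered += 1
            if base == derived:
                n_matching += 1
    return n_matching, n_covered
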