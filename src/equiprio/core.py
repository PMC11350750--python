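"""Domain types and interval arithmetic shared by every pipeline stage.

Coordinates are 1-based and inclusive throughout (Ensembl convention), so a
single nucleotide is the interval ``[p, p]`` and two intervals overlap when
they share at least one base.  BED inputs (0-based, half-open) are converted
on read by :mod:`equiprio.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "EquiprioError",
    "CoordinateSystemError",
    "ConflictingAnnotationError",
    "InfeasibleScenarioError",
    "InputError",
    "GenomicInterval",
    "QtlRecord",
    "GeneRecord",
    "OrthologPair",
    "MarkerProbe",
    "MarkerLocus",
    "overlaps",
    "extend_interval",
]


class EquiprioError(Exception):
    """Base class for all package errors."""


class CoordinateSystemError(EquiprioError):
    """Intervals from different assemblies were compared."""


class ConflictingAnnotationError(EquiprioError):
    """Two annotation records for one SNP disagree."""


class InfeasibleScenarioError(EquiprioError):
    """A synthetic scenario config asks for more planted sites than exist."""


class InputError(EquiprioError):
    """Malformed or missing user input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed 1-based interval ``[start, end]`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (e.g. ``"3"`` or ``"chr3"``; compared verbatim).
    start, end : int
        1-based inclusive bounds; ``1 <= start <= end``.
    assembly : str
        Assembly label (e.g. ``"EquCab3.0"``).  Empty string acts as a
        wildcard: only two *non-empty, differing* labels raise on comparison.
    """

    chrom: str
    start: int
    end: int
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InputError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InputError(
                f"interval end ({self.end}) precedes start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Closed-interval point test: true iff ``start <= pos <= end``."""
        return chrom == self.chrom and self.start <= pos <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        _check_assembly(self, other)
        return (
            other.chrom == self.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def extend(self, flank: int) -> "GenomicInterval":
        return extend_interval(self, flank)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def _check_assembly(a: GenomicInterval, b: GenomicInterval) -> None:
    if a.assembly and b.assembly and a.assembly != b.assembly:
        raise CoordinateSystemError(
            f"cannot compare intervals on assemblies "
            f"{a.assembly!r} and {b.assembly!r}"
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two closed intervals share at least one position.

    Symmetric and reflexive.  Raises :class:`CoordinateSystemError` when the
    two intervals carry differing non-empty assembly labels.
    """
    _check_assembly(a, b)
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


def extend_interval(iv: GenomicInterval, flank: int) -> GenomicInterval:
    """Symmetric flank extension, clamped at position 1 on the left.

    The flank is applied in coordinate orientation on both sides regardless
    of strand; no right clamp is applied because chromosome lengths are not
    required as input.  Monotone in ``flank`` and always contains ``iv``.
    """
    if flank < 0:
        raise InputError(f"flank must be non-negative, got {flank}")
    return GenomicInterval(
        chrom=iv.chrom,
        start=max(1, iv.start - flank),
        end=iv.end + flank,
        assembly=iv.assembly,
    )


@dataclass(frozen=True)
class QtlRecord:
    """A trait-associated locus, given either as an interval or as a peak.

    Exactly one of ``interval`` / ``peak`` is populated, matching ``form``.
    ``peak`` is a ``(chrom, position)`` pair.
    """

    qtl_id: str
    species: str
    trait_category: str
    form: str  # "interval" | "peak"
    interval: Optional[GenomicInterval] = None
    peak: Optional[Tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.form not in ("interval", "peak"):
            raise InputError(f"unknown QTL form {self.form!r}")
        if self.form == "interval" and (self.interval is None or self.peak is not None):
            raise InputError(f"QTL {self.qtl_id}: form=interval requires interval only")
        if self.form == "peak" and (self.peak is None or self.interval is not None):
            raise InputError(f"QTL {self.qtl_id}: form=peak requires peak only")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic span.  Strand is stored but never used by
    overlap logic (flank extension is symmetric)."""

    gene_id: str
    symbol: str
    species: str
    interval: GenomicInterval
    strand: str = "unknown"  # "+", "-", "unknown"
    biotype: str = "protein_coding"


@dataclass(frozen=True)
class OrthologPair:
    """A source->target ortholog assignment with protein-level identity and
    similarity percentages (0-100, identity <= similarity when both known)."""

    source_gene_id: str
    target_gene_id: str
    percent_identity: Optional[float] = None
    percent_similarity: Optional[float] = None

    def __post_init__(self) -> None:
        for v, name in (
            (self.percent_identity, "percent_identity"),
            (self.percent_similarity, "percent_similarity"),
        ):
            if v is not None and not (0.0 <= v <= 100.0):
                raise InputError(f"{name} out of [0, 100]: {v}")
        if (
            self.percent_identity is not None
            and self.percent_similarity is not None
            and self.percent_identity > self.percent_similarity
        ):
            raise InputError(
                f"identity ({self.percent_identity}) exceeds similarity "
                f"({self.percent_similarity}) for "
                f"{self.source_gene_id}->{self.target_gene_id}"
            )


@dataclass(frozen=True)
class MarkerProbe:
    """A single array probe assaying one genomic position."""

    probe_name: str
    chrom: str
    position: int
    alleles: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError(
                f"probe {self.probe_name}: position must be >= 1, "
                f"got {self.position}"
            )


@dataclass(frozen=True)
class MarkerLocus:
    """The deduplication group of all probes assaying one (chrom, position)."""

    chrom: str
    position: int
    probe_names: Tuple[str, ...]
    gene_ids: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.probe_names:
            raise InputError("a marker locus must carry at least one probe")

    @property
    def n_probes(self) -> int:
        return len(self.probe_names)
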