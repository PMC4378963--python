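"""Core domain types shared across the pipeline.

All genomic intervals are 0-based, half-open, on the forward strand, with an
explicit strand flag.  Dialect-specific conventions (1-based inclusive tblout
coordinates, reversed minus-strand bounds, ...) are converted at the I/O
boundary and never leak past it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

STRANDS = ("+", "-")

CHROM_CLASSES = ("macro", "micro", "unassigned")


class AvincError(Exception):
    """Base class for package errors."""


class ParseError(AvincError):
    """Malformed input; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def _check_interval(start: int, end: int, strand: str) -> None:
    if not (0 <= start < end):
        raise ValueError(f"invalid interval [{start}, {end}): need 0 <= start < end")
    if strand not in STRANDS:
        raise ValueError(f"invalid strand {strand!r}")


@dataclass
class Hit:
    """One homology-search match of a family model to a genomic interval."""

    genome_id: str
    scaffold_id: str
    family_id: str
    start: int
    end: int
    strand: str
    bit_score: float
    evalue: float
    pseudogene: bool = False
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_interval(self.start, self.end, self.strand)
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FamilyMeta:
    """Family identity, clan membership, RNA class and curated GA bit-score cutoff."""

    family_id: str
    clan_id: Optional[str]
    rna_class: str
    ga_threshold: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ga_threshold):
            raise ValueError(f"{self.family_id}: GA threshold must be finite")


@dataclass
class Annotation:
    """A competed, collapsed ncRNA locus assigned to one family and RNA class."""

    genome_id: str
    scaffold_id: str
    family_id: str
    start: int
    end: int
    strand: str
    best_bit_score: float
    best_evalue: float
    rna_class: str = ""
    n_merged: int = 1

    def __post_init__(self) -> None:
        _check_interval(self.start, self.end, self.strand)
        if self.n_merged < 1:
            raise ValueError("n_merged must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return (
            f"{self.genome_id}|{self.scaffold_id}:{self.start}-{self.end}"
            f"({self.strand})|{self.family_id}"
        )


@dataclass(frozen=True)
class FilterConfig:
    """Hit retention rule: bit score >= family GA and E-value <= evalue_max."""

    evalue_max: float = 5e-4
    apply_ga: bool = True

    def __post_init__(self) -> None:
        if not self.evalue_max > 0:
            raise ValueError("evalue_max must be positive")


@dataclass
class GenomeIndex:
    """Scaffold ids and lengths of one genome assembly."""

    genome_id: str
    scaffolds: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        seen = set()
        for sid, length in self.scaffolds:
            if sid in seen:
                raise ValueError(f"duplicate scaffold id {sid!r} in {self.genome_id}")
            seen.add(sid)
            if length <= 0:
                raise ValueError(f"scaffold {sid!r} has non-positive length {length}")

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(self.scaffolds)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.scaffolds)


@dataclass(frozen=True)
class ReadInterval:
    """One aligned read (BED6 record)."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    read_id: str = "."

    def __post_init__(self) -> None:
        _check_interval(self.start, self.end, self.strand)


@dataclass(frozen=True)
class Region:
    """A bare genomic interval (used for null-model regions)."""

    scaffold_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        _check_interval(self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConservationConfig:
    """Minimum fraction of genomes a family must appear in to be retained."""

    min_genome_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_genome_fraction <= 1):
            raise ValueError("min_genome_fraction must be in (0, 1]")


@dataclass(frozen=True)
class EnrichmentTable:
    """A 2x2 contingency table with its Fisher exact test result.

    Layout::

        [[a, b],
         [c, d]]

    ``p_value_str`` renders extreme p-values as a "<1e-300" bound to avoid
    underflow ambiguity.
    """

    a: int
    b: int
    c: int
    d: int
    p_value: float
    odds_ratio: float
    sidedness: str = "greater"

    @property
    def p_value_str(self) -> str:
        if self.p_value < 1e-300:
            return "<1e-300"
        return f"{self.p_value:.6g}"


@dataclass
class CountVector:
    """Read counts over a list of intervals, in input order."""

    ids: List[str]
    counts: "np.ndarray"  # type: ignore[name-defined]  # noqa: F821
    strand_aware: bool


@dataclass
class NullSample:
    """Random un-annotated regions with (optionally) their read counts."""

    regions: List[Region]
    seed: int
    counts: Optional[CountVector] = None


@dataclass(frozen=True)
class ExpressionThreshold:
    """Minimum read count that keeps the empirical null exceedance <= target."""

    min_count: int
    target_fpr: float
    achieved_fpr: float

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not (0 < self.target_fpr < 1):
            raise ValueError("target_fpr must be in (0, 1)")


@dataclass(frozen=True)
class DomainOrderSpec:
    """Reference (human) order of a lncRNA's RNA-domain families."""

    lncrna_id: str
    reference_order: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.reference_order)) != len(self.reference_order):
            raise ValueError(f"{self.lncrna_id}: duplicate domain ids in reference order")


@dataclass(frozen=True)
class SyntenyCheck:
    """Observed domain order on one scaffold versus the reference order.

    ``consistent`` is None (n/a) when fewer than two domains were observed.
    """

    lncrna_id: str
    genome_id: str
    scaffold_id: str
    observed_order: Tuple[str, ...]
    n_domains: int
    consistent: Optional[bool]
    orientation: str  # "forward" | "reverse" | "n/a"


def sort_annotations(annotations: Sequence[Annotation]) -> List[Annotation]:
    """Canonical ordering: scaffold, start, end, family, strand."""
    return sorted(
        annotations,
        key=lambda a: (a.scaffold_id, a.start, a.end, a.family_id, a.strand),
    )
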