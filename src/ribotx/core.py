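"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive on the forward genome axis throughout the
package; conversion to 0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-")
VALID_LIBRARIES = ("TEX_plus", "TEX_minus")

#: TSS class labels: primary, secondary, internal, antisense, intergenic (novel).
TSS_CLASSES = ("P", "S", "I", "A", "N")

LEADER_STATUSES = ("leaderless", "leadered", "long_leader", "undefined")


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single-chromosome genome: name plus an uppercase A/C/G/T/N string."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError("genome sequence must be non-empty")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(f"genome contains non-ACGTN characters: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice on the forward strand."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise IndexError(f"slice [{start},{end}] outside genome of length {len(self)}")
        return self.sequence[start - 1 : end]


@dataclass
class GeneModel:
    """An annotated ORF.

    ``start``/``end`` are 1-based inclusive forward-axis coordinates
    (start <= end regardless of strand).  The start codon sits at ``start``
    on + genes and at ``end`` on - genes.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    category: str = "other"
    operon_id: Optional[str] = None
    stoichiometry: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.stoichiometry is not None and self.stoichiometry < 1:
            raise FormatError(f"gene {self.gene_id}: stoichiometry must be positive")

    @property
    def start_codon_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FivePrimeProfile:
    """Per-position 5'-end read counts for one library on one strand.

    ``counts`` is a sparse map position -> count holding only positions with
    count > 0.
    """

    library: str
    strand: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library not in VALID_LIBRARIES:
            raise ValueError(f"library must be one of {VALID_LIBRARIES}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")
        for pos, c in self.counts.items():
            if pos < 1:
                raise ValueError(f"position {pos} < 1")
            if c <= 0:
                raise ValueError(f"stored count must be > 0 (position {pos}: {c})")

    def add(self, position: int, count: int) -> None:
        if count < 0:
            raise ValueError("count must be non-negative")
        if count == 0:
            return
        if position < 1:
            raise ValueError(f"position {position} < 1")
        self.counts[position] = self.counts.get(position, 0) + count

    def positions(self) -> list[int]:
        return sorted(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PeakCluster:
    """A run of nearby nonzero 5'-end positions on one strand."""

    positions: list[int]
    counts: list[int]
    strand: str

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.counts):
            raise ValueError("positions and counts must have equal length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        if any(c <= 0 for c in self.counts):
            raise ValueError("all counts must be > 0")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class CandidateTSS:
    """A TSS candidate: the maximal peak of one sub-cluster."""

    position: int
    strand: str
    height: int
    validated: bool = False

    def __post_init__(self) -> None:
        if self.height < 1:
            raise ValueError("height must be >= 1")


@dataclass
class TSSRecord:
    """A classified TSS."""

    position: int
    strand: str
    height: int
    class_label: str
    gene_id: Optional[str] = None
    utr_length: Optional[int] = None
    leader_status: str = "undefined"

    def __post_init__(self) -> None:
        if self.class_label not in TSS_CLASSES:
            raise ValueError(f"class_label must be one of {TSS_CLASSES}")
        if self.class_label in ("P", "S") and self.gene_id is None:
            raise ValueError("P/S records require a gene_id")
        if self.leader_status not in LEADER_STATUSES:
            raise ValueError(f"leader_status must be one of {LEADER_STATUSES}")
        if self.utr_length is not None and self.utr_length < 0:
            raise ValueError("utr_length must be non-negative or None")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
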