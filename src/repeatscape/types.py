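"""Shared domain types.

All genomic intervals are 0-based half-open; conversion to/from 1-based
inclusive conventions happens only at format boundaries (see
:mod:`repeatscape.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A named contig with residues over {A,C,G,T,N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TeAnnotation:
    """A classified repeat interval.

    ``te_class`` is one of LINE, SINE, LTR, DNA, other; simple repeats and
    low-complexity intervals carry te_class "other" with ``raw_class``
    preserving the annotation source's label so they can be separated from
    true TE rows.
    """

    contig: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    raw_class: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.family:
            raise ValueError("family must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SsrLocus:
    """A perfect tandem-repeat interval.

    ``unit`` is the observed repeat unit on the forward strand;
    ``canonical_motif`` is the rotation/strand-normalized unit so that e.g.
    TAGAA, CTATT and AATAG all pool under one motif.
    """

    contig: str
    start: int
    end: int
    unit: str
    canonical_motif: str
    n_units: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.n_units * len(self.unit):
            raise ValueError(
                "array length must equal n_units x unit length: "
                f"[{self.start},{self.end}) vs {self.n_units} x {len(self.unit)}"
            )

    @property
    def array_length(self) -> int:
        return self.end - self.start

    @property
    def unit_length(self) -> int:
        return len(self.unit)


@dataclass
class NeSeries:
    """An effective-population-size trajectory (e.g. PSMC output).

    Times are years before present, strictly increasing; generation time and
    mutation rate are carried as metadata only.
    """

    species: str
    points: list  # list[(time_before_present_years, ne)]
    generation_time: float = 3.0
    mutation_rate: Optional[float] = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(ne <= 0 for _, ne in self.points):
            raise ValueError("Ne must be positive at every point")

    @property
    def times(self):
        return [t for t, _ in self.points]

    @property
    def ne_values(self):
        return [ne for _, ne in self.points]


@dataclass
class Region:
    """A plain genomic interval with optional side/source metadata."""

    contig: str
    start: int
    end: int
    side: Optional[str] = None  # "5p" or "3p" relative to a source locus
    source: Optional[int] = None  # index of the source locus, if any

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Read:
    """A sequencing read; qualities, if present on input, are discarded."""

    id: str
    sequence: str
    # provenance fields filled by the simulator, absent for real data
    contig: Optional[str] = None
    start: Optional[int] = None
    strand: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)
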