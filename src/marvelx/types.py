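"""Core domain types shared across the package.

Coordinate convention: everything in memory is 1-based inclusive (GTF style).
Splice junctions are identified by their first and last *intronic* bases, the
convention used by STAR's SJ.out.tab output. rMATS 0-based exon starts are
converted once, at the read boundary, and never again.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import pandas as pd


class JunctionKey(NamedTuple):
    """A splice junction: the intron removed by splicing (1-based inclusive)."""

    chrom: str
    start: int
    end: int

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"

    @classmethod
    def from_string(cls, s: str) -> "JunctionKey":
        chrom, start, end = s.rsplit(":", 2)
        return cls(chrom, int(start), int(end))

    def validate(self) -> "JunctionKey":
        if not self.chrom:
            raise ValueError("junction chromosome must be nonempty")
        if self.start > self.end:
            raise ValueError(f"junction start > end: {self}")
        return self


class EventType(str, enum.Enum):
    SE = "SE"
    MXE = "MXE"
    RI = "RI"
    A5SS = "A5SS"
    A3SS = "A3SS"
    AFE = "AFE"
    ALE = "ALE"


class Modality(str, enum.Enum):
    INCLUDED = "included"
    EXCLUDED = "excluded"
    BIMODAL = "bimodal"
    MIDDLE = "middle"
    MULTIMODAL = "multimodal"


class SubModality(str, enum.Enum):
    PRIMARY = "primary"
    DISPERSED = "dispersed"
    NONE = "none"


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"exon end < start: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]  # strand-ordered (transcription order)
    biotype: Optional[str] = None
    cds: list[Exon] = field(default_factory=list)  # strand-ordered CDS intervals

    @property
    def genomic_exons(self) -> list[Exon]:
        """Exons in ascending genomic order regardless of strand."""
        return sorted(self.exons, key=lambda e: e.start)

    def first_exon(self) -> Exon:
        """First exon in transcription order."""
        ge = self.genomic_exons
        return ge[0] if self.strand != "-" else ge[-1]

    def last_exon(self) -> Exon:
        ge = self.genomic_exons
        return ge[-1] if self.strand != "-" else ge[0]


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class Annotation:
    """Gene/transcript/exon models read from a GTF."""

    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    @property
    def n_exons(self) -> int:
        return sum(len(t.exons) for t in self.transcripts.values())

    def all_exons(self) -> list[tuple[str, str, Exon]]:
        """(gene_id, transcript_id, exon) triples over the whole annotation."""
        out = []
        for t in self.transcripts.values():
            for e in t.exons:
                out.append((t.gene_id, t.transcript_id, e))
        return out


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event with its junction evidence sets.

    ``included_junctions`` support the alternative (included) form,
    ``excluded_junctions`` the skipped form. For MXE the "included" form is
    the first alternative exon of the rMATS record.
    """

    event_id: str
    event_type: EventType
    gene_id: str
    chrom: str
    strand: str
    included_junctions: tuple[JunctionKey, ...]
    excluded_junctions: tuple[JunctionKey, ...]
    # role-tagged coordinates: for SE/MXE the alternative exon(s); for RI the
    # intron interval; for A5SS/A3SS the alternative extension segment.
    alt_coords: tuple[tuple[int, int], ...] = ()

    def all_junctions(self) -> tuple[JunctionKey, ...]:
        return self.included_junctions + self.excluded_junctions


@dataclass(frozen=True)
class IndependentIntron:
    """Retained-intron candidate overlapping no annotated exon of any gene."""

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    skip_junction: JunctionKey

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Session:
    """Validated in-memory analysis session for one dataset.

    All matrices share an identical, canonically ordered cell axis.
    """

    mode: str  # "plate" | "droplet"
    junction_counts: pd.DataFrame  # junctions x cells, index "chrom:start:end"
    expression: pd.DataFrame  # genes x cells, linear-scale normalized
    annotation: Optional[Annotation] = None
    events: Optional[list[SpliceEvent]] = None
    cell_metadata: Optional[pd.DataFrame] = None  # index = cell ids
    embedding: Optional[pd.DataFrame] = None  # cells x 2 (droplet)
    intron_coverage: Optional[pd.DataFrame] = None  # introns x cells (plate RI)
    gene_counts: Optional[pd.DataFrame] = None  # genes x cells raw counts (droplet)
    junction_strand: Optional[dict[str, str]] = None

    @property
    def cells(self) -> list[str]:
        return list(self.junction_counts.columns)

    def groups(self, column: str = "group") -> pd.Series:
        if self.cell_metadata is None or column not in self.cell_metadata:
            raise ValueError(f"cell metadata column {column!r} not available")
        return self.cell_metadata[column]
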