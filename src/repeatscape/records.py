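"""Domain record types shared across the pipeline.

All internal coordinates are 0-based half-open (BED convention); formats that
are 1-based inclusive on disk (TRF .dat, 12-column tabular hits) are converted
at parse time and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(slots=True)
class SequenceRecord:
    """A named nucleotide sequence.

    Lowercase residues denote soft-masked (repeat-annotated) bases; 'N'/'n'
    are ambiguity characters and count as neither repeat nor non-repeat.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(slots=True)
class GenomicInterval:
    """Half-open interval on a named sequence (BED semantics)."""

    seq_id: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class PafRecord:
    """One PAF mapping line (minimap2 dialect, optional tags folded in)."""

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (self.query_start < self.query_end <= self.query_length):
            raise ValueError(f"bad query coordinates for read {self.query_id}")
        if self.residue_matches > self.block_length:
            raise ValueError(f"matches exceed block length for {self.query_id}")

    @property
    def aligned_query_span(self) -> int:
        """Aligned span on the query (query_end - query_start)."""
        return self.query_end - self.query_start


@dataclass(slots=True)
class TabularHit:
    """One 12-column tabular similarity-search hit (BLAST outfmt 6 dialect).

    Coordinates are kept 1-based inclusive exactly as on disk.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


_GAP = "-"


@dataclass(slots=True)
class AlignedPair:
    """A gapped copy-vs-consensus alignment for one annotated repeat copy."""

    copy_row: str
    consensus_row: str
    family: str
    superfamily: str
    location: GenomicInterval
    subgenome: str = ""

    def __post_init__(self) -> None:
        if len(self.copy_row) != len(self.consensus_row):
            raise ValueError(
                f"row lengths differ ({len(self.copy_row)} vs "
                f"{len(self.consensus_row)}) at {self.location.seq_id}:"
                f"{self.location.start}"
            )
        if len(self.copy_row) == 0:
            raise ValueError("alignment has no columns")
        for a, b in zip(self.copy_row, self.consensus_row):
            if a == _GAP and b == _GAP:
                raise ValueError("column gapped in both rows")


@dataclass(slots=True)
class TandemArray:
    """A detected tandem-repeat array with its monomer consensus."""

    location: GenomicInterval
    period: int
    copy_number: float
    monomer_consensus: str
    mean_monomer_identity: float

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass(slots=True)
class SatFamilyCandidate:
    """Arrays pooled by identical canonical monomer, pre-curation."""

    consensus: str
    monomer_length: int
    total_copy_number: float
    total_bp: int
    member_arrays: list[TandemArray] = field(default_factory=list)


@dataclass(slots=True)
class SatFamily:
    """A curated satellite-DNA family (canonical monomer consensus)."""

    id: str
    consensus: str
    members: list[SatFamilyCandidate] = field(default_factory=list)
    novel: bool = True

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def total_copy_number(self) -> float:
        return sum(c.total_copy_number for c in self.members)

    @property
    def total_bp(self) -> int:
        return sum(c.total_bp for c in self.members)
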