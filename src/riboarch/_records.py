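"""Core record types shared across the pipeline.

All genomic intervals are 0-based half-open; conversions from 1-based
inclusive conventions (GFF3, Infernal tblout) happen at the I/O boundary
only. Minus-strand intergenic regions are stored reverse-complemented so
that position always increases toward the downstream gene's start codon,
which lets every later windowing step (terminator scan, junction gaps)
ignore orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (IUPAC beyond ACGTN not handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with its genome, phylum and orthology context."""

    genome_id: str
    species: str
    phylum: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    gene_id: str
    cog_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntergenicRegion:
    """Strand-aware upstream region of one gene.

    ``start``/``end`` are contig coordinates. ``sequence`` is in transcript
    orientation of the downstream gene: for ``orientation == '-'`` it is the
    reverse complement of the plus-strand contig slice, so index 0 is the
    5'-most transcribed position and the sequence runs toward the start codon.
    """

    genome_id: str
    contig: str
    start: int
    end: int
    downstream_gene_id: str
    orientation: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"region upstream of {self.downstream_gene_id}: interval length "
                f"{self.end - self.start} != sequence length {len(self.sequence)}"
            )
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")

    @property
    def region_id(self) -> str:
        return f"{self.genome_id}|{self.downstream_gene_id}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AptamerHit:
    """One covariance-model match, the atomic unit of riboswitch evidence.

    Coordinates are 0-based half-open in the coordinate system of the scanned
    target (here: an intergenic region in transcript orientation).
    """

    hit_id: str
    model_class: str
    start: int
    end: int
    strand: str
    bit_score: float
    evalue: float
    region_ref: str = ""
    genome_id: str = ""
    contig: str = ""
    family: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"hit {self.hit_id}: start must be < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TerminatorCall:
    """A stem-loop + T-run pair supporting a tandem junction."""

    aptamer_ref: str
    t_run: tuple[int, int]
    hairpin: "HairpinFold"
    gap: int


@dataclass(frozen=True)
class HairpinFold:
    """A single stem-loop structure with its nearest-neighbor free energy."""

    stem_pairs: tuple[tuple[int, int], ...]  # outermost first
    loop: tuple[int, int]
    dg: float  # kcal/mol at 37 degC
    span: tuple[int, int]

    def dot_bracket(self, length: int) -> str:
        chars = ["."] * length
        for i, j in self.stem_pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


@dataclass
class ContiguousGroup:
    """All aptamer hits sharing one intergenic region / regulated gene."""

    region_ref: str
    regulated_gene_ids: list[str]
    aptamers: list[AptamerHit]
    junction_gaps: list[int] = field(default_factory=list)
    junction_classes: list[str] = field(default_factory=list)
    group_class: str = ""  # single | tandem | adjacent | mixed
    homogeneity: str = "n/a"  # homogeneous | heterogeneous | n/a
    architecture_string: str = ""
    terminator_evidence: list[bool] = field(default_factory=list)

    @property
    def n_aptamers(self) -> int:
        return len(self.aptamers)
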