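"""Shared domain types: sequence records, gene features, RS motifs, references.

Coordinates on all in-memory features are 0-based half-open on the plus strand
of the carrying sequence; minus-strand genes keep plus-strand coordinates with
``strand == '-'`` and their sequence is extracted as the reverse complement on
demand.  File output (GFF3) converts to 1-based inclusive at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from Bio.Seq import Seq

__all__ = [
    "IUPAC_DNA",
    "SeqRecord",
    "CloneRecord",
    "Tissue",
    "RSMotif",
    "GeneFeature",
    "VReference",
    "JReference",
    "revcomp",
    "translate",
]

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

DEFECT_KINDS = (
    "stop_codon",
    "frameshift",
    "missing_leader",
    "bad_splice_donor",
    "bad_splice_acceptor",
    "defective_rs",
    "bad_length",
    "missing_conserved_aa",
)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string; incomplete trailing codon is dropped."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable].upper()).translate())


class Tissue(str, Enum):
    SPLEEN = "spleen"
    TONSIL = "tonsil"
    BLOOD = "blood"
    OTHER = "other"


@dataclass
class SeqRecord:
    """A DNA sequence; lowercase letters mark soft-masked regions."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"record {self.id!r} contains non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CloneRecord:
    """A rearranged productive V-(D)-J-C cDNA clone with its tissue of origin."""

    id: str
    tissue: Tissue
    seq: str

    def __post_init__(self) -> None:
        if isinstance(self.tissue, str) and not isinstance(self.tissue, Tissue):
            self.tissue = Tissue(self.tissue)
        if len(self.seq) < 100:
            raise ValueError(f"clone {self.id!r} is shorter than 100 nt")


@dataclass
class RSMotif:
    """A heptamer/spacer/nonamer recombination-signal hit.

    ``strand`` gives the orientation of the signal itself: '+' means the
    heptamer reads CACAGTG-like left to right (signal points leftward into the
    element that ends at the heptamer), '-' means the signal is reverse
    complemented on the plus strand (nonamer-rc .. spacer .. heptamer-rc, as on
    the 5' side of D and J genes).
    """

    heptamer_span: tuple[int, int]
    spacer_len: int
    nonamer_span: tuple[int, int]
    strand: str
    heptamer_mismatches: int
    nonamer_mismatches: int
    score: float
    non_canonical_cac: bool = False
    spacer_slack: int = 0

    @property
    def start(self) -> int:
        return min(self.heptamer_span[0], self.nonamer_span[0])

    @property
    def end(self) -> int:
        return max(self.heptamer_span[1], self.nonamer_span[1])


@dataclass
class GeneFeature:
    """An annotated germline gene with its functionality call and defects."""

    label: str
    gene_type: str  # V, D, J, C
    span: tuple[int, int]
    strand: str
    functionality: str = "F"  # F, ORF, P
    defects: list[str] = field(default_factory=list)
    exon_spans: list[tuple[int, int]] = field(default_factory=list)
    rs: list[RSMotif] = field(default_factory=list)
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.gene_type not in {"V", "D", "J", "C"}:
            raise ValueError(f"bad gene_type {self.gene_type!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.span[0] >= self.span[1]:
            raise ValueError(f"empty span {self.span} for {self.label!r}")
        for d in self.defects:
            if d not in DEFECT_KINDS:
                raise ValueError(f"unknown defect {d!r}")

    def sequence(self, genome: str) -> str:
        """Gene sequence in transcriptional orientation."""
        sub = genome[self.span[0] : self.span[1]]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass
class VReference:
    """A germline V gene used for homology search and anchor projection.

    ``seq`` is the full plus-orientation gene region (L-PART1 + intron +
    V-EXON); spans are 0-based half-open within ``seq``.  ``cys2_codon_start``
    indexes the 2nd-CYS codon within the spliced coding sequence
    (L-PART1 + V-EXON), the anchor from which CDR3-IMGT extraction starts.
    """

    id: str
    seq: str
    lpart1_span: tuple[int, int]
    intron_span: tuple[int, int]
    vexon_span: tuple[int, int]
    cys2_codon_start: int
    subgroup: str | None = None
    # codon index (within the spliced coding sequence) -> expected residue,
    # e.g. the 1st-CYS / TRP / 2nd-CYS anchors of the V-REGION
    conserved_aa: dict[int, str] = field(default_factory=dict)

    @property
    def coding_seq(self) -> str:
        a, b = self.lpart1_span
        c, d = self.vexon_span
        return self.seq[a:b] + self.seq[c:d]

    @property
    def v_trail(self) -> str:
        """Germline CDR3 trail: coding nucleotides after the 2nd-CYS codon."""
        return self.coding_seq[self.cys2_codon_start + 3 :]


@dataclass
class JReference:
    """A germline J coding region; ``anchor_offset`` is the nt index of the
    F/W (position 118) codon within ``seq``."""

    id: str
    seq: str
    anchor_offset: int

    @property
    def head(self) -> str:
        """Germline J contribution to CDR3 (5' of the anchor codon)."""
        return self.seq[: self.anchor_offset]
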