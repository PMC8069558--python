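"""Ground-truth synthetic TRA/TRD-like loci and rearranged clone repertoires.

The generator emulates the structural layout the analysis assumes: a V cluster
built from tandemly duplicated units (with a fraction of genes inverted), a
D-J-C cluster in which every D gene is flanked by a 12-spacer signal on its 5'
side and a 23-spacer signal on its 3' side, J genes carrying a 5' 12-spacer
signal, an F/W-G-X-G anchor motif and a 3' splice donor, a C gene with three
translated exons plus one untranslated exon, and a single inverted V gene
downstream of C.  Divergence between duplicated genes is substitution-only so
that every true coordinate is preserved exactly and can serve as an oracle.

Rearranged clones are assembled as trimmed V + [P][N] + (trimmed D + [P][N])*k
+ trimmed J + C-head, with D genes drawn without replacement in genomic order,
palindromic (P) nucleotides added only at untrimmed ends as the reverse
complement of the terminal nucleotides, junction frame enforced by resampling
the non-templated (N) inserts, and uniform somatic hypermutation applied after
assembly.  Truth records everything pre-mutation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .features import (
    CloneRecord,
    GeneFeature,
    JReference,
    SeqRecord,
    Tissue,
    VReference,
    revcomp,
    translate,
)
from .params import Params

__all__ = [
    "LocusBlueprint",
    "RepertoireBlueprint",
    "LocusTruth",
    "CloneTruth",
    "generate_locus",
    "generate_repertoire",
]

_NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

# Fixed synthetic V gene geometry (nt).  The spliced coding sequence is
# L-PART1 (46) + L-PART2 (11) + V-REGION (288) = 345 nt = 115 codons; the
# leader occupies the first 19 codons.  Conserved residues sit at V-REGION
# codons 23 (1st-CYS), 41 (TRP) and 93 (2nd-CYS); the three codons after the
# 2nd-CYS are the germline CDR3 trail.
LPART1_LEN = 46
LPART2_LEN = 11
VREGION_CODONS = 96
VREGION_LEN = VREGION_CODONS * 3
INTRON_LEN = 89
LEADER_CODONS = 19
CYS1_CODON = 23   # 1-based within V-REGION
TRP_CODON = 41
CYS2_CODON = VREGION_CODONS - 3  # = 93; three trail codons follow
CODING_LEN = LPART1_LEN + LPART2_LEN + VREGION_LEN
CYS2_CODING_OFFSET = LEADER_CODONS * 3 + (CYS2_CODON - 1) * 3  # nt index of 2nd-CYS codon
V_TRAIL_LEN = CODING_LEN - (CYS2_CODING_OFFSET + 3)  # 9 nt

J_ANCHOR_TO_DONOR = 21  # F/W codon + G-X-G + three more codons before the donor
C_HEAD_LEN = 60



_CONSERVED_AA = {
    LEADER_CODONS + CYS1_CODON - 1: "C",
    LEADER_CODONS + TRP_CODON - 1: "W",
    LEADER_CODONS + CYS2_CODON - 1: "C",
}

def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _rand_codons(rng: np.random.Generator, n: int) -> list[str]:
    out = []
    while len(out) < n:
        codon = _rand_dna(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return out


@dataclass
class LocusBlueprint:
    """Layout of a synthetic locus.

    ``genes_per_subgroup`` maps subgroup size to the number of V subgroups of
    that size (emulating the skewed subgroup-size distribution of real TR
    loci); subgroups of the same size are co-duplicated within one tandem
    duplication unit.  ``inverted_fraction`` defaults to the observed 26/83
    minus-strand V genes, ``pseudogene_fraction`` to the observed 55%
    non-functional share.
    """

    genes_per_subgroup: dict[int, int] = field(
        default_factory=lambda: {8: 1, 7: 1, 6: 1, 3: 2, 1: 3}
    )
    n_d: int = 6
    n_j: int = 4
    d_length_choices: tuple[int, ...] = (13, 11, 9, 13, 13, 11)
    pseudogene_fraction: float = 0.55
    inverted_fraction: float = 26 / 83
    duplication_unit_size: int = 3000
    include_inverted_v_after_c: bool = True
    intergenic_length_range: tuple[int, int] = (300, 700)
    within_subgroup_divergence: float = 0.06
    noncanonical_d3_heptamer: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_d < 1:
            raise ValueError("n_d must be >= 1")
        for p in (self.pseudogene_fraction, self.inverted_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.genes_per_subgroup or any(
            s < 1 or s > 8 or k < 0 for s, k in self.genes_per_subgroup.items()
        ):
            raise ValueError("genes_per_subgroup must map sizes 1..8 to counts")
        if sum(self.genes_per_subgroup.values()) < 1:
            raise ValueError("at least one V subgroup required")

    @property
    def n_v_subgroups(self) -> int:
        return sum(self.genes_per_subgroup.values())

    @property
    def n_v_genes(self) -> int:
        return sum(size * count for size, count in self.genes_per_subgroup.items())


@dataclass
class RepertoireBlueprint:
    """Statistical model of a simulated delta-chain cDNA cohort.

    Defaults mirror the reference cohort of 61 clones: tissue split
    22 spleen / 15 tonsil / 24 blood and D-count distribution proportional to
    4 / 14 / 20 / 17 / 6 for 0-4 incorporated D genes.
    """

    n_clones: int = 61
    d_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 4 / 61, 1: 14 / 61, 2: 20 / 61, 3: 17 / 61, 4: 6 / 61}
    )
    tissue_proportions: dict[str, float] = field(
        default_factory=lambda: {"spleen": 22 / 61, "tonsil": 15 / 61, "blood": 24 / 61}
    )
    trim_geom_p: float = 0.5
    max_v_trim: int = 4
    max_d_trim: int = 2  # per D end; keeps every retained D >= 5 nt
    max_j_trim: int = 8
    n_insertion_mean: float = 2.0
    max_n_insertion: int = 6
    p_insertion_probability: float = 0.75
    shm_rate: float = 0.01
    max_frame_attempts: int = 200
    seed: int = 0

    def validate(self) -> None:
        for dist in (self.d_count_distribution, self.tissue_proportions):
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"distribution must sum to 1, got {total}")
        if not 0 <= self.shm_rate <= 0.2:
            raise ValueError("shm_rate must lie in [0, 0.2]")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


@dataclass
class CloneTruth:
    """Pre-mutation ground truth for one simulated clone."""

    clone_id: str
    tissue: str
    v_label: str
    j_label: str
    d_labels: list[str]
    # ordered (source, start, end) spans within cdr3_nt; source is one of
    # "V_trail", "P", "N", "D:<label>", "J_head"
    segments: list[tuple[str, int, int]]
    d_spans_within_d: list[tuple[int, int]]
    cdr3_nt: str
    mutated_positions: list[int]
    v_trim: int
    j_trim: int

    @property
    def d_count(self) -> int:
        return len(self.d_labels)


@dataclass
class LocusTruth:
    """Per-gene truth plus the germline reference material for downstream steps."""

    genes: list[GeneFeature]
    v_references: list[VReference]          # one structured ancestor per subgroup
    v_gene_refs: dict[str, VReference]      # per-gene structure (coding seq, anchors)
    d_refs: list[tuple[str, str]]           # genomic order (label, D-REGION seq)
    j_refs: list[JReference]
    c_exons: list[str]
    clones: dict[str, CloneTruth] = field(default_factory=dict)

    def functional(self, gene_type: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.gene_type == gene_type and g.functionality == "F"]


# ---------------------------------------------------------------------------
# germline gene construction


def _make_v_coding(rng: np.random.Generator) -> str:
    codons = _rand_codons(rng, LEADER_CODONS + VREGION_CODONS)
    codons[0] = "ATG"
    codons[LEADER_CODONS + CYS1_CODON - 1] = "TGT"
    codons[LEADER_CODONS + TRP_CODON - 1] = "TGG"
    codons[LEADER_CODONS + CYS2_CODON - 1] = "TGC"
    return "".join(codons)


def _make_intron(rng: np.random.Generator) -> str:
    return "GT" + _rand_dna(rng, INTRON_LEN - 4) + "AG"


def _assemble_v_gene(coding: str, intron: str) -> str:
    return coding[:LPART1_LEN] + intron + coding[LPART1_LEN:]


def _mutate_v(
    coding: str, intron: str, rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Substitution-only divergence preserving structure, frame and anchors."""
    protected_codons = {
        0,
        LEADER_CODONS + CYS1_CODON - 1,
        LEADER_CODONS + TRP_CODON - 1,
        LEADER_CODONS + CYS2_CODON - 1,
    }
    cod = [coding[i : i + 3] for i in range(0, len(coding), 3)]
    for idx in range(len(cod)):
        if idx in protected_codons:
            continue
        codon = list(cod[idx])
        for j in range(3):
            if rng.random() < rate:
                codon[j] = str(rng.choice([b for b in "ACGT" if b != codon[j]]))
        if "".join(codon) not in _STOPS:
            cod[idx] = "".join(codon)
    new_intron = list(intron)
    for i in range(2, len(intron) - 2):  # keep GT..AG
        if rng.random() < rate:
            new_intron[i] = str(rng.choice([b for b in "ACGT" if b != new_intron[i]]))
    return "".join(cod), "".join(new_intron)


_BROKEN_HEPTAMER = "TGTACAA"  # 6 mismatches to the consensus heptamer


def _inject_defect(
    coding: str, intron: str, heptamer: str, kind: str, rng: np.random.Generator
) -> tuple[str, str, str]:
    cod = list(coding)
    if kind == "stop_codon":
        # random V-REGION codon away from the conserved anchors and the trail
        while True:
            idx = int(rng.integers(LEADER_CODONS + 2, LEADER_CODONS + CYS2_CODON - 2))
            if idx not in (LEADER_CODONS + CYS1_CODON - 1, LEADER_CODONS + TRP_CODON - 1):
                break
        stop = str(rng.choice(["TAA", "TAG", "TGA"]))
        cod[idx * 3 : idx * 3 + 3] = list(stop)
    elif kind == "frameshift":
        pos = int(rng.integers(LEADER_CODONS * 3 + 30, CYS2_CODING_OFFSET - 30))
        del cod[pos]
    elif kind == "missing_leader":
        cod[0:3] = list("CTG")
    elif kind == "missing_conserved_aa":
        cod[(LEADER_CODONS + TRP_CODON - 1) * 3 : (LEADER_CODONS + TRP_CODON - 1) * 3 + 3] = list("CGG")
    elif kind == "bad_splice_donor":
        intron = "CT" + intron[2:]
    elif kind == "bad_splice_acceptor":
        intron = intron[:-2] + "AC"
    elif kind == "defective_rs":
        heptamer = _BROKEN_HEPTAMER
    else:
        raise ValueError(f"unknown defect kind {kind!r}")
    return "".join(cod), intron, heptamer


def _make_j_gene(rng: np.random.Generator, length: int, use_trp: bool = False) -> tuple[str, int]:
    """Return (coding seq, anchor offset).  The coding region contains no GT
    dinucleotide so the downstream splice donor is unambiguous."""
    head_len = length - J_ANCHOR_TO_DONOR
    anchor = ("TGG" if use_trp else "TTT") + "GGA"
    # X codon of F/W-G-X-G, avoiding stops and GT
    while True:
        x = _rand_dna(rng, 3)
        if x not in _STOPS and "GT" not in (anchor[-1] + x) and "GT" not in x:
            break
    tail3 = []
    prev = "A"
    gxg_g = "GGA"
    while len(tail3) < 3:
        codon = _rand_dna(rng, 3)
        joint = (tail3[-1][-1] if tail3 else gxg_g[-1]) + codon
        if codon not in _STOPS and "GT" not in codon and "GT" not in joint[:2]:
            tail3.append(codon)
    suffix = anchor + x + gxg_g + "".join(tail3)
    # the head is read in the frame anchored at the F/W codon whatever the
    # trimming, so its anchor-aligned codons must be stop-free
    while True:
        rem = head_len % 3
        head = _rand_dna(rng, rem) + "".join(_rand_codons(rng, head_len // 3))
        if "GT" in head or "GT" in head[-1:] + suffix[0]:
            continue
        if any(head[i : i + 3] in _STOPS for i in range(rem, head_len, 3)):
            continue
        break
    seq = head + suffix
    assert "GT" not in seq and len(seq) == length
    return seq, head_len


def _make_d_region(rng: np.random.Generator, length: int) -> str:
    """A D coding region readable through all three phases (no stop in any frame)."""
    while True:
        seq = _rand_dna(rng, length)
        frames_ok = all(
            all(seq[i : i + 3] not in _STOPS for i in range(f, length - 2, 3))
            for f in range(3)
        )
        if frames_ok:
            return seq


# ---------------------------------------------------------------------------
# locus assembly


class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0

    def add(self, seq: str) -> tuple[int, int]:
        span = (self.pos, self.pos + len(seq))
        self.parts.append(seq)
        self.pos = span[1]
        return span

    def sequence(self) -> str:
        return "".join(self.parts)


def _forward_rs(heptamer: str, spacer: int, nonamer: str, rng: np.random.Generator) -> str:
    return heptamer + _rand_dna(rng, spacer) + nonamer


def _reverse_rs(heptamer: str, spacer: int, nonamer: str, rng: np.random.Generator) -> str:
    """RS on the 5' side of an element, reverse complemented on the plus strand."""
    return revcomp(nonamer) + _rand_dna(rng, spacer) + revcomp(heptamer)


def generate_locus(bp: LocusBlueprint, params: Params) -> tuple[SeqRecord, LocusTruth]:
    """Generate a synthetic locus sequence with exhaustive ground truth."""
    bp.validate()
    rng = np.random.default_rng(bp.seed)
    hept, nona = params.heptamer_consensus, params.nonamer_consensus
    b = _Builder()
    genes: list[GeneFeature] = []
    v_references: list[VReference] = []
    v_gene_refs: dict[str, VReference] = {}

    def intergenic() -> None:
        lo, hi = bp.intergenic_length_range
        b.add(_rand_dna(rng, int(rng.integers(lo, hi + 1))))

    def functionality_plan() -> tuple[str, str | None]:
        if rng.random() >= bp.pseudogene_fraction:
            return "F", None
        if rng.random() < 0.6:
            return "P", str(rng.choice(["stop_codon", "frameshift"]))
        return "ORF", str(
            rng.choice(
                [
                    "missing_leader",
                    "bad_splice_donor",
                    "bad_splice_acceptor",
                    "defective_rs",
                    "missing_conserved_aa",
                ]
            )
        )

    def place_v(label: str, subgroup: str, coding: str, intron: str,
                inverted: bool, forced_functionality: str | None = None) -> GeneFeature:
        if forced_functionality == "F":
            func, defect = "F", None
        else:
            func, defect = functionality_plan()
        heptamer = hept
        if defect is not None:
            coding, intron, heptamer = _inject_defect(coding, intron, heptamer, defect, rng)
        gene_seq = _assemble_v_gene(coding, intron)
        rs = _forward_rs(heptamer, params.spacer_lengths["V-RS"], nona, rng)
        block = gene_seq + rs
        if inverted:
            start0 = b.pos
            b.add(revcomp(block))
            span = (start0 + len(rs), start0 + len(block))
            strand = "-"
        else:
            span0 = b.add(block)
            span = (span0[0], span0[0] + len(gene_seq))
            strand = "+"
        feature = GeneFeature(
            label=label,
            gene_type="V",
            span=span,
            strand=strand,
            functionality=func,
            defects=[defect] if defect else [],
            subgroup=subgroup,
        )
        genes.append(feature)
        if func == "F":
            lp1 = (0, LPART1_LEN)
            intr = (LPART1_LEN, LPART1_LEN + len(intron))
            vex = (intr[1], len(gene_seq))
            v_gene_refs[label] = VReference(
                id=label, seq=gene_seq, lpart1_span=lp1, intron_span=intr,
                vexon_span=vex, cys2_codon_start=CYS2_CODING_OFFSET, subgroup=subgroup,
                conserved_aa=dict(_CONSERVED_AA),
            )
        return feature

    # --- V cluster as tandem duplication units --------------------------------
    b.add(_rand_dna(rng, 300))
    subgroup_idx = 0
    unit_families = sorted(bp.genes_per_subgroup.items(), key=lambda kv: -kv[0])
    for size, n_subgroups in unit_families:
        if n_subgroups == 0:
            continue
        slot_names = []
        slot_ancestors = []
        for _ in range(n_subgroups):
            subgroup_idx += 1
            name = f"SG{subgroup_idx}"
            slot_names.append(name)
            coding, intron = _make_v_coding(rng), _make_intron(rng)
            slot_ancestors.append((coding, intron))
            gene_seq = _assemble_v_gene(coding, intron)
            v_references.append(
                VReference(
                    id=name, seq=gene_seq, lpart1_span=(0, LPART1_LEN),
                    intron_span=(LPART1_LEN, LPART1_LEN + len(intron)),
                    vexon_span=(LPART1_LEN + len(intron), len(gene_seq)),
                    cys2_codon_start=CYS2_CODING_OFFSET, subgroup=name,
                    conserved_aa=dict(_CONSERVED_AA),
                )
            )
        for copy in range(1, size + 1):
            for name, (coding, intron) in zip(slot_names, slot_ancestors):
                coding_m, intron_m = _mutate_v(
                    coding, intron, bp.within_subgroup_divergence, rng
                )
                inverted = bool(rng.random() < bp.inverted_fraction)
                place_v(f"{name}-{copy}", name, coding_m, intron_m, inverted)
                intergenic()

    # --- D genes --------------------------------------------------------------
    d_refs: list[tuple[str, str]] = []
    lengths = list(bp.d_length_choices)
    for i in range(bp.n_d):
        length = lengths[i % len(lengths)]
        d_seq = _make_d_region(rng, length)
        label = f"D{i + 1}"
        hept3 = hept
        first_9mer = not any(len(s) == 9 for _, s in d_refs)
        if bp.noncanonical_d3_heptamer and length == 9 and first_9mer:
            hept3 = hept[:2] + "T" + hept[3:]  # third position C->T
        five_rs = _reverse_rs(hept, params.spacer_lengths["5'D-RS"], nona, rng)
        three_rs = _forward_rs(hept3, params.spacer_lengths["3'D-RS"], nona, rng)
        b.add(five_rs)
        span = b.add(d_seq)
        b.add(three_rs)
        genes.append(
            GeneFeature(label=label, gene_type="D", span=span, strand="+",
                        functionality="F")
        )
        d_refs.append((label, d_seq))
        intergenic()

    # --- J genes --------------------------------------------------------------
    j_refs: list[JReference] = []
    for i in range(bp.n_j):
        length = int(rng.integers(49, 61))
        j_seq, anchor = _make_j_gene(rng, length)
        label = f"J{i + 1}"
        b.add(_reverse_rs(hept, params.spacer_lengths["J-RS"], nona, rng))
        span = b.add(j_seq)
        b.add("GT" + _rand_dna(rng, 4))  # donor splice head
        genes.append(
            GeneFeature(label=label, gene_type="J", span=span, strand="+",
                        functionality="F")
        )
        j_refs.append(JReference(id=label, seq=j_seq, anchor_offset=anchor))
        intergenic()

    # --- C gene (TRAC/TRDC-like geometry) -------------------------------------
    exon_lens = (261, 45, 108, 573)
    intron_lens = (1456, 1008, 660)
    ex1 = "".join(_rand_codons(rng, exon_lens[0] // 3))
    ex2 = "".join(_rand_codons(rng, exon_lens[1] // 3))
    ex3 = "".join(_rand_codons(rng, exon_lens[2] // 3 - 1)) + "TAA"
    ex4 = _rand_dna(rng, exon_lens[3])
    c_exons = [ex1, ex2, ex3, ex4]
    exon_spans = []
    for i, ex in enumerate(c_exons):
        exon_spans.append(b.add(ex))
        if i < 3:
            b.add("GT" + _rand_dna(rng, intron_lens[i] - 4) + "AG")
    genes.append(
        GeneFeature(label="C1", gene_type="C", span=(exon_spans[0][0], exon_spans[-1][1]),
                    strand="+", functionality="F", exon_spans=exon_spans)
    )
    intergenic()

    # --- inverted V after C (TRDV3-like) --------------------------------------
    if bp.include_inverted_v_after_c:
        subgroup_idx += 1
        name = f"SG{subgroup_idx}"
        coding, intron = _make_v_coding(rng), _make_intron(rng)
        gene_seq = _assemble_v_gene(coding, intron)
        v_references.append(
            VReference(id=name, seq=gene_seq, lpart1_span=(0, LPART1_LEN),
                       intron_span=(LPART1_LEN, LPART1_LEN + len(intron)),
                       vexon_span=(LPART1_LEN + len(intron), len(gene_seq)),
                       cys2_codon_start=CYS2_CODING_OFFSET, subgroup=name,
                       conserved_aa=dict(_CONSERVED_AA))
        )
        coding_m, intron_m = _mutate_v(coding, intron, bp.within_subgroup_divergence, rng)
        place_v(f"{name}-1", name, coding_m, intron_m, inverted=True,
                forced_functionality="F")
    b.add(_rand_dna(rng, 300))

    record = SeqRecord(id="synthetic_locus", seq=b.sequence(),
                       description="synthetic TRA/TRD-like locus")
    truth = LocusTruth(genes=genes, v_references=v_references,
                       v_gene_refs=v_gene_refs, d_refs=d_refs, j_refs=j_refs,
                       c_exons=c_exons)
    return record, truth


# ---------------------------------------------------------------------------
# repertoire assembly


def _geom_trim(rng: np.random.Generator, p: float, cap: int) -> int:
    return min(int(rng.geometric(p) - 1), cap)


def _p_ext_right(seq: str, k: int) -> str:
    """Palindromic extension appended after an untrimmed 3' end."""
    return revcomp(seq[-k:])


def _p_ext_left(seq: str, k: int) -> str:
    """Palindromic extension prepended before an untrimmed 5' end."""
    return revcomp(seq[:k])


def generate_repertoire(
    locus_truth: LocusTruth, bp: RepertoireBlueprint, params: Params
) -> tuple[list[CloneRecord], LocusTruth]:
    """Simulate rearranged cDNA clones from a locus truth.

    Returns the clone records plus a copy of the truth carrying per-clone
    :class:`CloneTruth` entries (the input truth is left untouched).
    """
    bp.validate()
    locus_truth = dataclasses.replace(locus_truth, clones={})
    rng = np.random.default_rng(bp.seed)
    functional_v = [g.label for g in locus_truth.functional("V")]
    functional_j = [j.id for j in locus_truth.j_refs]
    if not functional_v or not locus_truth.d_refs or not functional_j:
        raise ValueError("locus truth must contain at least one functional V, D and J")
    c_head = locus_truth.c_exons[0][:C_HEAD_LEN]

    d_counts = sorted(bp.d_count_distribution)
    d_probs = np.array([bp.d_count_distribution[k] for k in d_counts])
    tissues = sorted(bp.tissue_proportions)
    t_probs = np.array([bp.tissue_proportions[t] for t in tissues])

    clones: list[CloneRecord] = []
    for idx in range(bp.n_clones):
        clone_id = f"clone{idx + 1:04d}"
        tissue = tissues[int(rng.choice(len(tissues), p=t_probs))]
        k = d_counts[int(rng.choice(len(d_counts), p=d_probs))]
        k = min(k, len(locus_truth.d_refs))

        def draw_genes() -> tuple:
            """Redraw V/J/D choices each attempt: only productive (in-frame,
            stop-free) rearrangements survive, as in a real repertoire."""
            v_label = functional_v[int(rng.integers(len(functional_v)))]
            j_label = functional_j[int(rng.integers(len(functional_j)))]
            vref = locus_truth.v_gene_refs[v_label]
            jref = next(j for j in locus_truth.j_refs if j.id == j_label)
            d_idx = sorted(
                rng.choice(len(locus_truth.d_refs), size=k, replace=False).tolist()
            )
            chosen_d = [locus_truth.d_refs[i] for i in d_idx]
            return v_label, j_label, vref, jref, chosen_d

        def attempt() -> tuple | None:
            """Draw genes, trims, P additions and N inserts; None when no
            in-frame, stop-free junction arises within a few N redraws."""
            v_label, j_label, vref, jref, chosen_d = draw_genes()
            v_trim = _geom_trim(rng, bp.trim_geom_p, min(bp.max_v_trim, V_TRAIL_LEN))
            j_trim = _geom_trim(rng, bp.trim_geom_p, min(bp.max_j_trim, jref.anchor_offset - 1))
            trail = vref.v_trail[: V_TRAIL_LEN - v_trim]
            j_head = jref.head[j_trim:]
            d_parts = []
            for _, d_seq in chosen_d:
                lt = _geom_trim(rng, bp.trim_geom_p, bp.max_d_trim)
                rt = _geom_trim(rng, bp.trim_geom_p, bp.max_d_trim)
                d_parts.append((d_seq, lt, rt, d_seq[lt : len(d_seq) - rt]))

            def draw_p(end_seq: str, untrimmed: bool, left: bool) -> str:
                if not untrimmed or params.max_p_len == 0:
                    return ""
                if rng.random() >= bp.p_insertion_probability:
                    return ""
                klen = int(rng.integers(1, params.max_p_len + 1))
                return _p_ext_left(end_seq, klen) if left else _p_ext_right(end_seq, klen)

            # boundaries: after V, after each D (the last attaches to J)
            segments_right = [(seg, lt == 0) for (d_seq, lt, rt, seg) in d_parts] + [
                (j_head, j_trim == 0)
            ]
            boundary_left = [(trail, v_trim == 0)] + [
                (seg, rt == 0) for (d_seq, lt, rt, seg) in d_parts
            ]
            n_boundaries = len(d_parts) + 1
            left_ps: list[str] = []
            right_ps: list[str] = []
            for bidx in range(n_boundaries):
                lseq, l_untrimmed = boundary_left[bidx]
                rseq, r_untrimmed = segments_right[bidx]
                left_ps.append(draw_p(lseq, l_untrimmed and len(lseq) > 0, left=False))
                right_ps.append(draw_p(rseq, r_untrimmed and len(rseq) > 0, left=True))

            def build(n_lens: list[int]):
                segs: list[tuple[str, int, int]] = []
                d_spans: list[tuple[int, int]] = []
                out = []
                pos = 0

                def push(source: str, s: str) -> None:
                    nonlocal pos
                    if s:
                        segs.append((source, pos, pos + len(s)))
                        out.append(s)
                        pos += len(s)

                push("V_trail", trail)
                for bidx in range(n_boundaries):
                    push("P", left_ps[bidx])
                    push("N", _rand_dna(rng, n_lens[bidx]))
                    push("P", right_ps[bidx])
                    if bidx < len(d_parts):
                        d_seq, lt, rt, seg = d_parts[bidx]
                        d_spans.append((lt, len(d_seq) - rt))
                        push(f"D:{chosen_d[bidx][0]}", seg)
                push("J_head", j_head)
                return "".join(out), segs, d_spans

            for _n_try in range(25):
                n_lens = [
                    min(int(rng.poisson(bp.n_insertion_mean)), bp.max_n_insertion)
                    for _ in range(n_boundaries)
                ]
                cand, segs, d_spans = build(n_lens)
                if len(cand) % 3 == 0 and "*" not in translate(cand):
                    return cand, segs, d_spans, v_trim, j_trim, v_label, j_label, vref, jref, chosen_d
            return None

        result = None
        for _outer in range(bp.max_frame_attempts):
            result = attempt()
            if result is not None:
                break
        if result is None:
            raise RuntimeError(
                f"could not assemble an in-frame, stop-free junction for {clone_id}"
            )
        cdr3, segs, d_spans, v_trim, j_trim, v_label, j_label, vref, jref, chosen_d = result

        full = (
            vref.coding_seq[: CYS2_CODING_OFFSET + 3]
            + cdr3
            + jref.seq[jref.anchor_offset :]
            + c_head
        )
        # somatic hypermutation, uniform independent substitutions
        mutated_positions: list[int] = []
        if bp.shm_rate > 0:
            arr = list(full)
            hits = np.nonzero(rng.random(len(arr)) < bp.shm_rate)[0]
            for h in hits:
                arr[h] = str(rng.choice([x for x in "ACGT" if x != arr[h]]))
                mutated_positions.append(int(h))
            full = "".join(arr)

        clones.append(CloneRecord(id=clone_id, tissue=Tissue(tissue), seq=full))
        locus_truth.clones[clone_id] = CloneTruth(
            clone_id=clone_id, tissue=tissue, v_label=v_label, j_label=j_label,
            d_labels=[lab for lab, _ in chosen_d], segments=segs,
            d_spans_within_d=d_spans, cdr3_nt=cdr3,
            mutated_positions=mutated_positions, v_trim=v_trim, j_trim=j_trim,
        )
    return clones, locus_truth
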