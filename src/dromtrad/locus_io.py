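"""Readers/writers for on-disk formats and the coordinate-convention boundary.

Internal coordinates are 0-based half-open; everything written to disk (GFF3)
is 1-based inclusive, matching NCBI-style positions.  This module is the only
place that conversion happens.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .features import CloneRecord, GeneFeature, RSMotif, SeqRecord, Tissue

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_clones",
    "write_clone_tissues",
    "write_gff",
    "read_gff",
]

log = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-FASTA file, preserving order and letter case.

    Raises on empty files, duplicate ids and non-IUPAC characters.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_clones(fasta_path: str | Path, tissue_table_path: str | Path) -> list[CloneRecord]:
    """Read clone cDNA FASTA plus a sidecar TSV (columns: id, tissue).

    Every FASTA id must appear in the TSV; TSV ids with no FASTA record are
    warned about and ignored.  Per-tissue counts are logged.
    """
    records = read_fasta(fasta_path)
    table: dict[str, str] = {}
    lines = [ln for ln in Path(tissue_table_path).read_text().splitlines() if ln.strip()]
    for ln in lines:
        parts = ln.split("\t")
        if parts[0] in ("id",):  # optional header
            continue
        if len(parts) < 2:
            raise ValueError(f"malformed tissue table line: {ln!r}")
        table[parts[0]] = parts[1].strip()
    if not table:
        raise ValueError(f"tissue table {tissue_table_path} is empty")
    missing = [r.id for r in records if r.id not in table]
    if missing:
        raise ValueError(f"clone ids missing from tissue table: {missing}")
    extra = set(table) - {r.id for r in records}
    if extra:
        log.warning("tissue table ids with no FASTA record (ignored): %s", sorted(extra))
    clones = [CloneRecord(id=r.id, tissue=Tissue(table[r.id]), seq=r.seq) for r in records]
    counts = Counter(c.tissue.value for c in clones)
    log.info("clone tissue counts: %s", dict(counts))
    return clones


def write_clone_tissues(clones: list[CloneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\ttissue\n")
        for c in clones:
            fh.write(f"{c.id}\t{c.tissue.value}\n")


_GFF_COLUMNS = "seqid source type start end score strand phase attributes".split()


def _format_attributes(feature: GeneFeature) -> str:
    attrs = [f"ID={feature.label}", f"gene_type={feature.gene_type}",
             f"functionality={feature.functionality}"]
    if feature.subgroup is not None:
        attrs.append(f"subgroup={feature.subgroup}")
    if feature.defects:
        attrs.append("defects=" + ",".join(feature.defects))
    if feature.exon_spans:
        # stored 1-based inclusive, pipe-separated
        attrs.append(
            "exons=" + "|".join(f"{a + 1}-{b}" for a, b in feature.exon_spans)
        )
    return ";".join(attrs)


def write_gff(features: list[GeneFeature], path: str | Path, seqid: str = "locus") -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    Two features with identical label raise an error when their spans overlap.
    """
    by_label: dict[str, GeneFeature] = {}
    for f in features:
        other = by_label.get(f.label)
        if other is not None and f.span[0] < other.span[1] and other.span[0] < f.span[1]:
            raise ValueError(f"overlapping features with identical label {f.label!r}")
        by_label[f.label] = f
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.span, x.label)):
            start, end = f.span[0] + 1, f.span[1]  # 0-based half-open -> 1-based inclusive
            row = [seqid, "dromtrad", f"{f.gene_type}_gene", str(start), str(end), ".",
                   f.strand, ".", _format_attributes(f)]
            fh.write("\t".join(row) + "\n")


def read_gff(path: str | Path) -> list[GeneFeature]:
    """Read a GFF3 file written by :func:`write_gff` back into features."""
    features: list[GeneFeature] = []
    for ln in Path(path).read_text().splitlines():
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {ln!r}")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
        start, end = int(cols[3]) - 1, int(cols[4])  # back to 0-based half-open
        exon_spans = []
        if "exons" in attrs:
            for part in attrs["exons"].split("|"):
                a, b = part.split("-")
                exon_spans.append((int(a) - 1, int(b)))
        features.append(
            GeneFeature(
                label=attrs["ID"],
                gene_type=attrs["gene_type"],
                span=(start, end),
                strand=cols[6],
                functionality=attrs.get("functionality", "F"),
                defects=attrs["defects"].split(",") if "defects" in attrs else [],
                exon_spans=exon_spans,
                subgroup=attrs.get("subgroup"),
            )
        )
    return features
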