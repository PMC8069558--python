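#!/usr/bin/env python
"""Self-comparison dot plot of the locus: direct and inverted internal
homology segments, grouped into duplication units with their gene content."""

import argparse
from pathlib import Path

from dromtrad.dotplot import detect_units, render_dotplot, self_match
from dromtrad.locus_io import read_fasta, read_gff


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--word-size", type=int, default=12)
    ap.add_argument("--min-seg-len", type=int, default=300)
    ap.add_argument("--max-gap", type=int, default=60)
    args = ap.parse_args()

    record = read_fasta(args.outdir / "locus.fasta")[0]
    annotation = read_gff(args.outdir / "annotation.gff3")
    matches = self_match(record, word_size=args.word_size,
                         min_seg_len=args.min_seg_len, max_gap=args.max_gap)
    with open(args.outdir / "dotplot_matches.tsv", "w") as fh:
        fh.write("a_start\ta_end\tb_start\tb_end\torientation\tlength\tidentity_pct\n")
        for m in matches:
            fh.write(f"{m.span_a[0]}\t{m.span_a[1]}\t{m.span_b[0]}\t{m.span_b[1]}\t"
                     f"{m.orientation}\t{m.length}\t{m.identity:.1f}\n")

    units = detect_units(matches, annotation)
    with open(args.outdir / "duplication_units.tsv", "w") as fh:
        fh.write("unit\tmember_span\torientation_pattern\tgenes\n")
        for i, u in enumerate(units, start=1):
            for span, genes in zip(u.member_spans, u.genes):
                fh.write(f"U{i}\t{span[0]}-{span[1]}\t{u.orientation_pattern}\t"
                         f"{','.join(genes) or '-'}\n")

    render_dotplot(matches, args.outdir / "dotplot.png", seq_len=len(record.seq))

    n_inv = sum(m.orientation == "inverted" for m in matches)
    print(f"{len(matches)} homology segments ({len(matches) - n_inv} direct, "
          f"{n_inv} inverted); {len(units)} duplication units")
    biggest = max(units, key=lambda u: len(u.member_spans), default=None)
    if biggest is not None:
        print(f"largest unit: {len(biggest.member_spans)} copies containing "
              f"{sorted({g for gs in biggest.genes for g in gs})}")
    print(f"wrote dotplot_matches.tsv, duplication_units.tsv, dotplot.png to {args.outdir}/")


if __name__ == "__main__":
    main()
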