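#!/usr/bin/env python
"""CDR3 length tables: by V group x tissue, and by number of incorporated D
genes (clones with no recognisable D reported separately)."""

import argparse
import csv
from pathlib import Path

from dromtrad.cdr3_decompose import JunctionDecomposition, Segment
from dromtrad.repertoire_stats import (
    render_table,
    summarize_by_dcount,
    summarize_by_v_tissue,
)


def _load(path: Path) -> list[JunctionDecomposition]:
    decs = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            n = int(row["cdr3_len_aa"]) * 3
            k = int(row["d_count"])
            segments = []
            pos = 0
            for i in range(k):
                end = n if i == k - 1 else pos + n // max(k, 1)
                segments.append(Segment(f"D:D{i + 1}", (pos, end), d_span=(0, end - pos)))
                pos = end
            if not segments and n:
                segments = [Segment("N", (0, n))]
            decs.append(JunctionDecomposition(
                clone_id=row["clone_id"], v_label=row["v_group"],
                j_label=row["j_label"], cdr3_nt="N" * n, cdr3_aa=row["cdr3_aa"],
                segments=segments, productive=row["productive"] == "1",
                tissue=row["tissue"],
            ))
    return decs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    decs = _load(args.outdir / "junctions.tsv")
    by_vt = summarize_by_v_tissue(decs)
    by_dc, zero_d = summarize_by_dcount(decs)
    by_vt.to_csv(args.outdir / "cdr3_by_v_tissue.tsv", sep="\t", index=False)
    by_dc.to_csv(args.outdir / "cdr3_by_dcount.tsv", sep="\t", index=False)

    total = by_vt[(by_vt.tissue == "all") & (by_vt.v_group == "all")].iloc[0]
    print(f"{int(total.n_clones)} productive clones; mean CDR3 "
          f"{total.mean_len:.1f} aa (range {int(total.min_len)}-{int(total.max_len)})")
    print("\nCDR3 length by V group and tissue:")
    print(render_table(by_vt))
    print("\nCDR3 length by number of incorporated D genes:")
    print(render_table(by_dc))
    if not zero_d.empty:
        z = zero_d.iloc[0]
        print(f"\nexcluded from the D-count table: {int(z.n_clones)} clones with "
              f"no recognisable D (mean {z.mean_len:.1f} aa)")
    print(f"\nwrote cdr3_by_v_tissue.tsv, cdr3_by_dcount.tsv to {args.outdir}/")


if __name__ == "__main__":
    main()
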