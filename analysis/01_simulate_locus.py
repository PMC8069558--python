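#!/usr/bin/env python
"""Simulate a TRA/TRD-like locus with ground truth.

Writes the locus FASTA, the true gene annotation as GFF3, the germline
reference material for downstream steps, and a metadata file so later steps
can regenerate the identical truth from the seed.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from dromtrad.locus_io import write_fasta, write_gff
from dromtrad.params import load_params
from dromtrad.synthetic_locus import LocusBlueprint, generate_locus


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = load_params()
    bp = LocusBlueprint(seed=args.seed)
    record, truth = generate_locus(bp, params)

    write_fasta([record], args.outdir / "locus.fasta")
    write_gff(truth.genes, args.outdir / "locus_truth.gff3", seqid=record.id)
    (args.outdir / "locus_meta.json").write_text(
        json.dumps({"seed": args.seed, "blueprint": "default"}, indent=2) + "\n"
    )

    counts = Counter((g.gene_type, g.functionality) for g in truth.genes)
    n_v = sum(v for (t, _), v in counts.items() if t == "V")
    n_func = counts.get(("V", "F"), 0)
    print(f"locus: {len(record.seq):,} nt; {n_v} V genes "
          f"({n_func} functional, {n_v - n_func} ORF/P), "
          f"{sum(v for (t, _), v in counts.items() if t == 'D')} D, "
          f"{sum(v for (t, _), v in counts.items() if t == 'J')} J, 1 C")
    print(f"wrote locus.fasta, locus_truth.gff3 to {args.outdir}/")


if __name__ == "__main__":
    main()
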