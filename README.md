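# dromtrad

Annotation and δ-chain repertoire analysis of a TRA/TRD-like T-cell receptor
locus, built around the questions raised by "γδ-high" species such as camels:
a small germline V repertoire whose expressed diversity comes from somatic
hypermutation and from stringing up to four D genes into a single CDR3.

The package implements the full computational chain as a reusable library with
a ground-truth simulator, so that every step can be validated on loci and
repertoires where the right answer is known:

- **Germline gene annotation** (`germline_scan`): V, D, J and C genes located
  by recombination-signal (RS) motifs (heptamer `CACAGTG` / nonamer
  `ACAAAAACC` with the 12/23-spacer rule), splice sites and homology to
  references, and classified IMGT-style as **F** (functional), **ORF**
  (open frame with splice/RS/conserved-residue defects) or **P** (pseudogene:
  stop codons or frameshifts).
- **Subgroup and same-gene classification** (`gene_classify`): single-linkage
  clustering of V genes at >75% V-REGION nucleotide identity; one-to-one
  matching of gene sets at >97% identity ("same gene"); a structure-based
  fallback for heavily defective pseudogenes.
- **CDR3-IMGT junction decomposition** (`cdr3_decompose`): the conserved
  anchors (V 2nd-CYS, codon 104; J F/W of the F/W-G-X-G motif, codon 118) are
  projected from germline alignments onto each cDNA clone, the CDR3 (codons
  105–117) is excised, and germline D segments are assigned by an exact
  dynamic program: non-overlapping stretches of ≥5 consecutive nucleotides
  matching a germline D, each D used at most once, labels in genomic order,
  maximising total matched nucleotides. Leftover nucleotides are labelled P
  (palindromic, at untrimmed germline ends) or N (non-templated). Recurrent
  unassigned motifs are reported as candidate D genes missing from the
  reference (`flag_unplaced_d`).
- **Repertoire statistics** (`repertoire_stats`): CDR3 length summaries by
  V group × tissue and by number of incorporated D genes.
- **Phylogenetics** (`phylo`): p-distance with pairwise deletion,
  Saitou–Nei neighbour joining with deterministic tie-breaks, bootstrap
  support, monophyly checks, newick I/O.
- **Duplication analysis** (`dotplot`): genomic self-comparison by exact
  k-mer seeding and diagonal/anti-diagonal chaining; direct and inverted
  internal homology segments grouped into duplication units with their gene
  content.
- **Simulation** (`synthetic_locus`): loci with tandemly duplicated V units,
  inverted genes, injected functionality defects, and rearranged
  V–(D)–J–C clone cohorts with trimming, P/N additions and uniform somatic
  hypermutation — all with exhaustive ground truth.

## Worked example

The analysis is organised as numbered drivers under `analysis/`, chained
through `results/`:

```bash
python analysis/01_simulate_locus.py --seed 1
python analysis/02_annotate_germline.py
python analysis/03_classify_subgroups.py
python analysis/04_simulate_repertoire.py --seed 2
python analysis/05_decompose_junctions.py
python analysis/06_repertoire_tables.py
python analysis/07_phylogeny.py
python analysis/08_dotplot.py
```

With these seeds the run prints, step by step:

```
locus: 40,468 nt; 31 V genes (15 functional, 16 ORF/P), 6 D, 4 J, 1 C
annotated 42 genes; span recall 100.0%, functionality agreement 100.0%, 0 spurious calls
31 V genes -> 9 subgroups (truth: 9)
same-gene matching (>97% identity): 15 matched, 0/0 unmatched
61 clones; tissues {'blood': 30, 'tonsil': 15, 'spleen': 16}
decomposed 61 junctions; D-count agreement with simulation truth 51/61
57 productive clones; mean CDR3 23.2 aa (range 14-31)
NJ tree over 15 functional V genes (sum of branch lengths 3.2129, bootstrap 100 replicates)
subgroup monophyly: SG1:yes, SG2:yes, SG3:yes
49 homology segments (29 direct, 20 inverted); 5 duplication units
```

Reading the output: the annotation step recovers every simulated gene with
its exact coordinates and F/ORF/P call; the 75% identity rule reconstructs
the simulated subgroup structure exactly; the junction decomposition credits
a D gene to every ≥5-nt germline stretch, so its D counts agree with the
generative truth for 51/61 clones (the misses are chance ≥5-nt matches inside
non-templated additions — see `docs/methods.md`); and the D-count table shows
the expected CDR3 length progression (here 18.7 → 23.2 → 26.5 → 30.4 aa for
1→4 D genes), the signature of multi-D incorporation driving CDR3 length.

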