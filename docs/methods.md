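# Methods

This note records the models, conventions and design choices behind the
package, and what validation on simulated data does and does not establish.

## The locus model

The simulator (`synthetic_locus`) emulates the structural layout of a
mammalian TRA/TRD locus at desk scale: a V cluster of tandemly duplicated
units, a D–J–C cluster, and a single transcriptionally inverted V gene
downstream of C.

**V gene geometry.** Every synthetic V gene is L-PART1 (46 nt, starting ATG)
+ intron (89 nt, `GT…AG`) + V-EXON (L-PART2 11 nt + V-REGION 288 nt), i.e. a
345-nt spliced coding sequence of 115 codons with a 19-codon leader, followed
by a 23-spacer RS. Real V-EXONs run roughly 270–320 nt, which brackets this
choice. Conserved residues sit at V-REGION codons 23 (1st-CYS), 41 (TRP) and
93 (2nd-CYS). IMGT numbering places the 2nd-CYS at position 104 of a *gapped*
V-REGION; the synthetic sequences are ungapped, so the package anchors the
2nd-CYS three codons before the V-REGION 3′ end (the ungapped equivalent,
leaving a 9-nt germline CDR3 trail) and records the anchor offset explicitly
on every `VReference`. All anchor projection works from these per-reference
offsets, never from absolute IMGT positions, so the convention is a data
property rather than a code assumption.

**Duplication units.** Subgroups of equal size are co-duplicated: one
ancestor gene per subgroup forms a unit template, and each copy of the unit
contributes one diverged member to every subgroup in it. This mirrors how
multimember V subgroups in real loci arise interleaved within repeated
blocks. Divergence is substitution-only (default 6% within subgroups), which
keeps every true coordinate exact and usable as an oracle; the cost is that
the simulator never exercises indel tolerance in the annotation aligner
(a stated limitation). A configurable fraction of V genes (default 26/83) is
inverted in place.

**Functionality defects.** A V gene is non-functional with probability 0.55
(the observed non-functional share in the reference locus); non-functional
genes receive one injected defect — a stop codon or 1-nt frameshift
(pseudogenes, 60%) or a broken leader, splice site, RS or conserved residue
(ORF, 40%). The P/ORF split within the non-functional class is a simulator
choice, not a reported value.

**D, J and C genes.** D genes are 9/11/13-nt regions readable in all three
frames, flanked by an inverted 12-spacer RS (5′) and a 23-spacer RS (3′); the
first 9-nt D carries the naturally observed non-canonical 3′ heptamer
(third position C→T). J genes are 49–60 nt with a 5′ inverted 12-spacer RS,
an F/W-G-X-G motif in frame with the 3′ `GT` donor, and no internal `GT`
(making the donor unambiguous); their anchor-aligned codons are stop-free,
as in real J-REGIONs. The C gene uses the reference exon geometry
261/45/108/573 nt with introns 1456/1008/660 nt; the three translated exons
encode 137 aa excluding the stop — the value the exon arithmetic gives.

## Annotation conventions

`scan_rs` is an exact sliding-window scanner: heptamer/nonamer mismatches up
to (2, 3) by default, spacer slack ±1 nt flagged, score = 2·heptamer
mismatches + nonamer mismatches + |slack|. *Calling* genes demands stricter
signals than scanning: D and V-RS anchors require score ≤ 2 (which still
admits the non-canonical D heptamer at score 2), J signals score ≤ 1, because
J candidacy is otherwise flooded by chance inverted 12-spacer signals, and a
D gene's own 5′ signal is exactly a J-type signal (such hits are excluded by
checking for a paired 23-spacer RS at D range). These bounds are calling
conventions of this package, stated here because the source material gives
no mismatch tolerances.

V genes are found by k-mer seeding (k = 14) plus local alignment
(+1/−1, gap −2) of structured references on both strands, accepting
candidates at ≥60% identity over ≥80% reference coverage, resolving overlaps
by score then leftmost start. Boundaries are projected through the alignment
and verified against splice motifs at the projected positions (chance GT/AG
nearby never relocates a boundary); the V-EXON end snaps to the detected RS
heptamer, or falls back to the reference exon length when the RS is defective.
Functionality is a deterministic precedence: stop codon or frameshift → P;
any other structural defect → ORF; otherwise F. When the coding length is
out of frame, downstream stops are treated as consequences of the frameshift
and not reported separately.

## Identity metric and clustering

Percent identity is computed from a global, end-gap-free alignment
(match +1, mismatch −1, gap open −2, extend −1, end gaps free):
identity = matches / alignment columns, where columns gapped in exactly one
sequence count against identity. The published subgroup percentages came from
a different (Clustal-based) pipeline and are not exactly reconstructible;
this definition is deterministic and declared in output metadata. Subgroup
clustering is single linkage at >75%, because "belongs to the same subgroup"
is a pairwise relation that chains; same-gene matching is greedy best-first
one-to-one at >97% with deterministic label-order tie-breaks.

## Junction decomposition

D assignment is an exact dynamic program over the junction: candidate
segments are stretches of ≥ `min_d_match_len` (default 5) nucleotides
matching a germline D with ≤ `max_d_mismatches` substitutions (default 0 —
the rule is a literal-stretch rule; tolerance is exposed but off); selected
segments must be non-overlapping, labels non-decreasing in genomic order,
each D used at most once. The objective maximises total matched nucleotides,
then prefers fewer segments, then leftmost placement, then earliest genomic
labels and D offsets. The DP is verified against exhaustive enumeration on
junctions up to 40 nt. A label that could be swapped for another D at equal
score survives the tie-breaks as the earliest genomic label and is flagged
ambiguous.

P nucleotides are labelled at untrimmed germline ends only, as the reverse
complement of the adjacent terminal nucleotides (the hairpin-opening
palindrome: an end `…TG` extends as `CA`), up to 2 nt; all other unassigned
nucleotides are N. The V-trail and J-head contributions are the longest
germline-matching prefix/suffix of the junction.

**What rule-based decomposition can and cannot recover.** With literal
≥5-nt matching, any non-templated run that happens to contain five
consecutive nucleotides of an order-compatible unused D is credited as that
D. Under the cohort model below this credits a spurious D in roughly 5–10%
of clones, and single mutations can occasionally split or shift a true
segment. The acceptance run therefore reports the measured D-count recovery
accuracy against generative truth rather than assuming the rule is lossless;
structural guarantees (segments tile the junction; every true D retained at
≥5 unmutated nucleotides is credited; true P positions are never labelled N)
are asserted in the unit suite. The exact P/germline boundary is not uniquely
invertible either — a P base can be absorbed into an adjacent germline match
by chance palindromic continuation — so P recovery is asserted positionally
(covered, never mislabelled N), not as exact spans.

## The cohort model

Clone assembly: spliced leader + V-REGION up to the 2nd-CYS, then the
junction (trimmed V trail + [P][N] + (trimmed D + [P][N])·k + trimmed J
head), then the J from its anchor and a 60-nt C head. D counts follow the
reference cohort's distribution (proportional to 4/14/20/17/6 for 0–4 D);
tissues follow the 22/15/24 spleen/tonsil/blood split. Trimming is
min(Geometric(0.5) − 1, cap) per end with caps 4 (V), 2 (each D end — keeping
every retained D ≥5 nt) and 8 (J); N inserts are min(Poisson(2), 6); P
additions occur with probability 0.75 at untrimmed ends, length 1–2. These
are simulator choices where the source describes P/N qualitatively. Junction
frame and stop-freedom are enforced by resampling inserts, then trims, then
the V/J/D draw itself — the biological analogue of selection for productive
rearrangements. Somatic hypermutation is modelled as uniform independent
substitutions (default 1%) with no hotspot motifs; truth records the
pre-mutation junction. Uniform SHM means validation says nothing about
hotspot-biased mutation patterns, and the fixed 60-nt C head says nothing
about isotype-level effects.

## Phylogenetics and duplication detection

p-distance uses pairwise deletion: for each pair, sites gapped or ambiguous
(non-ACGT) in either sequence are removed; a pair with no comparable sites is
an error. Neighbour joining is the standard Saitou–Nei algorithm; Q-matrix
ties break on the lowest leaf-label pair, negative branch lengths are clamped
to zero and counted, and the sum of branch lengths is reported. Bootstrap
resamples columns with replacement and reports, per internal bipartition of
the full-data tree, the percentage of replicate trees containing it.
NJ is tested to recover random additive matrices exactly and is cross-checked
against an independent NJ implementation. Multiple alignment construction is
out of scope: inputs are pre-aligned, and `trivial_alignment` covers the
simulator's substitution-only (hence column-aligned) sequences.

The dot-plot uses exact k-mer seeds (default 12), skipping soft-masked
(lowercase) windows at seeding only, chained along diagonals (direct) and
anti-diagonals (inverted) with gaps ≤ `max_gap`; segment identity is direct
column comparison. Duplication units are single-linkage groups of intervals
connected by match segments, with overlapping intervals merged; there is no
quantitative definition of a "homology unit" in the source, so the default
minimum segment length (1 kb at genome scale, 300 nt in the desk-scale
analysis) is a declared choice.

## Problem sizes and determinism

The shipped analysis and acceptance run use a ~40-kb locus (30 + 1 V genes in
8 + 1 subgroups, 6–7 D, 4 J, 1 C), cohorts of 61 and 500 clones, 1,000
DP-oracle junctions and 200 additive trees; these sizes make every validation
exact or tightly seeded while keeping a full run under a minute. Every
stochastic step takes an explicit seed; the acceptance script derives all
sub-seeds from a single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- Substitution-only germline divergence: indel handling in annotation is
  implemented (alignment projection) but not exercised by the simulator.
- Uniform SHM, no indels, no hotspots; no clonotype abundance model.
- Gene labels are positional (`V1…`, `D1…`); no nomenclature service lookup.
- The identity metric is not the Clustal definition used historically;
  percentages can differ slightly near thresholds.
- Rule-based D crediting overcounts relative to generative truth at realistic
  non-templated-insert lengths (quantified by the acceptance run), which is a
  property of the ≥5-nt rule itself, not of this implementation.
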