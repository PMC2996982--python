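# ighscribe

Annotation of duplicated teleost immunoglobulin heavy-chain (IgH) loci and
classification of rearranged V(D)J-C cDNAs, built around the duplicated
Atlantic salmon isoloci *IGH-A* and *IGH-B*.

Salmonids carry two parallel IgH loci from an ancestral genome
duplication.  Each locus is a translocon array (VH)n-(D)m-(JH)x-(CH)y with
multiple Cτ (IgT) genes upstream of Cμ and Cδ — some inverted, partial or
frameshifted — and hundreds of VH genes falling into families defined at
>75% nucleotide identity.  Expressed IgD is typically a chimeric
transcript that splices the first Cμ exon (Cμ1) in front of the Cδ exons,
but a minority of δ transcripts join the V body directly into a δ exon at
a short repeat shared by both ends (microhomology), and some transcripts
pair a V from one locus with a constant gene from the other (trans-locus
rearrangement).  This package implements the computational side of
characterising such loci, for immunogeneticists and comparative
immunologists working with non-model vertebrates.

## What it computes

**Germline annotation** (`ighscribe.annotate`). Recombination signal
sequences (RSSs) are scanned as heptamer/spacer/nonamer motifs (consensus
`CACAGTG` / `ACAAAAACC`, Hamming budgets 1 and 2, `CAC` exact).  D
segments are spans enclosed by convergent 12-bp-spacer RSSs; JH segments
follow a 5' 24-bp-spacer RSS, end at an `AGGT`/`TGGT` splice donor and
must translate to the conserved joining motif `FDYWGKGTXVTVS`; VH genes
end at a 3' RSS (default 23-bp spacer) downstream of a spliced two-exon
gene with an `ATG(C/T)AAA(G/T)` promoter octamer.  Constant genes are
mapped by edit-distance alignment of reference coding exons on both
strands and chained into gene calls with orientation, completeness
(complete/partial/frameshift) and the tandem Cδ2-Cδ3-Cδ4 repeat count.

**Family clustering** (`ighscribe.families`). Pairwise percent identity
from global alignment with pairwise deletion (gap columns excluded);
single-linkage components of the identity->75% graph define families;
UPGMA on p-distances `(100 − identity)/100` builds ultrametric phylograms
written as Newick.

**Repertoire classification** (`ighscribe.repertoire`). Exact-duplicate
removal; V assignment requiring ≥98% identity over ≥30 bp; JH/D
resolution in the junction (sequence-identical JH pairs between loci are
returned as ambiguity sets; tandem D joins are detected); constant-gene
and locus assignment via diagnostic nucleotides; chimeric-Cμ1 detection
for δ reads; open-reading-frame (productivity) checking anchored on the
germline V frame; and microhomology detection at direct V-to-C joins.
Each read gets one category: `canonical`, `chimeric_mu1_delta`,
`noncanonical_delta`, `trans_locus` or `unresolved`.

**Usage statistics** (`ighscribe.usage`). JH × constant-gene and
VH-family × constant-gene tables with column proportions, and category
fractions (including the δ-conditional chimeric/noncanonical split).

**Synthetic data** (`ighscribe.simulate`). A fully seeded generator that
builds a locus pair with the germline complement described above (18 VH
families, 25 D, 20 JH by default, δ repeats 3× in A and 4× in B) plus
truth files, and repertoires of the four read categories with latent-truth
tables, so every pipeline stage is testable without any downloads.

## Worked example

`examples/` contains one short script per capability.  For instance:

```bash
$ python examples/annotate_synthetic_locus.py
locus IGH-A-synthetic: 61,970 bp
  CH_exon      truth= 32 called= 32 recall=1.00 precision=1.00
  D_segment    truth= 17 called= 17 recall=1.00 precision=1.00
  JH_segment   truth= 12 called= 12 recall=1.00 precision=1.00
  VH_exon2     truth= 53 called= 53 recall=1.00 precision=1.00
constant genes:
  Ctau_A-4   inverted complete
  Cdelta_A   forward  complete delta-repeats=3
  ...
```

Every planted segment interval is recovered exactly at zero mutation, and
the constant-gene table shows the inverted τ gene and the tandem δ-repeat
count.  Similarly:

```bash
$ python examples/classify_repertoire.py
400 reads, 40 duplicates removed, 360 unique
  canonical              0.639
  chimeric_mu1_delta     0.242
  noncanonical_delta     0.033
  trans_locus            0.086
  delta reads chimeric:     0.879
  delta reads noncanonical: 0.121
category agreement with simulation truth: 360/360
```

About 90% of δ reads carry the Cμ1 exon (the typical chimeric teleost IgD
form), ~10% are direct noncanonical joins, and every category call agrees
with the simulation's latent truth at zero sequencing error.
`examples/microhomology_junctions.py` prints a junction table (shared
repeat, repeat length, join position within the δ exon), and
`examples/jh_usage_tables.py` shows the middle-JH usage peak and the
opposite VH-family-8/family-6 preferences of the two μ genes.

A thin CLI wraps the same functions (`ighscribe annotate`, `cluster`,
`classify`, `stats`, `simulate-locus`, `simulate-repertoire`,
`convert`); run `ighscribe --help`.

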