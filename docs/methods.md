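# Methods

## The problem and the model

The duplicated salmonid IgH isoloci (here called A and B) are translocon
arrays: blocks of VH genes followed, for each constant gene, by its
complement of D and JH segments.  The package answers three questions:

1. **Where are the germline building blocks?**  Somatic V(D)J
   recombination leaves a fixed geometric fingerprint — the recombination
   signal sequence (RSS) — and the annotator reads that fingerprint
   instead of relying on homology to curated V/D/J sets:

   * an RSS is a heptamer (consensus `CACAGTG`) and a nonamer
     (`ACAAAAACC`) separated by a spacer of characteristic length;
   * D segments sit between two *convergent* 12-bp-spacer RSSs;
   * JH segments follow a 5' 24-bp-spacer RSS, terminate at an
     `AGGT`/`TGGT` splice donor, and their translation ends with the
     conserved motif `FDYWGKGTXVTVS` (X free);
   * VH genes end at a 3' RSS; upstream they carry a spliced exon-1/exon-2
     structure (GT…AG intron) and an `ATG(C/T)AAA(G/T)` promoter octamer.

   Constant (CH) genes are not discovered de novo: reference coding exons
   (e.g. from cDNA) are located by edit-distance alignment on both strands
   and chained into gene calls, which captures inverted genes, partial
   relics, frameshifted pseudogenes, and tandem repeats of the δ
   exon2-exon3-exon4 block.

2. **How do the VH genes relate?**  Families are defined by the WHO-IUIS
   convention — >75% nucleotide identity over complete exon 2 — using
   global alignments with pairwise deletion, single-linkage components,
   and UPGMA phylograms on p-distances.

3. **What did the animal express?**  cDNA reads are deduplicated, V is
   assigned at a BLAST-like ≥98%-identity-over-≥30-bp bar, JH/D are
   resolved in the junction, the constant gene and its locus are called,
   and each read is categorised as canonical, chimeric IgD (Cμ1 spliced
   before the δ exons), noncanonical δ (direct V-to-δ join, usually at a
   shared repeat, i.e. microhomology), trans-locus (V and C from different
   loci) or unresolved.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| heptamer / nonamer mismatch budgets | 1 / 2 (CAC exact) | RSS conservation is strongest in the heptamer; the CAC core is functionally critical.  Config-exposed. |
| spacer lengths (D / JH / VH) | 12 / 24 / 23 bp, ±1 | 12/24 are the observed salmonid D and JH spacers; 23 is the canonical V-side spacer (not directly observable from rearranged products) and is config-exposed. |
| D length bounds | 5–40 bp | generous envelope around teleost D cores (~10–30 bp). |
| JH motif similarity | ≥0.70 over non-X positions, C-terminally anchored | the joining motif is well conserved but not invariant; 0.70 separates genuine JH from background in the synthetic calibration. |
| VH exon-2 length | 240–360 bp, multiple of 3 | envelope around teleost VH exon 2 (~290–310 bp). |
| VH intron length / promoter window | 40–300 bp / 250 bp of the acceptor | the promoter window is deliberately tight so a neighbouring cassette's octamer cannot masquerade as structure. |
| CH exon identity | ≥0.90 (0.80 for the synthetic study, whose τ genes diverge up to ~25% from the founder references) | set by the divergence of the references from the locus. |
| V acceptance | ≥98% identity over ≥30 aligned bp | the repertoire curation filter; both knobs config-exposed. |
| D match | ≥5 bp exact (primary), ≥8 bp for tandem (secondary) matches; optional 1 mismatch | short D cores make a long minimum lose true joins; secondary matches need stronger evidence because 5-mers recur by chance. |
| chimeric Cμ1 detection | ≥90% identity over ≥50 bp upstream of the δ match | presence/absence of the Cμ1 exon is the biological signal; the thresholds only guard against noise. |
| microhomology | longest string that is a suffix of the germline V side *and* prefix of the germline C side of the join, present once in the read | the operational definition of homology-directed joining evidence. |
| artifact flag | microhomology ≥10 bp | very long repeats are compatible with PCR template switching; flagged, not removed. |

## Numerical and procedural choices

* **Coordinates** are 0-based half-open on the forward strand everywhere;
  GFF3 output converts to 1-based inclusive.
* **Overlap resolution** among segment calls is greedy and deterministic:
  fewest RSS mismatches + spacer deviation first, promoterless fragments
  ranked below structured calls, then longest span, leftmost start,
  forward strand.  No two emitted segments overlap.
* **D-segment strand**: the flanking-RSS geometry of a D segment is
  perfectly strand-symmetric, so D calls are normalised to the + strand.
  The strand-symmetry property of the annotator therefore holds exactly
  for VH/JH and up to strand for D.
* **VH exon-2 delimitation** compares three candidate boundaries by span
  length: the longest acceptor candidate with full promoter structure
  (pseudogenes keep their stops), the longest stop-free acceptor candidate
  without structure, and the longest end-anchored stop-free open span
  (fragments with no acceptor).  Candidates without either structure or an
  open frame are not called.
* **Pairwise identity** = identical residue pairs / aligned residue pairs
  (pairwise deletion) on a global alignment with match +1, mismatch −1,
  gap open −5, gap extend −1 (config-exposed).  Where co-optimal
  alignments exist the aligner's deterministic first traceback is used;
  the test suite checks the value against an independent DP oracle's
  identity range over all co-optimal alignments.
* **Family labels** are numbered from 1 by descending family size, ties by
  the lexicographically smallest member id, making the assignment
  independent of input order.  Single linkage is the default (complete
  linkage available) and the >75% threshold is strict.
* **UPGMA** uses size-weighted arithmetic-mean updates with ties broken by
  the lexicographically smallest member-id pair; output trees are
  ultrametric to 1e-9 and reconstruct ultrametric inputs exactly.
* **Junction anchoring**: score-optimal local alignments can over-run a
  junction by a few lucky bases, so breakpoints are re-anchored by maximal
  exact extension (isolated mismatches tolerated only when the following
  5 bp agree).  Microhomology is computed from the germline contexts at
  those maximally-extended breakpoints.
* **Productivity** requires the junction to preserve the germline V
  reading frame into the constant chain and no stop codon from the first
  complete V codon through the end of the constant match.
* **Degenerate inputs**: N-containing windows are never RSS matches;
  empty read sets, zero-count usage columns (proportions reported as NaN,
  never 0/0) and repertoires without δ reads (conditional fractions
  absent, not zero) are handled explicitly.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline targets:

* two loci with 18 VH families (three present only in locus A, one
  single-member family), ~2–4 members per family per locus, ~40%
  stop-codon pseudogenes and ~30% promoterless fragments (≈70%
  non-functional overall);
* within-family member divergence 4–8% (pairwise identity ≥ ~84%) and
  independent random founders between families (pairwise identity ≤ ~65%),
  leaving a guard band around the 75% threshold;
* 25 D and 20 JH segments across the pair, distributed per constant gene;
  JH codings identical between loci except the third μ-associated pair;
  one JH pseudogene (TAC→TAG in the conserved motif); `TGGT` donors at 10%;
* a constant-gene layout with five τ genes in A (one inverted, two
  partial, one frameshifted) and three in B, μ and δ at the 3' end, δ
  exon2-4 repeated 3× (A) and 4× (B), and exactly five diagnostic
  nucleotide differences between the two μ chains inside the region
  covered by reads;
* repertoires with 60% canonical, 27% chimeric δ, 3% noncanonical δ and
  10% trans-locus reads (so 90/10 of δ reads are chimeric/noncanonical),
  uniform 0–5 bp exonuclease trimming, 0–8 bp N insertions, truncated
  geometric microhomology lengths (support 1–7), 10% exact duplicates and
  an optional per-base substitution error rate.  Junctional statistics are
  generic V(D)J placeholders: no salmon-specific trimming/insertion
  measurements exist.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: repeat/transposon-rich intergenic sequence
(spacers are uniform random DNA, additionally scrubbed of chance promoter
octamers, and VH introns are built AG-free so exon boundaries are
unambiguous), somatic hypermutation, indel sequencing errors, chromatogram
quality, assembly gaps beyond N-runs, and alleles beyond the two loci.
Real-locus annotation accuracy will be lower than the synthetic 1.0
recall/precision, mainly through decoy RSS-like motifs and degraded
pseudogene structure; the mutation-rate sweep in the test suite (recall
declining monotonically as planted RSS mutations accumulate) bounds that
behaviour qualitatively, not quantitatively.

The RSS mutation model draws per-position uniforms unconditionally, so
raising the rate under a fixed seed only ever adds mutations; recall is
then non-increasing in the rate deterministically, which the test suite
asserts.

## Known limitations

* VH frameshift pseudogenes are not distinguished from intact genes by
  the de novo caller (detecting a frameshift needs a reference frame);
  the `pseudogene_frameshift` status is reserved for reference-based
  workflows, and the generator plants stop-codon pseudogenes.
* A V segment used only over a short prefix (deep noncanonical donors)
  may be genuinely ambiguous between family members identical over that
  prefix; ties resolve lexicographically and are reported with the match
  length so users can filter.
* Locus assignment relies on diagnostic sites (μ) or alignment margin
  (τ, δ); δ reads are frequently locus-ambiguous, as expected from the
  near-identity of the two δ genes, and are excluded from trans-locus
  calls.
* The crossover point of trans-locus reads within the constant region is
  reported as the first covered diagnostic site disagreeing with the vote
  only descriptively, via the per-site votes; no recombination-point
  estimator is implemented.
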