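"""Annotate a synthetic germline IgH locus and compare against truth.

Builds one locus of the default synthetic pair (VH cassettes, D segments
with 12-bp-spacer RSSs, JH segments with 24-bp-spacer RSSs, constant
genes), runs the de novo annotator and prints per-class recovery.
"""

from ighscribe.annotate import AnnotatorConfig, annotate_locus, compare_annotations
from ighscribe.simulate import LocusSpec, generate_locus

record, truth, db, ch_refs = generate_locus(LocusSpec(seed=1), locus="A")
print(f"locus {record.id}: {len(record):,} bp")

config = AnnotatorConfig(ch_min_exon_identity=0.8, locus_tag="A")
result = annotate_locus(record, config, ch_references=ch_refs)

for kind, stats in compare_annotations(truth, result.features).items():
    print(
        f"  {kind:<12} truth={stats['n_truth']:>3} called={stats['n_called']:>3} "
        f"recall={stats['recall']:.2f} precision={stats['precision']:.2f}"
    )

print("constant genes:")
for gene in result.ch_genes:
    extra = f" delta-repeats={gene.delta_repeat_count}" if gene.isotype == "delta" else ""
    print(f"  {gene.gene_name:<10} {gene.orientation:<8} {gene.completeness}{extra}")

# recall/precision of 1.00 means every planted segment interval was
# recovered exactly and nothing spurious was called; the constant-gene
# table shows orientation (the inverted tau), completeness and the tandem
# delta exon2-4 repeat count.
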