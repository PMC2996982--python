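"""Unit tests for the D, JH, VH and CH callers on planted constructs."""

import numpy as np
import pytest

from ighscribe.annotate import (
    RssMotif,
    call_d_segments,
    call_jh_segments,
    call_vh_segments,
    map_ch_genes,
    scan_rss,
)
from ighscribe.dna import revcomp, translate
from ighscribe.seqio import SequenceRecord

HEPT = "CACAGTG"
NONA = "ACAAAAACC"


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _rss5(spacer_seq):
    return revcomp(NONA) + spacer_seq + revcomp(HEPT)


def _rss3(spacer_seq):
    return HEPT + spacer_seq + NONA


# --- D segments -----------------------------------------------------------


def test_planted_d_segment_called():
    rng = np.random.default_rng(3)
    core = _rand(rng, 15)
    seq = SequenceRecord(
        "s", _rand(rng, 40) + _rss5(_rand(rng, 12)) + core + _rss3(_rand(rng, 12)) + _rand(rng, 40)
    )
    hits = scan_rss(seq, RssMotif(spacer_length=12))
    calls = call_d_segments(seq, hits)
    assert len(calls) == 1
    call = calls[0]
    assert call.kind == "D"
    assert seq.residues[call.start : call.end] == core
    assert call.rss_5prime is not None and call.rss_3prime is not None


def test_one_sided_rss_is_not_a_d_segment():
    rng = np.random.default_rng(4)
    seq = SequenceRecord("s", _rand(rng, 40) + _rss3(_rand(rng, 12)) + _rand(rng, 40))
    hits = scan_rss(seq, RssMotif(spacer_length=12))
    assert call_d_segments(seq, hits) == []


def test_d_length_bounds_respected():
    rng = np.random.default_rng(5)
    core = _rand(rng, 60)  # longer than the default maximum of 40
    seq = SequenceRecord(
        "s", _rand(rng, 30) + _rss5(_rand(rng, 12)) + core + _rss3(_rand(rng, 12)) + _rand(rng, 30)
    )
    hits = scan_rss(seq, RssMotif(spacer_length=12))
    assert call_d_segments(seq, hits) == []
    assert len(call_d_segments(seq, hits, max_len=80)) == 1


# --- JH segments ----------------------------------------------------------

JH_CODING = "TTTGACTACTGGGGCAAAGGAACCATGGTCACCGTCAGC"  # FDYWGKGTMVTVS


def _jh_construct(coding, splice="AGGT", seed=6):
    rng = np.random.default_rng(seed)
    return SequenceRecord(
        "s", _rand(rng, 35) + _rss5(_rand(rng, 24)) + coding + splice + _rand(rng, 35)
    )


def test_planted_jh_called_intact_with_perfect_motif():
    assert translate(JH_CODING) == "FDYWGKGTMVTVS"
    seq = _jh_construct(JH_CODING)
    hits = scan_rss(seq, RssMotif(spacer_length=24))
    calls = call_jh_segments(seq, hits)
    assert len(calls) == 1
    call = calls[0]
    assert seq.residues[call.start : call.end] == JH_CODING
    assert call.functional_status == "intact"
    assert call.evidence["motif_similarity"] == 1.0  # X matches the M
    assert call.evidence["splice_site"] == "AGGT"


def test_stop_codon_marks_jh_pseudogene():
    # TAC (Y) -> TAG stop inside the conserved motif
    coding = JH_CODING[:6] + "TAG" + JH_CODING[9:]
    seq = _jh_construct(coding)
    hits = scan_rss(seq, RssMotif(spacer_length=24))
    calls = call_jh_segments(seq, hits)
    assert len(calls) == 1
    assert calls[0].functional_status == "pseudogene_stop"


def test_tggt_splice_site_still_called_and_recorded():
    seq = _jh_construct(JH_CODING, splice="TGGT")
    hits = scan_rss(seq, RssMotif(spacer_length=24))
    calls = call_jh_segments(seq, hits)
    assert len(calls) == 1
    assert calls[0].evidence["splice_site"] == "TGGT"


def test_low_motif_similarity_rejected():
    rng = np.random.default_rng(8)
    junk = "".join(c for c in _rand(rng, 39))
    seq = _jh_construct(junk)
    hits = scan_rss(seq, RssMotif(spacer_length=24))
    calls = call_jh_segments(seq, hits, min_motif_similarity=0.95)
    assert calls == []


# --- VH segments ----------------------------------------------------------


def _codons(rng, n):
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n:
        c = _rand(rng, 3)
        if c not in stops:
            out.append(c)
    return "".join(out)


def _vh_construct(seed=9, with_promoter=True, plant_stop=False):
    rng = np.random.default_rng(seed)
    exon2 = _codons(rng, 100)  # 300 bp
    if plant_stop:
        exon2 = exon2[:150] + "TAA" + exon2[153:]
    pad = "TTAATTAATTAA"
    if with_promoter:
        upstream = (
            "ATGCAAAG"
            + _rand(rng, 20).replace("AG", "AC")
            + "ATG" + _codons(rng, 15).replace("AG", "AT")
            + "GT" + _rand(rng, 80).replace("AG", "AC")
            + pad + "TAG"
        )
    else:
        upstream = pad
    seq = upstream + exon2 + _rss3(_rand(rng, 23))
    record = SequenceRecord("s", "T" * 10 + seq + "T" * 10)
    start = 10 + len(upstream)
    return record, start, exon2


def test_full_vh_cassette_called_intact():
    record, start, exon2 = _vh_construct()
    hits = scan_rss(record, RssMotif(spacer_length=23))
    calls = call_vh_segments(record, hits)
    assert len(calls) == 1
    call = calls[0]
    assert (call.start, call.end) == (start, start + len(exon2))
    assert call.functional_status == "intact"
    assert "octamer_start" in call.evidence


def test_exon2_with_rss_only_is_a_fragment():
    record, start, exon2 = _vh_construct(with_promoter=False)
    hits = scan_rss(record, RssMotif(spacer_length=23))
    calls = call_vh_segments(record, hits)
    assert len(calls) == 1
    call = calls[0]
    assert (call.start, call.end) == (start, start + len(exon2))
    assert call.functional_status == "fragment"


def test_in_frame_stop_marks_vh_pseudogene():
    record, start, exon2 = _vh_construct(plant_stop=True)
    hits = scan_rss(record, RssMotif(spacer_length=23))
    calls = call_vh_segments(record, hits)
    assert len(calls) == 1
    assert calls[0].functional_status == "pseudogene_stop"
    assert (calls[0].start, calls[0].end) == (start, start + len(exon2))


# --- CH genes -------------------------------------------------------------


def _exon_refs(rng, isotype, lens):
    return [
        SequenceRecord(f"{isotype}_exon{i+1}", _codons(rng, n // 3))
        for i, n in enumerate(lens)
    ]


def _gene_block(rng, refs, order=None):
    order = order or list(range(len(refs)))
    parts = []
    for k, idx in enumerate(order):
        if k:
            parts.append("GT" + _rand(rng, 90) + "AG")
        parts.append(refs[idx].residues)
    return "".join(parts)


def test_forward_mu_gene_complete():
    rng = np.random.default_rng(21)
    refs = _exon_refs(rng, "mu", (300, 300, 300, 300))
    seq = SequenceRecord("s", _rand(rng, 100) + _gene_block(rng, refs) + _rand(rng, 100))
    calls = map_ch_genes(seq, refs)
    assert len(calls) == 1
    gene = calls[0]
    assert (gene.isotype, gene.orientation, gene.completeness) == ("mu", "forward", "complete")
    assert len(gene.exons) == 4


def test_inverted_tau_gene():
    rng = np.random.default_rng(22)
    refs = _exon_refs(rng, "tau", (300, 300, 300, 300))
    block = revcomp(_gene_block(rng, refs))
    seq = SequenceRecord("s", _rand(rng, 100) + block + _rand(rng, 100))
    calls = map_ch_genes(seq, refs)
    assert len(calls) == 1
    assert calls[0].orientation == "inverted"
    assert calls[0].completeness == "complete"


def test_delta_repeats_collapsed_with_count():
    rng = np.random.default_rng(23)
    refs = _exon_refs(rng, "delta", (300, 312, 306, 309, 300, 300, 300))
    order = [0] + [1, 2, 3] * 4 + [4, 5, 6]
    seq = SequenceRecord("s", _rand(rng, 80) + _gene_block(rng, refs, order) + _rand(rng, 80))
    calls = map_ch_genes(seq, refs)
    assert len(calls) == 1
    assert calls[0].isotype == "delta"
    assert calls[0].delta_repeat_count == 4
    assert calls[0].completeness == "complete"


def test_partial_and_frameshifted_genes():
    rng = np.random.default_rng(24)
    refs = _exon_refs(rng, "tau", (300, 300, 300, 300))
    # only exons 2..4 present
    partial = _gene_block(rng, refs, [1, 2, 3])
    # all exons but a 1 bp deletion inside exon 2
    fs_refs = [r.residues for r in refs]
    fs_refs[1] = fs_refs[1][:150] + fs_refs[1][151:]
    fs = []
    for k, r in enumerate(fs_refs):
        if k:
            fs.append("GT" + _rand(rng, 90) + "AG")
        fs.append(r)
    seq = SequenceRecord(
        "s", _rand(rng, 80) + partial + _rand(rng, 4000) + "".join(fs) + _rand(rng, 80)
    )
    calls = map_ch_genes(seq, refs)
    assert len(calls) == 2
    assert calls[0].completeness == "partial"
    assert calls[1].completeness == "frameshift"


def test_reference_id_must_carry_isotype_and_exon():
    with pytest.raises(ValueError):
        map_ch_genes(SequenceRecord("s", "ACGT" * 100), [SequenceRecord("exonA", "ACGT" * 30)])
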