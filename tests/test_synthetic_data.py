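"""Generator contracts: determinism, planted structure, error model."""

import numpy as np
import pytest

from ighscribe.families import pairwise_identity
from ighscribe.repertoire import longest_join_overlap
from ighscribe.seqio import SequenceRecord
from ighscribe.simulate import (
    LocusSpec,
    RepertoireSpec,
    generate_locus,
    generate_locus_pair,
    generate_repertoire,
    inject_errors,
)


def test_same_seed_gives_identical_loci_and_truth():
    a = generate_locus_pair(LocusSpec(seed=31))
    b = generate_locus_pair(LocusSpec(seed=31))
    assert a.records["A"].residues == b.records["A"].residues
    assert a.records["B"].residues == b.records["B"].residues
    assert a.features == b.features
    assert sorted(a.db.vh) == sorted(b.db.vh)
    c = generate_locus_pair(LocusSpec(seed=32))
    assert a.records["A"].residues != c.records["A"].residues


def test_single_locus_matches_pair(locus_pair):
    record, feats, db, refs = generate_locus(LocusSpec(seed=1), locus="A")
    assert record.residues == locus_pair.records["A"].residues
    assert feats == locus_pair.features_for("A")
    assert all(g.locus == "A" for g in db.vh.values())


def test_planted_germline_complement_counts(locus_pair):
    kinds = [f.kind for f in locus_pair.features]
    assert kinds.count("D_segment") == 25
    assert kinds.count("JH_segment") == 20
    families = {
        f.attributes["family"]
        for f in locus_pair.features
        if f.kind == "VH_exon2"
    }
    assert len(families) == 18


def test_vh_identity_bands_straddle_family_threshold(locus_pair):
    """Within-family pairs stay above 75% identity, between-family below."""
    by_family = {}
    for gene in locus_pair.db.vh.values():
        by_family.setdefault(gene.family, []).append(gene)
    rng = np.random.default_rng(0)
    within, between = [], []
    fams = sorted(by_family)
    for fam in fams[:6]:
        members = by_family[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                within.append(
                    pairwise_identity(
                        SequenceRecord("a", members[i].exon2),
                        SequenceRecord("b", members[j].exon2),
                    )
                )
    for i in range(len(fams)):
        for _ in range(2):
            j = int(rng.integers(0, len(fams)))
            if i == j:
                continue
            a = by_family[fams[i]][0]
            b = by_family[fams[j]][0]
            between.append(
                pairwise_identity(
                    SequenceRecord("a", a.exon2), SequenceRecord("b", b.exon2)
                )
            )
    assert min(within) > 75.0
    assert max(between) < 75.0


def test_repertoire_determinism_and_duplicate_truth(locus_pair):
    spec = RepertoireSpec(seed=21, n_reads=300)
    reads1, truth1 = generate_repertoire(locus_pair.db, spec)
    reads2, truth2 = generate_repertoire(locus_pair.db, spec)
    assert [r.residues for r in reads1] == [r.residues for r in reads2]
    assert truth1.equals(truth2)
    n_dup = int(round(300 * spec.duplicate_fraction))
    assert (truth1.duplicate_of != "").sum() == n_dup
    assert len({r.residues for r in reads1}) == 300 - n_dup


def test_empty_repertoire(locus_pair):
    reads, truth = generate_repertoire(
        locus_pair.db, RepertoireSpec(seed=1, n_reads=0)
    )
    assert reads == []
    assert len(truth) == 0


def test_category_mixture_must_sum_to_one():
    with pytest.raises(ValueError):
        RepertoireSpec(seed=1, category_mixture=(("canonical", 0.5),))


def test_infeasible_identity_band_rejected():
    with pytest.raises(ValueError):
        LocusSpec(seed=1, within_family_divergence=(0.2, 0.3))


def test_noncanonical_reads_carry_their_repeat_exactly_once(locus_pair):
    spec = RepertoireSpec(
        seed=13,
        n_reads=300,
        category_mixture=(
            ("canonical", 0.0),
            ("chimeric_mu1_delta", 0.0),
            ("noncanonical_delta", 1.0),
            ("trans_locus", 0.0),
        ),
        duplicate_fraction=0.0,
    )
    reads, truth = generate_repertoire(locus_pair.db, spec)
    lengths = []
    for read, row in zip(reads, truth.itertuples()):
        repeat = row.microhomology
        assert len(repeat) >= 1
        lengths.append(len(repeat))
        d = int(row.v_breakpoint)
        # the repeat sits once across the junction ...
        assert read.residues[d - len(repeat) : d] == repeat
        # ... and is not tandem-duplicated at the join
        assert read.residues[d : d + len(repeat)] != repeat
        # and it is exactly the longest shared germline flank
        v_seq = locus_pair.db.vh[row.v_call].exon2
        chain = locus_pair.db.ch[row.c_call].cdna
        a = int(row.c_germ_start)
        assert longest_join_overlap(v_seq[:d], chain[a:]) == repeat
    assert max(lengths) <= 7 and min(lengths) >= 1


def test_inject_errors_rate_zero_and_one():
    reads = [SequenceRecord("r", "ACGT" * 25)]
    same = inject_errors(reads, 0.0, seed=3)
    assert same[0].residues == reads[0].residues
    flipped = inject_errors(reads, 1.0, seed=3)
    assert all(a != b for a, b in zip(flipped[0].residues, reads[0].residues))
    with pytest.raises(ValueError):
        inject_errors(reads, 1.5, seed=3)


def test_inject_errors_binomial_count():
    rng = np.random.default_rng(8)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
    reads = [SequenceRecord("r", seq)]
    rate = 0.02
    out = inject_errors(reads, rate, seed=4)
    n_sub = sum(a != b for a, b in zip(out[0].residues, seq))
    mean = 100_000 * rate
    sigma = (100_000 * rate * (1 - rate)) ** 0.5
    assert abs(n_sub - mean) < 3 * sigma
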