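"""Unit tests for read classification against a germline database."""

import numpy as np
import pytest

from _oracles import brute_force_overlap
from ighscribe.repertoire import (
    ChGene,
    GermlineDb,
    RepertoireConfig,
    assign_ch,
    assign_vh,
    check_orf,
    classify_rearrangement,
    dedup_reads,
    detect_microhomology,
    longest_join_overlap,
    resolve_junction,
)
from ighscribe.seqio import SequenceRecord
from ighscribe.simulate import LocusSpec, generate_locus_pair


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# --- dedup ----------------------------------------------------------------


def test_dedup_collapses_exact_duplicates():
    reads = [
        SequenceRecord("r1", "ACGTACGT"),
        SequenceRecord("r2", "ACGTACGT"),
        SequenceRecord("r3", "TTTTAAAA"),
    ]
    unique, members = dedup_reads(reads)
    assert [r.id for r in unique] == ["r1", "r3"]
    assert members["r1"] == ["r1", "r2"]
    assert members["r3"] == ["r3"]


def test_dedup_all_distinct_is_identity():
    reads = [SequenceRecord(f"r{i}", "ACGT" + "ACGT" * i) for i in range(5)]
    unique, members = dedup_reads(reads)
    assert len(unique) == 5
    assert all(members[r.id] == [r.id] for r in reads)


# --- V assignment ---------------------------------------------------------


def test_planted_v_prefix_assigned_perfectly(locus_pair):
    db = locus_pair.db
    vh_id = sorted(db.vh)[0]
    gene = db.vh[vh_id]
    rng = np.random.default_rng(0)
    read = SequenceRecord("r", gene.exon2[:60] + _rand(rng, 80))
    a = assign_vh(read, db)
    assert a is not None
    assert a.vh_id == vh_id
    assert a.identity == 100.0
    assert a.match_length >= 60


def test_v_below_identity_threshold_rejected(locus_pair):
    db = locus_pair.db
    gene = db.vh[sorted(db.vh)[0]]
    rng = np.random.default_rng(1)
    # a 95%-identity copy: one substitution every 10 bp leaves no clean
    # >=30 bp window and no >=98% stretch
    chars = list(gene.exon2[:150])
    for pos in range(4, 150, 10):
        chars[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[pos]]
    read = SequenceRecord("r", "".join(chars) + _rand(rng, 60))
    assert assign_vh(read, db) is None


# --- toy database for junction tests --------------------------------------


@pytest.fixture(scope="module")
def toy_db():
    rng = np.random.default_rng(42)
    db = GermlineDb()
    from ighscribe.repertoire import DGene, JhGene, VhGene

    v_seq = "".join(_codon(rng) for _ in range(100))  # stop-free, frame 0
    db.vh["V1"] = VhGene("V1", 1, "A", v_seq)
    db.d["D1"] = DGene("D1", "A", "GGCTACTATAGTAGCT")
    db.d["D2"] = DGene("D2", "A", "CCTTAACGGAACT")
    coding = "TTTGACTACTGGGGCAAAGGAACCATGGTCACCGTCAGC"
    db.jh["J_A"] = JhGene("J_A", "A", coding)
    db.jh["J_B"] = JhGene("J_B", "B", coding)  # cross-locus identical pair
    mu_exons = tuple(
        (f"exon{i+1}", "".join(_codon(rng) for _ in range(100))) for i in range(4)
    )
    db.ch["Cmu_A"] = ChGene("Cmu_A", "mu", "A", mu_exons)
    return db


def _codon(rng):
    stops = {"TAA", "TAG", "TGA"}
    while True:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in stops:
            return c


def test_junction_recovers_planted_d_and_ambiguous_jh(toy_db):
    rng = np.random.default_rng(5)
    v = toy_db.vh["V1"].exon2
    d_piece = toy_db.d["D1"].core[4:12]  # 8 bp exact
    n1, n2 = "CC", "GGA"
    j = toy_db.jh["J_A"].coding
    c_chain = toy_db.ch["Cmu_A"].cdna
    read = SequenceRecord("r", v + n1 + d_piece + n2 + j + c_chain[:250])
    va = assign_vh(read, toy_db)
    ca = assign_ch(read, toy_db)
    junction = resolve_junction(read, va, ca, toy_db)
    assert junction.jh_ids == frozenset({"J_A", "J_B"})  # identical pair
    assert [d for d, _, _ in junction.d_segments] == ["D1"]
    assert junction.np1 == n1
    assert junction.np2 == n2


def test_tandem_d_detection_in_order(toy_db):
    rng = np.random.default_rng(6)
    v = toy_db.vh["V1"].exon2
    d1 = toy_db.d["D1"].core
    d2 = toy_db.d["D2"].core
    j = toy_db.jh["J_A"].coding
    spacer = _rand(rng, 35)  # intervening genomic sequence
    read = SequenceRecord(
        "r", v + d1 + spacer + d2 + j + toy_db.ch["Cmu_A"].cdna[:250]
    )
    junction = resolve_junction(
        read, assign_vh(read, toy_db), assign_ch(read, toy_db), toy_db
    )
    assert [d for d, _, _ in junction.d_segments] == ["D1", "D2"]


# --- ORF / frame ----------------------------------------------------------


def test_in_frame_read_is_productive(toy_db):
    v = toy_db.vh["V1"].exon2  # length 300, frame 0
    j = toy_db.jh["J_A"].coding  # 39 nt
    read = SequenceRecord("r", v + j + toy_db.ch["Cmu_A"].cdna[:240])
    va, ca = assign_vh(read, toy_db), assign_ch(read, toy_db)
    ok, reason = check_orf(read, va, ca)
    assert ok, reason


def test_frame_shifting_junction_is_unproductive(toy_db):
    v = toy_db.vh["V1"].exon2
    j = toy_db.jh["J_A"].coding
    read = SequenceRecord("r", v + "A" + j + toy_db.ch["Cmu_A"].cdna[:240])
    va, ca = assign_vh(read, toy_db), assign_ch(read, toy_db)
    ok, reason = check_orf(read, va, ca)
    assert not ok
    assert "frame" in reason or "stop" in reason


def test_no_v_means_unproductive_with_reason(toy_db):
    read = SequenceRecord("r", "ACGT" * 30)
    ok, reason = check_orf(read, None, None)
    assert not ok and "frame" in reason


# --- microhomology --------------------------------------------------------


def test_microhomology_examples():
    db = GermlineDb()
    from ighscribe.repertoire import VhGene

    db.vh["V"] = VhGene("V", 1, "A", "TTTTTTTTTTCTAG")
    db.ch["Cd"] = ChGene("Cd", "delta", "A", (("exon1", "CTAGAAAAAAAAAA"),))
    assert detect_microhomology(db, "V", 14, "Cd", 0) == ("CTAG", 4)

    db.vh["V2"] = VhGene("V2", 1, "A", "GGGGGGGGCATCAG")
    db.ch["Cd2"] = ChGene("Cd2", "delta", "A", (("exon1", "CATCAGTTTTTTTT"),))
    assert detect_microhomology(db, "V2", 14, "Cd2", 0) == ("CATCAG", 6)

    db.vh["V3"] = VhGene("V3", 1, "A", "AAAACCCC")
    db.ch["Cd3"] = ChGene("Cd3", "delta", "A", (("exon1", "GGGGTTTT"),))
    assert detect_microhomology(db, "V3", 8, "Cd3", 0) == ("", 0)


def test_microhomology_breakpoints_validated():
    db = GermlineDb()
    from ighscribe.repertoire import VhGene

    db.vh["V"] = VhGene("V", 1, "A", "ACGTACGT")
    db.ch["C"] = ChGene("C", "delta", "A", (("exon1", "ACGTACGT"),))
    with pytest.raises(ValueError):
        detect_microhomology(db, "V", 9, "C", 0)
    with pytest.raises(ValueError):
        detect_microhomology(db, "V", 4, "C", 99)


@pytest.mark.parametrize("seed", range(5))
def test_join_overlap_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(900 + seed)
    for _ in range(60):
        donor = _rand(rng, int(rng.integers(1, 40)))
        acceptor = _rand(rng, int(rng.integers(1, 40)))
        if rng.random() < 0.5:  # force a shared junction text
            k = int(rng.integers(1, 8))
            shared = _rand(rng, k)
            donor = donor + shared
            acceptor = shared + acceptor
        assert longest_join_overlap(donor, acceptor, cap=100) == brute_force_overlap(
            donor, acceptor
        )


# --- end-to-end single-read classification --------------------------------


def test_planted_canonical_read_classified(locus_pair):
    db = locus_pair.db
    gene = db.ch["Cmu_A"]
    v = db.vh[sorted(vid for vid in db.vh if db.vh[vid].locus == "A")[0]]
    jh = db.jh["JH-mu_A-3"]
    d = db.d["D-mu_A-1"]
    read = SequenceRecord(
        "r", v.exon2 + d.core + jh.coding + gene.cdna[:300]
    )
    call = classify_rearrangement(read, db)
    assert call.category == "canonical"
    assert call.vh_id == v.id
    assert call.ch_locus == "A"
    assert "JH-mu_A-3" in call.jh_ids


def test_trans_locus_read_detected(locus_pair):
    db = locus_pair.db
    gene = db.ch["Cmu_B"]
    v = db.vh[sorted(vid for vid in db.vh if db.vh[vid].locus == "A")[0]]
    jh = db.jh["JH-mu_B-1"]
    read = SequenceRecord("r", v.exon2 + jh.coding + gene.cdna[:300])
    call = classify_rearrangement(read, db)
    assert call.category == "trans_locus"
    assert call.vh_locus == "A" and call.ch_locus == "B"


def test_unassignable_read_is_unresolved(locus_pair):
    rng = np.random.default_rng(77)
    read = SequenceRecord("r", _rand(rng, 500))
    call = classify_rearrangement(read, locus_pair.db)
    assert call.category == "unresolved"


def test_db_directory_round_trip(tmp_path, locus_pair):
    db = locus_pair.db
    db.to_dir(tmp_path / "db")
    back = GermlineDb.from_dir(tmp_path / "db")
    assert set(back.vh) == set(db.vh)
    assert all(back.vh[k].exon2 == db.vh[k].exon2 for k in db.vh)
    assert set(back.ch) == set(db.ch)
    assert all(back.ch[k].cdna == db.ch[k].cdna for k in db.ch)
    assert back.diagnostic_sites == db.diagnostic_sites


def test_prefix_containment_dedup_option():
    reads = [
        SequenceRecord("r1", "ACGTACGTACGT"),
        SequenceRecord("r2", "ACGTACGT"),  # prefix of r1
        SequenceRecord("r3", "TTTT"),
    ]
    unique, members = dedup_reads(reads, collapse_prefixes=True)
    assert [r.id for r in unique] == ["r1", "r3"]
    assert members["r1"] == ["r1", "r2"]


def test_one_mismatch_d_matching_option(toy_db):
    v = toy_db.vh["V1"].exon2
    core = toy_db.d["D1"].core
    variant = core[:7] + ("A" if core[7] != "A" else "C") + core[8:]
    j = toy_db.jh["J_A"].coding
    read = SequenceRecord("r", v + variant + j + toy_db.ch["Cmu_A"].cdna[:250])
    va, ca = assign_vh(read, toy_db), assign_ch(read, toy_db)
    strict = resolve_junction(read, va, ca, toy_db)
    loose = resolve_junction(
        read, va, ca, toy_db, RepertoireConfig(d_allow_one_mismatch=True)
    )
    strict_len = max((e - s for _, s, e in strict.d_segments), default=0)
    loose_hits = {d: (e - s) for d, s, e in loose.d_segments}
    assert loose_hits.get("D1", 0) == len(core)
    assert strict_len < len(core)
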