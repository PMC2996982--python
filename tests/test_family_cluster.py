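import numpy as np
import pytest
from skbio import TreeNode

from _oracles import affine_dp_identity_range
from ighscribe.families import (
    IdentityMatrix,
    build_identity_matrix,
    cluster_families,
    pairwise_identity,
    tree_to_newick,
    upgma_tree,
    write_newick,
)
from ighscribe.seqio import SequenceRecord


def _rec(i, s):
    return SequenceRecord(i, s)


# --- pairwise identity ----------------------------------------------------


def test_identity_of_identical_sequences_is_100():
    rng = np.random.default_rng(1)
    s = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    assert pairwise_identity(_rec("a", s), _rec("b", s)) == 100.0


def test_identity_simple_mismatch():
    assert pairwise_identity(_rec("a", "ACGT"), _rec("b", "ACGA")) == 75.0


def test_identity_pairwise_deletion_excludes_gap_columns():
    # the optimal alignment leaves the trailing TT unpaired; identity is
    # computed over residue-pair columns only
    ident = pairwise_identity(_rec("a", "ACGTACGTTT"), _rec("b", "ACGTACG"))
    assert ident == 100.0


def test_identity_errors():
    with pytest.raises(ValueError):
        pairwise_identity(_rec("a", "ACGT"), _rec("b", "ACGT"), mode="rna")


@pytest.mark.parametrize("seed", range(10))
def test_identity_against_independent_dp_oracle(seed):
    """Score equals the affine-DP optimum; identity falls inside the
    oracle's min/max identity range over co-optimal alignments."""
    rng = np.random.default_rng(400 + seed)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    b = list(a)
    for pos in rng.choice(60, size=int(rng.integers(0, 8)), replace=False):
        b[int(pos)] = "ACGT"[int(rng.integers(0, 4))]
    b = "".join(b)
    if rng.random() < 0.5:
        cut = int(rng.integers(5, 50))
        b = b[:cut] + b[cut + int(rng.integers(1, 4)) :]
    opt, lo, hi = affine_dp_identity_range(a, b)
    from ighscribe.families import make_aligner

    assert abs(make_aligner().score(a, b) - opt) < 1e-9
    ident = pairwise_identity(_rec("a", a), _rec("b", b))
    assert lo - 1e-9 <= ident <= hi + 1e-9


# --- identity matrix ------------------------------------------------------


def test_matrix_symmetric_diagonal_100():
    rng = np.random.default_rng(2)
    recs = [
        _rec(f"s{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 80)))
        for i in range(4)
    ]
    m = build_identity_matrix(recs)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 100.0)
    m2 = build_identity_matrix(recs[::-1])
    # same values under reversed input order
    idx = {i: m2.ids.index(i) for i in m.ids}
    for i, a in enumerate(m.ids):
        for j, b in enumerate(m.ids):
            assert m.values[i, j] == m2.values[idx[a], idx[b]]


def test_matrix_rejects_duplicates_and_singletons():
    with pytest.raises(ValueError):
        build_identity_matrix([_rec("a", "ACGT")])
    with pytest.raises(ValueError):
        build_identity_matrix([_rec("a", "ACGT"), _rec("a", "ACGT")])


# --- family clustering ----------------------------------------------------


def _matrix(ids, entries):
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for (i, j), v in entries.items():
        vals[i, j] = vals[j, i] = v
    return IdentityMatrix(ids=tuple(ids), values=vals)


def test_single_linkage_chains_through_intermediate():
    m = _matrix("abc", {(0, 1): 80, (1, 2): 80, (0, 2): 60})
    fam = cluster_families(m, threshold=75)
    assert fam.n_families == 1
    assert cluster_families(m, threshold=75, linkage="complete").n_families > 1


def test_threshold_is_strict():
    m = _matrix("ab", {(0, 1): 75.0})
    assert cluster_families(m, threshold=75).n_families == 2


def test_monotone_in_threshold():
    rng = np.random.default_rng(3)
    n = 12
    vals = np.round(rng.uniform(40, 100, size=(n, n)), 1)
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    m = IdentityMatrix(ids=tuple(f"s{i}" for i in range(n)), values=vals)
    counts = [cluster_families(m, threshold=t).n_families for t in (50, 60, 70, 80, 90)]
    assert counts == sorted(counts)


def test_family_numbering_order_independent():
    rng = np.random.default_rng(4)
    n = 10
    vals = rng.uniform(40, 100, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    ids = tuple(f"s{i}" for i in range(n))
    m = IdentityMatrix(ids=ids, values=vals)
    perm = rng.permutation(n)
    m2 = IdentityMatrix(
        ids=tuple(ids[i] for i in perm), values=vals[np.ix_(perm, perm)]
    )
    f1 = cluster_families(m)
    f2 = cluster_families(m2)
    assert f1.labels == f2.labels
    # labels are contiguous from 1 and numbered by descending size
    sizes = [list(f1.labels.values()).count(k) for k in range(1, f1.n_families + 1)]
    assert sizes == sorted(sizes, reverse=True)


def test_planted_families_recovered(locus_pair):
    truth = {g.id: g.family for g in locus_pair.db.vh.values()}
    sample = sorted(truth)[::2]  # every other gene keeps the test fast
    recs = [_rec(i, locus_pair.db.vh[i].exon2) for i in sample]
    m = build_identity_matrix(recs)
    fam = cluster_families(m, threshold=75)
    groups = {}
    for vid, lab in fam.labels.items():
        groups.setdefault(lab, set()).add(truth[vid])
    assert all(len(g) == 1 for g in groups.values())
    assert fam.n_families == len({truth[i] for i in sample})


# --- UPGMA ----------------------------------------------------------------


def test_two_leaves_branch_length_is_half_distance():
    tree = upgma_tree((["A", "B"], [[0, 0.4], [0.4, 0]]))
    a, b = tree.find("A"), tree.find("B")
    assert a.length == pytest.approx(0.2)
    assert b.length == pytest.approx(0.2)


def test_three_leaf_hand_calculation():
    # d(AB)=0.2, d(AC)=d(BC)=0.6: AB join at height 0.1, root at 0.3
    tree = upgma_tree((["A", "B", "C"], [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))
    assert tree.find("A").length == pytest.approx(0.1)
    assert tree.find("C").length == pytest.approx(0.3)
    ab_parent = tree.find("A").parent
    assert ab_parent.length == pytest.approx(0.2)  # 0.3 - 0.1


def test_equal_distances_join_lexicographically_and_ultrametric():
    ids = ["d", "b", "c", "a"]
    dist = np.full((4, 4), 0.5)
    np.fill_diagonal(dist, 0.0)
    tree = upgma_tree((ids, dist))
    # first join is the lexicographically smallest pair {a, b}
    a = tree.find("a")
    siblings = {t.name for t in a.parent.tips()}
    assert siblings == {"a", "b"}
    depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
    assert max(depths) - min(depths) < 1e-9


def test_nan_distances_rejected():
    with pytest.raises(ValueError):
        upgma_tree((["a", "b"], [[0, float("nan")], [float("nan"), 0]]))


def _random_ultrametric(rng, n):
    """Random ultrametric matrix built by agglomerating at growing heights."""
    clusters = [[i] for i in range(n)]
    heights = sorted(rng.uniform(0.05, 1.0, size=n - 1))
    dist = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for x in clusters[i]:
            for y in clusters[j]:
                dist[x, y] = dist[y, x] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return dist


@pytest.mark.parametrize("seed", range(8))
def test_upgma_reconstructs_ultrametric_matrices(seed):
    rng = np.random.default_rng(700 + seed)
    n = 6
    dist = _random_ultrametric(rng, n)
    ids = [f"t{i}" for i in range(n)]
    tree = upgma_tree((ids, dist))
    for i in range(n):
        for j in range(i + 1, n):
            got = tree.find(ids[i]).distance(tree.find(ids[j]))
            assert abs(got - dist[i, j]) < 1e-9


# --- Newick ---------------------------------------------------------------


def test_newick_round_trip(tmp_path):
    tree = upgma_tree((["A", "B", "C"], [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]))
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = TreeNode.read(str(path))
    assert {t.name for t in back.tips()} == {"A", "B", "C"}
    assert back.find("A").distance(back.find("B")) == pytest.approx(0.2)


def test_newick_escapes_names_with_spaces_losslessly():
    # spaces are written with the standard Newick underscore convention
    # and survive a parse round trip
    tree = upgma_tree((["fam 1", "fam 2"], [[0, 0.3], [0.3, 0]]))
    text = tree_to_newick(tree)
    assert " " not in text.split(";")[0]
    back = TreeNode.read([text])
    assert {t.name for t in back.tips()} == {"fam 1", "fam 2"}
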