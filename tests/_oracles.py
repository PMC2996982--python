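"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive or closed-form methods,
sharing no code with the implementation paths they check.
"""

from __future__ import annotations

NEG = float("-inf")


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def brute_force_rss(seq: str, spacer: int, tolerance: int, max_hept: int,
                    max_nona: int, exact_prefix: int = 3,
                    heptamer: str = "CACAGTG", nonamer: str = "ACAAAAACC"):
    """Every heptamer/nonamer window pair within budget, both strands.

    Returns a set of (heptamer_start, nonamer_start, strand) triples in
    forward coordinates.  Windows containing N never match.
    """
    hits = set()
    n = len(seq)
    rc_h, rc_n = revcomp(heptamer), revcomp(nonamer)
    for sp in range(spacer - tolerance, spacer + tolerance + 1):
        if sp < 0:
            continue
        # plus strand: heptamer ... spacer ... nonamer
        for h in range(n - 7 + 1):
            hw = seq[h : h + 7]
            if "N" in hw or hw[:exact_prefix] != heptamer[:exact_prefix]:
                continue
            if hamming(hw, heptamer) > max_hept:
                continue
            ns = h + 7 + sp
            if ns + 9 > n:
                continue
            nw = seq[ns : ns + 9]
            if "N" in nw or hamming(nw, nonamer) > max_nona:
                continue
            hits.add((h, ns, "+"))
        # minus strand: RC(nonamer) ... spacer ... RC(heptamer)
        for ns in range(n - 9 + 1):
            nw = seq[ns : ns + 9]
            if "N" in nw or hamming(nw, rc_n) > max_nona:
                continue
            h = ns + 9 + sp
            if h + 7 > n:
                continue
            hw = seq[h : h + 7]
            if "N" in hw or hw[7 - exact_prefix :] != rc_h[7 - exact_prefix :]:
                continue
            if hamming(hw, rc_h) > max_hept:
                continue
            hits.add((h, ns, "-"))
    return hits


def brute_force_overlap(donor: str, acceptor: str) -> str:
    """Longest shared suffix/prefix by scanning every length explicitly."""
    best = ""
    for k in range(1, min(len(donor), len(acceptor)) + 1):
        if donor[len(donor) - k :] == acceptor[:k]:
            best = acceptor[:k]
    return best


def _prune(pairs_set):
    """Keep only the min/max identity count for each aligned-pair count.

    Future identity/pair increments along a path do not depend on the
    counts accumulated so far, so ratio extremes at the end are always
    realised by per-pair-count extremes here.
    """
    by_pairs = {}
    for idn, pr in pairs_set:
        lo, hi = by_pairs.get(pr, (idn, idn))
        by_pairs[pr] = (min(lo, idn), max(hi, idn))
    out = set()
    for pr, (lo, hi) in by_pairs.items():
        out.add((lo, pr))
        out.add((hi, pr))
    return out


def affine_dp_identity_range(a: str, b: str, match=1.0, mismatch=-1.0,
                             gap_open=-5.0, gap_extend=-1.0):
    """Global affine-gap DP: the optimal score, and the min/max identity
    (identical pairs / aligned pairs, x100) over all optimal alignments.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; end gaps are
    penalized.  States: M (residue pair), X (gap in b), Y (gap in a).
    """
    n, m = len(a), len(b)

    def sub(i, j):
        return match if a[i - 1] == b[j - 1] else mismatch

    def new():
        return [[NEG] * (m + 1) for _ in range(n + 1)]

    FM, FX, FY = new(), new(), new()
    FM[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                prev = max(FM[i - 1][j - 1], FX[i - 1][j - 1], FY[i - 1][j - 1])
                if prev > NEG:
                    FM[i][j] = prev + sub(i, j)
            if i > 0:
                FX[i][j] = max(
                    FM[i - 1][j] + gap_open if FM[i - 1][j] > NEG else NEG,
                    FX[i - 1][j] + gap_extend if FX[i - 1][j] > NEG else NEG,
                    FY[i - 1][j] + gap_open if FY[i - 1][j] > NEG else NEG,
                )
            if j > 0:
                FY[i][j] = max(
                    FM[i][j - 1] + gap_open if FM[i][j - 1] > NEG else NEG,
                    FX[i][j - 1] + gap_open if FX[i][j - 1] > NEG else NEG,
                    FY[i][j - 1] + gap_extend if FY[i][j - 1] > NEG else NEG,
                )

    BM, BX, BY = new(), new(), new()
    BM[n][m] = BX[n][m] = BY[n][m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            for name, B in (("M", BM), ("X", BX), ("Y", BY)):
                best = NEG
                if i < n and j < m and BM[i + 1][j + 1] > NEG:
                    best = max(best, BM[i + 1][j + 1] + sub(i + 1, j + 1))
                if i < n and BX[i + 1][j] > NEG:
                    best = max(best, BX[i + 1][j] + (gap_extend if name == "X" else gap_open))
                if j < m and BY[i][j + 1] > NEG:
                    best = max(best, BY[i][j + 1] + (gap_extend if name == "Y" else gap_open))
                B[i][j] = best

    opt = max(FM[n][m], FX[n][m], FY[n][m])
    eps = 1e-9
    F = {"M": FM, "X": FX, "Y": FY}
    B = {"M": BM, "X": BX, "Y": BY}

    def admissible(state, i, j):
        f, bk = F[state][i][j], B[state][i][j]
        return f > NEG and bk > NEG and abs(f + bk - opt) < eps

    sets: dict = {}
    if admissible("M", 0, 0):
        sets[("M", 0, 0)] = {(0, 0)}
    for i in range(n + 1):
        for j in range(m + 1):
            for state in ("M", "X", "Y"):
                cur = sets.get((state, i, j))
                if not cur:
                    continue
                cur = _prune(cur)
                sets[(state, i, j)] = cur
                fij = F[state][i][j]
                if i < n and j < m and admissible("M", i + 1, j + 1):
                    if abs(fij + sub(i + 1, j + 1) - FM[i + 1][j + 1]) < eps:
                        inc = 1 if a[i] == b[j] else 0
                        dest = sets.setdefault(("M", i + 1, j + 1), set())
                        dest |= {(idn + inc, pr + 1) for idn, pr in cur}
                if i < n and admissible("X", i + 1, j):
                    cost = gap_extend if state == "X" else gap_open
                    if abs(fij + cost - FX[i + 1][j]) < eps:
                        sets.setdefault(("X", i + 1, j), set()).update(cur)
                if j < m and admissible("Y", i, j + 1):
                    cost = gap_extend if state == "Y" else gap_open
                    if abs(fij + cost - FY[i][j + 1]) < eps:
                        sets.setdefault(("Y", i, j + 1), set()).update(cur)

    finals = set()
    for state in ("M", "X", "Y"):
        if F[state][n][m] > NEG and abs(F[state][n][m] - opt) < eps:
            finals |= sets.get((state, n, m), set())
    identities = [100.0 * idn / pr for idn, pr in finals if pr > 0]
    return opt, min(identities), max(identities)
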