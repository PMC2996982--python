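"""Germline locus annotation: RSS scanning and V/D/JH/CH gene calling.

Somatic V(D)J recombination is guided by recombination signal sequences
(RSSs): a conserved heptamer (consensus CACAGTG) and nonamer (consensus
ACAAAAACC) separated by a spacer of characteristic length.  In the salmonid
IgH loci handled here, D segments are flanked on both sides by 12-bp-spacer
RSSs, JH segments carry a 5' 24-bp-spacer RSS followed by a short coding
span ending in an AGGT (occasionally TGGT) splice donor, and VH genes end
at a 3' RSS (spacer configurable, default 23 bp) downstream of a two-exon
gene preceded by an ATG(C/T)AAA(G/T) promoter octamer.

Constant-region (CH) genes are located by mapping reference coding exons
onto the locus with edit-distance alignment on both strands, then chaining
colinear exon hits into gene calls.  IgD (delta) genes may carry tandem
repeats of the exon2-exon3-exon4 block; consecutive repeats are collapsed
into one gene call with a repeat count.

Coordinates are 0-based half-open on the forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .dna import degenerate_regex, revcomp, translate
from .seqio import Feature, SequenceRecord

__all__ = [
    "RssMotif",
    "RssHit",
    "SegmentCall",
    "ChGeneCall",
    "AnnotatorConfig",
    "scan_rss",
    "call_d_segments",
    "call_jh_segments",
    "call_vh_segments",
    "map_ch_genes",
    "annotate_locus",
    "segments_to_features",
    "compare_annotations",
]

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"


@dataclass(frozen=True)
class RssMotif:
    """RSS search parameters.

    The first ``exact_heptamer_prefix`` bases of the heptamer (the CAC that
    is functionally critical for recombination) must match exactly; the
    remaining positions are allowed ``max_heptamer_mismatches`` in total.
    """

    spacer_length: int
    heptamer_consensus: str = HEPTAMER_CONSENSUS
    nonamer_consensus: str = NONAMER_CONSENSUS
    spacer_tolerance: int = 1
    max_heptamer_mismatches: int = 1
    max_nonamer_mismatches: int = 2
    exact_heptamer_prefix: int = 3

    def __post_init__(self):
        if len(self.heptamer_consensus) != 7 or len(self.nonamer_consensus) != 9:
            raise ValueError("heptamer must be 7 bp and nonamer 9 bp")
        if self.spacer_length < 0 or self.spacer_tolerance < 0:
            raise ValueError("spacer length/tolerance must be non-negative")
        if self.max_heptamer_mismatches < 0 or self.max_nonamer_mismatches < 0:
            raise ValueError("mismatch budgets must be non-negative")


@dataclass(frozen=True)
class RssHit:
    """One heptamer/nonamer pair within budget.

    ``strand`` is the strand on which the motif reads in its canonical
    heptamer->spacer->nonamer order.  ``orientation`` states on which side
    of the RSS the associated coding segment would lie (forward-strand
    coordinates): a ``+`` hit has its heptamer at the left edge, abutting a
    coding segment 5' of it (orientation ``coding_5prime``, the V-type
    geometry); a ``-`` hit reads nonamer-RC..heptamer-RC and abuts a coding
    segment 3' of it (``coding_3prime``, the J-type geometry).
    """

    seq_id: str
    heptamer_start: int
    nonamer_start: int
    strand: str
    orientation: str
    heptamer_mismatches: int
    nonamer_mismatches: int
    spacer_observed: int
    spacer_deviation: int = 0

    @property
    def start(self) -> int:
        return min(self.heptamer_start, self.nonamer_start)

    @property
    def end(self) -> int:
        return max(self.heptamer_start + 7, self.nonamer_start + 9)

    @property
    def total_mismatches(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches


@dataclass
class SegmentCall:
    """A discovered germline V, D or JH segment."""

    seq_id: str
    kind: str  # VH | D | JH
    start: int
    end: int
    strand: str
    name: str | None = None
    rss_5prime: RssHit | None = None
    rss_3prime: RssHit | None = None
    functional_status: str = "intact"
    evidence: dict = field(default_factory=dict)

    @property
    def rss_mismatches(self) -> int:
        total = 0
        for rss in (self.rss_5prime, self.rss_3prime):
            if rss is not None:
                total += rss.total_mismatches
        return total

    @property
    def spacer_deviation(self) -> int:
        total = 0
        for rss in (self.rss_5prime, self.rss_3prime):
            if rss is not None:
                total += rss.spacer_deviation
        return total


@dataclass
class ChGeneCall:
    """A constant-region gene assembled from chained exon hits."""

    seq_id: str
    isotype: str  # mu | delta | tau
    gene_name: str
    exons: list  # ordered (label, start, end) along the reading direction
    orientation: str  # forward | inverted
    completeness: str  # complete | partial | frameshift
    delta_repeat_count: int = 0

    @property
    def start(self) -> int:
        return min(s for _, s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, _, e in self.exons)


# ---------------------------------------------------------------------------
# RSS scanning
# ---------------------------------------------------------------------------

_BIG = 10_000


def _mismatch_profile(arr: np.ndarray, pattern: str, exact: set[int]) -> tuple:
    """Hamming mismatches of every window of ``arr`` against ``pattern``.

    Returns (mismatch counts, window-violates-exact-positions flags).
    Windows containing N are given an effectively infinite count so they
    can never match (they are counted by the caller, not reported).
    """
    m = len(pattern)
    n = len(arr) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32), np.empty(0, dtype=bool)
    mm = np.zeros(n, dtype=np.int32)
    bad = np.zeros(n, dtype=bool)
    n_code = ord("N")
    for j, base in enumerate(pattern.encode()):
        col = arr[j : j + n]
        neq = col != base
        mm += neq
        if j in exact:
            bad |= neq
        mm += np.where(col == n_code, _BIG, 0).astype(np.int32)
    return mm, bad


def scan_rss(
    seq: SequenceRecord, motif: RssMotif, strands: str = "both"
) -> list[RssHit]:
    """Find all heptamer/spacer/nonamer arrangements within budget.

    Hits on both strands are expressed in forward coordinates and sorted by
    heptamer start.  Windows containing N are never matched.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    min_total = 16 + motif.spacer_length
    if len(seq) < min_total:
        raise ValueError(f"sequence shorter than {min_total} bp cannot hold an RSS")

    arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    hits: list[RssHit] = []

    hept = motif.heptamer_consensus
    nona = motif.nonamer_consensus
    exact_plus = set(range(motif.exact_heptamer_prefix))
    # on the reverse-complement pattern the heptamer reads backwards, so the
    # critical prefix maps to the *last* positions of the RC heptamer window
    exact_minus = {6 - i for i in exact_plus}

    spacers = range(
        motif.spacer_length - motif.spacer_tolerance,
        motif.spacer_length + motif.spacer_tolerance + 1,
    )

    if strands in ("+", "both"):
        h_mm, h_bad = _mismatch_profile(arr, hept, exact_plus)
        n_mm, _ = _mismatch_profile(arr, nona, set())
        for spacer in spacers:
            if spacer < 0:
                continue
            offset = 7 + spacer
            limit = min(len(h_mm), len(n_mm) - offset)
            if limit <= 0:
                continue
            ok = (
                (h_mm[:limit] <= motif.max_heptamer_mismatches)
                & ~h_bad[:limit]
                & (n_mm[offset : offset + limit] <= motif.max_nonamer_mismatches)
            )
            for h in np.flatnonzero(ok):
                h = int(h)
                hits.append(
                    RssHit(
                        seq_id=seq.id,
                        heptamer_start=h,
                        nonamer_start=h + offset,
                        strand="+",
                        orientation="coding_5prime",
                        heptamer_mismatches=int(h_mm[h]),
                        nonamer_mismatches=int(n_mm[h + offset]),
                        spacer_observed=spacer,
                        spacer_deviation=abs(spacer - motif.spacer_length),
                    )
                )

    if strands in ("-", "both"):
        rc_h = revcomp(hept)
        rc_n = revcomp(nona)
        h_mm, h_bad = _mismatch_profile(arr, rc_h, exact_minus)
        n_mm, _ = _mismatch_profile(arr, rc_n, set())
        for spacer in spacers:
            if spacer < 0:
                continue
            offset = 9 + spacer  # heptamer window begins after RC nonamer + spacer
            limit = min(len(n_mm), len(h_mm) - offset)
            if limit <= 0:
                continue
            ok = (
                (n_mm[:limit] <= motif.max_nonamer_mismatches)
                & (h_mm[offset : offset + limit] <= motif.max_heptamer_mismatches)
                & ~h_bad[offset : offset + limit]
            )
            for p in np.flatnonzero(ok):
                p = int(p)
                hits.append(
                    RssHit(
                        seq_id=seq.id,
                        heptamer_start=p + offset,
                        nonamer_start=p,
                        strand="-",
                        orientation="coding_3prime",
                        heptamer_mismatches=int(h_mm[p + offset]),
                        nonamer_mismatches=int(n_mm[p]),
                        spacer_observed=spacer,
                        spacer_deviation=abs(spacer - motif.spacer_length),
                    )
                )

    hits.sort(key=lambda h: (h.heptamer_start, h.strand, h.spacer_observed))
    return hits


# ---------------------------------------------------------------------------
# Segment callers (forward-strand logic; annotate_locus handles the reverse
# strand by mirroring)
# ---------------------------------------------------------------------------


def _resolve_overlaps(calls: list[SegmentCall], key) -> list[SegmentCall]:
    """Greedy non-overlap selection; ``key`` orders candidates best-first."""
    kept: list[SegmentCall] = []
    for call in sorted(calls, key=key):
        if all(call.end <= k.start or call.start >= k.end for k in kept):
            kept.append(call)
    kept.sort(key=lambda c: c.start)
    return kept


def call_d_segments(
    seq: SequenceRecord,
    rss_hits: list[RssHit],
    min_len: int = 5,
    max_len: int = 40,
) -> list[SegmentCall]:
    """Call D segments as spans enclosed by convergent 12-bp-spacer RSSs.

    A D segment requires a 5' RSS in J-type geometry (heptamer at the
    segment's left edge) and a 3' RSS in V-type geometry, with the enclosed
    length within [min_len, max_len].  Overlaps are resolved by lowest total
    RSS mismatches, then leftmost start.  Note the RSS geometry of a D
    segment is strand-symmetric, so calls are reported on the + strand.
    """
    lefts = [h for h in rss_hits if h.orientation == "coding_3prime"]
    rights = [h for h in rss_hits if h.orientation == "coding_5prime"]
    candidates: list[SegmentCall] = []
    for left in lefts:
        d_start = left.heptamer_start + 7
        for right in rights:
            length = right.heptamer_start - d_start
            if min_len <= length <= max_len:
                candidates.append(
                    SegmentCall(
                        seq_id=seq.id,
                        kind="D",
                        start=d_start,
                        end=right.heptamer_start,
                        strand="+",
                        rss_5prime=left,
                        rss_3prime=right,
                    )
                )
    return _resolve_overlaps(
        candidates, key=lambda c: (c.rss_mismatches, c.start, c.end)
    )


DEFAULT_SPLICE_SITES = ("AGGT", "TGGT")
DEFAULT_JH_MOTIF = "FDYWGKGTXVTVS"


def _motif_similarity(peptide: str, motif: str) -> float:
    """C-terminally anchored identity to the consensus, over non-X positions."""
    k = min(len(peptide), len(motif))
    if k == 0:
        return 0.0
    pep, mot = peptide[-k:], motif[-k:]
    scored = matched = 0
    for p, m in zip(pep, mot):
        if m == "X":
            continue
        scored += 1
        if p == m:
            matched += 1
    return matched / scored if scored else 0.0


def call_jh_segments(
    seq: SequenceRecord,
    rss_hits: list[RssHit],
    splice_sites=DEFAULT_SPLICE_SITES,
    motif_consensus: str = DEFAULT_JH_MOTIF,
    min_motif_similarity: float = 0.70,
    coding_len_range: tuple[int, int] = (21, 75),
) -> list[SegmentCall]:
    """Call JH segments downstream of 5' 24-bp-spacer RSSs.

    The coding span runs from the heptamer to a splice donor from
    ``splice_sites``; it is translated in the RSS-anchored frame and must
    match the consensus joining-segment motif (X matches anything) at
    ``min_motif_similarity`` or better.  An in-frame stop marks the call
    ``pseudogene_stop``.
    """
    splice_sites = set(splice_sites)
    s = seq.residues
    min_len, max_len = coding_len_range
    candidates: list[SegmentCall] = []
    for hit in rss_hits:
        if hit.orientation != "coding_3prime":
            continue
        start = hit.heptamer_start + 7
        best = None
        for length in range(min_len - min_len % 3, max_len + 1, 3):
            if length < min_len:
                continue
            donor = s[start + length : start + length + 4]
            if donor not in splice_sites:
                continue
            peptide = translate(s[start : start + length])
            sim = _motif_similarity(peptide, motif_consensus)
            if best is None or (sim, length) > (best[0], best[1]):
                best = (sim, length, donor, peptide)
        if best is None:
            continue
        sim, length, donor, peptide = best
        if sim < min_motif_similarity:
            continue
        candidates.append(
            SegmentCall(
                seq_id=seq.id,
                kind="JH",
                start=start,
                end=start + length,
                strand="+",
                rss_5prime=hit,
                functional_status=(
                    "pseudogene_stop" if "*" in peptide else "intact"
                ),
                evidence={
                    "splice_site": donor,
                    "motif_similarity": round(sim, 4),
                    "peptide": peptide,
                },
            )
        )
    return _resolve_overlaps(
        candidates,
        key=lambda c: (
            -c.evidence["motif_similarity"],
            c.rss_mismatches,
            c.start,
        ),
    )


DEFAULT_OCTAMER = "ATGYAAAK"


def call_vh_segments(
    seq: SequenceRecord,
    rss_hits: list[RssHit],
    octamer_pattern: str = DEFAULT_OCTAMER,
    exon2_len_range: tuple[int, int] = (240, 360),
    intron_len_range: tuple[int, int] = (40, 300),
    promoter_window: int = 250,
) -> list[SegmentCall]:
    """Call VH genes ending at a 3' RSS.

    Candidate exon-2 spans end at the RSS heptamer, begin after an AG splice
    acceptor and have a length in ``exon2_len_range`` that is a multiple of
    three.  A full gene additionally requires, upstream of the acceptor, a
    GT splice donor at an intron-compatible distance and a promoter octamer
    within ``promoter_window`` of the donor; candidates lacking that
    upstream structure are emitted with status ``fragment``.  An in-frame
    stop in exon 2 marks ``pseudogene_stop``.  The reported span is exon 2.
    """
    s = seq.residues
    min_len, max_len = exon2_len_range
    octamer_re = degenerate_regex(octamer_pattern)
    octamer_positions = [m.start() for m in octamer_re.finditer(s)]
    intron_min, intron_max = intron_len_range

    def upstream_structure(p: int):
        """Rightmost GT donor at intron distance, with a promoter octamer
        within ``promoter_window`` of the exon-2 splice acceptor."""
        q_hi = p - 2 - intron_min
        q_lo = max(0, p - 2 - intron_max)
        for q in range(q_hi, q_lo - 1, -1):
            if s[q : q + 2] != "GT":
                continue
            octs = [o for o in octamer_positions if p - promoter_window <= o < q - 8]
            if octs:
                return {"donor": q, "octamer": octs[-1]}
        return None

    candidates: list[SegmentCall] = []
    for hit in rss_hits:
        if hit.orientation != "coding_5prime":
            continue
        end = hit.heptamer_start
        acceptor_starts = [
            p
            for p in range(max(2, end - max_len), end - min_len + 1)
            if (end - p) % 3 == 0 and s[p - 2 : p] == "AG"
        ]
        # three competing exon-2 delimitations, compared by span length:
        # (a) the longest splice-acceptor candidate with full promoter and
        #     exon-1 structure (may contain stops: pseudogene);
        # (b) the longest stop-free splice-acceptor candidate without
        #     promoter structure (gene fragment);
        # (c) the longest end-anchored stop-free open span, for fragments
        #     that retain no splice acceptor at all.
        structured_choice = structure = None
        for p in acceptor_starts:  # ascending start = descending length
            up = upstream_structure(p)
            if up is not None:
                structured_choice, structure = p, up
                break
        stop_free = [p for p in acceptor_starts if "*" not in translate(s[p:end])]
        acceptor_choice = stop_free[0] if stop_free else None
        length = 0
        while length + 3 <= max_len and end - length - 3 >= 0:
            codon = s[end - length - 3 : end - length]
            if translate(codon) == "*":
                break
            length += 3
        anchored_choice = end - length if length >= min_len else None

        ranked = [
            (p, rank)
            for rank, p in enumerate(
                (structured_choice, acceptor_choice, anchored_choice)
            )
            if p is not None
        ]
        if not ranked:
            continue
        chosen, which = min(ranked, key=lambda t: (t[0], t[1]))
        if which != 0:
            structure = None
        peptide = translate(s[chosen:end])
        if "*" in peptide:
            status = "pseudogene_stop"
        elif structure is None:
            status = "fragment"
        else:
            status = "intact"
        evidence = {"acceptor": s[max(0, chosen - 2) : chosen]}
        if structure is not None:
            evidence.update(
                octamer_start=structure["octamer"],
                splice_donor=structure["donor"],
                intron_length=chosen - 2 - structure["donor"],
            )
        candidates.append(
            SegmentCall(
                seq_id=seq.id,
                kind="VH",
                start=chosen,
                end=end,
                strand="+",
                rss_3prime=hit,
                functional_status=status,
                evidence=evidence,
            )
        )
    return _resolve_overlaps(
        candidates, key=lambda c: (c.rss_mismatches, -(c.end - c.start), c.start)
    )


# ---------------------------------------------------------------------------
# CH gene mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _ExonHit:
    isotype: str
    exon_index: int
    start: int
    end: int
    strand: str
    distance: int
    net_indel: int


def _parse_reference_id(ref_id: str) -> tuple[str, int]:
    try:
        isotype, exon_part = ref_id.split("_exon")
        index = int(exon_part)
    except ValueError as exc:
        raise ValueError(
            f"CH reference id {ref_id!r} must look like 'mu_exon2'"
        ) from exc
    if isotype not in ("mu", "delta", "tau"):
        raise ValueError(f"unknown CH isotype in reference id {ref_id!r}")
    return isotype, index


def _find_occurrences(target: str, query: str, max_dist: int):
    """All approximate occurrences of query in target (iterative masking)."""
    occurrences = []
    work = target
    while True:
        res = edlib.align(query, work, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] == -1:
            break
        found_any = False
        mask_spans = []
        last_end = -1
        for st, en in res["locations"]:
            if st <= last_end:  # co-best shifted variants of the same site
                continue
            last_end = en
            occurrences.append((st, en + 1, res["editDistance"]))
            mask_spans.append((st, en + 1))
            found_any = True
        if not found_any:
            break
        chars = list(work)
        for st, en in mask_spans:
            chars[st:en] = "X" * (en - st)
        work = "".join(chars)
    return occurrences


def map_ch_genes(
    seq: SequenceRecord,
    references: list[SequenceRecord],
    min_exon_identity: float = 0.9,
    max_intron: int = 2500,
) -> list[ChGeneCall]:
    """Map CH genes by homology of reference coding exons, both strands.

    References must be named ``<isotype>_exon<N>`` (isotype mu/delta/tau).
    Colinear exon hits within ``max_intron`` of each other are chained into
    gene calls; minus-strand chains are reported as inverted.  Consecutive
    delta exon2-exon3-exon4 repeats collapse into one gene with
    ``delta_repeat_count`` set.  Genes missing leading/trailing exons are
    ``partial``; a net exon indel not divisible by three marks
    ``frameshift``.
    """
    expected: dict[str, set[int]] = {}
    parsed = []
    for ref in references:
        isotype, index = _parse_reference_id(ref.id)
        expected.setdefault(isotype, set()).add(index)
        parsed.append((isotype, index, ref.residues))

    L = len(seq)
    rc = revcomp(seq.residues)
    hits: list[_ExonHit] = []
    for isotype, index, ref_seq in parsed:
        max_dist = int((1 - min_exon_identity) * len(ref_seq))
        for strand, target in (("+", seq.residues), ("-", rc)):
            for st, en, dist in _find_occurrences(target, ref_seq, max_dist):
                if strand == "-":
                    st, en = L - en, L - st
                hits.append(
                    _ExonHit(
                        isotype=isotype,
                        exon_index=index,
                        start=st,
                        end=en,
                        strand=strand,
                        distance=dist,
                        net_indel=(en - st) - len(ref_seq),
                    )
                )

    calls: list[ChGeneCall] = []
    for strand in ("+", "-"):
        strand_hits = [h for h in hits if h.strand == strand]
        # order along the gene's reading direction
        strand_hits.sort(key=lambda h: h.start, reverse=(strand == "-"))
        chain: list[_ExonHit] = []

        def flush():
            if chain:
                calls.append(_chain_to_call(seq.id, chain, expected, strand))
                chain.clear()

        for hit in strand_hits:
            if chain:
                prev = chain[-1]
                gap = (
                    hit.start - prev.end if strand == "+" else prev.start - hit.end
                )
                compatible = hit.exon_index == prev.exon_index + 1 or (
                    hit.isotype == "delta"
                    and prev.exon_index == 4
                    and hit.exon_index == 2
                )
                if hit.isotype != prev.isotype or gap > max_intron or gap < 0 or not compatible:
                    flush()
            chain.append(hit)
        flush()

    calls.sort(key=lambda c: c.start)
    for i, call in enumerate(calls, start=1):
        call.gene_name = f"C{call.isotype}-{i}"
    return calls


def _chain_to_call(seq_id, chain, expected, strand) -> ChGeneCall:
    isotype = chain[0].isotype
    indices = [h.exon_index for h in chain]
    repeat_count = 0
    if isotype == "delta":
        # count complete 2-3-4 cycles
        i = 0
        while i + 2 < len(indices) + 1:
            if indices[i : i + 3] == [2, 3, 4]:
                repeat_count += 1
                i += 3
            else:
                i += 1
    covered = set(indices)
    if any(h.net_indel % 3 != 0 for h in chain):
        completeness = "frameshift"
    elif covered == expected[isotype]:
        completeness = "complete"
    else:
        completeness = "partial"
    exons = [(f"exon{h.exon_index}", h.start, h.end) for h in chain]
    return ChGeneCall(
        seq_id=seq_id,
        isotype=isotype,
        gene_name=f"C{isotype}-?",
        exons=exons,
        orientation="forward" if strand == "+" else "inverted",
        completeness=completeness,
        delta_repeat_count=repeat_count,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatorConfig:
    """Tunable parameters of the locus annotator (documented defaults)."""

    d_spacer: int = 12
    jh_spacer: int = 24
    vh_spacer: int = 23
    spacer_tolerance: int = 1
    max_heptamer_mismatches: int = 1
    max_nonamer_mismatches: int = 2
    d_len_range: tuple[int, int] = (5, 40)
    splice_sites: tuple = DEFAULT_SPLICE_SITES
    jh_motif: str = DEFAULT_JH_MOTIF
    min_motif_similarity: float = 0.70
    octamer: str = DEFAULT_OCTAMER
    exon2_len_range: tuple[int, int] = (240, 360)
    intron_len_range: tuple[int, int] = (40, 300)
    ch_min_exon_identity: float = 0.9
    ch_max_intron: int = 2500
    strands: str = "both"
    locus_tag: str = ""

    def motif(self, spacer: int) -> RssMotif:
        return RssMotif(
            spacer_length=spacer,
            spacer_tolerance=self.spacer_tolerance,
            max_heptamer_mismatches=self.max_heptamer_mismatches,
            max_nonamer_mismatches=self.max_nonamer_mismatches,
        )


@dataclass
class AnnotationResult:
    segments: list[SegmentCall]
    ch_genes: list[ChGeneCall]
    features: list[Feature]


def _forward_pass(seq: SequenceRecord, config: AnnotatorConfig):
    hits12 = scan_rss(seq, config.motif(config.d_spacer))
    hits24 = scan_rss(seq, config.motif(config.jh_spacer))
    hits23 = scan_rss(seq, config.motif(config.vh_spacer))
    d = call_d_segments(seq, hits12, *config.d_len_range)
    j = call_jh_segments(
        seq,
        hits24,
        splice_sites=config.splice_sites,
        motif_consensus=config.jh_motif,
        min_motif_similarity=config.min_motif_similarity,
    )
    v = call_vh_segments(
        seq,
        hits23,
        octamer_pattern=config.octamer,
        exon2_len_range=config.exon2_len_range,
        intron_len_range=config.intron_len_range,
    )
    return d, j, v


def _mirror(call: SegmentCall, L: int) -> SegmentCall:
    return replace(
        call,
        start=L - call.end,
        end=L - call.start,
        strand="-",
        rss_5prime=None,
        rss_3prime=None,
        evidence={**call.evidence, "mirrored": True,
                  "rss_mismatches": call.rss_mismatches,
                  "spacer_deviation": call.spacer_deviation,
                  "status_rank": 1 if call.functional_status == "fragment" else 0},
    )


def annotate_locus(
    seq: SequenceRecord,
    config: AnnotatorConfig = AnnotatorConfig(),
    ch_references: list[SequenceRecord] | None = None,
) -> AnnotationResult:
    """Run the full germline annotation on one locus sequence.

    V/D/JH segments are discovered by RSS geometry on the forward strand
    and, when ``config.strands == "both"``, on the reverse complement with
    coordinates mirrored back.  D segments are strand-symmetric by RSS
    geometry alone and are normalised to the + strand.  After overlap
    resolution no two emitted segments overlap; segments are named by kind,
    nearest CH gene and 5'-to-3' ordinal.
    """
    d, j, v = _forward_pass(seq, config)
    segments = list(d) + list(j) + list(v)
    if config.strands == "both":
        rc_seq = SequenceRecord(seq.id, revcomp(seq.residues), seq.description)
        _d_rc, j_rc, v_rc = _forward_pass(rc_seq, config)
        L = len(seq)
        segments += [_mirror(c, L) for c in j_rc + v_rc]

    ch_genes = (
        map_ch_genes(
            seq,
            ch_references,
            min_exon_identity=config.ch_min_exon_identity,
            max_intron=config.ch_max_intron,
        )
        if ch_references
        else []
    )

    # exclude segment calls that land inside CH exons, then resolve overlaps
    ch_spans = [(s, e) for g in ch_genes for _, s, e in g.exons]

    def in_ch(call):
        return any(call.start < e and call.end > s for s, e in ch_spans)

    def evidence_key(call):
        mm = call.evidence.get("rss_mismatches", call.rss_mismatches)
        dev = call.evidence.get("spacer_deviation", call.spacer_deviation)
        # segments whose RSS spacer deviates from its canonical length are
        # weaker evidence, and promoterless fragments weaker still; prefer
        # forward-strand calls on exact ties for determinism
        rank = call.evidence.get(
            "status_rank", 1 if call.functional_status == "fragment" else 0
        )
        return (mm + dev, rank, -(call.end - call.start), call.start, call.strand)

    segments = _resolve_overlaps(
        [c for c in segments if not in_ch(c)], key=evidence_key
    )

    _name_calls(segments, ch_genes, config.locus_tag)
    features = segments_to_features(segments, ch_genes)
    return AnnotationResult(segments=segments, ch_genes=ch_genes, features=features)


def _name_calls(segments, ch_genes, locus_tag):
    """Name segments after the nearest CH gene, 5'-to-3' within each group."""
    tag = locus_tag or "X"
    tau_ordinal = {}
    n_tau = 0
    for gene in ch_genes:
        if gene.isotype == "tau":
            n_tau += 1
            tau_ordinal[id(gene)] = n_tau
            gene.gene_name = f"Ctau_{tag}-{n_tau}"
        else:
            gene.gene_name = f"C{gene.isotype}_{tag}"

    def gene_label(gene):
        if gene.isotype == "tau":
            return f"tau_{tag}{tau_ordinal[id(gene)]}"
        return f"{gene.isotype}_{tag}"

    def nearest(call):
        best, best_dist = None, None
        centre = (call.start + call.end) / 2
        for gene in ch_genes:
            dist = abs((gene.start + gene.end) / 2 - centre)
            if best_dist is None or dist < best_dist:
                best, best_dist = gene, dist
        return best

    counters: dict[tuple, int] = {}
    for call in sorted(segments, key=lambda c: c.start):
        gene = nearest(call)
        group = gene_label(gene) if gene is not None else tag
        key = (call.kind, group)
        counters[key] = counters.get(key, 0) + 1
        if call.kind == "VH":
            call.name = f"VH_{tag}-{counters[key]:03d}"
        else:
            call.name = f"{call.kind}-{group}-{counters[key]}"


_KIND_TO_FEATURE = {"VH": "VH_exon2", "D": "D_segment", "JH": "JH_segment"}


def segments_to_features(segments, ch_genes) -> list[Feature]:
    features = []
    for call in segments:
        attrs = {"status": call.functional_status}
        if call.name:
            attrs["Name"] = call.name
        features.append(
            Feature(
                seq_id=call.seq_id,
                kind=_KIND_TO_FEATURE[call.kind],
                start=call.start,
                end=call.end,
                strand=call.strand,
                attributes=attrs,
            )
        )
    for gene in ch_genes:
        strand = "+" if gene.orientation == "forward" else "-"
        for label, s, e in gene.exons:
            features.append(
                Feature(
                    seq_id=gene.seq_id,
                    kind="CH_exon",
                    start=s,
                    end=e,
                    strand=strand,
                    attributes={
                        "Name": f"{gene.gene_name}_{label}",
                        "gene": gene.gene_name,
                        "isotype": gene.isotype,
                        "completeness": gene.completeness,
                    },
                )
            )
    features.sort(key=lambda f: (f.seq_id, f.start, f.end, f.kind))
    return features


def compare_annotations(
    truth: list[Feature], called: list[Feature], kinds=None
) -> dict:
    """Exact-interval recall/precision of called features against truth."""
    if kinds is None:
        kinds = sorted({f.kind for f in truth})
    out = {}
    for kind in kinds:
        t = {(f.seq_id, f.start, f.end) for f in truth if f.kind == kind}
        c = {(f.seq_id, f.start, f.end) for f in called if f.kind == kind}
        tp = len(t & c)
        out[kind] = {
            "recall": tp / len(t) if t else float("nan"),
            "precision": tp / len(c) if c else float("nan"),
            "n_truth": len(t),
            "n_called": len(c),
        }
    return out
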