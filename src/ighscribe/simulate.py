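"""Synthetic germline loci and rearranged repertoires with truth records.

The generator emulates the structure of a duplicated salmonid IgH locus
pair (loci A and B): VH genes grouped into families that are well separated
around the 75% identity threshold, D segments flanked by 12-bp-spacer RSSs,
JH segments with 24-bp-spacer RSSs, AGGT/TGGT splice donors and a conserved
FDYWGKGTXVTVS joining motif, and a constant-gene layout with multiple tau
genes (complete, partial, inverted or frameshifted), one mu and one delta
gene per locus, and tandem delta exon2-exon3-exon4 repeats (three copies in
locus A, four in locus B).  The default layout carries 25 D and 20 JH
segments across the pair and 18 VH families, mirroring the germline
complement the annotation pipeline is designed to recover.

Repertoires are mixtures of canonical V-D-J-C reads, chimeric IgD reads
(Cmu exon 1 spliced before the delta exons), noncanonical delta reads that
join the V body directly into a delta exon through a planted microhomology,
and trans-locus reads (V from one locus, constant gene from the other).
Every latent variable is recorded in a truth table.

All randomness flows from the seed field of the parameter objects through
one generator, so equal parameters produce byte-identical outputs.

Synthetic sequences differ from real genomic DNA in documented ways: VH
introns are built free of AG dinucleotides so exon-2 boundaries are
unambiguous, and intergenic spacers are uniform random DNA rather than
repeat-element-rich sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dna import revcomp
from .repertoire import ChGene, DGene, GermlineDb, JhGene, VhGene, longest_join_overlap
from .seqio import Feature, SequenceRecord

__all__ = [
    "ChGeneSpec",
    "LocusSpec",
    "RepertoireSpec",
    "SyntheticLocusPair",
    "LOCUS_A_LAYOUT",
    "LOCUS_B_LAYOUT",
    "generate_locus_pair",
    "generate_locus",
    "generate_repertoire",
    "inject_errors",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
STOP_PAD = "TTAATTAATTAA"  # stop codons in all three frames, AG-free
JH_MOTIF = "FDYWGKGTXVTVS"

_MU_EXON_LENS = (324, 321, 318, 315)
_TAU_EXON_LENS = (309, 315, 312, 306)
_DELTA_EXON_LENS = (315, 330, 327, 324, 318, 312, 306)

_CODONS = {
    "F": ("TTT", "TTC"),
    "D": ("GAT", "GAC"),
    "Y": ("TAT", "TAC"),
    "W": ("TGG",),
    "G": ("GGA", "GGC", "GGT", "GGG"),
    "K": ("AAA", "AAG"),
    "T": ("ACA", "ACC", "ACT", "ACG"),
    "V": ("GTA", "GTC", "GTT", "GTG"),
    "S": ("AGC", "TCA", "TCC", "TCT"),
}


def _rand_dna(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _rand_codons(rng, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = _rand_dna(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _no_ag(seq: str) -> str:
    """Remove every AG dinucleotide (used for synthetic VH introns)."""
    chars = list(seq)
    for i in range(1, len(chars)):
        if chars[i - 1] == "A" and chars[i] == "G":
            chars[i] = "C"
    return "".join(chars)


_OCTAMER_RE = None


def _no_octamer(seq: str) -> str:
    """Remove chance promoter-octamer motifs from filler sequence."""
    global _OCTAMER_RE
    if _OCTAMER_RE is None:
        import re

        _OCTAMER_RE = re.compile("ATG[CT]AAA[GT]")
    while True:
        m = _OCTAMER_RE.search(seq)
        if m is None:
            return seq
        i = m.start() + 1
        seq = seq[:i] + "C" + seq[i + 1 :]


def _mutate(rng, seq: str, n_sub: int, protect: int = 2, keep_orf: bool = False) -> str:
    """Apply ``n_sub`` random substitutions, avoiding the first/last
    ``protect`` bases and (optionally) never creating an in-frame stop."""
    chars = list(seq)
    positions = rng.permutation(np.arange(protect, len(seq) - protect))
    done = 0
    for pos in positions:
        if done >= n_sub:
            break
        pos = int(pos)
        old = chars[pos]
        alternatives = [b for b in "ACGT" if b != old]
        rng.shuffle(alternatives)
        for new in alternatives:
            chars[pos] = new
            if keep_orf:
                cstart = pos - pos % 3
                if "".join(chars[cstart : cstart + 3]) in _STOPS:
                    chars[pos] = old
                    continue
            done += 1
            break
    return "".join(chars)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChGeneSpec:
    """Layout entry for one constant gene."""

    name: str
    isotype: str  # mu | delta | tau
    n_d: int = 0
    n_jh: int = 0
    orientation: str = "forward"
    exons_present: Optional[tuple] = None  # None = all exons
    frameshift: bool = False
    delta_repeat_count: int = 1
    functional: bool = True
    jh_pseudogene: bool = False  # plant a TAC->TAG stop in the first JH


#: default layouts: five tau genes in locus A (one inverted, two partial,
#: one frameshifted) and three in locus B, mu and delta at the 3' end,
#: delta exon2-4 repeated three times in A and four times in B; D/JH
#: complements total 25 D and 20 JH across the pair.
LOCUS_A_LAYOUT = (
    ChGeneSpec("Ctau_A-1", "tau", exons_present=(4,), functional=False),
    ChGeneSpec("Ctau_A-2", "tau", n_d=2, n_jh=2, exons_present=(1, 2), functional=False),
    ChGeneSpec("Ctau_A-3", "tau", n_jh=1, frameshift=True, functional=False),
    ChGeneSpec("Ctau_A-4", "tau", n_d=5, n_jh=2, orientation="inverted"),
    ChGeneSpec("Ctau_A-5", "tau", n_d=1, n_jh=2),
    ChGeneSpec("Cmu_A", "mu", n_d=9, n_jh=5),
    ChGeneSpec("Cdelta_A", "delta", delta_repeat_count=3),
)

LOCUS_B_LAYOUT = (
    ChGeneSpec("Ctau_B-1", "tau", n_jh=1, frameshift=True, functional=False,
               jh_pseudogene=True),
    ChGeneSpec("Ctau_B-2", "tau", n_d=2, n_jh=2),
    ChGeneSpec("Ctau_B-3", "tau", exons_present=(2, 3, 4), functional=False),
    ChGeneSpec("Cmu_B", "mu", n_d=6, n_jh=5),
    ChGeneSpec("Cdelta_B", "delta", delta_repeat_count=4),
)


@dataclass(frozen=True)
class LocusSpec:
    """Parameters of the synthetic germline locus pair.

    The defaults are the study conditions: 18 VH families, within-family
    divergence low enough to keep pairwise identity comfortably above the
    75% family threshold and unrelated founders below it, roughly 70% of
    VH genes non-functional (stop-codon pseudogenes plus promoterless
    fragments), and the constant-gene layouts above.
    """

    seed: int
    n_families: int = 18
    members_per_family: tuple = (2, 4)  # per locus, inclusive range
    within_family_divergence: tuple = (0.04, 0.08)  # per-member substitution rate
    between_family_identity_max: float = 65.0
    pseudogene_fraction: float = 0.40
    fragment_fraction: float = 0.30
    a_only_families: tuple = (13, 14, 18)
    ch_layout_a: tuple = LOCUS_A_LAYOUT
    ch_layout_b: tuple = LOCUS_B_LAYOUT
    intergenic_length: tuple = (150, 350)
    rss_mutation_rate: float = 0.0
    tggt_splice_rate: float = 0.10
    d_core_length: tuple = (12, 28)
    n_diagnostic_sites: int = 5

    def __post_init__(self):
        lo, hi = self.within_family_divergence
        if not (0 < lo <= hi < 0.12):
            raise ValueError(
                "within-family divergence must keep identities above the "
                "75% family threshold"
            )
        if self.pseudogene_fraction + self.fragment_fraction > 1:
            raise ValueError("status fractions exceed 1")


@dataclass(frozen=True)
class RepertoireSpec:
    """Parameters of the synthetic rearranged-cDNA repertoire.

    The default category mixture puts 30% of reads on delta, split 90/10
    between chimeric (Cmu1-containing) and noncanonical direct joins, and
    10% of reads on trans-locus rearrangements, matching the proportions
    reported for expressed salmon IgH cDNA; junctional trimming/insertion
    ranges are generic V(D)J defaults since no salmon-specific statistics
    exist.
    """

    seed: int
    n_reads: int = 2000
    category_mixture: tuple = (
        ("canonical", 0.60),
        ("chimeric_mu1_delta", 0.27),
        ("noncanonical_delta", 0.03),
        ("trans_locus", 0.10),
    )
    v_trim_max: int = 5
    d_trim_max: int = 2
    j_trim_max: int = 3
    n_insertion_max: int = 8
    microhomology_geometric_p: float = 0.45
    microhomology_max: int = 7
    jh_weights_5: tuple = (0.1, 0.2, 0.4, 0.2, 0.1)
    gene_weights: Optional[tuple] = None  # ((gene_name, weight), ...)
    family_bias: tuple = ((("Cmu_A",), 8), (("Cmu_B",), 6))
    duplicate_fraction: float = 0.10
    error_rate: float = 0.0
    c_portion_length: tuple = (300, 400)

    def __post_init__(self):
        total = sum(w for _, w in self.category_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category mixture must sum to 1")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error rate must be in [0, 1]")


_DEFAULT_GENE_WEIGHTS = (
    ("Cmu_A", 0.25),
    ("Cmu_B", 0.35),
    ("Ctau_A-4", 0.25),
    ("Ctau_A-5", 0.04),
    ("Ctau_B-2", 0.11),
)


@dataclass
class SyntheticLocusPair:
    records: dict  # locus tag -> SequenceRecord
    features: list  # truth Feature list across both loci
    db: GermlineDb
    ch_references: list  # founder exon SequenceRecords for map_ch_genes

    def features_for(self, locus: str) -> list:
        seq_id = self.records[locus].id
        return [f for f in self.features if f.seq_id == seq_id]


# ---------------------------------------------------------------------------
# germline construction
# ---------------------------------------------------------------------------


def _make_rss(rng, spacer: int, rate: float) -> tuple[str, str]:
    """(5'-side, 3'-side) RSS text with coupled mutation sampling.

    Mutation positions are decided by per-position uniforms drawn
    unconditionally, so raising the rate with the same seed only ever adds
    mutations (recall degrades monotonically in the rate by construction).
    """

    def mutated(motif: str) -> str:
        u = rng.random(len(motif))
        swap = rng.integers(1, 4, size=len(motif))
        chars = list(motif)
        for i in range(len(motif)):
            if u[i] < rate:
                chars[i] = "ACGT"[("ACGT".index(chars[i]) + int(swap[i])) % 4]
        return "".join(chars)

    hept5, nona5 = mutated(HEPTAMER), mutated(NONAMER)
    spacer5 = _rand_dna(rng, spacer)
    hept3, nona3 = mutated(HEPTAMER), mutated(NONAMER)
    spacer3 = _rand_dna(rng, spacer)
    # the 5'-side RSS in forward coordinates reads RC(nonamer)+spacer+RC(heptamer)
    five = revcomp(nona5) + spacer5 + revcomp(hept5)
    three = hept3 + spacer3 + nona3
    return five, three


def _jh_coding(rng) -> str:
    parts = []
    for aa in JH_MOTIF:
        if aa == "X":
            parts.append(_rand_codons(rng, 1))
        else:
            codons = _CODONS[aa]
            parts.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(parts)


def _build_vh_pool(rng, spec: LocusSpec):
    """Family founders plus per-locus member sequences with status labels."""
    founders = {}
    for fam in range(1, spec.n_families + 1):
        length = 279 + 3 * ((fam * 7) % 11)
        founders[fam] = _rand_codons(rng, length // 3)
    members = []  # (locus, family, index, status, exon2)
    seen = set()
    lo, hi = spec.members_per_family
    div_lo, div_hi = spec.within_family_divergence
    for locus in ("A", "B"):
        for fam in range(1, spec.n_families + 1):
            if locus == "B" and fam in spec.a_only_families:
                continue
            count = 1 if fam == 18 else int(rng.integers(lo, hi + 1))
            for idx in range(1, count + 1):
                u = rng.random()
                if u < spec.pseudogene_fraction:
                    status = "pseudogene_stop"
                elif u < spec.pseudogene_fraction + spec.fragment_fraction:
                    status = "fragment"
                else:
                    status = "intact"
                for _attempt in range(50):
                    rate = div_lo + (div_hi - div_lo) * rng.random()
                    n_sub = max(3, int(round(rate * len(founders[fam]))))
                    exon2 = _mutate(rng, founders[fam], n_sub, protect=0, keep_orf=True)
                    if status == "pseudogene_stop":
                        codon = int(rng.integers(3, len(exon2) // 3 - 3))
                        exon2 = exon2[: codon * 3] + "TAA" + exon2[codon * 3 + 3 :]
                    key = exon2[: len(exon2) - 6]
                    if key not in seen:
                        seen.add(key)
                        break
                else:
                    raise RuntimeError("could not generate a distinct VH member")
                members.append((locus, fam, idx, status, exon2))
    return founders, members


_OCTAMERS = ("ATGCAAAG", "ATGCAAAT", "ATGTAAAG", "ATGTAAAT")


class _LocusAssembler:
    def __init__(self, rng, spec: LocusSpec, seq_id: str):
        self.rng = rng
        self.spec = spec
        self.seq_id = seq_id
        self.parts: list[str] = []
        self.length = 0
        self.features: list[Feature] = []

    def add(self, seq: str) -> int:
        start = self.length
        self.parts.append(seq)
        self.length += len(seq)
        return start

    def intergenic(self):
        lo, hi = self.spec.intergenic_length
        self.add(_no_octamer(_rand_dna(self.rng, int(self.rng.integers(lo, hi + 1)))))

    def feature(self, kind, start, end, strand="+", **attrs):
        self.features.append(
            Feature(self.seq_id, kind, start, end, strand, dict(attrs))
        )

    def vh_cassette(self, exon2: str, status: str, name: str, family: int):
        rng = self.rng
        if status != "fragment":
            octamer = _OCTAMERS[int(rng.integers(0, len(_OCTAMERS)))]
            spacer = _no_octamer(_no_ag(_rand_dna(rng, int(rng.integers(15, 31)))))
            exon1 = _no_octamer("ATG" + _no_ag(_rand_codons(rng, int(rng.integers(12, 20)))))
            if exon1[-1] == "A":
                exon1 = exon1[:-1] + "C"
            intron_core = _no_octamer(_no_ag(_rand_dna(rng, int(rng.integers(46, 107)))))
            self.add(octamer + spacer)
            self.add(exon1)
            # intron ends with a TAG: the AG is the splice acceptor and the
            # in-frame stop makes the exon-2 boundary unambiguous
            self.add("GT" + intron_core + STOP_PAD + "TAG")
        else:
            self.add(STOP_PAD)
        start = self.add(exon2)
        self.feature(
            "VH_exon2", start, start + len(exon2),
            status=status, Name=name, family=family,
        )
        _, rss3 = _make_rss(rng, 23, self.spec.rss_mutation_rate)
        self.add(rss3)

    def d_segment(self, core: str, name: str):
        rss5, rss3 = _make_rss(self.rng, 12, self.spec.rss_mutation_rate)
        self.add(rss5)
        start = self.add(core)
        self.feature("D_segment", start, start + len(core), Name=name)
        self.add(rss3)

    def jh_segment(self, coding: str, name: str, pseudogene: bool):
        rng = self.rng
        rss5, _ = _make_rss(rng, 24, self.spec.rss_mutation_rate)
        self.add(rss5)
        start = self.add(coding)
        splice = "TGGT" if rng.random() < self.spec.tggt_splice_rate else "AGGT"
        self.feature(
            "JH_segment", start, start + len(coding),
            Name=name, status="pseudogene_stop" if pseudogene else "intact",
            splice_site=splice,
        )
        self.add(splice)

    def ch_gene(self, gene_spec: ChGeneSpec, exon_seqs: dict):
        """Plant a constant gene; returns nothing, records truth features.

        ``exon_seqs`` maps exon index (or (index, copy) for delta repeats)
        to sequence.
        """
        rng = self.rng
        order = _ch_exon_order(gene_spec)
        pieces = []  # (exon label index, seq) in genomic order
        for key in order:
            idx = key[0] if isinstance(key, tuple) else key
            seq = exon_seqs[key]
            pieces.append((idx, seq))
        if gene_spec.frameshift:
            idx0, seq0 = pieces[0]
            drop = len(seq0) // 2
            pieces[0] = (idx0, seq0[:drop] + seq0[drop + 1 :])
        # assemble with introns
        assembled = []
        exon_spans = []
        pos = 0
        for i, (idx, seq) in enumerate(pieces):
            if i > 0:
                intron = "GT" + _rand_dna(rng, int(rng.integers(80, 151))) + "AG"
                assembled.append(intron)
                pos += len(intron)
            exon_spans.append((idx, pos, pos + len(seq)))
            assembled.append(seq)
            pos += len(seq)
        block = "".join(assembled)
        strand = "+"
        if gene_spec.orientation == "inverted":
            block = revcomp(block)
            exon_spans = [
                (idx, len(block) - e, len(block) - s) for idx, s, e in exon_spans
            ]
            strand = "-"
        offset = self.add(block)
        completeness = (
            "frameshift"
            if gene_spec.frameshift
            else ("complete" if gene_spec.exons_present is None else "partial")
        )
        for idx, s, e in exon_spans:
            self.feature(
                "CH_exon", offset + s, offset + e, strand=strand,
                Name=f"{gene_spec.name}_exon{idx}", gene=gene_spec.name,
                isotype=gene_spec.isotype, completeness=completeness,
            )


def _ch_exon_order(gene_spec: ChGeneSpec):
    n_exons = {"mu": 4, "tau": 4, "delta": 7}[gene_spec.isotype]
    if gene_spec.exons_present is not None:
        return list(gene_spec.exons_present)
    if gene_spec.isotype != "delta":
        return list(range(1, n_exons + 1))
    order: list = [1]
    for copy in range(gene_spec.delta_repeat_count):
        order += [(2, copy), (3, copy), (4, copy)]
    order += [5, 6, 7]
    return order


def _build_ch_sequences(rng, spec: LocusSpec):
    """Founder and per-locus exon sequences for every constant gene."""
    founders = {
        "mu": {i + 1: _rand_codons(rng, n // 3) for i, n in enumerate(_MU_EXON_LENS)},
        "tau": {i + 1: _rand_codons(rng, n // 3) for i, n in enumerate(_TAU_EXON_LENS)},
        "delta": {
            i + 1: _rand_codons(rng, n // 3) for i, n in enumerate(_DELTA_EXON_LENS)
        },
    }
    # locus B mu differs from locus A mu at exactly the diagnostic sites
    mu_chain_a = "".join(founders["mu"][i] for i in range(1, 5))
    sites = []
    taken = set()
    while len(sites) < spec.n_diagnostic_sites:
        off = int(rng.integers(20, 270))
        if any(abs(off - t) < 4 for t in taken):
            continue
        codon_start = off - off % 3
        base_a = mu_chain_a[off]
        for base_b in "ACGT":
            if base_b == base_a:
                continue
            codon = (
                mu_chain_a[codon_start:off] + base_b + mu_chain_a[off + 1 : codon_start + 3]
            )
            if codon not in _STOPS:
                sites.append((off, base_a, base_b))
                taken.add(off)
                break
    sites.sort()

    per_gene: dict[str, dict] = {}

    def tau_variant(rate):
        # wide protected margins keep exon termini exact so homology
        # mapping recovers unambiguous boundaries
        return {
            i: _mutate(rng, founders["tau"][i], int(rate * len(founders["tau"][i])),
                       protect=6, keep_orf=True)
            for i in founders["tau"]
        }

    # functional tau genes: A-4 and A-5 close to each other (~87%), B-2
    # more diverged (~75-80%); non-functional relics anywhere in between
    per_gene["Ctau_A-1"] = tau_variant(0.08)
    per_gene["Ctau_A-2"] = tau_variant(0.08)
    per_gene["Ctau_A-3"] = tau_variant(0.08)
    per_gene["Ctau_A-4"] = tau_variant(0.065)
    per_gene["Ctau_A-5"] = tau_variant(0.065)
    per_gene["Ctau_B-1"] = tau_variant(0.10)
    per_gene["Ctau_B-2"] = tau_variant(0.12)
    per_gene["Ctau_B-3"] = tau_variant(0.10)

    mu_a = dict(founders["mu"])
    mu_b = dict(founders["mu"])
    chain_offsets = {}
    pos = 0
    for i in range(1, 5):
        chain_offsets[i] = pos
        pos += len(mu_a[i])
    for off, _a, base_b in sites:
        for i in range(1, 5):
            start = chain_offsets[i]
            if start <= off < start + len(mu_b[i]):
                rel = off - start
                mu_b[i] = mu_b[i][:rel] + base_b + mu_b[i][rel + 1 :]
                break
    per_gene["Cmu_A"] = mu_a
    per_gene["Cmu_B"] = mu_b

    def delta_exons(locus_rate, repeat_count):
        exons: dict = {}
        for i in founders["delta"]:
            exons[i] = _mutate(
                rng, founders["delta"][i],
                int(locus_rate * len(founders["delta"][i])), protect=6,
                keep_orf=True,
            )
        for copy in range(repeat_count):
            for i in (2, 3, 4):
                if copy == 0:
                    exons[(i, copy)] = exons[i]
                else:
                    exons[(i, copy)] = _mutate(
                        rng, exons[i], max(3, int(0.015 * len(exons[i]))),
                        protect=6, keep_orf=True,
                    )
        return exons

    repeat_a = next(g.delta_repeat_count for g in LOCUS_A_LAYOUT if g.isotype == "delta")
    repeat_b = next(g.delta_repeat_count for g in LOCUS_B_LAYOUT if g.isotype == "delta")
    per_gene["Cdelta_A"] = delta_exons(0.0, repeat_a)
    per_gene["Cdelta_B"] = delta_exons(0.02, repeat_b)

    references = []
    for isotype, exons in founders.items():
        for i, seq in exons.items():
            references.append(SequenceRecord(f"{isotype}_exon{i}", seq))
    return per_gene, sites, references


def _gene_label(gene_name: str) -> str:
    # "Cmu_A" -> "mu_A"; "Ctau_A-4" -> "tau_A4"
    label = gene_name[1:]
    return label.replace("-", "")


def generate_locus_pair(spec: LocusSpec) -> SyntheticLocusPair:
    """Build both loci, the truth feature set and the germline database."""
    rng = np.random.default_rng(spec.seed)
    vh_founders, vh_members = _build_vh_pool(rng, spec)
    ch_seqs, diag_sites, references = _build_ch_sequences(rng, spec)

    db = GermlineDb()
    db.diagnostic_sites["mu"] = diag_sites
    records = {}
    features: list[Feature] = []

    jh_codings_mu_a: list[str] = []

    for locus, layout in (("A", spec.ch_layout_a), ("B", spec.ch_layout_b)):
        asm = _LocusAssembler(rng, spec, f"IGH-{locus}-synthetic")
        asm.intergenic()
        # VH region
        order = [m for m in vh_members if m[0] == locus]
        perm = rng.permutation(len(order))
        for pi in perm:
            locus_tag, fam, idx, status, exon2 = order[int(pi)]
            name = f"VH_{locus}-F{fam:02d}-{idx}"
            asm.vh_cassette(exon2, status, name, fam)
            db.add_vh(VhGene(name, fam, locus, exon2))
            asm.intergenic()
        # constant blocks with their D and JH complements
        for gene_spec in layout:
            label = _gene_label(gene_spec.name)
            for i in range(1, gene_spec.n_d + 1):
                core = _rand_dna(
                    rng, int(rng.integers(spec.d_core_length[0], spec.d_core_length[1] + 1))
                )
                d_name = f"D-{label}-{i}"
                asm.d_segment(core, d_name)
                if gene_spec.functional:
                    db.d[d_name] = DGene(d_name, locus, core)
                asm.intergenic()
            for i in range(1, gene_spec.n_jh + 1):
                if gene_spec.isotype == "mu":
                    if locus == "A":
                        coding = _jh_coding(rng)
                        jh_codings_mu_a.append(coding)
                    else:
                        coding = jh_codings_mu_a[i - 1]
                        if i == 3:
                            # the one mu JH pair that differs between loci
                            coding = coding[:24] + _rand_codons(rng, 1) + coding[27:]
                            while coding == jh_codings_mu_a[2]:
                                coding = coding[:24] + _rand_codons(rng, 1) + coding[27:]
                else:
                    coding = _jh_coding(rng)
                pseudo = gene_spec.jh_pseudogene and i == 1
                if pseudo:
                    # interrupt the conserved motif with a TAG stop (Y codon)
                    coding = coding[:6] + "TAG" + coding[9:]
                jh_name = f"JH-{label}-{i}"
                asm.jh_segment(coding, jh_name, pseudo)
                if gene_spec.functional or gene_spec.isotype == "mu":
                    db.jh[jh_name] = JhGene(jh_name, locus, coding)
                asm.intergenic()
            asm.ch_gene(gene_spec, ch_seqs[gene_spec.name])
            asm.intergenic()
            if gene_spec.functional:
                exons = [
                    (f"exon{k[0] if isinstance(k, tuple) else k}", ch_seqs[gene_spec.name][k])
                    for k in _ch_exon_order(gene_spec)
                ]
                db.ch[gene_spec.name] = ChGene(
                    gene_spec.name, gene_spec.isotype, locus, tuple(exons)
                )
        records[locus] = SequenceRecord(
            asm.seq_id, "".join(asm.parts), f"synthetic locus {locus}"
        )
        features.extend(asm.features)

    return SyntheticLocusPair(
        records=records, features=features, db=db, ch_references=references
    )


def generate_locus(spec: LocusSpec, locus: str = "A"):
    """One locus of the pair: (record, truth features, db, CH references).

    The returned database is restricted to the requested locus.  Generating
    locus A and locus B from the same spec yields the same pair as
    :func:`generate_locus_pair`.
    """
    pair = generate_locus_pair(spec)
    record = pair.records[locus]
    feats = pair.features_for(locus)
    db = GermlineDb()
    db.vh = {k: v for k, v in pair.db.vh.items() if v.locus == locus}
    db.d = {k: v for k, v in pair.db.d.items() if v.locus == locus}
    db.jh = {k: v for k, v in pair.db.jh.items() if v.locus == locus}
    db.ch = {k: v for k, v in pair.db.ch.items() if v.locus == locus}
    db.diagnostic_sites = dict(pair.db.diagnostic_sites)
    return record, feats, db, pair.ch_references


# ---------------------------------------------------------------------------
# repertoire construction
# ---------------------------------------------------------------------------


def _support(db: GermlineDb, gene_name: str):
    """JH and D complements associated with a constant gene (delta shares
    the mu complement of its locus)."""
    gene = db.ch[gene_name]
    label = _gene_label(gene_name if gene.isotype != "delta" else f"Cmu_{gene.locus}")
    jh = sorted(
        (g for g in db.jh.values() if g.id.startswith(f"JH-{label}-")),
        key=lambda g: g.id,
    )
    d = sorted(
        (g for g in db.d.values() if g.id.startswith(f"D-{label}-")),
        key=lambda g: g.id,
    )
    return jh, d


def _jh_weights(spec: RepertoireSpec, n: int) -> np.ndarray:
    if n == 5:
        w = np.array(spec.jh_weights_5, dtype=float)
    elif n == 2:
        w = np.array([0.4, 0.6])
    else:
        w = np.ones(n)
    return w / w.sum()


def _family_weights(spec: RepertoireSpec, gene_name: str, families: list[int]):
    base = {f: 1.0 for f in families}
    for f in (1, 6, 8):
        if f in base:
            base[f] = 4.0
    for gene_names, fam in spec.family_bias:
        if gene_name in gene_names and fam in base:
            base[fam] *= 3.0
    w = np.array([base[f] for f in families], dtype=float)
    return w / w.sum()


def _scan_stops(seq: str, anchor: int, end: int) -> bool:
    for i in range(anchor, end - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return False
    return True


def _plant_microhomology(rng, v_seq: str, chain: str, length: int, a_hi: int):
    """Find (donor d, acceptor a) with a shared repeat of exactly ``length``."""
    for L in range(length, 0, -1):
        ends: dict[str, list[int]] = {}
        for d in range(35 + L, len(v_seq) + 1):
            ends.setdefault(v_seq[d - L : d], []).append(d)
        order = rng.permutation(np.arange(max(1, L), a_hi))
        for a in order:
            a = int(a)
            s = chain[a : a + L]
            for d in ends.get(s, []):
                if d < len(v_seq) and v_seq[d] == chain[a + L]:
                    continue  # repeat would extend on the V side
                if v_seq[d - L - 1] == chain[a - 1]:
                    continue  # repeat would extend on the C side
                if longest_join_overlap(v_seq[:d], chain[a:]) != s:
                    continue
                if chain[a + L : a + 2 * L] == s:
                    continue  # repeat would appear twice across the join
                return d, a, s
    raise RuntimeError("could not plant a microhomology junction")


def generate_repertoire(db: GermlineDb, spec: RepertoireSpec):
    """Simulate reads and their truth table: ``(reads, truth DataFrame)``.

    Read architecture per category (error-free, before optional errors):

    * canonical: trimmed V exon2 + N + trimmed D + N + trimmed JH + spliced
      constant chain from exon 1;
    * chimeric_mu1_delta: V-D-J as above, then the full Cmu exon 1, then
      the delta chain from exon 1;
    * noncanonical_delta: V body cut at a donor point joined directly into
      the delta chain through a planted shared repeat (microhomology);
    * trans_locus: canonical mu read whose V comes from the other locus.
    """
    rng = np.random.default_rng(spec.seed)
    categories = [c for c, _ in spec.category_mixture]
    probs = np.array([w for _, w in spec.category_mixture], dtype=float)

    gene_weights = spec.gene_weights or tuple(
        (g, w) for g, w in _DEFAULT_GENE_WEIGHTS if g in db.ch
    )
    can_genes = [g for g, _ in gene_weights]
    can_probs = np.array([w for _, w in gene_weights], dtype=float)
    can_probs /= can_probs.sum()

    vh_by_locus_family: dict[str, dict[int, list[VhGene]]] = {}
    for gene in db.vh.values():
        vh_by_locus_family.setdefault(gene.locus, {}).setdefault(gene.family, []).append(gene)
    for fams in vh_by_locus_family.values():
        for lst in fams.values():
            lst.sort(key=lambda g: g.id)

    def sample_v(locus: str, gene_name: str) -> VhGene:
        families = sorted(vh_by_locus_family[locus])
        w = _family_weights(spec, gene_name, families)
        fam = int(rng.choice(families, p=w))
        members = vh_by_locus_family[locus][fam]
        return members[int(rng.integers(0, len(members)))]

    n_dup = int(round(spec.n_reads * spec.duplicate_fraction))
    n_unique = spec.n_reads - n_dup
    cats = rng.choice(len(categories), p=probs, size=n_unique)

    sequences: list[str] = []
    rows: list[dict] = []

    for i in range(n_unique):
        category = categories[int(cats[i])]
        row: dict = {"category": category, "duplicate_of": ""}

        if category == "noncanonical_delta":
            locus = "AB"[int(rng.integers(0, 2))]
            delta = db.ch[f"Cdelta_{locus}"]
            chain = delta.cdna
            v = sample_v(locus, f"Cdelta_{locus}")
            a_hi = sum(
                e - s for label, s, e in delta.exon_offsets()[:3]
            )  # acceptors within the first three delta exons
            length = min(
                spec.microhomology_max, int(rng.geometric(spec.microhomology_geometric_p))
            )
            d_pos, a_pos, repeat = _plant_microhomology(rng, v.exon2, chain, length, a_hi)
            plen = int(rng.integers(*spec.c_portion_length))
            seq = v.exon2[:d_pos] + chain[a_pos + len(repeat) : a_pos + len(repeat) + plen]
            anchor = 0
            c_read_start = d_pos - len(repeat)
            productive = (
                (c_read_start - anchor - a_pos) % 3 == 0
                and _scan_stops(seq, anchor, len(seq))
            )
            row.update(
                v_call=v.id, v_locus=v.locus, d_call="", j_call="",
                c_call=delta.name, c_locus=locus,
                v_breakpoint=d_pos, c_breakpoint=delta.position_label(a_pos),
                c_germ_start=a_pos,
                microhomology=repeat, microhomology_length=len(repeat),
                productive=productive,
            )
            sequences.append(seq)
            rows.append(row)
            continue

        if category == "trans_locus":
            v_locus = "AB"[int(rng.integers(0, 2))]
            c_locus = "B" if v_locus == "A" else "A"
            gene = db.ch[f"Cmu_{c_locus}"]
        elif category == "chimeric_mu1_delta":
            locus = "AB"[int(rng.integers(0, 2))]
            gene = db.ch[f"Cdelta_{locus}"]
            v_locus = c_locus = locus
        else:
            gene = db.ch[str(rng.choice(can_genes, p=can_probs))]
            v_locus = c_locus = gene.locus

        jh_pool, d_pool = _support(db, gene.name)
        v = sample_v(v_locus, gene.name)
        jh = jh_pool[int(rng.choice(len(jh_pool), p=_jh_weights(spec, len(jh_pool))))]
        d = d_pool[int(rng.integers(0, len(d_pool)))]

        v_trim = int(rng.integers(0, spec.v_trim_max + 1))
        d_left = int(rng.integers(0, spec.d_trim_max + 1))
        d_right = int(rng.integers(0, spec.d_trim_max + 1))
        j_trim = int(rng.integers(0, spec.j_trim_max + 1))
        n1 = _rand_dna(rng, int(rng.integers(0, spec.n_insertion_max + 1)))
        n2 = _rand_dna(rng, int(rng.integers(0, spec.n_insertion_max + 1)))

        v_part = v.exon2[: len(v.exon2) - v_trim]
        d_part = d.core[d_left : len(d.core) - d_right]
        j_part = jh.coding[j_trim:]

        if category == "chimeric_mu1_delta":
            mu1 = db.ch[f"Cmu_{c_locus}"].exons[0][1]
            prefix = v_part + n1 + d_part + n2 + j_part + mu1
        else:
            prefix = v_part + n1 + d_part + n2 + j_part

        chain = gene.cdna
        plen = int(rng.integers(*spec.c_portion_length))
        plen = min(plen, len(chain))
        seq = prefix + chain[:plen]

        c_read_start = len(prefix)
        productive = (c_read_start % 3 == 0) and _scan_stops(seq, 0, len(seq))
        row.update(
            v_call=v.id, v_locus=v.locus, d_call=d.id if len(d_part) > 0 else "",
            j_call=jh.id, c_call=gene.name, c_locus=c_locus,
            v_breakpoint=len(v_part),
            c_breakpoint=gene.position_label(0), c_germ_start=0,
            microhomology="", microhomology_length=0,
            productive=productive,
        )
        row["d_core_remaining"] = len(d_part)
        sequences.append(seq)
        rows.append(row)

    # duplicates: copies of earlier reads under new ids
    source = rng.integers(0, n_unique, size=n_dup) if n_unique else []
    for src in source:
        src = int(src)
        row = dict(rows[src])
        row["duplicate_of"] = f"read_{src + 1:06d}"
        rows.append(row)
        sequences.append(sequences[src])

    reads = [
        SequenceRecord(f"read_{i + 1:06d}", seq)
        for i, seq in enumerate(sequences)
    ]
    for i, row in enumerate(rows):
        row["read_id"] = f"read_{i + 1:06d}"

    if spec.error_rate > 0:
        reads = inject_errors(reads, spec.error_rate, int(rng.integers(0, 2**31)))

    base_cols = [
        "read_id", "category", "v_call", "v_locus", "d_call", "j_call",
        "c_call", "c_locus", "v_breakpoint", "c_breakpoint", "c_germ_start",
        "microhomology", "microhomology_length", "productive",
        "duplicate_of",
    ]
    truth = pd.DataFrame(rows, columns=None if rows else base_cols)
    cols = ["read_id"] + [c for c in truth.columns if c != "read_id"]
    return reads, truth[cols]


def inject_errors(reads: list[SequenceRecord], rate: float, seed: int):
    """Per-base substitution errors with a uniform alternative base."""
    if not 0 <= rate <= 1:
        raise ValueError("error rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        arr = np.frombuffer(read.residues.encode(), dtype=np.uint8).copy()
        hit = rng.random(arr.size) < rate
        if hit.any():
            shifts = rng.integers(1, 4, size=int(hit.sum()))
            idx = np.flatnonzero(hit)
            lookup = {65: 0, 67: 1, 71: 2, 84: 3}
            for k, pos in enumerate(idx):
                code = int(arr[pos])
                base_idx = lookup.get(code)
                if base_idx is None:
                    continue
                arr[pos] = _BASES[(base_idx + int(shifts[k])) % 4]
        out.append(SequenceRecord(read.id, arr.tobytes().decode(), read.description))
    return out
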