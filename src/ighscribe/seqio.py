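"""Sequence and annotation I/O with fixed coordinate conventions.

All coordinates inside the package are 0-based half-open on the forward
strand.  GFF3 output converts to the standard 1-based inclusive columns.
FASTA and GenBank parsing is delegated to Biopython; this module wraps the
results in lightweight records so the rest of the pipeline does not depend
on Biopython objects.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SequenceRecord",
    "Feature",
    "FEATURE_KINDS",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_gff3",
    "read_gff3",
]

#: feature vocabulary used in GFF3 output (column 3)
FEATURE_KINDS = frozenset(
    {
        "VH_exon1",
        "VH_exon2",
        "D_segment",
        "JH_segment",
        "CH_exon",
        "RSS",
        "octamer",
        "splice_site",
    }
)


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA or protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Feature:
    """A located annotation on a sequence (0-based half-open coordinates)."""

    seq_id: str
    kind: str
    start: int
    end: int
    strand: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.kind}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_fasta(path, return_mask: bool = False):
    """Read a multi-FASTA file; residues are uppercased.

    Lowercase (soft-masked) residues are uppercased so motif scanning sees
    every base; with ``return_mask=True`` a second value maps each id to
    the 0-based half-open intervals that were lowercase in the input.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    an empty file or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    masks: dict[str, list] = {}
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        raw = str(rec.seq)
        records.append(SequenceRecord(rec.id, raw.upper(), desc))
        if return_mask:
            runs = []
            start = None
            for i, c in enumerate(raw):
                if c.islower():
                    if start is None:
                        start = i
                elif start is not None:
                    runs.append((start, i))
                    start = None
            if start is not None:
                runs.append((start, len(raw)))
            masks[rec.id] = runs
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return (records, masks) if return_mask else records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA.  Byte output is deterministic."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


#: default mapping from GenBank feature keys to this package's feature
#: vocabulary, used only when existing annotation is imported for
#: benchmarking (deposited records vary; pass a custom map as needed)
DEFAULT_GENBANK_KEY_MAP = {
    "V_segment": "VH_exon2",
    "D_segment": "D_segment",
    "J_segment": "JH_segment",
    "C_region": "CH_exon",
    "CDS": "CH_exon",
}


def read_genbank(path, import_features: bool = False, key_map=None):
    """Read sequence(s) from a GenBank flat file.

    By default only the accession and the sequence are consumed — existing
    feature tables are ignored because annotation is recomputed de novo.
    With ``import_features=True`` the deposited feature table is converted
    through ``key_map`` (GenBank key -> feature vocabulary) and returned as
    a second value, for benchmarking against this package's output.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    key_map = DEFAULT_GENBANK_KEY_MAP if key_map is None else key_map
    records: list[SequenceRecord] = []
    features: list[Feature] = []
    for rec in _BioSeqIO.parse(str(path), "genbank"):
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), rec.description or "")
        )
        if import_features:
            for feat in rec.features:
                kind = key_map.get(feat.type)
                if kind is None:
                    continue
                features.append(
                    Feature(
                        seq_id=rec.id,
                        kind=kind,
                        start=int(feat.location.start),
                        end=int(feat.location.end),
                        strand="-" if feat.location.strand == -1 else "+",
                        attributes={
                            k: ";".join(v)
                            for k, v in feat.qualifiers.items()
                        },
                    )
                )
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    return (records, features) if import_features else records


# GFF3 reserved characters that must be percent-encoded in column 9
_GFF3_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in ';=&,%"'
)


def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe=_GFF3_SAFE + " ")


def write_gff3(features: Iterable[Feature], path, source: str = "ighscribe") -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    features = list(features)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(
                f"{_gff3_escape(k)}={_gff3_escape(v)}"
                for k, v in sorted(feat.attributes.items())
            )
            fh.write(
                "\t".join(
                    [
                        feat.seq_id,
                        source,
                        feat.kind,
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    """Read a GFF3 file written by :func:`write_gff3` back into features."""
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, _src, kind, start1, end1, _score, strand, _phase, attrs = cols
            attributes = {}
            if attrs != ".":
                for pair in attrs.split(";"):
                    key, _, value = pair.partition("=")
                    attributes[urllib.parse.unquote(key)] = urllib.parse.unquote(value)
            features.append(
                Feature(
                    seq_id=seq_id,
                    kind=kind,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    attributes=attributes,
                )
            )
    return features
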