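"""Sequence and annotation IO shared by every pipeline stage.

Internal convention: all coordinates are 0-based half-open on the forward
strand.  GFF3's 1-based inclusive coordinates exist only at file boundaries.
FASTA parsing/writing goes through Biopython; GFF3 is read and written as the
9-column TSV it is, with introns synthesised from exon gaps on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("tedyn")

VALID_BASES = set("ACGTN")

FEATURE_KINDS = {
    "gene",
    "exon",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "repeat_region",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP)[::-1]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named chromosome/scaffold sequence, uppercase over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("empty record name")
        if not self.sequence:
            raise ValueError(f"record {self.name!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureInterval:
    """A located annotation feature, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_sequence(name: str, raw: str) -> str:
    seq = raw.upper()
    n_bad = sum(1 for c in set(seq) if c not in VALID_BASES)
    if n_bad:
        bad = {c for c in set(seq) if c not in VALID_BASES}
        table = str.maketrans({c: "N" for c in bad})
        seq = seq.translate(table)
        log.warning("record %s: %d non-ACGTN symbol kinds mapped to N", name, n_bad)
    if raw != raw.upper():
        log.info("record %s: lowercase bases uppercased", name)
    return seq


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (uppercased, non-ACGTN -> N)."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: sequence before any header")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_sequence(rec.id, str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        # distinguish empty/malformed from absent
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip() and not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: sequence before any header")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    ]
    writer_path = str(path)
    with open(writer_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def _format_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def synthesize_introns(features: Sequence[FeatureInterval]) -> list[FeatureInterval]:
    """Derive intron intervals from the gaps between exons sharing a Parent."""
    by_parent: dict[tuple, list[FeatureInterval]] = {}
    for f in features:
        if f.kind == "exon":
            parent = f.attributes.get("Parent", f.attributes.get("ID", ""))
            by_parent.setdefault((f.chrom, f.strand, parent), []).append(f)
    introns = []
    for (chrom, strand, parent), exons in by_parent.items():
        exons = sorted(exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                introns.append(
                    FeatureInterval(
                        chrom, a.end, b.start, strand, "intron",
                        {"Parent": parent} if parent else {},
                    )
                )
    return introns


def read_gff3(path: str | Path, add_introns: bool = True) -> list[FeatureInterval]:
    """Read GFF3, converting to 0-based half-open; optionally add introns."""
    features: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, kind, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start")
            features.append(
                FeatureInterval(
                    chrom, start1 - 1, end1,
                    strand if strand in "+-" else ".",
                    kind, _parse_attributes(attr_s),
                )
            )
    if add_introns:
        features.extend(synthesize_introns(features))
    return features


def write_gff3(
    features: Iterable[FeatureInterval], path: str | Path, source: str = "tedyn"
) -> None:
    """Write features as GFF3 (1-based inclusive); introns are not re-emitted."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.kind == "intron":
                continue  # derived on read; keeps round-trip involutive
            fh.write(
                "\t".join(
                    [
                        f.chrom, source, f.kind,
                        str(f.start + 1), str(f.end),
                        ".", f.strand, ".",
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


__all__ = [
    "GenomeRecord",
    "FeatureInterval",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "synthesize_introns",
    "revcomp",
    "replace",
]
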