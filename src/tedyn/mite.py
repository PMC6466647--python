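"""Structural MITE detection, classification, clustering and annotation.

A MITE is validated structurally: terminal inverted repeat (10-30 bp,
at most one mismatch between the two termini), an exact target-site
duplication whose length is diagnostic of the superfamily (TTA/TAA for
PIF-Harbinger, 8 bp for hAT, 9-10 bp for Mutator), and total length at most
800 bp.  Families are greedy centroid clusters at 80% global-alignment
identity; genome-wide copies are annotated by seed-and-extend homology
against family representatives, with a copy called full-length when the hit
covers more than 90% of its representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import KmerIndex, global_identity, resolve_overlaps, scan_homology, encode
from .seqio import FeatureInterval, GenomeRecord, revcomp

MAX_MITE_LENGTH = 800
TIR_RANGE = (10, 30)
TIR_MAX_MISMATCH = 1
ALL_TSD_LENGTHS = (3, 8, 9, 10)

SUPERFAMILY_TSD = {
    "PIF-Harbinger": (3,),
    "hAT": (8,),
    "Mutator": (9, 10),
}


@dataclass
class MiteElement:
    """A located MITE copy with its structural evidence."""

    location: FeatureInterval
    sequence: str
    tir_length: int | None = None
    tir_mismatches: int | None = None
    tsd: str | None = None
    superfamily: str = "unknown"
    family_id: str = ""
    full_length: bool = False
    identity_to_representative: float = 0.0


@dataclass
class MiteFamily:
    family_id: str
    superfamily: str
    representative: str
    members: list[MiteElement] = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# structural detectors
# ---------------------------------------------------------------------------

def detect_tir(sequence: str) -> tuple[int, int] | None:
    """Longest terminal inverted repeat of length 10-30 with <= 1 mismatch.

    Returns (tir_length, mismatches) or None.  The 5' terminus is compared
    to the reverse complement of the 3' terminus.
    """
    n = len(sequence)
    if n < 30:
        return None
    lo, hi = TIR_RANGE
    hi = min(hi, n // 2)
    head = encode(sequence[:hi])
    tail = encode(revcomp(sequence[-hi:]))
    best = None
    for L in range(lo, hi + 1):
        mism = int(np.count_nonzero(head[:L] != tail[:L]))
        if mism <= TIR_MAX_MISMATCH:
            best = (L, mism)
    return best


def detect_tsd(
    left_flank: str, right_flank: str, allowed_lengths=ALL_TSD_LENGTHS
) -> str | None:
    """Longest exact direct repeat (left suffix == right prefix) whose length
    is in ``allowed_lengths``.  Exact match is mandatory."""
    if len(left_flank) < 10 or len(right_flank) < 10:
        return None
    for L in sorted(allowed_lengths, reverse=True):
        if L > len(left_flank) or L > len(right_flank):
            continue
        if left_flank[-L:] == right_flank[:L]:
            return left_flank[-L:]
    return None


def classify_superfamily(tsd: str | None) -> str:
    """Superfamily from the TSD: TTA/TAA -> PIF-Harbinger, 8 bp -> hAT,
    9-10 bp -> Mutator, anything else -> unknown."""
    if tsd is None:
        return "unknown"
    if tsd in ("TTA", "TAA"):
        return "PIF-Harbinger"
    if len(tsd) == 8:
        return "hAT"
    if len(tsd) in (9, 10):
        return "Mutator"
    return "unknown"


@dataclass
class Rejection:
    reason: str  # no_tir | no_tsd | too_long


def validate_mite(
    sequence: str,
    left_flank: str,
    right_flank: str,
    location: FeatureInterval | None = None,
) -> MiteElement | Rejection:
    """Structural validation of a candidate: TIR, TSD and the 800 bp cap."""
    if len(sequence) > MAX_MITE_LENGTH:
        return Rejection("too_long")
    tir = detect_tir(sequence)
    if tir is None:
        return Rejection("no_tir")
    tsd = detect_tsd(left_flank, right_flank)
    superfamily = classify_superfamily(tsd)
    if tsd is None or superfamily == "unknown":
        return Rejection("no_tsd")
    if location is None:
        location = FeatureInterval("?", 0, len(sequence), ".", "repeat_region")
    return MiteElement(
        location=location,
        sequence=sequence,
        tir_length=tir[0],
        tir_mismatches=tir[1],
        tsd=tsd,
        superfamily=superfamily,
    )


# ---------------------------------------------------------------------------
# family clustering
# ---------------------------------------------------------------------------

_FAMILY_PREFIX = {"Mutator": "DTM", "hAT": "DTA", "PIF-Harbinger": "DTH", "unknown": "DTX"}


def cluster_families(
    elements: list[MiteElement], identity_threshold: float = 0.80
) -> list[MiteFamily]:
    """Greedy centroid clustering of validated elements.

    Elements are processed by descending length (ties broken
    lexicographically by sequence); each joins the first existing centroid
    at >= threshold global-alignment identity (inclusive), else founds a new
    family.  Family ids carry the superfamily prefix (DTA/DTM/DTH) and an
    ordinal assigned by descending family size.
    """
    ordered = sorted(elements, key=lambda e: (-len(e.sequence), e.sequence))
    families: list[MiteFamily] = []
    for elem in ordered:
        joined = False
        for fam in families:
            if global_identity(elem.sequence, fam.representative) >= identity_threshold:
                fam.members.append(elem)
                joined = True
                break
        if not joined:
            families.append(
                MiteFamily("", elem.superfamily, elem.sequence, [elem])
            )
    # ordinals by descending size within each superfamily prefix
    counters: dict[str, int] = {}
    for fam in sorted(families, key=lambda f: (-f.copy_number, f.representative)):
        prefix = _FAMILY_PREFIX.get(fam.superfamily, "DTX")
        counters[prefix] = counters.get(prefix, 0) + 1
        fam.family_id = f"{prefix}{counters[prefix]}"
        for m in fam.members:
            m.family_id = fam.family_id
            m.identity_to_representative = global_identity(
                m.sequence, fam.representative
            )
    return sorted(families, key=lambda f: f.family_id)


# ---------------------------------------------------------------------------
# genome-wide annotation
# ---------------------------------------------------------------------------

def annotate_copies(
    genome: list[GenomeRecord],
    families: list[MiteFamily],
    min_identity: float = 0.80,
    full_length_coverage: float = 0.90,
    snap_bp: int = 5,
) -> list[MiteElement]:
    """Annotate family copies genome-wide by seed-and-extend homology.

    Non-overlapping hits at >= ``min_identity``; a hit is full-length when it
    covers more than ``full_length_coverage`` of its representative.  Both
    strands are scanned; minus-strand hits are stored in plus coordinates
    with a strand flag.  Hit boundaries are snapped outward to the
    representative's TIR ends when the extension stops within ``snap_bp`` of
    them.  No reported element exceeds 800 bp.
    """
    out: list[MiteElement] = []
    for record in genome:
        index = KmerIndex(record.sequence, 12)
        n = len(record.sequence)
        tagged = []
        for fam in families:
            rep_len = len(fam.representative)
            for hit in scan_homology(
                record.sequence,
                fam.representative,
                k=12,
                min_identity=min_identity,
                min_length=max(30, int(rep_len * 0.3)),
                index=index,
            ):
                start, end = hit.start, hit.end
                q_start, q_end = hit.q_start, hit.q_end
                # snap outward to the representative termini
                if 0 < q_start <= snap_bp:
                    shift = q_start if hit.strand == "+" else 0
                    shift_r = q_start if hit.strand == "-" else 0
                    start = max(0, start - shift)
                    end = min(n, end + shift_r)
                    q_start = 0
                if 0 < rep_len - q_end <= snap_bp:
                    tail = rep_len - q_end
                    if hit.strand == "+":
                        end = min(n, end + tail)
                    else:
                        start = max(0, start - tail)
                    q_end = rep_len
                if end - start > MAX_MITE_LENGTH:
                    continue
                coverage = (q_end - q_start) / rep_len
                tagged.append((hit, fam, start, end, coverage))
        resolved = resolve_overlaps(
            [
                _AnnotatedHit(start, end, hit.identity, hit.matches, hit.strand, fam, cov)
                for hit, fam, start, end, cov in tagged
            ]
        )
        for h in resolved:
            seq = record.sequence[h.start : h.end]
            left = record.sequence[max(0, h.start - 20) : h.start]
            right = record.sequence[h.end : h.end + 20]
            tsd = detect_tsd(left, right) if len(left) >= 10 and len(right) >= 10 else None
            tir = detect_tir(seq)
            out.append(
                MiteElement(
                    location=FeatureInterval(
                        record.name, h.start, h.end, h.strand, "repeat_region",
                        {"family": h.family.family_id},
                    ),
                    sequence=seq,
                    tir_length=tir[0] if tir else None,
                    tir_mismatches=tir[1] if tir else None,
                    tsd=tsd,
                    superfamily=h.family.superfamily,
                    family_id=h.family.family_id,
                    full_length=h.coverage > full_length_coverage,
                    identity_to_representative=h.identity,
                )
            )
    return out


@dataclass(frozen=True)
class _AnnotatedHit:
    start: int
    end: int
    identity: float
    matches: int
    strand: str
    family: "MiteFamily"
    coverage: float


# ---------------------------------------------------------------------------
# conserved-terminal scan for autonomous-partner candidates
# ---------------------------------------------------------------------------

TERMINAL_5 = "GGACTTG"
TERMINAL_3 = "CAGGTCC"


@dataclass(frozen=True)
class TerminalHit:
    start: int
    end: int
    strand: str
    tsd: str


def _motif_positions(enc: np.ndarray, motif: str, max_mismatch: int = 1) -> np.ndarray:
    m = encode(motif)
    if len(enc) < len(m):
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, len(m))
    mism = (windows != m).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch)


def scan_conserved_terminals(
    region: str,
    min_length: int = 100,
    max_length: int = 20_000,
    tsd_lengths=(9, 10),
) -> list[TerminalHit]:
    """Scan a candidate region for Mutator-like autonomous element structure:
    a sub-interval starting GGACTTG and ending CAGGTCC (each with at most
    one mismatch) flanked by an exact 9-10 bp TSD.  Both strands."""
    hits = []
    n = len(region)
    for strand, seq in (("+", region), ("-", revcomp(region))):
        enc = encode(seq)
        starts = _motif_positions(enc, TERMINAL_5)
        ends = _motif_positions(enc, TERMINAL_3)
        for s in starts:
            for e0 in ends:
                e = int(e0) + len(TERMINAL_3)
                length = e - int(s)
                if length < min_length or length > max_length:
                    continue
                left = seq[max(0, s - 12) : s]
                right = seq[e : e + 12]
                tsd = detect_tsd(left, right, tsd_lengths) if len(left) >= 10 else None
                if tsd is None:
                    continue
                if strand == "+":
                    hits.append(TerminalHit(int(s), e, "+", tsd))
                else:
                    hits.append(TerminalHit(n - e, n - int(s), "-", tsd))
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def family_summary(
    annotated: dict[str, list[MiteElement]], genome_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-genome copy counts and genome content, mirroring a comparative
    copy-number table (copy number, full-length copies, Mb, content %)."""
    rows = []
    for genome_id, elements in annotated.items():
        total_bp = sum(len(e.sequence) for e in elements)
        glen = genome_lengths[genome_id]
        rows.append(
            {
                "genome": genome_id,
                "copy_number": len(elements),
                "full_length_copy_number": sum(e.full_length for e in elements),
                "length_mb": total_bp / 1e6,
                "content_pct": 100.0 * total_bp / glen,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "MiteElement",
    "MiteFamily",
    "Rejection",
    "TerminalHit",
    "detect_tir",
    "detect_tsd",
    "classify_superfamily",
    "validate_mite",
    "cluster_families",
    "annotate_copies",
    "scan_conserved_terminals",
    "family_summary",
    "MAX_MITE_LENGTH",
]
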