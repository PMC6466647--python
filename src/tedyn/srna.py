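"""Small-RNA tag mapping to MITE sequences and the MITE-derived fraction.

Tags are unique collapsed sequences with counts.  Mapping is full-length,
ungapped, at most one mismatch, both strands (the same matcher serves the
genome denominator, for determinism).  A tag is MITE-derived iff it has at
least one qualifying alignment to a selected representative copy; the
reported fraction is tag-level over genome-mapped tags, with a
count-weighted variant behind a flag.  Each qualifying alignment contributes
its midpoint/target-length relative position to a 100-bin histogram,
weighted by the tag count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import KmerIndex, encode
from .seqio import GenomeRecord, revcomp

SEED_K = 9
MAX_MISMATCH = 1


@dataclass(frozen=True)
class SrnaTag:
    sequence: str
    count: int = 1

    def __post_init__(self):
        if not (18 <= len(self.sequence) <= 30):
            raise ValueError(f"tag length {len(self.sequence)} outside 18-30 nt")
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass(frozen=True)
class TagAlignment:
    target: str
    position: int  # 0-based target offset of the tag start
    strand: str
    mismatches: int


@dataclass
class SrnaReport:
    total_tags: int
    genome_mapped_tags: int
    mite_mapped_tags: int
    mite_fraction: float  # percent of genome-mapped tags
    length_histogram: dict[int, int] = field(default_factory=dict)
    position_histogram: np.ndarray = field(default_factory=lambda: np.zeros(100))


def read_tags_tsv(path) -> list[SrnaTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("sequence"):
            fh.seek(0)
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            tags.append(SrnaTag(parts[0], int(parts[1]) if len(parts) > 1 else 1))
    return tags


def select_representative_copies(members: list[str], seed: str) -> list[str]:
    """Members whose length differs from the family seed length by strictly
    less than 1% of the seed length (guards positional statistics against
    truncated copies)."""
    limit = 0.01 * len(seed)
    return [m for m in members if abs(len(m) - len(seed)) < limit]


class TagMapper:
    """Full-length ungapped <=1-mismatch matcher over a set of targets.

    Targets are concatenated with N spacers and indexed with exact 9-mers;
    by pigeonhole, a tag with at most one mismatch matches one of two
    disjoint seed segments exactly, so looking up the 9-mer at offset 0 and
    at offset len//2 covers all placements.
    """

    def __init__(self, targets: dict[str, str]):
        self.names = list(targets)
        spacer = "N" * 32
        offsets = {}
        parts = []
        pos = 0
        for name in self.names:
            offsets[name] = pos
            parts.append(targets[name])
            pos += len(targets[name]) + len(spacer)
            parts.append(spacer)
        self.concat = "".join(parts)
        self.enc = encode(self.concat)
        self.index = KmerIndex(self.concat, SEED_K)
        self.offsets = offsets
        self.bounds = sorted((v, k) for k, v in offsets.items())
        self.lengths = {k: len(v) for k, v in targets.items()}

    def _locate(self, concat_pos: int) -> tuple[str, int] | None:
        starts = [b[0] for b in self.bounds]
        i = int(np.searchsorted(starts, concat_pos, side="right")) - 1
        if i < 0:
            return None
        start, name = self.bounds[i]
        off = concat_pos - start
        if off + 1 > self.lengths[name]:
            return None
        return name, off

    def map_tag(self, sequence: str, max_mismatch: int = MAX_MISMATCH) -> list[TagAlignment]:
        out = []
        L = len(sequence)
        seen: set[tuple[int, str]] = set()
        for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
            tag_enc = encode(seq)
            candidates: set[int] = set()
            for off in (0, L // 2):
                seed = seq[off : off + SEED_K]
                if len(seed) < SEED_K:
                    continue
                for p in self.index.positions(seed):
                    candidates.add(int(p) - off)
            for start in sorted(candidates):
                if start < 0 or start + L > len(self.enc):
                    continue
                window = self.enc[start : start + L]
                mism = int(np.count_nonzero((window != tag_enc) | (window >= 4)))
                if mism > max_mismatch:
                    continue
                key = (start, strand)
                if key in seen:
                    continue
                seen.add(key)
                loc = self._locate(start)
                if loc is None:
                    continue
                name, off = loc
                if off + L > self.lengths[name]:
                    continue
                out.append(TagAlignment(name, off, strand, mism))
        return out


def map_tags(
    tags: list[SrnaTag], targets: dict[str, str], max_mismatch: int = MAX_MISMATCH
) -> dict[str, list[TagAlignment]]:
    """All qualifying alignments per tag sequence."""
    mapper = TagMapper(targets)
    return {t.sequence: mapper.map_tag(t.sequence, max_mismatch) for t in tags}


def summarize(
    tags: list[SrnaTag],
    genome: list[GenomeRecord],
    mite_targets: dict[str, str],
    count_weighted_fraction: bool = False,
) -> SrnaReport:
    """Map tags to the genome (denominator) and to MITE targets (numerator);
    compute the MITE-derived fraction, the length distribution of
    MITE-derived tags and the 100-bin relative-position histogram."""
    genome_mapper = TagMapper({g.name: g.sequence for g in genome})
    mite_mapper = TagMapper(mite_targets) if mite_targets else None
    genome_mapped = 0
    mite_mapped = 0
    genome_mapped_w = 0
    mite_mapped_w = 0
    length_hist: dict[int, int] = {}
    pos_hist = np.zeros(100)
    for tag in tags:
        g_hits = genome_mapper.map_tag(tag.sequence)
        if not g_hits:
            continue
        genome_mapped += 1
        genome_mapped_w += tag.count
        m_hits = mite_mapper.map_tag(tag.sequence) if mite_mapper else []
        if not m_hits:
            continue
        mite_mapped += 1
        mite_mapped_w += tag.count
        L = len(tag.sequence)
        length_hist[L] = length_hist.get(L, 0) + tag.count
        for hit in m_hits:
            target_len = len(mite_targets[hit.target])
            rel = (hit.position + L / 2) / target_len
            b = min(int(rel * 100), 99)
            pos_hist[b] += tag.count
    if genome_mapped == 0:
        raise ValueError("no tags map to the genome; MITE fraction undefined")
    if count_weighted_fraction:
        fraction = 100.0 * mite_mapped_w / genome_mapped_w
    else:
        fraction = 100.0 * mite_mapped / genome_mapped
    return SrnaReport(
        total_tags=len(tags),
        genome_mapped_tags=genome_mapped,
        mite_mapped_tags=mite_mapped,
        mite_fraction=fraction,
        length_histogram=length_hist,
        position_histogram=pos_hist,
    )


def mite_fraction_from_counts(mite_mapped: int, genome_mapped: int) -> float:
    """Percent of genome-mapped tags that are MITE-derived."""
    if genome_mapped <= 0:
        raise ValueError("genome_mapped must be positive")
    return 100.0 * mite_mapped / genome_mapped


__all__ = [
    "SrnaTag",
    "TagAlignment",
    "SrnaReport",
    "TagMapper",
    "read_tags_tsv",
    "select_representative_copies",
    "map_tags",
    "summarize",
    "mite_fraction_from_counts",
]
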