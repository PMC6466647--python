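"""Presence/absence (P/A) polymorphism calling of MITE loci between genomes.

For every full-length element in one genome, the 1 kb flanks (taken
immediately adjacent to the element, so the TSD copy stays in the flank and
the empty allele still anchors) are mapped to the partner genome.  A locus
is allelic when both flanks map uniquely to the same chromosome and strand
with their inner ends less than 1 kb apart, and the mapping is reciprocal.
The insertion is present in both genomes when a copy of the same family
overlaps the inter-flank interval, otherwise absent in the target.

BLAST's e-value stringency is operationalised deterministically as
(aligned length >= 100, identity >= 0.90, unique best hit); ambiguous or
truncated loci are unresolved and excluded from the polymorphic ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from ._align import KmerIndex, scan_homology
from .mite import MiteElement
from .seqio import GenomeRecord

FLANK = 1000
MIN_ANCHOR_LENGTH = 100
MIN_ANCHOR_IDENTITY = 0.90
MAX_ALLELIC_DISTANCE = 1000


@dataclass(frozen=True)
class FlankPair:
    left: str
    right: str
    left_truncated: bool
    right_truncated: bool


@dataclass(frozen=True)
class PartnerAnchor:
    chrom: str
    strand: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]

    @property
    def inner_interval(self) -> tuple[int, int]:
        """The between-flank interval in partner coordinates."""
        if self.strand == "+":
            return self.left_span[1], self.right_span[0]
        return self.right_span[1], self.left_span[0]

    @property
    def inner_distance(self) -> int:
        a, b = self.inner_interval
        return b - a


@dataclass
class PaLocus:
    element_id: str
    family_id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    anchor: PartnerAnchor | None
    allelic: bool
    status: str  # present_both | absent_in_partner | absent_in_reference | unresolved


@dataclass(frozen=True)
class PaSummary:
    partner_id: str
    absent_in_reference: int
    absent_in_partner: int
    commonly_present: int

    @property
    def common_loci(self) -> int:
        return self.absent_in_reference + self.absent_in_partner + self.commonly_present

    @property
    def polymorphic_ratio(self) -> float:
        """Percent of common loci that are polymorphic."""
        if self.common_loci == 0:
            return 0.0
        return 100.0 * (self.absent_in_reference + self.absent_in_partner) / self.common_loci


def extract_flanks(
    element: MiteElement, genome: dict[str, str], flank: int = FLANK
) -> FlankPair:
    """1 kb flanks immediately adjacent to the element boundary (TSD
    included in the flank); truncation at chromosome ends is flagged."""
    seq = genome[element.location.chrom]
    start, end = element.location.start, element.location.end
    left = seq[max(0, start - flank) : start]
    right = seq[end : end + flank]
    return FlankPair(left, right, len(left) < flank, len(right) < flank)


class _GenomeMapper:
    """Unique-best-hit mapper of flank sequences onto one genome."""

    def __init__(self, genome: list[GenomeRecord], k: int = 31):
        self.records = genome
        self.k = k
        self.indexes = {g.name: KmerIndex(g.sequence, k) for g in genome}

    def best_hit(self, query: str):
        """Unique best-scoring qualifying hit as
        (chrom, start, end, strand, matches) or None (absent or ambiguous)."""
        if len(query) < MIN_ANCHOR_LENGTH:
            return None
        candidates = []
        for rec in self.records:
            for h in scan_homology(
                rec.sequence,
                query,
                k=self.k,
                min_identity=MIN_ANCHOR_IDENTITY,
                min_length=MIN_ANCHOR_LENGTH,
                index=self.indexes[rec.name],
            ):
                candidates.append((h.matches, rec.name, h))
        if not candidates:
            return None
        candidates.sort(key=lambda c: (-c[0], c[1], c[2].start))
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            return None  # ambiguous: multiple equal best hits
        _, chrom, h = candidates[0]
        return chrom, h.start, h.end, h.strand, h.matches


def anchor_flanks(
    flanks: FlankPair,
    target_mapper: _GenomeMapper,
    target_genome: dict[str, str],
    back_mapper: "_GenomeMapper | None" = None,
    ref_span: tuple[str, int, int] | None = None,
) -> PartnerAnchor | None:
    """Anchor a flank pair on the target genome.

    Both flanks must map uniquely to the same chromosome and strand with
    inner ends < 1 kb apart.  When ``back_mapper`` is given, reciprocality
    is enforced by mapping the anchored target sequence back and requiring
    it to land on the originating locus (``ref_span``)."""
    if flanks.left_truncated or flanks.right_truncated:
        return None
    left_hit = target_mapper.best_hit(flanks.left)
    right_hit = target_mapper.best_hit(flanks.right)
    if left_hit is None or right_hit is None:
        return None
    lc, ls, le, lstrand, _ = left_hit
    rc, rs, re, rstrand, _ = right_hit
    if lc != rc or lstrand != rstrand:
        return None
    anchor = PartnerAnchor(lc, lstrand, (ls, le), (rs, re))
    a, b = anchor.inner_interval
    if not (-50 <= anchor.inner_distance < MAX_ALLELIC_DISTANCE):
        return None
    if back_mapper is not None and ref_span is not None:
        tseq = target_genome[anchor.chrom]
        back = back_mapper.best_hit(tseq[ls:le])
        ref_chrom, ref_start, ref_end = ref_span
        if back is None:
            return None
        bchrom, bs, be, _, _ = back
        window = (ref_start - 2 * FLANK, ref_end + 2 * FLANK)
        if bchrom != ref_chrom or be <= window[0] or bs >= window[1]:
            return None
    return anchor


def call_presence(
    anchor: PartnerAnchor,
    family_id: str,
    partner_annotation: dict[str, IntervalTree],
) -> str:
    """present_both iff an annotated copy of the same family overlaps the
    inter-flank interval; otherwise the insertion is absent in the target."""
    a, b = anchor.inner_interval
    tree = partner_annotation.get(anchor.chrom)
    if tree is not None and b > a:
        for iv in tree.overlap(a, b):
            if iv.data == family_id:
                return "present_both"
    return "absent_in_target"


def _annotation_trees(elements: list[MiteElement]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for e in elements:
        trees.setdefault(e.location.chrom, IntervalTree()).addi(
            e.location.start, e.location.end, e.family_id
        )
    return trees


def _call_direction(
    query_elements: list[MiteElement],
    query_genome: list[GenomeRecord],
    target_genome: list[GenomeRecord],
    target_annotation: dict[str, IntervalTree],
    flank: int = FLANK,
) -> list[PaLocus]:
    """One direction of the pairwise comparison: anchor every query element's
    flanks on the target and call presence."""
    qdict = {g.name: g.sequence for g in query_genome}
    tdict = {g.name: g.sequence for g in target_genome}
    fwd = _GenomeMapper(target_genome)
    back = _GenomeMapper(query_genome)
    loci = []
    for idx, elem in enumerate(query_elements):
        flanks = extract_flanks(elem, qdict, flank)
        ref_span = (elem.location.chrom, elem.location.start, elem.location.end)
        anchor = anchor_flanks(flanks, fwd, tdict, back_mapper=back, ref_span=ref_span)
        if anchor is None:
            status, allelic = "unresolved", False
        else:
            status = call_presence(anchor, elem.family_id, target_annotation)
            allelic = True
        loci.append(
            PaLocus(
                element_id=f"q{idx}",
                family_id=elem.family_id,
                ref_chrom=elem.location.chrom,
                ref_start=elem.location.start,
                ref_end=elem.location.end,
                anchor=anchor,
                allelic=allelic,
                status=status,
            )
        )
    return loci


def compare_pair(
    reference_elements: list[MiteElement],
    reference_genome: list[GenomeRecord],
    partner_elements: list[MiteElement],
    partner_genome: list[GenomeRecord],
    partner_id: str = "partner",
) -> tuple[list[PaLocus], PaSummary]:
    """Full pairwise P/A comparison.

    Loci present in the reference are anchored on the partner
    (present_both / absent_in_partner); partner elements absent from the
    reference contribute absent_in_reference.  Unresolved loci are excluded
    from every count.
    """
    ref_annot = _annotation_trees(reference_elements)
    partner_annot = _annotation_trees(partner_elements)

    fwd_loci = _call_direction(
        reference_elements, reference_genome, partner_genome, partner_annot
    )
    rev_loci = _call_direction(
        partner_elements, partner_genome, reference_genome, ref_annot
    )

    commonly_present = sum(1 for l in fwd_loci if l.status == "present_both")
    absent_in_partner = sum(1 for l in fwd_loci if l.status == "absent_in_target")
    absent_in_reference = sum(1 for l in rev_loci if l.status == "absent_in_target")

    merged: list[PaLocus] = []
    for l in fwd_loci:
        status = "absent_in_partner" if l.status == "absent_in_target" else l.status
        merged.append(
            PaLocus(l.element_id, l.family_id, l.ref_chrom, l.ref_start, l.ref_end,
                    l.anchor, l.allelic, status)
        )
    for l in rev_loci:
        if l.status == "absent_in_target":
            # reference coordinates are the anchor site on the reference
            a, b = l.anchor.inner_interval
            merged.append(
                PaLocus(l.element_id, l.family_id, l.anchor.chrom,
                        a, max(b, a + 1), l.anchor, l.allelic, "absent_in_reference")
            )
    summary = PaSummary(partner_id, absent_in_reference, absent_in_partner, commonly_present)
    return merged, summary


def build_common_index(
    per_partner_loci: dict[str, list[PaLocus]],
) -> pd.DataFrame:
    """Union of resolved allelic loci keyed by reference coordinates, with a
    per-partner status column; a locus is conserved iff present in all
    partners."""
    rows: dict[tuple, dict] = {}
    for partner, loci in per_partner_loci.items():
        for l in loci:
            if l.status == "unresolved":
                continue
            key = (l.ref_chrom, l.ref_start, l.ref_end, l.family_id)
            row = rows.setdefault(
                key,
                {"chrom": l.ref_chrom, "start": l.ref_start, "end": l.ref_end,
                 "family": l.family_id},
            )
            row[partner] = l.status
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        return df
    partners = list(per_partner_loci)
    df["conserved"] = df.apply(
        lambda r: all(r.get(p) == "present_both" for p in partners), axis=1
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def summary_table(summaries: list[PaSummary]) -> pd.DataFrame:
    """Five-row comparison table: common loci, the two absence counts, the
    commonly-present count and the polymorphic ratio, one column per partner."""
    data = {}
    for s in summaries:
        data[s.partner_id] = [
            s.common_loci,
            s.absent_in_reference,
            s.absent_in_partner,
            s.commonly_present,
            round(s.polymorphic_ratio, 2),
        ]
    return pd.DataFrame(
        data,
        index=[
            "common_loci",
            "absent_in_reference",
            "absent_in_partner",
            "commonly_present",
            "polymorphic_ratio_pct",
        ],
    )


def region_proportions(
    loci_by_class: dict[str, list[tuple[str, int, int]]],
    region_assign,
) -> pd.DataFrame:
    """Per locus class (e.g. conserved / non-conserved / newly-inserted),
    the fraction of loci falling in each genomic region (midpoint rule).

    ``region_assign`` maps (chrom, position) -> region name (see
    context.RegionModel.classify).  Empty classes are reported as absent.
    """
    rows = {}
    for cls, loci in loci_by_class.items():
        if not loci:
            continue
        counts: dict[str, int] = {}
        for chrom, start, end in loci:
            region = region_assign(chrom, (start + end) // 2)
            counts[region] = counts.get(region, 0) + 1
        total = sum(counts.values())
        rows[cls] = {k: v / total for k, v in counts.items()}
    return pd.DataFrame(rows).T.fillna(0.0)


__all__ = [
    "FlankPair",
    "PartnerAnchor",
    "PaLocus",
    "PaSummary",
    "extract_flanks",
    "anchor_flanks",
    "call_presence",
    "compare_pair",
    "build_common_index",
    "summary_table",
    "region_proportions",
    "FLANK",
]
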