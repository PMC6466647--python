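"""Genomic-region model and element context statistics.

The genome is partitioned into promoter (1 kb upstream of the TSS,
strand-aware), 5'/3' UTR, intron, gene body (remaining exonic bp) and
intergenic classes.  Overlaps resolve by painting classes in increasing
priority: intergenic < promoter < intron < gene_body < UTR, so a UTR always
wins and a promoter never overrides genic sequence.  The partition conserves
genome length exactly by construction.

Relative abundance apportions element bp across the classes it overlaps
(bp-conserving, insensitive to boundary jitter); a midpoint-count variant
is available for positional profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import FeatureInterval, GenomeRecord, synthesize_introns

REGION_CLASSES = [
    "intergenic",
    "promoter",
    "intron",
    "gene_body",
    "five_prime_UTR",
    "three_prime_UTR",
]
_CODE = {name: i for i, name in enumerate(REGION_CLASSES)}
PROMOTER_BP = 1000


@dataclass
class RegionModel:
    """Per-chromosome class paint (uint8 codes) plus class bp totals."""

    paint: dict[str, np.ndarray]
    class_bp: dict[str, int]
    genome_length: int

    def classify(self, chrom: str, position: int) -> str:
        arr = self.paint[chrom]
        position = min(max(position, 0), len(arr) - 1)
        return REGION_CLASSES[arr[position]]


def build_region_model(
    genes: list[FeatureInterval], genome: list[GenomeRecord]
) -> RegionModel:
    """Paint the genome with region classes from gene features.

    Requires stranded gene features; introns are derived from exon gaps when
    not explicitly present.
    """
    paint = {g.name: np.zeros(len(g.sequence), dtype=np.uint8) for g in genome}
    feats = list(genes)
    if not any(f.kind == "intron" for f in feats):
        feats.extend(synthesize_introns(feats))

    def spans(kind: str):
        return [f for f in feats if f.kind == kind]

    for f in spans("gene"):
        if f.strand not in "+-":
            raise ValueError(f"gene at {f.chrom}:{f.start} lacks a strand")

    # promoters: 1 kb upstream of the TSS, strand-aware, clipped at ends
    promoters = []
    for f in spans("gene"):
        n = len(paint[f.chrom])
        if f.strand == "+":
            s, e = max(0, f.start - PROMOTER_BP), f.start
        else:
            s, e = f.end, min(n, f.end + PROMOTER_BP)
        if e > s:
            promoters.append((f.chrom, s, e))

    for chrom, s, e in promoters:
        paint[chrom][s:e] = _CODE["promoter"]
    for f in spans("intron"):
        paint[f.chrom][f.start : f.end] = _CODE["intron"]
    for f in spans("exon"):
        paint[f.chrom][f.start : f.end] = _CODE["gene_body"]
    for kind in ("five_prime_UTR", "three_prime_UTR"):
        for f in spans(kind):
            paint[f.chrom][f.start : f.end] = _CODE[kind]

    class_bp = {name: 0 for name in REGION_CLASSES}
    for arr in paint.values():
        counts = np.bincount(arr, minlength=len(REGION_CLASSES))
        for i, name in enumerate(REGION_CLASSES):
            class_bp[name] += int(counts[i])
    return RegionModel(paint, class_bp, sum(len(g.sequence) for g in genome))


@dataclass
class RelativeAbundance:
    table: pd.DataFrame  # index: region class; columns: element_bp, class_bp, density, relative


def relative_abundance(
    elements: list[FeatureInterval], model: RegionModel
) -> RelativeAbundance:
    """bp-apportioned element density per region class, normalised by the
    genome-wide density (1.0 = uniform insertion in expectation)."""
    elem_bp = {name: 0 for name in REGION_CLASSES}
    total_elem = 0
    for e in elements:
        arr = model.paint[e.chrom][e.start : e.end]
        counts = np.bincount(arr, minlength=len(REGION_CLASSES))
        for i, name in enumerate(REGION_CLASSES):
            elem_bp[name] += int(counts[i])
        total_elem += e.end - e.start
    genome_density = total_elem / model.genome_length if model.genome_length else 0.0
    rows = []
    for name in REGION_CLASSES:
        cbp = model.class_bp[name]
        if cbp == 0:
            continue  # empty class: density undefined, reported as missing
        density = elem_bp[name] / cbp
        rows.append(
            {
                "region": name,
                "element_bp": elem_bp[name],
                "class_bp": cbp,
                "density": density,
                "relative": density / genome_density if genome_density else 0.0,
            }
        )
    return RelativeAbundance(pd.DataFrame(rows).set_index("region"))


def tss_tts_profile(
    elements: list[FeatureInterval],
    genes: list[FeatureInterval],
    span: int = 5000,
    bin_width: int = 100,
) -> pd.DataFrame:
    """Binned counts of element midpoints in strand-oriented coordinates
    upstream of the TSS and downstream of the TTS.

    Rows are bins; the ``offset`` column is the bin's strand-oriented start
    (negative upstream of the TSS, positive downstream of the TTS).
    """
    genes_only = [f for f in genes if f.kind == "gene"]
    mids: dict[str, list[int]] = {}
    for e in elements:
        mids.setdefault(e.chrom, []).append((e.start + e.end) // 2)
    mid_arrays = {c: np.array(sorted(v)) for c, v in mids.items()}
    n_bins = span // bin_width
    up = np.zeros(n_bins, dtype=int)
    down = np.zeros(n_bins, dtype=int)
    for g in genes_only:
        arr = mid_arrays.get(g.chrom)
        if arr is None or len(arr) == 0:
            continue
        if g.strand == "+":
            tss, tts, sign = g.start, g.end, 1
        else:
            tss, tts, sign = g.end, g.start, -1
        # upstream of TSS
        rel = sign * (arr - tss)
        sel = rel[(rel >= -span) & (rel < 0)]
        if len(sel):
            up += np.histogram(sel, bins=n_bins, range=(-span, 0))[0]
        # downstream of TTS
        rel = sign * (arr - tts)
        sel = rel[(rel >= 0) & (rel < span)]
        if len(sel):
            down += np.histogram(sel, bins=n_bins, range=(0, span))[0]
    offsets_up = np.arange(-span, 0, bin_width)
    offsets_down = np.arange(0, span, bin_width)
    return pd.DataFrame(
        {
            "offset": np.concatenate([offsets_up, offsets_down]),
            "side": ["upstream_tss"] * n_bins + ["downstream_tts"] * n_bins,
            "count": np.concatenate([up, down]),
        }
    )


def windowed_density(
    elements: list[FeatureInterval],
    genome: list[GenomeRecord],
    window: int = 1_000_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window element bp fraction (trailing partial windows dropped).

    A chromosome shorter than one window contributes zero windows.
    """
    cover = {g.name: np.zeros(len(g.sequence), dtype=np.uint8) for g in genome}
    for e in elements:
        cover[e.chrom][e.start : e.end] = 1
    rows = []
    for g in genome:
        n = len(g.sequence)
        if n < window:
            continue
        cum = np.concatenate([[0], np.cumsum(cover[g.name], dtype=np.int64)])
        for start in range(0, n - window + 1, step):
            bp = int(cum[start + window] - cum[start])
            rows.append(
                {"chrom": g.name, "start": start, "end": start + window,
                 "density": bp / window}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "density"])


__all__ = [
    "RegionModel",
    "RelativeAbundance",
    "REGION_CLASSES",
    "PROMOTER_BP",
    "build_region_model",
    "relative_abundance",
    "tss_tts_profile",
    "windowed_density",
]
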