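"""Shared synthetic fixtures.

All fixtures are generated programmatically at session scope; nothing is
read from disk.  Seeds are fixed so every run sees identical data.
"""

from __future__ import annotations

import numpy as np
import pytest

from tedyn import mite, synthio
from tedyn.seqio import FeatureInterval


def iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    return max(0, e - s) / (max(a[1], b[1]) - min(a[0], b[0]))


def recall(detections, truths, thr: float = 0.9) -> float:
    if not truths:
        return 1.0
    hit = 0
    for t in truths:
        span = (t.start, t.end)
        if any(
            d.location.chrom == t.chrom
            and iou((d.location.start, d.location.end), span) >= thr
            for d in detections
        ):
            hit += 1
    return hit / len(truths)


def precision(detections, truths, thr: float = 0.9) -> float:
    if not detections:
        return 1.0
    hit = 0
    for d in detections:
        span = (d.location.start, d.location.end)
        if any(
            d.location.chrom == t.chrom and iou(span, (t.start, t.end)) >= thr
            for t in truths
        ):
            hit += 1
    return hit / len(detections)


def families_from_truth(truth: synthio.TruthTable) -> list[mite.MiteFamily]:
    """Cluster the planted MITE family seeds into MiteFamily objects and map
    detected ids back to planted ids via the representative sequence."""
    elements = [
        mite.MiteElement(
            location=FeatureInterval(fam, 0, len(seq), ".", "repeat_region"),
            sequence=seq,
        )
        for fam, seq in truth.family_seeds.items()
        if fam.startswith("DT")
    ]
    return mite.cluster_families(elements)


def family_id_map(
    families: list[mite.MiteFamily], truth: synthio.TruthTable
) -> dict[str, str]:
    """planted family id -> clustered family id."""
    by_seq = {f.representative: f.family_id for f in families}
    return {
        fam: by_seq[seq]
        for fam, seq in truth.family_seeds.items()
        if seq in by_seq
    }


@pytest.fixture(scope="session")
def planted_genome():
    """One genome with three MITE families (two superfamilies, mixed
    divergence <= 0.10) and two LTR families with solos."""
    cfg = synthio.SynthConfig(
        seed=42,
        genome_length=700_000,
        n_chromosomes=2,
        mite_families=[
            synthio.MiteFamilyPlan("Mutator", 14, 9, 260, 30, (0.10,)),
            synthio.MiteFamilyPlan("hAT", 12, 8, 480, 20, (0.05,)),
            synthio.MiteFamilyPlan("PIF-Harbinger", 14, "TTA", 350, 20, (0.08,)),
        ],
        ltr_families=[
            synthio.LtrFamilyPlan(250, 1800, 16, 1.8, 0.4),
            synthio.LtrFamilyPlan(150, 1300, 12, 1.0, 0.3),
        ],
        gene_density=25,
        pa_polymorphism_rate=0.0,
    )
    records, features, truth = synthio.generate_genome(cfg)
    return cfg, records, features, truth


@pytest.fixture(scope="session")
def planted_mite_annotation(planted_genome):
    """Family clustering of the planted seeds plus genome-wide annotation."""
    _cfg, records, _features, truth = planted_genome
    families = families_from_truth(truth)
    copies = mite.annotate_copies(records, families)
    return families, copies


@pytest.fixture(scope="session")
def genome_pair():
    """An orthologous pair with 40% planted P/A polymorphism."""
    cfg = synthio.SynthConfig(
        seed=7,
        genome_length=400_000,
        n_chromosomes=2,
        mite_families=[
            synthio.MiteFamilyPlan("Mutator", 14, 9, 260, 40, (0.05,)),
            synthio.MiteFamilyPlan("hAT", 12, 8, 400, 20, (0.02,)),
        ],
        ltr_families=[],
        gene_density=20,
        pa_polymorphism_rate=0.4,
    )
    rec_a, rec_b, feat_a, feat_b, truth = synthio.generate_pair(cfg)
    return cfg, rec_a, rec_b, feat_a, feat_b, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
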