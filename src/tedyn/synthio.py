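"""Synthetic genomes with planted transposable-element ground truth.

The generator emulates the statistical structure the downstream analyses
assume: i.i.d. background sequence at a stated GC content, gene models,
MITE families planted as a seed sequence mutated per copy at a planted
divergence (substitutions only, so p-distance equals planted divergence),
complete LTR retrotransposons whose 5'/3' LTR pair distance is set from a
planted insertion time via the inverse Jukes-Cantor transform and T = k/2r,
solo-LTRs, clean presence/absence polymorphism between genome pairs (an
excised locus retains exactly one TSD copy, which is the native host
sequence), and small-RNA tags emitted preferentially from MITE terminals.

Insertion semantics: a host site ...XYZ[tsd]ABC... becomes
...XYZ[tsd][element][tsd']ABC... on insertion, where [tsd'] duplicates the
native [tsd].  The empty allele therefore carries one TSD copy and both
alleles share their 1 kb flanks exactly, which is what reciprocal flank
anchoring requires.

Mutations never touch the TIR termini, the TG..CA dinucleotides, or the
PBS/PPT motifs, so planted elements always satisfy the structural
definitions the detectors test for; mutation counts are drawn
Binomial(length, divergence) over the whole element so the empirical
divergence against the seed is an unbiased estimate of the planted value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from intervaltree import IntervalTree

from .seqio import FeatureInterval, GenomeRecord, revcomp

# per-lineage substitution rate, substitutions/site/year (non-coding)
DEFAULT_RATE = 5.62e-9

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SynthError(ValueError):
    """Invalid or infeasible synthesis configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MiteFamilyPlan:
    """One planted MITE family.

    ``tsd_spec`` is either an integer TSD length (8 for hAT, 9/10 for
    Mutator) or the literal string "TTA" for PIF-Harbinger (TTA/TAA chosen
    per copy).  ``burst_divergences`` are mean per-copy divergences from the
    family seed; copies are split evenly across bursts, so k bursts give a
    k-modal pairwise-divergence distribution.
    """

    superfamily: str = "Mutator"
    tir_length: int = 14
    tsd_spec: int | str = 9
    element_length: int = 300
    copy_number: int = 50
    burst_divergences: tuple[float, ...] = (0.13,)

    def __post_init__(self):
        if self.superfamily not in {"Mutator", "hAT", "PIF-Harbinger"}:
            raise SynthError(f"unknown superfamily {self.superfamily!r}")
        if self.copy_number < 0 or self.tir_length < 10:
            raise SynthError("copy_number >= 0 and tir_length >= 10 required")
        if any(not (0 <= d < 0.75) for d in self.burst_divergences):
            raise SynthError("burst divergences must lie in [0, 0.75)")
        if 2 * self.tir_length >= self.element_length:
            raise SynthError("element_length must exceed twice tir_length")

    @property
    def tsd_length(self) -> int:
        return 3 if self.tsd_spec in ("TTA", "TAA") else int(self.tsd_spec)


@dataclass
class LtrFamilyPlan:
    """One planted LTR-retrotransposon family.

    Insertion times are drawn from an exponential distribution with the
    stated half-life (My); a ``solo_fraction`` of planted copies become
    solo-LTRs (single LTR with TSD flanks) instead of complete elements.
    """

    ltr_length: int = 200
    internal_length: int = 1500
    copy_number: int = 30
    half_life_my: float = 1.8
    solo_fraction: float = 0.0
    superfamily: str = "unknown"

    def __post_init__(self):
        if self.ltr_length < 100 or self.internal_length < 1000:
            raise SynthError("ltr_length >= 100 and internal_length >= 1000 required")
        if not (0.0 <= self.solo_fraction <= 1.0):
            raise SynthError("solo_fraction must lie in [0, 1]")
        if self.copy_number < 0 or self.half_life_my <= 0:
            raise SynthError("copy_number >= 0 and half_life_my > 0 required")


@dataclass
class SrnaPlan:
    """Small-RNA tag emission plan.

    ``terminal_bias`` over-weights the terminal 10% bands of the element;
    1.0 means uniform emission.  ``tag_lengths`` maps length -> probability,
    peaked at 24 nt by default as in plant heterochromatic siRNA data.
    """

    tags_per_mite: int = 20
    terminal_bias: float = 4.0
    background_tags: int = 1000
    tag_lengths: dict[int, float] = field(
        default_factory=lambda: {21: 0.12, 22: 0.08, 23: 0.10, 24: 0.55, 25: 0.15}
    )

    def __post_init__(self):
        if self.terminal_bias <= 0:
            raise SynthError("terminal_bias must be positive")
        total = sum(self.tag_lengths.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise SynthError("tag length probabilities must sum to 1")
        if any(not (18 <= l <= 30) for l in self.tag_lengths):
            raise SynthError("tag lengths must lie in [18, 30]")


@dataclass
class SynthConfig:
    """Full description of one synthetic genome (or genome pair)."""

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.38
    mite_families: list[MiteFamilyPlan] = field(
        default_factory=lambda: [
            MiteFamilyPlan("Mutator", 14, 9, 260, 60, (0.13,)),
            MiteFamilyPlan("Mutator", 14, 10, 150, 40, (0.01,)),
            MiteFamilyPlan("hAT", 12, 8, 560, 30, (0.05,)),
            MiteFamilyPlan("PIF-Harbinger", 14, "TTA", 430, 30, (0.12,)),
        ]
    )
    ltr_families: list[LtrFamilyPlan] = field(
        default_factory=lambda: [
            LtrFamilyPlan(250, 1800, 25, 1.8, 0.58),
            LtrFamilyPlan(150, 1200, 20, 1.8, 0.58),
        ]
    )
    gene_density: float = 40.0  # genes per Mb
    pa_polymorphism_rate: float = 0.5
    srna_plan: SrnaPlan = field(default_factory=SrnaPlan)
    substitution_rate: float = DEFAULT_RATE
    min_locus_gap: int = 2500  # bp between planted loci (keeps 1 kb flanks clean)
    allow_genic_planting: bool = False

    def __post_init__(self):
        if not (0.0 <= self.gc_content <= 1.0):
            raise SynthError("gc_content must lie in [0, 1]")
        if not (0.0 <= self.pa_polymorphism_rate <= 1.0):
            raise SynthError("pa_polymorphism_rate must lie in [0, 1]")
        if self.n_chromosomes < 1 or self.genome_length < 10_000:
            raise SynthError("need >= 1 chromosome and >= 10 kb of genome")
        planted = self.planted_bp()
        if planted > self.genome_length:
            raise SynthError(
                f"config demands {planted} planted bp but genome_length is "
                f"{self.genome_length}"
            )

    def planted_bp(self) -> int:
        total = 0
        for fam in self.mite_families:
            total += fam.copy_number * (fam.element_length + 2 * fam.tsd_length)
        for fam in self.ltr_families:
            total += fam.copy_number * (2 * fam.ltr_length + fam.internal_length + 12)
        return total

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mite_families" in raw:
            raw["mite_families"] = [
                MiteFamilyPlan(
                    **{**f, "burst_divergences": tuple(f.get("burst_divergences", (0.13,)))}
                )
                for f in raw["mite_families"]
            ]
        if "ltr_families" in raw:
            raw["ltr_families"] = [LtrFamilyPlan(**f) for f in raw["ltr_families"]]
        if "srna_plan" in raw:
            plan = dict(raw["srna_plan"])
            if "tag_lengths" in plan:
                plan["tag_lengths"] = {int(k): float(v) for k, v in plan["tag_lengths"].items()}
            raw["srna_plan"] = SrnaPlan(**plan)
        return cls(**raw)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedElement:
    """Ground truth for one planted element copy in one genome."""

    element_id: str
    genome_id: str
    chrom: str
    start: int  # 0-based half-open, element proper (TSDs excluded)
    end: int
    kind: str  # MITE | LTR_complete | solo_LTR
    family_id: str
    superfamily: str
    divergence: float  # realized p-distance from the family seed
    insertion_time_my: float | None
    tsd: str
    status: str  # present_both | absent_in_partner | absent_in_reference | single
    sequence: str = ""
    ltr_length: int = 0
    internal_length: int = 0
    locus_id: str = ""


@dataclass
class PlantedTag:
    sequence: str
    count: int
    source_element_id: str | None  # None for background tags
    source_offset: int | None


@dataclass
class TruthTable:
    """Planted ground truth; the yardstick for every recovery test."""

    elements: list[PlantedElement] = field(default_factory=list)
    tags: list[PlantedTag] = field(default_factory=list)
    family_seeds: dict[str, str] = field(default_factory=dict)
    genomes: dict[str, list[GenomeRecord]] = field(default_factory=dict)
    trnas: list[GenomeRecord] = field(default_factory=list)

    def elements_of(self, genome_id: str, kind: str | None = None) -> list[PlantedElement]:
        return [
            e
            for e in self.elements
            if e.genome_id == genome_id and (kind is None or e.kind == kind)
        ]

    def polymorphic_ratio(self) -> float:
        """Planted P/A ratio over MITE loci (fraction, not percent)."""
        loci = {e.locus_id: e.status for e in self.elements if e.kind == "MITE"}
        if not loci:
            return 0.0
        poly = sum(1 for s in loci.values() if s.startswith("absent"))
        return poly / len(loci)

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "element_id", "genome_id", "chrom", "start", "end", "kind",
            "family_id", "superfamily", "divergence", "insertion_time_my",
            "tsd", "status", "ltr_length", "internal_length", "locus_id",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for e in self.elements:
                t = "" if e.insertion_time_my is None else f"{e.insertion_time_my:.6f}"
                fh.write(
                    "\t".join(
                        [
                            e.element_id, e.genome_id, e.chrom, str(e.start),
                            str(e.end), e.kind, e.family_id, e.superfamily,
                            f"{e.divergence:.6f}", t, e.tsd, e.status,
                            str(e.ltr_length), str(e.internal_length), e.locus_id,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    n_mut: int,
    protected: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Substitute ``n_mut`` distinct unprotected sites to a different base."""
    allowed = np.flatnonzero(~protected)
    n_mut = min(n_mut, len(allowed))
    if n_mut == 0:
        return seq.copy(), 0
    sites = rng.choice(allowed, size=n_mut, replace=False)
    out = seq.copy()
    shift = rng.integers(1, 4, size=n_mut)
    out[sites] = (out[sites] + shift) % 4
    return out, n_mut


def make_mite_seed(rng: np.random.Generator, plan: MiteFamilyPlan, gc: float) -> np.ndarray:
    """Family seed: random interior wrapped in a perfect TIR."""
    seq = _random_seq(rng, plan.element_length, gc)
    tir = seq[: plan.tir_length]
    rc = (3 - tir)[::-1]  # reverse complement in 2-bit encoding
    seq[-plan.tir_length:] = rc
    return seq


_PURINES = np.array([0, 2], dtype=np.uint8)  # A, G


def make_trnas(rng: np.random.Generator, n: int = 3, length: int = 72) -> list[GenomeRecord]:
    """Synthetic tRNA stand-ins (uniform random; only the 3' end matters)."""
    return [
        GenomeRecord(f"tRNA{i + 1}", _to_str(_random_seq(rng, length, 0.5)))
        for i in range(n)
    ]


def make_ltr_seed(
    rng: np.random.Generator, plan: LtrFamilyPlan, gc: float, trna_seq: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Family seeds: (ltr, internal, protected-internal-mask).

    The LTR starts TG and ends CA.  The internal region carries a PBS
    (reverse complement of the tRNA 3'-terminal 14 nt, 2 bp downstream of
    the 5' LTR) and a 12 nt polypurine tract 4 bp upstream of the 3' LTR.
    """
    ltr = _random_seq(rng, plan.ltr_length, gc)
    ltr[0], ltr[1] = 3, 2  # TG
    ltr[-2], ltr[-1] = 1, 0  # CA
    internal = _random_seq(rng, plan.internal_length, gc)
    pbs = np.array(
        [{"A": 3, "C": 2, "G": 1, "T": 0}[c] for c in trna_seq[-14:]], dtype=np.uint8
    )[::-1]  # reverse complement of the tRNA 3' end
    internal[2 : 2 + 14] = pbs
    ppt = _PURINES[rng.integers(0, 2, size=12)]
    internal[-16:-4] = ppt
    protected = np.zeros(plan.internal_length, dtype=bool)
    protected[: 2 + 14] = True
    protected[-16:] = True
    return ltr, internal, protected


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

class _Placer:
    """Greedy randomized placement of non-overlapping reservations."""

    def __init__(self, rng: np.random.Generator, chrom_lengths: dict[str, int]):
        self.rng = rng
        self.lengths = chrom_lengths
        self.trees = {c: IntervalTree() for c in chrom_lengths}
        self.names = list(chrom_lengths)
        total = sum(chrom_lengths.values())
        self.weights = np.array([chrom_lengths[c] / total for c in self.names])

    def place(self, width: int, margin: int, retries: int = 400) -> tuple[str, int]:
        # half-margin per side: pairwise separation >= margin without
        # double-counting the gap between neighbours
        half = (margin + 1) // 2
        edge = max(margin, 1200)
        for _ in range(retries):
            chrom = self.names[int(self.rng.choice(len(self.names), p=self.weights))]
            limit = self.lengths[chrom] - width - edge
            if limit <= edge:
                continue
            pos = int(self.rng.integers(edge, limit))
            if not self.trees[chrom].overlap(pos - half, pos + width + half):
                self.trees[chrom].addi(pos - half, pos + width + half)
                return chrom, pos
        raise SynthError(
            "could not place all planted features: planted bp plus spacing "
            "exceeds genome capacity; enlarge genome_length or reduce copy "
            "numbers / gene_density"
        )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GENE_LEN = 3200
_EXONS = [(0, 700), (1400, 1900), (2600, 3200)]  # background-relative
_UTR5 = (0, 200)
_UTR3 = (3000, 3200)


def _gene_features(chrom: str, pos: int, strand: str, gid: str) -> list[FeatureInterval]:
    feats = [
        FeatureInterval(chrom, pos, pos + _GENE_LEN, strand, "gene", {"ID": gid})
    ]
    spans = {"exon": _EXONS, "five_prime_UTR": [_UTR5], "three_prime_UTR": [_UTR3]}
    for kind, intervals in spans.items():
        for s, e in intervals:
            if strand == "-" and kind in ("five_prime_UTR", "three_prime_UTR"):
                # mirror UTRs so the 5' UTR sits at the transcription start
                s, e = _GENE_LEN - e, _GENE_LEN - s
            feats.append(
                FeatureInterval(chrom, pos + s, pos + e, strand, kind, {"Parent": gid})
            )
    return feats


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _Insertion:
    chrom: str
    anchor: int  # background coordinate of the native TSD start
    tsd: str
    seq: str  # element proper
    element: PlantedElement  # template record (coords filled per genome)


def _chrom_lengths(config: SynthConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    out = {}
    for i in range(config.n_chromosomes):
        extra = config.genome_length - base * config.n_chromosomes if i == 0 else 0
        out[f"chr{i + 1}"] = base + extra
    return out


def _inverse_jc(k: float) -> float:
    """p such that the Jukes-Cantor correction of p equals k."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


def _build_insertions(
    config: SynthConfig, rng: np.random.Generator, trnas: list[GenomeRecord]
) -> tuple[list[_Insertion], dict[str, str], list[FeatureInterval], dict[str, np.ndarray]]:
    chrom_lengths = _chrom_lengths(config)
    backgrounds = {
        c: _random_seq(rng, n, config.gc_content) for c, n in chrom_lengths.items()
    }
    placer = _Placer(rng, chrom_lengths)

    # genes first (they carry a 1 kb promoter margin)
    genes: list[FeatureInterval] = []
    n_genes = int(round(config.gene_density * config.genome_length / 1e6))
    for gi in range(n_genes):
        chrom, pos = placer.place(_GENE_LEN, margin=1100)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.extend(_gene_features(chrom, pos, strand, f"g{gi + 1}"))

    insertions: list[_Insertion] = []
    seeds: dict[str, str] = {}
    counters = {"Mutator": 0, "hAT": 0, "PIF-Harbinger": 0}
    prefix = {"Mutator": "DTM", "hAT": "DTA", "PIF-Harbinger": "DTH"}
    eid = 0

    for plan in config.mite_families:
        counters[plan.superfamily] += 1
        family_id = f"{prefix[plan.superfamily]}{counters[plan.superfamily]}"
        seed = make_mite_seed(rng, plan, config.gc_content)
        seeds[family_id] = _to_str(seed)
        protected = np.zeros(plan.element_length, dtype=bool)
        protected[: plan.tir_length] = True
        protected[-plan.tir_length:] = True
        bursts = plan.burst_divergences
        for ci in range(plan.copy_number):
            d = bursts[ci * len(bursts) // max(plan.copy_number, 1)]
            n_mut = int(rng.binomial(plan.element_length, d))
            copy, realized = _mutate(rng, seed, n_mut, protected)
            chrom, anchor = placer.place(
                plan.element_length + 2 * plan.tsd_length, margin=config.min_locus_gap
            )
            if plan.tsd_spec in ("TTA", "TAA"):
                tsd = "TTA" if rng.random() < 0.5 else "TAA"
            else:
                tsd = _to_str(rng.integers(0, 4, size=plan.tsd_length).astype(np.uint8))
            # overwrite the native site so the host carries the TSD sequence
            tenc = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in tsd], np.uint8)
            backgrounds[chrom][anchor : anchor + len(tsd)] = tenc
            eid += 1
            insertions.append(
                _Insertion(
                    chrom, anchor, tsd, _to_str(copy),
                    PlantedElement(
                        element_id=f"E{eid}", genome_id="", chrom=chrom,
                        start=0, end=0, kind="MITE", family_id=family_id,
                        superfamily=plan.superfamily,
                        divergence=realized / plan.element_length,
                        insertion_time_my=None, tsd=tsd, status="single",
                        sequence=_to_str(copy), locus_id=f"L{eid}",
                    ),
                )
            )

    rlx = 0
    for plan in config.ltr_families:
        rlx += 1
        family_id = f"RLX{rlx}"
        trna_seq = trnas[(rlx - 1) % len(trnas)].sequence
        ltr_seed, int_seed, int_protected = make_ltr_seed(
            rng, plan, config.gc_content, trna_seq
        )
        full_seed = np.concatenate([ltr_seed, int_seed, ltr_seed])
        seeds[family_id] = _to_str(full_seed)
        ltr_protected = np.zeros(plan.ltr_length, dtype=bool)
        ltr_protected[:2] = True
        ltr_protected[-2:] = True
        for _ci in range(plan.copy_number):
            t_my = float(rng.exponential(plan.half_life_my / math.log(2)))
            k = 2.0 * config.substitution_rate * t_my * 1e6
            p = min(_inverse_jc(k), 0.45)
            is_solo = rng.random() < plan.solo_fraction
            tsd_len = int(rng.integers(4, 7))
            tsd = _to_str(rng.integers(0, 4, size=tsd_len).astype(np.uint8))
            tenc = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in tsd], np.uint8)
            eid += 1
            if is_solo:
                n_mut = int(rng.binomial(plan.ltr_length, min(p, 0.3)))
                solo, realized = _mutate(rng, ltr_seed, n_mut, ltr_protected)
                seq = _to_str(solo)
                kind = "solo_LTR"
                ltr_len, int_len = plan.ltr_length, 0
                div = realized / plan.ltr_length
            else:
                # pairwise LTR distance = p: mutations at distinct sites,
                # each assigned to the 5' or the 3' LTR copy
                n_mut = int(rng.binomial(plan.ltr_length, p))
                allowed = np.flatnonzero(~ltr_protected)
                n_mut = min(n_mut, len(allowed))
                sites = rng.choice(allowed, size=n_mut, replace=False) if n_mut else []
                ltr5, ltr3 = ltr_seed.copy(), ltr_seed.copy()
                for s in sites:
                    target = ltr5 if rng.random() < 0.5 else ltr3
                    target[s] = (target[s] + rng.integers(1, 4)) % 4
                n_int = int(rng.binomial(plan.internal_length, min(p / 2, 0.2)))
                internal, _ = _mutate(rng, int_seed, n_int, int_protected)
                full = np.concatenate([ltr5, internal, ltr3])
                seq = _to_str(full)
                kind = "LTR_complete"
                ltr_len, int_len = plan.ltr_length, plan.internal_length
                div = n_mut / (2 * plan.ltr_length)
            chrom, anchor = placer.place(len(seq) + 2 * tsd_len, margin=config.min_locus_gap)
            backgrounds[chrom][anchor : anchor + tsd_len] = tenc
            insertions.append(
                _Insertion(
                    chrom, anchor, tsd, seq,
                    PlantedElement(
                        element_id=f"E{eid}", genome_id="", chrom=chrom,
                        start=0, end=0, kind=kind, family_id=family_id,
                        superfamily=plan.superfamily, divergence=div,
                        insertion_time_my=t_my, tsd=tsd, status="single",
                        sequence=seq, ltr_length=ltr_len, internal_length=int_len,
                        locus_id=f"L{eid}",
                    ),
                )
            )

    return insertions, seeds, genes, backgrounds


def _assemble_genome(
    genome_id: str,
    backgrounds: dict[str, np.ndarray],
    insertions: list[_Insertion],
    genes: list[FeatureInterval],
    include,
) -> tuple[list[GenomeRecord], list[FeatureInterval], list[PlantedElement]]:
    """Assemble one genome from the shared background plus selected insertions."""
    from dataclasses import replace as _replace

    records = []
    features: list[FeatureInterval] = []
    truth: list[PlantedElement] = []
    by_chrom: dict[str, list[_Insertion]] = {c: [] for c in backgrounds}
    for ins in insertions:
        if include(ins):
            by_chrom[ins.chrom].append(ins)
    for chrom, bg in backgrounds.items():
        chosen = sorted(by_chrom[chrom], key=lambda i: i.anchor)
        parts = []
        offsets = []  # (background position, cumulative inserted length)
        prev = 0
        cum = 0
        bg_str = _to_str(bg)
        for ins in chosen:
            point = ins.anchor + len(ins.tsd)  # insert after the native TSD
            parts.append(bg_str[prev:point])
            inserted = ins.seq + ins.tsd
            parts.append(inserted)
            start = point + cum
            truth.append(
                _replace(
                    ins.element,
                    genome_id=genome_id,
                    start=start,
                    end=start + len(ins.seq),
                )
            )
            cum += len(inserted)
            offsets.append((point, cum))
            prev = point
        parts.append(bg_str[prev:])
        records.append(GenomeRecord(chrom, "".join(parts)))
        # shift gene features through the insertion offsets
        points = np.array([p for p, _ in offsets] or [0])
        cums = np.array([c for _, c in offsets] or [0])

        def shift(x: int) -> int:
            i = int(np.searchsorted(points, x, side="right")) - 1
            return x + (int(cums[i]) if i >= 0 and offsets else 0)

        for f in genes:
            if f.chrom != chrom:
                continue
            features.append(
                FeatureInterval(chrom, shift(f.start), shift(f.end), f.strand, f.kind,
                                dict(f.attributes))
            )
    return records, features, truth


def generate_genome(config: SynthConfig) -> tuple[list[GenomeRecord], list[FeatureInterval], TruthTable]:
    """Generate one synthetic genome with planted ground truth.

    Returns (chromosome records, gene features, truth table); deterministic
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    trnas = make_trnas(rng)
    insertions, seeds, genes, backgrounds = _build_insertions(config, rng, trnas)
    records, features, truth_elems = _assemble_genome(
        "genomeA", backgrounds, insertions, genes, include=lambda i: True
    )
    truth = TruthTable(elements=truth_elems, family_seeds=seeds, trnas=trnas)
    truth.genomes["genomeA"] = records
    for e in truth.elements:
        e.status = "single"
    return records, features, truth


def generate_pair(
    config: SynthConfig,
) -> tuple[list[GenomeRecord], list[GenomeRecord], list[FeatureInterval], list[FeatureInterval], TruthTable]:
    """Generate an orthologous genome pair with planted P/A polymorphism.

    A ``pa_polymorphism_rate`` fraction of MITE loci is made genome-specific,
    split alternately between loci excised from the partner
    (absent_in_partner) and loci present only in the partner
    (absent_in_reference).  Excision retains exactly one TSD copy (the
    native host bases), so both alleles share their flanks.
    """
    rng = np.random.default_rng(config.seed)
    trnas = make_trnas(rng)
    insertions, seeds, genes, backgrounds = _build_insertions(config, rng, trnas)

    mite_idx = [i for i, ins in enumerate(insertions) if ins.element.kind == "MITE"]
    n_poly = int(round(config.pa_polymorphism_rate * len(mite_idx)))
    poly = rng.choice(len(mite_idx), size=n_poly, replace=False) if n_poly else []
    statuses = {i: "present_both" for i in mite_idx}
    for j, pi in enumerate(sorted(int(x) for x in poly)):
        statuses[mite_idx[pi]] = (
            "absent_in_partner" if j % 2 == 0 else "absent_in_reference"
        )
    for i, ins in enumerate(insertions):
        if ins.element.kind == "MITE":
            ins.element.status = statuses[i]
        else:
            ins.element.status = "present_both"

    rec_a, feat_a, truth_a = _assemble_genome(
        "genomeA", backgrounds, insertions, genes,
        include=lambda ins: ins.element.status != "absent_in_reference",
    )
    rec_b, feat_b, truth_b = _assemble_genome(
        "genomeB", backgrounds, insertions, genes,
        include=lambda ins: ins.element.status != "absent_in_partner",
    )
    truth = TruthTable(elements=truth_a + truth_b, family_seeds=seeds, trnas=trnas)
    truth.genomes["genomeA"] = rec_a
    truth.genomes["genomeB"] = rec_b
    return rec_a, rec_b, feat_a, feat_b, truth


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def generate_srna(
    config: SynthConfig, truth: TruthTable, genome_id: str = "genomeA"
) -> list[PlantedTag]:
    """Emit small-RNA tags from planted MITEs (terminal-biased) plus background.

    With terminal_bias B, start positions fall in the terminal 10% bands of
    the element with density B relative to the middle; B = 1 is uniform.
    Background tags are sliced from non-MITE genome sequence.  Tags are
    collapsed to unique sequences with counts.
    """
    rng = np.random.default_rng(config.seed + 1)
    plan = config.srna_plan
    genomes = {g.name: g.sequence for g in truth.genomes.get(genome_id, [])}
    if not genomes:
        raise SynthError(f"truth table carries no sequences for {genome_id!r}")
    mites = truth.elements_of(genome_id, "MITE")
    lengths = np.array(sorted(plan.tag_lengths))
    probs = np.array([plan.tag_lengths[l] for l in lengths])
    probs = probs / probs.sum()

    b = plan.terminal_bias
    p_terminal = (b * 0.2) / (b * 0.2 + 0.8)

    collapsed: dict[str, PlantedTag] = {}

    def emit(seq: str, source: str | None, offset: int | None):
        if "N" in seq:
            return
        tag = collapsed.get(seq)
        if tag is None:
            collapsed[seq] = PlantedTag(seq, 1, source, offset)
        else:
            tag.count += 1

    for e in mites:
        elem_seq = genomes[e.chrom][e.start : e.end]
        L = len(elem_seq)
        for _ in range(plan.tags_per_mite):
            tag_len = int(rng.choice(lengths, p=probs))
            if tag_len >= L:
                continue
            span = L - tag_len
            if rng.random() < p_terminal:
                u = rng.random() * 0.2
                u = u if u < 0.1 else u + 0.8  # bands [0, 0.1) and [0.9, 1.0)
            else:
                u = 0.1 + rng.random() * 0.8  # middle band (exclusive mixture)
            start = int(round(u * span))
            emit(elem_seq[start : start + tag_len], e.element_id, start)

    # background tags from non-MITE sequence
    occupied = {c: IntervalTree() for c in genomes}
    for e in mites:
        occupied[e.chrom].addi(e.start, e.end)
    chroms = sorted(genomes)
    weights = np.array([len(genomes[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    emitted = 0
    attempts = 0
    while emitted < plan.background_tags and attempts < plan.background_tags * 20:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        tag_len = int(rng.choice(lengths, p=probs))
        limit = len(genomes[chrom]) - tag_len
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if occupied[chrom].overlap(start, start + tag_len):
            continue
        emit(genomes[chrom][start : start + tag_len], None, None)
        emitted += 1

    tags = list(collapsed.values())
    truth.tags = tags
    return tags


def simulate_ltr_pairs(
    n: int,
    half_life_my: float = 1.8,
    ltr_length: int = 1500,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    gc: float = 0.38,
) -> list[tuple[float, str, str]]:
    """Simulate aged 5'/3' LTR pairs for dating-pipeline validation.

    Ages are exponential with the stated half-life (My); each pair starts
    identical and accumulates Binomial(L, p) substitutions at distinct
    sites, with p set from the age via the inverse Jukes-Cantor transform
    and k = 2 r T.  Returns (true_age_my, ltr5, ltr3) triples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t_my = float(rng.exponential(half_life_my / math.log(2)))
        k = 2.0 * rate * t_my * 1e6
        p = min(_inverse_jc(k), 0.70)
        seed_arr = _random_seq(rng, ltr_length, gc)
        n_mut = int(rng.binomial(ltr_length, p))
        sites = (
            rng.choice(ltr_length, size=n_mut, replace=False) if n_mut else np.array([], int)
        )
        a, b = seed_arr.copy(), seed_arr.copy()
        for s in sites:
            target = a if rng.random() < 0.5 else b
            target[s] = (target[s] + rng.integers(1, 4)) % 4
        out.append((t_my, _to_str(a), _to_str(b)))
    return out


def write_srna_tsv(tags: Sequence[PlantedTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for t in tags:
            fh.write(f"{t.sequence}\t{t.count}\n")


__all__ = [
    "SynthConfig",
    "MiteFamilyPlan",
    "LtrFamilyPlan",
    "SrnaPlan",
    "SynthError",
    "TruthTable",
    "PlantedElement",
    "PlantedTag",
    "generate_genome",
    "generate_pair",
    "generate_srna",
    "simulate_ltr_pairs",
    "write_srna_tsv",
    "make_trnas",
]
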