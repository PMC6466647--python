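"""Structural detection and validation of LTR retrotransposons.

A complete element is a pair of direct long terminal repeats (each starting
TG and ending CA) enclosing an internal region that carries a primer
binding site (PBS, complementary to a tRNA 3' end, just downstream of the
5' LTR) and a polypurine tract (PPT, just upstream of the 3' LTR), flanked
by an exact 4-6 bp target-site duplication.  Candidates come from a
transparent repeat-pair scanner (exact k-mer seeds grouped by separation
and chained per diagonal), replacing heuristic LTR finders with a testable
rule set: repeats >= 100 bp at >= 80% identity separated by a 1-15 kb
internal region.

Solo-LTRs are homology hits to family LTRs with exact 4-6 bp TSD flanks
that do not overlap any complete element; families cluster on LTR sequence
alone at 75% identity so completes and solos cluster together.  Superfamily
is assigned by a flagged length proxy (Copia-like < 8 kb <= Gypsy-like)
unless an override table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import KmerIndex, encode, global_identity, kmer_codes, resolve_overlaps, scan_homology
from .seqio import FeatureInterval, GenomeRecord, revcomp

MIN_LTR_LEN = 100
MIN_LTR_PAIR_IDENTITY = 0.80
MIN_INTERNAL = 1000
MAX_INTERNAL = 15_000
TSD_LENGTHS = (6, 5, 4)  # longest qualifying wins
SNAP_BP = 15
PBS_MIN = 12
PBS_MAX_MISMATCH = 1
PBS_WINDOW = 20
PPT_MIN = 10
PPT_WINDOW = 20
PPT_PURINE_FRACTION = 0.80
FAMILY_IDENTITY = 0.75
SOLO_MIN_IDENTITY = 0.75
SOLO_MIN_COVERAGE = 0.80
LENGTH_PROXY_SPLIT = 8000


class ConfigurationError(ValueError):
    pass


@dataclass
class LtrCandidate:
    chrom: str
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    identity: float

    @property
    def start(self) -> int:
        return self.ltr5_start

    @property
    def end(self) -> int:
        return self.ltr3_end


@dataclass
class LtrElement:
    """A validated complete LTR retrotransposon."""

    location: FeatureInterval
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    internal: tuple[int, int]
    tsd: str
    pbs_found: bool
    ppt_found: bool
    ltr5_seq: str
    ltr3_seq: str
    family_id: str = ""
    superfamily: str = "unknown"
    superfamily_is_proxy: bool = True
    ltr_pair_p: float = 0.0
    insertion_time: float | None = None  # years

    @property
    def ltr_length(self) -> float:
        return ((self.ltr5[1] - self.ltr5[0]) + (self.ltr3[1] - self.ltr3[0])) / 2

    @property
    def internal_length(self) -> int:
        return self.internal[1] - self.internal[0]

    @property
    def total_length(self) -> int:
        return self.location.end - self.location.start


@dataclass
class SoloLtr:
    location: FeatureInterval
    tsd: str
    sequence: str
    family_id: str = ""
    identity_to_family_ltr: float = 0.0


@dataclass
class LtrFamily:
    family_id: str
    superfamily: str
    representative_ltr: str
    complete_members: list[LtrElement] = field(default_factory=list)
    solo_members: list[SoloLtr] = field(default_factory=list)

    @property
    def s_over_c(self) -> float | None:
        if not self.complete_members:
            return None
        return len(self.solo_members) / len(self.complete_members)


@dataclass
class Rejection:
    reason: str  # no_tg_ca | no_tsd | no_pbs | no_ppt | bad_geometry


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def detect_ltr_candidates(
    genome: GenomeRecord,
    k: int = 16,
    min_ltr: int = MIN_LTR_LEN,
    min_internal: int = MIN_INTERNAL,
    max_internal: int = MAX_INTERNAL,
    min_seeds: int = 2,
) -> list[LtrCandidate]:
    """Direct-repeat pairs >= 100 bp at >= 80% identity separated by 1-15 kb.

    Exact k-mers occurring twice within the admissible separation range are
    grouped by separation (substitution-only divergence keeps the diagonal
    exact); each seed group is extended ungapped in both directions under
    +1/-1 scoring with an X-drop of 6; boundary refinement happens at
    validation (TG..CA snap within +-15 bp plus the exact-TSD requirement).
    """
    seq = genome.sequence
    enc = encode(seq)
    n = len(seq)
    codes = kmer_codes(seq, k)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    # group seed pairs by (separation); collect position lists per separation
    by_sep: dict[int, list[int]] = {}
    max_sep = max_internal + max_internal // 2 + min_ltr  # generous upper bound
    min_sep = min_internal  # separation >= internal length
    start = 0
    m = len(sorted_codes)
    while start < m:
        end = start + 1
        while end < m and sorted_codes[end] == sorted_codes[start]:
            end += 1
        if sorted_codes[start] >= 0 and 1 < end - start <= 50:
            pos = np.sort(order[start:end])
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    sep = int(pos[j] - pos[i])
                    if sep > max_sep:
                        break
                    if sep >= min_sep:
                        by_sep.setdefault(sep, []).append(int(pos[i]))
        start = end

    candidates: list[LtrCandidate] = []
    for sep, positions in sorted(by_sep.items()):
        positions.sort()
        # chain seeds on the same diagonal into clusters
        clusters: list[list[int]] = []
        for p in positions:
            if clusters and p - clusters[-1][-1] <= 2 * min_ltr:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cluster in clusters:
            if len(cluster) < min_seeds:
                continue
            lo, hi = cluster[0], cluster[-1] + k
            # ungapped X-drop extension of the repeat pair
            s1, e1 = _extend_pair(enc, lo, hi, sep, n)
            length = e1 - s1
            if length < min_ltr:
                continue
            internal_len = sep - length
            if not (min_internal <= internal_len <= max_internal):
                continue
            a = enc[s1:e1]
            b = enc[s1 + sep : e1 + sep]
            ident = float(np.count_nonzero(a == b)) / length
            if ident < MIN_LTR_PAIR_IDENTITY:
                continue
            candidates.append(
                LtrCandidate(genome.name, s1, e1, s1 + sep, e1 + sep, ident)
            )
    # drop exact duplicates only; overlap resolution happens after
    # structural validation so a spurious cross-element repeat pair cannot
    # shadow the true elements it spans
    seen: set[tuple[int, int, int]] = set()
    unique = []
    for c in candidates:
        key = (c.ltr5_start, c.ltr5_end, c.ltr3_start)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


@dataclass(frozen=True)
class _Cand:
    start: int
    end: int
    identity: float
    matches: int
    cand: LtrCandidate


def _extend_pair(
    enc: np.ndarray, lo: int, hi: int, sep: int, n: int, xdrop: int = 6
) -> tuple[int, int]:
    """Extend a seeded repeat pair outward under +1/-1 with an X-drop."""
    # left
    best, score, best_pos = 0, 0, lo
    i = lo - 1
    while i >= 0 and i + sep < n and best - score <= xdrop:
        score += 1 if enc[i] == enc[i + sep] else -1
        if score > best:
            best, best_pos = score, i
        i -= 1
    s = best_pos
    # right
    best, score, best_pos = 0, 0, hi
    i = hi
    while i + sep < n and best - score <= xdrop:
        score += 1 if enc[i] == enc[i + sep] else -1
        if score > best:
            best, best_pos = score, i + 1
        i += 1
    return s, best_pos


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _find_tg_ca_offsets(seq: str, pos: int, want: str, span: int = SNAP_BP):
    """Offsets d (|d| <= span, by increasing |d|) where the dinucleotide at
    pos+d is ``want`` ('TG' at a start, 'CA' ending at pos+d)."""
    for d in sorted(range(-span, span + 1), key=lambda x: (abs(x), x)):
        if want == "TG":
            if 0 <= pos + d and seq[pos + d : pos + d + 2] == "TG":
                yield d
        else:
            if pos + d <= len(seq) and seq[pos + d - 2 : pos + d] == "CA":
                yield d


def _exact_tsd(seq: str, start: int, end: int) -> str | None:
    for L in TSD_LENGTHS:
        if start - L >= 0 and end + L <= len(seq):
            if seq[start - L : start] == seq[end : end + L]:
                return seq[start - L : start]
    return None


def find_pbs(seq: str, ltr5_end: int, trnas: list[str]) -> bool:
    """PBS: >= 12 bp complementary to the 3' end of any tRNA (<= 1 mismatch)
    starting within 20 bp downstream of the 5' LTR."""
    for trna in trnas:
        probe = revcomp(trna[-PBS_MIN:])
        penc = encode(probe)
        for off in range(0, PBS_WINDOW + 1):
            window = seq[ltr5_end + off : ltr5_end + off + PBS_MIN]
            if len(window) < PBS_MIN:
                break
            if int(np.count_nonzero(encode(window) != penc)) <= PBS_MAX_MISMATCH:
                return True
    return False


def find_ppt(seq: str, ltr3_start: int) -> bool:
    """PPT: a >= 10 bp window with >= 80% purines ending within 20 bp
    upstream of the 3' LTR."""
    region_start = max(0, ltr3_start - PPT_WINDOW - PPT_MIN)
    region = seq[region_start:ltr3_start]
    if len(region) < PPT_MIN:
        return False
    enc = encode(region)
    purine = (enc == 0) | (enc == 2)  # A or G
    for s in range(0, len(region) - PPT_MIN + 1):
        if purine[s : s + PPT_MIN].mean() >= PPT_PURINE_FRACTION:
            return True
    return False


def validate_ltr(
    candidate: LtrCandidate, genome: GenomeRecord, trnas: list[str]
) -> LtrElement | Rejection:
    """Snap boundaries to TG..CA within +-10 bp, then require an exact
    4-6 bp TSD, a PBS and a PPT."""
    if not trnas:
        raise ConfigurationError("PBS check impossible without a tRNA set")
    seq = genome.sequence
    sep = candidate.ltr3_start - candidate.ltr5_start
    found = None
    for ds in _find_tg_ca_offsets(seq, candidate.ltr5_start, "TG"):
        s5 = candidate.ltr5_start + ds
        s3 = s5 + sep
        if seq[s3 : s3 + 2] != "TG":
            continue
        for de in _find_tg_ca_offsets(seq, candidate.ltr5_end, "CA"):
            e5 = candidate.ltr5_end + de
            e3 = e5 + sep
            if e5 - s5 < MIN_LTR_LEN or e3 > len(seq):
                continue
            if seq[e3 - 2 : e3] != "CA":
                continue
            tsd = _exact_tsd(seq, s5, e3)
            if tsd is None:
                continue
            found = (s5, e5, s3, e3, tsd)
            break
        if found:
            break
    if found is None:
        # distinguish the rejection: TG..CA geometry vs missing TSD
        has_geometry = False
        for ds in _find_tg_ca_offsets(seq, candidate.ltr5_start, "TG"):
            s5 = candidate.ltr5_start + ds
            if seq[s5 + sep : s5 + sep + 2] == "TG":
                for de in _find_tg_ca_offsets(seq, candidate.ltr5_end, "CA"):
                    e5 = candidate.ltr5_end + de
                    if seq[e5 + sep - 2 : e5 + sep] == "CA" and e5 - s5 >= MIN_LTR_LEN:
                        has_geometry = True
                        break
            if has_geometry:
                break
        return Rejection("no_tsd" if has_geometry else "no_tg_ca")
    s5, e5, s3, e3, tsd = found
    internal = (e5, s3)
    if internal[1] - internal[0] < MIN_INTERNAL:
        return Rejection("bad_geometry")
    if not find_pbs(seq, e5, trnas):
        return Rejection("no_pbs")
    if not find_ppt(seq, s3):
        return Rejection("no_ppt")
    ltr5_seq = seq[s5:e5]
    ltr3_seq = seq[s3:e3]
    ea, eb = encode(ltr5_seq), encode(ltr3_seq)
    p = float(np.count_nonzero(ea != eb)) / len(ea)
    return LtrElement(
        location=FeatureInterval(genome.name, s5, e3, "+", "repeat_region"),
        ltr5=(s5, e5),
        ltr3=(s3, e3),
        internal=internal,
        tsd=tsd,
        pbs_found=True,
        ppt_found=True,
        ltr5_seq=ltr5_seq,
        ltr3_seq=ltr3_seq,
        ltr_pair_p=p,
    )


def detect_and_validate(
    genome: GenomeRecord, trnas: list[str], **kwargs
) -> list[LtrElement]:
    """Detect candidates, validate them structurally, then resolve overlaps
    among the survivors (higher LTR-pair identity wins)."""
    validated = []
    for cand in detect_ltr_candidates(genome, **kwargs):
        res = validate_ltr(cand, genome, trnas)
        if isinstance(res, LtrElement):
            validated.append(res)
    resolved = resolve_overlaps(
        [
            _Validated(e.location.start, e.location.end, 1.0 - e.ltr_pair_p,
                       int(e.ltr_length), e)
            for e in validated
        ]
    )
    return [r.element for r in resolved]


@dataclass(frozen=True)
class _Validated:
    start: int
    end: int
    identity: float
    matches: int
    element: LtrElement


# ---------------------------------------------------------------------------
# superfamily proxy and clustering
# ---------------------------------------------------------------------------

def classify_superfamily_by_length(element: LtrElement) -> str:
    """Length-proxy call: total length < 8 kb -> Copia-like, >= 8 kb ->
    Gypsy-like (flagged as proxy; an override table supersedes this)."""
    return "Copia" if element.total_length < LENGTH_PROXY_SPLIT else "Gypsy"


def cluster_ltr_families(
    completes: list[LtrElement],
    solos: list[SoloLtr] | None = None,
    identity_threshold: float = FAMILY_IDENTITY,
    superfamily_override: dict[str, str] | None = None,
) -> list[LtrFamily]:
    """Greedy centroid clustering on LTR sequences at 75% identity.

    Complete elements contribute their 5' LTR, solos their whole sequence,
    so both cluster together.  Ids are RLC/RLG (Copia/Gypsy) or RLX with
    ordinals by descending family size.
    """
    solos = solos or []
    items: list[tuple[str, object]] = [(e.ltr5_seq, e) for e in completes]
    items += [(s.sequence, s) for s in solos]
    items.sort(key=lambda t: (-len(t[0]), t[0]))
    families: list[LtrFamily] = []
    for seq, obj in items:
        placed = None
        for fam in families:
            if global_identity(seq, fam.representative_ltr) >= identity_threshold:
                placed = fam
                break
        if placed is None:
            placed = LtrFamily("", "unknown", seq)
            families.append(placed)
        if isinstance(obj, LtrElement):
            placed.complete_members.append(obj)
            obj.family_id = ""  # assigned below
        else:
            placed.solo_members.append(obj)
        if isinstance(obj, SoloLtr):
            obj.identity_to_family_ltr = global_identity(seq, placed.representative_ltr)

    # superfamily per family: majority of length-proxy calls on completes
    for fam in families:
        calls = [classify_superfamily_by_length(e) for e in fam.complete_members]
        if calls:
            fam.superfamily = max(("Copia", "Gypsy"), key=calls.count)
    prefix_of = {"Copia": "RLC", "Gypsy": "RLG", "unknown": "RLX"}
    counters: dict[str, int] = {}
    ordered = sorted(
        families,
        key=lambda f: (-(len(f.complete_members) + len(f.solo_members)), f.representative_ltr),
    )
    for fam in ordered:
        prefix = prefix_of[fam.superfamily]
        counters[prefix] = counters.get(prefix, 0) + 1
        fam.family_id = f"{prefix}{counters[prefix]}"
        if superfamily_override and fam.family_id in superfamily_override:
            fam.superfamily = superfamily_override[fam.family_id]
        for e in fam.complete_members:
            e.family_id = fam.family_id
            e.superfamily = fam.superfamily
        for s in fam.solo_members:
            s.family_id = fam.family_id
    return sorted(families, key=lambda f: f.family_id)


# ---------------------------------------------------------------------------
# solo-LTR detection
# ---------------------------------------------------------------------------

def detect_solo_ltrs(
    genome: GenomeRecord,
    families: list[LtrFamily],
    completes: list[LtrElement],
    min_identity: float = SOLO_MIN_IDENTITY,
    min_coverage: float = SOLO_MIN_COVERAGE,
) -> list[SoloLtr]:
    """Homology hits to family LTR representatives with exact 4-6 bp TSD
    flanks, never overlapping a reported complete element."""
    seq = genome.sequence
    index = KmerIndex(seq, 12)
    complete_spans = [
        (e.location.start, e.location.end)
        for e in completes
        if e.location.chrom == genome.name
    ]
    hits = []
    for fam in families:
        rep = fam.representative_ltr
        for h in scan_homology(
            seq, rep, k=12, min_identity=min_identity,
            min_length=max(MIN_LTR_LEN, int(len(rep) * min_coverage)), index=index,
        ):
            if (h.q_end - h.q_start) / len(rep) < min_coverage:
                continue
            if any(h.start < e and s < h.end for s, e in complete_spans):
                continue
            hits.append((h, fam))
    resolved = resolve_overlaps([_SoloHit(h.start, h.end, h.identity, h.matches, fam) for h, fam in hits])
    out = []
    for r in resolved:
        start, end = r.start, r.end
        snapped = _snap_solo(seq, start, end)
        if snapped is None:
            continue
        start, end, tsd = snapped
        if any(start < e and s < end for s, e in complete_spans):
            continue
        out.append(
            SoloLtr(
                location=FeatureInterval(genome.name, start, end, "+", "repeat_region"),
                tsd=tsd,
                sequence=seq[start:end],
                family_id=r.family.family_id,
                identity_to_family_ltr=r.identity,
            )
        )
    return out


@dataclass(frozen=True)
class _SoloHit:
    start: int
    end: int
    identity: float
    matches: int
    family: LtrFamily


def _snap_solo(seq: str, start: int, end: int) -> tuple[int, int, str] | None:
    """Adjust boundaries within +-10 bp to find TG..CA termini with an exact
    4-6 bp TSD; fall back to a TSD at the raw boundaries."""
    for ds in sorted(range(-SNAP_BP, SNAP_BP + 1), key=abs):
        s = start + ds
        if s < 0 or seq[s : s + 2] != "TG":
            continue
        for de in sorted(range(-SNAP_BP, SNAP_BP + 1), key=abs):
            e = end + de
            if e > len(seq) or seq[e - 2 : e] != "CA":
                continue
            tsd = _exact_tsd(seq, s, e)
            if tsd is not None:
                return s, e, tsd
    tsd = _exact_tsd(seq, start, end)
    if tsd is not None:
        return start, end, tsd
    return None


__all__ = [
    "LtrCandidate",
    "LtrElement",
    "SoloLtr",
    "LtrFamily",
    "Rejection",
    "ConfigurationError",
    "detect_ltr_candidates",
    "validate_ltr",
    "detect_and_validate",
    "cluster_ltr_families",
    "detect_solo_ltrs",
    "classify_superfamily_by_length",
    "find_pbs",
    "find_ppt",
]
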