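"""Shared alignment and k-mer machinery (private).

Global alignment uses Biopython's PairwiseAligner with the package-wide
scoring (match +1, mismatch -1, gap -2, linear).  For equal-length sequences
the gapless alignment is provably optimal under this scoring (an inserted
ins+del pair costs -4, strictly worse than the mismatch -1 it replaces), so a
vectorised Hamming comparison is used on that path.

Homology scanning is exact k-mer seeding on an encoded genome followed by
ungapped maximal-segment evaluation on each seed diagonal (Kadane with
match +1 / mismatch -1).  The synthetic mutation model is substitution-only,
for which the ungapped diagonal is the optimal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

MATCH, MISMATCH, GAP = 1, -1, -2

_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC_TABLE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3; anything else -> 4."""
    return _ENC_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP
    aligner.extend_gap_score = GAP
    return aligner


_ALIGNER = make_aligner()


def align_columns(a: str, b: str) -> tuple[int, int, int]:
    """Return (match, mismatch, gap) column counts of the optimal global
    alignment of ``a`` and ``b`` under the package scoring.

    Deterministic: Biopython returns alignments in a fixed order; the first
    optimal alignment is used.
    """
    if len(a) == len(b):
        ea, eb = encode(a), encode(b)
        mism = int(np.count_nonzero(ea != eb))
        return len(a) - mism, mism, 0
    aln = _ALIGNER.align(a, b)[0]
    match = mism = 0
    aligned_a = aligned_b = 0
    for (sa, ea_), (sb, eb_) in zip(*aln.aligned):
        xa = encode(a[sa:ea_])
        xb = encode(b[sb:eb_])
        m = int(np.count_nonzero(xa == xb))
        match += m
        mism += len(xa) - m
        aligned_a += ea_ - sa
        aligned_b += eb_ - sb
    gaps = (len(a) - aligned_a) + (len(b) - aligned_b)
    return match, mism, gaps


def global_identity(a: str, b: str) -> float:
    """Matching columns / alignment length under global alignment."""
    match, mism, gaps = align_columns(a, b)
    total = match + mism + gaps
    return match / total if total else 0.0


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact-match k-mer index over one sequence (k <= 31)."""

    def __init__(self, seq: str, k: int):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        self.enc = encode(seq)
        n = len(self.enc)
        m = n - k + 1
        if m <= 0:
            self._codes = np.empty(0, dtype=np.int64)
            self._order = np.empty(0, dtype=np.int64)
            self._sorted = np.empty(0, dtype=np.int64)
            return
        codes = np.zeros(m, dtype=np.int64)
        for j in range(k):
            codes = codes * 4 + self.enc[j : j + m]
        # windows containing N are invalidated
        bad = (self.enc >= 4).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(bad)])
        n_bad = cs[k:] - cs[:-k]
        codes[n_bad > 0] = -1
        self._codes = codes
        self._order = np.argsort(codes, kind="stable").astype(np.int64)
        self._sorted = codes[self._order]

    def positions(self, kmer: str) -> np.ndarray:
        """All start positions of an exact occurrence of ``kmer``."""
        e = encode(kmer)
        if len(e) != self.k or (e >= 4).any():
            return np.empty(0, dtype=np.int64)
        code = 0
        for v in e:
            code = code * 4 + int(v)
        lo = np.searchsorted(self._sorted, code, side="left")
        hi = np.searchsorted(self._sorted, code, side="right")
        return np.sort(self._order[lo:hi])

    def code_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted, code, side="left")
        hi = np.searchsorted(self._sorted, code, side="right")
        return np.sort(self._order[lo:hi])


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Rolling k-mer codes of ``seq`` (-1 where the window contains non-ACGT)."""
    enc = encode(seq)
    m = len(enc) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + m]
    bad = (enc >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    codes[(cs[k:] - cs[:-k]) > 0] = -1
    return codes


# ---------------------------------------------------------------------------
# ungapped seed-and-extend homology scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    """An ungapped homology segment of a query on a genome."""

    start: int          # genome, 0-based half-open
    end: int
    q_start: int        # query coordinates of the matched segment
    q_end: int
    strand: str
    identity: float
    matches: int

    @property
    def score(self) -> int:
        return 2 * self.matches - (self.end - self.start)

    def __len__(self) -> int:
        return self.end - self.start


def _best_segment(eq: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment of a boolean match array under
    +1/-1 scoring (Kadane).  Returns (start, end, matches); ties resolve to
    the leftmost, longest segment."""
    score = np.where(eq, 1, -1).astype(np.int64)
    best = run = 0
    best_s = best_e = cur_s = 0
    for i, s in enumerate(score):
        if run <= 0:
            run = 0
            cur_s = i
        run += s
        if run > best:
            best = run
            best_s, best_e = cur_s, i + 1
    if best <= 0:
        return 0, 0, 0
    matches = int(np.count_nonzero(eq[best_s:best_e]))
    return best_s, best_e, matches


def scan_homology(
    genome_seq: str,
    query: str,
    *,
    k: int = 12,
    min_identity: float = 0.80,
    min_length: int = 30,
    index: KmerIndex | None = None,
) -> list[HomologyHit]:
    """Find ungapped homology hits of ``query`` (both strands) on a genome.

    Seeds are exact k-mers; each seed diagonal is evaluated by maximal-segment
    scoring.  Hits below ``min_identity`` or shorter than ``min_length`` are
    dropped.  Overlapping hits on the same diagonal collapse naturally; hits
    across strands/diagonals are returned unresolved (callers pick winners).
    """
    from .seqio import revcomp

    if index is None:
        index = KmerIndex(genome_seq, k)
    genc = index.enc
    n = len(genc)
    hits: list[HomologyHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        m = len(q)
        if m < k:
            continue
        qcodes = kmer_codes(q, k)
        diagonals: set[int] = set()
        step = max(1, k // 3)
        for qpos in range(0, len(qcodes), step):
            code = qcodes[qpos]
            if code < 0:
                continue
            for gpos in index.code_positions(int(code)):
                diagonals.add(int(gpos) - qpos)
        qenc = encode(q)
        seen: set[tuple[int, int]] = set()
        for d in sorted(diagonals):
            g_lo = max(0, d)
            g_hi = min(n, d + m)
            if g_hi - g_lo < min_length:
                continue
            q_lo = g_lo - d
            eq = genc[g_lo:g_hi] == qenc[q_lo : q_lo + (g_hi - g_lo)]
            s, e, matches = _best_segment(eq)
            length = e - s
            if length < min_length:
                continue
            identity = matches / length
            if identity < min_identity:
                continue
            g_start, g_end = g_lo + s, g_lo + e
            key = (g_start, g_end)
            if key in seen:
                continue
            seen.add(key)
            q_start = q_lo + s
            q_end = q_lo + e
            if strand == "-":
                q_start, q_end = m - q_end, m - q_start
            hits.append(
                HomologyHit(g_start, g_end, q_start, q_end, strand, identity, matches)
            )
    return hits


def resolve_overlaps(hits: list, key=None) -> list:
    """Greedy non-overlap resolution keeping the better hit first.

    ``key`` maps a hit to a sort key (default: identity, then matches); ties
    resolve by genome coordinate for determinism.
    """
    if key is None:
        key = lambda h: (h.identity, h.matches)
    ordered = sorted(hits, key=lambda h: (tuple(-x for x in key(h)), h.start, h.end))
    kept: list = []
    occupied: list[tuple[int, int]] = []
    for h in ordered:
        if any(h.start < e and s < h.end for s, e in occupied):
            continue
        kept.append(h)
        occupied.append((h.start, h.end))
    return sorted(kept, key=lambda h: h.start)


def count_mismatches(a: str, b: str) -> int:
    """Hamming mismatches between equal-length strings (N never matches)."""
    ea, eb = encode(a), encode(b)
    return int(np.count_nonzero((ea != eb) | (ea >= 4)))
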