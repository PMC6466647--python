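"""Divergence, Jukes-Cantor dating, modality profiles and NJ trees.

The dating convention follows the molecular-clock arithmetic used for plant
transposable elements: observed proportion of differing sites p is corrected
to k = -(3/4) ln(1 - 4p/3) (JC69) and converted to years by T = k / (2 r)
with a per-lineage substitution rate r (default 5.62e-9 substitutions per
site per year, i.e. twice a coding-region rate of 2.81e-9).  Family
amplification time is taken directly from the mean pairwise divergence of
full-length members, a deliberate convention (pairwise, not pair-to-root).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ._align import align_columns

JC_SATURATION = 0.75


class SaturationError(ValueError):
    """Observed divergence at or beyond the JC69 domain boundary (p >= 0.75)."""


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class DatingConfig:
    """Substitution-rate configuration.

    ``coding_rate`` is a per-year synonymous-site rate in coding sequence;
    the non-coding rate used for dating is twice that.
    """

    coding_rate: float = 2.81e-9

    @property
    def rate(self) -> float:
        return 2.0 * self.coding_rate


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing ungapped columns under global alignment.

    Gapped columns contribute to neither numerator nor denominator.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    match, mism, _gaps = align_columns(seq_a, seq_b)
    total = match + mism
    if total == 0:
        raise SaturationError("no ungapped columns; distance undefined")
    return mism / total


def jc_correct(p: float) -> float:
    """Jukes-Cantor corrected distance k = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= JC_SATURATION:
        raise SaturationError(f"p = {p} >= 0.75: JC distance undefined (saturation)")
    # log1p keeps k >= p down to subnormal p
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def date_from_k(k: float, config: DatingConfig | None = None) -> float:
    """Age in years from a divergence k: T = k / (2 r)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    config = config or DatingConfig()
    return k / (2.0 * config.rate)


# ---------------------------------------------------------------------------
# divergence profiles
# ---------------------------------------------------------------------------

@dataclass
class DivergenceProfile:
    family_id: str
    k_values: np.ndarray
    mean_k: float
    histogram: np.ndarray  # counts per 0.02 bin over [0, 1.5]
    bin_edges: np.ndarray
    modality: str  # unimodal | multimodal
    peak_positions: list[float] = field(default_factory=list)


HIST_BIN = 0.02
HIST_MAX = 1.5
PEAK_FLOOR = 0.05  # of pair count
SMOOTH_WINDOW = 3


def _find_peaks(smoothed: np.ndarray, floor: float) -> list[int]:
    peaks = []
    n = len(smoothed)
    for i in range(n):
        v = smoothed[i]
        if v < floor or v <= 0:
            continue
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[i + 1] if i < n - 1 else -np.inf
        if v > left and v >= right:  # plateau ties resolve leftward
            peaks.append(i)
    return peaks


def divergence_profile(
    members: list[str], family_id: str = "", max_pairs: int | None = None, seed: int = 0
) -> DivergenceProfile:
    """Pairwise JC distances among full-length members with a smoothed
    histogram (0.02 bins), peak calling (local maxima at >= 5% of the pair
    count after 3-bin moving-average smoothing) and a modality call.

    ``max_pairs``, if given, subsamples pairs deterministically for large
    families.
    """
    if len(members) < 2:
        raise InsufficientDataError("divergence profile needs >= 2 members")
    pairs = list(itertools.combinations(range(len(members)), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    ks = []
    for i, j in pairs:
        p = p_distance(members[i], members[j])
        if p < JC_SATURATION:
            ks.append(jc_correct(p))
    if not ks:
        raise SaturationError("all pairs saturated")
    ks = np.array(ks)
    edges = np.arange(0.0, HIST_MAX + HIST_BIN, HIST_BIN)
    hist, _ = np.histogram(np.clip(ks, 0, HIST_MAX - 1e-9), bins=edges)
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    smoothed = np.convolve(hist, kernel, mode="same")
    floor = PEAK_FLOOR * len(ks)
    peak_idx = _find_peaks(smoothed, floor)
    if not peak_idx:  # degenerate spread: fall back to the tallest bin
        peak_idx = [int(np.argmax(smoothed))]
    centers = (edges[:-1] + edges[1:]) / 2
    return DivergenceProfile(
        family_id=family_id,
        k_values=ks,
        mean_k=float(ks.mean()),
        histogram=hist,
        bin_edges=edges,
        modality="unimodal" if len(peak_idx) == 1 else "multimodal",
        peak_positions=[float(centers[i]) for i in peak_idx],
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name or ""
        inner = ",".join(
            f"{child._newick()}:{length:.6f}" for child, length in self.children
        )
        return f"({inner}){self.name or ''}"

    def edges(self) -> list[tuple[float, bool]]:
        """All (length, is_terminal) edges below this node."""
        out = []
        for child, length in self.children:
            out.append((length, child.is_leaf()))
            out.extend(child.edges())
        return out


def nj_tree(distance_matrix: np.ndarray, names: list[str]) -> TreeNode:
    """Neighbor-joining with the deterministic lowest-index-pair tie-break.

    Input must be symmetric with a zero diagonal; the result is an unrooted
    tree represented with a trifurcating (or, for n = 2, single-edge) root.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2 or len(names) != n:
        raise ValueError("need >= 2 taxa and matching names")
    nodes = [TreeNode(name) for name in names]
    active = list(range(n))
    dm = d.copy()
    while len(active) > 2:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest joint index pair among minima
        flat = np.flatnonzero(np.isclose(q, q.min(), rtol=0, atol=1e-12))
        i_loc, j_loc = sorted(divmod(int(flat[0]), m))
        i, j = active[i_loc], active[j_loc]
        dij = dm[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        new_row = 0.5 * (dm[i, :] + dm[j, :] - dij)
        dm = np.vstack([dm, new_row])
        new_col = np.append(new_row, 0.0)
        dm = np.column_stack([dm, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j = active
    dij = dm[i, j]
    if nodes[j].is_leaf() and not nodes[i].is_leaf():
        i, j = j, i
    root = nodes[j]
    if root.is_leaf():  # two-taxon case: single edge split in half
        root = TreeNode()
        root.children = [(nodes[i], dij / 2), (nodes[j], dij / 2)]
    else:
        root.children.append((nodes[i], dij))
    return root


def star_shape_score(tree: TreeNode) -> float:
    """Internal-branch length sum over total branch length.

    Near-zero values indicate a star-like (single-burst) amplification.
    Negative NJ branch lengths are clamped to zero for the ratio.
    """
    edges = tree.edges()
    total = sum(max(length, 0.0) for length, _ in edges)
    internal = sum(max(length, 0.0) for length, term in edges if not term)
    return internal / total if total > 0 else 0.0


def family_distance_matrix(members: list[str]) -> np.ndarray:
    """Pairwise JC distance matrix for a family's member sequences."""
    n = len(members)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = jc_correct(p_distance(members[i], members[j]))
    return dm


__all__ = [
    "DatingConfig",
    "DivergenceProfile",
    "SaturationError",
    "InsufficientDataError",
    "TreeNode",
    "p_distance",
    "jc_correct",
    "date_from_k",
    "divergence_profile",
    "nj_tree",
    "star_shape_score",
    "family_distance_matrix",
]
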