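"""LTR retrotransposon insertion/elimination dynamics.

At insertion the two LTRs of an element are identical; their subsequent
divergence dates the element: T = k / (2 r), with k the Jukes-Cantor
corrected 5'/3' LTR distance.  The genome-wide age distribution is fitted
with the base-2 exponential decay y = a * 2^(b*x) (counts per age bin),
whose half-life is -1/b directly; the base-2 parameterisation is kept
exactly as is conventional for this decay so the printed initialisation
(a0 = 270, b0 = -0.5) carries over.  Solo-LTR formation is examined through
per-family S/C ratios against candidate drivers (mean insertion time, LTR
length, LTR/internal ratio) with Spearman rank correlations and seeded
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .evodate import DatingConfig, SaturationError, jc_correct, p_distance
from .ltr import LtrElement, LtrFamily

DEFAULT_BIN_MY = 0.5
DEFAULT_INIT = (270.0, -0.5)
MIN_FAMILY_COMPLETES = 10


def insertion_time(element: LtrElement, config: DatingConfig | None = None) -> float:
    """Element age in years from 5'/3' LTR divergence: T = k/(2r).

    Raises SaturationError (element undatable) at p >= 0.75.
    """
    config = config or DatingConfig()
    if min(len(element.ltr5_seq), len(element.ltr3_seq)) < 50:
        raise ValueError("LTRs shorter than 50 bp cannot be dated reliably")
    p = p_distance(element.ltr5_seq, element.ltr3_seq)
    k = jc_correct(p)
    t = k / (2.0 * config.rate)
    element.insertion_time = t
    return t


def date_elements(
    elements: list[LtrElement], config: DatingConfig | None = None
) -> list[float]:
    """Insertion times (years) for all datable elements; saturated elements
    are flagged (insertion_time stays None) and skipped."""
    times = []
    for e in elements:
        try:
            times.append(insertion_time(e, config))
        except SaturationError:
            e.insertion_time = None
    return times


@dataclass
class ExpFit:
    a: float
    b: float  # per My; negative for decay
    rss: float
    bin_width: float
    n_bins: int
    fallback_used: bool = False

    @property
    def half_life(self) -> float | None:
        """Half-life in My: -1/b (defined only for decaying fits)."""
        if self.b >= 0:
            return None
        return -1.0 / self.b


def _decay(x, a, b):
    return a * np.power(2.0, b * x)


def fit_age_distribution(
    times_years: np.ndarray | list[float],
    bin_width: float = DEFAULT_BIN_MY,
    init: tuple[float, float] = DEFAULT_INIT,
) -> ExpFit:
    """Histogram insertion times (My) and fit y = a * 2^(b*x) by nonlinear
    least squares from the stated initialisation.

    x is the bin midpoint in My, y the element count per bin.  If the
    iteration fails to converge the fit falls back to log-linear regression
    on the non-empty bins (flagged).
    """
    t = np.asarray(times_years, dtype=float) / 1e6
    if len(t) < 3:
        raise ValueError("need >= 3 insertion times")
    if np.allclose(t, t[0]):
        raise ValueError("all insertion times identical: degenerate fit")
    n_bins = max(3, int(np.ceil(t.max() / bin_width)))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(t, bins=edges)
    if np.count_nonzero(counts) < 3:
        raise ValueError("need >= 3 non-empty age bins")
    x = (edges[:-1] + edges[1:]) / 2
    y = counts.astype(float)
    try:
        popt, _ = curve_fit(_decay, x, y, p0=init, maxfev=10_000)
        a, b = float(popt[0]), float(popt[1])
        rss = float(np.sum((y - _decay(x, a, b)) ** 2))
        return ExpFit(a, b, rss, bin_width, len(x))
    except RuntimeError:
        nz = counts > 0
        coeffs = np.polyfit(x[nz], np.log2(y[nz]), 1)
        b, log2a = float(coeffs[0]), float(coeffs[1])
        a = float(2.0 ** log2a)
        rss = float(np.sum((y - _decay(x, a, b)) ** 2))
        return ExpFit(a, b, rss, bin_width, len(x), fallback_used=True)


# ---------------------------------------------------------------------------
# per-family dynamics
# ---------------------------------------------------------------------------

@dataclass
class FamilyDynamics:
    family_id: str
    n_complete: int
    n_solo: int
    s_over_c: float
    mean_insertion_time_my: float
    mean_ltr_length: float
    mean_internal_length: float
    ltr_over_internal: float
    excluded: bool  # families with < 10 completes excluded from correlations


def family_dynamics(
    families: list[LtrFamily], config: DatingConfig | None = None
) -> list[FamilyDynamics]:
    """Per-family S/C, mean insertion time (complete members' mean stands in
    for solo ages), mean LTR/internal lengths and their ratio; families with
    fewer than 10 complete members are flagged excluded."""
    config = config or DatingConfig()
    out = []
    for fam in families:
        completes = fam.complete_members
        if not completes:
            continue
        times = []
        for e in completes:
            if e.insertion_time is None:
                try:
                    insertion_time(e, config)
                except (SaturationError, ValueError):
                    continue
            if e.insertion_time is not None:
                times.append(e.insertion_time)
        mean_t = float(np.mean(times)) / 1e6 if times else float("nan")
        mean_ltr = float(np.mean([e.ltr_length for e in completes]))
        mean_int = float(np.mean([e.internal_length for e in completes]))
        out.append(
            FamilyDynamics(
                family_id=fam.family_id,
                n_complete=len(completes),
                n_solo=len(fam.solo_members),
                s_over_c=len(fam.solo_members) / len(completes),
                mean_insertion_time_my=mean_t,
                mean_ltr_length=mean_ltr,
                mean_internal_length=mean_int,
                ltr_over_internal=mean_ltr / mean_int if mean_int else float("nan"),
                excluded=len(completes) < MIN_FAMILY_COMPLETES,
            )
        )
    return out


def dynamics_table(dynamics: list[FamilyDynamics]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in dynamics])


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j < len(sx) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = (i + j - 1) / 2 + 1  # average rank, 1-based
        i = j
    return ranks


def spearman(
    x, y, n_permutations: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman's rho as the Pearson correlation of mid-ranks, with a
    two-sided seeded permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    rx, ry = _midranks(x), _midranks(y)

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = pearson(rx, ry)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        if abs(pearson(rx, perm)) >= abs(rho) - 1e-12:
            extreme += 1
    p_value = (extreme + 1) / (n_permutations + 1)
    return rho, p_value


def solo_formation_correlations(
    dynamics: list[FamilyDynamics], n_permutations: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """S/C against mean insertion time, LTR length and LTR/internal ratio
    over families with >= 10 completes."""
    kept = [d for d in dynamics if not d.excluded and np.isfinite(d.mean_insertion_time_my)]
    rows = []
    sc = np.array([d.s_over_c for d in kept])
    factors = {
        "insertion_time": np.array([d.mean_insertion_time_my for d in kept]),
        "ltr_length": np.array([d.mean_ltr_length for d in kept]),
        "ltr_over_internal": np.array([d.ltr_over_internal for d in kept]),
    }
    for name, values in factors.items():
        if len(kept) < 3:
            rows.append({"factor": name, "rho": float("nan"), "p_value": float("nan")})
            continue
        try:
            rho, p = spearman(values, sc, n_permutations, seed)
        except ValueError:
            rho, p = float("nan"), float("nan")
        rows.append({"factor": name, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


__all__ = [
    "ExpFit",
    "FamilyDynamics",
    "insertion_time",
    "date_elements",
    "fit_age_distribution",
    "family_dynamics",
    "dynamics_table",
    "spearman",
    "solo_formation_correlations",
    "MIN_FAMILY_COMPLETES",
]
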