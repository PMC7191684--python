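"""Between-population hotspot comparisons.

Consensus construction (merged union of all populations' hotspots), the
Boolean sharing matrix, subset counts, pairwise Fisher overlap tests with
bedtools:fisher contingency semantics, Jaccard distances, and the Mantel
test against a differentiation matrix.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeLayout, Interval
from .ratemap import RegressionResult, confound_regression

__all__ = [
    "SharingMatrix",
    "merge_intervals",
    "build_consensus",
    "count_sharing_sets",
    "ubiquitous_hotspots",
    "fisher_overlap",
    "FisherOverlap",
    "jaccard_distance_matrix",
    "mantel_test",
    "MantelResult",
    "hotspot_count_regression",
]

logger = logging.getLogger(__name__)


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge intervals that overlap by >= 1 bp (touching intervals stay
    separate)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # >= 1 bp overlap
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out


def _any_overlap(query: Interval, sorted_by_chrom: dict[str, np.ndarray]) -> bool:
    arr = sorted_by_chrom.get(query.chrom)
    if arr is None or arr.shape[0] == 0:
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    i = int(np.searchsorted(starts, query.end, side="left"))
    return i > 0 and ends[:i].max() > query.start


def _index_by_chrom(intervals: Sequence[Interval]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in by.items()
    }


@dataclass
class SharingMatrix:
    """Consensus intervals plus a Boolean populations x consensus matrix."""

    consensus: list[Interval]
    matrix: pd.DataFrame  # index = populations, columns = consensus labels

    def __post_init__(self) -> None:
        if len(self.consensus) != self.matrix.shape[1]:
            raise ValueError("matrix columns must match consensus intervals")

    @property
    def populations(self) -> list[str]:
        return list(self.matrix.index)

    def presence_counts(self) -> np.ndarray:
        return self.matrix.values.sum(axis=0)


def _consensus_label(iv: Interval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def build_consensus(
    hotspot_sets: Mapping[str, Sequence[Interval]],
) -> SharingMatrix:
    """Merge all populations' hotspots into a consensus and mark presence.

    A population is present at a consensus interval iff one of its hotspots
    overlaps it by >= 1 bp.  Overlap chains merge transitively.
    """
    pops = list(hotspot_sets)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    union = [iv for pop in pops for iv in hotspot_sets[pop]]
    consensus = merge_intervals(union) if union else []
    cols = [_consensus_label(iv) for iv in consensus]
    mat = pd.DataFrame(False, index=pops, columns=cols, dtype=bool)
    cons_idx = _index_by_chrom(consensus)
    # map each consensus interval to its column for lookups
    lookup: dict[tuple[str, int, int], str] = {
        (iv.chrom, iv.start, iv.end): lbl for iv, lbl in zip(consensus, cols)
    }
    for pop in pops:
        for hs in hotspot_sets[pop]:
            arr = cons_idx.get(hs.chrom)
            if arr is None:
                continue
            starts, ends = arr[:, 0], arr[:, 1]
            i0 = int(np.searchsorted(ends, hs.start, side="right"))
            i1 = int(np.searchsorted(starts, hs.end, side="left"))
            for k in range(i0, i1):
                lbl = lookup[(hs.chrom, int(starts[k]), int(ends[k]))]
                mat.loc[pop, lbl] = True
    return SharingMatrix(consensus=consensus, matrix=mat)


@dataclass
class SharingCounts:
    counts: dict[frozenset, int]
    private_fraction: float
    n_consensus: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(sorted(k)), "size": len(k), "count": v}
            for k, v in sorted(
                self.counts.items(), key=lambda kv: -kv[1]
            )
        ]
        return pd.DataFrame(rows)


def count_sharing_sets(sharing: SharingMatrix) -> SharingCounts:
    """Upset-style counts: consensus hotspots per distinct presence pattern."""
    counts: dict[frozenset, int] = {}
    private = 0
    m = sharing.matrix
    for col in m.columns:
        present = frozenset(m.index[m[col]])
        if not present:
            continue
        counts[present] = counts.get(present, 0) + 1
        if len(present) == 1:
            private += 1
    n = len(sharing.consensus)
    return SharingCounts(
        counts=counts,
        private_fraction=private / n if n else float("nan"),
        n_consensus=n,
    )


def ubiquitous_hotspots(
    sharing: SharingMatrix, min_pops: int = 8
) -> list[Interval]:
    """Consensus intervals present in at least ``min_pops`` populations."""
    if min_pops > len(sharing.populations):
        return []
    counts = sharing.presence_counts()
    return [iv for iv, c in zip(sharing.consensus, counts) if c >= min_pops]


# ---------------------------------------------------------------------------
# Fisher overlap (bedtools:fisher semantics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherOverlap:
    n11: int
    n12: int
    n21: int
    n22: int
    p_right: float

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.n11, self.n12), (self.n21, self.n22))


def _count_intersections(a: list[Interval], b: list[Interval]) -> int:
    """Number of >= 1 bp intersection events between two merged sets."""
    b_idx = _index_by_chrom(b)
    n = 0
    for iv in a:
        arr = b_idx.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        i0 = int(np.searchsorted(ends, iv.start, side="right"))
        i1 = int(np.searchsorted(starts, iv.end, side="left"))
        n += max(i1 - i0, 0)
    return n


def hypergeom_right_tail(n11: int, n12: int, n21: int, n22: int) -> float:
    """P(X >= n11) for the 2x2 table's hypergeometric distribution
    (Fisher's exact test, enrichment alternative)."""
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return float(p)


def fisher_overlap(
    hotspots_a: Sequence[Interval],
    hotspots_b: Sequence[Interval],
    layout: GenomeLayout,
) -> FisherOverlap:
    """Right-tailed Fisher's exact test for overlap enrichment of two sets.

    Contingency construction follows the bedtools:fisher genome-bin
    heuristic: the genome is treated as round(G / mean merged-union interval
    length) placeable slots.
    """
    if not hotspots_a or not hotspots_b:
        raise ValueError("both hotspot sets must be non-empty")
    a = merge_intervals(hotspots_a)
    b = merge_intervals(hotspots_b)
    n11 = _count_intersections(a, b)
    n12 = len(a) - n11
    n21 = len(b) - n11
    if n12 < 0 or n21 < 0:
        logger.info("multi-overlap events clamped (n12=%d, n21=%d)", n12, n21)
        n12 = max(n12, 0)
        n21 = max(n21, 0)
    union = merge_intervals(list(a) + list(b))
    mean_len = float(np.mean([iv.length for iv in union]))
    g = layout.total_bp
    n22 = int(round(g / mean_len)) - n11 - n12 - n21
    if n22 < 0:
        logger.info("n22 clamped from %d to 0", n22)
        n22 = 0
    p = hypergeom_right_tail(n11, n12, n21, n22)
    return FisherOverlap(n11=n11, n12=n12, n21=n21, n22=n22, p_right=p)


# ---------------------------------------------------------------------------
# Jaccard + Mantel
# ---------------------------------------------------------------------------

def jaccard_distance_matrix(sharing: "SharingMatrix | pd.DataFrame") -> pd.DataFrame:
    """Pairwise Jaccard distances between Boolean presence rows.

    d(p, q) = 1 - |p AND q| / |p OR q|; two all-false rows get d = 0 with a
    warning.
    """
    m = sharing.matrix if isinstance(sharing, SharingMatrix) else sharing
    m = m.astype(bool)
    pops = list(m.index)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    X = m.values
    d = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, j in itertools.combinations(range(len(pops)), 2):
        union = np.count_nonzero(X[i] | X[j])
        if union == 0:
            warnings.warn(
                f"rows {pops[i]} and {pops[j]} are both empty; distance set "
                "to 0",
                stacklevel=2,
            )
            dist = 0.0
        else:
            inter = np.count_nonzero(X[i] & X[j])
            dist = 1.0 - inter / union
        d.iloc[i, j] = d.iloc[j, i] = dist
    return d


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    exhaustive: bool


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices_from(m, k=-1)]


def mantel_test(
    d1: "pd.DataFrame | np.ndarray",
    d2: "pd.DataFrame | np.ndarray",
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided Mantel test (r >= r_obs) by row/column permutation of d2.

    When n! <= n_perm all permutations are enumerated (p = k / n!);
    otherwise ``n_perm`` seeded random permutations give
    p = (1 + k) / (1 + n_perm).
    """
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if list(d1.index) != list(d2.index):
            d2 = d2.loc[d1.index, d1.index]
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    n = a.shape[0]
    if n < 4:
        raise ValueError("need >= 4 populations for a Mantel test")
    if a.shape != (n, n) or b.shape != (n, n):
        raise ValueError("matrices must be square and aligned")
    va = _lower_triangle(a)
    vb = _lower_triangle(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant distance matrix")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    if math.factorial(n) <= n_perm:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p_idx = np.array(perm)
            r = float(np.corrcoef(va, _lower_triangle(b[np.ix_(p_idx, p_idx)]))[0, 1])
            if r >= r_obs - 1e-12:
                hits += 1
            total += 1
        return MantelResult(r=r_obs, p=hits / total, n_perm=total,
                            exhaustive=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        r = float(np.corrcoef(va, _lower_triangle(b[np.ix_(p_idx, p_idx)]))[0, 1])
        if r >= r_obs - 1e-12:
            hits += 1
    return MantelResult(
        r=r_obs, p=(1.0 + hits) / (1.0 + n_perm), n_perm=n_perm,
        exhaustive=False,
    )


def hotspot_count_regression(
    counts: Mapping[str, int],
    predictors: Mapping[str, Mapping[str, float]],
) -> dict[str, RegressionResult]:
    """Regress per-population hotspot counts on each predictor separately.

    ``predictors`` maps predictor name -> {population: value}.
    """
    pops = list(counts)
    y = np.array([counts[p] for p in pops], dtype=float)
    out = {}
    for name, values in predictors.items():
        x = np.array([values[p] for p in pops], dtype=float)
        out[name] = confound_regression(y, x)
    return out
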