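"""Resampling nulls for hotspot/feature association.

Both tests share one null generator: for each observed hotspot a simulated
interval of the same length is placed uniformly on the same chromosome,
rejection-resampling until the simulated set is mutually non-overlapping.
The feature test counts hotspots intersecting >= 1 bp with any feature; the
repeat test measures the percentage of hotspot bp covered by a repeat class.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GenomeLayout, Interval
from .comparison import merge_intervals

__all__ = [
    "derive_flanks",
    "random_hotspot_set",
    "feature_overlap_test",
    "repeat_content_test",
    "OverlapTestResult",
    "RepeatTestResult",
]


def derive_flanks(
    genes: Sequence,
    layout: GenomeLayout,
    flank: int = 500,
) -> tuple[list[Interval], list[Interval]]:
    """Strand-aware TSS/TTS flank tracks of ``flank`` bp around gene spans.

    For a + strand gene [s, e): TSS = [s - flank, s), TTS = [e, e + flank);
    swapped on the - strand.  Flanks are clipped to chromosome bounds (with
    a warning) and genes flush against an edge may yield no flank there.
    """
    import warnings

    tss: list[Interval] = []
    tts: list[Interval] = []
    clipped = 0
    for g in genes:
        length = layout[g.chrom]
        upstream = (max(g.start - flank, 0), g.start)
        downstream = (g.end, min(g.end + flank, length))
        if upstream[1] - upstream[0] < flank or downstream[1] - downstream[0] < flank:
            clipped += 1
        first, second = (upstream, downstream) if g.strand == "+" else (
            downstream, upstream
        )
        if first[0] < first[1]:
            tss.append(Interval(g.chrom, first[0], first[1], strand=g.strand))
        if second[0] < second[1]:
            tts.append(Interval(g.chrom, second[0], second[1], strand=g.strand))
    if clipped:
        warnings.warn(
            f"{clipped} flank(s) clipped at chromosome ends", stacklevel=2
        )
    return tss, tts


def random_hotspot_set(
    template: Sequence[Interval],
    layout: GenomeLayout,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> list[Interval]:
    """Count- and size-matched uniform placement, non-overlapping per set.

    Each template interval is re-placed on its own chromosome with start
    ~ Uniform{0 .. L - len}; placements overlapping an already placed
    simulated interval are redrawn (up to ``max_attempts`` per interval).
    """
    placed_starts: dict[str, list[int]] = {}
    placed_ends: dict[str, list[int]] = {}
    out: list[Interval] = []
    for iv in template:
        length = iv.length
        chrom_len = layout[iv.chrom]
        if length > chrom_len:
            raise ValueError(
                f"template interval of {length} bp exceeds {iv.chrom} "
                f"length {chrom_len}"
            )
        starts = placed_starts.setdefault(iv.chrom, [])
        ends = placed_ends.setdefault(iv.chrom, [])
        for attempt in range(max_attempts):
            s = int(rng.integers(0, chrom_len - length + 1))
            e = s + length
            # neighbors in the sorted placed list
            i = bisect.bisect_left(starts, s)
            ok = (i == len(starts) or starts[i] >= e) and (
                i == 0 or ends[i - 1] <= s
            )
            if ok:
                starts.insert(i, s)
                ends.insert(i, e)
                out.append(Interval(iv.chrom, s, e))
                break
        else:
            raise RuntimeError(
                f"could not place a {length} bp interval on {iv.chrom} "
                f"after {max_attempts} attempts"
            )
    return out


def _merged_arrays(intervals: Sequence[Interval]) -> dict[str, np.ndarray]:
    merged = merge_intervals(intervals) if intervals else []
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.asarray(v, dtype=np.int64) for c, v in by.items()}


def _count_overlapping(
    queries: Sequence[Interval], features: dict[str, np.ndarray]
) -> int:
    """Number of query intervals intersecting >= 1 bp with any feature."""
    n = 0
    for iv in queries:
        arr = features.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        i0 = int(np.searchsorted(ends, iv.start, side="right"))
        if i0 < starts.size and starts[i0] < iv.end:
            n += 1
    return n


def _covered_bp(
    queries: Sequence[Interval], features: dict[str, np.ndarray]
) -> int:
    """Total bp of query intervals covered by (merged) features."""
    total = 0
    for iv in queries:
        arr = features.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        i0 = int(np.searchsorted(ends, iv.start, side="right"))
        i1 = int(np.searchsorted(starts, iv.end, side="left"))
        if i1 > i0:
            s = np.maximum(starts[i0:i1], iv.start)
            e = np.minimum(ends[i0:i1], iv.end)
            total += int(np.sum(e - s))
    return total


@dataclass
class OverlapTestResult:
    observed: int
    null_counts: np.ndarray
    prop_below: float       # P(sim < observed): the Table-4-style statistic
    p_enrich: float         # (1 + #{sim >= observed}) / (1 + nsims)


def feature_overlap_test(
    hotspots: Sequence[Interval],
    features: Sequence[Interval],
    layout: GenomeLayout,
    nsims: int = 1000,
    seed: int | None = None,
) -> OverlapTestResult:
    """Count hotspots touching features vs the matched uniform null."""
    if not hotspots or not features:
        raise ValueError("hotspots and features must be non-empty")
    feat = _merged_arrays(features)
    observed = _count_overlapping(merge_intervals(hotspots), feat)
    rng = np.random.default_rng(seed)
    template = merge_intervals(hotspots)
    null = np.empty(nsims, dtype=np.int64)
    for k in range(nsims):
        sim = random_hotspot_set(template, layout, rng)
        null[k] = _count_overlapping(sim, feat)
    prop_below = float(np.count_nonzero(null < observed)) / nsims
    p_enrich = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + nsims)
    return OverlapTestResult(
        observed=observed,
        null_counts=null,
        prop_below=prop_below,
        p_enrich=float(p_enrich),
    )


@dataclass
class RepeatTestResult:
    observed_pct: float
    null_mean_pct: float
    pct_sims_above: float   # % of simulations exceeding the observed value
    null_pct: np.ndarray


def repeat_content_test(
    hotspots: Sequence[Interval],
    repeats: Sequence[Interval],
    layout: GenomeLayout,
    nsims: int = 1000,
    seed: int | None = None,
) -> RepeatTestResult:
    """Percent of hotspot bp covered by a repeat class vs the matched null."""
    if not hotspots:
        raise ValueError("hotspot set must be non-empty")
    template = merge_intervals(hotspots)
    total_bp = sum(iv.length for iv in template)
    rep = _merged_arrays(repeats)
    observed = 100.0 * _covered_bp(template, rep) / total_bp
    rng = np.random.default_rng(seed)
    null = np.empty(nsims, dtype=float)
    for k in range(nsims):
        sim = random_hotspot_set(template, layout, rng)
        null[k] = 100.0 * _covered_bp(sim, rep) / total_bp
    return RepeatTestResult(
        observed_pct=float(observed),
        null_mean_pct=float(null.mean()),
        pct_sims_above=100.0 * float(np.count_nonzero(null > observed)) / nsims,
        null_pct=null,
    )
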