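"""Hotspot detection on a recombination-rate map.

A non-overlapping 1 kb scan compares each window's genetic length (sum of
rho * interval length) to a simulation null in which per-interval rates are
drawn from a gamma distribution fitted (method of moments) to the map's
local background — the per-interval rates within +/- ``flank_bp`` of the
window.  Windows whose empirical p falls at or below alpha are merged into
hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import Interval
from .ratemap import RateMap

__all__ = [
    "Hotspot",
    "HotspotSet",
    "scan_windows",
    "call_hotspots",
    "hotspot_rate_contrast",
    "WindowScan",
    "RateContrast",
]


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    start: int
    end: int
    p_value: float
    mean_rate_inside: float = float("nan")
    mean_rate_flank: float = float("nan")

    def as_interval(self, name: str = "") -> Interval:
        return Interval(self.chrom, self.start, self.end, name=name,
                        score=self.p_value)


@dataclass
class HotspotSet:
    population: str
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        hs = sorted(self.hotspots, key=lambda h: (h.chrom, h.start))
        for a, b in zip(hs, hs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("hotspots overlap after merge")
        self.hotspots = hs

    def __len__(self) -> int:
        return len(self.hotspots)

    def intervals(self) -> list[Interval]:
        return [
            h.as_interval(name=f"{self.population}_hs{i}")
            for i, h in enumerate(self.hotspots, start=1)
        ]


@dataclass
class WindowScan:
    """Per-window scan results (windows with a testable background only)."""

    starts: np.ndarray        # window start, bp
    ends: np.ndarray
    observed: np.ndarray      # genetic length per window, Morgans
    p_values: np.ndarray
    n_skipped: int = 0


def _clipped_genetic_length(
    positions: np.ndarray,
    rates: np.ndarray,
    lo: int,
    hi: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Interval lengths clipped to [lo, hi) and their genetic length."""
    i0 = int(np.searchsorted(positions, lo, side="right")) - 1
    i0 = max(i0, 0)
    i1 = int(np.searchsorted(positions, hi, side="left"))
    i1 = min(i1, positions.size - 1)
    if i1 <= i0:
        return np.empty(0), np.empty(0), 0.0
    starts = np.maximum(positions[i0:i1], lo)
    ends = np.minimum(positions[i0 + 1 : i1 + 1], hi)
    lens = np.maximum(ends - starts, 0).astype(float)
    keep = lens > 0
    r = rates[i0:i1][keep]
    lens = lens[keep]
    return r, lens, float(np.sum(r * lens))


def _flank_rates(
    positions: np.ndarray, rates: np.ndarray, w0: int, w1: int, flank_bp: int
) -> np.ndarray:
    """Per-interval rates overlapping the two flanks of window [w0, w1)."""
    left, _, _ = _clipped_genetic_length(positions, rates, w0 - flank_bp, w0)
    right, _, _ = _clipped_genetic_length(positions, rates, w1, w1 + flank_bp)
    return np.concatenate([left, right])


def scan_windows(
    ratemap: RateMap,
    window_bp: int = 1000,
    step_bp: int = 1000,
    flank_bp: int = 50_000,
    nsims: int = 1000,
    seed: int | None = None,
    min_background: int = 10,
) -> WindowScan:
    """Empirical p-value per window under the single-background-gamma null.

    p = (1 + #{T_sim >= T_obs}) / (1 + nsims); windows with fewer than
    ``min_background`` flanking intervals, or a degenerate (all-equal)
    background, are skipped with a warning summary.
    """
    rng = np.random.default_rng(seed)
    pos, rho = ratemap.positions, ratemap.rates
    span_lo, span_hi = ratemap.span
    starts, ends, observed, pvals = [], [], [], []
    n_skipped = 0
    w0 = span_lo
    while w0 + window_bp <= span_hi:
        w1 = w0 + window_bp
        win_rates, win_lens, t_obs = _clipped_genetic_length(pos, rho, w0, w1)
        if win_rates.size == 0:
            w0 += step_bp
            continue
        bg = _flank_rates(pos, rho, w0, w1, flank_bp)
        m = bg.mean() if bg.size else 0.0
        v = bg.var() if bg.size else 0.0
        if bg.size < min_background or m <= 0 or v <= 0:
            n_skipped += 1
            w0 += step_bp
            continue
        shape = m * m / v
        scale = v / m
        sims = rng.gamma(shape, scale, size=(nsims, win_lens.size))
        t_sim = sims @ win_lens
        p = (1.0 + np.count_nonzero(t_sim >= t_obs)) / (1.0 + nsims)
        starts.append(w0)
        ends.append(w1)
        observed.append(t_obs)
        pvals.append(p)
        w0 += step_bp
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} window(s) with insufficient or degenerate "
            "background",
            stacklevel=2,
        )
    return WindowScan(
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        observed=np.asarray(observed, dtype=float),
        p_values=np.asarray(pvals, dtype=float),
        n_skipped=n_skipped,
    )


def _weighted_mean_rate(
    positions: np.ndarray, rates: np.ndarray, lo: int, hi: int
) -> float:
    r, lens, total = _clipped_genetic_length(positions, rates, lo, hi)
    covered = float(np.sum(lens)) if lens.size else 0.0
    if covered == 0:
        return float("nan")
    return total / covered


def call_hotspots(
    ratemap: RateMap,
    window_bp: int = 1000,
    step_bp: int = 1000,
    flank_bp: int = 50_000,
    nsims: int = 1000,
    alpha: float = 0.001,
    seed: int | None = None,
    contrast_flank_bp: int = 5000,
) -> HotspotSet:
    """Scan, retain windows with p <= alpha, merge touching windows.

    Per-hotspot p is the minimum over its constituent windows; each hotspot
    also records the length-weighted mean rate inside and in its +/- 5 kb
    flanks.
    """
    span_lo, span_hi = ratemap.span
    if span_hi - span_lo < window_bp + 2 * flank_bp:
        warnings.warn(
            "map span is shorter than window + 2*flank; background is "
            "one-sided or truncated",
            stacklevel=2,
        )
    scan = scan_windows(
        ratemap,
        window_bp=window_bp,
        step_bp=step_bp,
        flank_bp=flank_bp,
        nsims=nsims,
        seed=seed,
    )
    sig = scan.p_values <= alpha
    hotspots: list[Hotspot] = []
    i = 0
    idx = np.flatnonzero(sig)
    pos, rho = ratemap.positions, ratemap.rates
    while i < idx.size:
        j = i
        # merge runs of retained windows that touch or overlap
        while (
            j + 1 < idx.size
            and scan.starts[idx[j + 1]] <= scan.ends[idx[j]]
        ):
            j += 1
        start = int(scan.starts[idx[i]])
        end = int(scan.ends[idx[j]])
        p = float(np.min(scan.p_values[idx[i] : idx[j] + 1]))
        inside = _weighted_mean_rate(pos, rho, start, end)
        left = _weighted_mean_rate(pos, rho, start - contrast_flank_bp, start)
        right = _weighted_mean_rate(pos, rho, end, end + contrast_flank_bp)
        flank_vals = [v for v in (left, right) if np.isfinite(v)]
        flank = float(np.mean(flank_vals)) if flank_vals else float("nan")
        hotspots.append(
            Hotspot(
                chrom=ratemap.chrom,
                start=start,
                end=end,
                p_value=p,
                mean_rate_inside=inside,
                mean_rate_flank=flank,
            )
        )
        i = j + 1
    return HotspotSet(population=ratemap.population, hotspots=hotspots)


@dataclass(frozen=True)
class RateContrast:
    n_hotspots: int
    genome_ratio: float   # mean rate in hotspot bp / genome-wide mean rate
    flank_ratio: float    # mean rate in hotspot bp / mean rate in +/-5 kb flanks


def hotspot_rate_contrast(
    hotspot_set: HotspotSet,
    ratemap: RateMap,
    flank_bp: int = 5000,
) -> RateContrast:
    """Length-weighted hotspot-vs-genome and hotspot-vs-flank rate ratios."""
    if len(hotspot_set) == 0:
        return RateContrast(0, float("nan"), float("nan"))
    pos, rho = ratemap.positions, ratemap.rates
    total_in = 0.0
    bp_in = 0.0
    total_flank = 0.0
    bp_flank = 0.0
    excluded = 0
    for h in hotspot_set.hotspots:
        if h.chrom != ratemap.chrom:
            continue
        r, lens, gl = _clipped_genetic_length(pos, rho, h.start, h.end)
        if lens.size == 0:
            excluded += 1
            continue
        total_in += gl
        bp_in += float(np.sum(lens))
        for lo, hi in ((h.start - flank_bp, h.start), (h.end, h.end + flank_bp)):
            _, flens, fgl = _clipped_genetic_length(pos, rho, lo, hi)
            total_flank += fgl
            bp_flank += float(np.sum(flens))
    if excluded:
        warnings.warn(
            f"excluded {excluded} hotspot(s) with no SNP intervals",
            stacklevel=2,
        )
    if bp_in == 0:
        return RateContrast(0, float("nan"), float("nan"))
    mean_in = total_in / bp_in
    lens_all = ratemap.interval_lengths
    genome_mean = ratemap.total_genetic_length() / float(np.sum(lens_all))
    flank_mean = total_flank / bp_flank if bp_flank > 0 else float("nan")
    return RateContrast(
        n_hotspots=len(hotspot_set),
        genome_ratio=mean_in / genome_mean if genome_mean > 0 else float("nan"),
        flank_ratio=mean_in / flank_mean if flank_mean and flank_mean > 0
        else float("nan"),
    )
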