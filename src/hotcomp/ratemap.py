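"""Recombination-rate maps: window planning/stitching, unit conversion,
summaries, trace uncertainty, and between-population rate comparisons.

A :class:`RateMap` holds one chromosome of one population: ``n`` strictly
increasing SNP positions (bp) and ``n - 1`` per-interval population-scaled
rates rho in Morgans/bp.  Per-generation rates ``r`` are reported in cM/Mb
via ``r = rho / (4 Ne) * 1e8``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RateMap",
    "RateTrace",
    "PopulationMeta",
    "WindowPlan",
    "plan_windows",
    "stitch_windows",
    "rho_to_r",
    "r_to_rho",
    "summarize_ratemap",
    "trace_uncertainty",
    "wilcoxon_rank_sum",
    "compare_rates",
    "bonferroni_cutoff",
    "confound_regression",
    "RegressionResult",
]


@dataclass
class RateMap:
    """Per-interval recombination map for one chromosome of one population."""

    chrom: str
    positions: np.ndarray  # SNP positions, bp, strictly increasing
    rates: np.ndarray      # rho per inter-SNP interval, Morgans/bp
    population: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.positions.size < 2:
            raise ValueError("a rate map needs at least 2 SNP positions")
        if np.any(np.diff(self.positions) <= 0):
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0]) + 1
            raise ValueError(f"positions not strictly increasing at index {bad}")
        if self.rates.shape != (self.positions.size - 1,):
            raise ValueError(
                f"expected {self.positions.size - 1} rates, got {self.rates.size}"
            )
        if np.any(self.rates < 0):
            raise ValueError("negative recombination rate")

    @property
    def n_intervals(self) -> int:
        return self.positions.size - 1

    @property
    def interval_lengths(self) -> np.ndarray:
        return np.diff(self.positions).astype(float)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.positions[:-1] + self.positions[1:]) / 2.0

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    def total_genetic_length(self) -> float:
        """Map length in Morgans: sum of rho * interval length."""
        return float(np.sum(self.rates * self.interval_lengths))


@dataclass
class RateTrace:
    """Post-burn-in MCMC samples of rho, aligned to a map's intervals."""

    samples: np.ndarray  # shape (n_intervals, n_samples)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if np.any(self.samples < 0):
            raise ValueError("negative trace sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class PopulationMeta:
    name: str
    ne: float
    inbreeding_f: float
    sample_size: int

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError(f"{self.name}: Ne must be > 0")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError(f"{self.name}: F must be in [0, 1]")
        if self.sample_size < 1:
            raise ValueError(f"{self.name}: sample size must be >= 1")


# ---------------------------------------------------------------------------
# window planning and stitching
# ---------------------------------------------------------------------------

@dataclass
class WindowPlan:
    """SNP-index windows (1-based, inclusive) covering a chromosome.

    Windows start at 1, 1 + stride, 1 + 2*stride, ... with
    stride = window - overlap; the final window always holds the last
    ``window`` SNPs, so its overlap with the previous window is variable
    but never below ``overlap``.
    """

    n_snps: int
    window: int
    overlap: int
    windows: list[tuple[int, int]] = field(default_factory=list)

    def contributions(self, trim: int = 250) -> list[tuple[int, int]]:
        """Per-window contributed inter-SNP interval ranges (1-based, incl.).

        Interval ``i`` sits between SNPs ``i`` and ``i + 1``.  Each window
        except the last contributes up to interval ``end - trim`` (the
        interval bridging two kept SNP ranges goes to the preceding window);
        the ranges partition 1 .. n_snps - 1.
        """
        k = len(self.windows)
        if k == 1:
            return [(1, self.n_snps - 1)]
        ranges: list[tuple[int, int]] = []
        lo = 1
        for j, (start, end) in enumerate(self.windows):
            if j == k - 1:
                hi = self.n_snps - 1
            else:
                hi = end - trim
            if not (start <= lo and lo <= hi <= max(end - 1, start)):
                raise ValueError(
                    f"trim={trim} infeasible for window {j} [{start},{end}]"
                )
            ranges.append((lo, hi))
            lo = hi + 1
        return ranges


def plan_windows(n_snps: int, window: int = 2000, overlap: int = 500) -> WindowPlan:
    """Partition ``n_snps`` SNPs into overlapping estimation windows.

    Chromosomes with at most ``window`` SNPs form a single window.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if not 0 < overlap < window:
        raise ValueError("require 0 < overlap < window")
    if n_snps <= window:
        return WindowPlan(n_snps, window, overlap, [(1, n_snps)])
    stride = window - overlap
    windows: list[tuple[int, int]] = []
    start = 1
    while start + window - 1 <= n_snps:
        windows.append((start, start + window - 1))
        start += stride
    if windows[-1][1] < n_snps:  # final window = last `window` SNPs
        windows.append((n_snps - window + 1, n_snps))
    return WindowPlan(n_snps, window, overlap, windows)


def stitch_windows(
    per_window_rates: Sequence[np.ndarray],
    plan: WindowPlan,
    trim: int = 250,
) -> np.ndarray:
    """Merge per-window interval rate estimates into one chromosome-wide map.

    ``per_window_rates[k]`` must hold one rate per inter-SNP interval of
    window ``k`` (window of ``w`` SNPs -> ``w - 1`` rates).  Returns an array
    of length ``n_snps - 1``.
    """
    if len(per_window_rates) != len(plan.windows):
        raise ValueError(
            f"plan has {len(plan.windows)} windows, got "
            f"{len(per_window_rates)} rate vectors"
        )
    for k, ((start, end), rates) in enumerate(zip(plan.windows, per_window_rates)):
        expected = end - start
        if len(rates) != expected:
            raise ValueError(
                f"window {k} [{start},{end}] expects {expected} rates, "
                f"got {len(rates)}"
            )
    pieces = []
    for (start, _end), (lo, hi), rates in zip(
        plan.windows, plan.contributions(trim), per_window_rates
    ):
        rates = np.asarray(rates, dtype=float)
        # global interval index i -> local index i - start
        pieces.append(rates[lo - start : hi - start + 1])
    out = np.concatenate(pieces)
    assert out.size == plan.n_snps - 1
    return out


# ---------------------------------------------------------------------------
# unit conversion and summaries
# ---------------------------------------------------------------------------

def rho_to_r(rho_m_per_bp, ne: float):
    """Convert population-scaled rho (Morgans/bp) to r in cM/Mb.

    r = rho / (4 Ne), rescaled from Morgans/bp to cM/Mb (factor 1e8).
    """
    if ne <= 0:
        raise ValueError("Ne must be > 0")
    rho = np.asarray(rho_m_per_bp, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    out = rho / (4.0 * ne) * 1e8
    return float(out) if np.isscalar(rho_m_per_bp) else out


def r_to_rho(r_cm_per_mb, ne: float):
    """Inverse of :func:`rho_to_r`."""
    if ne <= 0:
        raise ValueError("Ne must be > 0")
    r = np.asarray(r_cm_per_mb, dtype=float)
    out = r * 4.0 * ne / 1e8
    return float(out) if np.isscalar(r_cm_per_mb) else out


def summarize_ratemap(
    ratemaps: Mapping[str, Sequence[RateMap]],
    meta: Mapping[str, PopulationMeta],
    n_boot: int = 1000,
    seed: int | None = 0,
):
    """Per-population mean/median r (cM/Mb) with a bootstrap 95% CI of the mean.

    One observation per inter-SNP interval, pooled over chromosomes,
    unweighted by interval length.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for pop, maps in ratemaps.items():
        if not maps:
            raise ValueError(f"{pop}: no rate maps")
        rho = np.concatenate([m.rates for m in maps])
        if rho.size == 0:
            raise ValueError(f"{pop}: empty rate map")
        r = rho_to_r(rho, meta[pop].ne)
        if np.ptp(r) == 0:
            lo = hi = float(r[0])
        else:
            idx = rng.integers(0, r.size, size=(n_boot, r.size))
            boot_means = r[idx].mean(axis=1)
            lo, hi = np.percentile(boot_means, [2.5, 97.5])
        rows.append(
            {
                "population": pop,
                "mean_rho": float(np.mean(rho)),
                "ne": meta[pop].ne,
                "mean_r": float(np.mean(r)),
                "median_r": float(np.median(r)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_intervals": int(r.size),
            }
        )
    return pd.DataFrame(rows).set_index("population")


@dataclass(frozen=True)
class TraceUncertainty:
    median_cri_low: float
    median_cri_high: float
    genome_low: float
    genome_high: float

    @property
    def median_cri_width(self) -> float:
        return self.median_cri_high - self.median_cri_low

    @property
    def genome_width(self) -> float:
        return self.genome_high - self.genome_low

    @property
    def width_ratio(self) -> float:
        """Genome-wide spread of estimates over median per-site CrI width."""
        if self.median_cri_width == 0:
            return np.inf if self.genome_width > 0 else np.nan
        return self.genome_width / self.median_cri_width


def trace_uncertainty(
    traces: Sequence[RateTrace],
    ratemaps: Sequence[RateMap],
) -> TraceUncertainty:
    """Compare per-site MCMC credibility to genome-wide rate spread.

    Per-site CrI = [2.5, 97.5] percentiles of each interval's trace; the
    reported bounds are the medians across intervals.  The genome interval
    is [2.5, 97.5] percentiles of the point estimates themselves.
    """
    if len(traces) != len(ratemaps):
        raise ValueError("traces and ratemaps must align")
    lows, highs, estimates = [], [], []
    for trace, rmap in zip(traces, ratemaps):
        if trace.samples.shape[0] != rmap.n_intervals:
            raise ValueError("trace not aligned to map intervals")
        if trace.n_samples < 40:
            warnings.warn(
                f"only {trace.n_samples} trace samples; "
                "2.5/97.5 percentiles are unstable",
                stacklevel=2,
            )
        q = np.percentile(trace.samples, [2.5, 97.5], axis=1)
        lows.append(q[0])
        highs.append(q[1])
        estimates.append(rmap.rates)
    lows = np.concatenate(lows)
    highs = np.concatenate(highs)
    estimates = np.concatenate(estimates)
    g_lo, g_hi = np.percentile(estimates, [2.5, 97.5])
    return TraceUncertainty(
        median_cri_low=float(np.median(lows)),
        median_cri_high=float(np.median(highs)),
        genome_low=float(g_lo),
        genome_high=float(g_hi),
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumerating index combinations.

    Mid-ranks handle ties; p = P(|W - E[W]| >= |W_obs - E[W]|) over all
    C(n+m, n) equally likely assignments of ranks to the first sample.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = len(x), len(y)
    total = n + m
    w_obs = ranks[:n].sum()
    mu = n * (total + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    hits = 0
    count = 0
    for combo in itertools.combinations(range(total), n):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev:
            hits += 1
        count += 1
    return hits / count


def wilcoxon_rank_sum(x, y, exact: bool | None = None) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration (tie-safe, mid-ranks) when both samples have <= 10
    observations or ``exact=True``; otherwise scipy's normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if exact is None:
        exact = x.size <= 10 and y.size <= 10
    if exact:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def bonferroni_cutoff(n_comparisons: int, family_alpha: float = 0.05) -> float:
    """Per-test significance cutoff controlling the family-wise error rate."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons


@dataclass
class CompareRatesResult:
    kruskal_p: float
    pairwise_p: "object"        # pandas DataFrame, symmetric, NaN diagonal
    bonferroni: float
    n_comparisons: int


def compare_rates(
    values_by_pop: Mapping[str, np.ndarray],
    family_alpha: float = 0.05,
) -> CompareRatesResult:
    """Kruskal-Wallis over all populations + pairwise Wilcoxon rank-sum.

    ``values_by_pop`` maps population -> per-interval r values.
    """
    import pandas as pd

    pops = list(values_by_pop)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    for pop in pops:
        if len(values_by_pop[pop]) < 2:
            raise ValueError(f"{pop}: fewer than 2 intervals")
    kw = stats.kruskal(*[np.asarray(values_by_pop[p], float) for p in pops])
    pairs = list(itertools.combinations(pops, 2))
    pmat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for a, b in pairs:
        p = wilcoxon_rank_sum(values_by_pop[a], values_by_pop[b])
        pmat.loc[a, b] = p
        pmat.loc[b, a] = p
    return CompareRatesResult(
        kruskal_p=float(kw.pvalue),
        pairwise_p=pmat,
        bonferroni=bonferroni_cutoff(len(pairs), family_alpha),
        n_comparisons=len(pairs),
    )


# ---------------------------------------------------------------------------
# simple linear confound regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    df_resid: int


def confound_regression(y, x) -> RegressionResult:
    """OLS of y on a single predictor with a two-sided t-test on the slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length vectors")
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 observations")
    if np.any(np.isnan(y)) or np.any(np.isnan(x)):
        raise ValueError("missing values not allowed")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("constant predictor: slope undefined")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    df = n - 2
    s2 = np.sum(resid**2) / df
    se = np.sqrt(s2 / sxx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(se),
        slope_p=float(p),
        df_resid=df,
    )
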