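"""Recessive-model association between missense homozygosity and
population-level recombination rate.

The response is each population's median r; predictors are per-mutation
frequencies of homozygous-alternative genotypes.  Perfectly correlated
predictors (r^2 = 1) are pruned greedily, then a Gaussian identity-link GLM
(ordinary least squares with t-tests) is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "homozygosity_frequencies",
    "prune_correlated",
    "recessive_glm",
    "GlmResult",
]

_HOM_ALT = {"1/1", "1|1"}
_MISSING = {"./.", ".|.", ".", ""}
_KNOWN = _HOM_ALT | _MISSING | {"0/0", "0|0", "0/1", "1/0", "0|1", "1|0"}


def homozygosity_frequencies(
    genotypes: Mapping[str, Mapping[str, Sequence[str]]],
) -> pd.DataFrame:
    """Frequency of homozygous-alternative genotypes per population/mutation.

    ``genotypes[population][mutation]`` is a list of genotype codes
    ('0/0', '0/1', '1/1', './.').  Each cell is #hom-alt / #non-missing;
    an all-missing cell is a hard error.
    """
    pops = list(genotypes)
    muts: list[str] = []
    for pop in pops:
        for m in genotypes[pop]:
            if m not in muts:
                muts.append(m)
    table = pd.DataFrame(index=pops, columns=muts, dtype=float)
    for pop in pops:
        for mut in muts:
            calls = genotypes[pop].get(mut)
            if calls is None:
                raise ValueError(f"{pop}: missing mutation {mut}")
            unknown = [c for c in calls if c not in _KNOWN]
            if unknown:
                raise ValueError(f"{pop}/{mut}: unknown genotype {unknown[0]!r}")
            valid = [c for c in calls if c not in _MISSING]
            if not valid:
                raise ValueError(f"{pop}/{mut}: all genotypes missing")
            hom = sum(1 for c in valid if c in _HOM_ALT)
            table.loc[pop, mut] = hom / len(valid)
    return table


def prune_correlated(
    table: pd.DataFrame,
    r2_threshold: float = 1.0,
    tol: float = 1e-12,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop columns in complete (or >= threshold) squared correlation.

    Greedy left-to-right: a column is dropped if its r^2 with any retained
    column reaches the threshold (within ``tol``).  Zero-variance columns
    are dropped with a warning.  Returns (pruned table, dropped -> kept).
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 mutations to prune")
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.var(x) == 0:
            warnings.warn(f"column {col} has zero variance; dropped",
                          stacklevel=2)
            dropped[col] = "<zero variance>"
            continue
        hit = None
        for ref in kept:
            r = np.corrcoef(x, table[ref].to_numpy(dtype=float))[0, 1]
            if r * r >= r2_threshold - tol:
                hit = ref
                break
        if hit is None:
            kept.append(col)
        else:
            dropped[col] = hit
    return table[kept], dropped


@dataclass
class GlmResult:
    params: pd.Series
    se: pd.Series
    p_values: pd.Series
    df_resid: int
    residuals: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])


def recessive_glm(
    table: pd.DataFrame,
    median_r_by_population: Mapping[str, float],
) -> GlmResult:
    """OLS of median r on homozygosity columns plus an intercept.

    Requires more populations than retained predictors with at least one
    residual degree of freedom; rank-deficient designs are an error naming
    the collinear columns (prune them first).
    """
    pops = list(table.index)
    y = np.array([float(median_r_by_population[p]) for p in pops])
    X = np.column_stack([np.ones(len(pops)), table.to_numpy(dtype=float)])
    names = ["intercept"] + list(table.columns)
    n, k = X.shape
    if n - k < 1:
        raise ValueError(
            f"{n} populations cannot support {k - 1} predictors "
            "(residual df < 1); prune further"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify offending columns by incremental rank
        collinear = []
        cols = [X[:, 0]]
        for j in range(1, k):
            trial = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(names[j])
            else:
                cols.append(X[:, j])
        raise ValueError(
            f"design matrix rank-deficient; collinear columns: {collinear}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return GlmResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        p_values=pd.Series(p, index=names),
        df_resid=df,
        residuals=resid,
    )
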