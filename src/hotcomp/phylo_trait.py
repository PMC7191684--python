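"""Phylogenetic trait analysis of hotspot sharing.

Turns a Boolean population x consensus-hotspot sharing matrix into
correspondence-analysis coordinates and fits Brownian-motion and
Ornstein-Uhlenbeck models along a drift tree, compared by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DriftTree",
    "TraitMatrix",
    "mca",
    "fit_brownian",
    "fit_ou",
    "compare_models",
    "BMFit",
    "OUFit",
    "ModelComparison",
]

_RIDGE = 1e-10
_SIGMA2_FLOOR = 1e-12


class DriftTree:
    """Rooted tree over populations with branch lengths in drift units."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                if edge.length is None:
                    edge.length = 0.0
                continue
            if edge.length is None:
                raise ValueError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise ValueError("negative branch length")
        self.taxa: list[str] = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate tip labels")
        # root-to-node depths
        depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            depth[node] = depth[node.parent_node] + node.edge.length
        self._tip_depth = {
            leaf.taxon.label: depth[leaf] for leaf in tree.leaf_node_iter()
        }
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        n = len(self.taxa)
        dist = np.zeros((n, n))
        for i, a in enumerate(self.taxa):
            for j, b in enumerate(self.taxa):
                if i < j:
                    d = pdm.patristic_distance(tax[a], tax[b])
                    dist[i, j] = dist[j, i] = d
        self._patristic = dist

    @classmethod
    def from_newick(cls, newick: str) -> "DriftTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls(tree)

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return max(self._tip_depth.values())

    def tip_depths(self, order: list[str] | None = None) -> np.ndarray:
        order = order or self.taxa
        return np.array([self._tip_depth[t] for t in order])

    def patristic_matrix(self, order: list[str] | None = None) -> np.ndarray:
        order = order or self.taxa
        idx = [self.taxa.index(t) for t in order]
        return self._patristic[np.ix_(idx, idx)]

    def shared_path_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """C[i, j] = root-to-MRCA path length = (depth_i + depth_j - d_ij)/2."""
        order = order or self.taxa
        depths = self.tip_depths(order)
        d = self.patristic_matrix(order)
        c = (depths[:, None] + depths[None, :] - d) / 2.0
        return np.maximum(c, 0.0)  # numerical guard

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# multiple correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class TraitMatrix:
    coords: pd.DataFrame          # populations x retained dimensions
    inertia: np.ndarray           # per-dimension principal inertia
    dropped_columns: list = field(default_factory=list)


def mca(boolean_matrix: pd.DataFrame, n_dims: int = 9) -> TraitMatrix:
    """Multiple correspondence analysis of a Boolean presence matrix.

    Each Boolean column is expanded to a two-category indicator pair
    (complete disjunctive coding); row principal coordinates come from the
    SVD of the standardized residuals of the correspondence matrix.
    """
    B = boolean_matrix.astype(float)
    if B.shape[0] < 2 or B.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    constant = [c for c in B.columns if B[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant column(s) from MCA", stacklevel=2
        )
        B = B.drop(columns=constant)
    if B.shape[1] < 2:
        raise ValueError("fewer than 2 varying columns")
    Z = np.hstack([B.values, 1.0 - B.values])  # n x 2J indicator matrix
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-10
    U, sv = U[:, keep], sv[keep]
    if n_dims > sv.size:
        warnings.warn(
            f"requested {n_dims} dimensions, only {sv.size} non-degenerate; "
            "truncating",
            stacklevel=2,
        )
        n_dims = sv.size
    F = (U * sv) / np.sqrt(r)[:, None]  # row principal coordinates
    coords = pd.DataFrame(
        F[:, :n_dims],
        index=boolean_matrix.index,
        columns=[f"dim{i + 1}" for i in range(n_dims)],
    )
    return TraitMatrix(coords=coords, inertia=sv[:n_dims] ** 2,
                       dropped_columns=constant)


# ---------------------------------------------------------------------------
# BM / OU fits
# ---------------------------------------------------------------------------

def _solve_psd(C: np.ndarray, *rhs: np.ndarray):
    """Cholesky solve with a ridge fallback; returns (solutions..., logdet)."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; adding ridge 1e-10", stacklevel=3)
        L = np.linalg.cholesky(C + _RIDGE * np.eye(C.shape[0]))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    sols = []
    for b in rhs:
        z = np.linalg.solve(L, b)
        sols.append(np.linalg.solve(L.T, z))
    return (*sols, logdet)


def _profile_gaussian(C0: np.ndarray, y: np.ndarray):
    """MLE of (mean, scale) for y ~ N(mu 1, sigma2 C0); returns fit pieces."""
    n = y.size
    one = np.ones(n)
    Ci_y, Ci_1, logdet = _solve_psd(C0, y, one)
    mu = float(one @ Ci_y) / float(one @ Ci_1)
    resid = y - mu
    q = float(resid @ (Ci_y - mu * Ci_1))  # resid' C0^-1 resid
    sigma2 = q / n
    degenerate = sigma2 < _SIGMA2_FLOOR
    if degenerate:
        sigma2 = _SIGMA2_FLOOR
    lnl = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + q / sigma2)
    return mu, sigma2, float(lnl), degenerate


@dataclass(frozen=True)
class BMFit:
    mu: float
    sigma2: float
    lnl: float
    k: int = 2


@dataclass(frozen=True)
class OUFit:
    theta: float
    sigma2: float
    alpha: float
    lnl: float
    k: int = 3
    converged: bool = True


def fit_brownian(tree: DriftTree, trait: "pd.Series | dict") -> BMFit:
    """ML Brownian-motion fit: tip covariance = shared root-to-MRCA path."""
    y = np.array([float(trait[t]) for t in tree.taxa])
    C = tree.shared_path_matrix()
    if tree.depth <= 0:
        raise ValueError("tree has zero depth")
    mu, sigma2, lnl, degenerate = _profile_gaussian(C, y)
    if degenerate:
        warnings.warn("constant trait: sigma2 floored", stacklevel=2)
    return BMFit(mu=mu, sigma2=sigma2, lnl=lnl)


def _ou_correlation(alpha: float, d: np.ndarray, t_shared: np.ndarray) -> np.ndarray:
    """Stationary Hansen covariance at sigma2 = 1:
    V0 = exp(-alpha d) (1 - exp(-2 alpha t_a)) / (2 alpha)."""
    return np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * t_shared)) / (2.0 * alpha)


def fit_ou(tree: DriftTree, trait: "pd.Series | dict") -> OUFit:
    """ML Ornstein-Uhlenbeck fit (stationary-start Hansen form, root at theta).

    alpha is profiled by bounded 1-D search; theta and sigma2 are analytic
    given alpha.  As alpha -> 0 the model collapses to Brownian motion.
    """
    y = np.array([float(trait[t]) for t in tree.taxa])
    d = tree.patristic_matrix()
    t_shared = tree.shared_path_matrix()
    depth = tree.depth
    if depth <= 0:
        raise ValueError("tree has zero depth")
    lo, hi = 1e-8, 50.0 / depth

    def nll(alpha: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, lnl, _ = _profile_gaussian(_ou_correlation(alpha, d, t_shared), y)
        return -lnl

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [(nll(lo), lo), (nll(hi), hi)]
    if res.success:
        candidates.append((float(res.fun), float(res.x)))
    best_nll, alpha = min(candidates)
    theta, sigma2, lnl, degenerate = _profile_gaussian(
        _ou_correlation(alpha, d, t_shared), y
    )
    if degenerate:
        warnings.warn("constant trait: sigma2 floored", stacklevel=2)
    converged = bool(res.success) and lo * 1.01 < alpha < hi * 0.99
    return OUFit(theta=theta, sigma2=sigma2, alpha=alpha, lnl=lnl,
                 converged=converged)


@dataclass
class ModelComparison:
    lnl_bm: float
    lnl_ou: float
    aic_bm: float
    aic_ou: float
    preferred: str
    bm_fits: list[BMFit] = field(default_factory=list)
    ou_fits: list[OUFit] = field(default_factory=list)


def aic(lnl: float, k: int) -> float:
    return 2.0 * k - 2.0 * lnl


def compare_models(tree: DriftTree, traits: pd.DataFrame) -> ModelComparison:
    """Fit BM and OU independently per trait dimension; compare summed AIC."""
    if traits.shape[1] < 1:
        raise ValueError("need >= 1 trait dimension")
    bm_fits = [fit_brownian(tree, traits[c]) for c in traits.columns]
    ou_fits = [fit_ou(tree, traits[c]) for c in traits.columns]
    lnl_bm = sum(f.lnl for f in bm_fits)
    lnl_ou = sum(f.lnl for f in ou_fits)
    k_bm = sum(f.k for f in bm_fits)
    k_ou = sum(f.k for f in ou_fits)
    aic_bm = aic(lnl_bm, k_bm)
    aic_ou = aic(lnl_ou, k_ou)
    return ModelComparison(
        lnl_bm=lnl_bm,
        lnl_ou=lnl_ou,
        aic_bm=aic_bm,
        aic_ou=aic_ou,
        preferred="BM" if aic_bm <= aic_ou else "OU",
        bm_fits=bm_fits,
        ou_fits=ou_fits,
    )
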