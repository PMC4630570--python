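"""Canonical correlation integration and bipartite correlation networks.

The centrepiece of the pipeline: fit CCA between a transcript block X and a
metabolite block Y over matched samples, report canonical correlations,
weights and variable-canonical loadings, score every gene-metabolite pair,
threshold the scores into a signed bipartite network, and nominate common
regulators appearing in both a TF-metabolite and a TF-gene network.

The CCA solution comes from the singular value decomposition of the whitened
cross-correlation matrix Sxx^(-1/2) Sxy Syy^(-1/2); an optional ridge term on
the diagonal of Sxx/Syy handles sample-starved blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "CCAResult",
    "ScoreMatrix",
    "BipartiteNetwork",
    "CommonTFReport",
    "standardize",
    "cca_fit",
    "variable_loadings",
    "association_scores",
    "build_network",
    "rank_regulators",
]

ScoreMethod = Literal["direct_pearson", "cross_loading", "loading_product"]
SCORE_METHODS = ("direct_pearson", "cross_loading", "loading_product")


def _as_frame(M, prefix: str) -> pd.DataFrame:
    if isinstance(M, pd.DataFrame):
        return M
    M = np.asarray(M, dtype=float)
    return pd.DataFrame(M, columns=[f"{prefix}{j}" for j in range(M.shape[1])])


def standardize(M) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, SD 1 with n-1); errors on a constant column."""
    df = _as_frame(M, "x")
    sd = df.std(ddof=1)
    zero = sd[~(sd > 0)].index.tolist()
    if zero:
        raise ValueError(f"constant column(s): {zero}")
    return (df - df.mean()) / sd


def _inv_sqrt(S: np.ndarray, ridge: float, what: str) -> np.ndarray:
    if ridge > 0:
        S = S + ridge * np.eye(len(S))
    vals, vecs = linalg.eigh(S)
    tol = len(S) * np.finfo(float).eps * max(vals.max(), 1.0)
    if vals.min() < tol:
        raise np.linalg.LinAlgError(
            f"{what} correlation block is singular (n too small for the number of "
            "variables); pass ridge > 0 or reduce the block"
        )
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


@dataclass(frozen=True)
class CCAResult:
    """Fitted canonical correlation analysis.

    ``rho`` holds the canonical correlations in descending order; U and V are
    the canonical-variable sample scores (unit sample variance per column);
    the loading vectors are Pearson correlations of each raw variable with
    the first canonical pair.
    """

    rho: np.ndarray
    x_weights: pd.DataFrame  # p x k, applied to z-scored X
    y_weights: pd.DataFrame  # q x k
    U: np.ndarray  # n x k
    V: np.ndarray  # n x k
    x_loadings_U1: pd.Series
    x_crossloadings_V1: pd.Series
    y_loadings_V1: pd.Series
    y_crossloadings_U1: pd.Series
    n_samples: int
    ridge: float = 0.0


def _colcorr(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with vector v."""
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (vc**2).sum())
    return (Mc.T @ vc) / denom


def cca_fit(X, Y, ridge: float = 0.0) -> CCAResult:
    """Canonical correlation analysis on matched sample rows.

    X (n x p) and Y (n x q) are standardized internally; the canonical
    directions diagonalise the whitened cross-correlation, so successive
    canonical variables are sample-uncorrelated within each block and
    corr(U_i, V_i) = rho_i.  Requires n > max(p, q) unless ridge > 0.  The
    sign of each component is fixed so that U_i correlates positively with
    the X variable of largest absolute loading on it.
    """
    Xdf = _as_frame(X, "x")
    Ydf = _as_frame(Y, "y")
    if len(Xdf) != len(Ydf):
        raise ValueError("X and Y must have matched sample rows")
    n, p = Xdf.shape
    q = Ydf.shape[1]
    if n < 3:
        raise ValueError("need at least three samples")
    if Xdf.isna().any().any() or Ydf.isna().any().any():
        raise ValueError("NaN in inputs; drop or impute before fitting")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge == 0 and n <= max(p, q):
        raise np.linalg.LinAlgError(
            f"n={n} samples cannot support p={p}, q={q} variables without "
            "regularisation; pass ridge > 0 (e.g. 1e-3)"
        )
    Xz = standardize(Xdf).to_numpy()
    Yz = standardize(Ydf).to_numpy()
    Sxx = Xz.T @ Xz / (n - 1)
    Syy = Yz.T @ Yz / (n - 1)
    Sxy = Xz.T @ Yz / (n - 1)
    Wx = _inv_sqrt(Sxx, ridge, "X")
    Wy = _inv_sqrt(Syy, ridge, "Y")
    Uhat, d, Vt = linalg.svd(Wx @ Sxy @ Wy, full_matrices=False)
    k = min(p, q)
    rho = np.clip(d[:k], 0.0, 1.0)
    A = Wx @ Uhat[:, :k]  # x weights (on z-scored X)
    B = Wy @ Vt.T[:, :k]
    Uc = Xz @ A
    Vc = Yz @ B
    # sign convention: U_i positively correlated with its largest-|loading| X variable
    for i in range(k):
        load = _colcorr(Xz, Uc[:, i])
        jmax = int(np.argmax(np.abs(load)))
        if load[jmax] < 0:
            A[:, i] *= -1
            B[:, i] *= -1
            Uc[:, i] *= -1
            Vc[:, i] *= -1
    comp = [f"cc{i + 1}" for i in range(k)]
    return CCAResult(
        rho=rho,
        x_weights=pd.DataFrame(A, index=Xdf.columns, columns=comp),
        y_weights=pd.DataFrame(B, index=Ydf.columns, columns=comp),
        U=Uc,
        V=Vc,
        x_loadings_U1=pd.Series(_colcorr(Xz, Uc[:, 0]), index=Xdf.columns),
        x_crossloadings_V1=pd.Series(_colcorr(Xz, Vc[:, 0]), index=Xdf.columns),
        y_loadings_V1=pd.Series(_colcorr(Yz, Vc[:, 0]), index=Ydf.columns),
        y_crossloadings_U1=pd.Series(_colcorr(Yz, Uc[:, 0]), index=Ydf.columns),
        n_samples=n,
        ridge=ridge,
    )


def variable_loadings(result: CCAResult, X, Y) -> pd.DataFrame:
    """Correlations of every raw variable with U1 and V1.

    Returns one row per variable with columns (block, corr_U1, corr_V1); the
    layout of the supplementary loading tables such analyses report.
    """
    Xdf = _as_frame(X, "x")
    Ydf = _as_frame(Y, "y")
    if Xdf.shape != (result.n_samples, len(result.x_weights)) or Ydf.shape != (
        result.n_samples,
        len(result.y_weights),
    ):
        raise ValueError("X/Y dimensions do not match the fitted result")
    rows = []
    for col in Xdf.columns:
        v = Xdf[col].to_numpy(dtype=float)
        rows.append(
            {
                "variable": col,
                "block": "X",
                "corr_U1": float(_colcorr(v[:, None], result.U[:, 0])[0]),
                "corr_V1": float(_colcorr(v[:, None], result.V[:, 0])[0]),
            }
        )
    for col in Ydf.columns:
        v = Ydf[col].to_numpy(dtype=float)
        rows.append(
            {
                "variable": col,
                "block": "Y",
                "corr_U1": float(_colcorr(v[:, None], result.U[:, 0])[0]),
                "corr_V1": float(_colcorr(v[:, None], result.V[:, 0])[0]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScoreMatrix:
    """Gene x metabolite association scores in [-1, 1] with the method tag."""

    scores: pd.DataFrame
    method: str


def association_scores(
    X,
    Y,
    method: ScoreMethod = "direct_pearson",
    ridge: float = 0.0,
    cutoff_of_record: float = 0.5,
) -> ScoreMatrix:
    """Per-pair gene-metabolite association scores.

    direct_pearson: plain Pearson r between each gene and metabolite profile
    (the per-pair "variable correlation coefficient" used for network
    edges).  cross_loading: a gene's correlation with the metabolite-side
    canonical variable V1, attributed to metabolite k only when that
    metabolite itself loads on V1 at or above ``cutoff_of_record`` (sign
    aligned with the metabolite's loading; 0 otherwise).  loading_product:
    corr(x_j, U1) * rho1 * corr(y_k, V1), the rank-1 canonical approximation
    of the cross-correlation.
    """
    if method not in SCORE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {SCORE_METHODS}")
    Xdf = _as_frame(X, "x")
    Ydf = _as_frame(Y, "y")
    if len(Xdf) != len(Ydf):
        raise ValueError("X and Y must have matched sample rows")
    if method == "direct_pearson":
        Xz = standardize(Xdf).to_numpy()
        Yz = standardize(Ydf).to_numpy()
        S = Xz.T @ Yz / (len(Xdf) - 1)
    else:
        fit = cca_fit(Xdf, Ydf, ridge=ridge)
        if method == "cross_loading":
            xcl = fit.x_crossloadings_V1.to_numpy()
            ycl = fit.y_loadings_V1.to_numpy()
            indicator = np.where(np.abs(ycl) >= cutoff_of_record, np.sign(ycl), 0.0)
            S = np.outer(xcl, indicator)
        else:  # loading_product
            S = np.outer(
                fit.x_loadings_U1.to_numpy(), fit.rho[0] * fit.y_loadings_V1.to_numpy()
            )
    S = np.clip(S, -1.0, 1.0)
    return ScoreMatrix(
        scores=pd.DataFrame(S, index=Xdf.columns, columns=Ydf.columns), method=method
    )


@dataclass(frozen=True)
class BipartiteNetwork:
    """Signed, weighted edges between two node sets, thresholded at a cutoff."""

    left_nodes: tuple[str, ...]
    right_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float, int], ...]  # (left, right, weight, sign)
    cutoff: float
    signed_only: bool = False

    def edge_set(self) -> set[tuple[str, str]]:
        return {(l, r) for l, r, _, _ in self.edges}

    def neighbors_of_left(self, node: str) -> set[str]:
        return {r for l, r, _, _ in self.edges if l == node}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.left_nodes, bipartite=0)
        g.add_nodes_from(self.right_nodes, bipartite=1)
        for l, r, w, s in self.edges:
            g.add_edge(l, r, weight=w, sign=s)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["left", "right", "weight", "sign"])

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


def build_network(
    scores: ScoreMatrix | pd.DataFrame,
    cutoff: float = 0.5,
    signed_only: bool = False,
) -> BipartiteNetwork:
    """Threshold a score matrix into a bipartite network.

    An edge (j, k) exists iff |score| >= cutoff (or score >= cutoff in
    ``signed_only`` strict-replication mode).  Nodes without edges are kept
    as isolated vertices.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    df = scores.scores if isinstance(scores, ScoreMatrix) else scores
    edges = []
    for l in df.index:
        for r in df.columns:
            w = float(df.at[l, r])
            passing = w >= cutoff if signed_only else abs(w) >= cutoff
            if passing:
                edges.append((str(l), str(r), w, 1 if w >= 0 else -1))
    return BipartiteNetwork(
        left_nodes=tuple(str(i) for i in df.index),
        right_nodes=tuple(str(c) for c in df.columns),
        edges=tuple(edges),
        cutoff=cutoff,
        signed_only=signed_only,
    )


@dataclass(frozen=True)
class CommonTFReport:
    """Per-family TF hits in each network and their intersection.

    ``metabolite_correlated`` / ``gene_correlated`` map family -> sorted TF
    lists with at least one surviving edge in the TF-metabolite / TF-gene
    network; ``common`` is the per-family intersection and ``common_union``
    its union across families.  ``top_per_entity`` ranks, for every
    metabolite or gene, the top-k TFs by |edge weight| (ties by id).
    """

    metabolite_correlated: dict[str, tuple[str, ...]]
    gene_correlated: dict[str, tuple[str, ...]]
    common: dict[str, tuple[str, ...]]
    common_union: tuple[str, ...]
    top_per_entity: dict[str, tuple[str, ...]]
    top_k: int


def rank_regulators(
    tf_metab_net: BipartiteNetwork,
    tf_gene_net: BipartiteNetwork,
    family_labels: Mapping[str, str],
    top_k: int = 3,
) -> CommonTFReport:
    """Nominate regulators correlated with both metabolites and pathway genes.

    For each TF family, collect the TFs holding >= 1 edge in each network;
    the family-wise intersections (unioned) are the nominated common
    regulators.  Every TF node in either network must carry a family label.
    """
    tfs = set(tf_metab_net.left_nodes) | set(tf_gene_net.left_nodes)
    missing = sorted(t for t in tfs if t not in family_labels)
    if missing:
        raise KeyError(f"family label missing for TF node(s): {missing}")

    def per_family(net: BipartiteNetwork) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for l, _r, _w, _s in net.edges:
            out.setdefault(family_labels[l], set()).add(l)
        return out

    met = per_family(tf_metab_net)
    gen = per_family(tf_gene_net)
    families = sorted(set(met) | set(gen))
    common = {
        fam: tuple(sorted(met.get(fam, set()) & gen.get(fam, set()))) for fam in families
    }
    union = tuple(sorted({t for ts in common.values() for t in ts}))

    top: dict[str, tuple[str, ...]] = {}
    for net in (tf_metab_net, tf_gene_net):
        by_right: dict[str, list[tuple[float, str]]] = {}
        for l, r, w, _s in net.edges:
            by_right.setdefault(r, []).append((w, l))
        for r, pairs in by_right.items():
            ranked = sorted(pairs, key=lambda t: (-abs(t[0]), t[1]))
            top[r] = tuple(l for _w, l in ranked[:top_k])
    return CommonTFReport(
        metabolite_correlated={f: tuple(sorted(s)) for f, s in met.items()},
        gene_correlated={f: tuple(sorted(s)) for f, s in gen.items()},
        common=common,
        common_union=union,
        top_per_entity=top,
        top_k=top_k,
    )
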