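"""Compositionally aware sparse-PLS association networks between taxa and genes.

The procedure mirrors the compPLS framework: (i) centered log-ratio transform
of the taxa composition and log transform of normalized expression; (ii) a
two-factor (sex x treatment) variance decomposition that removes between-cell
differences and keeps within-cell variation; (iii) a sparse partial least
squares (sPLS) regression of the gene block on the taxa block, with the
sparsity level chosen by stability selection (StARS) over subsamples and the
significance of the selected support assessed by stratified-bootstrap
empirical p-values with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from micropat.stats import bh_fdr, clr_transform, empirical_pvalue, median_ratio_normalize

__all__ = [
    "FeatureBlock",
    "SplsModel",
    "StarsResult",
    "AssociationEdge",
    "prepare_features",
    "variance_decompose",
    "spls_fit",
    "stars_select",
    "bootstrap_significance",
    "build_network",
]

_RANK_RTOL = 1e-8  # relative cutoff for "non-zero" singular values
_SUPPORT_TOL = 1e-12


@dataclass
class FeatureBlock:
    """Aligned taxa (X) and gene (Y) residual blocks with stratum labels."""

    X: pd.DataFrame  # samples x taxa, clr residuals
    Y: pd.DataFrame  # samples x genes, log-expression residuals
    strata: pd.Series  # sample -> "sex:treatment"

    def __post_init__(self) -> None:
        if not (self.X.index.equals(self.Y.index) and self.X.index.equals(self.strata.index)):
            raise ValueError("X, Y and strata must share the same sample index")
        sizes = self.strata.value_counts()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"every stratum needs >= 2 samples; too small: {small}")


@dataclass
class SplsModel:
    """Fitted sparse-PLS model mapping the taxa block to the gene block."""

    K: int
    lam: float
    coefficients: pd.DataFrame  # taxa x genes
    support: pd.DataFrame  # boolean taxa x genes

    @property
    def support_size(self) -> int:
        return int(self.support.to_numpy().sum())


@dataclass
class StarsResult:
    """StARS diagnostics: per-lambda edge instability and the selected value."""

    lambda_grid: np.ndarray
    frequencies: list[np.ndarray]  # per lambda, taxa x genes selection frequency
    instability: np.ndarray
    monotone_instability: np.ndarray
    beta: float
    selected_lambda: float
    n_subsamples: int
    subsample_size: int
    seed: int | None = None

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "instability": self.instability,
                "monotone_instability": self.monotone_instability,
            }
        )


@dataclass(frozen=True)
class AssociationEdge:
    """One taxon-gene association with its bootstrap significance."""

    taxon: str
    gene: str
    coefficient: float
    sign: str  # "+" or "-"
    empirical_p: float
    q: float
    selected: bool


def variance_decompose(M: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Within-stratum centering: subtract each stratum's column means.

    With a single stratum this is global column centering.  Idempotent.
    Raises on singleton strata, whose rows would become exact zeros.
    """
    strata = strata.loc[M.index]
    sizes = strata.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"singleton strata cannot be centered: {small}")
    out = M.astype(float).copy()
    for s in sizes.index:
        mask = (strata == s).to_numpy()
        out.iloc[mask] = out.iloc[mask] - out.iloc[mask].mean(axis=0)
    return out


def prepare_features(
    taxa: pd.DataFrame,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    min_rel_abund: float = 1e-4,
    pseudocount: float = 0.5,
) -> FeatureBlock:
    """Filter, transform and decompose paired taxa/gene tables.

    Taxa (samples x taxa counts) are dropped if absent from every sample or
    if their overall mean relative abundance is <= min_rel_abund (strict >
    retains), then clr-transformed per sample.  Expression (genes x samples
    counts) is median-ratio normalized and log2(x+1)-transformed.  Both
    blocks are then centered within each sex x treatment stratum.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    shared = [s for s in taxa.index if s in set(expr.columns) & set(meta.index)]
    if not shared:
        raise ValueError("no shared samples between taxa, expression and metadata")
    taxa = taxa.loc[shared]
    expr = expr[shared]
    meta = meta.loc[shared]

    rel = taxa.div(taxa.sum(axis=1), axis=0)
    keep = (rel.mean(axis=0) > min_rel_abund) & (taxa.sum(axis=0) > 0)
    taxa = taxa.loc[:, keep]
    if taxa.shape[1] < 2:
        raise ValueError("fewer than two taxa survive abundance filtering")

    x = pd.DataFrame(
        clr_transform(taxa.to_numpy(dtype=float), pseudocount=pseudocount),
        index=taxa.index,
        columns=taxa.columns,
    )
    counts = expr.to_numpy(dtype=float)
    try:
        _, normed = median_ratio_normalize(counts)
    except ValueError:
        _, normed = median_ratio_normalize(counts + 1.0)
    y = pd.DataFrame(np.log2(normed + 1.0).T, index=shared, columns=expr.index)

    strata = (meta["sex"].astype(str) + ":" + meta["treatment"].astype(str)).rename("stratum")
    return FeatureBlock(
        X=variance_decompose(x, strata),
        Y=variance_decompose(y, strata),
        strata=strata,
    )


def _soft(z: np.ndarray, threshold: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - threshold, 0.0)


def _sparse_singular_pair(
    M: np.ndarray, v0: np.ndarray, lam: float, n_iter: int = 30
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Leading sparse singular pair of M by alternating soft-thresholded
    power iterations (penalized-matrix-decomposition style).

    Each half-step soft-thresholds the raw weight at lam times its largest
    absolute entry and renormalizes, so lam is a fraction in [0, 1] and
    lam >= 1 zeroes every weight.  Returns (w, c) unit vectors or
    (None, None) if either side vanishes.
    """
    v = v0
    w = None
    for _ in range(n_iter):
        zx = M @ v
        w = _soft(zx, lam * np.max(np.abs(zx)))
        norm_w = np.linalg.norm(w)
        if norm_w <= _SUPPORT_TOL:
            return None, None
        w /= norm_w
        zy = M.T @ w
        c = _soft(zy, lam * np.max(np.abs(zy)))
        norm_c = np.linalg.norm(c)
        if norm_c <= _SUPPORT_TOL:
            return None, None
        c /= norm_c
        if np.linalg.norm(c - v) < 1e-10:
            v = c
            break
        v = c
    return w, v


def _spls_core(
    X: np.ndarray, Y: np.ndarray, lam: float, K: int | None
) -> tuple[np.ndarray, int]:
    """Sparse PLS coefficients by W2A deflation with sparse singular pairs.

    Per component, the leading sparse singular pair (w, c) of the current
    cross-covariance M = X_k'Y_k / (n-1) is found by alternating
    soft-thresholded power iterations initialized at the dense leading
    right singular vector; the component score t = X_k w is then projected
    out of both blocks.  A component whose weights vanish entirely
    terminates the deflation.  Coefficients follow the classical PLS2
    formula B = W (P'W)^{-1} C', masked to the union over components of
    supp(w_k) x supp(c_k) so the nonzero pattern is edge-sparse on both
    the taxa and the gene side.
    """
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 rows")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not np.any(X) or not np.any(Y):
        raise ValueError("X and Y must be non-zero")
    Xk = np.array(X, dtype=float)
    Yk = np.array(Y, dtype=float)
    M = Xk.T @ Yk / (n - 1)
    s_all = np.linalg.svd(M, compute_uv=False)
    if K is None:
        K = int(np.sum(s_all > _RANK_RTOL * s_all[0])) if s_all[0] > 0 else 0
    if K < 1:
        return np.zeros((p, q)), 0
    Ws, Ps, Cs = [], [], []
    mask = np.zeros((p, q), dtype=bool)
    for _ in range(K):
        M = Xk.T @ Yk / (n - 1)
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        if s[0] <= _SUPPORT_TOL:
            break
        w, cdir = _sparse_singular_pair(M, vt[0], lam)
        if w is None:
            break
        t = Xk @ w
        tt = float(t @ t)
        if tt <= _SUPPORT_TOL:
            break
        mask |= np.outer(w != 0, cdir != 0)
        p_load = Xk.T @ t / tt
        c_load = Yk.T @ t / tt
        Xk = Xk - np.outer(t, p_load)
        Yk = Yk - np.outer(t, c_load)
        Ws.append(w)
        Ps.append(p_load)
        Cs.append(c_load)
    if not Ws:
        return np.zeros((p, q)), 0
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    C = np.column_stack(Cs)
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return np.where(mask, B, 0.0), W.shape[1]


def spls_fit(
    block: FeatureBlock,
    lam: float,
    K: int | None = None,
) -> SplsModel:
    """Fit a sparse PLS model of the gene block on the taxa block.

    ``lam`` is the sparsity level as a fraction in [0, 1] of the largest
    absolute raw weight entry, applied to both the taxa and the gene side of
    each component; ``lam >= 1`` yields the all-zero model.  If ``K`` is not
    given it is set to the number of singular values of the cross-covariance
    matrix exceeding 1e-8 times the largest.
    """
    B, k_used = _spls_core(block.X.to_numpy(), block.Y.to_numpy(), lam, K)
    coef = pd.DataFrame(B, index=block.X.columns, columns=block.Y.columns)
    support = coef.abs() > _SUPPORT_TOL
    return SplsModel(K=k_used, lam=lam, coefficients=coef, support=support)


def _stratified_subsample(
    rng: np.random.Generator, strata: pd.Series, frac: float
) -> np.ndarray:
    """Row indices of a without-replacement subsample, proportional by stratum."""
    idx = []
    codes = strata.to_numpy()
    for s in np.unique(codes):
        rows = np.flatnonzero(codes == s)
        take = max(2, int(round(frac * len(rows))))
        take = min(take, len(rows))
        idx.append(rng.choice(rows, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def default_lambda_grid(n_values: int = 20) -> np.ndarray:
    """Decreasing sparsity grid on (0, 1]: the empty model (lam=1) first."""
    return np.linspace(1.0, 0.05, n_values)


def stars_select(
    block: FeatureBlock,
    lambda_grid: np.ndarray | None = None,
    n_subsamples: int = 50,
    beta: float = 0.05,
    seed: int = 0,
    K: int | None = None,
) -> StarsResult:
    """Choose the sPLS sparsity level by StARS stability selection.

    For each of ``n_subsamples`` stratified subsamples of size
    min(floor(10*sqrt(n)), floor(0.8*n)) and each lambda, the sPLS support
    is recorded; the edge-selection frequencies theta give the instability
    D(lambda) = mean over edges of 2*theta*(1-theta).  D is monotonized by a
    running supremum from the sparsest (largest lambda) end, and the
    selected lambda is the densest (smallest) value whose monotonized
    instability is <= beta; if none qualifies the sparsest lambda is used.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size < 2:
        raise ValueError("lambda grid needs >= 2 values")
    if np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing (sparsest first)")
    if n_subsamples < 2:
        raise ValueError("need >= 2 subsamples")
    n = len(block.X)
    b = min(int(10 * np.sqrt(n)), int(0.8 * n))
    frac = b / n
    rng = np.random.default_rng(seed)
    Xa, Ya = block.X.to_numpy(), block.Y.to_numpy()
    p, q = Xa.shape[1], Ya.shape[1]
    freq = np.zeros((grid.size, p, q))
    for _ in range(n_subsamples):
        rows = _stratified_subsample(rng, block.strata, frac)
        Xs = Xa[rows] - Xa[rows].mean(axis=0)
        Ys = Ya[rows] - Ya[rows].mean(axis=0)
        for li, lam in enumerate(grid):
            B, _ = _spls_core(Xs, Ys, lam, K)
            freq[li] += np.abs(B) > _SUPPORT_TOL
    freq /= n_subsamples
    instability = np.array([(2 * f * (1 - f)).mean() for f in freq])
    monotone = np.maximum.accumulate(instability)  # running sup from sparsest end
    ok = np.flatnonzero(monotone <= beta)
    selected = float(grid[ok[-1]]) if ok.size else float(grid[0])
    return StarsResult(
        lambda_grid=grid,
        frequencies=[f for f in freq],
        instability=instability,
        monotone_instability=monotone,
        beta=beta,
        selected_lambda=selected,
        n_subsamples=n_subsamples,
        subsample_size=b,
        seed=seed,
    )


def _stratified_bootstrap_rows(
    rng: np.random.Generator, strata: pd.Series
) -> np.ndarray:
    codes = strata.to_numpy()
    idx = []
    for s in np.unique(codes):
        rows = np.flatnonzero(codes == s)
        idx.append(rng.choice(rows, size=len(rows), replace=True))
    return np.concatenate(idx)


def bootstrap_significance(
    block: FeatureBlock,
    model: SplsModel,
    B: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[AssociationEdge]:
    """Bootstrap empirical p-values for the StARS-selected support.

    Rows are resampled with replacement within each stratum (preserving the
    design); the model is refit at the selected lambda on each resample.
    Each support edge's null reference is its bootstrap coefficient
    distribution recentred at zero (coefficients minus their bootstrap
    mean), compared with the observed coefficient through the +1-corrected
    empirical p-value; BH correction runs across support edges.
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap resamples for a stable p floor")
    sup = model.support.to_numpy()
    edges = np.argwhere(sup)
    if edges.size == 0:
        return []
    rng = np.random.default_rng(seed)
    Xa, Ya = block.X.to_numpy(), block.Y.to_numpy()
    boot = np.empty((B, len(edges)))
    for rep in range(B):
        rows = _stratified_bootstrap_rows(rng, block.strata)
        Xb = Xa[rows] - Xa[rows].mean(axis=0)
        Yb = Ya[rows] - Ya[rows].mean(axis=0)
        Bb, _ = _spls_core(Xb, Yb, model.lam, None)
        boot[rep] = Bb[edges[:, 0], edges[:, 1]]
    boot -= boot.mean(axis=0, keepdims=True)

    obs = model.coefficients.to_numpy()[edges[:, 0], edges[:, 1]]
    pvals = np.array(
        [empirical_pvalue(o, boot[:, j]) for j, o in enumerate(obs)]
    )
    qvals = bh_fdr(pvals)
    taxa = list(model.coefficients.index)
    genes = list(model.coefficients.columns)
    out = []
    for (i, j), coef, p, q_ in zip(edges, obs, pvals, qvals):
        out.append(
            AssociationEdge(
                taxon=taxa[i],
                gene=genes[j],
                coefficient=float(coef),
                sign="+" if coef >= 0 else "-",
                empirical_p=float(p),
                q=float(q_),
                selected=bool(q_ < alpha),
            )
        )
    return out


def build_network(
    edges: list[AssociationEdge],
    taxa: pd.DataFrame,
    genes: list[str] | None = None,
    significant_only: bool = True,
) -> nx.Graph:
    """Bipartite taxon-gene graph with attributes ready for GraphML export.

    Taxon nodes carry their mean relative abundance and (if the taxa table
    has a ``families`` attr) family annotation; edges carry sign,
    coefficient, empirical p, q and a width = -log10(empirical p).
    """
    rel = taxa.div(taxa.sum(axis=1), axis=0).mean(axis=0)
    families = taxa.attrs.get("families", {})
    g = nx.Graph()
    for taxon in sorted(taxa.columns):
        g.add_node(
            taxon,
            kind="taxon",
            mean_rel_abundance=float(rel[taxon]),
            family=str(families.get(taxon, "unknown")),
        )
    for gene in sorted(genes or {e.gene for e in edges}):
        g.add_node(gene, kind="gene")
    for e in sorted(edges, key=lambda e: (e.taxon, e.gene)):
        if significant_only and not e.selected:
            continue
        if e.taxon not in g or e.gene not in g:
            raise ValueError(f"edge references unknown node: {e.taxon}-{e.gene}")
        g.add_edge(
            e.taxon,
            e.gene,
            sign=e.sign,
            coefficient=e.coefficient,
            empirical_p=e.empirical_p,
            q=e.q,
            width=float(-np.log10(e.empirical_p)),
        )
    return g
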