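"""Brownian-motion phylogenetic comparative statistics.

All methods in this module assume continuous traits evolving by Brownian
motion (BM) along a rooted tree with branch lengths, under which the tip
values of each trait are jointly Gaussian with covariance proportional to
C, the tips x tips matrix of shared root-to-MRCA path lengths. On top of
that model the module provides:

* maximum-likelihood ancestral state estimates (GLS; the root estimate is
  the phylogenetically weighted mean),
* the multivariate phylogenetic-signal statistic K_mult with a
  tip-permutation test (K_mult = 1 in expectation under BM; 0 means
  phenotype independent of phylogeny),
* scalar phylogenetic generalized least squares (PGLS) regression,
* multivariate shape regression with residual-randomization permutation
  (RRPP) p-values on C^(-1/2)-transformed data,
* phylogenetic two-block partial least squares (evolutionary covariance
  PLS) for morphological integration, and
* phylomorphospace tables (tips plus estimated ancestors with tree edges).

Trees are parsed and traversed with dendropy; the statistics are computed
here from C directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phylogeny container

class Phylogeny:
    """Rooted tree with branch lengths and the derived BM trait covariance C.

    ``C[i, j]`` is the shared path length from the root to the most recent
    common ancestor of tips i and j; ``C[i, i]`` is the root-to-tip path
    length. C is symmetric positive definite for trees with distinct tips
    and positive branch lengths.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._label_nodes()
        self.tip_labels: list[str] = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        self._depths = self._node_depths()
        self.C = self._covariance()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, source, assume_unit_lengths: bool = False) -> "Phylogeny":
        """Parse a Newick tree from a path or a string.

        Every non-root edge must carry a branch length unless
        ``assume_unit_lengths`` is set, in which case missing lengths
        become 1.
        """
        import os

        s = str(source)
        if "(" in s and ";" in s:  # newick data, possibly with a [&R] rooting comment
            text = s
        elif os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        else:
            raise FileNotFoundError(f"no such tree file: {s}")
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                if assume_unit_lengths:
                    edge.length = 1.0
                else:
                    raise ValueError(
                        "tree has edges without branch lengths; "
                        "pass assume_unit_lengths=True to use unit lengths"
                    )
            elif edge.length < 0:
                raise ValueError("negative branch length")
        return cls(tree)

    def _label_nodes(self) -> None:
        counter = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise ValueError("leaf without a taxon label")
            elif not node.label:
                node.label = "root" if node is self.tree.seed_node else f"node{counter}"
                counter += 1

    def _node_depths(self) -> dict:
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + float(node.edge.length)
        return depths

    def _covariance(self) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        n = len(self.tip_labels)
        C = np.zeros((n, n))
        leaf_sets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                leaf_sets[node] = [i]
                C[i, i] = self._depths[node]
            else:
                child_sets = [leaf_sets[ch] for ch in node.child_nodes()]
                depth = self._depths[node]
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i in child_sets[a]:
                            for j in child_sets[b]:
                                C[i, j] = C[j, i] = depth
                leaf_sets[node] = [i for s in child_sets for i in s]
        return C

    # -- helpers -----------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def match_traits(self, traits: pd.DataFrame | pd.Series) -> pd.DataFrame:
        """Reorder a species-indexed trait table to tip order; error on mismatch."""
        if isinstance(traits, pd.Series):
            traits = traits.to_frame()
        missing = [t for t in self.tip_labels if t not in traits.index]
        extra = [s for s in traits.index if s not in self.tip_labels]
        if missing or extra:
            raise ValueError(
                f"tip/trait mismatch: tips without traits {missing}; traits without tips {extra}"
            )
        out = traits.loc[self.tip_labels]
        if out.isna().to_numpy().any():
            raise ValueError("trait table contains missing values")
        return out

    def internal_labels(self) -> list[str]:
        return [n.label for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) label pairs for every edge."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            parent = node.parent_node
            plabel = parent.label if not parent.is_leaf() else parent.taxon.label
            clabel = node.taxon.label if node.is_leaf() else node.label
            out.append((plabel, clabel))
        return out


def _c_inv_sqrt(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of C via eigendecomposition."""
    w, U = np.linalg.eigh(C)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("phylogenetic covariance matrix is not positive definite")
    return U @ np.diag(1.0 / np.sqrt(w)) @ U.T


def phylogenetic_weighted_mean(C: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-column GLS mean (1' C^-1 Y) / (1' C^-1 1) — the BM root estimate."""
    ones = np.ones(C.shape[0])
    w = np.linalg.solve(C, ones)
    return (w @ Y) / (ones @ w)


# ---------------------------------------------------------------------------
# Ancestral states

def bm_ancestral_states(phylo: Phylogeny, traits: pd.DataFrame) -> pd.DataFrame:
    """ML ancestral state estimates for every internal node under BM.

    Equivalent to GLS: internal states jointly minimize the sum over edges
    of (state change)^2 / branch length, whose stationarity conditions form
    a weighted-Laplacian linear system solved here exactly. The root row
    equals the phylogenetically weighted mean of the tip values.
    """
    traits = phylo.match_traits(traits)
    Y = traits.to_numpy(dtype=float)
    internals = [n for n in phylo.tree.preorder_node_iter() if not n.is_leaf()]
    idx = {n: i for i, n in enumerate(internals)}
    tip_index = {lab: i for i, lab in enumerate(phylo.tip_labels)}
    m = len(internals)
    A = np.zeros((m, m))
    B = np.zeros((m, Y.shape[1]))
    for node in internals:
        i = idx[node]
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            edge = nb.edge if nb in node.child_nodes() else node.edge
            length = float(edge.length)
            if length <= 0:
                raise ValueError("branch lengths must be positive for ancestral estimation")
            w = 1.0 / length
            A[i, i] += w
            if nb.is_leaf():
                B[i] += w * Y[tip_index[nb.taxon.label]]
            else:
                A[i, idx[nb]] -= w
    states = np.linalg.solve(A, B)
    return pd.DataFrame(states, index=[n.label for n in internals], columns=traits.columns)


# ---------------------------------------------------------------------------
# Phylogenetic signal: K_mult

@dataclass
class KmultResult:
    K: float
    p: float
    iterations: int
    seed: int | None
    permuted: np.ndarray | None = None  # permutation distribution (observed first)


def kmult_statistic(C: np.ndarray, Y: np.ndarray, C_inv: np.ndarray | None = None) -> float:
    """The multivariate phylogenetic-signal statistic K_mult.

    K_mult = [sum_j e_j' e_j / sum_j e_j' C^-1 e_j]
             / [(tr C - N / (1' C^-1 1)) / (N - 1)]

    with e_j = y_j - a_j 1 and a_j the phylogenetically weighted mean of
    trait j. Equal to 1 in expectation under BM on the given tree; scale-
    invariant in the traits.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == 1:
        Y = Y.T
    N = C.shape[0]
    if C_inv is None:
        C_inv = np.linalg.inv(C)
    ones = np.ones(N)
    w = C_inv @ ones
    denom_w = ones @ w
    a = (w @ Y) / denom_w
    E = Y - np.outer(ones, a)
    num = float(np.sum(E * E))
    den = float(np.sum(E * (C_inv @ E)))
    scale = float(np.sum(Y * Y)) + 1.0
    if den <= scale * 1e-14 or num <= scale * 1e-14:
        raise ValueError("traits have zero variance")
    expected = (np.trace(C) - N / denom_w) / (N - 1)
    return (num / den) / expected


def kmult_test(
    phylo: Phylogeny,
    traits: pd.DataFrame,
    iterations: int = 10000,
    seed: int | None = None,
    keep_null: bool = False,
) -> KmultResult:
    """Permutation test for phylogenetic signal with the K_mult statistic.

    Tip rows are permuted across the tree ``iterations`` times (the
    observed arrangement counts as one of them); p is the proportion of
    permutations with K at least as large as observed, so p lies in
    (0, 1] and can never be exactly 0.
    """
    if phylo.n_tips < 4:
        raise ValueError("need at least 4 tips")
    Y = phylo.match_traits(traits).to_numpy(dtype=float)
    C = phylo.C
    C_inv = np.linalg.inv(C)
    K_obs = kmult_statistic(C, Y, C_inv)
    rng = np.random.default_rng(seed)
    null = np.empty(iterations)
    null[0] = K_obs
    for i in range(1, iterations):
        null[i] = kmult_statistic(C, Y[rng.permutation(Y.shape[0])], C_inv)
    p = float(np.mean(null >= K_obs))
    return KmultResult(
        K=float(K_obs), p=p, iterations=iterations, seed=seed,
        permuted=null if keep_null else None,
    )


def simulate_bm_tips(
    phylo: Phylogeny,
    n_traits: int,
    rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    mean: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate independent BM traits on the tree (tips x traits).

    Each trait's tip values are multivariate normal with covariance
    ``rate * C``; columns are independent unless a shared structure is
    added by the caller.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    L = np.linalg.cholesky(phylo.C)
    Z = rng.standard_normal((phylo.n_tips, n_traits))
    X = np.sqrt(rate) * (L @ Z)
    if mean is not None:
        X = X + np.asarray(mean, float)
    return pd.DataFrame(X, index=phylo.tip_labels, columns=[f"trait{j}" for j in range(n_traits)])


# ---------------------------------------------------------------------------
# Scalar PGLS

@dataclass
class PglsResult:
    """Scalar GLS regression under the BM covariance."""

    params: pd.DataFrame  # coef, se, t, p per term
    sigma2: float
    df_resid: int
    residuals: np.ndarray  # raw-scale residuals y - X beta


def pgls_scalar(
    phylo: Phylogeny,
    y: pd.Series,
    X: pd.DataFrame,
    add_intercept: bool = True,
) -> PglsResult:
    """Phylogenetic GLS of a scalar response on species covariates.

    beta = (X' C^-1 X)^-1 X' C^-1 y with t-tests on N - p degrees of
    freedom. With a star phylogeny (C proportional to I) this reduces
    exactly to ordinary least squares. Used e.g. to screen body size and
    anchor size for collinearity before the shape regression.
    """
    y = phylo.match_traits(y).iloc[:, 0].to_numpy(dtype=float)
    Xdf = phylo.match_traits(X)
    names = list(Xdf.columns)
    Xm = Xdf.to_numpy(dtype=float)
    if add_intercept:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ["intercept"] + names
    N, p = Xm.shape
    if N <= p:
        raise ValueError("need more species than parameters")
    P = _c_inv_sqrt(phylo.C)
    Xt, yt = P @ Xm, P @ y
    XtX = Xt.T @ Xt
    if np.linalg.matrix_rank(XtX) < p:
        raise np.linalg.LinAlgError("singular design matrix")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ Xt.T @ yt
    resid_t = yt - Xt @ beta
    df = N - p
    sigma2 = float(resid_t @ resid_t / df)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    params = pd.DataFrame({"coef": beta, "se": se, "t": tvals, "p": pvals}, index=names)
    return PglsResult(params=params, sigma2=sigma2, df_resid=df, residuals=y - Xm @ beta)


# ---------------------------------------------------------------------------
# Multivariate shape regression with RRPP

def _design_terms(X: pd.DataFrame, interaction: bool) -> list[tuple[str, np.ndarray]]:
    terms = [(str(c), X[c].to_numpy(dtype=float)[:, None]) for c in X.columns]
    if interaction:
        cols = list(X.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                terms.append(
                    (
                        f"{cols[i]}:{cols[j]}",
                        (X[cols[i]] * X[cols[j]]).to_numpy(dtype=float)[:, None],
                    )
                )
    return terms


def pgls_shape_rrpp(
    phylo: Phylogeny,
    Y: pd.DataFrame,
    X: pd.DataFrame,
    interaction: bool = False,
    iterations: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Phylogenetic regression of a multivariate shape response with RRPP p-values.

    Data and design are premultiplied by the symmetric C^(-1/2); sums of
    squares are sequential (type I) in the user-supplied covariate order,
    with interaction terms (products of covariate pairs) appended last when
    requested. For each term, the residuals of the reduced model (all
    preceding terms) are permuted across species, the response rebuilt, and
    the term's F recomputed; p is the proportion of permutations (observed
    included) with F at least as large as observed.

    Returns an ANOVA-style table: term, df, SS, MS, F, p, plus residual and
    total rows.
    """
    if iterations < 100:
        logger.warning("RRPP with %d iterations is unreliable; use >= 100", iterations)
    Ym = phylo.match_traits(Y).to_numpy(dtype=float)
    Xdf = phylo.match_traits(X)
    N = Ym.shape[0]
    terms = _design_terms(Xdf, interaction)
    P = _c_inv_sqrt(phylo.C)
    Yt = P @ Ym
    intercept = P @ np.ones((N, 1))

    # nested designs D_0 (intercept) .. D_K (all terms), transformed
    designs = [intercept]
    for _, block in terms:
        designs.append(np.column_stack([designs[-1], P @ block]))
    ranks = [np.linalg.matrix_rank(D) for D in designs]
    if ranks[-1] >= N:
        raise np.linalg.LinAlgError("design is saturated or singular after transformation")
    if ranks[-1] - ranks[0] < len(terms):
        raise np.linalg.LinAlgError("singular transformed design (collinear terms)")
    hats = [D @ np.linalg.pinv(D) for D in designs]

    def rss(H: np.ndarray, Ydata: np.ndarray) -> float:
        R = Ydata - H @ Ydata
        return float(np.sum(R * R))

    rss_all = [rss(H, Yt) for H in hats]
    df_terms = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    df_resid = N - ranks[-1]
    mse = rss_all[-1] / df_resid
    rows = []
    rng = np.random.default_rng(seed)
    for k, (name, _) in enumerate(terms):
        ss = rss_all[k] - rss_all[k + 1]
        ms = ss / df_terms[k]
        F_obs = ms / mse
        # RRPP: permute reduced-model residuals
        fitted_red = hats[k] @ Yt
        resid_red = Yt - fitted_red
        count = 1  # observed included
        for _ in range(iterations - 1):
            Yp = fitted_red + resid_red[rng.permutation(N)]
            r_red = rss(hats[k], Yp)
            r_full_k = rss(hats[k + 1], Yp)
            r_full = rss(hats[-1], Yp)
            F_perm = ((r_red - r_full_k) / df_terms[k]) / (r_full / df_resid)
            if F_perm >= F_obs:
                count += 1
        rows.append(
            {"term": name, "df": df_terms[k], "SS": ss, "MS": ms, "F": F_obs,
             "p": count / iterations}
        )
    rows.append(
        {"term": "residual", "df": df_resid, "SS": rss_all[-1], "MS": mse,
         "F": np.nan, "p": np.nan}
    )
    rows.append(
        {"term": "total", "df": N - ranks[0], "SS": rss_all[0], "MS": np.nan,
         "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phylogenetic two-block PLS

@dataclass
class PlsResult:
    """Evolutionary two-block partial least squares."""

    r_pls: float
    p: float
    singular_values: np.ndarray
    left_vectors: np.ndarray  # columns: singular directions in block A
    right_vectors: np.ndarray
    iterations: int
    seed: int | None


def phylo_pls(
    phylo: Phylogeny,
    blockA: pd.DataFrame,
    blockB: pd.DataFrame,
    iterations: int = 10000,
    seed: int | None = None,
) -> PlsResult:
    """Phylogenetic two-block PLS (morphological integration).

    The evolutionary cross-covariance R_AB = (A - a)' C^-1 (B - b)/(N - 1)
    (a, b the phylogenetically weighted column means) is decomposed by SVD;
    r_PLS is the Pearson correlation of the first-pair projection scores
    computed on C^(-1/2)-transformed centered blocks. Significance comes
    from permuting one block's rows across tips (observed included).
    """
    A = phylo.match_traits(blockA).to_numpy(dtype=float)
    B = phylo.match_traits(blockB).to_numpy(dtype=float)
    N = A.shape[0]
    C = phylo.C
    P = _c_inv_sqrt(C)
    # C^-1 = P'P for the symmetric root, so the evolutionary cross-covariance
    # equals the ordinary cross-product of the transformed centered blocks
    At = P @ (A - phylogenetic_weighted_mean(C, A))
    Bt = P @ (B - phylogenetic_weighted_mean(C, B))
    for name, M, raw in (("A", At, A), ("B", Bt, B)):
        if float(np.sum(M * M)) <= 1e-12 * (float(np.sum(raw * raw)) + 1.0):
            raise ValueError(f"block {name} has zero variance")

    def r_first(Bmat: np.ndarray):
        R = At.T @ Bmat / (N - 1)
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        sa = At @ U[:, 0]
        sb = Bmat @ Vt[0]
        return float(np.corrcoef(sa, sb)[0, 1]), s, U, Vt

    r_obs, s, U, Vt = r_first(Bt)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(iterations - 1):
        r_perm, _, _, _ = r_first(Bt[rng.permutation(N)])
        if r_perm >= r_obs:
            count += 1
    return PlsResult(
        r_pls=r_obs, p=count / iterations, singular_values=s,
        left_vectors=U, right_vectors=Vt.T, iterations=iterations, seed=seed,
    )


# ---------------------------------------------------------------------------
# Phylomorphospace

def phylomorphospace_table(
    phylo: Phylogeny, traits: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Tip and estimated-ancestor coordinates for phylomorphospace plots.

    Tips carry the observed trait values; internal nodes carry the BM
    ancestral estimates. The accompanying edge list (parent, child labels)
    lets a caller draw the projected tree through the scatter.
    """
    tips = phylo.match_traits(traits)
    anc = bm_ancestral_states(phylo, traits)
    table = pd.concat([tips.assign(is_tip=True), anc.assign(is_tip=False)])
    table.index.name = "node"
    return table, phylo.edges()
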