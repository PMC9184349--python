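"""Environmental, spatial and host-phylogeny drivers of community turnover.

The driver analysis relates a turnover matrix (betaNTI or RCbray) to
candidate predictors:

* spatial structure, decomposed into PCNM axes (principal coordinates of
  a truncated neighbour distance matrix — Moran eigenvector maps over the
  sampling locations, from broad to fine spatial scales);
* soil covariates (pH, OM, GM);
* host-plant phylogeny, entering as the first two PCoA axes of the plant
  phylogenetic distance matrix.

All candidates are combined by PCA into orthogonal predictor axes, and the
axes driving turnover are found by permutation forward selection in a
distance-based redundancy analysis (dbRDA: PCoA of the response distances
followed by redundancy analysis of the retained axes).  Finally, PCoA axes
of the turnover matrix can be screened against external variables (e.g.
taxon relative abundances) by Spearman correlation with Bonferroni
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "AxisSet", "SelectionTable",
    "pcnm", "pca", "pcoa", "dbrda_forward", "correlate_axes",
    "rda_stats", "shift_to_nonnegative",
]


@dataclass
class AxisSet:
    """Ordered ordination axes (scores per sample, one column per axis)."""

    kind: str                      # "PCNM" | "PCA" | "PCoA"
    scores: pd.DataFrame           # rows = samples, cols = axis names
    eigenvalues: np.ndarray | None = None       # PCNM / PCoA
    explained_variance: np.ndarray | None = None  # PCA
    loadings: pd.DataFrame | None = None          # PCA
    negative_eigenvalues: np.ndarray | None = None  # PCoA, reported not fixed

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclass
class SelectionTable:
    """Forward-selection path of a dbRDA model."""

    steps: pd.DataFrame   # predictor, adj_r2_cum, df_resid, aic, pseudo_F, p
    full_model_adj_r2: float
    alpha: float
    n_perm: int
    seed: int

    @property
    def selected(self) -> list[str]:
        return list(self.steps.index)


# ---------------------------------------------------------------------------
# Ordinations

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d, ids=None, eps: float = 1e-10) -> AxisSet:
    """Principal coordinates of a symmetric dissimilarity matrix.

    Gower double-centering followed by eigendecomposition; axes kept for
    eigenvalues above ``eps`` (relative to the largest), scores scaled by
    sqrt(eigenvalue).  Negative eigenvalues (semimetric input) are reported
    unchanged, not corrected.
    """
    mat = np.asarray(getattr(d, "data", d), dtype=float)
    if ids is None:
        ids = list(getattr(d, "ids", range(mat.shape[0])))
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    g = _gower_center(mat)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(vals.max(), 1.0) if vals.size else 1.0
    pos = vals > eps * scale
    if pos.any():
        scores = vecs[:, pos] * np.sqrt(vals[pos])
        # deterministic sign: largest-magnitude element positive
        for k in range(scores.shape[1]):
            j = np.argmax(np.abs(scores[:, k]))
            if scores[j, k] < 0:
                scores[:, k] *= -1
    else:
        scores = np.zeros((mat.shape[0], 0))
    cols = [f"PCoA{k + 1}" for k in range(scores.shape[1])]
    return AxisSet(kind="PCoA",
                   scores=pd.DataFrame(scores, index=list(ids), columns=cols),
                   eigenvalues=vals[pos],
                   negative_eigenvalues=vals[vals < -eps * scale])


def pcnm(coords: np.ndarray, ids=None, eps: float = 1e-10) -> AxisSet:
    """Principal coordinates of neighbour matrices over sampling locations.

    The Euclidean distance matrix is truncated at t = the longest edge of
    its minimum spanning tree; distances above t are replaced by 4t; the
    truncated matrix is subjected to PCoA and positive-eigenvalue axes are
    returned as spatial predictors, broadest scale first.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 points with 2D coordinates")
    d = squareform(pdist(coords))
    if d.max() == 0:
        raise ValueError("all points identical")
    mst = minimum_spanning_tree(d).toarray()
    t = mst.max()
    trunc = np.where(d <= t, d, 4.0 * t)
    np.fill_diagonal(trunc, 0.0)
    axes = pcoa(trunc, ids=ids, eps=eps)
    scores = axes.scores
    scores.columns = [f"PCNM{k + 1}" for k in range(scores.shape[1])]
    return AxisSet(kind="PCNM", scores=scores, eigenvalues=axes.eigenvalues)


def pca(predictors: pd.DataFrame) -> AxisSet:
    """PCA of z-scored predictor variables (orthonormal loadings)."""
    x = predictors.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in predictors; refusing to impute")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(predictors.columns[sd == 0])
        raise ValueError(f"zero-variance variable(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    model = _SkPCA(n_components=min(z.shape), svd_solver="full")
    scores = model.fit_transform(z)
    # deterministic sign convention
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(model.components_[k]))
        if model.components_[k, j] < 0:
            model.components_[k] *= -1
            scores[:, k] *= -1
    cols = [f"PCA{k + 1}" for k in range(scores.shape[1])]
    return AxisSet(
        kind="PCA",
        scores=pd.DataFrame(scores, index=predictors.index, columns=cols),
        explained_variance=model.explained_variance_,
        loadings=pd.DataFrame(model.components_.T,
                              index=predictors.columns, columns=cols),
    )


def shift_to_nonnegative(values: np.ndarray) -> np.ndarray:
    """Shift a score matrix (e.g. betaNTI, which may be negative) so its
    minimum off-diagonal entry is 0, keeping the zero diagonal."""
    v = np.array(values, dtype=float)
    off = ~np.eye(v.shape[0], dtype=bool)
    m = np.nanmin(v[off])
    if m < 0:
        v[off] = v[off] - m
    np.fill_diagonal(v, 0.0)
    return v


# ---------------------------------------------------------------------------
# dbRDA with permutation forward selection

def _response_matrix(response, ids=None) -> tuple[np.ndarray, list]:
    """PCoA-embed a distance-like response; pass score matrices through."""
    data = getattr(response, "data", response)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and \
            np.allclose(arr, arr.T, equal_nan=True) and \
            np.allclose(np.diag(np.nan_to_num(arr)), 0):
        axes = pcoa(response if ids is None else arr, ids=ids)
        return axes.scores.to_numpy(), list(axes.scores.index)
    idx = list(response.index) if hasattr(response, "index") else \
        (list(ids) if ids is not None else list(range(arr.shape[0])))
    return arr - arr.mean(axis=0), idx


def rda_stats(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(R^2, pseudo-F) of a redundancy analysis of y on x (both centred)."""
    n, q = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    ss_tot = float((y ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    ss_res = ss_tot - ss_fit
    df_res = n - q - 1
    if df_res <= 0 or ss_res <= 0:
        return ss_fit / ss_tot, np.inf
    f = (ss_fit / q) / (ss_res / df_res)
    return ss_fit / ss_tot, f


def _adj_r2(r2: float, n: int, q: int) -> float:
    if n - q - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def _aic_like(ss_res: float, n: int, q: int) -> float:
    if ss_res <= 0:
        return -np.inf
    return n * np.log(ss_res / n) + 2.0 * (q + 1)


def dbrda_forward(response, axes: AxisSet, alpha: float = 0.05,
                  n_perm: int = 999, seed: int = 0,
                  ids=None) -> SelectionTable:
    """Permutation forward selection of predictor axes in a dbRDA.

    ``response`` is either a symmetric dissimilarity matrix (embedded by
    PCoA) or an already-embedded score matrix with rows aligned to
    ``axes.scores``.  At each step the candidate with the smallest
    permutation p-value of its partial pseudo-F enters; permutations use
    residuals of the reduced model (Freedman-Lane).  Selection stops when
    no candidate reaches ``alpha`` or when the cumulative adjusted R^2
    exceeds the full model's adjusted R^2.
    """
    if n_perm < int(round(1.0 / alpha)) - 1:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve alpha={alpha}")
    y, row_ids = _response_matrix(response, ids=ids)
    xall = axes.scores
    if set(row_ids) == set(xall.index):
        xall = xall.loc[row_ids]
    elif len(row_ids) != len(xall):
        raise ValueError("response and predictor rows not aligned")
    names = list(xall.columns)
    x = xall.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    r2_full, _ = rda_stats(y, x)
    adj_full = _adj_r2(r2_full, n, x.shape[1])

    selected: list[int] = []
    rows = []
    ss_tot = float((y ** 2).sum())
    while len(selected) < len(names):
        x_sel = x[:, selected] if selected else np.zeros((n, 0))
        if selected:
            beta, *_ = np.linalg.lstsq(x_sel, y, rcond=None)
            y_fit = x_sel @ beta
        else:
            y_fit = np.zeros_like(y)
        resid = y - y_fit
        ss_sel = float((y_fit ** 2).sum())

        candidates = [j for j in range(len(names)) if j not in selected]
        best = None
        perms = [rng.permutation(n) for _ in range(n_perm)]
        for j in candidates:
            xj = np.column_stack([x_sel, x[:, [j]]])
            f_obs = _partial_f(y, xj, ss_sel, ss_tot, n, len(selected) + 1)
            count = 0
            for perm in perms:
                y_perm = y_fit + resid[perm]
                ssp_tot = float((y_perm ** 2).sum())
                beta_p, *_ = np.linalg.lstsq(x_sel, y_perm, rcond=None) \
                    if selected else (np.zeros((0, y.shape[1])),)
                y_fit_p = x_sel @ beta_p if selected else np.zeros_like(y_perm)
                ssp_sel = float((y_fit_p ** 2).sum())
                f_p = _partial_f(y_perm, xj, ssp_sel, ssp_tot, n,
                                 len(selected) + 1)
                if f_p >= f_obs:
                    count += 1
            p = (1.0 + count) / (1.0 + n_perm)
            if best is None or p < best[0] or (p == best[0] and f_obs > best[1]):
                best = (p, f_obs, j)
        p, f_obs, j = best
        if p > alpha:
            break
        trial = selected + [j]
        r2_trial, _ = rda_stats(y, x[:, trial])
        adj_trial = _adj_r2(r2_trial, n, len(trial))
        if adj_trial > adj_full + 1e-10:  # tolerance for exact-fit ties
            break
        selected = trial
        ss_res = ss_tot * (1.0 - r2_trial)
        rows.append({
            "predictor": names[j],
            "adj_r2_cum": adj_trial,
            "df_resid": n - len(trial) - 1,
            "aic": _aic_like(ss_res, n, len(trial)),
            "pseudo_F": f_obs,
            "p": p,
        })
    steps = pd.DataFrame(rows).set_index("predictor") if rows else \
        pd.DataFrame(columns=["adj_r2_cum", "df_resid", "aic",
                              "pseudo_F", "p"])
    return SelectionTable(steps=steps, full_model_adj_r2=adj_full,
                          alpha=alpha, n_perm=n_perm, seed=seed)


def _partial_f(y, x_new, ss_reduced, ss_tot, n, q_new) -> float:
    """Partial pseudo-F of the last predictor added in x_new."""
    beta, *_ = np.linalg.lstsq(x_new, y, rcond=None)
    ss_full = float(((x_new @ beta) ** 2).sum())
    ss_res = ss_tot - ss_full
    df_res = n - q_new - 1
    if df_res <= 0 or ss_res <= 0:
        return np.inf
    return (ss_full - ss_reduced) / (ss_res / df_res)


# ---------------------------------------------------------------------------
# Correlation screen

def correlate_axes(a: pd.DataFrame, b: pd.DataFrame,
                   family: int | None = None) -> pd.DataFrame:
    """Spearman correlations of every column pair, Bonferroni-adjusted.

    ``family`` defaults to the number of tests performed
    (columns(a) x columns(b)).
    """
    rows = []
    n_tests = a.shape[1] * b.shape[1]
    fam = family if family is not None else n_tests
    for ca in a.columns:
        xa = a[ca].to_numpy(dtype=float)
        if np.ptp(xa) == 0:
            raise ValueError(f"constant column {ca!r}")
        for cb in b.columns:
            xb = b[cb].to_numpy(dtype=float)
            if np.ptp(xb) == 0:
                raise ValueError(f"constant column {cb!r}")
            rho, p = stats.spearmanr(xa, xb)
            rows.append({"axis": ca, "variable": cb, "rho": float(rho),
                         "p": float(p),
                         "p_bonferroni": float(min(1.0, p * fam))})
    return pd.DataFrame(rows)
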