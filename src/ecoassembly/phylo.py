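"""Abundance-weighted MNTD/NTI and betaMNTD/betaNTI with taxa-shuffle nulls.

MNTD is the abundance-weighted mean distance from each taxon in a community
to its nearest phylogenetic neighbour in the same community; betaMNTD is the
between-community analogue (nearest neighbour in the *other* community).
Both are compared against a null distribution obtained by shuffling the
taxon labels of the cophenetic distance matrix — abundances stay put, only
the identity (hence the phylogenetic position) of each taxon changes.

NTI = -(MNTD_obs - mean_null) / sd_null, so phylogenetic clustering
(observed distances smaller than null) gives NTI > 0.  betaNTI keeps the
raw z-score sign: betaNTI > 2 means more phylogenetic turnover than the
null (heterogeneous selection), betaNTI < -2 less (homogeneous selection).

The shuffle pool is the set of taxa occurring in the restricted sample
pool, not the full regional tree: restricting the input matrix to a habitat
unit therefore restricts the null the way scale-dependent inference
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import Dataset, DatedTree, OtuTable, relative_abundance

__all__ = [
    "cophenetic_distances",
    "mntd_weighted",
    "beta_mntd",
    "nti",
    "beta_nti_matrix",
    "NtiResult",
    "TurnoverMatrix",
]


def cophenetic_distances(tree: DatedTree,
                         ids: list[str] | None = None) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances."""
    return tree.cophenetic(ids=ids)


def mntd_weighted(f: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted mean nearest-taxon distance within one community.

    ``f`` is a relative-abundance vector over the taxa indexing ``d``;
    the nearest neighbour excludes the taxon itself.  Communities with
    fewer than two taxa have no nearest neighbour: returns NaN.
    """
    f = np.asarray(f, dtype=float)
    support = np.flatnonzero(f > 0)
    if support.size < 2:
        return float("nan")
    sub = np.array(d)[np.ix_(support, support)].astype(float)
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    w = f[support] / f[support].sum()
    return float(w @ nearest)


def beta_mntd(f_k: np.ndarray, f_l: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted between-community mean nearest-taxon distance.

    0.5 * [ sum_i f_ik * min_{j in l} d(i,j) + sum_j f_jl * min_{i in k} d(j,i) ].
    Taxa shared by both communities contribute distance 0.
    """
    f_k = np.asarray(f_k, dtype=float)
    f_l = np.asarray(f_l, dtype=float)
    d = np.asarray(d, dtype=float)
    sk = np.flatnonzero(f_k > 0)
    sl = np.flatnonzero(f_l > 0)
    if sk.size == 0 or sl.size == 0:
        raise ValueError("empty community")
    wk = f_k[sk] / f_k[sk].sum()
    wl = f_l[sl] / f_l[sl].sum()
    to_l = d[np.ix_(sk, sl)].min(axis=1)
    to_k = d[np.ix_(sl, sk)].min(axis=1)
    return float(0.5 * (wk @ to_l + wl @ to_k))


# ---------------------------------------------------------------------------
# Result containers

@dataclass
class NtiResult:
    """Per-sample MNTD and its taxa-shuffle z-score (NTI)."""

    table: pd.DataFrame  # sample_id-indexed: mntd_obs, null_mean, null_sd, nti, valid
    n_null: int
    seed: int
    pool_id: str = "region"

    def __getitem__(self, sample_id: str) -> pd.Series:
        return self.table.loc[sample_id]


@dataclass
class TurnoverMatrix:
    """Pairwise turnover scores with null-model provenance.

    ``values[i, j]`` is the score for the (i, j) sample pair; the diagonal
    and any pair whose null collapsed (sd = 0) are flagged invalid.
    """

    ids: list[str]
    values: np.ndarray
    metric: str                      # "bNTI" or "RCbray"
    pool_id: str
    n_null: int
    seed: int
    valid: np.ndarray = field(default=None)  # boolean mask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        assert self.values.shape == (n, n)
        if self.valid is None:
            self.valid = ~np.eye(n, dtype=bool)
        assert np.allclose(self.values, self.values.T, equal_nan=True)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered within-pool pair."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "sample_a": self.ids[i],
                    "sample_b": self.ids[j],
                    "pool_id": self.pool_id,
                    "metric": self.metric,
                    "value": self.values[i, j],
                    "valid": bool(self.valid[i, j]),
                })
        return pd.DataFrame(rows)

    def pair_value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# Null models

def _pool_setup(table: OtuTable, d: DistanceMatrix, pool):
    """Restrict table to the pool's samples and occurring taxa; return
    (sample ids, relative abundances, distance submatrix)."""
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError("null pool needs at least 2 samples")
    sub = table.subset(pool, drop_empty_otus=True)
    f = relative_abundance(sub).to_numpy()
    ids = list(d.ids)
    idx = [ids.index(o) for o in sub.otu_ids]
    dsub = np.asarray(d.data)[np.ix_(idx, idx)]
    return sub, f, dsub


def nti(table: OtuTable, d: DistanceMatrix, pool=None,
        n_null: int = 999, seed: int = 0, pool_id: str = "region") -> NtiResult:
    """NTI per sample against a taxa-labels shuffle over the pool's taxa.

    ``pool`` defaults to all samples.  The null permutes the taxon labels of
    the (pool-restricted) distance matrix uniformly at random and recomputes
    the weighted MNTD of every sample under each permutation.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    pool = list(pool) if pool is not None else table.sample_ids
    sub, f, dsub = _pool_setup(table, d, pool)
    rng = np.random.default_rng(seed)
    n_samp, n_tax = f.shape

    obs = np.array([mntd_weighted(f[s], dsub) for s in range(n_samp)])
    nulls = np.empty((n_null, n_samp))
    for r in range(n_null):
        perm = rng.permutation(n_tax)
        dperm = dsub[np.ix_(perm, perm)]
        nulls[r] = [mntd_weighted(f[s], dperm) for s in range(n_samp)]
    null_mean = np.nanmean(nulls, axis=0)
    null_sd = np.nanstd(nulls, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = -(obs - null_mean) / null_sd
    sd_floor = 1e-10 * np.maximum(np.abs(null_mean), 1.0)
    valid = np.isfinite(obs) & (null_sd > sd_floor)
    z = np.where(valid, z, np.nan)
    tbl = pd.DataFrame({
        "mntd_obs": obs, "null_mean": null_mean, "null_sd": null_sd,
        "nti": z, "valid": valid,
    }, index=pd.Index(sub.sample_ids, name="sample_id"))
    return NtiResult(tbl, n_null=n_null, seed=seed, pool_id=pool_id)


def _beta_mntd_all_pairs(f: np.ndarray, d: np.ndarray,
                         supports: list[np.ndarray]) -> np.ndarray:
    """betaMNTD for every sample pair, vectorised.

    nearest[s, i] = distance from taxon i to its nearest taxon present in
    sample s (0 if i itself is present); the pair matrix is then the
    symmetrised weighted average  0.5 * (F @ nearest.T + (F @ nearest.T).T).
    """
    n_samp, n_tax = f.shape
    nearest = np.empty((n_samp, n_tax))
    for s in range(n_samp):
        nearest[s] = d[:, supports[s]].min(axis=1)
    g = f @ nearest.T  # g[k, l] = sum_i f_ik * min_{j in l} d(i, j)
    return 0.5 * (g + g.T)


def beta_nti_matrix(table: OtuTable, d: DistanceMatrix, pool=None,
                    n_null: int = 999, seed: int = 0,
                    pool_id: str = "region") -> TurnoverMatrix:
    """betaNTI for every within-pool sample pair under the taxa-shuffle null.

    One shared permutation stream serves the whole matrix: permutation r is
    applied to the distance matrix and betaMNTD recomputed for all pairs, so
    the result is reproducible from the seed alone.  Pairs whose null
    distribution is degenerate (sd = 0, e.g. identical communities, whose
    shared taxa sit at distance 0 under every relabelling) are flagged
    invalid rather than scored.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    pool = list(pool) if pool is not None else table.sample_ids
    sub, f, dsub = _pool_setup(table, d, pool)
    rng = np.random.default_rng(seed)
    n_samp, n_tax = f.shape
    supports = [np.flatnonzero(f[s] > 0) for s in range(n_samp)]

    obs = _beta_mntd_all_pairs(f, dsub, supports)
    nulls = np.empty((n_null, n_samp, n_samp))
    for r in range(n_null):
        perm = rng.permutation(n_tax)
        dperm = dsub[np.ix_(perm, perm)]
        nulls[r] = _beta_mntd_all_pairs(f, dperm, supports)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - null_mean) / null_sd
    sd_floor = 1e-10 * np.maximum(np.abs(null_mean), 1.0)
    valid = (null_sd > sd_floor) & ~np.eye(n_samp, dtype=bool)
    z = np.where(valid, z, np.nan)
    np.fill_diagonal(z, np.nan)
    return TurnoverMatrix(ids=sub.sample_ids, values=z, metric="bNTI",
                          pool_id=pool_id, n_null=n_null, seed=seed,
                          valid=valid)
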