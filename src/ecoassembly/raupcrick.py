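"""Bray-Curtis dissimilarity and its Raup-Crick null model (RCbray).

RCbray asks whether two communities are more, or less, compositionally
different than expected if each were assembled probabilistically from the
regional (or scale-restricted) species pool.  Null communities preserve
each real community's richness and total read count; species identities
are drawn without replacement with probability proportional to occupancy
across the pool, and the remaining individuals are assigned multinomially
with probability proportional to pool-wide relative abundance.  The
observed Bray-Curtis value is located within the null distribution and
rescaled to [-1, 1]:

    RCbray = 2 * ( (#{null < obs} + 0.5 * #{null == obs}) / n_null - 0.5 )

RCbray > 0.95: more turnover than chance (dispersal limitation candidate);
RCbray < -0.95: less turnover than chance (homogenizing dispersal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OtuTable
from .phylo import TurnoverMatrix

__all__ = ["bray_curtis", "RcConfig", "rc_bray_matrix", "null_community"]


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC = sum|x_i - y_i| / sum(x_i + y_i); counts or relative abundances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("empty community")
    return float(np.abs(x - y).sum() / (x + y).sum())


@dataclass
class RcConfig:
    """Null-assembly recipe for RCbray.

    occupancy_weighting: first-draw species probabilities proportional to
    the number of pool samples each species occurs in (else uniform).
    abundance_fill: remaining individuals assigned proportionally to
    pool-wide relative abundance (else uniform over the drawn species).
    relative_mode: score observed pairs on relative abundances instead of
    raw counts (nulls are always built on the count scale).
    """

    n_null: int = 999
    occupancy_weighting: bool = True
    abundance_fill: bool = True
    relative_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")

    def provenance(self) -> dict:
        return {
            "n_null": self.n_null,
            "occupancy_weighting": self.occupancy_weighting,
            "abundance_fill": self.abundance_fill,
            "relative_mode": self.relative_mode,
            "totals": "preserve each sample's observed total",
            "seed": self.seed,
        }


def null_community(richness: int, total: int, occ_p: np.ndarray,
                   ab_p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One null community with the given richness and total count.

    Each drawn species receives one individual; the remaining
    ``total - richness`` individuals are filled multinomially.
    """
    n_tax = occ_p.size
    assert richness <= n_tax, "richness exceeds pool richness"
    chosen = rng.choice(n_tax, size=richness, replace=False, p=occ_p)
    counts = np.zeros(n_tax, dtype=np.int64)
    counts[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        fill_p = ab_p[chosen]
        fill_p = fill_p / fill_p.sum()
        counts[chosen] += rng.multinomial(remaining, fill_p)
    return counts


def _bc_matrix(counts: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis over rows of a count matrix."""
    sums = counts.sum(axis=1)
    num = np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)
    den = sums[:, None] + sums[None, :]
    return num / den


def rc_bray_matrix(table: OtuTable, pool=None,
                   cfg: RcConfig | None = None,
                   pool_id: str = "region") -> TurnoverMatrix:
    """RCbray for every within-pool sample pair.

    Per null replicate one null community is drawn for each pool sample
    (preserving its richness and total) and all pairwise Bray-Curtis
    values of that replicate are scored against the observed ones.
    """
    cfg = cfg or RcConfig()
    pool = list(pool) if pool is not None else table.sample_ids
    if len(pool) < 2:
        raise ValueError("null pool needs at least 2 samples")
    sub = table.subset(pool, drop_empty_otus=True)
    counts = sub.counts.to_numpy(dtype=np.int64)
    n_samp, n_tax = counts.shape

    occupancy = (counts > 0).sum(axis=0).astype(float)
    pooled = counts.sum(axis=0).astype(float)
    occ_p = (occupancy / occupancy.sum() if cfg.occupancy_weighting
             else np.full(n_tax, 1.0 / n_tax))
    ab_p = (pooled / pooled.sum() if cfg.abundance_fill
            else np.full(n_tax, 1.0 / n_tax))

    if cfg.relative_mode:
        rel = counts / counts.sum(axis=1, keepdims=True)
        obs = _bc_matrix_float(rel)
    else:
        obs = _bc_matrix(counts)

    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    rng = np.random.default_rng(cfg.seed)
    less = np.zeros((n_samp, n_samp))
    ties = np.zeros((n_samp, n_samp))
    null_counts = np.empty_like(counts)
    for _ in range(cfg.n_null):
        for s in range(n_samp):
            null_counts[s] = null_community(int(richness[s]), int(totals[s]),
                                            occ_p, ab_p, rng)
        null_bc = _bc_matrix(null_counts)
        less += null_bc < obs
        ties += null_bc == obs
    rc = 2.0 * ((less + 0.5 * ties) / cfg.n_null - 0.5)
    np.fill_diagonal(rc, np.nan)
    valid = ~np.eye(n_samp, dtype=bool)
    return TurnoverMatrix(ids=sub.sample_ids, values=rc, metric="RCbray",
                          pool_id=pool_id, n_null=cfg.n_null, seed=cfg.seed,
                          valid=valid)


def _bc_matrix_float(rel: np.ndarray) -> np.ndarray:
    num = np.abs(rel[:, None, :] - rel[None, :, :]).sum(axis=2)
    den = rel.sum(axis=1)[:, None] + rel.sum(axis=1)[None, :]
    return num / den
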