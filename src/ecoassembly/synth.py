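"""Synthetic datasets with known community-assembly regimes.

The generator emulates the statistical structure the inference assumes: a
dated birth-death phylogeny over OTUs, Brownian niche evolution along it
(phylogenetic conservatism of the environmental optimum), a nested sampling
design (sites > plots > host individuals) with hierarchical coordinates,
latent environmental values mapped to soil covariates, and read counts
drawn multinomially from scenario-specific expected abundances:

* ``env_filtering``  — Gaussian niche filtering around each sample's
  environment (deterministic selection; strength set by ``sigma_env`` in
  units of the niche standard deviation, smaller = stronger filtering);
* ``dispersal_limitation`` — exponential distance decay from each taxon's
  home location (kernel length ``decay_length`` in coordinate metres);
* ``homogenizing_dispersal`` — per-plot lognormal abundance perturbations
  mixed toward the regional pool with migration weight ``m``;
* ``neutral_drift``  — multinomial resampling chains from the regional
  pool with no selection term;
* ``mixed``          — filtering and distance decay combined.

Default design mirrors a two-park field survey: 2 sites x 4 plots x
3 host species x 4 individuals minus 4 dropouts = 92 samples, 449 OTUs.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import Dataset, DatedTree, OtuTable, SampleFrame, align

__all__ = ["SynthConfig", "GroundTruth", "simulate_tree", "evolve_niche",
           "simulate_metacommunity", "simulate_dataset", "SCENARIOS"]

SCENARIOS = ["neutral_drift", "env_filtering", "dispersal_limitation",
             "homogenizing_dispersal", "mixed"]

#: expected dominant classifier outcome per scenario (ground truth labels)
_EXPECTED_DOMINANT = {
    "neutral_drift": "drift/dispersal (stochastic)",
    "env_filtering": "selection",
    "dispersal_limitation": "dispersal_limitation",
    "homogenizing_dispersal": "homogenizing_dispersal",
    "mixed": "selection + dispersal_limitation",
}


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the emulated study design."""

    n_taxa: int = 449
    birth_rate: float = 1.0
    death_rate: float = 0.5
    n_sites: int = 2
    n_plots: int = 4          # per site
    n_hosts: int = 3          # per plot
    n_reps: int = 4           # individuals per host per plot
    n_dropout: int = 4        # samples removed from the full design
    scenario: str = "neutral_drift"
    sigma_env: float = 0.4    # filter width, units of niche sd
    niche_rate: float = 1.0   # Brownian rate per unit branch time
    migration: float = 0.9    # homogenizing mixing weight m in [0, 1]
    decay_length: float = 2000.0   # distance-decay lambda, metres
    env_contrast: float = 2.0  # site env offset, units of niche sd
    reads_per_sample: int = 2000
    drift_generations: int = 2
    drift_pop_size: int = 2000  # individuals per resampling step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("birth_rate", "death_rate", "sigma_env", "niche_rate",
                     "migration", "decay_length", "reads_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_reps - (self.n_dropout > 0) < 1:
            raise ValueError("design must keep >= 1 replicate per unit")


@dataclass
class GroundTruth:
    """What the generator planted, recorded before sampling noise."""

    scenario: str
    env: dict            # sample_id -> latent environment value
    niche: dict          # otu_id -> niche optimum
    taxon_home: dict | None   # otu_id -> (x, y), dispersal scenarios only
    expected_dominant_process: str
    config: dict = field(default_factory=dict)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


# ---------------------------------------------------------------------------

def simulate_tree(cfg: SynthConfig, max_retries: int = 20) -> DatedTree:
    """Birth-death tree conditioned on ``n_taxa`` extant leaves."""
    if cfg.birth_rate <= cfg.death_rate:
        raise ValueError("birth rate must exceed death rate")
    rng = random.Random(cfg.seed)
    last_err = None
    for _ in range(max_retries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=cfg.birth_rate, death_rate=cfg.death_rate,
                num_extant_tips=cfg.n_taxa, rng=rng)
            break
        except Exception as exc:  # total extinction: resample
            last_err = exc
    else:
        raise RuntimeError(f"tree simulation failed: {last_err}")
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1:04d}"
    return DatedTree(tree)


def evolve_niche(tree: DatedTree, rate: float, seed: int = 0,
                 root_value: float = 0.0) -> pd.Series:
    """Brownian-motion trait along the tree; returns tip optima.

    Tip variance accumulates as rate x root-to-tip path length.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
            continue
        el = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(rate * el)) if rate * el > 0 else 0.0
        values[id(node)] = values[id(node.parent_node)] + step
    tips = {lf.taxon.label: values[id(lf)]
            for lf in tree.tree.leaf_node_iter()}
    return pd.Series(tips, name="niche")


# ---------------------------------------------------------------------------

def _design_frame(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sampling design: ids, factors, hierarchical coordinates, seasons."""
    rows = []
    site_centers = {f"S{si + 1}": np.array([si * 100_000.0, 0.0])
                    for si in range(cfg.n_sites)}
    hosts = [f"H{h + 1}" for h in range(cfg.n_hosts)]
    for si in range(cfg.n_sites):
        site = f"S{si + 1}"
        plot_offsets = rng.uniform(-1000, 1000, size=(cfg.n_plots, 2))
        for pi in range(cfg.n_plots):
            plot = f"{site}P{pi + 1}"
            plot_xy = site_centers[site] + plot_offsets[pi]
            for host in hosts:
                for r in range(cfg.n_reps):
                    xy = plot_xy + rng.uniform(-20, 20, size=2)
                    rows.append({
                        "sample_id": f"{plot}{host}R{r + 1}",
                        "site": site, "plot": plot, "host": host,
                        "season": "spring" if r % 2 == 0 else "autumn",
                        "x": xy[0], "y": xy[1],
                    })
    return pd.DataFrame(rows)


def _latent_environment(df: pd.DataFrame, cfg: SynthConfig,
                        niche_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Planted gradient: contrasting sites, smaller plot and host offsets."""
    sites = sorted(df["site"].unique())
    site_val = {s: cfg.env_contrast * niche_sd * (2 * i / max(len(sites) - 1, 1) - 1)
                for i, s in enumerate(sites)}
    plots = sorted(df["plot"].unique())
    plot_val = {p: rng.normal(0.0, 0.2 * niche_sd) for p in plots}
    hosts = sorted(df["host"].unique())
    host_val = {h: rng.normal(0.0, 0.1 * niche_sd) for h in hosts}
    env = (df["site"].map(site_val).to_numpy()
           + df["plot"].map(plot_val).to_numpy()
           + df["host"].map(host_val).to_numpy()
           + rng.normal(0.0, 0.05 * niche_sd, size=len(df)))
    return env


def _covariates(env: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Soil covariates as noisy linear maps of the latent environment."""
    z = (env - env.mean()) / (env.std() or 1.0)
    return pd.DataFrame({
        "pH": 7.0 + 0.6 * z + rng.normal(0, 0.1, size=z.size),
        "OM": np.clip(12.0 + 4.0 * z + rng.normal(0, 1.0, size=z.size), 0.5, None),
        "GM": np.clip(20.0 + 5.0 * z + rng.normal(0, 2.0, size=z.size), 1.0, None),
    })


def simulate_metacommunity(tree: DatedTree, niches: pd.Series,
                           cfg: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """OTU table + metadata under the configured assembly scenario."""
    rng = np.random.default_rng(cfg.seed + 1)
    otu_ids = list(niches.index)
    n_tax = len(otu_ids)
    niche = niches.to_numpy(dtype=float)
    niche_sd = niche.std() or 1.0

    df = _design_frame(cfg, rng)
    env = _latent_environment(df, cfg, niche_sd, rng)
    cov = _covariates(env, rng)
    meta = pd.concat([df, cov], axis=1)

    # regional pool: lognormal base abundances, independent of phylogeny
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_tax)
    base /= base.sum()

    taxon_home = None
    if cfg.scenario in ("dispersal_limitation", "mixed"):
        # each taxon originates at a uniformly chosen sampling location
        home_idx = rng.integers(0, len(df), size=n_tax)
        taxon_home = df[["x", "y"]].to_numpy()[home_idx]

    plot_perturb = {}
    if cfg.scenario == "homogenizing_dispersal":
        for p in sorted(df["plot"].unique()):
            plot_perturb[p] = rng.lognormal(0.0, 1.0, size=n_tax)

    counts = np.zeros((len(df), n_tax), dtype=np.int64)
    for s in range(len(df)):
        row = df.iloc[s]
        if cfg.scenario == "neutral_drift":
            # independent demographic chain per sample from the regional pool
            p = base
            for _ in range(cfg.drift_generations):
                draw = rng.multinomial(cfg.drift_pop_size, p)
                if (draw > 0).sum() < 2:   # absorbing state: restart chain
                    p = base
                    break
                p = draw / cfg.drift_pop_size
            w = p
        else:
            w = base.copy()
            if cfg.scenario in ("env_filtering", "mixed"):
                if cfg.sigma_env == 0:
                    raise ValueError(
                        "sigma_env = 0 with heterogeneous environment "
                        "collapses communities to single taxa")
                width = cfg.sigma_env * niche_sd
                w = w * np.exp(-(env[s] - niche) ** 2 / (2.0 * width ** 2))
            if cfg.scenario in ("dispersal_limitation", "mixed"):
                dist = np.hypot(taxon_home[:, 0] - row["x"],
                                taxon_home[:, 1] - row["y"])
                w = w * np.exp(-dist / cfg.decay_length)
            if cfg.scenario == "homogenizing_dispersal":
                local = base * plot_perturb[row["plot"]]
                local /= local.sum()
                w = (1.0 - cfg.migration) * local + cfg.migration * base
        if w.sum() <= 0:
            raise ValueError("degenerate expected abundances (all zero)")
        w = w / w.sum()
        counts[s] = rng.multinomial(cfg.reads_per_sample, w)

    meta = meta.set_index("sample_id")
    table = pd.DataFrame(counts, index=meta.index, columns=otu_ids)

    if cfg.n_dropout > 0:
        units = meta.groupby(["site", "plot", "host"], observed=True)
        unit_list = [g.index.to_list() for _, g in units]
        drop_units = rng.choice(len(unit_list), size=cfg.n_dropout,
                                replace=False)
        drop = [unit_list[u][int(rng.integers(len(unit_list[u])))]
                for u in drop_units]
        table = table.drop(index=drop)
        meta = meta.drop(index=drop)

    # drop never-observed taxa; guard the no-empty-sample invariant
    table = table.loc[:, table.sum(axis=0) > 0]
    assert (table.sum(axis=1) > 0).all()

    ds = align(OtuTable(table), tree, SampleFrame(meta))
    truth = GroundTruth(
        scenario=cfg.scenario,
        env=dict(zip(df["sample_id"], map(float, env))),
        niche={k: float(v) for k, v in niches.items()},
        taxon_home=(None if taxon_home is None else
                    {otu_ids[i]: (float(taxon_home[i, 0]),
                                  float(taxon_home[i, 1]))
                     for i in range(n_tax)}),
        expected_dominant_process=_EXPECTED_DOMINANT[cfg.scenario],
        config=asdict(cfg),
    )
    return ds, truth


def simulate_dataset(cfg: SynthConfig | None = None,
                     **overrides) -> tuple[Dataset, GroundTruth]:
    """One-call generator: tree + niches + metacommunity from a config."""
    if cfg is None:
        cfg = SynthConfig(**overrides)
    elif overrides:
        cfg = SynthConfig(**{**asdict(cfg), **overrides})
    tree = simulate_tree(cfg)
    niches = evolve_niche(tree, cfg.niche_rate, seed=cfg.seed + 7)
    return simulate_metacommunity(tree, niches, cfg)
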