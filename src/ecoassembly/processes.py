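"""Assembly-process classification and its scale dependency.

Each community pair is assigned one ecological assembly process from its
phylogenetic (betaNTI) and compositional (RCbray) turnover:

    betaNTI >  2                     -> heterogeneous selection
    betaNTI < -2                     -> homogeneous selection
    |betaNTI| <= 2 and RC >  0.95    -> dispersal limitation
    |betaNTI| <= 2 and RC < -0.95    -> homogenizing dispersal
    |betaNTI| <= 2 and |RC| <= 0.95  -> drift

Thresholds are strict inequalities; boundary values fall through to the
next rule; non-finite inputs are "unclassified".  Scale dependency is
obtained by recomputing both metrics with the null pool restricted to each
habitat unit of a nesting level (region / site / plot / host) and counting
within-unit pair assignments per level; a chi-square test of homogeneity on
the [assigned vs not] x [levels] table detects variation across scales.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .phylo import beta_nti_matrix, nti
from .raupcrick import RcConfig, rc_bray_matrix

__all__ = [
    "PROCESS_LABELS",
    "SCALE_LEVELS",
    "classify_pair",
    "partition_by_scale",
    "chi_square_across_scales",
    "nti_by_scale",
    "ProcessTable",
]

logger = logging.getLogger(__name__)

PROCESS_LABELS = [
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
]

#: coarse-to-fine nesting levels and the metadata columns defining units
SCALE_LEVELS = ["region", "site", "plot", "host"]

SELECTION = {"heterogeneous_selection", "homogeneous_selection"}


def classify_pair(bnti: float, rc: float) -> str:
    """Assembly-process label for one pair of communities."""
    if not (math.isfinite(bnti) and math.isfinite(rc)):
        return "unclassified"
    if bnti > 2:
        return "heterogeneous_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class ProcessTable:
    """Per-scale pair labels, process counts/percentages and chi-square tests."""

    pairs: pd.DataFrame       # level, unit, sample_a, sample_b, bnti, rcbray, process
    by_scale: pd.DataFrame    # level x process counts, pct, selection aggregate
    chi_square: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    def counts(self, level: str) -> pd.Series:
        return self.by_scale.loc[level, [f"n_{p}" for p in PROCESS_LABELS]]


def _summarise_level(pairs: pd.DataFrame, level: str) -> dict:
    sub = pairs[(pairs["level"] == level) & (pairs["process"] != "unclassified")]
    n = len(sub)
    row = {"level": level, "n_pairs": n}
    for p in PROCESS_LABELS:
        c = int((sub["process"] == p).sum())
        row[f"n_{p}"] = c
        row[f"pct_{p}"] = 100.0 * c / n if n else np.nan
    row["n_selection"] = row["n_heterogeneous_selection"] + row["n_homogeneous_selection"]
    row["pct_selection"] = (100.0 * row["n_selection"] / n) if n else np.nan
    return row


def partition_by_scale(ds: Dataset, levels=SCALE_LEVELS, n_null: int = 999,
                       rc_config: RcConfig | None = None, seed: int = 0,
                       min_unit_size: int = 2) -> ProcessTable:
    """Classify all within-unit pairs at each nesting level.

    For every habitat unit at a level, betaNTI and RCbray are computed with
    the null pool equal to that unit's samples (taxa restricted to those
    occurring in the unit) and each within-unit pair is classified.  Units
    with fewer than ``min_unit_size`` samples are skipped with a warning.
    Seeds for the per-unit null models are derived deterministically from
    ``seed`` and the unit key, so the result is reproducible and does not
    depend on unit iteration order.
    """
    d = ds.cophenetic()
    rc_base = rc_config or RcConfig(n_null=n_null)
    rows = []
    warnings: list[str] = []
    ss = np.random.SeedSequence(seed)
    for level in levels:
        keys = ds.meta.unit_keys(level)
        for unit in sorted(keys.unique()):
            members = list(keys.index[keys == unit])
            if len(members) < min_unit_size:
                msg = f"unit {unit!r} at level {level!r} has {len(members)} sample(s); skipped"
                warnings.append(msg)
                logger.warning(msg)
                continue
            sub_seed = _unit_seed(ss, level, unit)
            bnti = beta_nti_matrix(ds.otu, d, pool=members, n_null=n_null,
                                   seed=sub_seed, pool_id=f"{level}:{unit}")
            rc_cfg = RcConfig(n_null=rc_base.n_null,
                              occupancy_weighting=rc_base.occupancy_weighting,
                              abundance_fill=rc_base.abundance_fill,
                              relative_mode=rc_base.relative_mode,
                              seed=sub_seed + 1)
            rc = rc_bray_matrix(ds.otu, pool=members, cfg=rc_cfg,
                                pool_id=f"{level}:{unit}")
            for a, b in itertools.combinations(bnti.ids, 2):
                bv = bnti.pair_value(a, b)
                rv = rc.pair_value(a, b)
                rows.append({
                    "level": level, "unit": unit,
                    "sample_a": a, "sample_b": b,
                    "bnti": bv, "rcbray": rv,
                    "process": classify_pair(bv, rv),
                })
    pairs = pd.DataFrame(rows)
    by_scale = pd.DataFrame([_summarise_level(pairs, lv) for lv in levels]
                            ).set_index("level")
    pt = ProcessTable(pairs=pairs, by_scale=by_scale, warnings=warnings)
    pt.chi_square = _chi_square_table(pt)
    return pt


def _unit_seed(ss: np.random.SeedSequence, level: str, unit: str) -> int:
    """Stable per-unit child seed (< 2**31), independent of iteration order."""
    h = np.frombuffer(f"{level}|{unit}".encode(), dtype=np.uint8)
    child = np.random.SeedSequence(entropy=ss.entropy,
                                   spawn_key=tuple(int(v) for v in h))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31 - 1))


def chi_square_across_scales(pt: ProcessTable, process: str,
                             omnibus: bool = False):
    """Chi-square homogeneity test of a process's share across levels.

    Builds the 2 x S table [pairs assigned to ``process``, pairs assigned
    elsewhere] over the S levels (``process`` may be the aggregate
    "selection").  With ``omnibus=True`` tests the full 5 x S table
    instead.  No continuity correction.  Returns (chi2, df, p) plus a
    recorded warning when any expected cell is below 1.
    """
    classified = pt.pairs[pt.pairs["process"] != "unclassified"]
    levels = [lv for lv in classified["level"].unique()
              if (classified["level"] == lv).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 levels with classified pairs")
    if omnibus:
        table = np.array([[int(((classified["level"] == lv)
                                & (classified["process"] == p)).sum())
                           for lv in levels] for p in PROCESS_LABELS])
        table = table[table.sum(axis=1) > 0]
    else:
        in_proc = (classified["process"].isin(SELECTION)
                   if process == "selection"
                   else classified["process"] == process)
        hit = np.array([int((in_proc & (classified["level"] == lv)).sum())
                        for lv in levels])
        tot = np.array([int((classified["level"] == lv).sum())
                        for lv in levels])
        table = np.vstack([hit, tot - hit])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    col_tot = table.sum(axis=0, keepdims=True)
    props = table / col_tot
    if np.all(props == props[:, [0]]):
        # proportions identical across levels: chi2 is exactly 0
        df = (table.shape[0] - 1) * (table.shape[1] - 1)
        return 0.0, int(df), 1.0
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if expected.min() < 1:
        pt.warnings.append(
            f"chi-square for {process!r}: expected cell below 1")
    return float(chi2), int(df), float(p)


def _chi_square_table(pt: ProcessTable) -> pd.DataFrame:
    rows = []
    for proc in ["selection"] + PROCESS_LABELS:
        try:
            chi2, df, p = chi_square_across_scales(pt, proc)
        except ValueError:
            continue
        rows.append({"process": proc, "chi2": chi2, "df": df, "p": p})
    if not rows:
        return pd.DataFrame(columns=["chi2", "df", "p"],
                            index=pd.Index([], name="process"))
    return pd.DataFrame(rows).set_index("process")


def nti_by_scale(ds: Dataset, levels=SCALE_LEVELS, n_null: int = 999,
                 seed: int = 0, min_unit_size: int = 2):
    """Scale-restricted NTI per sample, with per-level tests.

    NTI for a sample at a level uses the null pool of the sample's own
    habitat unit at that level.  Per level: one-sample two-sided t test of
    the NTI values against 0; across levels: Tukey HSD on the level means.

    Returns (per-sample long DataFrame, per-level summary DataFrame,
    Tukey result or None).
    """
    d = ds.cophenetic()
    ss = np.random.SeedSequence(seed)
    long_rows = []
    for level in levels:
        keys = ds.meta.unit_keys(level)
        for unit in sorted(keys.unique()):
            members = list(keys.index[keys == unit])
            if len(members) < min_unit_size:
                continue
            res = nti(ds.otu, d, pool=members, n_null=n_null,
                      seed=_unit_seed(ss, level, unit),
                      pool_id=f"{level}:{unit}")
            for sid, row in res.table.iterrows():
                long_rows.append({"level": level, "unit": unit,
                                  "sample_id": sid, "nti": row["nti"],
                                  "valid": bool(row["valid"])})
    long = pd.DataFrame(long_rows)
    summaries = []
    groups = []
    for level in levels:
        vals = long.loc[(long["level"] == level) & long["valid"], "nti"].dropna()
        if len(vals) < 2:
            continue
        if np.ptp(vals.to_numpy()) == 0:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_1samp(vals, 0.0)
        summaries.append({"level": level, "n": len(vals),
                          "mean_nti": float(vals.mean()),
                          "sd_nti": float(vals.std(ddof=1)),
                          "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
                          "p": float(p) if np.isfinite(p) else np.nan})
        groups.append(vals.to_numpy())
    summary = pd.DataFrame(summaries).set_index("level")
    tukey = None
    if len(groups) >= 2 and any(np.ptp(g) > 0 for g in groups):
        tukey = stats.tukey_hsd(*groups)
    return long, summary, tukey
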