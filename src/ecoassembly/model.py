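"""Model/Results front end for the assembly-process inference.

Two model classes mirror the two halves of the analysis:

* :class:`AssemblyModel` — null-model inference: per-scale betaNTI and
  RCbray turnover, assembly-process classification, chi-square scale
  dependency, and scale-restricted NTI.  ``fit()`` returns an
  :class:`AssemblyResults` with the tables, tests and a ``summary()``.
* :class:`DriversModel` — PCNM + covariates + host-phylogeny PCA and
  permutation forward selection in a dbRDA of turnover, plus the
  PCoA/Spearman axis screen.  ``fit()`` returns :class:`DriversResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drivers import (AxisSet, SelectionTable, correlate_axes, dbrda_forward,
                      pca, pcnm, pcoa, shift_to_nonnegative)
from .io import Dataset, align, read_metadata, read_otu_table, read_tree
from .processes import (PROCESS_LABELS, SCALE_LEVELS, ProcessTable,
                        nti_by_scale, partition_by_scale)
from .raupcrick import RcConfig

__all__ = ["AssemblyModel", "AssemblyResults", "DriversModel",
           "DriversResults"]


class AssemblyModel:
    """Null-model community-assembly inference over nested habitat scales.

    Parameters
    ----------
    dataset : Dataset
        Aligned OTU table, dated tree and metadata.
    levels : sequence of str
        Nesting levels to analyse (subset of region/site/plot/host).
    n_null : int
        Null replicates for both the taxa-shuffle and Raup-Crick nulls.
    rc_config : RcConfig, optional
        Raup-Crick assembly recipe; defaults to occupancy-weighted draws
        with abundance filling.
    """

    def __init__(self, dataset: Dataset, levels=SCALE_LEVELS,
                 n_null: int = 999, rc_config: RcConfig | None = None):
        self.dataset = dataset
        self.levels = list(levels)
        self.n_null = n_null
        self.rc_config = rc_config or RcConfig(n_null=n_null)

    @classmethod
    def from_files(cls, otu_path, tree_path, metadata_path,
                   orientation: str = "samples-rows",
                   drop_missing_otus: bool = False, **kwargs):
        ds = align(read_otu_table(otu_path, orientation=orientation),
                   read_tree(tree_path), read_metadata(metadata_path),
                   drop_missing_otus=drop_missing_otus)
        return cls(ds, **kwargs)

    def fit(self, seed: int = 0, compute_nti: bool = True) -> "AssemblyResults":
        pt = partition_by_scale(self.dataset, levels=self.levels,
                                n_null=self.n_null,
                                rc_config=self.rc_config, seed=seed)
        nti_long = nti_summary = nti_tukey = None
        if compute_nti:
            nti_long, nti_summary, nti_tukey = nti_by_scale(
                self.dataset, levels=self.levels, n_null=self.n_null,
                seed=seed + 1)
        return AssemblyResults(model=self, seed=seed, process_table=pt,
                               nti_long=nti_long, nti_summary=nti_summary,
                               nti_tukey=nti_tukey)


@dataclass
class AssemblyResults:
    """Fitted assembly-process partition and NTI tables."""

    model: AssemblyModel
    seed: int
    process_table: ProcessTable
    nti_long: pd.DataFrame | None = None
    nti_summary: pd.DataFrame | None = None
    nti_tukey: object | None = None

    # -- convenience views --------------------------------------------------
    @property
    def pairs(self) -> pd.DataFrame:
        return self.process_table.pairs

    @property
    def by_scale(self) -> pd.DataFrame:
        return self.process_table.by_scale

    @property
    def chi_square(self) -> pd.DataFrame:
        return self.process_table.chi_square

    def proportions(self, level: str) -> pd.Series:
        row = self.by_scale.loc[level]
        return row[[f"pct_{p}" for p in PROCESS_LABELS]]

    # -- output --------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Community assembly process partition",
                 "=" * 60,
                 f"levels: {', '.join(self.model.levels)}   "
                 f"n_null: {self.model.n_null}   seed: {self.seed}",
                 "",
                 "% of classified pairs per process"]
        hdr = f"{'level':<8}" + "".join(f"{p[:12]:>14}" for p in PROCESS_LABELS)
        lines.append(hdr)
        for lv in self.model.levels:
            row = self.by_scale.loc[lv]
            lines.append(f"{lv:<8}" + "".join(
                f"{row[f'pct_{p}']:>14.1f}" for p in PROCESS_LABELS))
        lines.append("")
        lines.append("chi-square across scales (2 x S, no continuity correction)")
        lines.append(f"{'process':<26}{'chi2':>10}{'df':>5}{'p':>12}")
        for proc, row in self.chi_square.iterrows():
            lines.append(f"{proc:<26}{row['chi2']:>10.2f}{int(row['df']):>5}"
                         f"{row['p']:>12.4g}")
        if self.nti_summary is not None and len(self.nti_summary):
            lines.append("")
            lines.append("NTI by scale (one-sample t test vs 0)")
            lines.append(f"{'level':<8}{'n':>5}{'mean':>9}{'sd':>9}"
                         f"{'t':>9}{'p':>12}")
            for lv, row in self.nti_summary.iterrows():
                lines.append(f"{lv:<8}{int(row['n']):>5}{row['mean_nti']:>9.2f}"
                             f"{row['sd_nti']:>9.2f}{row['t']:>9.2f}"
                             f"{row['p']:>12.4g}")
        return "\n".join(lines)

    def write_tables(self, out_dir) -> None:
        """pairs.csv, processes_by_scale.csv, chi_square.csv, nti_by_scale.csv."""
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out / "pairs.csv", index=False)
        self.by_scale.to_csv(out / "processes_by_scale.csv")
        self.chi_square.to_csv(out / "chi_square.csv")
        if self.nti_long is not None:
            self.nti_long.to_csv(out / "nti_by_scale.csv", index=False)

    def plot_process_proportions(self, ax=None):
        """Stacked bars of process percentages per habitat scale."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        bottom = np.zeros(len(self.model.levels))
        for p in PROCESS_LABELS:
            vals = np.array([self.by_scale.loc[lv, f"pct_{p}"]
                             for lv in self.model.levels])
            ax.bar(self.model.levels, vals, bottom=bottom,
                   label=p.replace("_", " "))
            bottom += np.nan_to_num(vals)
        ax.set_ylabel("% of community pairs")
        ax.set_xlabel("habitat scale")
        ax.legend(fontsize=8)
        return ax


# ---------------------------------------------------------------------------

class DriversModel:
    """Environmental/spatial/host-phylogeny driver analysis of turnover.

    Builds the candidate predictor set (soil covariates, PCNM axes of the
    sampling coordinates, and optionally the first two PCoA axes of a
    host-plant phylogenetic distance matrix), combines them by PCA, and
    forward-selects PCA axes in a dbRDA of each supplied turnover matrix.
    """

    def __init__(self, dataset: Dataset, bnti=None, rcbray=None,
                 plant_distance: pd.DataFrame | None = None,
                 alpha: float = 0.05, n_perm: int = 999):
        if not dataset.meta.has_complete_covariates():
            raise ValueError("metadata has missing covariates; driver "
                             "analysis refuses to impute")
        self.dataset = dataset
        self.bnti = bnti
        self.rcbray = rcbray
        self.plant_distance = plant_distance
        self.alpha = alpha
        self.n_perm = n_perm

    # -- predictor assembly --------------------------------------------------
    def predictor_frame(self) -> tuple[pd.DataFrame, AxisSet]:
        meta = self.dataset.meta.frame
        coords = meta[["x", "y"]].to_numpy(dtype=float)
        spatial = pcnm(coords, ids=list(meta.index))
        blocks = [meta[["pH", "OM", "GM"]].astype(float),
                  spatial.scores]
        if self.plant_distance is not None:
            plant_axes = pcoa(self.plant_distance.to_numpy(),
                              ids=list(self.plant_distance.index))
            two = plant_axes.scores.iloc[:, :2].copy()
            two.columns = [f"plantPCo{k + 1}" for k in range(two.shape[1])]
            per_sample = two.loc[meta["host"]].set_index(meta.index)
            blocks.append(per_sample)
        return pd.concat(blocks, axis=1), spatial

    def fit(self, seed: int = 0) -> "DriversResults":
        predictors, spatial = self.predictor_frame()
        axes = pca(predictors)
        results = {}
        ordinations = {}
        for name, tm in (("bNTI", self.bnti), ("RCbray", self.rcbray)):
            if tm is None:
                continue
            vals = np.array(tm.values, dtype=float)
            off = ~np.eye(vals.shape[0], dtype=bool)
            bad = off & ~np.isfinite(vals)
            if bad.any():
                # pairs with degenerate nulls: impute the mean valid score
                vals[bad] = np.nanmean(vals[off & np.isfinite(vals)])
            vals = shift_to_nonnegative(vals)
            embedded = pcoa(vals, ids=tm.ids)
            ordinations[name] = embedded
            results[name] = dbrda_forward(
                embedded.scores.to_numpy(), axes, alpha=self.alpha,
                n_perm=self.n_perm, seed=seed,
                ids=list(embedded.scores.index))
        return DriversResults(model=self, seed=seed, predictor_axes=axes,
                              spatial_axes=spatial, selections=results,
                              ordinations=ordinations)


@dataclass
class DriversResults:
    """Selected predictor axes and supporting ordinations."""

    model: DriversModel
    seed: int
    predictor_axes: AxisSet
    spatial_axes: AxisSet
    selections: dict[str, SelectionTable]
    ordinations: dict[str, AxisSet] = field(default_factory=dict)

    def loading_report(self, axis: str, top: int = 3) -> pd.Series:
        """Largest-magnitude loadings of a selected PCA axis — which
        measured (soil/host) or spatial (PCNM) variables dominate it."""
        lo = self.predictor_axes.loadings[axis]
        return lo.reindex(lo.abs().sort_values(ascending=False).index)[:top]

    def correlate(self, metric: str, variables: pd.DataFrame,
                  family: int | None = None) -> pd.DataFrame:
        """Spearman/Bonferroni screen of turnover PCoA axes vs variables."""
        axes = self.ordinations[metric].scores
        return correlate_axes(axes, variables.loc[axes.index], family=family)

    def summary(self) -> str:
        lines = ["Turnover driver analysis (dbRDA forward selection)",
                 "=" * 60,
                 f"alpha: {self.model.alpha}   permutations: "
                 f"{self.model.n_perm}   seed: {self.seed}",
                 f"candidate PCA axes: {self.predictor_axes.n_axes} "
                 f"(PCNM axes: {self.spatial_axes.n_axes})"]
        for metric, sel in self.selections.items():
            lines.append("")
            lines.append(f"response: {metric} (shifted to nonnegative, "
                         "PCoA-embedded)")
            if not len(sel.steps):
                lines.append("  no predictor axis selected "
                             f"(full-model adj R2 = {sel.full_model_adj_r2:.3f})")
                continue
            lines.append(f"  {'axis':<8}{'adjR2cum':>10}{'df':>5}"
                         f"{'AIC':>10}{'F':>9}{'p':>9}")
            for name, row in sel.steps.iterrows():
                lines.append(f"  {name:<8}{row['adj_r2_cum']:>10.3f}"
                             f"{int(row['df_resid']):>5}{row['aic']:>10.1f}"
                             f"{row['pseudo_F']:>9.3f}{row['p']:>9.4f}")
                for var, val in self.loading_report(name).items():
                    lines.append(f"      loading {var:<10} {val:+.3f}")
        return "\n".join(lines)

    def write_tables(self, out_dir) -> None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spatial_axes.scores.to_csv(out / "pcnm.csv")
        self.predictor_axes.loadings.to_csv(out / "pca_loadings.csv")
        for metric, sel in self.selections.items():
            sel.steps.to_csv(out / f"selection_{metric.lower()}.csv")
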