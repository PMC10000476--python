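"""Model / Results objects tying the pipeline stages together.

``DGEModel`` holds a count matrix and a two-group design; ``fit()`` runs
filtering, TMM normalization, the log2-CPM transform and the empirical-
Bayes moderated-t fit, returning a ``DGEResults`` object that carries the
per-gene estimates, the global shrinkage parameters, and hooks for the
descriptive outputs (PCA, clustering, volcano) and for downstream
phenotyping. ``SetScoreModel`` scores marker gene sets per sample with the
average z-score statistic and tests group differences; its ``fit()``
returns a ``SetScorePanel``.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import dge as _dge
from . import phenotyping as _ph
from . import report as _report
from . import setscore as _ss
from .containers import CountMatrix, ExpressionMatrix, MarkerSet, SampleDesign

__all__ = ["DGEModel", "DGEResults", "SetScoreModel", "SetScorePanel"]


class DGEModel:
    """Two-group moderated differential expression model on counts.

    Parameters
    ----------
    counts : CountMatrix
        Raw gene x sample counts.
    design : SampleDesign
        Two-level design; log2FC is treatment minus reference.
    min_cpm, min_samples : float, int
        Expression filter: keep genes with raw CPM >= min_cpm in at least
        min_samples samples (default: the smaller group size).
    prior_count : float
        Prior count of the log2-CPM transform.
    trim_m, trim_a : float
        TMM trim fractions for M-values and A-values.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleDesign,
        min_cpm: float = 1.0,
        min_samples: int | None = None,
        prior_count: float = 0.5,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
    ):
        self.counts = counts
        self.design = design
        self.min_cpm = min_cpm
        self.min_samples = min_samples
        self.prior_count = prior_count
        self.trim_m = trim_m
        self.trim_a = trim_a

    @classmethod
    def from_files(cls, counts_path, design_path, reference=None, **kwargs):
        from .io import read_counts, read_design

        return cls(read_counts(counts_path), read_design(design_path, reference), **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        lfc_tiers: tuple[float, ...] = (0.5, 0.25),
        d0_override: float | None = None,
    ) -> "DGEResults":
        filtered = _dge.filter_low_expression(
            self.counts, self.design, min_cpm=self.min_cpm, min_samples=self.min_samples
        )
        factors = _dge.tmm_norm_factors(filtered, trim_m=self.trim_m, trim_a=self.trim_a)
        expr = _dge.log_cpm(filtered, factors, prior=self.prior_count)
        de = _dge.fit_moderated_de(
            expr, self.design, alpha=alpha, lfc_tiers=lfc_tiers, d0_override=d0_override
        )
        return DGEResults(model=self, filtered=filtered, norm_factors=factors,
                          expression=expr, de=de)


@dataclass
class DGEResults:
    """Fitted differential expression results.

    Attributes
    ----------
    filtered : CountMatrix
        Counts after the low-expression filter.
    norm_factors : NormFactors
        TMM factors and library sizes.
    expression : ExpressionMatrix
        log2-CPM used for the fit (and for downstream set scoring).
    de : DEResult
        Per-gene table plus empirical-Bayes parameters d0 and s0^2.
    """

    model: DGEModel
    filtered: CountMatrix
    norm_factors: object
    expression: ExpressionMatrix
    de: _dge.DEResult

    @property
    def table(self) -> pd.DataFrame:
        return self.de.table

    def summary(self) -> str:
        de = self.de
        n = len(de.table)
        n_sig = int(de.table["sig_core"].sum())
        lines = [
            "Moderated two-group differential expression",
            "=" * 47,
            f"genes (post-filter):        {n}",
            f"samples:                    {self.filtered.shape[1]} "
            f"({de.treatment} vs {de.reference})",
            f"prior df (d0):              {de.d0:.4g}",
            f"prior variance (s0^2):      {de.s0_sq:.4g}",
            f"residual df per gene:       {de.table['df_resid'].iloc[0]:.0f}",
            f"significant (adj p <= {de.alpha:g}): {n_sig}",
        ]
        for tau in de.lfc_tiers:
            k = int(de.table[f"sig_lfc_{tau}"].sum())
            lines.append(f"  ... and |log2FC| >= {tau}:  {k}")
        return "\n".join(lines)

    # descriptive outputs -------------------------------------------------
    def pca(self, **kwargs) -> _report.PCAResult:
        return _report.pca_scores(self.expression, **kwargs)

    def hclust(self, axis: str = "samples", significant_only: bool = True, **kwargs):
        x = self.expression.values
        if significant_only:
            sig = [g for g in self.de.significant_genes if g in x.index]
            x = x.loc[sig]
        return _report.hclust_pearson(x, axis=axis, **kwargs)

    def volcano(self, alpha: float | None = None, lfc: float = 0.5):
        return _report.volcano_table(self.de, alpha=alpha or self.de.alpha, lfc=lfc)

    # phenotyping ---------------------------------------------------------
    def intersect_markers(self, sets: list[MarkerSet], alpha: float | None = None):
        return _ph.intersect_markers(self.de, sets, alpha=alpha or self.de.alpha)

    def categorize(
        self,
        union_sets: list[MarkerSet],
        category_sets: list[MarkerSet],
        lfc_floor: float | None = None,
        alpha: float | None = None,
    ) -> _ph.CategorizedGeneTable:
        inter = _ph.intersect_markers(self.de, union_sets, alpha=alpha or self.de.alpha)
        cts = {s.cell_type for s in category_sets if s.cell_type}
        ct = next(iter(cts)) if len(cts) == 1 else None
        if lfc_floor is None:
            lfc_floor = _ph.DEFAULT_LFC_FLOORS.get(ct or "", 0.0)
        table = next(iter(inter.values())) if inter else pd.DataFrame()
        return _ph.categorize(table, category_sets, lfc_floor=lfc_floor, cell_type=ct)


class SetScoreModel:
    """Average z-score set statistic over a log2-CPM matrix.

    Genes are z-scored across all samples; each set's per-sample score is
    the mean z over its genes; groups are compared with a pooled-variance
    two-tailed t-test. Sets with fewer than ``min_set_size`` usable genes
    are reported but not tested.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        design: SampleDesign,
        sets: list[MarkerSet],
        min_set_size: int = _ss.MIN_SET_SIZE,
    ):
        self.expression = expression
        self.design = design
        self.sets = sets
        self.min_set_size = min_set_size

    def fit(self, alpha: float = 0.05) -> "SetScorePanel":
        results = _ss.run_setscore_panel(
            self.expression,
            self.design,
            self.sets,
            alpha=alpha,
            min_set_size=self.min_set_size,
        )
        return SetScorePanel(model=self, results=results, alpha=alpha)


@dataclass
class SetScorePanel:
    """Fitted set-score panel: one result (or skip record) per set."""

    model: SetScoreModel
    results: list[_ss.SetScoreResult]
    alpha: float = 0.05

    @property
    def table(self) -> pd.DataFrame:
        return _ss.panel_table(self.results)

    def __getitem__(self, name: str) -> _ss.SetScoreResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Average z-score set panel",
            "=" * 47,
            f"sets: {len(t)} ({int(t['tested'].sum())} tested, "
            f"{int((~t['tested']).sum())} skipped)",
            "",
            t.to_string(
                float_format=lambda v: f"{v:.4g}",
                columns=["n_genes", "mean_control", "mean_treatment", "t", "p_value",
                         "direction", "note"],
            ),
        ]
        return "\n".join(lines)
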