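"""Descriptive outputs: PCA, Pearson hierarchical clustering, volcano
classification, and figure/report rendering.

Everything here is deterministic: PCA uses an explicit sign convention
(the coordinate with the largest absolute loading is made positive) and
clustering ties break on item order, so repeated runs produce identical
tables byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ValidationError
from .dge import DEResult

__all__ = [
    "pca_scores",
    "hclust_pearson",
    "volcano_table",
    "render_report",
    "PCAResult",
    "DendrogramSpec",
]


@dataclass
class PCAResult:
    """Sample coordinates and explained-variance fractions."""

    coordinates: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def pca_scores(expr: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of samples on gene-centered (unscaled) log2-CPM.

    Decomposes the sample x gene matrix after removing each gene's mean.
    Component signs follow a fixed convention: the sample coordinate with
    the largest magnitude on each component is positive.
    """
    x = expr.values.T.to_numpy(float)  # samples x genes
    n_samples = x.shape[0]
    if n_samples < 2:
        raise ValidationError("PCA needs at least two samples")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    k = min(n_samples - 1, len(s))
    if n_components is not None:
        k = min(k, n_components)
    coords = u[:, :k] * s[:k]
    # deterministic signs
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    total_var = (xc**2).sum()
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(
        coordinates=pd.DataFrame(
            coords,
            index=expr.sample_ids,
            columns=[f"PC{j + 1}" for j in range(k)],
        ),
        variance_fraction=var_frac,
    )


@dataclass
class DendrogramSpec:
    """Hierarchical clustering result over samples or genes.

    ``merges`` is the scipy linkage matrix (pairs + heights); ``items``
    names the leaves in input order; distance is 1 - Pearson r.
    """

    merges: np.ndarray
    items: list[str]
    linkage: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def pearson_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation distances between rows."""
    r = np.corrcoef(mat)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hclust_pearson(
    matrix: pd.DataFrame, axis: str = "samples", linkage: str = "average"
) -> DendrogramSpec:
    """Agglomerative clustering with 1 - Pearson correlation distance.

    ``axis`` is "samples" (cluster columns) or "genes" (cluster rows);
    linkage is "average" (default) or "complete".
    """
    if linkage not in ("average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if axis == "samples":
        mat = matrix.T.to_numpy(float)
        items = list(matrix.columns)
    elif axis == "genes":
        mat = matrix.to_numpy(float)
        items = list(matrix.index)
    else:
        raise ValidationError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if len(items) < 2:
        raise ValidationError("clustering needs at least two items")
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = [items[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance items cannot be clustered: {bad[:5]}")
    d = pearson_distance_matrix(mat)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return DendrogramSpec(merges=z, items=items, linkage=linkage)


def volcano_table(
    de: DEResult | pd.DataFrame, alpha: float = 0.05, lfc: float = 0.5
) -> tuple[pd.DataFrame, dict]:
    """Classify genes as sig_up / sig_down / ns at (alpha, lfc) thresholds.

    Returns the annotated table and a count summary including the
    percentage of up- and down-regulated genes among the significant ones.
    """
    table = (de.table if isinstance(de, DEResult) else de).copy()
    sig = (table["adj_p"] <= alpha) & (table["log2fc"].abs() >= lfc)
    cls = np.where(~sig, "ns", np.where(table["log2fc"] > 0, "sig_up", "sig_down"))
    table["class"] = cls
    n_up = int((cls == "sig_up").sum())
    n_down = int((cls == "sig_down").sum())
    n_sig = n_up + n_down
    counts = {
        "total": int(len(table)),
        "sig": n_sig,
        "sig_up": n_up,
        "sig_down": n_down,
        "ns": int((cls == "ns").sum()),
        "pct_up": 100.0 * n_up / n_sig if n_sig else 0.0,
        "pct_down": 100.0 * n_down / n_sig if n_sig else 0.0,
    }
    return table, counts


# ---------------------------------------------------------------------------
# rendering

def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    d = df[keep]
    return d.sub(d.mean(axis=1), axis=0).div(sd[keep], axis=0)


def render_report(
    outdir,
    expr: ExpressionMatrix | None = None,
    de: DEResult | None = None,
    panel_results=None,
    categorized=None,
    alpha: float = 0.05,
    lfc: float = 0.5,
) -> dict[str, Path]:
    """Write figures (PNG) and a markdown summary for whatever stages ran.

    TSV outputs are written before any plotting so a rendering failure
    never corrupts the tabular results.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary_lines = ["# glialseq run report", ""]

    # --- tables first
    if de is not None:
        p = outdir / "de_results.tsv"
        de.table.rename_axis("gene").to_csv(p, sep="\t")
        written["de_results.tsv"] = p
        vt, counts = volcano_table(de, alpha=alpha, lfc=lfc)
        p = outdir / "volcano_table.tsv"
        vt.rename_axis("gene").to_csv(p, sep="\t")
        written["volcano_table.tsv"] = p
        summary_lines += [
            f"- {counts['sig']} of {counts['total']} genes significant at "
            f"adj p <= {alpha} and |log2FC| >= {lfc} "
            f"({counts['sig_up']} up, {counts['sig_down']} down).",
        ]
    if panel_results:
        from .setscore import panel_table

        pt = panel_table(panel_results)
        p = outdir / "set_scores.tsv"
        pt.to_csv(p, sep="\t")
        written["set_scores.tsv"] = p
        tested = pt[pt["tested"]]
        summary_lines += [
            f"- set-score panel: {len(tested)} sets tested, "
            f"{int((tested['p_value'] <= alpha).sum())} significant at p <= {alpha}, "
            f"{int((~pt['tested']).sum())} skipped (too few genes).",
        ]
    elif panel_results is not None:
        summary_lines += ["- set-score panel: no sets tested."]
    if categorized is not None and not categorized.table.empty:
        p = outdir / "categorized_genes.tsv"
        categorized.table.rename_axis("gene").to_csv(p, sep="\t")
        written["categorized_genes.tsv"] = p

    # --- figures
    if expr is not None:
        try:
            pca = pca_scores(expr)
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(pca.coordinates["PC1"], pca.coordinates["PC2"])
            for s in pca.coordinates.index:
                ax.annotate(s, (pca.coordinates.loc[s, "PC1"], pca.coordinates.loc[s, "PC2"]))
            ax.set_xlabel(f"PC1 ({pca.variance_fraction[0]:.1%})")
            ax.set_ylabel(f"PC2 ({pca.variance_fraction[1]:.1%})")
            fig.tight_layout()
            p = outdir / "pca.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written["pca.png"] = p
        except Exception as e:  # plotting failures must not kill the run
            summary_lines.append(f"- PCA figure failed: {e}")
    if expr is not None and de is not None and len(de.significant_genes) >= 2:
        try:
            sig = [g for g in de.significant_genes if g in expr.values.index]
            z = _zscore_rows(expr.values.loc[sig])
            fig, ax = plt.subplots(figsize=(6, 6))
            im = ax.imshow(z.to_numpy(), aspect="auto", cmap="bwr", vmin=-2.5, vmax=2.5)
            ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=6)
            ax.set_yticks([])
            fig.colorbar(im, ax=ax, label="z-score")
            fig.tight_layout()
            p = outdir / "heatmap_significant.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written["heatmap_significant.png"] = p
        except Exception as e:
            summary_lines.append(f"- heatmap failed: {e}")
    if de is not None:
        try:
            vt, _ = volcano_table(de, alpha=alpha, lfc=lfc)
            fig, ax = plt.subplots(figsize=(5, 4))
            colors = vt["class"].map(
                {"ns": "0.7", "sig_up": "tab:red", "sig_down": "tab:blue"}
            )
            ax.scatter(
                vt["log2fc"], -np.log10(vt["adj_p"].clip(lower=1e-300)), s=4, c=colors
            )
            ax.set_xlabel("log2 fold change")
            ax.set_ylabel("-log10 adj p")
            fig.tight_layout()
            p = outdir / "volcano.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written["volcano.png"] = p
        except Exception as e:
            summary_lines.append(f"- volcano figure failed: {e}")
    if panel_results:
        try:
            tested = [r for r in panel_results if r.tested]
            if tested:
                fig, ax = plt.subplots(figsize=(max(4, len(tested)), 4))
                names = [r.name for r in tested]
                xs = np.arange(len(tested))
                ax.bar(xs - 0.2, [r.mean_control for r in tested], 0.4, label="control")
                ax.bar(xs + 0.2, [r.mean_treatment for r in tested], 0.4, label="treatment")
                ax.set_xticks(xs, names, rotation=45, ha="right")
                ax.set_ylabel("mean z-score")
                ax.legend()
                fig.tight_layout()
                p = outdir / "set_scores.png"
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written["set_scores.png"] = p
        except Exception as e:
            summary_lines.append(f"- set-score figure failed: {e}")

    summary = outdir / "report.md"
    summary.write_text("\n".join(summary_lines) + "\n")
    written["report.md"] = summary
    return written
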