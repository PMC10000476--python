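"""Intersect differentially expressed genes with cell-type marker lists and
assign glial phenotype categories.

The workflow mirrors how glial phenotypes are read out of bulk DE results:
the significant gene list is intersected with a cell type's union marker
list (e.g., 822 microglia markers), and the intersecting genes are then
assigned to phenotype categories (homeostatic vs neurodegenerative
microglia; acute-injury / pan-injury / chronic-neurodegenerative reactive
astrocytes; OPC/COP/NFOL/MFOL/MOL oligodendrocyte lineage stages) using
curated category membership lists. A per-cell-type fold-change floor can
additionally be required for categorization (0.25 for microglia, 0 for the
other schemes).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .containers import MarkerSet
from .dge import DEResult

log = logging.getLogger("glialseq")

__all__ = [
    "intersect_markers",
    "categorize",
    "category_summary",
    "CategorizedGeneTable",
]

DEFAULT_LFC_FLOORS = {"microglia": 0.25, "astrocyte": 0.0, "oligodendrocyte": 0.0}


def _de_table(de) -> pd.DataFrame:
    """Accept a DEResult or a bare DataFrame with log2fc / adj_p columns."""
    table = de.table if isinstance(de, DEResult) else de
    missing = {"log2fc", "adj_p"} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    return table


def intersect_markers(
    de, sets: list[MarkerSet], alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Per cell type, the significant DE genes that are also markers.

    ``sets`` may mix cell types; markers of the same cell type are unioned.
    Returns a mapping cell type -> table (gene index; log2fc, adj_p),
    preserving the DE table's row order. Empty intersections are allowed
    and logged.
    """
    table = _de_table(de)
    sig = table[table["adj_p"] <= alpha]
    by_cell: dict[str, set] = {}
    for s in sets:
        ct = s.cell_type or s.name
        by_cell.setdefault(ct, set()).update(s.genes)
    out = {}
    for ct, markers in by_cell.items():
        hit = sig[sig.index.isin(markers)][["log2fc", "adj_p"]]
        if hit.empty:
            log.info("no significant DE genes intersect the %s marker list", ct)
        out[ct] = hit
    return out


@dataclass
class CategorizedGeneTable:
    """Phenotype-category assignments of intersecting DE genes.

    ``table`` rows: (gene index; cell_type, category, log2fc, adj_p) — a
    gene assigned to several categories appears once per category.
    ``uncategorized`` lists intersecting significant genes in no category
    set (after the fold-change floor is applied to categories only).
    ``multi_category`` flags genes kept in more than one category.
    """

    table: pd.DataFrame
    uncategorized: tuple[str, ...] = ()
    multi_category: tuple[str, ...] = ()

    @property
    def counts(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=int)
        return self.table.groupby("category", sort=False).size()

    def genes_in(self, category: str) -> list[str]:
        return self.table.index[self.table["category"] == category].tolist()


def categorize(
    intersection: pd.DataFrame,
    category_sets: list[MarkerSet],
    lfc_floor: float = 0.0,
    cell_type: str | None = None,
) -> CategorizedGeneTable:
    """Assign intersecting genes to phenotype categories.

    A gene is assigned to every category set that contains it, provided
    ``|log2fc| >= lfc_floor``. Genes clearing the floor but matching no
    category set are reported as uncategorized.
    """
    if not category_sets:
        raise ValueError("at least one category set is required")
    cts = {s.cell_type for s in category_sets if s.cell_type}
    if cell_type is None and len(cts) == 1:
        cell_type = next(iter(cts))
    if len(cts) > 1:
        raise ValueError(f"category sets span multiple cell types: {sorted(cts)}")
    names = [s.name for s in category_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate category set names")

    eligible = intersection[intersection["log2fc"].abs() >= lfc_floor]
    rows = []
    assigned: dict[str, list[str]] = {}
    for s in category_sets:
        cat = s.category or s.name
        members = eligible[eligible.index.isin(set(s.genes))]
        for gene, r in members.iterrows():
            rows.append((gene, cell_type, cat, r["log2fc"], r["adj_p"]))
            assigned.setdefault(gene, []).append(cat)
    multi = tuple(g for g, cats in assigned.items() if len(cats) > 1)
    if multi:
        warnings.warn(
            f"genes assigned to multiple categories (kept in all): {list(multi)[:10]}",
            UserWarning,
            stacklevel=2,
        )
    uncategorized = tuple(g for g in eligible.index if g not in assigned)
    table = pd.DataFrame(
        rows, columns=["gene", "cell_type", "category", "log2fc", "adj_p"]
    ).set_index("gene")
    return CategorizedGeneTable(
        table=table, uncategorized=uncategorized, multi_category=multi
    )


def category_summary(table: CategorizedGeneTable) -> pd.DataFrame:
    """Per-category gene counts and up/down tallies.

    Columns: n, n_up (log2fc > 0), n_down (log2fc < 0), n_zero.
    """
    if table.table.empty:
        return pd.DataFrame(columns=["n", "n_up", "n_down", "n_zero"])
    g = table.table.groupby("category", sort=False)
    out = pd.DataFrame(
        {
            "n": g.size(),
            "n_up": g.apply(lambda d: int((d["log2fc"] > 0).sum()), include_groups=False),
            "n_down": g.apply(lambda d: int((d["log2fc"] < 0).sum()), include_groups=False),
            "n_zero": g.apply(lambda d: int((d["log2fc"] == 0).sum()), include_groups=False),
        }
    )
    return out
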