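"""Loaders for the packaged worked-example tables.

Four text tables ship with the package, reproducing published categorized
glial gene lists from a mouse cerebellum ethanol study (two-group bulk
RNA-seq): the 151 microglia-associated DE genes, the 23 of them assigned
homeostatic/neurodegenerative phenotypes, the 56 categorized astrocyte
genes (acute-injury / pan-injury / chronic-neurodegenerative), and the 195
categorized oligodendrocyte-lineage genes (OPC/COP/NFOL/MFOL/MOL).
Symbols keep their printed mixed case on disk and are normalized on load.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import MarkerSet
from .io import collapse_duplicate_results, normalize_symbol

__all__ = [
    "load_fixture_table",
    "microglia_de_fixture",
    "microglia_category_sets",
    "astrocyte_de_fixture",
    "astrocyte_category_sets",
    "oligodendrocyte_de_fixture",
    "oligodendrocyte_category_sets",
]

_CELL_TYPES = {
    "microglia_categorized.tsv": "microglia",
    "astrocyte_categorized.tsv": "astrocyte",
    "oligodendrocyte_categorized.tsv": "oligodendrocyte",
}


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged TSV by file name, with symbols normalized."""
    path = resources.files("glialseq.data").joinpath(name)
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df["symbol"] = [normalize_symbol(s) for s in df["symbol"]]
    return df


def _de_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.set_index("symbol")[["log2fc", "adj_p"]]
    return collapse_duplicate_results(out)


def _category_sets(fname: str) -> list[MarkerSet]:
    df = load_fixture_table(fname)
    cell_type = _CELL_TYPES[fname]
    sets = []
    for cat in df["category"].unique():
        genes = tuple(df.loc[df["category"] == cat, "symbol"])
        sets.append(
            MarkerSet(
                name=f"{cell_type}_{cat}", genes=genes, cell_type=cell_type, category=cat
            )
        )
    return sets


def microglia_de_fixture() -> pd.DataFrame:
    """The 151 microglia-associated DE genes (log2fc, adj_p), symbol-indexed."""
    return _de_frame(load_fixture_table("microglia_de_genes.tsv"))


def microglia_category_sets() -> list[MarkerSet]:
    """Homeostatic and neurodegenerative microglia category sets (15 + 8)."""
    return _category_sets("microglia_categorized.tsv")


def astrocyte_de_fixture() -> pd.DataFrame:
    """The 56 categorized astrocyte genes as a DE-style table."""
    return _de_frame(load_fixture_table("astrocyte_categorized.tsv"))


def astrocyte_category_sets() -> list[MarkerSet]:
    """Acute-injury, pan-injury and chronic-neurodegenerative astrocyte sets."""
    return _category_sets("astrocyte_categorized.tsv")


def oligodendrocyte_de_fixture() -> pd.DataFrame:
    """Unique oligodendrocyte-lineage genes as a DE-style table.

    Genes printed in more than one lineage column appear once (the
    duplicate-collapse policy applies; printed values agree).
    """
    return _de_frame(load_fixture_table("oligodendrocyte_categorized.tsv"))


def oligodendrocyte_category_sets() -> list[MarkerSet]:
    """OPC, COP, NFOL, MFOL and MOL lineage category sets."""
    return _category_sets("oligodendrocyte_categorized.tsv")
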