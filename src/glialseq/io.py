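"""Readers and writers for the pipeline's tab-delimited formats.

Counts and designs are plain TSV with a header row; gene sets use the
standard GMT layout (set name, description, then one gene symbol per
field). Gene symbols are harmonized by uppercasing only — curated marker
lists and genome annotations differ in case (``Hpgds`` vs ``HPGDS``) but no
alias or orthology mapping is attempted.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    MarkerSet,
    SampleDesign,
    ValidationError,
)

log = logging.getLogger("glialseq")

__all__ = [
    "normalize_symbol",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_run_summary",
]


def normalize_symbol(raw: str) -> str:
    """Uppercase and strip a gene symbol; no alias mapping.

    Raises
    ------
    ValidationError
        If the token is empty after stripping.
    """
    s = str(raw).strip().upper()
    if not s:
        raise ValidationError(f"empty gene symbol token: {raw!r}")
    return s


def read_counts(path) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene id, header row).

    Duplicate symbols (after normalization) are collapsed by summing their
    counts; the collapse is logged with the offending symbols.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) == 0:
        raise ValidationError(f"{path}: no sample columns")
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample names {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    # locate bad values with row/column for the error message
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.round(vals.fillna(0)))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: invalid count {df.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} (counts must be non-negative integers)"
            )
    df.index = [normalize_symbol(g) for g in df.index]
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        log.warning("%s: collapsing duplicate gene rows by sum: %s", path, dups)
        df = df.groupby(level=0, sort=False).sum()
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> Path:
    path = Path(path)
    df = cm.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    return path


def read_design(path, reference: str | None = None) -> SampleDesign:
    """Read a sample design TSV with columns ``sample`` and ``group``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"{path}: duplicate sample names {dups}")
    groups = pd.Series(df["group"].values, index=df["sample"].values)
    return SampleDesign(groups, reference=reference)


def write_design(design: SampleDesign, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"sample": design.sample_ids, "group": design.groups.values}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_gmt(path, cell_type: str | None = None) -> list[MarkerSet]:
    """Read marker sets from a GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``. The
    description field may carry ``cell_type:category`` metadata written by
    :func:`write_gmt`; otherwise it is ignored.
    """
    path = Path(path)
    sets: list[MarkerSet] = []
    seen_names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, desc = fields[0], fields[1]
            if name in seen_names:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen_names.add(name)
            ct, cat = cell_type, None
            if ":" in desc:
                left, _, right = desc.partition(":")
                ct = left or cell_type
                cat = right or None
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            sets.append(MarkerSet(name=name, genes=tuple(genes), cell_type=ct, category=cat))
    return sets


def write_gmt(sets: list[MarkerSet], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            desc = f"{s.cell_type or ''}:{s.category or ''}"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")
    return path


def collapse_duplicate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows in a DE-style table.

    Keeps, per symbol, the row with the smallest adjusted p; ties broken by
    larger ``|log2fc|``, then lexicographic row position.
    """
    if not table.index.has_duplicates:
        return table
    order = np.lexsort(
        (
            np.arange(len(table)),
            -table["log2fc"].abs().to_numpy(),
            table["adj_p"].to_numpy(),
        )
    )
    ranked = table.iloc[order]
    return ranked[~ranked.index.duplicated(keep="first")].sort_index()


def write_run_summary(path, *, seed=None, params=None, inputs=None) -> Path:
    """Write a JSON run summary: package versions, seed, parameters, inputs."""
    import hashlib

    from . import __version__

    def _hash(p):
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        return h.hexdigest()[:16]

    summary = {
        "glialseq_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "params": params or {},
        "input_hashes": {str(k): _hash(v) for k, v in (inputs or {}).items()},
    }
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, default=str))
    return path
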