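"""Negative-binomial count simulation with planted group effects.

The generator emulates the statistical structure the pipeline assumes: a
two-group bulk RNA-seq design (default 5 vs 5 samples), gene-specific
baseline means spanning the bulk dynamic range, NB counts with a
mean-dispersion parameterization (variance mu + phi * mu^2; phi = 0
degenerates to Poisson), log-normal library-size variation, and optional
composition bias to exercise TMM normalization. Planted differential
expression — background genes and/or directional marker sets — is recorded
in a ground-truth table for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, MarkerSet, SampleDesign, ValidationError
from .io import write_counts, write_design, write_gmt

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_counts",
    "generate_marker_sets",
    "simulate_experiment",
    "write_fixture_bundle",
]

#: marker-set sizes of the curated glial lists the generator can emulate
FULL_SCALE_SET_SPEC = [
    ("microglia_union", 822, "null"),
    ("astrocyte_union", 309, "null"),
    ("OPC", 381, "null"),
    ("COP", 55, "null"),
    ("NFOL", 9, "null"),
    ("MFOL", 347, "null"),
    ("MOL", 7, "null"),
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults are test scale (2,000 genes); the full design the generator
    emulates is ~18,000 detected genes, 5 samples per group.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    baseline_log2_mean_range: tuple[float, float] = (2.0, 11.0)
    dispersion: float = 0.1
    libsize_log2_sd: float = 0.2
    effect_log2fc: float = 0.0
    frac_de_background: float = 0.0
    comp_bias_frac: float = 0.0
    comp_bias_log2fc: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.frac_de_background <= 1:
            raise ValidationError("frac_de_background must lie in [0, 1]")
        if not 0 <= self.comp_bias_frac <= 1:
            raise ValidationError("comp_bias_frac must lie in [0, 1]")
        if self.libsize_log2_sd < 0:
            raise ValidationError("libsize_log2_sd must be >= 0")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise ValidationError("baseline_log2_mean_range must be (low, high)")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment.

    ``de_genes`` maps gene id -> planted signed log2 fold change (treatment
    over control); ``set_directions`` maps marker-set name -> up/down/null;
    ``lib_scales`` holds each sample's true library scale factor;
    ``comp_bias_genes`` are the genes inflated in the treatment group to
    create composition bias (tracked separately from planted DE).
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    set_directions: dict[str, str] = field(default_factory=dict)
    lib_scales: pd.Series | None = None
    comp_bias_genes: tuple[str, ...] = ()


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def generate_counts(
    config: SimConfig,
    planted_effects: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, SampleDesign, SyntheticTruth]:
    """Draw an NB count matrix with planted effects.

    ``planted_effects`` (gene -> signed log2FC) supplements the background
    DE fraction drawn from ``config``; background genes are drawn from
    genes without a supplied effect. Identical config and seed give
    byte-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n = config.n_per_group
    samples = [f"C{i + 1}" for i in range(n)] + [f"E{i + 1}" for i in range(n)]
    group = np.array(["C"] * n + ["E"] * n)

    lo, hi = config.baseline_log2_mean_range
    base_mu = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)

    effects = dict(planted_effects or {})
    unknown = [g for g in effects if g not in set(genes)]
    if unknown:
        raise ValidationError(f"planted effect genes not in matrix: {unknown[:5]}")
    n_bg = int(round(config.frac_de_background * config.n_genes))
    if n_bg > 0 and config.effect_log2fc != 0:
        free = [g for g in genes if g not in effects]
        chosen = rng.choice(len(free), size=min(n_bg, len(free)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        for idx, s in zip(chosen, signs):
            effects[free[idx]] = s * config.effect_log2fc
    effects = {g: e for g, e in effects.items() if e != 0}

    lfc = np.array([effects.get(g, 0.0) for g in genes])
    comp_genes: tuple[str, ...] = ()
    comp_lfc = np.zeros(config.n_genes)
    if config.comp_bias_frac > 0:
        n_comp = int(round(config.comp_bias_frac * config.n_genes))
        idx = rng.choice(config.n_genes, size=n_comp, replace=False)
        comp_lfc[idx] = config.comp_bias_log2fc
        comp_genes = tuple(genes[i] for i in idx)

    lib_scale = 2.0 ** rng.normal(0.0, config.libsize_log2_sd, size=2 * n)
    # mean for sample s, gene g
    mu = np.empty((config.n_genes, 2 * n))
    for j in range(2 * n):
        shift = 2.0 ** (lfc + comp_lfc) if group[j] == "E" else 1.0
        mu[:, j] = base_mu * shift * lib_scale[j]

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    design = SampleDesign(pd.Series(group, index=samples), reference="C")
    truth = SyntheticTruth(
        de_genes=effects,
        lib_scales=pd.Series(lib_scale, index=samples),
        comp_bias_genes=comp_genes,
    )
    return cm, design, truth


def generate_marker_sets(
    config: SimConfig,
    gene_ids,
    set_spec: list[tuple[str, int, str]],
    rng: np.random.Generator | None = None,
) -> tuple[list[MarkerSet], dict[str, str]]:
    """Draw pairwise-disjoint marker sets of requested sizes and directions.

    ``set_spec`` is a list of (name, size, direction) with direction in
    {"up", "down", "null"}. Returns the sets and a name -> direction map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(gene_ids)
    names = [name for name, _, _ in set_spec]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate marker-set names in set_spec")
    total = sum(size for _, size, _ in set_spec)
    if total > len(gene_ids):
        raise ValidationError(
            f"requested {total} marker genes but only {len(gene_ids)} available"
        )
    for _, _, direction in set_spec:
        if direction not in ("up", "down", "null"):
            raise ValidationError(f"direction must be up/down/null, got {direction!r}")
    perm = rng.permutation(len(gene_ids))
    sets, directions = [], {}
    pos = 0
    for name, size, direction in set_spec:
        members = tuple(gene_ids[i] for i in perm[pos : pos + size])
        pos += size
        sets.append(MarkerSet(name=name, genes=members))
        directions[name] = direction
    return sets, directions


def simulate_experiment(
    config: SimConfig, set_spec: list[tuple[str, int, str]] | None = None
):
    """Full simulation: marker sets, planted set effects, NB counts, truth.

    Members of "up"/"down" sets receive +/- ``config.effect_log2fc``;
    background DE (``frac_de_background``) is planted only outside the
    marker sets so that null sets stay effect-free.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sets: list[MarkerSet] = []
    directions: dict[str, str] = {}
    effects: dict[str, float] = {}
    reserved: set[str] = set()
    if set_spec:
        sets, directions = generate_marker_sets(config, genes, set_spec, rng=rng)
        for s in sets:
            reserved.update(s.genes)
            d = directions[s.name]
            if d == "up":
                for g in s.genes:
                    effects[g] = abs(config.effect_log2fc)
            elif d == "down":
                for g in s.genes:
                    effects[g] = -abs(config.effect_log2fc)
    # reserve null-set members by planting an explicit zero, stripped later
    bg_block = {g: 0.0 for g in reserved if g not in effects}
    cm, design, truth = generate_counts(
        config, planted_effects={**effects, **bg_block}, rng=rng
    )
    truth.set_directions = directions
    return cm, design, truth, sets


# ---------------------------------------------------------------------------
# fixture bundle

FIXTURE_TABLES = {
    "table1_microglia_de.tsv": ("microglia_de_genes.tsv", 151),
    "table2_microglia_categorized.tsv": ("microglia_categorized.tsv", 23),
    "table3_astrocyte_categorized.tsv": ("astrocyte_categorized.tsv", 56),
    "table4_oligodendrocyte_categorized.tsv": ("oligodendrocyte_categorized.tsv", 195),
}


def write_fixture_bundle(
    outdir,
    config: SimConfig | None = None,
    set_spec: list[tuple[str, int, str]] | None = None,
) -> dict[str, Path]:
    """Write the packaged worked-example tables plus one synthetic bundle.

    The worked-example TSVs reproduce the published categorized glial gene
    tables; the synthetic bundle (counts, design, GMT, truth) comes from
    :func:`simulate_experiment` under ``config``.
    """
    from importlib import resources

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for out_name, (src_name, _) in FIXTURE_TABLES.items():
        src = resources.files("glialseq.data").joinpath(src_name)
        dest = outdir / out_name
        dest.write_text(src.read_text())
        paths[out_name] = dest

    config = config or SimConfig()
    if set_spec is None:
        set_spec = [
            ("set_down", 20, "down"),
            ("set_up", 20, "up"),
            ("set_null", 20, "null"),
        ]
    cm, design, truth, sets = simulate_experiment(config, set_spec)
    paths["counts.tsv"] = write_counts(cm, outdir / "counts.tsv")
    paths["design.tsv"] = write_design(design, outdir / "design.tsv")
    paths["markers.gmt"] = write_gmt(sets, outdir / "markers.gmt")
    truth_df = pd.DataFrame(
        sorted(truth.de_genes.items()), columns=["gene", "planted_log2fc"]
    )
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth.tsv"] = outdir / "truth.tsv"
    return paths
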