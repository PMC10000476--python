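import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from glialseq import (
    CountMatrix,
    SampleDesign,
    SimConfig,
    ValidationError,
    bh_adjust,
    filter_low_expression,
    fit_moderated_de,
    generate_counts,
    log_cpm,
    tmm_norm_factors,
)
from glialseq.dge import squeeze_variance, trigamma_inverse


def _cm(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# filtering

def test_filter_removes_all_zero_gene():
    cm = _cm([[0, 0], [10, 12]])
    out = filter_low_expression(cm, min_cpm=0.5, min_samples=1)
    assert list(out.gene_ids) == ["g1"]


def test_filter_hand_computed_cpm_case():
    """Library 1e6 in both samples; counts (2, 0) give CPM 2 in only one
    sample, so min_cpm=1 in both samples removes the gene."""
    filler = [999_998, 1_000_000]
    cm = _cm([[2, 0], filler])
    assert cm.lib_sizes.tolist() == [1_000_000, 1_000_000]
    out = filter_low_expression(cm, min_cpm=1.0, min_samples=2)
    assert "g0" not in out.gene_ids


def test_filter_min_cpm_zero_keeps_everything():
    cm = _cm([[1, 0], [5, 5], [0, 2]])
    out = filter_low_expression(cm, min_cpm=0.0, min_samples=2)
    assert out.shape == cm.shape


def test_filter_empty_result_raises():
    cm = _cm([[1, 1], [2, 2]])
    with pytest.raises(ValidationError, match="filter"):
        filter_low_expression(cm, min_cpm=1e9, min_samples=1)


# ---------------------------------------------------------------------------
# TMM

def test_tmm_identical_columns_gives_unit_factors():
    col = np.random.default_rng(0).poisson(40, 100)
    cm = _cm(np.column_stack([col, col, col]))
    f = tmm_norm_factors(cm)
    assert np.allclose(f.factors, 1.0)


def test_tmm_depth_change_gives_unit_factors():
    col = np.random.default_rng(1).poisson(80, 200) + 1
    cm = _cm(np.column_stack([col, 2 * col]))
    f = tmm_norm_factors(cm)
    assert np.allclose(f.factors, 1.0)
    # and the invariance holds after a further global rescale
    cm2 = _cm(np.column_stack([col, 6 * col]))
    assert np.allclose(tmm_norm_factors(cm2).factors, 1.0)


def _tmm_oracle_two_sample(obs, ref, trim_m=0.30, trim_a=0.05):
    """Direct trimmed weighted mean on the M/A arrays (independent route)."""
    no, nr = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / no, ref[keep] / nr
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (no - obs[keep]) / (no * obs[keep]) + (nr - ref[keep]) / (nr * ref[keep])
    n = len(m)
    # survivors of the double trim, via order statistics
    def surviving(v, frac):
        k = int(np.floor(n * frac))
        order = np.argsort(v, kind="stable")
        ranks = np.empty(n, int)
        ranks[order] = np.arange(n)
        return (ranks >= k) & (ranks <= n - k - 1)

    keep2 = surviving(m, trim_m) & surviving(a, trim_a)
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 2.0**f


def test_tmm_composition_bias_matches_direct_oracle():
    """Sample B has 5% of genes inflated 8-fold; factors must match a
    brute-force trimmed weighted mean computed straight from M/A arrays."""
    rng = np.random.default_rng(42)
    n = 400
    a = rng.poisson(120, n) + 1
    b = a.copy()
    idx = rng.choice(n, size=20, replace=False)
    b[idx] *= 8
    cm = _cm(np.column_stack([a, b]))
    f = tmm_norm_factors(cm)
    expected = _tmm_oracle_two_sample(b.astype(float), a.astype(float))
    ratio = f.factors.iloc[1] / f.factors.iloc[0]
    assert ratio == pytest.approx(expected, rel=1e-10)
    # geometric mean exactly 1
    assert np.prod(f.factors) == pytest.approx(1.0, abs=1e-12)


def test_tmm_matches_edger_on_simulated_data(tmp_path):
    """Cross-check against edgeR's calcNormFactors on an NB instance with
    composition bias and library-size variation."""
    cfg = SimConfig(n_genes=300, n_per_group=3, dispersion=0.15, comp_bias_frac=0.05,
                    libsize_log2_sd=0.3, seed=4)
    cm, _, _ = generate_counts(cfg)
    ours = tmm_norm_factors(cm).factors
    counts_path = tmp_path / "c.tsv"
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- read.delim("{counts_path}", row.names=1)
        f <- calcNormFactors(DGEList(counts=x), method="TMM")$samples$norm.factors
        cat(sprintf("%.10f", f), sep="\\n")
    """)
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    theirs = np.array([float(v) for v in r.stdout.split()])
    assert np.allclose(ours.to_numpy(), theirs, atol=1e-8)


def test_tmm_no_shared_genes_names_sample():
    cm = _cm([[5, 0], [9, 0], [0, 7], [0, 3]])
    with pytest.raises(ValidationError, match="s"):
        tmm_norm_factors(cm)


# ---------------------------------------------------------------------------
# log2-CPM

def test_log_cpm_direct_formula_values():
    filler = [1_000_000, 999_900]
    cm = _cm([[0, 100], filler])
    assert cm.lib_sizes.tolist() == [1_000_000, 1_000_000]
    expr = log_cpm(cm, factors=None, prior=0.5)
    assert expr.values.iloc[0, 0] == pytest.approx(
        math.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-12
    )  # ~ -1.0000014
    assert expr.values.iloc[0, 1] == pytest.approx(
        math.log2(100.5 / (1e6 + 1) * 1e6), abs=1e-12
    )  # ~ 6.6510


def test_log_cpm_doubling_depth_shifts_by_one():
    """Same counts against a doubled library lower every entry by ~1
    (exactly 1 in the prior -> 0 limit)."""
    rng = np.random.default_rng(3)
    base = rng.poisson(200, 50) + 1
    lib = base.sum()
    a = np.concatenate([base, [lib]])         # filler doubles nothing
    b = np.concatenate([base, [2 * lib + lib]])  # filler doubles the library
    cm = _cm(np.column_stack([a, b]))
    assert cm.lib_sizes.iloc[1] == 2 * cm.lib_sizes.iloc[0]
    tiny = 1e-9
    e = log_cpm(cm, prior=tiny).values.to_numpy()
    diffs = e[:-1, 0] - e[:-1, 1]
    assert np.allclose(diffs, 1.0, atol=1e-6)
    # with the default prior the shift is approximate but close to 1
    e2 = log_cpm(cm, prior=0.5).values.to_numpy()
    assert np.allclose(e2[:-1, 0] - e2[:-1, 1], 1.0, atol=0.02)


def test_log_cpm_misaligned_factors_error(small_counts):
    other = _cm([[1, 2], [3, 4]])
    f = tmm_norm_factors(other)
    with pytest.raises(ValidationError, match="misaligned"):
        log_cpm(small_counts, f)


# ---------------------------------------------------------------------------
# BH adjustment

def _bh_oracle(p):
    """Brute-force step-up: sort, q_i = p_i * m / i, enforce monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_worked_example():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_constant_and_singleton():
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
    assert bh_adjust([0.73])[0] == pytest.approx(0.73)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_equals_brute_force_oracle(pvals):
    assert np.allclose(bh_adjust(pvals), _bh_oracle(pvals))
    # adjusted >= raw always
    assert (bh_adjust(pvals) >= np.asarray(pvals) - 1e-12).all()


# ---------------------------------------------------------------------------
# empirical Bayes / moderated t

def test_trigamma_inverse_round_trips():
    for x in [0.01, 0.5, 1.0, 7.3, 500.0]:
        y = special.polygamma(1, x)
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


def test_squeeze_variance_all_equal_gives_infinite_prior_df():
    d0, s0 = squeeze_variance(np.full(50, 2.0), df=4)
    assert np.isinf(d0)
    # s0^2 is the common value corrected for the log-chi2 bias
    assert s0 == pytest.approx(
        2.0 * np.exp(-special.digamma(2.0) + np.log(2.0)), rel=1e-12
    )


def _toy_expr(seed=0, n_genes=50, n=4):
    cfg = SimConfig(n_genes=max(n_genes, 10), n_per_group=n, dispersion=0.1, seed=seed)
    cm, design, _ = generate_counts(cfg)
    expr = log_cpm(cm, tmm_norm_factors(cm))
    return expr, design


def test_moderated_t_with_zero_prior_df_equals_ordinary_t():
    """d0=0 must reproduce the textbook pooled two-sample t for every gene."""
    expr, design = _toy_expr(seed=8, n_genes=50)
    de = fit_moderated_de(expr, design, d0_override=0.0)
    c = expr.values[design.samples_in("C")]
    e = expr.values[design.samples_in("E")]
    t_ref, p_ref = stats.ttest_ind(e, c, axis=1, equal_var=True)
    assert np.allclose(de.table["t"], t_ref, atol=1e-10)
    assert np.allclose(de.table["p_value"], p_ref, atol=1e-12)


def test_moderated_t_interpolates_to_prior_variance_at_large_d0():
    expr, design = _toy_expr(seed=9, n_genes=80)
    de = fit_moderated_de(expr, design)
    big = fit_moderated_de(expr, design, d0_override=1e12)
    v = 1 / 4 + 1 / 4  # two groups of four samples
    expected = big.table["log2fc"] / np.sqrt(big.s0_sq * v)
    assert np.allclose(big.table["t"], expected, rtol=1e-4)
    assert np.isfinite(de.d0) and de.d0 > 0


def test_null_gene_has_zero_t_unit_p():
    expr, design = _toy_expr(seed=10, n_genes=20)
    x = expr.values.copy()
    x.iloc[0] = [1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0]  # equal group means
    from glialseq.containers import ExpressionMatrix

    de = fit_moderated_de(ExpressionMatrix(x, expr.prior_count), design)
    assert de.table["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert de.table["p_value"].iloc[0] == pytest.approx(1.0)


def test_moderated_t_matches_limma_on_simulated_data(tmp_path):
    """Full cross-check of d0, s0^2, t, p against limma's eBayes."""
    cfg = SimConfig(n_genes=200, n_per_group=4, dispersion=0.15,
                    effect_log2fc=1.0, frac_de_background=0.1, seed=42)
    cm, design, _ = generate_counts(cfg)
    expr = log_cpm(cm, tmm_norm_factors(cm))
    de = fit_moderated_de(expr, design)
    expr_path = tmp_path / "lc.tsv"
    expr.values.rename_axis("gene").to_csv(expr_path, sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        lc <- as.matrix(read.delim("{expr_path}", row.names=1))
        grp <- factor(c(rep("C",4), rep("E",4)), levels=c("C","E"))
        fit <- eBayes(lmFit(lc, model.matrix(~grp)))
        cat(sprintf("%.12f", fit$df.prior), "\\n")
        cat(sprintf("%.12f", fit$s2.prior), "\\n")
        write.table(topTable(fit, coef=2, number=Inf, sort.by="none"),
                    "{tmp_path}/r.tsv", sep="\\t", quote=FALSE)
    """)
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    d0_r, s0_r = [float(v) for v in r.stdout.split()]
    assert de.d0 == pytest.approx(d0_r, rel=1e-6)
    assert de.s0_sq == pytest.approx(s0_r, rel=1e-6)
    rt = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
    assert np.allclose(de.table["t"], rt["t"], atol=1e-8)
    assert np.allclose(de.table["p_value"], rt["P.Value"], atol=1e-10)
    assert np.allclose(de.table["adj_p"], rt["adj.P.Val"], atol=1e-10)


def test_significance_tiers_consistent(sim_null):
    cm, design, _ = sim_null
    expr = log_cpm(filter_low_expression(cm, design), None)
    de = fit_moderated_de(expr, design)
    t = de.table
    assert ((t["adj_p"] >= t["p_value"] - 1e-12).all())
    assert (t["p_value"].between(0, 1)).all() and (t["adj_p"].between(0, 1)).all()
    assert (t["sig_lfc_0.5"] <= t["sig_core"]).all()
    assert (t["sig_lfc_0.25"] >= t["sig_lfc_0.5"])[t["sig_core"]].all()


def test_groups_smaller_than_two_rejected():
    expr, _ = _toy_expr(seed=1, n_genes=15, n=2)
    bad = SampleDesign(pd.Series(["C", "C", "C", "E"], index=expr.sample_ids))
    with pytest.raises(ValidationError, match="two samples"):
        fit_moderated_de(expr, bad)
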