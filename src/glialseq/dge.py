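"""Differential expression for a two-group bulk RNA-seq design.

The stage mirrors the standard voom-free limma-style workflow on a counts
matrix: filter lowly expressed genes, compute trimmed-mean-of-M-values
(TMM) scaling factors, transform to log2 counts per million, fit a
per-gene two-group linear model, shrink residual variances with the
empirical-Bayes squeeze of Smyth (2004), and control FDR with
Benjamini-Hochberg.

Notation
--------
For gene g with residual variance ``s_g^2`` on ``d_g`` degrees of freedom,
the squeeze finds prior df ``d0`` and prior variance ``s0^2`` such that

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t statistic ``t_g = beta_g / (s~_g * sqrt(v))`` is
referred to a t distribution on ``d0 + d_g`` degrees of freedom, where
``v = 1/n1 + 1/n2`` is the contrast leverage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CountMatrix,
    ExpressionMatrix,
    NormFactors,
    SampleDesign,
    ValidationError,
)

__all__ = [
    "filter_low_expression",
    "tmm_norm_factors",
    "log_cpm",
    "bh_adjust",
    "squeeze_variance",
    "trigamma_inverse",
    "fit_moderated_de",
    "DEResult",
]


# ---------------------------------------------------------------------------
# filtering

def filter_low_expression(
    counts: CountMatrix,
    design: SampleDesign | None = None,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> CountMatrix:
    """Keep genes with raw CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    CPM here uses unnormalized library sizes (filtering happens before TMM).
    ``min_samples`` defaults to the smaller group size when a design is
    given, else to the total sample count.
    """
    n = counts.shape[1]
    if min_samples is None:
        if design is not None:
            min_samples = int(design.groups.value_counts().min())
        else:
            min_samples = n
    if min_samples > n:
        raise ValidationError(f"min_samples={min_samples} exceeds sample count {n}")
    cpm = counts.counts.to_numpy(float) / counts.lib_sizes.to_numpy(float) * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "no genes pass the expression filter; lower min_cpm or min_samples"
        )
    return CountMatrix(counts.counts.loc[keep])


# ---------------------------------------------------------------------------
# TMM normalization

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of ``obs`` against ``ref`` (raw count vectors)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValidationError("sample shares no expressed genes with the reference")
    o, r = obs[both] / n_obs, ref[both] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic binomial variance of M
    w = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (
        n_ref * ref[both]
    )
    # edgeR-style degenerate guard: near-identical scaled libraries
    if np.abs(m).max() < 1e-6:
        return 0.0
    k = len(m)
    lo_m, hi_m = np.floor(k * trim_m) + 1, k - np.floor(k * trim_m)
    lo_a, hi_a = np.floor(k * trim_a) + 1, k - np.floor(k * trim_a)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else f


def tmm_norm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed mean of M-values scaling factors (Robinson & Oshlack 2010).

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile. For every other sample, per-gene log-ratios M
    and average abundances A (over genes expressed in both) are doubly
    trimmed — ``trim_m`` of each M tail, ``trim_a`` of each A tail — and the
    factor is 2 to the inverse-variance-weighted mean of the surviving M
    values. Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    mat = counts.counts.to_numpy(float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise ValidationError(f"zero library size for samples {bad}")
    cpm = mat / lib * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        try:
            log_f[j] = _tmm_pair(mat[:, j], mat[:, ref_idx], trim_m, trim_a)
        except ValidationError as e:
            raise ValidationError(f"sample {counts.sample_ids[j]!r}: {e}") from None
    factors = 2.0 ** (log_f - log_f.mean())
    return NormFactors(
        factors=pd.Series(factors, index=counts.sample_ids),
        lib_sizes=pd.Series(lib, index=counts.sample_ids),
    )


# ---------------------------------------------------------------------------
# log2-CPM

def log_cpm(
    counts: CountMatrix, factors: NormFactors | None = None, prior: float = 0.5
) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count.

    Entry (g, s) is ``log2((y_gs + prior) / (L_s * f_s + 2 * prior) * 1e6)``
    with ``L_s`` the library size and ``f_s`` the TMM factor (1 if no
    factors are given).
    """
    if prior <= 0:
        raise ValidationError("prior count must be positive")
    if factors is None:
        eff = counts.lib_sizes.astype(float)
    else:
        if not factors.factors.index.equals(counts.sample_ids):
            raise ValidationError("normalization factors misaligned with samples")
        eff = factors.effective_lib_sizes
    vals = np.log2(
        (counts.counts.to_numpy(float) + prior)
        / (eff.to_numpy(float) + 2.0 * prior)
        * 1e6
    )
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        prior_count=prior,
    )


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical-Bayes variance squeeze

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValidationError("trigamma_inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from sample variances.

    Moment matching on ``e_g = ln s_g^2 - psi(d/2) + ln(d/2)`` (Smyth 2004):
    the excess of var(e) over trigamma(d/2) identifies trigamma(d0/2); the
    mean of e identifies s0^2. All-equal variances give ``d0 = inf`` with
    ``s0^2 = exp(mean(e))``.
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0:
        raise ValidationError("residual degrees of freedom must be positive")
    pos = s2 > 0
    if not pos.any():
        raise ValidationError("no positive residual variances to squeeze")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return float(d0), s0_sq


# ---------------------------------------------------------------------------
# the fit

@dataclass
class DEResult:
    """Per-gene moderated differential expression results.

    ``table`` has one row per gene with columns: log2fc, ave_expr, s2,
    df_resid, t, p_value, adj_p, sig_core and one ``sig_lfc_<tau>`` flag per
    fold-change tier. ``d0`` and ``s0_sq`` are the global empirical-Bayes
    prior df and prior variance.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    alpha: float
    lfc_tiers: tuple[float, ...] = (0.5, 0.25)
    reference: str = "C"
    treatment: str = "E"

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["sig_core"]]

    def significant(self, lfc: float | None = None) -> pd.DataFrame:
        """Rows passing adj p <= alpha, optionally also ``|log2fc| >= lfc``."""
        mask = self.table["sig_core"]
        if lfc is not None:
            mask = mask & (self.table["log2fc"].abs() >= lfc)
        return self.table[mask]


def fit_moderated_de(
    expr: ExpressionMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    lfc_tiers: tuple[float, ...] = (0.5, 0.25),
    d0_override: float | None = None,
) -> DEResult:
    """Fit per-gene two-group models with empirical-Bayes moderated t.

    log2FC is treatment minus reference group mean on the log2-CPM scale.
    ``d0_override`` pins the prior df (0 recovers the ordinary pooled t;
    inf gives a z-like statistic against the prior variance alone).
    """
    samples = expr.sample_ids
    missing = [s for s in samples if s not in design.groups.index]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    grp = design.groups.loc[samples]
    ctrl = grp.index[grp == design.reference]
    trt = grp.index[grp == design.treatment]
    n1, n2 = len(ctrl), len(trt)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least two samples")
    n = n1 + n2
    df_resid = n - 2
    x = expr.values
    mc = x[ctrl].mean(axis=1)
    mt = x[trt].mean(axis=1)
    beta = mt - mc
    rss = ((x[ctrl].sub(mc, axis=0)) ** 2).sum(axis=1) + (
        (x[trt].sub(mt, axis=0)) ** 2
    ).sum(axis=1)
    s2 = rss / df_resid
    v = 1.0 / n1 + 1.0 / n2

    if d0_override is not None:
        d0 = float(d0_override)
        # prior variance still estimated (unused when d0 == 0)
        _, s0_sq = squeeze_variance(s2.to_numpy(), df_resid)
    else:
        d0, s0_sq = squeeze_variance(s2.to_numpy(), df_resid)
    if not np.isfinite(d0):
        import warnings

        warnings.warn(
            "all residual variances identical: prior df is infinite and the "
            "moderated t degenerates to a z-like statistic on s0^2",
            RuntimeWarning,
            stacklevel=2,
        )
        s2_post = pd.Series(s0_sq, index=s2.index)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    if (s2_post <= 0).any():
        bad = s2.index[s2_post <= 0].tolist()
        raise ValidationError(f"zero posterior variance for genes {bad[:5]}")

    tstat = beta / np.sqrt(s2_post * v)
    if np.isfinite(df_total):
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    adj = bh_adjust(pvals)

    table = pd.DataFrame(
        {
            "log2fc": beta,
            "ave_expr": x.mean(axis=1),
            "s2": s2,
            "df_resid": float(df_resid),
            "t": tstat,
            "p_value": pvals,
            "adj_p": adj,
        }
    )
    table["sig_core"] = table["adj_p"] <= alpha
    for tau in lfc_tiers:
        table[f"sig_lfc_{tau}"] = table["sig_core"] & (table["log2fc"].abs() >= tau)
    return DEResult(
        table=table,
        d0=float(d0),
        s0_sq=float(s0_sq),
        alpha=alpha,
        lfc_tiers=tuple(lfc_tiers),
        reference=design.reference,
        treatment=design.treatment,
    )
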