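"""Per-sample average z-score gene-set statistic with a two-group t-test.

Each gene's log2-CPM profile is z-scored across all samples (both groups
jointly, n-1 standard deviation); a set's score for a sample is the mean z
over the set's genes; group scores are compared with a pooled-variance
two-tailed Student's t-test on n1 + n2 - 2 degrees of freedom.

The statistic treats genes as independent replicates within a sample;
correlated member genes make the test anti-conservative. The package
asserts the mechanics of the statistic, not its biological calibration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    SampleDesign,
    ValidationError,
    ZMatrix,
)

__all__ = [
    "zscore_genes",
    "sample_set_scores",
    "set_score_test",
    "run_setscore_panel",
    "SetScoreResult",
    "MIN_SET_SIZE",
]

MIN_SET_SIZE = 4  # sets with fewer usable genes are reported, not tested


def zscore_genes(expr: ExpressionMatrix, genes=None) -> ZMatrix:
    """Z-score each gene's expression row across all samples.

    Uses the sample standard deviation (n-1 denominator). Zero-variance
    rows are dropped with a warning and recorded in ``ZMatrix.dropped``.
    """
    x = expr.values if genes is None else expr.values.loc[list(genes)]
    if x.shape[1] < 2:
        raise ValidationError("z-scoring needs at least two samples")
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.all():
        raise ValidationError("all rows have zero variance; nothing to z-score")
    dropped = tuple(x.index[zero])
    if dropped:
        warnings.warn(
            f"dropping zero-variance genes from z-matrix: {list(dropped)[:10]}",
            UserWarning,
            stacklevel=2,
        )
        x, mu, sd = x[~zero], mu[~zero], sd[~zero]
    z = x.sub(mu, axis=0).div(sd, axis=0)
    return ZMatrix(values=z, dropped=dropped)


def sample_set_scores(
    z: ZMatrix, marker_set: MarkerSet, min_set_size: int = MIN_SET_SIZE
) -> pd.Series | None:
    """Per-sample mean z over the set's genes, or None if too few are usable.

    Small sets (fewer than ``min_set_size`` genes present in the z-matrix)
    are not scored, mirroring the practice of declining to test sets of two
    or three genes.
    """
    present = [g for g in marker_set.genes if g in z.values.index]
    if len(present) < min_set_size:
        return None
    return z.values.loc[present].mean(axis=0)


@dataclass
class SetScoreResult:
    """Result of the average z-score group comparison for one gene set."""

    name: str
    n_genes: int
    scores: pd.Series | None
    mean_control: float = np.nan
    mean_treatment: float = np.nan
    t: float = np.nan
    df: float = np.nan
    p_value: float = np.nan
    direction: str | None = None
    tested: bool = False
    skip_reason: str | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.tested and self.p_value <= self.alpha)


def set_score_test(
    scores: pd.Series,
    design: SampleDesign,
    alpha: float = 0.05,
    name: str = "",
    n_genes: int = 0,
) -> SetScoreResult:
    """Pooled-variance two-tailed Student's t-test on per-sample set scores.

    Direction is the sign of (treatment mean - control mean). Zero pooled
    variance with unequal means yields an infinite t and p = 0; with equal
    means, t = 0 and p = 1.
    """
    grp = design.groups.loc[scores.index]
    c = scores[grp == design.reference].to_numpy(float)
    t_ = scores[grp == design.treatment].to_numpy(float)
    n1, n2 = len(c), len(t_)
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need at least two scores")
    df = n1 + n2 - 2
    diff = t_.mean() - c.mean()
    sp2 = ((n1 - 1) * c.var(ddof=1) + (n2 - 1) * t_.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        tstat = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        tstat = diff / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
    direction = "up" if diff > 0 else ("down" if diff < 0 else None)
    return SetScoreResult(
        name=name,
        n_genes=n_genes,
        scores=scores,
        mean_control=float(c.mean()),
        mean_treatment=float(t_.mean()),
        t=float(tstat),
        df=float(df),
        p_value=float(p),
        direction=direction,
        tested=True,
        alpha=alpha,
    )


def run_setscore_panel(
    expr: ExpressionMatrix,
    design: SampleDesign,
    sets: list[MarkerSet],
    alpha: float = 0.05,
    min_set_size: int = MIN_SET_SIZE,
) -> list[SetScoreResult]:
    """Score and test every set; sets below the size minimum get skip records."""
    if not sets:
        return []
    z = zscore_genes(expr)
    results = []
    for s in sets:
        present = [g for g in s.genes if g in z.values.index]
        scores = sample_set_scores(z, s, min_set_size=min_set_size)
        if scores is None:
            results.append(
                SetScoreResult(
                    name=s.name,
                    n_genes=len(present),
                    scores=None,
                    tested=False,
                    skip_reason=f"not tested (n = {len(present)} < minimum {min_set_size})",
                    alpha=alpha,
                )
            )
            continue
        results.append(
            set_score_test(scores, design, alpha=alpha, name=s.name, n_genes=len(present))
        )
    return results


def panel_table(results: list[SetScoreResult]) -> pd.DataFrame:
    """Flatten panel results into a tidy per-set table."""
    rows = []
    for r in results:
        rows.append(
            {
                "set": r.name,
                "n_genes": r.n_genes,
                "mean_control": r.mean_control,
                "mean_treatment": r.mean_treatment,
                "t": r.t,
                "df": r.df,
                "p_value": r.p_value,
                "direction": r.direction,
                "tested": r.tested,
                "note": r.skip_reason or "",
            }
        )
    return pd.DataFrame(rows).set_index("set")
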