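"""Two-group differential expression with the empirical-Bayes moderated t-test.

Per gene g the model is a two-sample comparison on the log2 scale:
``logfc_g = mean(treated) - mean(control)`` with pooled within-group variance
``s2_g`` on ``d = n_T + n_C - 2`` degrees of freedom.  The gene-wise variances
are assumed exchangeable, drawn from a scaled inverse-chi-square prior with
``d0`` prior degrees of freedom and prior value ``s0sq``.  The posterior
variance ``s2_post = (d0*s0sq + d*s2_g)/(d0 + d)`` shrinks each gene toward
the prior, and the moderated statistic

    t_g = logfc_g / sqrt(s2_post * (1/n_T + 1/n_C))

follows a Student t distribution with ``d0 + d`` degrees of freedom under the
null.  The prior is estimated by moment matching on the log variances:
``trigamma(d0/2) = var(log s2) - trigamma(d/2)``, with ``d0 = +inf`` (full
shrinkage, normal reference) when the empirical spread does not exceed the
chi-square sampling spread.  ``d0 = 0`` is allowed as the no-moderation limit
and reproduces the classical pooled two-sample t-test.

Raw p-values are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .preprocess import (
    CONTROL,
    TREATED,
    DesignError,
    DomainError,
    ExpressionMatrix,
    InputError,
)

logger = logging.getLogger("pathrank.diffexp")

P_FLOOR = 1e-300  # keeps downstream logarithms finite

DE_TABLE_COLUMNS = ["gene", "logfc", "s2", "t_mod", "df_total", "p", "p_adj", "rank"]


@dataclass(frozen=True)
class ModerationPrior:
    """Scaled inverse-chi-square variance prior (d0 may be +inf; d0 = 0 is
    the no-moderation classical limit)."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or math.isnan(self.d0):
            raise DomainError(f"prior df d0 must be >= 0, got {self.d0}")
        if not (self.s0sq > 0):
            raise DomainError(f"prior variance s0sq must be > 0, got {self.s0sq}")


# ---------------------------------------------------------------------------
# Gene-level fits
# ---------------------------------------------------------------------------

def fit_gene_models(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log-fold change and pooled within-group variance.

    Returns a frame indexed by gene with columns ``logfc``, ``s2`` and the
    residual degrees of freedom ``d`` (identical for all genes).
    """
    treated = m.samples_in(TREATED)
    control = m.samples_in(CONTROL)
    if len(treated) < 2 or len(control) < 2:
        raise DesignError(
            f"both groups need >= 2 samples (treated={len(treated)}, "
            f"control={len(control)})"
        )
    xt = m.values[treated].to_numpy(dtype=float)
    xc = m.values[control].to_numpy(dtype=float)
    n_t, n_c = len(treated), len(control)
    d = n_t + n_c - 2
    logfc = xt.mean(axis=1) - xc.mean(axis=1)
    ss = xt.var(axis=1, ddof=1) * (n_t - 1) + xc.var(axis=1, ddof=1) * (n_c - 1)
    s2 = ss / d
    return pd.DataFrame(
        {"logfc": logfc, "s2": s2, "d": float(d)}, index=m.values.index
    )


# ---------------------------------------------------------------------------
# Prior estimation (moment matching on log variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return math.inf

    def f(x: float) -> float:
        return float(special.polygamma(1, x)) - y

    lo, hi = 1e-9, 1e9
    if f(lo) < 0:  # y larger than trigamma can reach in bracket
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_prior(s2_all: np.ndarray | pd.Series, d: float) -> ModerationPrior:
    """Estimate (d0, s0sq) from the observed gene-wise variances.

    Under the model, ``log s2_g`` has variance ``trigamma(d0/2) +
    trigamma(d/2)`` and mean ``log s0sq + digamma(d/2) - log(d/2) -
    digamma(d0/2) + log(d0/2)``; both moments are matched empirically.
    """
    s2 = np.asarray(s2_all, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise DomainError("all gene variances are zero: degenerate data")
    if pos.size < 10:
        raise InputError(f"need >= 10 genes with positive variance, got {pos.size}")
    if pos.size < s2.size:
        logger.warning(
            "%d genes with zero variance excluded from prior estimation",
            s2.size - pos.size,
        )
    z = np.log(pos)
    # e_g is an unbiased estimate of log(s0sq) shifted by the d0 terms
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return ModerationPrior(d0=math.inf, s0sq=float(np.exp(e.mean())))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(
        np.exp(e.mean() + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return ModerationPrior(d0=d0, s0sq=s0sq)


# ---------------------------------------------------------------------------
# Moderated t and multiplicity adjustment
# ---------------------------------------------------------------------------

def moderated_t(
    fits: pd.DataFrame, prior: ModerationPrior, n_t: int, n_c: int
) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values for every gene."""
    logfc = fits["logfc"].to_numpy(dtype=float)
    s2 = fits["s2"].to_numpy(dtype=float)
    d = float(fits["d"].iloc[0])
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d

    se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    zero_se = se == 0
    t[zero_se & (logfc > 0)] = math.inf
    t[zero_se & (logfc < 0)] = -math.inf

    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, P_FLOOR, 1.0)
    out = fits.copy()
    out["t_mod"] = t
    out["df_total"] = df_total
    out["p"] = p
    return out


def bh_adjust(p_list: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values in the input order."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_diffexp(
    m: ExpressionMatrix, prior: ModerationPrior | None = None
) -> tuple[pd.DataFrame, ModerationPrior]:
    """Full differential-expression table for a preprocessed gene matrix.

    Estimates the variance prior from the data unless one is supplied, then
    computes moderated t, raw and BH-adjusted p, and the ascending-raw-p rank
    (ties broken by gene id).  Returns (table, prior).
    """
    fits = fit_gene_models(m)
    n_t = len(m.samples_in(TREATED))
    n_c = len(m.samples_in(CONTROL))
    if prior is None:
        prior = estimate_prior(fits["s2"], float(fits["d"].iloc[0]))
        logger.info("estimated prior: d0=%.4g, s0sq=%.4g", prior.d0, prior.s0sq)
    table = moderated_t(fits, prior, n_t, n_c)
    table["p_adj"] = bh_adjust(table["p"])
    order = np.lexsort((table.index.astype(str), table["p"].to_numpy()))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return table, prior


def count_de(
    results: pd.DataFrame,
    thresholds: list[float],
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Threshold-stratified counts of up- and downregulated genes.

    Counts genes with (adjusted, by default) p-value at or below each
    threshold, split by the sign of the log-fold change.
    """
    if results.empty:
        raise InputError("empty differential-expression table")
    col = "p_adj" if use_adjusted else "p"
    rows = []
    for t in thresholds:
        sig = results[results[col] <= t]
        rows.append(
            {
                "threshold": t,
                "n_up": int((sig["logfc"] > 0).sum()),
                "n_down": int((sig["logfc"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["threshold", "n_up", "n_down"])


# ---------------------------------------------------------------------------
# I/O and figure-style export tables
# ---------------------------------------------------------------------------

def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    out = results[["logfc", "s2", "t_mod", "df_total", "p", "p_adj", "rank"]]
    out.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index = df.index.astype(str)
    return df


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (logfc, -log10 adjusted p) pairs for volcano plotting."""
    return pd.DataFrame(
        {
            "gene": results.index,
            "logfc": results["logfc"].to_numpy(),
            "neg_log10_p_adj": -np.log10(results["p_adj"].to_numpy()),
        }
    )


def cumulative_p_table(
    results: pd.DataFrame, thresholds: list[float] | None = None
) -> pd.DataFrame:
    """Cumulative adjusted-p distribution of up/down gene counts."""
    if thresholds is None:
        thresholds = sorted(
            np.unique(np.round(results["p_adj"].to_numpy(), 4)).tolist()
        )
    return count_de(results, thresholds, use_adjusted=True)
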