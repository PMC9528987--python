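"""Short-vs-long capped RNA composition analysis over peak count matrices.

Counts are modelled as negative binomial with variance mu + alpha*mu^2.
Library depth is normalised by median-of-ratios size factors (rescaled by
their median).  Each peak is tested for a shift in the short:long expression
ratio with a Wald test on the assay coefficient of a two-level NB log-linear
model with plug-in dispersion, followed by Benjamini-Hochberg adjustment
across peaks.  A variance-stabilising transform with a log2 asymptote feeds
per-timepoint fold changes and a one-way ANOVA time-course filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


@dataclass
class EnrichmentParams:
    alpha_adj: float = 0.05  # adjusted-p cutoff for the enriched classes
    vst_variant: str = "sqrt"  # "sqrt" (log2 asymptote) or "literal"
    expression_threshold: int = 1  # pooled tags needed to call a peak "expressed"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adj < 1:
            raise ValidationError("alpha_adj must be in (0,1)")
        if self.vst_variant not in ("sqrt", "literal"):
            raise ValidationError("vst_variant must be 'sqrt' or 'literal'")


# ---------------------------------------------------------------------------
# Normalisation and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, divided by their median.

    s_j = median over rows of count_ij / geometric-row-mean, computed over
    rows whose geometric mean is positive; the factors are then rescaled so
    their median is 1.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValidationError("count matrix must be 2-D with >=1 column")
    if mat.shape[1] == 1:
        return np.ones(1)
    with np.errstate(divide="ignore"):
        log_counts = np.log(mat)
    log_geomean = log_counts.mean(axis=1)
    ok = np.isfinite(log_geomean)
    if not np.any(ok):
        raise ValidationError("no row with all-positive counts for size factors")
    ratios = log_counts[ok] - log_geomean[ok, None]
    s = np.exp(np.median(ratios, axis=0))
    return s / np.median(s)


def estimate_dispersion(
    counts: pd.DataFrame | np.ndarray,
    s: Optional[np.ndarray] = None,
    aggregate: str = "mean",
) -> float:
    """Method-of-moments NB dispersion over replicate columns.

    Per row of normalised counts: alpha_row = max(0, (var - mean) / mean^2);
    the returned alpha aggregates rows with positive mean by the mean
    (default; approximately unbiased and well calibrated downstream) or the
    median (robust but biased low at few replicates).
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValidationError("dispersion estimation needs >=2 replicate columns")
    if s is not None:
        mat = mat / np.asarray(s, dtype=float)[None, :]
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    ok = mean > 0
    if not np.any(ok):
        return 0.0
    alpha_rows = np.maximum(0.0, (var[ok] - mean[ok]) / mean[ok] ** 2)
    if aggregate == "median":
        return float(np.median(alpha_rows))
    if aggregate == "mean":
        return float(np.mean(alpha_rows))
    raise ValidationError("aggregate must be 'median' or 'mean'")


def mean_assay_dispersion(
    counts: pd.DataFrame,
    s: np.ndarray,
    assays: Sequence[str] = ("short", "long"),
    aggregate: str = "mean",
) -> float:
    """Dispersion computed in each assay separately, then averaged."""
    cols = counts.columns.get_level_values("assay")
    alphas = []
    for assay in assays:
        mask = np.asarray(cols == assay)
        alphas.append(
            estimate_dispersion(counts.loc[:, mask].to_numpy(), s[mask], aggregate)
        )
    return float(np.mean(alphas))


# ---------------------------------------------------------------------------
# NB Wald enrichment test
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    peak_id: str
    log2_ratio: float  # short vs long, normalised, pseudocount 0.5
    p: float
    p_adj: float
    enriched: str  # "short_enriched" | "long_enriched" | "ns"
    expressed_short: bool
    expressed_long: bool
    all_zero: bool = False


def _nb_wald(
    y: np.ndarray,
    s: np.ndarray,
    is_short: np.ndarray,
    alpha: float,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Fisher scoring for log mu = log s + b0 + b1*short.

    Returns (b1, se_b1) per row of y.  Rows with an all-zero assay drift to
    an unbounded coefficient with an exploding standard error, so their Wald
    statistic degrades gracefully toward zero.
    """
    n_peaks = y.shape[0]
    x = is_short.astype(float)
    log_s = np.log(s)
    mean_short = (y[:, x == 1] / s[x == 1]).mean(axis=1)
    mean_long = (y[:, x == 0] / s[x == 0]).mean(axis=1)
    b0 = np.log(np.maximum(mean_long, 1e-8))
    b1 = np.log(np.maximum(mean_short, 1e-8)) - b0
    for _ in range(max_iter):
        eta = log_s[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -500, 500))
        w = mu / (1.0 + alpha * mu)
        resid = (y - mu) / (1.0 + alpha * mu)
        u0 = resid.sum(axis=1)
        u1 = (resid * x[None, :]).sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = (w * x[None, :]).sum(axis=1)
        i11 = i01
        det = np.maximum(i00 * i11 - i01 * i01, 1e-300)
        db0 = (i11 * u0 - i01 * u1) / det
        db1 = (i00 * u1 - i01 * u0) / det
        db0 = np.clip(db0, -5, 5)
        db1 = np.clip(db1, -5, 5)
        b0 += db0
        b1 += db1
        if np.max(np.abs(db0)) < tol and np.max(np.abs(db1)) < tol:
            break
    eta = log_s[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -500, 500))
    w = mu / (1.0 + alpha * mu)
    i00 = w.sum(axis=1)
    i01 = (w * x[None, :]).sum(axis=1)
    i11 = i01
    det = np.maximum(i00 * i11 - i01 * i01, 1e-300)
    var_b1 = i00 / det
    return b1, np.sqrt(np.maximum(var_b1, 1e-300))


def nb_enrichment_test(
    counts: pd.DataFrame,
    s: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
    params: EnrichmentParams = EnrichmentParams(),
) -> list[EnrichmentResult]:
    """Per-peak Wald test of the short:long composition ratio.

    ``counts`` has a (sample, assay) column MultiIndex with assays "short"
    and "long".  Dispersion defaults to the mean of the per-assay estimates;
    size factors default to median-of-ratios.
    """
    assays = np.asarray(counts.columns.get_level_values("assay"))
    is_short = assays == "short"
    is_long = assays == "long"
    if not is_short.any() or not is_long.any():
        raise ValidationError("need >=1 column per assay (short and long)")
    keep = is_short | is_long
    mat = counts.loc[:, keep].to_numpy(dtype=float)
    is_short = is_short[keep]
    if s is None:
        s = size_factors(mat)
    else:
        s = np.asarray(s, dtype=float)[keep]
    if alpha is None:
        alpha = mean_assay_dispersion(counts.loc[:, keep], s)

    norm = mat / s[None, :]
    mean_short = norm[:, is_short].mean(axis=1)
    mean_long = norm[:, ~is_short].mean(axis=1)
    sum_short = mat[:, is_short].sum(axis=1)
    sum_long = mat[:, ~is_short].sum(axis=1)
    all_zero = (sum_short + sum_long) == 0

    b1, se = _nb_wald(mat, s, is_short, alpha)
    z = np.where(se > 0, b1 / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[all_zero] = 1.0
    p_adj = multipletests(p, method="fdr_bh")[1]

    log2_ratio = np.log2((mean_short + 0.5) / (mean_long + 0.5))
    log2_ratio[all_zero] = 0.0

    results = []
    thr = params.expression_threshold
    for i, peak_id in enumerate(counts.index):
        if all_zero[i] or p_adj[i] >= params.alpha_adj:
            cls = "ns"
        elif b1[i] > 0:
            cls = "short_enriched"
        else:
            cls = "long_enriched"
        results.append(
            EnrichmentResult(
                peak_id=str(peak_id),
                log2_ratio=float(log2_ratio[i]),
                p=float(p[i]),
                p_adj=float(p_adj[i]),
                enriched=cls,
                expressed_short=bool(sum_short[i] >= thr),
                expressed_long=bool(sum_long[i] >= thr),
                all_zero=bool(all_zero[i]),
            )
        )
    return results


def venn_classify(results: Iterable[EnrichmentResult]) -> dict[str, int]:
    """Partition peaks by expression overlap and enrichment class.

    Outer classes: expressed in both assays, short only, or long only
    (peaks expressed in neither are excluded).  Inner classes: enriched for
    short, enriched for long, or not significant.
    """
    counts: dict[str, int] = {}
    for key in (
        "both",
        "short_only",
        "long_only",
        "enriched_short",
        "enriched_long",
        "ns",
    ):
        counts[key] = 0
    total = 0
    for res in results:
        if not res.expressed_short and not res.expressed_long:
            continue
        total += 1
        if res.expressed_short and res.expressed_long:
            counts["both"] += 1
        elif res.expressed_short:
            counts["short_only"] += 1
        else:
            counts["long_only"] += 1
        if res.enriched == "short_enriched":
            counts["enriched_short"] += 1
        elif res.enriched == "long_enriched":
            counts["enriched_long"] += 1
        else:
            counts["ns"] += 1
    counts["total_expressed"] = total
    return counts


# ---------------------------------------------------------------------------
# Variance-stabilising transform and time-course operations
# ---------------------------------------------------------------------------

def vst(x, a: float, variant: str = "sqrt"):
    """Variance-stabilising transform for NB counts with dispersion a.

    variant "sqrt" (default): (2*arcsinh(sqrt(a*x)) - ln a - ln 4) / ln 2,
    which tends to log2(x) for large x.  variant "literal":
    (2*arcsinh(a*x) - ln a - ln 4) / ln 2, with asymptote 2*log2(x).
    Both are strictly increasing; x must be >= 0.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("vst requires x >= 0")
    if a <= 0:
        raise ValidationError("vst requires a > 0")
    if variant == "sqrt":
        core = 2.0 * np.arcsinh(np.sqrt(a * arr))
    elif variant == "literal":
        core = 2.0 * np.arcsinh(a * arr)
    else:
        raise ValidationError("variant must be 'sqrt' or 'literal'")
    out = (core - math.log(a) - math.log(4.0)) / math.log(2.0)
    return out if out.shape else float(out)


def timecourse_fold_changes(
    counts: pd.DataFrame,
    s: np.ndarray,
    a: float,
    timepoints: dict[str, object],
    variant: str = "sqrt",
) -> pd.DataFrame:
    """Centered per-timepoint VST means, per peak and assay.

    value(peak, assay, t) = mean over replicates at t of vst(count / s_j),
    minus the across-timepoint average of those means; rows therefore average
    to zero within each assay.
    """
    samples = counts.columns.get_level_values("sample")
    assays = counts.columns.get_level_values("assay")
    transformed = vst(counts.to_numpy(dtype=float) / np.asarray(s)[None, :], a, variant)
    cols = {}
    for assay in sorted(set(assays)):
        tps = sorted({timepoints[s_] for s_, a_ in zip(samples, assays) if a_ == assay
                      and s_ in timepoints})
        means = {}
        for tp in tps:
            mask = np.asarray(
                [(a_ == assay and timepoints.get(s_) == tp)
                 for s_, a_ in zip(samples, assays)]
            )
            if not mask.any():
                continue
            means[tp] = transformed[:, mask].mean(axis=1)
        if not means:
            continue
        center = np.mean(list(means.values()), axis=0)
        for tp, v in means.items():
            cols[(assay, tp)] = v - center
    out = pd.DataFrame(cols, index=counts.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["assay", "timepoint"])
    return out


def anova_filter(
    groups_per_peak: Sequence[Sequence[np.ndarray]],
    p_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA keep/drop flags over per-peak timepoint groups.

    Each entry of ``groups_per_peak`` is a list of value arrays (one per
    timepoint).  All-identical values give p=1 (dropped); zero within-group
    variance with unequal means gives p=0 (kept).  Returns (keep, pvalues).
    """
    pvals = np.empty(len(groups_per_peak))
    for i, groups in enumerate(groups_per_peak):
        arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
        if len(arrays) < 2:
            pvals[i] = 1.0
            continue
        allvals = np.concatenate(arrays)
        if np.allclose(allvals, allvals[0]):
            pvals[i] = 1.0
            continue
        within_var = sum(float(np.var(a)) * len(a) for a in arrays)
        if within_var == 0:
            pvals[i] = 0.0
            continue
        stat, p = stats.f_oneway(*arrays)
        pvals[i] = p if np.isfinite(p) else 0.0
    return pvals < p_threshold, pvals


def anova_filter_counts(
    fold_changes: pd.DataFrame,
    counts: pd.DataFrame,
    s: np.ndarray,
    a: float,
    timepoints: dict[str, object],
    variant: str = "sqrt",
    p_threshold: float = 0.05,
) -> np.ndarray:
    """Keep a peak when either assay is time-course differential by ANOVA on
    per-replicate VST values."""
    samples = counts.columns.get_level_values("sample")
    assays = counts.columns.get_level_values("assay")
    transformed = vst(counts.to_numpy(dtype=float) / np.asarray(s)[None, :], a, variant)
    keep = np.zeros(len(counts), dtype=bool)
    for assay in sorted(set(assays)):
        groups_cols: dict[object, np.ndarray] = {}
        for tp in sorted({timepoints[s_] for s_, a_ in zip(samples, assays)
                          if a_ == assay and s_ in timepoints}):
            mask = np.asarray(
                [(a_ == assay and timepoints.get(s_) == tp)
                 for s_, a_ in zip(samples, assays)]
            )
            if mask.any():
                groups_cols[tp] = mask
        if len(groups_cols) < 2:
            continue
        groups_per_peak = [
            [transformed[i, mask] for mask in groups_cols.values()]
            for i in range(len(counts))
        ]
        flags, _ = anova_filter(groups_per_peak, p_threshold)
        keep |= flags
    return keep
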