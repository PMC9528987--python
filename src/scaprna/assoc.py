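"""Downstream association statistics for predicted enhancers.

Covers ChIP-mark window means and the proportionality-slope Z-test between
enhancer classes, GWAS-SNP overlap enrichment with a binomial test, and the
Fisher-exact / Mann-Whitney helpers used for reporter and mark-signal
comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, IntervalLookup, SignalTrack, SNPTable, ValidationError

logger = logging.getLogger(__name__)


def window_mean_signal(
    track: SignalTrack,
    chrom: str,
    center: int,
    halfwidth: int = 5000,
    chrom_length: Optional[int] = None,
) -> float:
    """Length-weighted mean track value over center +/- halfwidth.

    Positions absent from the track count as 0.  The window is clipped to
    chromosome bounds when a length is supplied (clipping is logged) and the
    mean is taken over the clipped window.
    """
    start = center - halfwidth
    end = center + halfwidth
    if start < 0 or (chrom_length is not None and end > chrom_length):
        logger.warning("window around %s:%d clipped to chromosome bounds",
                       chrom, center)
        start = max(0, start)
        if chrom_length is not None:
            end = min(end, chrom_length)
    if end <= start:
        return 0.0
    return track.window_sum(chrom, start, end) / (end - start)


@dataclass
class SlopeResult:
    slope: float
    sd: float  # standard error of the slope
    n: int


def proportionality_slope(
    x: Sequence[float],
    y: Sequence[float],
    intercept: bool = False,
) -> SlopeResult:
    """Least-squares proportionality constant between two mark scores.

    Default is regression through the origin: b = sum(xy)/sum(x^2) with the
    residual-based standard error sqrt(RSS/(n-1)/sum(x^2)).  The
    with-intercept variant returns the usual OLS slope and its standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >=3 paired scores")
    if np.allclose(x, x[0]) and intercept:
        raise ValidationError("x values must not all be equal")
    if not intercept:
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise ValidationError("sum(x^2) is zero")
        b = float(np.sum(x * y)) / sxx
        resid = y - b * x
        sigma2 = float(np.sum(resid**2)) / (len(x) - 1)
        return SlopeResult(b, math.sqrt(sigma2 / sxx), len(x))
    xc = x - x.mean()
    sxx = float(np.sum(xc * xc))
    if sxx == 0:
        raise ValidationError("x values must not all be equal")
    b = float(np.sum(xc * (y - y.mean()))) / sxx
    resid = y - y.mean() - b * xc
    sigma2 = float(np.sum(resid**2)) / (len(x) - 2)
    return SlopeResult(b, math.sqrt(sigma2 / sxx), len(x))


@dataclass
class SlopeZResult:
    z: float
    p: float
    infinite: bool = False


def slope_z_test(
    b1: float,
    sd1: float,
    b2: float,
    sd2: float,
    denominator: str = "rms",
) -> SlopeZResult:
    """Z-test on the difference between two proportionality constants.

    Default denominator is the root mean square of the two standard
    deviations, sqrt((sd1^2 + sd2^2)/2); the conventional standard-error
    combination sqrt(sd1^2 + sd2^2) is available as ``denominator="sum"``
    (the RMS variant is anti-conservative by a factor sqrt(2)).
    """
    if denominator == "rms":
        denom = math.sqrt((sd1**2 + sd2**2) / 2.0)
    elif denominator == "sum":
        denom = math.sqrt(sd1**2 + sd2**2)
    else:
        raise ValidationError("denominator must be 'rms' or 'sum'")
    if denom == 0:
        if b1 == b2:
            return SlopeZResult(0.0, 1.0)
        return SlopeZResult(math.inf if b1 > b2 else -math.inf, 0.0, infinite=True)
    z = (b1 - b2) / denom
    return SlopeZResult(z, 2.0 * float(stats.norm.sf(abs(z))))


@dataclass
class GwasEnrichmentResult:
    n_snps_in_regions: int
    n_gwas_in_regions: int
    background_fraction: float
    enrichment_factor: float
    fraction_sd: float  # binomial sd of the in-region GWAS fraction
    p: float
    undefined: bool = False


def gwas_enrichment(
    snps: SNPTable,
    regions: Sequence[GenomicInterval],
) -> GwasEnrichmentResult:
    """GWAS-trait enrichment of SNP loci inside a region set.

    Background is the genome-wide GWAS fraction of the same SNP table.  The
    p-value is the upper-tail binomial probability of the observed number of
    GWAS SNPs among in-region SNPs at the background rate.
    """
    if len(snps) == 0:
        raise ValidationError("empty SNP table")
    background = float(np.mean(snps.gwas))
    lookup = IntervalLookup(regions)
    inside = np.array(
        [lookup.contains(c, int(p)) for c, p in zip(snps.chroms, snps.positions)]
    )
    n_in = int(inside.sum())
    if n_in == 0:
        return GwasEnrichmentResult(0, 0, background, float("nan"), float("nan"),
                                    1.0, undefined=True)
    n_gwas = int(np.sum(snps.gwas[inside]))
    frac = n_gwas / n_in
    factor = frac / background if background > 0 else float("inf")
    sd = math.sqrt(frac * (1 - frac) / n_in)
    if background in (0.0, 1.0):
        p = 1.0
    else:
        p = float(stats.binom.sf(n_gwas - 1, n_in, background)) if n_gwas else 1.0
    return GwasEnrichmentResult(n_in, n_gwas, background, factor, sd, p)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on a 2x2 table; degenerate margins
    give p = 1."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValidationError("table entries must be non-negative")
    table = np.array([[a, b], [c, d]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def mannwhitney(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U test."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("groups must be non-empty")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
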