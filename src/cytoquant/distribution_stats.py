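"""Cell-by-cell heterogeneity: pooling, outlier exclusion, histograms,
moment statistics and the two-sample Kolmogorov-Smirnov comparison.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .errors import ComputationError
from .quantify import ReceptorSample

PooledSample = namedtuple("PooledSample", ["values", "n_excluded"])
KSResult = namedtuple("KSResult", ["D", "p"])


def pool_and_exclude(samples, k: float = 3.0) -> PooledSample:
    """Pool replicate samples and apply the single-pass k-SD rule.

    The pooled mean and SD are computed once and values with
    ``|v - mean| > k*SD`` are dropped; the rule is deliberately
    non-iterative, so re-running it on its own output may exclude a
    further (logged, small) fraction.
    """
    if k <= 0:
        raise ComputationError("SD multiplier k must be > 0")
    arrays = []
    for s in samples:
        arrays.append(s.per_cell if isinstance(s, ReceptorSample) else np.asarray(s, dtype=float))
    pooled = np.concatenate(arrays) if arrays else np.empty(0)
    if len(pooled) < 2:
        raise ComputationError("pooled sample needs n >= 2")
    center, sd = pooled.mean(), pooled.std()
    keep = np.abs(pooled - center) <= k * sd
    return PooledSample(values=pooled[keep], n_excluded=int((~keep).sum()))


@dataclass(frozen=True)
class DistributionSummary:
    """Cell-by-cell descriptive statistics of a receptor distribution."""

    n_cells: int
    median: float
    cv_percent: float
    skewness: float
    excess_kurtosis: float
    bin_edges: tuple
    counts: tuple
    n_excluded: int = 0

    @property
    def histogram(self):
        return np.asarray(self.bin_edges), np.asarray(self.counts)


def summarize(values, bin_width: float = 500.0, n_excluded: int = 0,
              excess: bool = True, bias_corrected: bool = False,
              ) -> DistributionSummary:
    """Summary statistics and a fixed-width histogram.

    cv_percent = 100*SD/mean; skewness = m3/m2^(3/2); kurtosis is
    excess by default (m4/m2^2 - 3, so a normal scores 0) using plain
    central-moment estimators.  ``bias_corrected=True`` switches both
    shape statistics to their small-sample-corrected forms and
    ``excess=False`` reports non-excess kurtosis, for cross-checks
    against software using other conventions.  Histogram bins are
    half-open [lo, hi) at multiples of ``bin_width`` starting at 0.

    Statistics whose moment ratios are undefined for the input (n < 2,
    or zero variance for the shape statistics) are reported as NaN.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ComputationError("cannot summarize an empty sample")
    if bin_width <= 0:
        raise ComputationError("bin_width must be > 0")
    mean = v.mean()
    if n >= 2 and mean == 0:
        raise ComputationError("CV undefined: sample mean is zero")
    cv_percent = 100.0 * v.std() / mean if n >= 2 else np.nan
    # shape statistics are reported whenever their moment ratios are
    # defined (n >= 2 and non-zero variance), NaN otherwise
    if n >= 2 and v.std() > 0:
        skw = float(stats.skew(v, bias=not bias_corrected))
        kur = float(stats.kurtosis(v, fisher=excess, bias=not bias_corrected))
    else:
        skw = kur = np.nan

    n_bins = int(v.max() // bin_width) + 1 if v.max() > 0 else 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    # np.histogram closes the last bin on the right; edges extend past
    # the maximum so every bin is effectively half-open [lo, hi)
    return DistributionSummary(
        n_cells=n,
        median=float(np.median(v)),
        cv_percent=float(cv_percent),
        skewness=skw,
        excess_kurtosis=kur,
        bin_edges=tuple(edges.tolist()),
        counts=tuple(int(c) for c in counts),
        n_excluded=int(n_excluded),
    )


def ks_two_sample(a, b) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test on raw values.

    D is the supremum distance between the two empirical CDFs and p
    comes from the asymptotic K-S distribution at effective sample
    size n_a*n_b/(n_a+n_b).  The comparison uses the raw per-cell
    values, not binned histograms — binning would discard information.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ComputationError("K-S test needs n >= 2 in both samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(D=float(res.statistic), p=float(res.pvalue))
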