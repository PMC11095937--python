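"""Histograms, Gaussian fits, box statistics and paired comparisons.

The index distributions produced by the trace and chem modules (RI, ReI, CI)
live on [-1, 1].  They are binned at a fixed width and summarized by fitting
one- or two-component Gaussian curves to the bin counts by nonlinear least
squares, mirroring the curve-overlay fits shown alongside such histograms.
Model order can be selected automatically by BIC with a conservative margin.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

HISTOGRAM_SOURCES = ("RI", "ReI_amp", "ReI_auc", "CI_voc", "CI_protein")


@dataclass
class IndexHistogram:
    """Fixed-width histogram of an index distribution on [-1, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    source: str = "RI"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def build_histogram(
    values: Sequence[float],
    bin_width: float = 0.05,
    source: str = "RI",
) -> IndexHistogram:
    """Bin index values on [-1, 1] with half-open bins (last bin closed).

    ``bin_width`` must divide the interval length 2 evenly.  Values outside
    [-1, 1] are clipped with a warning; NaNs are dropped.
    """
    n_bins = 2.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 2 evenly")
    n_bins = int(round(n_bins))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)

    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n_out = int(((arr < -1.0) | (arr > 1.0)).sum())
    if n_out:
        logger.warning("build_histogram: clipped %d values outside [-1, 1]", n_out)
        arr = np.clip(arr, -1.0, 1.0)
    counts, _ = np.histogram(arr, bins=edges)
    return IndexHistogram(
        bin_edges=edges,
        counts=counts.astype(int),
        n_total=int(arr.size),
        source=source,
    )


# ---------------------------------------------------------------------------
# Gaussian fits
# ---------------------------------------------------------------------------

@dataclass
class GaussianComponent:
    weight: float  # count-scale amplitude
    mu: float
    sigma: float


@dataclass
class GaussianFit:
    """Least-squares Gaussian curve fit to histogram bin counts."""

    components: list[GaussianComponent]
    n_components: int
    rss: float
    bic: float
    converged: bool
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.weight * np.exp(-0.5 * ((x - c.mu) / c.sigma) ** 2)
        return out

    def summary(self) -> str:
        lines = [f"Gaussian fit: {self.n_components} component(s), rss={self.rss:.3g}"]
        for i, c in enumerate(self.components, 1):
            lines.append(
                f"  component {i}: peak={c.mu:+.3f}  sigma={c.sigma:.3f}  "
                f"amplitude={c.weight:.1f}"
            )
        return "\n".join(lines)


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x)
    for w, mu, sigma in zip(params[0::3], params[1::3], params[2::3]):
        out += w * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return out


def _local_maxima(counts: np.ndarray) -> np.ndarray:
    """Indices of local maxima, largest counts first."""
    c = counts.astype(float)
    idx = [
        i
        for i in range(len(c))
        if c[i] > 0
        and (i == 0 or c[i] >= c[i - 1])
        and (i == len(c) - 1 or c[i] >= c[i + 1])
    ]
    return np.array(sorted(idx, key=lambda i: -c[i]), dtype=int)


def _bic(chi2: float, n: int, k: int) -> float:
    # Pearson chi-square (Poisson bin counts) plus the BIC complexity term:
    # calibrated for model selection where a raw-RSS criterion is not.
    return chi2 + k * math.log(n)


def _fit_k(
    centers: np.ndarray, counts: np.ndarray, k: int, bin_width: float
) -> GaussianFit:
    peaks = _local_maxima(counts)
    n = counts.size
    total = counts.sum()
    sigma0 = max(
        float(np.sqrt(np.clip(np.average(
            (centers - np.average(centers, weights=np.maximum(counts, 1e-12))) ** 2,
            weights=np.maximum(counts, 1e-12),
        ), 1e-6, None))),
        bin_width,
    )

    starts: list[list[float]] = []
    if k == 1:
        for i in peaks[:2] if peaks.size else [int(np.argmax(counts))]:
            starts.append([float(counts[i]), float(centers[i]), sigma0])
        starts.append([total * bin_width / (sigma0 * math.sqrt(2 * math.pi)),
                       float(np.average(centers, weights=np.maximum(counts, 1e-12))),
                       sigma0])
    else:
        top = list(peaks[:2])
        if len(top) < 2:
            top = [int(np.argmax(counts)), int(np.argmin(np.abs(centers)))]
        i, j = top[0], top[1]
        for si, sj in ((i, j), (j, i)):
            starts.append(
                [float(max(counts[si], 1)), float(centers[si]), sigma0 / 2,
                 float(max(counts[sj], 1)), float(centers[sj]), sigma0 / 2]
            )
        # symmetric fallback straddling the count-weighted mean
        mu0 = float(np.average(centers, weights=np.maximum(counts, 1e-12)))
        amp = float(max(counts.max(), 1))
        starts.append([amp, mu0 - sigma0, sigma0 / 2, amp, mu0 + sigma0, sigma0 / 2])

    lo = [0.0, float(centers[0]), bin_width / 4] * k
    hi = [float(max(counts.max() * 10, 10)), float(centers[-1]), 2.0] * k

    best: GaussianFit | None = None
    for p0 in starts:
        p0 = [min(max(v, l), h) for v, l, h in zip(p0, lo, hi)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = scipy.optimize.curve_fit(
                    _gauss_sum,
                    centers,
                    counts.astype(float),
                    p0=p0,
                    bounds=(lo, hi),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        pred = _gauss_sum(centers, *popt)
        rss = float(np.sum((counts - pred) ** 2))
        chi2 = float(np.sum((counts - pred) ** 2 / np.maximum(pred, 1.0)))
        fit = GaussianFit(
            components=sorted(
                [
                    GaussianComponent(float(w), float(mu), float(s))
                    for w, mu, s in zip(popt[0::3], popt[1::3], popt[2::3])
                ],
                key=lambda c: c.mu,
            ),
            n_components=k,
            rss=rss,
            bic=_bic(chi2, n, 3 * k),
            converged=True,
        )
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        return GaussianFit(
            components=[],
            n_components=k,
            rss=float("inf"),
            bic=float("inf"),
            converged=False,
            message=f"no start converged for k={k}",
        )
    return best


def fit_gaussians(
    hist: IndexHistogram, n_components: int | str = 1, bic_margin: float = 6.0
) -> GaussianFit:
    """Fit 1 or 2 Gaussian components to histogram counts.

    ``n_components`` may be 1, 2 or ``"auto"``; auto selects two components
    only when their BIC improves on the single component by at least
    ``bic_margin`` (favoring the simpler model otherwise).  Non-convergence
    of every start raises rather than returning silent defaults.
    """
    nonzero = int((hist.counts > 0).sum())
    if n_components == "auto":
        needed = 5
    else:
        needed = 5 if n_components == 1 else 8
    if nonzero < needed:
        raise ValueError(
            f"too few nonzero bins ({nonzero}) for a "
            f"{n_components}-component fit (need >= {needed})"
        )
    centers = hist.bin_centers
    counts = hist.counts

    if n_components == 1:
        fit = _fit_k(centers, counts, 1, hist.bin_width)
    elif n_components == 2:
        fit = _fit_k(centers, counts, 2, hist.bin_width)
    elif n_components == "auto":
        fit1 = _fit_k(centers, counts, 1, hist.bin_width)
        fit = fit1
        if nonzero >= 8:
            fit2 = _fit_k(centers, counts, 2, hist.bin_width)
            # a genuine second mode must be separated from the first; two
            # concentric components merely reshape one peak's tails
            separated = fit2.converged and len(fit2.components) == 2 and (
                abs(fit2.components[1].mu - fit2.components[0].mu)
                >= max(c.sigma for c in fit2.components)
            )
            if (
                separated
                and fit1.converged
                and fit1.bic - fit2.bic >= bic_margin
            ):
                fit = fit2
            elif not fit1.converged and fit2.converged:
                fit = fit2
    else:
        raise ValueError("n_components must be 1, 2 or 'auto'")
    if not fit.converged:
        raise RuntimeError(f"Gaussian fit failed to converge: {fit.message}")
    return fit


# ---------------------------------------------------------------------------
# box statistics
# ---------------------------------------------------------------------------

@dataclass
class BoxStats:
    """Box-and-whisker summary: quartile box, 10th/90th percentile whiskers,
    and individually flagged outliers beyond 1.5 IQR from the box edges."""

    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    n: int


def box_stats(values: Sequence[float]) -> BoxStats:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("box_stats needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    lo10, hi90 = np.percentile(arr, [10, 90])
    iqr = q3 - q1
    out = arr[(arr < q1 - 1.5 * iqr) | (arr > q3 + 1.5 * iqr)]
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_lo=float(lo10),
        whisker_hi=float(hi90),
        outliers=np.sort(out),
        n=int(arr.size),
    )


# ---------------------------------------------------------------------------
# paired / two-sample tests
# ---------------------------------------------------------------------------

PAIRED_TESTS = ("wilcoxon_signed_rank", "mann_whitney_u", "t_unpaired", "ks_two_sample")


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    significant: bool
    note: str = ""


def compare_paired(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "wilcoxon_signed_rank",
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided nonparametric / parametric comparison wrappers.

    ``wilcoxon_signed_rank`` requires paired (equal-length) samples; the
    remaining tests compare two independent samples.  All-zero paired
    differences make the signed-rank test undefined; this is reported (NaN
    p-value, note set) rather than raised.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "wilcoxon_signed_rank":
        if a.size != b.size:
            raise ValueError("signed-rank test requires paired samples")
        if np.all(a - b == 0):
            return TestResult(
                test=test,
                statistic=float("nan"),
                p_value=float("nan"),
                significant=False,
                note="all paired differences are zero; test undefined",
            )
        stat, p = scipy.stats.wilcoxon(a, b, alternative="two-sided")
    elif test == "mann_whitney_u":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t_unpaired":
        stat, p = scipy.stats.ttest_ind(a, b)
    elif test == "ks_two_sample":
        stat, p = scipy.stats.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}; choose from {PAIRED_TESTS}")
    return TestResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# percentage reporting
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage_report(
    counts: dict[str, int], denominator: int | None = None
) -> pd.DataFrame:
    """Percentages (100 x count / denominator) rounded half-up to 1 decimal.

    With no explicit denominator the category total is used.
    """
    denom = sum(counts.values()) if denominator is None else denominator
    if denom <= 0:
        raise ValueError("denominator must be > 0")
    rows = [
        {
            "category": k,
            "count": int(v),
            "denominator": int(denom),
            "percent": round_half_up(100.0 * v / denom),
        }
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)
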