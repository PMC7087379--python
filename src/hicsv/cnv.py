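"""Copy-number inference from Hi-C 1D coverage.

The per-bin row/column sums of an *unnormalized* contact matrix track copy
number (a region with extra copies interacts more with everything), on top
of systematic Hi-C biases. The model is a Poisson generalized additive
model on the 1D coverage,

    log E[Coverage_i] = s1(GC_i) + s2(Mappability_i) + s3(RestrSites_i),

with one unspecified smooth per covariate. Copy-number signal lives in the
residuals: the working residual log(obs) - log(fitted), divided by ln 2
and median-centered, is the per-bin log2 copy ratio. Log2 ratios are then
segmented by BIC-penalized merging of adjacent bins (BIC-seq style; the
penalty weight lambda controls smoothness, larger lambda -> fewer
segments), and segments are called gain (> 0.3), loss (< -0.3) or neutral.

Matrix-balancing normalization must NOT be applied upstream: making every
row sum to one removes exactly the copy-number signal this module reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBins
from .matrix import CoverageProfile

log = logging.getLogger(__name__)

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
DEFAULT_LAMBDA = 50.0
DEFAULT_BINSIZE = 50_000

MAPPABILITY_MIN = 0.5  # bins below this are unusable
MIN_USABLE_BINS = 50
COUNT_FLOOR = 0.5  # zero-coverage floor before taking logs


@dataclass
class BiasCovariates:
    """Per-bin covariates driving Hi-C coverage bias.

    ``usable`` marks bins that enter the regression: mappability >=
    ``map_min`` and at least one restriction site. Unusable bins get no
    copy-ratio estimate.
    """

    bins: GenomeBins
    gc: np.ndarray
    mappability: np.ndarray
    n_restriction_sites: np.ndarray
    map_min: float = MAPPABILITY_MIN
    usable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.bins.n_total
        self.gc = np.asarray(self.gc, dtype=float)
        self.mappability = np.asarray(self.mappability, dtype=float)
        self.n_restriction_sites = np.asarray(self.n_restriction_sites, dtype=float)
        for name in ("gc", "mappability", "n_restriction_sites"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} has length {arr.shape}, expected {n}")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc must lie in [0, 1]")
        if np.any((self.mappability < 0) | (self.mappability > 1)):
            raise ValueError("mappability must lie in [0, 1]")
        if np.any(self.n_restriction_sites < 0):
            raise ValueError("restriction-site counts must be >= 0")
        self.usable = ((self.mappability >= self.map_min)
                       & (self.n_restriction_sites > 0)
                       & np.isfinite(self.gc)
                       & np.isfinite(self.mappability))


@dataclass
class BiasModelFit:
    """Fitted bias model: per-bin fitted means and working residuals
    (natural-log scale) on usable bins, NaN elsewhere."""

    bins: GenomeBins
    fitted: np.ndarray
    residuals: np.ndarray
    fit_quality: float  # deviance explained, 1 - dev/null_dev
    usable: np.ndarray


@dataclass
class CopyRatioProfile:
    """Per-bin log2 copy ratios (median-centered over usable bins)."""

    bins: GenomeBins
    log2_ratio: np.ndarray
    source: str = "hic"


@dataclass
class SegmentationParams:
    lam: float = DEFAULT_LAMBDA  # BIC smoothness penalty
    binsize: int = DEFAULT_BINSIZE
    min_bins: int = 1

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    n_bins: int
    call: str = "neutral"  # gain | loss | neutral

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


# -- bias regression -------------------------------------------------------


def fit_bias_model(cov: CoverageProfile, x: BiasCovariates,
                   df: int = 5, degree: int = 3) -> BiasModelFit:
    """Fit the Poisson additive bias model on usable bins.

    Each covariate gets a cubic B-spline smooth (df effective parameters);
    a covariate that is (near-)constant degenerates to the intercept with a
    warning. Residuals are working residuals log(obs) - log(fitted) with
    observed counts floored at 0.5.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    usable = x.usable & np.isfinite(cov.values)
    n_use = int(usable.sum())
    if n_use < MIN_USABLE_BINS:
        raise ValueError(f"only {n_use} usable bins; need >= {MIN_USABLE_BINS}")
    y = np.round(cov.values[usable])
    cols, names = [], []
    for name, arr in (("gc", x.gc), ("mappability", x.mappability),
                      ("n_restriction_sites", x.n_restriction_sites)):
        v = arr[usable]
        if np.ptp(v) < 1e-12:
            warnings.warn(f"covariate {name} is constant; its smooth reduces "
                          "to the intercept", stacklevel=2)
            continue
        cols.append(v)
        names.append(name)
    exog = np.ones((n_use, 1))
    if cols:
        X = np.column_stack(cols)
        smoother = BSplines(X, df=[df] * len(cols), degree=[degree] * len(cols))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = GLMGam(y, exog=exog, smoother=smoother,
                         family=sm.families.Poisson()).fit()
    else:
        res = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
    mu = np.asarray(res.fittedvalues)
    fitted = np.full(x.bins.n_total, np.nan)
    residuals = np.full(x.bins.n_total, np.nan)
    fitted[usable] = mu
    residuals[usable] = np.log(np.maximum(y, COUNT_FLOOR)) - np.log(mu)
    null_dev = res.null_deviance
    quality = float(1.0 - res.deviance / null_dev) if null_dev > 0 else 0.0
    log.info("bias model: %d usable bins, smooths on %s, deviance explained %.3f",
             n_use, names or ["(intercept only)"], quality)
    return BiasModelFit(x.bins, fitted, residuals, quality, usable)


def residuals_to_log2ratio(fit: BiasModelFit) -> CopyRatioProfile:
    """Residuals (natural log) -> median-centered log2 copy ratios."""
    log2 = fit.residuals / np.log(2.0)
    med = np.nanmedian(log2[fit.usable])
    return CopyRatioProfile(fit.bins, log2 - med, source="hic")


# -- segmentation ----------------------------------------------------------


def _robust_noise_var(values: np.ndarray) -> float:
    """Noise variance of a piecewise-constant-plus-noise series, estimated
    from first differences (MAD-based, falls back to std)."""
    d = np.diff(values)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    sd = 1.4826 * mad / np.sqrt(2.0)
    if sd == 0:
        sd = np.std(d) / np.sqrt(2.0)
    return float(sd * sd)


def _greedy_merge(values: np.ndarray, threshold: float) -> list:
    """Greedy adjacent merging: repeatedly merge the pair of neighboring
    segments with the smallest RSS increase while that increase is below
    ``threshold``. Returns a list of (start, stop) index runs.

    The merge sequence does not depend on the threshold, only the stopping
    point does — hence #segments is non-increasing in lambda.
    """
    n = len(values)
    cnt = [1] * n
    tot = list(map(float, values))
    starts = list(range(n))
    while len(cnt) > 1:
        means = [t / c for t, c in zip(tot, cnt)]
        best, best_d = -1, np.inf
        for i in range(len(cnt) - 1):
            d = (cnt[i] * cnt[i + 1] / (cnt[i] + cnt[i + 1])
                 * (means[i] - means[i + 1]) ** 2)
            if d < best_d:
                best, best_d = i, d
        if best_d >= threshold and best_d > 1e-12:
            break
        cnt[best] += cnt.pop(best + 1)
        tot[best] += tot.pop(best + 1)
        starts.pop(best + 1)
    stops = starts[1:] + [n]
    return list(zip(starts, stops))


def segment_profile(p: CopyRatioProfile,
                    params: SegmentationParams | None = None) -> list:
    """Segment log2 copy ratios per chromosome by BIC-penalized merging.

    The objective is BIC(lambda) = RSS/sigma^2 + lambda * k * ln(n) with k
    the number of breakpoints and sigma estimated robustly from first
    differences; merging stops when no merge decreases it. Unusable (NaN)
    bins are skipped; a segment spans from its first to its last usable bin.
    """
    params = params or SegmentationParams()
    out = []
    for chrom in p.bins.chroms:
        vals = p.log2_ratio[p.bins.chrom_slice(chrom)]
        idx = np.flatnonzero(np.isfinite(vals))
        if idx.size == 0:
            continue
        v = vals[idx]
        threshold = params.lam * np.log(max(len(v), 2)) * _robust_noise_var(v)
        runs = _greedy_merge(v, threshold)
        for a, b in runs:
            if b - a < params.min_bins:
                continue
            first, last = idx[a], idx[b - 1]
            start = first * p.bins.resolution
            _, end = p.bins.bin_bounds(chrom, int(last))
            seg = CNVSegment(chrom, int(start), int(end),
                             float(np.mean(v[a:b])), int(b - a))
            out.append(seg)
    return call_segments(out)


def call_segments(segs: list, gain_thr: float = GAIN_THRESHOLD,
                  loss_thr: float = LOSS_THRESHOLD) -> list:
    """Label segments gain/loss/neutral by strict thresholds on the mean
    log2 ratio (a mean exactly at a threshold stays neutral)."""
    if gain_thr <= loss_thr:
        raise ValueError("gain threshold must exceed loss threshold")
    for s in segs:
        if s.mean_log2_ratio > gain_thr:
            s.call = "gain"
        elif s.mean_log2_ratio < loss_thr:
            s.call = "loss"
        else:
            s.call = "neutral"
    return segs


# -- concordance -----------------------------------------------------------


def segment_concordance(a: list, b: list, size_min: int | None = None) -> tuple:
    """Fraction of A segments supported by same-call segments of B.

    A segment is supported when its total overlap with same-call B segments
    exceeds half its own length. ``size_min`` restricts the reported
    fraction to A segments longer than that many bp. Returns
    ``(fraction, flags)`` with one flag per (retained) A segment.
    """
    flags = []
    kept = [s for s in a if size_min is None or s.length > size_min]
    for s in kept:
        ov = 0
        for t in b:
            if t.chrom != s.chrom or t.call != s.call:
                continue
            ov += max(0, min(s.end, t.end) - max(s.start, t.start))
        flags.append(ov > 0.5 * s.length)
    frac = float(np.mean(flags)) if flags else float("nan")
    return frac, flags


# -- covariate I/O ---------------------------------------------------------


def read_track_bed(path, bins: GenomeBins, value_col: int = 3) -> np.ndarray:
    """Read a 4-column BED-like table (chrom start end value) aligned to
    ``bins`` by start coordinate; missing bins become NaN."""
    values = np.full(bins.n_total, np.nan)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) <= value_col:
                raise ValueError(f"{path}:{ln}: expected >= {value_col + 1} columns")
            chrom, start = parts[0], int(parts[1])
            if chrom not in bins.chroms:
                continue
            i = bins.bin_index(chrom, start)
            values[bins.offset(chrom) + i] = float(parts[value_col])
    return values


def write_segments_bed(segs: list, path) -> None:
    """Write segments as BED: chrom start end mean_log2 call."""
    with open(path, "w") as fh:
        for s in segs:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t"
                     f"{s.mean_log2_ratio:.4f}\t{s.call}\n")
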