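"""Per-read methylation classification and size–methylation analyses.

Bisulfite- or enzymatic-conversion sequencing yields a binary
methylation state for every CpG a read covers.  Reads covering at
least ``min_cpgs`` sites (default 2) with an average state above 80%
are hyper-methylated, below 20% hypo-methylated; everything else is
unclassified (the thresholds are strict inequalities, so boundary
averages stay unclassified).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .core import FragmentSet, MethCalls

__all__ = [
    "MethylationClassRule",
    "SizeMethylationCurve",
    "classify_fragment",
    "classify_set",
    "size_by_methylation_class",
    "size_methylation_curve",
    "select_differential_cpgs",
    "fragments_covering",
    "sample_methylation_density",
]


@dataclasses.dataclass(frozen=True)
class MethylationClassRule:
    min_cpgs: int = 2
    hyper_threshold: float = 0.80
    hypo_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.hypo_threshold >= self.hyper_threshold:
            raise ValueError("hypo threshold must be below hyper threshold")
        if self.min_cpgs < 1:
            raise ValueError("minimum CpG count must be >= 1")


@dataclasses.dataclass
class SizeMethylationCurve:
    """Mean fragment methylation per 1-bp size bin."""

    sizes: np.ndarray
    mean_methylation: np.ndarray
    counts: np.ndarray
    slope: float
    slope_se: float
    pearson_r: float
    p_value: float


def classify_fragment(
    states: Sequence[int], rule: MethylationClassRule | None = None
) -> str:
    """Label one read 'hyper', 'hypo' or 'unclassified'."""
    rule = rule or MethylationClassRule()
    if len(states) < rule.min_cpgs:
        return "unclassified"
    avg = float(np.mean(states))
    if avg > rule.hyper_threshold:
        return "hyper"
    if avg < rule.hypo_threshold:
        return "hypo"
    return "unclassified"


def _meth_of(fs: FragmentSet, calls: MethCalls | None) -> MethCalls:
    meth = calls if calls is not None else fs.meth
    if meth is None:
        raise ValueError("no methylation calls available for this fragment set")
    if len(meth) != len(fs):
        raise ValueError("methylation calls do not align with fragments")
    return meth


def classify_set(
    fs: FragmentSet,
    calls: MethCalls | None = None,
    rule: MethylationClassRule | None = None,
) -> np.ndarray:
    """Vectorised per-fragment class labels ('hyper'/'hypo'/'unclassified')."""
    rule = rule or MethylationClassRule()
    meth = _meth_of(fs, calls)
    counts = meth.counts()
    means = meth.fragment_means()
    labels = np.full(len(fs), "unclassified", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[(counts >= rule.min_cpgs) & (means > rule.hyper_threshold)] = "hyper"
        labels[(counts >= rule.min_cpgs) & (means < rule.hypo_threshold)] = "hypo"
    return labels


@dataclasses.dataclass
class ClassSizeComparison:
    histograms: dict[str, np.ndarray]
    bin_sizes: np.ndarray
    short_fraction: dict[str, float]
    mean_size: dict[str, float]
    p_value: float


def size_by_methylation_class(
    fs: FragmentSet,
    calls: MethCalls | None = None,
    rule: MethylationClassRule | None = None,
    short_max: int = 147,
    size_range: tuple[int, int] = (50, 400),
) -> ClassSizeComparison:
    """Size histograms of hyper- vs hypo-methylated reads.

    The two size distributions are compared with a paired t test
    across matched 1-bp size bins of their cumulative distributions (a
    shift toward shorter sizes raises one CDF above the other in every
    bin; the per-bin frequencies themselves cannot be compared this
    way because normalised histograms have an identically zero mean
    difference).  Identical distributions report P = 1, and missing
    classes signal insufficient data with P = NaN.
    """
    labels = classify_set(fs, calls, rule)
    lo, hi = size_range
    bins = np.arange(lo, hi + 1)
    sizes = fs.sizes
    hists: dict[str, np.ndarray] = {}
    short_frac: dict[str, float] = {}
    mean_size: dict[str, float] = {}
    for cls in ("hyper", "hypo"):
        s = sizes[(labels == cls) & (sizes >= lo) & (sizes <= hi)]
        hists[cls] = np.bincount(s - lo, minlength=len(bins)) if len(s) else np.zeros(
            len(bins), dtype=np.int64
        )
        short_frac[cls] = float(np.mean(s <= short_max)) if len(s) else float("nan")
        mean_size[cls] = float(s.mean()) if len(s) else float("nan")
    if hists["hyper"].sum() == 0 or hists["hypo"].sum() == 0:
        warnings.warn("a methylation class is empty; comparison not possible")
        p = float("nan")
    else:
        a = np.cumsum(hists["hyper"]) / hists["hyper"].sum()
        b = np.cumsum(hists["hypo"]) / hists["hypo"].sum()
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
    return ClassSizeComparison(
        histograms=hists,
        bin_sizes=bins,
        short_fraction=short_frac,
        mean_size=mean_size,
        p_value=p,
    )


def size_methylation_curve(
    fs: FragmentSet,
    calls: MethCalls | None = None,
    size_range: tuple[int, int] = (50, 400),
) -> SizeMethylationCurve:
    """Mean per-fragment methylation by fragment size, with a trend fit.

    Per-fragment mean states are averaged within 1-bp size bins; the
    trend is a count-weighted ordinary least squares of mean
    methylation on size.
    """
    meth = _meth_of(fs, calls)
    frag_means = meth.fragment_means()
    sizes = fs.sizes
    lo, hi = size_range
    ok = ~np.isnan(frag_means) & (sizes >= lo) & (sizes <= hi)
    if ok.sum() == 0:
        raise ValueError("no fragments with CpG calls in the size range")
    s = sizes[ok]
    m = frag_means[ok]
    order = np.argsort(s, kind="stable")
    s, m = s[order], m[order]
    uniq, start = np.unique(s, return_index=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct sizes with data")
    sums = np.add.reduceat(m, start)
    counts = np.diff(np.concatenate([start, [len(s)]]))
    means = sums / counts

    X = sm.add_constant(uniq.astype(np.float64))
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.WLS(means, X, weights=counts).fit()
        slope = float(fit.params[1])
        se = float(fit.bse[1])  # lazy: keep inside errstate for 2-point fits
        p = float(fit.pvalues[1]) if len(uniq) > 2 else float("nan")
    if len(uniq) > 2:
        r = float(stats.pearsonr(uniq, means).statistic)
    else:
        r = float("nan")
    return SizeMethylationCurve(
        sizes=uniq,
        mean_methylation=means,
        counts=counts,
        slope=slope,
        slope_se=se,
        pearson_r=r,
        p_value=p,
    )


def select_differential_cpgs(
    positions: np.ndarray,
    meth_a: np.ndarray,
    meth_b: np.ndarray,
    hi: float = 0.8,
    lo: float = 0.2,
) -> np.ndarray:
    """CpG positions hyper-methylated in tissue A and hypo-methylated in B."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    positions = np.asarray(positions)
    meth_a = np.asarray(meth_a, dtype=np.float64)
    meth_b = np.asarray(meth_b, dtype=np.float64)
    if not (len(positions) == len(meth_a) == len(meth_b)):
        raise ValueError("site arrays must align on coordinates")
    return positions[(meth_a >= hi) & (meth_b <= lo)]


def fragments_covering(
    fs: FragmentSet, sites_by_class: Mapping[str, np.ndarray]
) -> dict[str, FragmentSet]:
    """Partition fragments by which selected CpG sites they cover.

    A fragment is assigned to every class for which it covers at least
    one of the class's sites (a fragment spanning sites of two classes
    appears in both subsets).
    """
    out = {}
    for name, sites in sites_by_class.items():
        sites = np.sort(np.asarray(sites, dtype=np.int64))
        lo = np.searchsorted(sites, fs.starts)
        hi = np.searchsorted(sites, fs.ends)
        out[name] = fs.subset(hi > lo)
    return out


def sample_methylation_density(
    fs: FragmentSet, calls: MethCalls | None = None
) -> float:
    """Methylated CpG observations over all CpG observations, in [0, 1].

    Returns NaN (with a warning) when the sample has no CpG
    observations at all.
    """
    meth = _meth_of(fs, calls)
    if meth.states.size == 0:
        warnings.warn("no CpG observations; methylation density undefined")
        return float("nan")
    return float(meth.states.mean())
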