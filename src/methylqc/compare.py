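"""Concordance statistics between two methylomes.

The headline statistic is the per-CpG average Pearson correlation (APC):
5-mCpG rates are first averaged per CpG across the samples of each dataset,
then the Pearson correlation of the two averaged vectors is computed over the
CpGs defined in both.  Its companion is the mean absolute difference (MAD) of
the paired rates.  Both get 95% confidence intervals: Fisher z for the
correlation, a normal approximation on the absolute differences for MAD.

For distribution-aware agreement, rates are binned into four methylation
states -- unmethylated [0, 0.15), low-methylated [0.15, 0.5), intermethylated
[0.5, 0.85) and methylated [0.85, 1] -- and a 4x4 confusion matrix tallies,
per truth (reference) category, how often the query method lands in the same
bin.  Boundary values are assigned upward.

TSS metaprofiles average site rates in fixed-width bins of signed distance to
transcription start sites, flipping the axis for minus-strand genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "CATEGORY_NAMES",
    "CATEGORY_EDGES",
    "PairedRates",
    "ComparisonReport",
    "ConfusionResult",
    "pair_rates",
    "average_rates_across_samples",
    "apc",
    "mad",
    "categorize",
    "categorize_array",
    "category_confusion",
    "per_sample_compare",
    "compare_methylomes",
    "tss_profile",
    "count_called_cpgs",
    "read_tss_bed",
]

CATEGORY_NAMES = ("unmethylated", "low", "inter", "methylated")
CATEGORY_EDGES = (0.15, 0.5, 0.85)

#: |delta rate| bin edges used to stratify incorrect category calls
DELTA_EDGES = (0.1, 0.25, 0.5)


@dataclass(frozen=True)
class PairedRates:
    """Complete-case matched rate vectors for two methods."""

    keys: np.ndarray
    rates_a: np.ndarray
    rates_b: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.keys) == len(self.rates_a) == len(self.rates_b)):
            raise InvalidInputError("paired vectors must have equal length")
        for v in (self.rates_a, self.rates_b):
            arr = np.asarray(v, dtype=float)
            if len(arr) and (np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any()):
                raise InvalidInputError("paired rates must be complete and in [0,1]")

    @property
    def n(self) -> int:
        return len(self.keys)


@dataclass(frozen=True)
class ConfusionResult:
    """4x4 category agreement between a query (A) and a reference (B)."""

    confusion: np.ndarray  # rows = reference category, cols = query category
    frac_correct: np.ndarray  # per reference category; NaN for empty rows
    delta_hist: dict[str, np.ndarray]  # per ref category, |delta| bins of errors
    n: int


@dataclass(frozen=True)
class ComparisonReport:
    """Bundle of the concordance statistics for one methylome pair."""

    apc_r: float
    apc_ci: tuple[float, float]
    mad: float
    mad_ci: tuple[float, float]
    n_sites: int
    confusion: np.ndarray | None = None
    frac_correct_per_category: np.ndarray | None = None


def pair_rates(a: pd.Series, b: pd.Series) -> PairedRates:
    """Complete-case intersection of two site-indexed rate series."""
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
    return PairedRates(
        keys=joined.index.to_numpy(),
        rates_a=joined["a"].to_numpy(dtype=float),
        rates_b=joined["b"].to_numpy(dtype=float),
    )


def average_rates_across_samples(rates: pd.DataFrame) -> pd.Series:
    """Unweighted per-CpG mean over samples with a defined rate.

    ``rates`` is sites x samples; sites missing in every sample are dropped.
    """
    mean = rates.mean(axis=1, skipna=True)
    return mean.dropna()


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3:
        return (float("nan"), float("nan"))
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zcrit = _st.norm.ppf(0.5 + level / 2)
    return (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))


def apc(paired: PairedRates) -> tuple[float, tuple[float, float]]:
    """Pearson correlation of paired per-CpG rates with a Fisher-z 95% CI."""
    if paired.n < 3:
        raise InsufficientDataError(f"need >= 3 paired sites, got {paired.n}")
    a, b = paired.rates_a, paired.rates_b
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in one of the rate vectors")
    r = float(_st.pearsonr(a, b).statistic)
    return r, _fisher_ci(r, paired.n)


def mad(paired: PairedRates) -> tuple[float, tuple[float, float]]:
    """Mean absolute difference of paired rates with a normal-theory 95% CI."""
    if paired.n < 1:
        raise InsufficientDataError("need >= 1 paired site for MAD")
    d = np.abs(paired.rates_a - paired.rates_b)
    m = float(d.mean())
    if paired.n > 1:
        se = float(d.std(ddof=1)) / math.sqrt(paired.n)
    else:
        se = 0.0
    return m, (m - 1.96 * se, m + 1.96 * se)


def categorize(rate: float) -> str:
    """Methylation-state category of a rate; boundary values go upward."""
    if not (0.0 <= rate <= 1.0):
        raise InvalidInputError(f"rate outside [0,1]: {rate!r}")
    return CATEGORY_NAMES[int(np.searchsorted(CATEGORY_EDGES, rate, side="right"))]


def categorize_array(rates: np.ndarray) -> np.ndarray:
    """Vectorised category indices (0..3) with upward boundary assignment."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) and ((rates < 0).any() or (rates > 1).any() or np.isnan(rates).any()):
        raise InvalidInputError("rates outside [0,1]")
    return np.searchsorted(CATEGORY_EDGES, rates, side="right")


def category_confusion(
    paired: PairedRates,
    min_ref_coverage: int = 0,
    ref_coverage: np.ndarray | None = None,
) -> ConfusionResult:
    """Per-category agreement of method A against reference B.

    Sites with reference coverage below ``min_ref_coverage`` are dropped
    first (pass ``ref_coverage`` aligned with the pairs).  Rows of the
    confusion matrix are reference categories, columns the query's; the
    correct fraction is the diagonal over the row sum.  Off-diagonal calls
    are additionally histogrammed by |rate_a - rate_b| with edges
    ``(0.1, 0.25, 0.5)`` per reference category.
    """
    a, b = paired.rates_a, paired.rates_b
    if min_ref_coverage > 0:
        if ref_coverage is None:
            raise InvalidParameterError(
                "min_ref_coverage given without ref_coverage vector"
            )
        keep = np.asarray(ref_coverage) >= min_ref_coverage
        a, b = a[keep], b[keep]
    if len(a) == 0:
        raise InsufficientDataError("no paired sites after the coverage filter")
    ia = categorize_array(a)
    ib = categorize_array(b)
    k = len(CATEGORY_NAMES)
    confusion = np.bincount(ib * k + ia, minlength=k * k).reshape(k, k)
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(row_sums > 0, np.diag(confusion) / np.maximum(row_sums, 1), np.nan)
    delta = np.abs(a - b)
    wrong = ia != ib
    delta_hist = {}
    edges = np.asarray(DELTA_EDGES)
    for ci, name in enumerate(CATEGORY_NAMES):
        sel = wrong & (ib == ci)
        delta_hist[name] = np.bincount(
            np.searchsorted(edges, delta[sel], side="right"), minlength=len(edges) + 1
        )
    return ConfusionResult(
        confusion=confusion, frac_correct=frac, delta_hist=delta_hist, n=int(len(a))
    )


def per_sample_compare(a: pd.Series, b: pd.Series) -> tuple[float, float, int]:
    """Pearson r and MAD over the shared sites of one sample pair."""
    paired = pair_rates(a, b)
    if paired.n < 3:
        raise InsufficientDataError(
            f"need >= 3 shared sites for a sample comparison, got {paired.n}"
        )
    r, _ = apc(paired)
    m, _ = mad(paired)
    return r, m, paired.n


def compare_methylomes(
    a: pd.Series,
    b: pd.Series,
    min_ref_coverage: int = 0,
    ref_coverage: pd.Series | None = None,
) -> ComparisonReport:
    """Full concordance report (APC, MAD, category confusion) for a pair."""
    paired = pair_rates(a, b)
    r, ci = apc(paired)
    m, mci = mad(paired)
    cov = None
    if ref_coverage is not None:
        cov = ref_coverage.reindex(pd.Index(paired.keys)).to_numpy(dtype=float)
        cov = np.nan_to_num(cov, nan=0.0)
    conf = category_confusion(paired, min_ref_coverage, cov)
    return ComparisonReport(
        apc_r=r,
        apc_ci=ci,
        mad=m,
        mad_ci=mci,
        n_sites=paired.n,
        confusion=conf.confusion,
        frac_correct_per_category=conf.frac_correct,
    )


def tss_profile(
    sites: pd.DataFrame,
    tss: pd.DataFrame,
    bin_size: int = 50,
    flank: int = 3000,
) -> pd.Series:
    """Mean methylation rate in fixed bins of signed distance to TSSs.

    ``sites`` needs columns ``chrom pos rate``; ``tss`` needs ``chrom pos
    strand``.  The offset of a site is ``pos - tss`` for plus-strand genes
    and ``tss - pos`` for minus-strand ones; sites with ``|offset| <= flank``
    fall into bin ``floor(offset / bin_size)``.  A site near several TSSs
    contributes once per TSS.  Returns a series indexed by bin left edge
    (bp); empty bins are NaN.
    """
    if flank % bin_size != 0:
        raise InvalidParameterError("flank must be a multiple of bin_size")
    bad = set(tss["strand"]) - {"+", "-"}
    if bad:
        raise InvalidInputError(f"TSS strand must be '+' or '-', got {sorted(bad)}")

    n_bins = 2 * flank // bin_size + 1  # last bin holds offset == flank only
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom, tss_grp in tss.groupby("chrom"):
        s = sites[sites["chrom"] == chrom]
        if s.empty:
            continue
        order = np.argsort(s["pos"].to_numpy())
        pos = s["pos"].to_numpy()[order]
        rate = s["rate"].to_numpy(dtype=float)[order]
        defined = ~np.isnan(rate)
        pos, rate = pos[defined], rate[defined]
        for t, strand in zip(tss_grp["pos"].to_numpy(), tss_grp["strand"]):
            lo = np.searchsorted(pos, t - flank, side="left")
            hi = np.searchsorted(pos, t + flank, side="right")
            if hi <= lo:
                continue
            offs = pos[lo:hi] - t
            if strand == "-":
                offs = -offs
            binned = np.floor_divide(offs, bin_size) + flank // bin_size
            np.add.at(sums, binned, rate[lo:hi])
            np.add.at(counts, binned, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = (np.arange(n_bins) - flank // bin_size) * bin_size
    return pd.Series(means, index=pd.Index(edges, name="offset"), name="mean_rate")


def count_called_cpgs(sites: pd.DataFrame, expand_units: bool = True) -> int:
    """Number of CpGs with a defined rate in one sample's summary frame.

    With ``expand_units`` each unit contributes one count per CpG position
    (``n_sites``); otherwise units count once.
    """
    if sites.empty:
        return 0
    called = sites["rate"].notna()
    if expand_units and "n_sites" in sites.columns:
        return int(sites.loc[called, "n_sites"].sum())
    return int(called.sum())


def read_tss_bed(path) -> pd.DataFrame:
    """TSS coordinates from BED6: the strand-aware start of each interval."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise InvalidInputError(f"{path}:{lineno}: BED6 with strand required")
            chrom, start, end, strand = f[0], int(f[1]), int(f[2]), f[5]
            if strand not in "+-":
                raise InvalidInputError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append({"chrom": chrom, "pos": start if strand == "+" else end - 1,
                         "strand": strand})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
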