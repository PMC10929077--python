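"""Quality filters for CpG units and dark-region detection.

Five indicators mark a CpG unit as problematic; a unit is high quality (hq)
iff none applies:

``in_dark``
    any CpG of the unit lies in a *dark region*: a stretch of at least 30 bp
    where short-read evidence is unreliable (>= 90% of reads with mapping
    quality < 10, depth < 5x, mean base quality < 20, assessed per base).
``near_variant``
    a sequence variant lies within 5 bp of any CpG C position of the unit
    (a variant on the C or G itself is distance 0 or 1).
``abnormal_coverage``
    unit coverage <= 0.5x or >= 1.5x the dataset mean coverage (bounds
    inclusive); flags collapsed duplications and mapping pile-ups.
``high_strand_bias``
    |rate_fw - rate_rv| >= 0.2; native methylation is strand-symmetric, so
    disagreement indicates a detection artifact.  An undefined strand bias
    (one strand uncovered) does not fail the unit.
``low_frr``
    fraction of reliable (unambiguous) reads <= 0.5.

All cutoffs live in :class:`QCConfig` and are inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregate import SiteSummary
from .call_model import CpGUnit
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "PerBasePileupStats",
    "QCConfig",
    "QCFlags",
    "FILTER_NAMES",
    "detect_dark_regions",
    "flag_near_variant",
    "flag_abnormal_coverage",
    "annotate_qc",
    "annotate_frame",
    "filter_hq",
    "HQPartition",
    "read_bed3",
    "write_bed3",
    "read_variant_positions",
]

FILTER_NAMES = (
    "in_dark",
    "near_variant",
    "abnormal_coverage",
    "high_strand_bias",
    "low_frr",
)


@dataclass(frozen=True, slots=True)
class PerBasePileupStats:
    """Short-read pileup summary for one reference base."""

    chrom: str
    pos: int
    depth: int
    frac_lowmapq: float
    mean_baseq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_lowmapq <= 1.0:
            raise InvalidInputError("frac_lowmapq outside [0,1]")
        if self.depth < 0:
            raise InvalidInputError("depth must be >= 0")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the five problematic-unit indicators (all inclusive)."""

    variant_window: int = 5
    cov_low_mult: float = 0.5
    cov_high_mult: float = 1.5
    strand_bias_max: float = 0.2
    frr_min: float = 0.5
    dark_mapq: int = 10
    dark_frac: float = 0.9
    dark_cov: int = 5
    dark_baseq: float = 20.0
    dark_min_len: int = 30

    def __post_init__(self) -> None:
        if not self.cov_low_mult < self.cov_high_mult:
            raise InvalidParameterError("cov_low_mult must be < cov_high_mult")
        for name in (
            "variant_window",
            "cov_low_mult",
            "cov_high_mult",
            "strand_bias_max",
            "frr_min",
            "dark_mapq",
            "dark_frac",
            "dark_cov",
            "dark_baseq",
            "dark_min_len",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True, slots=True)
class QCFlags:
    """The five indicators plus the derived hq status."""

    in_dark: bool
    near_variant: bool
    abnormal_coverage: bool
    high_strand_bias: bool
    low_frr: bool

    @property
    def hq(self) -> bool:
        return not (
            self.in_dark
            or self.near_variant
            or self.abnormal_coverage
            or self.high_strand_bias
            or self.low_frr
        )

    @property
    def reasons(self) -> tuple[str, ...]:
        return tuple(name for name in FILTER_NAMES if getattr(self, name))


def _is_dark_base(depth: float, frac_lowmapq: float, mean_baseq: float,
                  config: QCConfig) -> bool:
    if depth == 0:
        return True
    return (
        frac_lowmapq >= config.dark_frac
        and depth < config.dark_cov
        and mean_baseq < config.dark_baseq
    )


def detect_dark_regions(
    stats,
    config: QCConfig = QCConfig(),
) -> list[tuple[str, int, int]]:
    """Merge per-base dark calls into BED-style intervals of length >= 30 bp.

    ``stats`` is a frame with columns ``chrom pos depth frac_lowmapq
    mean_baseq`` or an iterable of :class:`PerBasePileupStats`, sorted by
    (chrom, pos).  A base is dark iff all three criteria fail there; a base
    *inside the track's span* with no record is treated as depth 0 and hence
    dark.  Maximal dark runs shorter than ``dark_min_len`` are dropped.
    Returns sorted, non-overlapping ``(chrom, start, end)`` half-open tuples.
    """
    if not isinstance(stats, pd.DataFrame):
        rows = list(stats)
        if not rows:
            return []
        stats = pd.DataFrame(
            {
                "chrom": [r.chrom for r in rows],
                "pos": [r.pos for r in rows],
                "depth": [r.depth for r in rows],
                "frac_lowmapq": [r.frac_lowmapq for r in rows],
                "mean_baseq": [r.mean_baseq for r in rows],
            }
        )
    if stats.empty:
        return []

    out: list[tuple[str, int, int]] = []
    seen_chroms: list = []
    for chrom, grp in stats.groupby("chrom", sort=False):
        seen_chroms.append(chrom)
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise InvalidInputError(
                f"pileup positions not strictly increasing on {chrom}"
            )
        depth = grp["depth"].to_numpy(dtype=float)
        frac = grp["frac_lowmapq"].to_numpy(dtype=float)
        baseq = grp["mean_baseq"].to_numpy(dtype=float)
        dark = (depth == 0) | (
            (frac >= config.dark_frac)
            & (depth < config.dark_cov)
            & (baseq < config.dark_baseq)
        )

        # Collect dark segments: recorded dark bases plus uncovered gaps
        # between consecutive records.
        segs: list[tuple[int, int]] = []
        for s, e in zip(pos[dark], pos[dark] + 1):
            segs.append((int(s), int(e)))
        gap_left = pos[:-1] + 1
        gap_right = pos[1:]
        for s, e in zip(gap_left[gap_right > gap_left], gap_right[gap_right > gap_left]):
            segs.append((int(s), int(e)))
        if not segs:
            continue
        segs.sort()
        merged: list[list[int]] = [list(segs[0])]
        for s, e in segs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= config.dark_min_len:
                out.append((str(chrom), s, e))
    if seen_chroms != sorted(seen_chroms, key=str):
        raise InvalidInputError("pileup chromosomes not sorted")
    return out


def flag_near_variant(
    unit: CpGUnit,
    variant_positions: Sequence[int],
    window: int = 5,
) -> bool:
    """True iff any CpG C of the unit lies within ``window`` bp of a variant."""
    return _any_near(np.asarray(unit.positions, dtype=np.int64),
                     np.asarray(sorted(variant_positions), dtype=np.int64),
                     window)


def _any_near(positions: np.ndarray, variants: np.ndarray, window: int) -> bool:
    if len(variants) == 0 or len(positions) == 0:
        return False
    idx = np.searchsorted(variants, positions)
    left = np.where(idx > 0, positions - variants[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    right = np.where(
        idx < len(variants), variants[np.minimum(idx, len(variants) - 1)] - positions,
        np.iinfo(np.int64).max,
    )
    return bool((np.minimum(left, right) <= window).any())


def flag_abnormal_coverage(
    coverage: float,
    mean_coverage: float,
    config: QCConfig = QCConfig(),
) -> bool:
    """True iff coverage <= low-mult x mean or >= high-mult x mean (inclusive)."""
    if not mean_coverage > 0:
        raise InvalidParameterError("mean_coverage must be > 0")
    return (
        coverage <= config.cov_low_mult * mean_coverage
        or coverage >= config.cov_high_mult * mean_coverage
    )


def _in_any_interval(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) == 0 or len(positions) == 0:
        return False
    idx = np.searchsorted(starts, positions, side="right") - 1
    valid = idx >= 0
    return bool((valid & (positions < ends[np.maximum(idx, 0)])).any())


def annotate_qc(
    summary: SiteSummary,
    dark: Sequence[tuple[str, int, int]],
    variants: Sequence[int],
    mean_coverage: float,
    config: QCConfig = QCConfig(),
) -> QCFlags:
    """Evaluate the five indicators for one summarized unit.

    ``dark`` holds sorted, merged (chrom, start, end) intervals; ``variants``
    holds positions on the unit's chromosome.  Missing strand bias / FRR does
    not fail the unit.
    """
    chrom = summary.unit.chrom
    starts = np.asarray([s for c, s, _ in dark if c == chrom], dtype=np.int64)
    ends = np.asarray([e for c, _, e in dark if c == chrom], dtype=np.int64)
    pos = np.asarray(summary.unit.positions, dtype=np.int64)
    sb = summary.strand_bias
    frr = summary.frr
    return QCFlags(
        in_dark=_in_any_interval(pos, starts, ends),
        near_variant=flag_near_variant(summary.unit, variants, config.variant_window),
        abnormal_coverage=flag_abnormal_coverage(
            summary.coverage, mean_coverage, config
        ),
        high_strand_bias=(sb is not None and sb >= config.strand_bias_max),
        low_frr=(frr is not None and frr <= config.frr_min),
    )


def annotate_frame(
    sites: pd.DataFrame,
    dark: Sequence[tuple[str, int, int]],
    variants: dict[str, np.ndarray] | Sequence[int],
    mean_coverage: float,
    config: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Vectorised :func:`annotate_qc` over a summarized sites frame.

    ``variants`` is either a mapping chrom -> sorted position array or a
    flat sequence applied to every chromosome.  Adds the five boolean flag
    columns and ``hq``.
    """
    if not mean_coverage > 0:
        raise InvalidParameterError("mean_coverage must be > 0")
    out = sites.copy()
    n = len(out)
    in_dark = np.zeros(n, dtype=bool)
    near_var = np.zeros(n, dtype=bool)

    pos_lists = out["positions"] if "positions" in out.columns else [
        (int(s),) for s in out["start"]
    ]
    flat_pos = np.concatenate([np.asarray(p, dtype=np.int64) for p in pos_lists]) if n else np.empty(0, dtype=np.int64)
    counts = np.asarray([len(p) for p in pos_lists], dtype=np.int64)
    row_of = np.repeat(np.arange(n), counts)
    chrom_arr = out["chrom"].to_numpy()
    flat_chrom = np.repeat(chrom_arr, counts)

    for chrom in pd.unique(chrom_arr):
        mask = flat_chrom == chrom
        cpos = flat_pos[mask]
        d_starts = np.asarray([s for c, s, _ in dark if c == chrom], dtype=np.int64)
        d_ends = np.asarray([e for c, _, e in dark if c == chrom], dtype=np.int64)
        if len(d_starts):
            idx = np.searchsorted(d_starts, cpos, side="right") - 1
            hit = (idx >= 0) & (cpos < d_ends[np.maximum(idx, 0)])
            np.maximum.at(in_dark, row_of[mask], hit)
        if isinstance(variants, dict):
            var = np.asarray(variants.get(chrom, ()), dtype=np.int64)
        else:
            var = np.asarray(sorted(variants), dtype=np.int64)
        if len(var):
            idx = np.searchsorted(var, cpos)
            big = np.iinfo(np.int64).max
            left = np.where(idx > 0, cpos - var[np.maximum(idx - 1, 0)], big)
            right = np.where(idx < len(var), var[np.minimum(idx, len(var) - 1)] - cpos, big)
            hit = np.minimum(left, right) <= config.variant_window
            np.maximum.at(near_var, row_of[mask], hit)

    cov = out["coverage"].to_numpy(dtype=float)
    sb = out["strand_bias"].to_numpy(dtype=float)
    frr = out["frr"].to_numpy(dtype=float)
    out["in_dark"] = in_dark
    out["near_variant"] = near_var
    out["abnormal_coverage"] = (cov <= config.cov_low_mult * mean_coverage) | (
        cov >= config.cov_high_mult * mean_coverage
    )
    out["high_strand_bias"] = np.nan_to_num(sb, nan=-1.0) >= config.strand_bias_max
    out["low_frr"] = (~np.isnan(frr)) & (frr <= config.frr_min)
    out["hq"] = ~(
        out["in_dark"]
        | out["near_variant"]
        | out["abnormal_coverage"]
        | out["high_strand_bias"]
        | out["low_frr"]
    )
    return out


@dataclass
class HQPartition:
    """Disjoint, exhaustive split of annotated units into hq and non-hq."""

    n_total: int
    n_hq: int
    n_non_hq: int
    reason_counts: dict[str, int]
    hq_fraction: float

    def __post_init__(self) -> None:
        assert self.n_hq + self.n_non_hq == self.n_total


def filter_hq(annotated) -> HQPartition:
    """Partition annotated units and tally failure reasons.

    Accepts the frame from :func:`annotate_frame` or an iterable of
    :class:`QCFlags`.  A unit failing several filters counts once in the
    non-hq total and once per reason, so reason counts may sum to more than
    the number of non-hq units.
    """
    if isinstance(annotated, pd.DataFrame):
        n_total = len(annotated)
        if n_total == 0:
            return HQPartition(0, 0, 0, {name: 0 for name in FILTER_NAMES}, 0.0)
        n_hq = int(annotated["hq"].sum())
        reason_counts = {name: int(annotated[name].sum()) for name in FILTER_NAMES}
    else:
        flags = list(annotated)
        n_total = len(flags)
        if n_total == 0:
            return HQPartition(0, 0, 0, {name: 0 for name in FILTER_NAMES}, 0.0)
        n_hq = sum(1 for f in flags if f.hq)
        reason_counts = {
            name: sum(1 for f in flags if getattr(f, name)) for name in FILTER_NAMES
        }
    return HQPartition(
        n_total=n_total,
        n_hq=n_hq,
        n_non_hq=n_total - n_hq,
        reason_counts=reason_counts,
        hq_fraction=n_hq / n_total,
    )


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) intervals from a BED3+ file."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(f"{path}:{lineno}: BED needs >= 3 fields")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed3(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_variant_positions(path: str | Path) -> dict[str, np.ndarray]:
    """Variant positions per chromosome from a VCF or a plain position list.

    VCF input (``.vcf``/``.vcf.gz``) uses the POS column converted to
    0-based; SNPs and indel start positions alike.  A plain list holds
    ``chrom<TAB>pos`` (0-based) or bare ``pos`` lines (chromosome '*',
    applied everywhere).
    """
    path = Path(path)
    by_chrom: dict[str, list[int]] = {}
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                by_chrom.setdefault(rec.chrom, []).append(rec.pos - 1)
    else:
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) >= 2:
                    by_chrom.setdefault(fields[0], []).append(int(fields[1]))
                else:
                    by_chrom.setdefault("*", []).append(int(fields[0]))
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}
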