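"""Aggregate per-read methylation calls into per-unit / per-site summaries.

The per-unit 5-mCpG rate is the fraction of reads classified methylated among
all *unambiguous* reads.  Alongside the rate, each unit carries the quality
covariates used by the downstream filters:

FRR (fraction of reliable reads)
    unambiguous reads / all reads at the unit (ambiguous reads count in the
    denominator only).
strand bias
    |rate_forward - rate_reverse|, undefined when either strand has no
    unambiguous read.  Methylation is symmetric across strands in native DNA,
    so a large disagreement flags a detection artifact.
coverage
    total reads overlapping the unit, ambiguous included.

Because a likelihood-ratio caller emits one call per unit, every CpG site in
a unit inherits the unit's rate when summaries are expanded to site level.

Two parallel APIs are provided: an object API over ``PerReadCall`` /
``SiteSummary`` for clarity at small scale, and a vectorised frame API
(``summarize_frame``) used by the pipeline on millions of reads.  The frame
column order is the package's bedMethyl-like dialect::

    chrom start end coverage rate n_meth n_unmeth n_ambig
    rate_fw rate_rv strand_bias frr
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .call_model import (
    FORWARD,
    REVERSE,
    CallerConfig,
    CpGUnit,
    MethylStatus,
    PerReadCall,
    classify_call,
)
from .errors import InvalidInputError, UndefinedResultError

__all__ = [
    "SiteSummary",
    "SampleSummary",
    "summarize_unit",
    "summarize_frame",
    "expand_units_to_sites",
    "expand_frame",
    "sample_overall_level",
    "overall_level_from_frame",
    "dataset_mean_coverage",
    "SITES_COLUMNS",
    "write_sites_tsv",
    "read_sites_tsv",
    "read_ref_methylome",
]

SITES_COLUMNS = (
    "chrom",
    "start",
    "end",
    "coverage",
    "rate",
    "n_meth",
    "n_unmeth",
    "n_ambig",
    "rate_fw",
    "rate_rv",
    "strand_bias",
    "frr",
)


@dataclass(frozen=True)
class SiteSummary:
    """Aggregated methylation evidence for one CpG unit in one sample."""

    unit: CpGUnit
    n_meth: int
    n_unmeth: int
    n_ambig: int
    n_meth_fw: int
    n_unmeth_fw: int
    n_meth_rv: int
    n_unmeth_rv: int
    below_coverage: bool = False

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth + self.n_ambig

    @property
    def rate(self) -> float | None:
        n = self.n_meth + self.n_unmeth
        return self.n_meth / n if n > 0 else None

    @property
    def rate_fw(self) -> float | None:
        n = self.n_meth_fw + self.n_unmeth_fw
        return self.n_meth_fw / n if n > 0 else None

    @property
    def rate_rv(self) -> float | None:
        n = self.n_meth_rv + self.n_unmeth_rv
        return self.n_meth_rv / n if n > 0 else None

    @property
    def strand_bias(self) -> float | None:
        fw, rv = self.rate_fw, self.rate_rv
        if fw is None or rv is None:
            return None
        return abs(fw - rv)

    @property
    def frr(self) -> float | None:
        cov = self.coverage
        if cov == 0:
            return None
        return (self.n_meth + self.n_unmeth) / cov


@dataclass(frozen=True)
class SampleSummary:
    """Whole-sample methylation level and coverage."""

    sample_id: str
    overall_level: float
    mean_coverage: float
    n_sites_called: int


def summarize_unit(
    calls: Sequence[PerReadCall],
    config: CallerConfig,
    positions: tuple[int, ...] | None = None,
) -> SiteSummary:
    """Tally one unit's reads into a :class:`SiteSummary`.

    All calls must share the same unit key.  ``positions`` overrides the
    unit's CpG coordinates; otherwise they are taken from the calls (context
    string) or default to the single start position.
    """
    if not calls:
        raise InvalidInputError("summarize_unit needs at least one call")
    keys = {c.unit_key for c in calls}
    if len(keys) != 1:
        raise InvalidInputError(f"calls span multiple unit keys: {sorted(keys)}")
    chrom, start, _end = keys.pop()
    if positions is None:
        for c in calls:
            if c.positions is not None:
                positions = c.positions
                break
        else:
            positions = (start,)
    counts = {(s, st): 0 for s in MethylStatus for st in (FORWARD, REVERSE)}
    for call in calls:
        counts[(classify_call(call, config), call.strand)] += 1
    n_meth_fw = counts[(MethylStatus.METHYLATED, FORWARD)]
    n_meth_rv = counts[(MethylStatus.METHYLATED, REVERSE)]
    n_unmeth_fw = counts[(MethylStatus.UNMETHYLATED, FORWARD)]
    n_unmeth_rv = counts[(MethylStatus.UNMETHYLATED, REVERSE)]
    n_ambig = (
        counts[(MethylStatus.AMBIGUOUS, FORWARD)]
        + counts[(MethylStatus.AMBIGUOUS, REVERSE)]
    )
    summary = SiteSummary(
        unit=CpGUnit(chrom, tuple(positions)),
        n_meth=n_meth_fw + n_meth_rv,
        n_unmeth=n_unmeth_fw + n_unmeth_rv,
        n_ambig=n_ambig,
        n_meth_fw=n_meth_fw,
        n_unmeth_fw=n_unmeth_fw,
        n_meth_rv=n_meth_rv,
        n_unmeth_rv=n_unmeth_rv,
    )
    if summary.coverage < config.min_site_coverage:
        summary = SiteSummary(
            unit=summary.unit,
            n_meth=summary.n_meth,
            n_unmeth=summary.n_unmeth,
            n_ambig=summary.n_ambig,
            n_meth_fw=summary.n_meth_fw,
            n_unmeth_fw=summary.n_unmeth_fw,
            n_meth_rv=summary.n_meth_rv,
            n_unmeth_rv=summary.n_unmeth_rv,
            below_coverage=True,
        )
    return summary


def _classify_codes(df: pd.DataFrame, config: CallerConfig) -> np.ndarray:
    """Vectorised read classification: 0 = meth, 1 = unmeth, 2 = ambiguous."""
    if "llr" in df.columns and df["llr"].notna().any():
        llr = df["llr"].to_numpy(dtype=float)
        if not np.isfinite(llr).all():
            raise InvalidInputError("non-finite LLR in calls frame")
        t = config.llr_threshold
        return np.select([llr > t, llr < -t], [0, 1], default=2)
    if "prob_meth" not in df.columns:
        raise InvalidInputError("calls frame needs an 'llr' or 'prob_meth' column")
    p = df["prob_meth"].to_numpy(dtype=float)
    if not (np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()):
        raise InvalidInputError("prob_meth outside [0,1] in calls frame")
    return np.select([p >= config.prob_high, p <= config.prob_low], [0, 1], default=2)


def summarize_frame(
    calls: pd.DataFrame,
    config: CallerConfig,
    positions_by_unit: dict[tuple[str, int], tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Aggregate a frame of per-read calls into one row per CpG unit.

    ``calls`` needs columns ``chrom, strand, start, end`` plus ``llr`` or
    ``prob_meth``; an optional ``positions`` column (tuple per row) or the
    ``positions_by_unit`` mapping keyed by ``(chrom, start)`` supplies CpG
    coordinates for multi-site units.  Returns a frame in
    :data:`SITES_COLUMNS` order plus ``positions`` and ``n_sites`` and a
    ``below_coverage`` flag, sorted by (chrom, start).
    """
    required = {"chrom", "strand", "start", "end"}
    missing = required - set(calls.columns)
    if missing:
        raise InvalidInputError(f"calls frame missing columns: {sorted(missing)}")
    if calls.empty:
        out = pd.DataFrame(columns=list(SITES_COLUMNS) + ["positions", "n_sites", "below_coverage"])
        return out

    codes = _classify_codes(calls, config)
    is_rev = (calls["strand"].to_numpy() == REVERSE).astype(np.int64)
    key_frame = calls[["chrom", "start", "end"]]
    unit_idx, uniques = pd.factorize(
        pd.MultiIndex.from_frame(key_frame), sort=True
    )
    n_units = len(uniques)
    # 6 cells per unit: status (3) x strand (2)
    cell = unit_idx * 6 + codes * 2 + is_rev
    tallies = np.bincount(cell, minlength=n_units * 6).reshape(n_units, 3, 2)

    n_meth_fw = tallies[:, 0, 0]
    n_meth_rv = tallies[:, 0, 1]
    n_unmeth_fw = tallies[:, 1, 0]
    n_unmeth_rv = tallies[:, 1, 1]
    n_ambig = tallies[:, 2, :].sum(axis=1)
    n_meth = n_meth_fw + n_meth_rv
    n_unmeth = n_unmeth_fw + n_unmeth_rv
    coverage = n_meth + n_unmeth + n_ambig

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_meth + n_unmeth > 0, n_meth / np.maximum(n_meth + n_unmeth, 1), np.nan)
        rate_fw = np.where(
            n_meth_fw + n_unmeth_fw > 0,
            n_meth_fw / np.maximum(n_meth_fw + n_unmeth_fw, 1),
            np.nan,
        )
        rate_rv = np.where(
            n_meth_rv + n_unmeth_rv > 0,
            n_meth_rv / np.maximum(n_meth_rv + n_unmeth_rv, 1),
            np.nan,
        )
        frr = np.where(coverage > 0, (n_meth + n_unmeth) / np.maximum(coverage, 1), np.nan)
    strand_bias = np.abs(rate_fw - rate_rv)  # NaN propagates when a strand is missing

    chroms = np.asarray([k[0] for k in uniques], dtype=object)
    starts = np.asarray([k[1] for k in uniques], dtype=np.int64)
    ends = np.asarray([k[2] for k in uniques], dtype=np.int64)

    positions_col: list[tuple[int, ...]] = []
    row_positions: dict[tuple[str, int], tuple[int, ...]] = {}
    if "positions" in calls.columns:
        sub = calls.loc[calls["positions"].notna(), ["chrom", "start", "positions"]]
        row_positions = {
            (c, s): tuple(p)
            for c, s, p in zip(sub["chrom"], sub["start"], sub["positions"])
        }
    for c, s in zip(chroms, starts):
        key = (c, int(s))
        if positions_by_unit is not None and key in positions_by_unit:
            positions_col.append(tuple(positions_by_unit[key]))
        elif key in row_positions:
            positions_col.append(row_positions[key])
        else:
            positions_col.append((int(s),))

    out = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "coverage": coverage,
            "rate": rate,
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
            "n_ambig": n_ambig,
            "rate_fw": rate_fw,
            "rate_rv": rate_rv,
            "strand_bias": strand_bias,
            "frr": frr,
        }
    )
    out["positions"] = positions_col
    out["n_sites"] = [len(p) for p in positions_col]
    out["below_coverage"] = coverage < config.min_site_coverage
    return out


def expand_units_to_sites(summary: SiteSummary) -> list[dict]:
    """One record per CpG site, all inheriting the unit's rate and covariates."""
    unit = summary.unit
    return [
        {
            "chrom": unit.chrom,
            "pos": p,
            "rate": summary.rate,
            "coverage": summary.coverage,
            "strand_bias": summary.strand_bias,
            "frr": summary.frr,
            "unit_start": unit.start,
        }
        for p in unit.positions
    ]


def expand_frame(sites: pd.DataFrame) -> pd.DataFrame:
    """Frame version of :func:`expand_units_to_sites`.

    Requires the ``positions`` column produced by :func:`summarize_frame`;
    every other column is copied unchanged onto each expanded site row.
    """
    if "positions" not in sites.columns:
        raise InvalidInputError("expand_frame needs a 'positions' column")
    counts = np.asarray([len(p) for p in sites["positions"]])
    rep = sites.loc[sites.index.repeat(counts)].reset_index(drop=True)
    rep["pos"] = np.concatenate([np.asarray(p) for p in sites["positions"]]) if len(sites) else []
    return rep.drop(columns=["positions"])


def sample_overall_level(
    summaries: Iterable[SiteSummary],
    sample_id: str = "sample",
) -> SampleSummary:
    """Whole-sample methylation level: methylated calls / unambiguous calls.

    Ambiguous reads count in neither numerator nor denominator.  Raises
    :class:`UndefinedResultError` when no unambiguous call exists.
    """
    tot_meth = tot_assigned = tot_cov = 0
    n_called = 0
    n = 0
    for s in summaries:
        n += 1
        tot_meth += s.n_meth
        tot_assigned += s.n_meth + s.n_unmeth
        tot_cov += s.coverage
        if s.rate is not None:
            n_called += 1
    if tot_assigned == 0:
        raise UndefinedResultError("no unambiguous calls in sample")
    return SampleSummary(
        sample_id=sample_id,
        overall_level=tot_meth / tot_assigned,
        mean_coverage=tot_cov / n if n else 0.0,
        n_sites_called=n_called,
    )


def overall_level_from_frame(sites: pd.DataFrame) -> float:
    """Frame version of the overall methylation level."""
    assigned = int((sites["n_meth"] + sites["n_unmeth"]).sum())
    if assigned == 0:
        raise UndefinedResultError("no unambiguous calls in sample")
    return float(sites["n_meth"].sum()) / assigned


def dataset_mean_coverage(summaries) -> float:
    """Arithmetic mean unit coverage, the anchor of the abnormal-coverage filter."""
    if isinstance(summaries, pd.DataFrame):
        if summaries.empty:
            raise InvalidInputError("mean coverage of an empty dataset is undefined")
        return float(summaries["coverage"].mean())
    covs = [s.coverage for s in summaries]
    if not covs:
        raise InvalidInputError("mean coverage of an empty dataset is undefined")
    return float(np.mean(covs))


# --------------------------------------------------------------------------
# bedMethyl-like TSV I/O
# --------------------------------------------------------------------------


def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    """Write the fixed 12-column site summary dialect (missing values = NA)."""
    cols = [c for c in SITES_COLUMNS]
    sites.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """Read a site summary TSV written by :func:`write_sites_tsv`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(SITES_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"sites TSV missing columns: {sorted(missing)}")
    if "positions" not in df.columns:
        df["positions"] = [(int(s),) for s in df["start"]]
        df["n_sites"] = 1
    return df


def read_ref_methylome(path: str | Path) -> pd.DataFrame:
    """Read a reference (bisulfite-style) per-site count table.

    Expects columns ``chrom start end coverage n_meth``; adds ``rate``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "end", "coverage", "n_meth"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"reference methylome missing columns: {sorted(missing)}")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rate"] = np.where(
            df["coverage"] > 0, df["n_meth"] / df["coverage"].clip(lower=1), np.nan
        )
    return df
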