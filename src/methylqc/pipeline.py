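"""Glue between the modules: calls -> site summaries -> QC -> comparison."""

from __future__ import annotations

import pandas as pd

from . import aggregate, qc, simulate
from .call_model import CallerConfig

__all__ = ["methylome_from_reads", "annotate_simulated", "site_rate_series"]


def methylome_from_reads(
    reads: pd.DataFrame,
    config: CallerConfig = CallerConfig(),
    truth: "simulate.SimTruth | None" = None,
) -> pd.DataFrame:
    """Summarize a per-read calls frame into a per-unit sites frame.

    When simulation truth is supplied its unit positions are attached so
    that unit -> site expansion and position-based QC are exact.
    """
    positions = simulate.reads_to_frame_columns(truth) if truth is not None else None
    return aggregate.summarize_frame(reads, config, positions_by_unit=positions)


def annotate_simulated(
    sites: pd.DataFrame,
    truth: "simulate.SimTruth",
    config: qc.QCConfig = qc.QCConfig(),
) -> pd.DataFrame:
    """Run the full QC annotation against a simulation's truth tracks.

    Dark regions are re-detected from the emitted pileup track (not read
    from the truth directly), exercising the same path real data takes.
    """
    pileup = simulate.emit_pileup_track(truth)
    dark = qc.detect_dark_regions(pileup, config)
    variants = {truth.chrom: truth.variant_positions}
    mean_cov = aggregate.dataset_mean_coverage(sites)
    return qc.annotate_frame(sites, dark, variants, mean_cov, config)


def site_rate_series(sites: pd.DataFrame) -> pd.Series:
    """Per-CpG-site rate series indexed by position (units expanded)."""
    expanded = aggregate.expand_frame(sites)
    return pd.Series(
        expanded["rate"].to_numpy(), index=expanded["pos"].to_numpy(), name="rate"
    )
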