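"""Synthetic methylomes, per-read calls and matched bisulfite counts.

The generator emulates the statistical shape of a whole-blood human
methylome as seen by a long-read likelihood-ratio caller, so that the
aggregation, QC and concordance machinery can be exercised end to end with
known ground truth:

* CpG C positions are laid down along one synthetic chromosome with a gap
  mixture that yields both singleton units and multi-CpG units under the
  10-bp chaining rule.
* Each unit draws a true methylation rate from a three-component beta
  mixture (unmethylated / intermediate / methylated modes), producing the
  bimodal rate distribution characteristic of real methylomes; every CpG in
  a unit shares its unit's rate, matching how joint callers report them.
* Reads arrive per unit with Poisson depth, a fair coin for strand, a
  Bernoulli(true rate) methylation state and a Gaussian LLR emission
  (N(+mu, sigma) for methylated templates, N(-mu, sigma) otherwise).  The
  emission model is a deliberate stand-in: real callers give no closed-form
  emission, and the Gaussian makes error rates of the +/-1.921 rule tunable
  and analytically checkable.
* Disjoint unit subsets receive one of four artifacts: a one-strand rate
  offset (strand bias), a depth multiplier (abnormal coverage), a dark
  region painted over the unit with read-level corruption, or a nearby
  variant with the same corruption.  Corruption re-draws a read's template
  with the site's rate replaced by ``(1-c) * rate + c * (1 - rate)``,
  emulating calls made against the wrong reference sequence.

Everything is driven by :class:`numpy.random.Generator` (PCG64) seeded
explicitly, so all drawn counts are reproducible bit for bit across runs.
What the generator does *not* model: sequence-dependent error, mapping,
haplotype structure or correlated noise between neighboring units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .call_model import CpGUnit, group_cpg_units
from .errors import InvalidParameterError

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_methylome",
    "simulate_reads",
    "simulate_oxbs",
    "emit_pileup_track",
    "reads_to_frame_columns",
]

ARTIFACT_CLASSES = ("strand_bias", "coverage", "dark", "variant")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the sequencing regime the package targets: ~20x
    long-read coverage, a blood-like bimodal methylome (about 70%
    methylated-mode CpGs), an LLR emission centred at +/-3 with unit
    standard deviation (about 14% ambiguous reads at the 1.921 cutoff), and
    15% of units carrying an artifact, split evenly over the four classes.
    """

    n_sites: int = 20_000
    n_samples: int = 1
    seed: int = 0
    coverage_mean: float = 20.0
    mixture_weights: tuple[float, float, float] = (0.2, 0.1, 0.7)
    beta_params: tuple[tuple[float, float], ...] = ((1.0, 20.0), (5.0, 5.0), (20.0, 1.0))
    llr_mu: float = 3.0
    llr_sigma: float = 1.0
    artifact_fracs: dict = field(
        default_factory=lambda: {
            "strand_bias": 0.0375,
            "coverage": 0.0375,
            "dark": 0.0375,
            "variant": 0.0375,
        }
    )
    unit_gap: int = 10
    strand_bias_offset: float = 0.5
    coverage_factor: float = 3.0
    corruption: float = 0.5
    variant_window: int = 5
    overdispersion: float | None = None  # negative-binomial shape; None = Poisson
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise InvalidParameterError("n_sites must be >= 0")
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != 3 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise InvalidParameterError("mixture_weights must be 3 non-negatives summing to 1")
        if self.llr_sigma < 0:
            raise InvalidParameterError("llr_sigma must be >= 0")
        fr = dict(self.artifact_fracs)
        if set(fr) - set(ARTIFACT_CLASSES):
            raise InvalidParameterError(f"unknown artifact class in {sorted(fr)}")
        vals = np.asarray([fr.get(k, 0.0) for k in ARTIFACT_CLASSES])
        if (vals < 0).any() or vals.sum() > 1:
            raise InvalidParameterError("artifact fractions must be in [0,1] and sum <= 1")
        if not 0.0 <= self.corruption <= 1.0:
            raise InvalidParameterError("corruption must be in [0,1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated methylome."""

    chrom: str
    positions: np.ndarray  # per-site forward-strand C position, increasing
    unit_index: np.ndarray  # per-site index into units
    units: tuple[CpGUnit, ...]
    unit_rates: np.ndarray  # per-unit true 5-mCpG rate
    unit_labels: np.ndarray  # per-unit artifact class or 'none'
    variant_positions: np.ndarray
    dark_intervals: tuple[tuple[str, int, int], ...]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def site_rates(self) -> np.ndarray:
        """Per-site true rate (each site inherits its unit's rate)."""
        return self.unit_rates[self.unit_index]

    @property
    def site_labels(self) -> np.ndarray:
        return self.unit_labels[self.unit_index]

    def to_frame(self) -> pd.DataFrame:
        """Per-site truth table (position, unit start, rate, artifact label)."""
        starts = np.asarray([u.start for u in self.units])
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "unit_start": starts[self.unit_index],
                "rate": self.site_rates,
                "artifact": self.site_labels,
            }
        )


def _draw_positions(rng: np.random.Generator, n_sites: int, unit_gap: int) -> np.ndarray:
    """CpG C positions: ~30% of gaps within the chaining distance."""
    if n_sites == 0:
        return np.empty(0, dtype=np.int64)
    within = rng.random(n_sites - 1) < 0.3
    gaps = np.where(
        within,
        rng.integers(2, unit_gap + 1, size=n_sites - 1),
        rng.integers(unit_gap + 1, 301, size=n_sites - 1),
    )
    return np.concatenate([[100], 100 + np.cumsum(gaps)]).astype(np.int64)


def simulate_methylome(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Draw a ground-truth methylome: positions, units, rates, artifacts.

    Deterministic for a fixed seed (``config.seed`` unless overridden).
    Artifact classes are assigned to disjoint unit sets; units that happen to
    fall inside an injected dark interval or variant window afterwards are
    relabelled to that class so truth labels stay consistent with the
    injected coordinates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    positions = _draw_positions(rng, config.n_sites, config.unit_gap)
    if config.n_sites == 0:
        return SimTruth(
            chrom=config.chrom,
            positions=positions,
            unit_index=np.empty(0, dtype=np.int64),
            units=(),
            unit_rates=np.empty(0),
            unit_labels=np.empty(0, dtype=object),
            variant_positions=np.empty(0, dtype=np.int64),
            dark_intervals=(),
        )
    units = tuple(group_cpg_units(positions.tolist(), config.unit_gap, config.chrom))
    unit_index = np.repeat(np.arange(len(units)), [u.n_sites for u in units])

    n_units = len(units)
    comp = rng.choice(3, size=n_units, p=np.asarray(config.mixture_weights))
    rates = np.empty(n_units)
    for k, (a, b) in enumerate(config.beta_params):
        mask = comp == k
        rates[mask] = rng.beta(a, b, size=int(mask.sum()))

    labels = np.full(n_units, "none", dtype=object)
    order = rng.permutation(n_units)
    taken = 0
    for cls in ARTIFACT_CLASSES:
        k = int(round(config.artifact_fracs.get(cls, 0.0) * n_units))
        labels[order[taken : taken + k]] = cls
        taken += k

    # variants: one per variant-unit, within the QC window of a random CpG
    variant_positions = []
    for ui in np.flatnonzero(labels == "variant"):
        p = int(rng.choice(np.asarray(units[ui].positions)))
        off = int(rng.integers(0, config.variant_window + 1))
        variant_positions.append(p + off if rng.random() < 0.5 else p - off)
    variant_positions = np.asarray(sorted(variant_positions), dtype=np.int64)

    # dark intervals: paint over the whole unit, min 35 bp
    dark = []
    for ui in np.flatnonzero(labels == "dark"):
        u = units[ui]
        s = u.start - 10
        e = max(u.positions[-1] + 25, s + 35)
        dark.append((s, e))
    dark.sort()
    merged: list[list[int]] = []
    for s, e in dark:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    dark_intervals = tuple((config.chrom, s, e) for s, e in merged)

    # keep labels consistent with the injected coordinates: an unlabelled
    # unit caught inside a dark interval / variant window adopts that class
    if len(merged):
        starts = np.asarray([s for s, _ in merged])
        ends = np.asarray([e for _, e in merged])
        for ui, u in enumerate(units):
            if labels[ui] != "none":
                continue
            p = np.asarray(u.positions)
            idx = np.searchsorted(starts, p, side="right") - 1
            if ((idx >= 0) & (p < ends[np.maximum(idx, 0)])).any():
                labels[ui] = "dark"
    if len(variant_positions):
        for ui, u in enumerate(units):
            if labels[ui] != "none":
                continue
            p = np.asarray(u.positions)
            idx = np.searchsorted(variant_positions, p)
            big = np.iinfo(np.int64).max
            left = np.where(idx > 0, p - variant_positions[np.maximum(idx - 1, 0)], big)
            right = np.where(
                idx < len(variant_positions),
                variant_positions[np.minimum(idx, len(variant_positions) - 1)] - p,
                big,
            )
            if (np.minimum(left, right) <= config.variant_window).any():
                labels[ui] = "variant"

    return SimTruth(
        chrom=config.chrom,
        positions=positions,
        unit_index=unit_index,
        units=units,
        unit_rates=rates,
        unit_labels=labels,
        variant_positions=variant_positions,
        dark_intervals=dark_intervals,
    )


def _depths(rng: np.random.Generator, mean: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.overdispersion is None:
        return rng.poisson(mean)
    r = config.overdispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_reads(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    sample: int = 0,
) -> pd.DataFrame:
    """Per-read LLR calls for one sample over a simulated methylome.

    Returns a calls frame (columns ``chrom strand start end read_id llr
    n_motifs`` plus hidden ``unit_index``) compatible with
    :func:`methylqc.aggregate.summarize_frame`.  Artifact effects:

    * strand-bias units shift the reverse-strand methylation probability by
      ``strand_bias_offset`` (toward the opposite mode);
    * coverage units multiply expected depth by ``coverage_factor``;
    * dark and variant units corrupt each read's template with probability
      ``corruption`` (rate -> 1 - rate), pulling the apparent rate toward 0.5.
    """
    rng = np.random.default_rng(config.seed + 1000 + sample if seed is None else seed)
    n_units = truth.n_units
    if n_units == 0:
        return pd.DataFrame(
            columns=["chrom", "strand", "start", "end", "read_id", "llr", "n_motifs", "unit_index"]
        )
    labels = truth.unit_labels
    depth_mean = np.full(n_units, config.coverage_mean)
    depth_mean[labels == "coverage"] *= config.coverage_factor
    depths = _depths(rng, depth_mean, config)
    total = int(depths.sum())

    unit_of_read = np.repeat(np.arange(n_units), depths)
    rate = truth.unit_rates[unit_of_read]
    is_rev = rng.random(total) < 0.5

    p = rate.copy()
    sb = labels[unit_of_read] == "strand_bias"
    shift_up = rate < 0.5
    p = np.where(sb & is_rev, np.where(shift_up, rate + config.strand_bias_offset,
                                       rate - config.strand_bias_offset), p)
    corrupted_unit = (labels[unit_of_read] == "dark") | (labels[unit_of_read] == "variant")
    corrupt_read = corrupted_unit & (rng.random(total) < config.corruption)
    p = np.where(corrupt_read, 1.0 - p, p)
    p = np.clip(p, 0.0, 1.0)

    meth = rng.random(total) < p
    llr = rng.normal(np.where(meth, config.llr_mu, -config.llr_mu), config.llr_sigma)

    starts = np.asarray([u.start for u in truth.units])[unit_of_read]
    ends = np.asarray([u.end for u in truth.units])[unit_of_read]
    n_motifs = np.asarray([u.n_sites for u in truth.units])[unit_of_read]
    return pd.DataFrame(
        {
            "chrom": truth.chrom,
            "strand": np.where(is_rev, "-", "+"),
            "start": starts,
            "end": ends,
            "read_id": [f"s{sample}_r{i}" for i in range(total)],
            "llr": llr,
            "n_motifs": n_motifs,
            "unit_index": unit_of_read,
        }
    )


def reads_to_frame_columns(truth: SimTruth) -> dict[tuple[str, int], tuple[int, ...]]:
    """Unit-position lookup keyed by (chrom, unit start) for summarize_frame."""
    return {(truth.chrom, u.start): u.positions for u in truth.units}


def simulate_oxbs(
    truth: SimTruth,
    coverage_mean: float = 25.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Matched bisulfite-style per-site counts: Binomial(Poisson depth, rate).

    Returns the reference methylome dialect (``chrom start end coverage
    n_meth`` + ``rate``).
    """
    rng = np.random.default_rng(seed)
    n = truth.n_sites
    cov = rng.poisson(coverage_mean, size=n)
    n_meth = rng.binomial(cov, truth.site_rates)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov > 0, n_meth / np.maximum(cov, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": truth.chrom,
            "start": truth.positions,
            "end": truth.positions + 1,
            "coverage": cov,
            "n_meth": n_meth,
            "rate": rate,
        }
    )


def emit_pileup_track(
    truth: SimTruth,
    depth_ok: int = 30,
    depth_dark: int = 2,
) -> pd.DataFrame:
    """Per-base short-read pileup stats over the simulated chromosome.

    Bases inside the truth's dark intervals fail all three dark criteria
    (low depth, >= 90% low-MAPQ reads, low base quality); all other bases
    pass all three.  The track is contiguous from 0 to just past the last
    CpG, sorted by position.
    """
    end = int(truth.positions[-1]) + 50 if truth.n_sites else 100
    for _, s, e in truth.dark_intervals:
        end = max(end, e + 10)
    pos = np.arange(end, dtype=np.int64)
    depth = np.full(end, depth_ok, dtype=np.int64)
    frac = np.full(end, 0.02)
    baseq = np.full(end, 35.0)
    for _, s, e in truth.dark_intervals:
        depth[s:e] = depth_dark
        frac[s:e] = 0.95
        baseq[s:e] = 10.0
    return pd.DataFrame(
        {"chrom": truth.chrom, "pos": pos, "depth": depth,
         "frac_lowmapq": frac, "mean_baseq": baseq}
    )
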