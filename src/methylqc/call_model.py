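"""Per-read methylation calls: data model, readers, classification, CpG units.

Long-read methylation callers emit one piece of evidence per read per CpG
locus.  Likelihood-ratio callers (Nanopolish-style) report a natural-log
likelihood ratio (LLR) of the locus being methylated versus unmethylated, for
a *CpG unit*: a group of CpG sites lying within ``unit_gap`` (default 10) bp
of each other that receive one joint call per read.  Probability callers
(basecaller-integrated, modified-base BAM tags) report a per-site methylation
probability in [0, 1].

Classification of a single read follows a likelihood-ratio test: under the
null, -2 log(Lambda) is asymptotically chi-squared distributed (Wilks), so an
LLR cutoff of half the chi-squared critical value gives a per-read test at
the chosen significance level.  At alpha = 0.05 with one degree of freedom the
critical value is 3.842 and the LLR threshold 1.921; reads with
``-t <= LLR <= t`` are *ambiguous* and excluded from rate estimates.

Coordinates are 0-based half-open throughout.  CpG sites are keyed by the
position of the forward-strand C; reverse-strand evidence maps to the same
key but keeps its strand label so that strand bias can be computed downstream.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from scipy import stats as _st

from .errors import (
    FormatError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "FORWARD",
    "REVERSE",
    "MethylStatus",
    "PerReadCall",
    "CpGUnit",
    "CallerConfig",
    "llr_threshold_from_alpha",
    "classify_llr",
    "classify_probability",
    "classify_call",
    "group_cpg_units",
    "read_nanopolish_tsv",
    "write_nanopolish_tsv",
    "read_modbam",
    "cpg_positions_from_sequence",
    "NANOPOLISH_COLUMNS",
]

FORWARD = "+"
REVERSE = "-"
_STRANDS = (FORWARD, REVERSE)


class MethylStatus(Enum):
    """Three-state read-level methylation call."""

    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True, slots=True)
class PerReadCall:
    """One read's methylation evidence for one CpG unit.

    Exactly one of ``llr`` (log-likelihood-ratio callers) and ``prob_meth``
    (probability callers) must be present.  ``positions`` optionally records
    the forward-strand C position of each CpG in the unit when the source
    format carries enough context to recover them.
    """

    chrom: str
    strand: str
    unit_start: int
    unit_end: int
    read_id: str
    llr: float | None = None
    prob_meth: float | None = None
    n_motifs: int = 1
    positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.unit_start < self.unit_end:
            raise InvalidInputError(
                f"unit_start must be < unit_end ({self.unit_start} >= {self.unit_end})"
            )
        if (self.llr is None) == (self.prob_meth is None):
            raise InvalidInputError("exactly one of llr / prob_meth must be set")
        if self.prob_meth is not None and not 0.0 <= self.prob_meth <= 1.0:
            raise InvalidInputError(f"prob_meth outside [0,1]: {self.prob_meth}")
        if self.n_motifs < 1:
            raise InvalidInputError(f"n_motifs must be >= 1, got {self.n_motifs}")

    @property
    def unit_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.unit_start, self.unit_end)


@dataclass(frozen=True, slots=True)
class CpGUnit:
    """A group of CpG sites called jointly, keyed by forward-strand C positions."""

    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise InvalidInputError("a CpG unit needs at least one position")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise InvalidInputError("unit positions must be strictly increasing")

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        """Half-open end: one past the last C position."""
        return self.positions[-1] + 1

    @property
    def unit_id(self) -> tuple[str, int]:
        return (self.chrom, self.positions[0])

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds controlling read classification and unit aggregation.

    llr_threshold
        Symmetric LLR cutoff (natural log).  Default 1.921 = half the 0.05
        chi-squared critical value with 1 df.
    prob_low, prob_high
        Probability cutoffs for modified-base-tag callers; calls in
        (low, high) are ambiguous.
    unit_gap
        Maximum distance in bp between consecutive CpG C positions sharing a
        unit (transitive chaining).
    min_site_coverage
        Units with fewer total reads are marked below-coverage; 1 keeps
        everything, 4 matches typical SMRT per-site filtering.
    """

    llr_threshold: float = 1.921
    prob_low: float = 0.2
    prob_high: float = 0.8
    unit_gap: int = 10
    min_site_coverage: int = 1

    def __post_init__(self) -> None:
        if not self.llr_threshold > 0:
            raise InvalidParameterError("llr_threshold must be > 0")
        if not 0.0 <= self.prob_low <= self.prob_high <= 1.0:
            raise InvalidParameterError("need 0 <= prob_low <= prob_high <= 1")
        if self.unit_gap < 0:
            raise InvalidParameterError("unit_gap must be >= 0")
        if self.min_site_coverage < 0:
            raise InvalidParameterError("min_site_coverage must be >= 0")


SMRT_PROFILE = CallerConfig(min_site_coverage=4)


def llr_threshold_from_alpha(alpha: float, df: int = 1) -> float:
    """LLR classification threshold from a significance level via Wilks' theorem.

    Under the null, -2 log(Lambda) ~ chi-squared(df) asymptotically, so a test
    at level ``alpha`` rejects when the log-likelihood ratio exceeds half the
    (1 - alpha) chi-squared quantile.  ``llr_threshold_from_alpha(0.05, 1)``
    gives 1.921 (critical value 3.842).
    """
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise InvalidParameterError(f"df must be an integer >= 1, got {df!r}")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha!r}")
    return 0.5 * float(_st.chi2.ppf(1.0 - alpha, df))


def classify_llr(llr: float, threshold: float) -> MethylStatus:
    """Classify a read-level LLR at a symmetric threshold.

    ``llr > threshold`` is methylated, ``llr < -threshold`` unmethylated and
    the closed interval ``[-threshold, threshold]`` ambiguous, so a call
    exactly at the boundary is excluded from rate estimates.
    """
    if not threshold > 0:
        raise InvalidParameterError("threshold must be > 0")
    if not math.isfinite(llr):
        raise InvalidInputError(f"non-finite LLR: {llr!r}")
    if llr > threshold:
        return MethylStatus.METHYLATED
    if llr < -threshold:
        return MethylStatus.UNMETHYLATED
    return MethylStatus.AMBIGUOUS


def classify_probability(p: float, low: float, high: float) -> MethylStatus:
    """Classify a per-read methylation probability at two cutoffs.

    ``p >= high`` is methylated, ``p <= low`` unmethylated, anything strictly
    between is ambiguous.
    """
    if not 0.0 <= low <= high <= 1.0:
        raise InvalidParameterError("need 0 <= low <= high <= 1")
    if not (math.isfinite(p) and 0.0 <= p <= 1.0):
        raise InvalidInputError(f"probability outside [0,1]: {p!r}")
    if p >= high:
        return MethylStatus.METHYLATED
    if p <= low:
        return MethylStatus.UNMETHYLATED
    return MethylStatus.AMBIGUOUS


def classify_call(call: PerReadCall, config: CallerConfig) -> MethylStatus:
    """Classify a :class:`PerReadCall` using whichever evidence it carries."""
    if call.llr is not None:
        return classify_llr(call.llr, config.llr_threshold)
    return classify_probability(call.prob_meth, config.prob_low, config.prob_high)


def group_cpg_units(
    positions: Sequence[int],
    unit_gap: int = 10,
    chrom: str = "",
) -> list[CpGUnit]:
    """Chain CpG C positions into units by transitive proximity.

    Consecutive positions at most ``unit_gap`` bp apart share a unit; the
    chaining is transitive, so a unit may span more than ``unit_gap`` bp end
    to end.  The concatenated unit positions reproduce the input exactly.
    """
    pos = list(positions)
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise InvalidInputError("positions must be strictly increasing")
    if not pos:
        return []
    units: list[CpGUnit] = []
    current = [pos[0]]
    for p in pos[1:]:
        if p - current[-1] <= unit_gap:
            current.append(p)
        else:
            units.append(CpGUnit(chrom, tuple(current)))
            current = [p]
    units.append(CpGUnit(chrom, tuple(current)))
    return units


# --------------------------------------------------------------------------
# Nanopolish-dialect TSV
# --------------------------------------------------------------------------

NANOPOLISH_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
)

#: bases of context flanking the first/last CpG in the ``sequence`` column
_SEQ_FLANK = 5


def cpg_positions_from_sequence(start: int, sequence: str) -> tuple[int, ...] | None:
    """Recover per-CpG C positions from a call row's sequence context.

    The ``sequence`` column holds the reference context of the unit with the
    first CpG's C at a fixed offset; every ``CG`` occurrence marks one motif.
    Returns ``None`` when the string contains no CG.
    """
    offsets = [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]
    if not offsets:
        return None
    return tuple(start + off - offsets[0] for off in offsets)


def _sequence_from_positions(positions: tuple[int, ...]) -> str:
    """Synthesize a context string with CG motifs at the unit's offsets."""
    first, last = positions[0], positions[-1]
    length = (last - first) + 2 + 2 * _SEQ_FLANK
    seq = ["A"] * length
    for p in positions:
        off = _SEQ_FLANK + (p - first)
        seq[off] = "C"
        seq[off + 1] = "G"
    return "".join(seq)


def read_nanopolish_tsv(path: str | Path) -> Iterator[PerReadCall]:
    """Stream per-read calls from a Nanopolish-dialect methylation TSV.

    The header must contain every column of :data:`NANOPOLISH_COLUMNS`
    (extras are tolerated).  ``start``/``end`` are the 0-based positions of
    the first and last CpG C in the unit (inclusive, the upstream
    convention); internally ``unit_end = end + 1`` (half-open).  Unparsable
    numeric fields raise :class:`FormatError` carrying the 1-based line
    number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header") from None
        idx = {name: i for i, name in enumerate(header)}
        for col in NANOPOLISH_COLUMNS:
            if col not in idx:
                raise FormatError(
                    f"{path}: missing required column {col!r}", column=col
                )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}",
                    line=lineno,
                )
            try:
                start = int(row[idx["start"]])
                end = int(row[idx["end"]])
                llr = float(row[idx["log_lik_ratio"]])
                n_motifs = int(row[idx["num_motifs"]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparsable numeric field ({exc})", line=lineno
                ) from exc
            strand_raw = row[idx["strand"]]
            if strand_raw not in _STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand_raw!r}",
                    line=lineno,
                )
            positions = cpg_positions_from_sequence(start, row[idx["sequence"]])
            if positions is not None and len(positions) != n_motifs:
                positions = None  # context string disagrees; don't guess
            yield PerReadCall(
                chrom=row[idx["chromosome"]],
                strand=strand_raw,
                unit_start=start,
                unit_end=end + 1,
                read_id=row[idx["read_name"]],
                llr=llr,
                n_motifs=n_motifs,
                positions=positions,
            )


def write_nanopolish_tsv(calls: Iterable[PerReadCall], path: str | Path) -> int:
    """Write LLR calls in the Nanopolish TSV dialect; returns rows written.

    Round-trips with :func:`read_nanopolish_tsv` field for field.  When a
    call knows its CpG positions a context string with the CG motifs at the
    right offsets is synthesized; otherwise the sequence column is left
    CG-free and positions are not recoverable.
    """
    path = Path(path)
    n = 0
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(NANOPOLISH_COLUMNS)
        for call in calls:
            if call.llr is None:
                raise InvalidInputError(
                    "nanopolish dialect requires LLR evidence, got probability"
                )
            seq = (
                _sequence_from_positions(call.positions)
                if call.positions
                else "A" * (2 * _SEQ_FLANK)
            )
            writer.writerow(
                [
                    call.chrom,
                    call.strand,
                    call.unit_start,
                    call.unit_end - 1,
                    call.read_id,
                    f"{call.llr:.2f}",
                    f"{call.llr:.2f}",
                    "0.00",
                    1,
                    call.n_motifs,
                    seq,
                ]
            )
            n += 1
    return n


# --------------------------------------------------------------------------
# modified-base BAM (MM/ML tags)
# --------------------------------------------------------------------------


def read_modbam(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> tuple[list[PerReadCall], int]:
    """Extract per-read 5mC calls from a BAM/SAM with MM/ML modified-base tags.

    One :class:`PerReadCall` is produced per read per CpG site (n_motifs=1)
    with ``prob_meth = (ML + 0.5) / 256``, the midpoint of the probability
    bin the integer tag encodes.  Sites are reported on the forward-strand C:
    evidence from a bottom-strand C (pairing with the reference G) maps to
    the preceding reference position and keeps strand '-'.

    Returns ``(calls, n_skipped)`` where ``n_skipped`` counts mapped reads
    without usable MM/ML tags.  A region query requires an index.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    calls: list[PerReadCall] = []
    n_skipped = 0
    with pysam.AlignmentFile(path, mode) as bam:
        if region is not None:
            chrom, start, end = region
            if not bam.has_index():
                raise InvalidInputError(
                    f"{path}: region query requires a BAM index"
                )
            read_iter = bam.fetch(chrom, start, end)
        else:
            read_iter = bam.fetch(until_eof=True)
        for read in read_iter:
            if read.is_unmapped or read.query_sequence is None:
                continue
            try:
                mods = read.modified_bases
            except (ValueError, KeyError):
                mods = None
            if not mods:
                n_skipped += 1
                continue
            pair_map = dict(read.get_aligned_pairs(matches_only=True))
            emitted = False
            for (canon, strand_flag, mod), entries in mods.items():
                if canon != "C" or mod != "m":
                    continue
                for qpos, qual in entries:
                    rpos = pair_map.get(qpos)
                    if rpos is None:
                        continue
                    # strand_flag 1 = C on the strand opposite the stored
                    # sequence, i.e. pairing with the reference G of the CpG
                    if strand_flag == 1:
                        site = rpos - 1
                        strand = REVERSE
                    else:
                        site = rpos
                        strand = FORWARD
                    if site < 0:
                        continue
                    if region is not None and not (region[1] <= site < region[2]):
                        continue
                    calls.append(
                        PerReadCall(
                            chrom=read.reference_name,
                            strand=strand,
                            unit_start=site,
                            unit_end=site + 1,
                            read_id=read.query_name,
                            prob_meth=(qual + 0.5) / 256.0,
                            n_motifs=1,
                            positions=(site,),
                        )
                    )
                    emitted = True
            if not emitted:
                n_skipped += 1
    return calls, n_skipped
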