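"""Quality filters: dark regions, variant proximity, coverage, bias, FRR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methylqc.aggregate import SiteSummary
from methylqc.call_model import CpGUnit
from methylqc.errors import InvalidInputError, InvalidParameterError
from methylqc.qc import (
    FILTER_NAMES,
    HQPartition,
    QCConfig,
    QCFlags,
    annotate_frame,
    annotate_qc,
    detect_dark_regions,
    filter_hq,
    flag_abnormal_coverage,
    flag_near_variant,
    read_bed3,
    read_variant_positions,
    write_bed3,
)

CFG = QCConfig()


def _track(spec):
    """Build a pileup frame from (pos, dark?) pairs; dark bases fail all criteria."""
    rows = []
    for pos, dark in spec:
        if dark:
            rows.append(("chr1", pos, 2, 0.95, 10.0))
        else:
            rows.append(("chr1", pos, 30, 0.02, 35.0))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "depth", "frac_lowmapq", "mean_baseq"]
    )


def _oracle_dark(track, config):
    """Brute-force per-base scan over the track span."""
    by_pos = {
        int(r.pos): (r.depth, r.frac_lowmapq, r.mean_baseq)
        for r in track.itertuples()
    }
    if not by_pos:
        return []
    lo, hi = min(by_pos), max(by_pos) + 1
    dark = []
    for p in range(lo, hi):
        if p not in by_pos:
            dark.append(True)  # no data = depth 0
            continue
        d, f, q = by_pos[p]
        dark.append(
            d == 0
            or (f >= config.dark_frac and d < config.dark_cov and q < config.dark_baseq)
        )
    regions, start = [], None
    for i, flag in enumerate(dark + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= config.dark_min_len:
                regions.append(("chr1", lo + start, lo + i))
            start = None
    return regions


class TestDetectDarkRegions:
    def test_fifty_base_failing_run_flanked_by_passing(self):
        spec = [(p, False) for p in range(0, 10)]
        spec += [(p, True) for p in range(10, 60)]
        spec += [(p, False) for p in range(60, 70)]
        assert detect_dark_regions(_track(spec), CFG) == [("chr1", 10, 60)]

    def test_short_run_dropped_by_length_filter(self):
        spec = [(p, p in range(10, 30)) for p in range(0, 50)]
        assert detect_dark_regions(_track(spec), CFG) == []

    def test_all_passing_yields_empty(self):
        assert detect_dark_regions(_track([(p, False) for p in range(60)]), CFG) == []

    def test_uncovered_gap_counts_as_dark(self):
        # records only at 0 and 100: the 99-base hole is depth-0 -> dark
        spec = [(0, False), (100, False)]
        assert detect_dark_regions(_track(spec), CFG) == [("chr1", 1, 100)]

    def test_unsorted_positions_rejected(self):
        track = _track([(5, False), (3, False)])
        with pytest.raises(InvalidInputError):
            detect_dark_regions(track, CFG)

    def test_single_failing_criterion_is_not_dark(self):
        # low depth alone (good mapq / baseq) must not trigger
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": range(50), "depth": 2,
             "frac_lowmapq": 0.02, "mean_baseq": 35.0}
        )
        assert detect_dark_regions(track, CFG) == []

    @given(
        st.lists(st.tuples(st.integers(0, 400), st.booleans()),
                 min_size=1, max_size=120, unique_by=lambda t: t[0]),
    )
    def test_matches_per_base_scan_oracle(self, spec):
        spec = sorted(spec)
        track = _track(spec)
        assert detect_dark_regions(track, CFG) == _oracle_dark(track, CFG)


class TestFlagNearVariant:
    @pytest.mark.parametrize(
        "positions,variant,window,expected",
        [
            ((100,), 105, 5, True),
            ((100,), 106, 5, False),
            ((100,), 100, 5, True),  # variant on the C itself
            ((100, 120), 125, 5, True),
        ],
    )
    def test_distance_rule(self, positions, variant, window, expected):
        unit = CpGUnit("chr1", positions)
        assert flag_near_variant(unit, [variant], window) is expected

    def test_empty_variant_list_is_false(self):
        assert flag_near_variant(CpGUnit("chr1", (100,)), [], 5) is False


class TestFlagAbnormalCoverage:
    @pytest.mark.parametrize(
        "cov,mean,expected",
        [(30, 20, True), (10, 20, True), (20, 20, False), (29, 20, False), (11, 20, False)],
    )
    def test_inclusive_multiples_of_mean(self, cov, mean, expected):
        assert flag_abnormal_coverage(cov, mean, CFG) is expected

    def test_requires_positive_mean(self):
        with pytest.raises(InvalidParameterError):
            flag_abnormal_coverage(10, 0.0, CFG)


def _summary(sb=None, frr=0.9, coverage=20, positions=(1000,)):
    """Summary with chosen covariates: counts engineered to hit sb/frr/coverage."""
    n_assigned = int(round(frr * coverage))
    n_ambig = coverage - n_assigned
    fw = n_assigned // 2
    rv = n_assigned - fw
    if sb is None:
        rv = 0
        n_ambig = coverage - fw
        meth_fw, unmeth_fw, meth_rv, unmeth_rv = fw, 0, 0, 0
    else:
        meth_fw, unmeth_fw = fw, 0
        meth_rv = int(round((1 - sb) * rv))
        unmeth_rv = rv - meth_rv
    return SiteSummary(
        unit=CpGUnit("chr1", positions),
        n_meth=meth_fw + meth_rv, n_unmeth=unmeth_fw + unmeth_rv, n_ambig=n_ambig,
        n_meth_fw=meth_fw, n_unmeth_fw=unmeth_fw,
        n_meth_rv=meth_rv, n_unmeth_rv=unmeth_rv,
    )


class TestAnnotateQC:
    def test_benign_unit_is_hq(self):
        flags = annotate_qc(_summary(sb=0.0), dark=[], variants=[], mean_coverage=20)
        assert flags.hq and flags.reasons == ()

    def test_strand_bias_at_or_over_cutoff_fails(self):
        flags = annotate_qc(_summary(sb=0.25), [], [], 20)
        assert flags.high_strand_bias and not flags.hq

    def test_frr_at_cutoff_fails_inclusively(self):
        flags = annotate_qc(_summary(sb=0.0, frr=0.5), [], [], 20)
        assert flags.low_frr and not flags.hq

    def test_missing_strand_bias_does_not_fail(self):
        flags = annotate_qc(_summary(sb=None), [], [], 20)
        assert not flags.high_strand_bias

    def test_dark_and_variant_flags_use_cpg_positions(self):
        s = _summary(sb=0.0, positions=(1000, 1008))
        flags = annotate_qc(s, dark=[("chr1", 1005, 1040)], variants=[996], mean_coverage=20)
        assert flags.in_dark and flags.near_variant

    def test_hq_monotone_under_threshold_relaxation(self):
        strict = QCConfig()
        relaxed = QCConfig(strand_bias_max=0.4, frr_min=0.25,
                           cov_low_mult=0.25, cov_high_mult=3.0, variant_window=2)
        rng = np.random.default_rng(5)
        for _ in range(200):
            s = _summary(
                sb=float(rng.random()),
                frr=float(rng.uniform(0.2, 1.0)),
                coverage=int(rng.integers(4, 60)),
                positions=(int(rng.integers(0, 3000)),),
            )
            f_strict = annotate_qc(s, [("chr1", 500, 600)], [1500], 20, strict)
            f_relaxed = annotate_qc(s, [("chr1", 500, 600)], [1500], 20, relaxed)
            if f_strict.hq:
                assert f_relaxed.hq


class TestFilterHQ:
    def test_partition_counts_single_failures(self):
        flags = [QCFlags(False, False, False, False, False)] * 7 + [
            QCFlags(True, False, False, False, False),
            QCFlags(False, True, False, False, False),
            QCFlags(False, False, False, True, False),
        ]
        part = filter_hq(flags)
        assert (part.n_hq, part.n_non_hq) == (7, 3)
        assert sum(part.reason_counts.values()) == 3

    def test_double_failure_counted_once_in_non_hq_twice_in_reasons(self):
        part = filter_hq([QCFlags(True, False, False, True, False)])
        assert part.n_non_hq == 1
        assert part.reason_counts["in_dark"] == 1
        assert part.reason_counts["high_strand_bias"] == 1
        assert sum(part.reason_counts.values()) == 2

    def test_empty_input(self):
        part = filter_hq([])
        assert part.n_total == 0 and all(v == 0 for v in part.reason_counts.values())

    def test_frame_and_object_paths_agree(self, small_sim):
        import methylqc as m

        cfg, truth, _, sites = small_sim
        annotated = m.pipeline.annotate_simulated(sites, truth)
        part = filter_hq(annotated)
        assert part.n_hq + part.n_non_hq == len(annotated)
        assert part.n_hq == int(annotated["hq"].sum())
        # frame flags match per-unit object evaluation on a sample of rows
        pileup = m.simulate.emit_pileup_track(truth)
        dark = detect_dark_regions(pileup)
        mean_cov = m.aggregate.dataset_mean_coverage(sites)
        for _, row in annotated.head(50).iterrows():
            s = SiteSummary(
                unit=CpGUnit(row["chrom"], tuple(row["positions"])),
                n_meth=int(row["n_meth"]), n_unmeth=int(row["n_unmeth"]),
                n_ambig=int(row["n_ambig"]),
                n_meth_fw=0, n_unmeth_fw=0, n_meth_rv=0, n_unmeth_rv=0,
            )
            flags = annotate_qc(s, dark, truth.variant_positions, mean_cov)
            assert flags.in_dark == bool(row["in_dark"])
            assert flags.near_variant == bool(row["near_variant"])
            assert flags.abnormal_coverage == bool(row["abnormal_coverage"])


class TestQCIO:
    def test_bed3_round_trip(self, tmp_path):
        intervals = [("chr1", 10, 60), ("chr2", 0, 35)]
        path = tmp_path / "dark.bed"
        write_bed3(intervals, path)
        assert read_bed3(path) == intervals

    def test_variant_positions_from_list_and_vcf(self, tmp_path):
        lst = tmp_path / "vars.txt"
        lst.write_text("chr1\t5\nchr1\t2\nchr2\t9\n")
        got = read_variant_positions(lst)
        assert got["chr1"].tolist() == [2, 5] and got["chr2"].tolist() == [9]

        vcf = tmp_path / "vars.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tA\tG\t.\t.\t.\n"
            "chr1\t51\t.\tC\tT\t.\t.\t.\n"
        )
        got = read_variant_positions(vcf)
        assert got["chr1"].tolist() == [50, 100]  # converted to 0-based
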