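"""Amplicon classification, mean CP, expression ratios and %-of-wild-type."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prnai.qpcr import (
    Amplicon,
    DsRnaRegion,
    ExpressionRatio,
    InsufficientReplicatesError,
    Nesting,
    WellMeasurement,
    amplicon_mean_efficiency,
    classify_amplicon,
    compute_percent_wt,
    compute_ratios,
    control_pool_cp,
    expression_ratio,
    mean_cp,
    percent_wt,
)

REGION = DsRnaRegion("g", 100, 700)


class TestClassifyAmplicon:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (150, 400, Nesting.NESTED),       # fully inside the dsRNA interval
            (100, 700, Nesting.NESTED),       # exactly coincident counts as nested
            (50, 150, Nesting.SEMI_NESTED),   # straddles the left boundary
            (650, 800, Nesting.SEMI_NESTED),  # straddles the right boundary
            (10, 50, Nesting.OUTSIDE),        # zero overlap
            (10, 99, Nesting.OUTSIDE),        # abuts but does not overlap
        ],
    )
    def test_containment_rules(self, start, end, expected):
        assert classify_amplicon(Amplicon("a", "g", start, end), REGION) == expected

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gene mismatch"):
            classify_amplicon(Amplicon("a", "other", 150, 400), REGION)

    @given(
        a=st.integers(1, 1000), b=st.integers(1, 1000),
        r1=st.integers(1, 1000), r2=st.integers(1, 1000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_partition_property(self, a, b, r1, r2):
        """Every valid amplicon gets exactly one label, and the label does not
        depend on how the interval endpoints were supplied."""
        amp = Amplicon("a", "g", min(a, b), max(a, b))
        region = DsRnaRegion("g", min(r1, r2), max(r1, r2))
        label = classify_amplicon(amp, region)
        assert label in set(Nesting)
        # brute-force positional check of the three-way partition
        apos = set(range(amp.start, amp.end + 1))
        rpos = set(range(region.start, region.end + 1))
        if apos <= rpos:
            assert label == Nesting.NESTED
        elif apos & rpos:
            assert label == Nesting.SEMI_NESTED
        else:
            assert label == Nesting.OUTSIDE


class TestMeanCp:
    def _wells(self, cps, qc):
        return [
            WellMeasurement("s", "a", i, cp, 1.9, ok)
            for i, (cp, ok) in enumerate(zip(cps, qc), start=1)
        ]

    def test_identical_replicates(self):
        assert mean_cp(self._wells([20.0, 20.0, 20.0], [True] * 3)) == 20.0

    def test_failed_well_excluded(self):
        wells = self._wells([20.0, 21.0, 35.0], [True, True, False])
        assert mean_cp(wells) == pytest.approx(20.5)

    def test_single_passing_well_insufficient(self):
        wells = self._wells([20.0, 30.0, 31.0], [True, False, False])
        with pytest.raises(InsufficientReplicatesError):
            mean_cp(wells)


class TestExpressionRatio:
    def test_one_cycle_doubling(self):
        assert expression_ratio(2.0, 1.0, 2.0, 0.0) == 2.0

    @pytest.mark.parametrize("x", [-3.0, 0.0, 1.7, 12.0])
    def test_target_tracking_reference_is_unity(self, x):
        assert expression_ratio(2.0, x, 2.0, x) == pytest.approx(1.0)

    def test_efficiency_corrected_closed_form(self):
        # direct evaluation of 1.9**3 / 1.95**2
        assert expression_ratio(1.9, 3.0, 1.95, 2.0) == pytest.approx(
            1.8038132807363576, rel=1e-12
        )

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            expression_ratio(0.9, 1.0, 2.0, 1.0)

    @given(
        e=st.floats(1.5, 2.0), d1=st.floats(-5, 5), d2=st.floats(-5, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity(self, e, d1, d2):
        """R increases in the target delta-CP and decreases in the reference
        delta-CP when efficiencies exceed 1."""
        lo, hi = sorted([d1, d2])
        if hi - lo > 1e-6:
            assert expression_ratio(e, hi, e, 0.0) > expression_ratio(e, lo, e, 0.0)
            assert expression_ratio(e, 0.0, e, hi) < expression_ratio(e, 0.0, e, lo)


class TestControlPool:
    def test_single_sample(self):
        assert control_pool_cp([20.0], 2.0) == pytest.approx(20.0)

    def test_two_samples_template_average(self):
        # pool of CP {20, 22} at E=2 holds (2^-20 + 2^-22)/2 template units,
        # i.e. CP = 22 - log2(2.5)
        expected = -math.log2((2.0**-20 + 2.0**-22) / 2)
        assert control_pool_cp([20.0, 22.0], 2.0) == pytest.approx(expected)
        assert expected == pytest.approx(22 - math.log2(2.5))

    def test_pool_lies_between_extremes(self):
        cp = control_pool_cp([18.0, 20.0, 25.0], 1.9)
        assert 18.0 < cp < 25.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            control_pool_cp([], 2.0)


class TestPercentWT:
    @pytest.mark.parametrize(
        "r_rnai,r_wt,pct,rounded",
        [
            (1.24, 4.88, 25.409836, 25),  # early-stage knockdown, nested amplicon
            (0.22, 4.51, 4.878049, 5),    # same samples, semi-nested amplicon
        ],
    )
    def test_published_fragment_ratios(self, r_rnai, r_wt, pct, rounded):
        p = percent_wt(ExpressionRatio("r", "g", r_rnai), ExpressionRatio("w", "g", r_wt))
        assert p.pct == pytest.approx(pct, abs=1e-5)
        assert p.rounded == rounded

    @given(r=st.floats(1e-6, 1e6))
    @settings(max_examples=50, derandomize=True)
    def test_identity_is_100(self, r):
        p = percent_wt(ExpressionRatio("a", "g", r), ExpressionRatio("b", "g", r))
        assert p.pct == pytest.approx(100.0)

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_wt(ExpressionRatio("a", "g1", 1.0), ExpressionRatio("b", "g2", 1.0))


class TestAmpliconMeanEfficiency:
    def test_plain_mean(self):
        assert amplicon_mean_efficiency([1.90, 1.92, 1.91]) == pytest.approx(1.91)

    def test_outlier_excluded(self):
        # 1.40 deviates far more than 5% from the median and is dropped
        assert amplicon_mean_efficiency([1.90, 1.92, 1.91, 1.40]) == pytest.approx(1.91)

    def test_too_few_fits(self):
        with pytest.raises(InsufficientReplicatesError):
            amplicon_mean_efficiency([1.9, 1.9])


class TestRatioPipeline:
    def test_noiseless_closed_forms(self, noiseless_experiment):
        """With zero noise, the semi-nested amplicon reads exactly 100k %WT
        and the nested amplicon 100(Mk + D)/M at every stage."""
        tables = noiseless_experiment["tables"]
        cfg = noiseless_experiment["config"]
        profile = noiseless_experiment["profile"]
        ratios = compute_ratios(tables["samples"], tables["wells"], "ref")
        pct = compute_percent_wt(ratios)
        for _, row in pct.iterrows():
            m = profile.window_mean(row["stage_start_h"], row["stage_end_h"])
            if row["amplicon"] == "semi":
                expected = 100 * cfg.knockdown_k
            else:
                expected = 100 * (m * cfg.knockdown_k + cfg.dsrna_level) / m
            assert row["pct_wt_mean"] == pytest.approx(expected, rel=1e-9)
            assert row["pct_wt_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_cp_outlier_well_flagged(self, noiseless_experiment):
        """A well whose CP deviates > 0.5 cycles from the replicate median is
        excluded from the mean without changing the other samples."""
        tables = noiseless_experiment["tables"]
        wells = tables["wells"].copy()
        idx = wells.index[
            (wells.sample_id == "WT_st0_b1") & (wells.amplicon == "semi")
        ][0]
        clean = compute_ratios(tables["samples"], tables["wells"], "ref")
        wells.loc[idx, "cp"] += 3.0
        dirty = compute_ratios(tables["samples"], wells, "ref")
        merged = clean.merge(dirty, on=["sample_id", "amplicon"], suffixes=("_c", "_d"))
        assert np.allclose(merged["mean_cp_c"], merged["mean_cp_d"])
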