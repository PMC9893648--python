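"""Thresholding, classification and the Poisson concentration estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dropquant import (
    DataError,
    NoClusterStructureError,
    SaturatedWellError,
    SimulationSpec,
    auto_threshold,
    classify,
    estimate_concentration,
    merge_wells,
    simulate_well,
    total_measurement,
)
from dropquant.quantify import DEFAULT_DROPLET_VOLUME_UL as VOL

from conftest import MIDPOINT


class TestAutoThreshold:
    def test_two_separated_clusters(self, rng):
        x = np.concatenate(
            [rng.normal(2000, 300, 15000), rng.normal(8000, 300, 5000)]
        )
        assert 4000.0 < auto_threshold(x) < 6000.0

    def test_all_negative_well_rejected(self, rng):
        with pytest.raises(NoClusterStructureError):
            auto_threshold(rng.normal(2000, 300, 20000))

    def test_degenerate_input_rejected(self):
        with pytest.raises(NoClusterStructureError, match="no cluster structure"):
            auto_threshold(np.full(500, 1234.5))
        with pytest.raises(DataError):
            auto_threshold(np.arange(50))  # too few droplets

    def test_permutation_invariant(self, rng):
        x = np.concatenate([rng.normal(2000, 300, 800), rng.normal(8000, 300, 200)])
        t1 = auto_threshold(x)
        t2 = auto_threshold(rng.permutation(x))
        assert t1 == pytest.approx(t2, abs=1e-9)


class TestClassify:
    def test_threshold_above_max_gives_zero_positives(self, duplex_well):
        cw = classify(duplex_well, thresholds=(1e9, 1e9))
        assert cw.k_ch1_pos == 0 and cw.k_ch2_pos == 0
        assert cw.k_double_neg == cw.n_total

    def test_counts_match_generator_labels_when_rain_free(self, duplex_well):
        cw = classify(duplex_well, thresholds=MIDPOINT)
        t = duplex_well.truth
        assert cw.k_ch1_pos == (t.wt_copies > 0).sum()
        assert cw.k_ch2_pos == (t.mut_copies > 0).sum()
        assert cw.k_double_pos == ((t.wt_copies > 0) & (t.mut_copies > 0)).sum()

    def test_quadrants_conserved_for_any_threshold(self, duplex_well):
        for thr in [(0.0, 0.0), (3000.0, 7000.0), MIDPOINT, (1e9, -1e9)]:
            cw = classify(duplex_well, thresholds=thr)
            only1 = cw.k_ch1_pos - cw.k_double_pos
            only2 = cw.k_ch2_pos - cw.k_double_pos
            assert only1 + only2 + cw.k_double_pos + cw.k_double_neg == cw.n_total

    def test_droplet_exactly_at_threshold_is_negative(self):
        from dropquant import DropletWell

        well = DropletWell("w", "s", "a", np.array([[5000.0, 4000.0], [5000.1, 6000.0]]))
        cw = classify(well, thresholds=(5000.0, 5000.0), min_droplets=0)
        assert cw.k_ch1_pos == 1  # the droplet at exactly 5000 counts negative
        assert cw.k_ch2_pos == 1

    def test_low_droplet_flag(self, duplex_well):
        assert classify(duplex_well, thresholds=MIDPOINT, min_droplets=30000).low_droplet_flag
        assert not classify(duplex_well, thresholds=MIDPOINT).low_droplet_flag


class TestEstimateConcentration:
    def test_zero_positives(self):
        m = estimate_concentration(0, 20000)
        assert m.lambda_hat == 0.0 and m.concentration == 0.0
        assert m.ci_low == 0.0 and m.ci_high > 0.0

    @pytest.mark.parametrize(
        "k, n, lam, conc",
        [
            (10000, 20000, math.log(2), -math.log(0.5) / VOL),  # ≈ 815.5 copies/µL
            (1900, 20000, -math.log(0.905), -math.log(0.905) / VOL),  # ≈ 117.4
        ],
    )
    def test_closed_form(self, k, n, lam, conc):
        m = estimate_concentration(k, n)
        assert m.lambda_hat == pytest.approx(lam, abs=1e-12)
        assert m.concentration == pytest.approx(conc, rel=1e-12)

    def test_saturated_well_raises(self):
        with pytest.raises(SaturatedWellError, match="saturated"):
            estimate_concentration(20000, 20000)

    def test_invalid_counts(self):
        with pytest.raises(DataError):
            estimate_concentration(-1, 100)
        with pytest.raises(DataError):
            estimate_concentration(5, 0)

    def test_exact_ci_brackets_delta_ci(self):
        delta = estimate_concentration(1900, 20000)
        exact = estimate_concentration(1900, 20000, exact_ci=True)
        # both are 95% intervals around the same point estimate
        assert exact.concentration == delta.concentration
        assert exact.ci_low < delta.concentration < exact.ci_high
        assert exact.ci_low == pytest.approx(delta.ci_low, rel=0.05)

    @given(st.integers(min_value=0, max_value=9998))
    def test_lambda_strictly_increasing_in_k(self, k):
        n = 10000
        a = estimate_concentration(k, n).lambda_hat
        b = estimate_concentration(k + 1, n).lambda_hat
        assert b > a


class TestMergeWells:
    def test_single_well_identity(self):
        one = estimate_concentration(100, 10000)
        assert merge_wells([one]) == one

    def test_pooling_additive(self):
        a = estimate_concentration(100, 10000)
        b = estimate_concentration(100, 10000)
        merged = merge_wells([a, b])
        direct = estimate_concentration(200, 20000)
        assert merged == direct

    def test_pooling_differs_from_averaging_when_n_differs(self):
        a = estimate_concentration(10, 1000)
        b = estimate_concentration(1000, 19000)
        merged = merge_wells([a, b])
        pooled_direct = estimate_concentration(1010, 20000)
        assert merged.concentration == pooled_direct.concentration
        naive_average = (a.concentration + b.concentration) / 2
        assert merged.concentration != pytest.approx(naive_average, rel=1e-3)

    def test_mixed_targets_rejected(self):
        a = estimate_concentration(10, 1000, target="WT")
        b = estimate_concentration(10, 1000, target="MUT")
        with pytest.raises(DataError, match="targets"):
            merge_wells([a, b])

    def test_total_measurement_adds_lambdas(self):
        a = estimate_concentration(1000, 20000, target="WT")
        b = estimate_concentration(500, 20000, target="MUT")
        tot = total_measurement(a, b)
        assert tot.lambda_hat == pytest.approx(a.lambda_hat + b.lambda_hat)
        assert tot.lambda_se == pytest.approx(math.hypot(a.lambda_se, b.lambda_se))


class TestCalibration:
    def test_estimator_unbiased_across_lambda_grid(self, rng):
        # binomial-level calibration of λ̂: mean relative bias < 1% at n = 20,000
        n, wells = 20000, 200
        for lam in (0.05, 0.1, 0.3, 0.7, 1.5):
            p = 1.0 - math.exp(-lam)
            ks = rng.binomial(n, p, size=wells)
            lams = -np.log1p(-ks / n)
            assert abs(lams.mean() - lam) / lam < 0.01

    def test_classify_then_estimate_recovers_truth_rain_free(self, clean_model):
        # end-to-end on clean amplitudes: within 3 SE of the true concentration
        spec = SimulationSpec(conc_wt=300.0, conc_mut=100.0, amplitude_model=clean_model, seed=11)
        well = simulate_well(spec)
        cw = classify(well, thresholds=MIDPOINT)
        for k, true_conc in ((cw.k_ch1_pos, 300.0), (cw.k_ch2_pos, 100.0)):
            m = estimate_concentration(k, cw.n_total)
            assert abs(m.concentration - true_conc) < 3.0 * m.concentration_se

    def test_rain_inflates_low_concentration_estimates(self):
        # uniform rain crossing the midpoint threshold adds a ~0.5% false-positive
        # rate, a documented multiplicative bias that dominates at low template
        # concentration (why the paired cDNA/gDNA design is simulated rain-free)
        spec = SimulationSpec(conc_wt=20.0, conc_mut=0.0, seed=13)  # default 1% rain
        well = simulate_well(spec)
        cw = classify(well, thresholds=MIDPOINT)
        m = estimate_concentration(cw.k_ch1_pos, cw.n_total)
        assert m.concentration > 20.0 + 3.0 * m.concentration_se
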