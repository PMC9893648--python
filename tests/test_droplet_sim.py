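"""Generator correctness: Poisson occupancy, amplitude clusters, designs, seeds."""

import math

import numpy as np
import pandas as pd
import pytest

from dropquant import (
    AmplitudeModel,
    ConfigError,
    DataError,
    SimulationSpec,
    simulate_experiment,
    simulate_snp_counts,
    simulate_well,
)
from dropquant.droplet_sim import MIXTURE_SERIES_FRACTIONS

VOL = 0.00085


def spec_for_lambda(lam_wt, lam_mut=0.0, **kw):
    return SimulationSpec(conc_wt=lam_wt / VOL, conc_mut=lam_mut / VOL, **kw)


class TestSimulateWell:
    def test_empty_sample_all_negative(self, clean_model):
        well = simulate_well(
            SimulationSpec(conc_wt=0.0, conc_mut=0.0, amplitude_model=clean_model, seed=1)
        )
        assert (well.truth.wt_copies == 0).all()
        assert (well.truth.mut_copies == 0).all()
        # every droplet sits in the negative cluster, far below the midpoint
        assert well.amplitudes.max() < 5000.0

    def test_occupancy_matches_binomial_oracle(self):
        # at λ = 0.1 the positive-droplet count is Binomial(n, 1 − e^−0.1)
        lam, n = 0.1, 20_000
        well = simulate_well(spec_for_lambda(lam, n_droplets=n, seed=3))
        k = int((well.truth.wt_copies > 0).sum())
        p = 1.0 - math.exp(-lam)
        assert abs(k - n * p) < 3.0 * math.sqrt(n * p * (1.0 - p))

    def test_targets_independent(self):
        # double-occupancy fraction factorizes into the two marginals
        well = simulate_well(spec_for_lambda(0.5, 0.3, seed=5))
        t = well.truth
        p1 = (t.wt_copies > 0).mean()
        p2 = (t.mut_copies > 0).mean()
        p12 = ((t.wt_copies > 0) & (t.mut_copies > 0)).mean()
        se = math.sqrt(p1 * p2 * (1 - p1 * p2) / t.wt_copies.size)
        assert abs(p12 - p1 * p2) < 4.0 * se

    def test_seed_determinism(self):
        spec = spec_for_lambda(0.3, 0.1, seed=77)
        a = simulate_well(spec).amplitudes
        b = simulate_well(spec).amplitudes
        np.testing.assert_array_equal(a, b)
        c = simulate_well(spec_for_lambda(0.3, 0.1, seed=78)).amplitudes
        assert not np.array_equal(a, c)

    def test_rain_bookkeeping(self):
        # classified positives = non-rain occupancy positives + rain above threshold
        well = simulate_well(
            SimulationSpec(
                conc_wt=300.0, conc_mut=0.0,
                amplitude_model=AmplitudeModel(rain_fraction=0.05), seed=9,
            )
        )
        t = well.truth
        pos = well.amplitudes[:, 0] > 5000.0
        expected = ((t.wt_copies > 0) & ~t.rain).sum() + (
            t.rain & (well.amplitudes[:, 0] > 5000.0)
        ).sum()
        assert pos.sum() == expected

    def test_mean_positive_fraction_calibrated(self):
        # over 200 replicate wells at λ = 0.3 the mean positive fraction
        # tracks 1 − e^−0.3 to better than 1% relative
        lam, n_wells = 0.3, 200
        fracs = [
            (simulate_well(spec_for_lambda(lam, n_droplets=2000, seed=s)).truth.wt_copies > 0).mean()
            for s in range(n_wells)
        ]
        expected = 1.0 - math.exp(-lam)
        assert abs(np.mean(fracs) - expected) / expected < 0.01

    def test_saturation_flagged_not_raised(self):
        # expected positive fraction > 99.9% → flag, still a valid well
        well = simulate_well(spec_for_lambda(8.0, seed=2, n_droplets=1000))
        assert "saturated_ch1" in well.flags
        assert well.accepted_count == 1000

    @pytest.mark.parametrize(
        "bad",
        [
            dict(conc_wt=-1.0, conc_mut=0.0),
            dict(conc_wt=0.0, conc_mut=0.0, n_droplets=0),
            dict(conc_wt=0.0, conc_mut=0.0, droplet_volume=0.0),
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(DataError):
            SimulationSpec(**bad)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(pos_mean_ch1=1000.0),  # positive below negative
            dict(neg_sd=0.0),
            dict(rain_fraction=0.6),
        ],
    )
    def test_invalid_amplitude_model_rejected(self, bad):
        with pytest.raises(DataError):
            AmplitudeModel(**bad)


class TestDesigns:
    def test_mixture_series_mirrors_validation_samples(self):
        wells, plate, assays = simulate_experiment(
            {"name": "mixture_series", "total_conc": 400.0, "seed": 1, "n_droplets": 500}
        )
        assert len(wells) == 7
        assert list(plate.rows["sample_id"]) == ["I", "II", "III", "IV", "V", "VI", "VII"]
        for well, f in zip(wells, MIXTURE_SERIES_FRACTIONS):
            assert well.truth.spec.conc_wt == pytest.approx(400.0 * f)
            assert well.truth.spec.conc_mut == pytest.approx(400.0 * (1.0 - f))

    def test_het_gdna_design(self):
        wells, plate, _ = simulate_experiment({"name": "het_gdna", "seed": 2, "n_droplets": 500})
        assert len(wells) == 3
        assert set(plate.rows["material"]) == {"gDNA"}
        assert all(w.truth.spec.conc_wt == w.truth.spec.conc_mut for w in wells)

    def test_knockdown_design_halves_target_only(self):
        wells, plate, assays = simulate_experiment(
            {"name": "knockdown", "seed": 3, "n_droplets": 500, "replicates": 1}
        )
        assert len(wells) == 4  # control/treated × target/reference
        by = {(r.group, r.assay_id): w for w, r in zip(wells, plate.rows.itertuples())}
        ctrl, trt = by[("control", "SNPdup")], by[("treated", "SNPdup")]
        assert trt.truth.spec.conc_wt == pytest.approx(ctrl.truth.spec.conc_wt / 2)
        assert trt.truth.spec.conc_mut == pytest.approx(ctrl.truth.spec.conc_mut / 2)
        refs = [by[("control", "REF")], by[("treated", "REF")]]
        assert refs[0].truth.spec.conc_wt == refs[1].truth.spec.conc_wt

    def test_paired_design_is_rain_free_by_default(self):
        wells, plate, _ = simulate_experiment(
            {"name": "paired_cdna_gdna", "seed": 4, "n_droplets": 500}
        )
        assert set(plate.rows["material"]) == {"cDNA", "gDNA"}
        assert all(w.truth.spec.amplitude_model.rain_fraction == 0.0 for w in wells)

    def test_unknown_design_rejected(self):
        with pytest.raises(ConfigError, match="unknown design"):
            simulate_experiment({"name": "no_such_design"})

    def test_experiment_seed_determinism(self):
        design = {"name": "het_gdna", "seed": 11, "n_droplets": 300}
        a, _, _ = simulate_experiment(design)
        b, _, _ = simulate_experiment(design)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.amplitudes, wb.amplitudes)


class TestSnpCounts:
    def test_recovers_fraction_within_binomial_error(self):
        # 3 SNP regions at depth 5,000, true 74.7% WT
        f, depth, n_snps = 0.747, 5000, 3
        table = simulate_snp_counts(f, depth, n_snps, seed=6)
        agg = table["wt_count"].sum() / (depth * n_snps)
        se = math.sqrt(f * (1 - f) / (depth * n_snps))
        assert abs(agg - f) < 4.0 * se

    def test_large_depth_converges(self):
        table = simulate_snp_counts(0.3, 10**6, 3, seed=7)
        f_hat = table["wt_count"].sum() / (3 * 10**6)
        assert abs(f_hat - 0.3) < 0.005

    def test_reproducible_and_valid(self):
        a = simulate_snp_counts(0.5, 100, 5, seed=8)
        b = simulate_snp_counts(0.5, 100, 5, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert ((a["wt_count"] + a["mut_count"]) == 100).all()

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            simulate_snp_counts(1.5, 100, 3, seed=0)
        with pytest.raises(DataError):
            simulate_snp_counts(0.5, 0, 3, seed=0)
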