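"""Synthetic cohort generator: determinism, censoring, block structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from metabodelta import (
    GeneratorConfig,
    ProductEffect,
    ThresholdEffect,
    compute_delta_glucose,
    generate_cohort,
    read_cohort,
    summarize_response,
    write_cohort,
)
from metabodelta.synthetic import ConfigurationError

from conftest import make_clinical


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_subjects": 0}, "n_subjects"),
            ({"n_signal": 10, "n_features": 5}, "n_signal"),
            ({"block_rho": 1.0}, "block_rho"),
            ({"lod_quantile": 1.0}, "lod_quantile"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"effect_linear": (1.0, 2.0)}, "effect_linear"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            GeneratorConfig(**kwargs)


class TestGenerateCohort:
    def test_default_dimensions_and_censoring(self):
        cohort = generate_cohort(GeneratorConfig(seed=0))
        assert cohort.features.values.shape == (172, 286)
        # floor(0.05 * 172) = 8 missing entries per feature, exactly
        missing = cohort.features.values.isna().sum()
        assert (missing == 8).all()

    def test_seeded_determinism(self):
        c1 = generate_cohort(GeneratorConfig(seed=42))
        c2 = generate_cohort(GeneratorConfig(seed=42))
        pd.testing.assert_frame_equal(c1.features.values, c2.features.values)
        pd.testing.assert_frame_equal(c1.clinical.data, c2.clinical.data)
        assert c1.truth == c2.truth

    def test_different_seeds_differ(self):
        c1 = generate_cohort(GeneratorConfig(seed=0))
        c2 = generate_cohort(GeneratorConfig(seed=1))
        assert not c1.features.values.equals(c2.features.values)

    def test_censored_values_below_observed(self):
        cfg = GeneratorConfig(n_subjects=50, n_features=10, lod_quantile=0.2, seed=7)
        cohort = generate_cohort(cfg)
        vals = cohort.features.values
        k = int(np.floor(0.2 * 50))
        for col in vals.columns:
            assert vals[col].isna().sum() == k
        # regenerate without censoring: the censored entries must be the smallest
        full = generate_cohort(
            GeneratorConfig(n_subjects=50, n_features=10, lod_quantile=0.0, seed=7)
        ).features.values
        for col in vals.columns:
            mask = vals[col].isna().to_numpy()
            assert full[col].to_numpy()[mask].max() <= full[col].to_numpy()[~mask].min()

    def test_noise_free_single_linear_effect_is_affine(self):
        cfg = GeneratorConfig(
            n_subjects=40,
            n_features=6,
            n_signal=1,
            n_blocks=3,
            lod_quantile=0.0,
            noise_sd=0.0,
            effect_linear=(1.3,),
            effect_products=(),
            effect_thresholds=(),
            seed=5,
        )
        cohort = generate_cohort(cfg)
        delta = compute_delta_glucose(cohort.clinical).to_numpy()
        sig = cohort.truth["signal_features"][0]
        logx = np.log(cohort.features.values[sig].to_numpy())
        r = np.corrcoef(logx, delta)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_truth_references_existing_features(self):
        cohort = generate_cohort(GeneratorConfig(seed=3))
        ids = set(cohort.features.feature_ids)
        assert set(cohort.truth["signal_features"]) <= ids
        assert len(set(cohort.truth["signal_features"])) == 9

    def test_intensities_positive_where_observed(self):
        vals = generate_cohort(GeneratorConfig(seed=1)).features.values.to_numpy()
        assert np.nanmin(vals) > 0

    def test_block_correlation_converges(self):
        cfg = GeneratorConfig(
            n_subjects=5000, n_features=12, n_signal=1, n_blocks=2, block_rho=0.6,
            lod_quantile=0.0, seed=11,
        )
        logx = np.log(generate_cohort(cfg).features.values.to_numpy())
        corr = np.corrcoef(logx, rowvar=False)
        block = np.arange(12) % 2
        same = corr[(block[:, None] == block[None, :]) & ~np.eye(12, dtype=bool)]
        other = corr[block[:, None] != block[None, :]]
        assert same.mean() == pytest.approx(0.6, abs=0.03)
        assert abs(other.mean()) < 0.05

    def test_clinical_decoupled_without_effect(self):
        from scipy.stats import spearmanr

        rhos = []
        for s in range(20):
            cohort = generate_cohort(GeneratorConfig(seed=s, n_features=20))
            delta = compute_delta_glucose(cohort.clinical).to_numpy()
            for col in ("bmi", "waist_cm", "age_years", "glucose_baseline"):
                rhos.append(abs(spearmanr(cohort.clinical.data[col], delta)[0]))
        assert np.median(rhos) < 0.2


class TestSummarizeResponse:
    def test_hand_computable_summary(self):
        # Δglucose = [-1, 0, 2, 3] via elapsed_years = 1
        base = np.full(4, 100.0)
        clin = make_clinical(base, base + np.array([-1.0, 0.0, 2.0, 3.0]), np.ones(4))
        cohort = generate_cohort(GeneratorConfig(n_subjects=4, n_features=2, n_signal=1, seed=0))
        cohort.clinical = clin
        s = summarize_response(cohort)
        assert s["median"] == pytest.approx(1.0)
        assert s["n_decrease"] == 2 and s["n_increase"] == 2
        assert s["n_decrease"] + s["n_increase"] == s["n"]

    def test_constant_delta(self):
        base = np.full(3, 90.0)
        clin = make_clinical(base, base + 2.0, np.ones(3))
        cohort = generate_cohort(GeneratorConfig(n_subjects=3, n_features=2, n_signal=1, seed=0))
        cohort.clinical = clin
        s = summarize_response(cohort)
        assert s["sd"] == 0.0 and s["min"] == s["max"] == pytest.approx(2.0)

    def test_degenerate_cohort_rejected(self):
        cohort = generate_cohort(GeneratorConfig(n_subjects=5, n_features=2, n_signal=1, seed=0))
        cohort.clinical.data = cohort.clinical.data.iloc[:1]
        with pytest.raises(ValueError, match="at least 2"):
            summarize_response(cohort)

    def test_default_calibration_median_near_observed(self):
        """Over 50 seeds the median of per-cohort medians sits near
        0.8 mg/(dl·a), the cohort value the generator was calibrated to."""
        medians = [
            summarize_response(generate_cohort(GeneratorConfig(seed=s)))["median"]
            for s in range(50)
        ]
        assert abs(np.median(medians) - 0.8) < 0.5

    def test_default_calibration_sd_near_observed(self):
        sds = [
            summarize_response(generate_cohort(GeneratorConfig(seed=s)))["sd"]
            for s in range(20)
        ]
        assert np.median(sds) == pytest.approx(2.3, abs=0.4)


class TestRoundTrip:
    def test_write_read_cycle(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_subjects=20, n_features=8, n_signal=2, seed=9))
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(back.features.values, cohort.features.values)
        assert back.truth["signal_features"] == cohort.truth["signal_features"]
        pd.testing.assert_series_equal(
            compute_delta_glucose(back.clinical), compute_delta_glucose(cohort.clinical)
        )

    def test_missing_written_as_empty_cell(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_subjects=20, n_features=4, n_signal=1,
                                                 lod_quantile=0.2, seed=2))
        paths = write_cohort(cohort, tmp_path)
        text = paths["features"].read_text()
        assert "\t\t" in text or "\t\n" in text  # empty cells present
        assert "nan" not in text
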