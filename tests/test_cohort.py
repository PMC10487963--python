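"""Synthetic-cohort generator: validity, determinism, and oracle structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from immunoclock import (
    GeneratorParams,
    generate_cohort,
    generate_followup,
    stratified_subsample,
    true_quantile,
)
from immunoclock.cohort import BIOMARKER_COLUMNS, ValidationError, validate_cohort


class TestGeneratorParams:
    def test_defaults_valid(self, default_params):
        default_params.validate()

    @pytest.mark.parametrize("bad, field", [
        (dict(age_components=((18, 40, 0.5), (40, 97, 0.4))), "age_components"),
        (dict(age_components=((10, 40, 1.0),)), "age_components"),
        (dict(biomarker_noise_sd=(0.1, 0.1, 0.1, 0.1, -1)), "biomarker_noise_sd"),
        (dict(biomarker_loadings=(1, 1, 1)), "biomarker_loadings"),
        (dict(sigma0=-0.1, sigma1=0.0), "sigma0"),
        (dict(centile_drift_sd=-0.5), "centile_drift_sd"),
    ])
    def test_invalid_params_name_the_field(self, bad, field):
        with pytest.raises(ValidationError, match=field):
            GeneratorParams(**bad).validate()

    def test_dict_round_trip(self, default_params):
        assert GeneratorParams.from_dict(default_params.to_dict()) == default_params


class TestTrueQuantile:
    def test_median_is_inverse_logit_of_linear_predictor_when_symmetric(self):
        p = GeneratorParams(skew=0.0)
        for age in (20.0, 50.0, 90.0):
            assert true_quantile(0.5, age, p) == pytest.approx(
                expit(p.mu0 + p.mu1 * age), abs=1e-12)

    def test_median_centering_holds_for_skewed_noise(self, default_params):
        # the skewed standard quantile is centred at its own median, so the
        # median curve is skew-free by construction
        assert true_quantile(0.5, 40.0, default_params) == pytest.approx(
            expit(default_params.mu0 + default_params.mu1 * 40.0), abs=1e-12)

    def test_strictly_increasing_in_u_at_fixed_age(self, default_params):
        rng = np.random.default_rng(42)
        for _ in range(5):
            age = rng.uniform(18, 100)
            u = np.sort(rng.uniform(0.001, 0.999, 200))
            q = true_quantile(u, np.full(200, age), default_params)
            assert np.all(np.diff(q) > 0)

    def test_median_increasing_along_age_grid(self, default_params):
        ages = np.arange(20.0, 91.0)
        q = true_quantile(np.full(len(ages), 0.5), ages, default_params)
        assert np.all(np.diff(q) > 0) and np.all((q > 0) & (q < 1))

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.2, 1.3])
    def test_u_outside_open_unit_interval_rejected(self, u, default_params):
        with pytest.raises(ValidationError, match="u"):
            true_quantile(u, 50.0, default_params)


class TestGenerateCohort:
    def test_rejects_empty_request(self, default_params):
        with pytest.raises(ValidationError, match="n"):
            generate_cohort(0, default_params)

    def test_seeded_reproducibility(self, default_params):
        a = generate_cohort(50, default_params, seed=3)
        b = generate_cohort(50, default_params, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_records_satisfy_schema(self, cohort1600):
        assert len(cohort1600) == 1600
        assert not validate_cohort(cohort1600, require_biomarkers=True)
        assert cohort1600["true_centile"].between(0, 1, inclusive="neither").all()
        assert cohort1600["immax"].equals(cohort1600["immax"].clip(0, 1))

    def test_immax_matches_oracle_quantile(self, cohort1600, default_params):
        q = true_quantile(cohort1600["true_centile"].to_numpy(),
                          cohort1600["age_years"].to_numpy(), default_params)
        np.testing.assert_allclose(cohort1600["immax"].to_numpy(), q, atol=1e-12)

    def test_age_binned_median_immax_increases_with_age(self, default_params):
        cohort = generate_cohort(2000, default_params, seed=5)
        bins = pd.cut(cohort["age_years"], 10)
        med = cohort.groupby(bins, observed=True)["immax"].median()
        centers = [iv.mid for iv in med.index]
        assert spearmanr(centers, med.to_numpy()).statistic > 0.9

    def test_each_biomarker_correlates_positively_with_immax(self, default_params):
        cohort = generate_cohort(2000, default_params, seed=9)
        for col in BIOMARKER_COLUMNS:
            rho = spearmanr(cohort[col], cohort["immax"]).statistic
            assert rho > 0, f"{col}: expected positive association, got {rho:.3f}"


class TestGenerateFollowup:
    def test_zero_drift_preserves_centile_exactly(self, default_params):
        base = generate_cohort(100, default_params, seed=1)
        p0 = GeneratorParams(centile_drift_sd=0.0)
        fup = generate_followup(base, 5.0, p0, seed=1)
        np.testing.assert_array_equal(fup["true_centile"], base["true_centile"])
        np.testing.assert_allclose(fup["age_years"],
                                   np.minimum(base["age_years"] + 5.0, 100.0))

    def test_zero_drift_immax_increases_for_every_subject(self, default_params):
        base = generate_cohort(200, default_params, seed=2)
        fup = generate_followup(base, 5.0, GeneratorParams(centile_drift_sd=0.0), seed=2)
        assert np.all(fup["immax"].to_numpy() > base["immax"].to_numpy())

    def test_drift_is_centred(self):
        p = GeneratorParams(centile_drift_sd=0.05)
        base = generate_cohort(500, p, seed=4)
        fup = generate_followup(base, 5.0, p, seed=4)
        delta = fup["true_centile"].to_numpy() - base["true_centile"].to_numpy()
        assert abs(delta.mean()) < 0.02

    def test_requires_latent_centile(self, default_params):
        base = generate_cohort(10, default_params, seed=1).drop(columns="true_centile")
        with pytest.raises(ValidationError, match="synthetic"):
            generate_followup(base, 5.0, default_params)

    def test_seeded_determinism(self, default_params):
        base = generate_cohort(30, default_params, seed=8)
        a = generate_followup(base, 5.0, default_params, seed=8)
        b = generate_followup(base, 5.0, default_params, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestStratifiedSubsample:
    def test_partition_property(self, default_params):
        cohort = generate_cohort(1605, default_params, seed=6)
        sub, rem = stratified_subsample(cohort, 25, seed=0)
        assert len(sub) == 25 and len(rem) == 1580
        combined = set(sub["subject_id"]) | set(rem["subject_id"])
        assert combined == set(cohort["subject_id"])
        assert not (set(sub["subject_id"]) & set(rem["subject_id"]))

    def test_proportional_allocation_on_uniform_ages(self):
        # 80 subjects spread evenly over eight decades: 10 per decade,
        # largest-remainder allocation gives each decade its share +/- 1
        ages = np.linspace(18.01, 97.99, 80)
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(80)], "age_years": ages})
        sub, _ = stratified_subsample(cohort, 10, stratum_width=10.0, seed=1)
        counts = np.floor((sub["age_years"] - 18) / 10).astype(int).value_counts()
        assert all(abs(c - 10 * 10 / 80) <= 1 for c in counts)

    def test_oversized_request_rejected(self, default_params):
        cohort = generate_cohort(20, default_params, seed=1)
        with pytest.raises(ValidationError, match="n_out"):
            stratified_subsample(cohort, 20, seed=0)

    def test_deterministic_given_seed(self, default_params):
        cohort = generate_cohort(200, default_params, seed=2)
        s1, _ = stratified_subsample(cohort, 30, seed=5)
        s2, _ = stratified_subsample(cohort, 30, seed=5)
        pd.testing.assert_frame_equal(s1, s2)
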