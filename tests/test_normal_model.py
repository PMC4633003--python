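import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fvri.core import ValidationError
from fvri.io import Cohort
from fvri.normal_model import (
    DEFAULT_VESSEL_CODING,
    FALCAO2015_DEFAULT,
    NormalModelSpec,
    TERM_NAMES,
    bootstrap_fit,
    design_row,
    fit_ols,
    predict_eem,
    select_training_frames,
)
from fvri.simulate import DEFAULT_COEFFICIENTS, SimulationConfig, simulate_cohort


def normal_equations_oracle(X, y):
    """Independent brute-force least squares: solve the Gram system built
    from explicit sums, without calling any regression routine."""
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    gram = np.empty((p + 1, p + 1))
    moment = np.empty(p + 1)
    for a in range(p + 1):
        moment[a] = float(np.sum(Xc[:, a] * y))
        for b in range(p + 1):
            gram[a, b] = float(np.sum(Xc[:, a] * Xc[:, b]))
    return np.linalg.solve(gram, moment)


def random_training_frame(rng, n=40, n_patients=5):
    X = np.column_stack(
        [
            rng.integers(0, 2, n),
            rng.integers(0, 4, n),
            rng.uniform(0, 4.5, n),
            rng.uniform(1.4, 2.2, n),
        ]
    ).astype(float)
    beta = np.array([12.2, -1.14, -1.73, -1.28, 2.6])
    y = beta[0] + X @ beta[1:] + rng.normal(0, 2.0, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i % n_patients}" for i in range(n)],
            "lumen_area_mm2": y,
            "dominance_indicator": X[:, 0],
            "vessel_code": X[:, 1],
            "log_distance": X[:, 2],
            "bsa_m2": X[:, 3],
        }
    )


class TestDesignRow:
    def test_log_term_zero_at_one_mm(self):
        row = design_row(1.0, "LAD", 0, 1.8)
        assert row[2] == 0.0

    def test_ostial_distance_clamped(self):
        assert design_row(0.0, "RCA", 1, 1.8)[2] == 0.0

    def test_reference_levels(self):
        row = design_row(1.0, "LM", 0, 2.0)
        assert row.tolist() == [0.0, 0.0, 0.0, 2.0]

    def test_unknown_vessel_rejected(self):
        with pytest.raises(ValidationError, match="coding"):
            design_row(5.0, "RI", 0, 1.8)


class TestFitOls:
    def test_matches_normal_equations_oracle_on_random_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_ols(X, y)
            expected = normal_equations_oracle(X, y)
            assert fit.coefficients == pytest.approx(expected, abs=1e-10)

    def test_five_point_toy_design_matches_oracle(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.9, 12.2])
        fit = fit_ols(X, y)
        assert fit.coefficients == pytest.approx(
            normal_equations_oracle(X, y), abs=1e-10
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        perm = rng.permutation(25)
        a = fit_ols(X, y).coefficients
        b = fit_ols(X[perm], y[perm]).coefficients
        assert a == pytest.approx(b, abs=1e-12)

    def test_exactly_linear_response_gives_adjusted_r2_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = 2.0 + X @ np.array([1.0, -0.5, 0.25, 3.0])
        fit = fit_ols(X, y)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-12)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        y = X[:, 0] + rng.normal(size=50)
        fit = fit_ols(X, y)
        n, p = 50, 2
        expected = 1 - (1 - fit.r2) * (n - 1) / (n - p - 1)
        assert fit.adjusted_r2 == pytest.approx(expected, abs=1e-12)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x, rng.normal(size=30), rng.normal(size=30)])
        with pytest.raises(ValidationError, match="dominance.*vessel"):
            fit_ols(X, rng.normal(size=30))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError, match="rows"):
            fit_ols(np.ones((4, 1)), np.ones(4))


class TestBootstrapFit:
    def test_degenerate_bootstrap_equals_point_fit(self):
        training = random_training_frame(np.random.default_rng(21))
        X = training[
            ["dominance_indicator", "vessel_code", "log_distance", "bsa_m2"]
        ].to_numpy()
        point = fit_ols(X, training["lumen_area_mm2"].to_numpy())
        spec = bootstrap_fit(training, n_bootstrap=1, seed=0, resample_unit="none")
        assert spec.coefficients == pytest.approx(point.coefficients, abs=1e-12)
        assert spec.adjusted_r2 == pytest.approx(point.adjusted_r2, abs=1e-12)

    def test_same_seed_bit_identical_different_seed_not(self):
        training = random_training_frame(np.random.default_rng(22), n=60)
        a = bootstrap_fit(training, n_bootstrap=50, seed=123)
        b = bootstrap_fit(training, n_bootstrap=50, seed=123)
        c = bootstrap_fit(training, n_bootstrap=50, seed=124)
        assert a.coefficients.tolist() == b.coefficients.tolist()
        assert a.ci_low == b.ci_low
        assert a.coefficients.tolist() != c.coefficients.tolist()

    def test_seed_required(self):
        training = random_training_frame(np.random.default_rng(23))
        with pytest.raises(ValidationError, match="seed"):
            bootstrap_fit(training, n_bootstrap=10)

    def test_bootstrap_mean_near_point_fit(self):
        training = random_training_frame(np.random.default_rng(24), n=200, n_patients=20)
        X = training[
            ["dominance_indicator", "vessel_code", "log_distance", "bsa_m2"]
        ].to_numpy()
        point = fit_ols(X, training["lumen_area_mm2"].to_numpy())
        spec = bootstrap_fit(training, n_bootstrap=800, seed=5, resample_unit="frame")
        half_width = np.array(
            [spec.ci_high[k] - spec.ci_low[k] for k in TERM_NAMES]
        ) / 2
        assert np.all(np.abs(spec.coefficients - point.coefficients) < half_width)

    def test_zero_noise_simulation_recovers_generating_coefficients(self):
        cfg = SimulationConfig(
            seed=77, n_patients=8, lumen_noise_cv=0.0, measurement_noise_sd_mm2=0.0
        )
        sim = simulate_cohort(cfg)
        training = select_training_frames(sim.cohort)
        X = training[
            ["dominance_indicator", "vessel_code", "log_distance", "bsa_m2"]
        ].to_numpy()
        fit = fit_ols(X, training["lumen_area_mm2"].to_numpy())
        assert fit.coefficients == pytest.approx(
            np.array(DEFAULT_COEFFICIENTS), abs=1e-8
        )


class TestPredict:
    def test_packaged_constant_at_reference_covariates(self):
        # LM at 1 mm, right dominance, BSA set to zero isolates the intercept
        assert predict_eem(FALCAO2015_DEFAULT, 1.0, "LM", 0, 0.0) == pytest.approx(
            12.20, abs=1e-12
        )

    def test_bsa_contribution(self):
        # 12.20 from the constant term plus 2 m2 * 2.60 mm2/m2
        value = predict_eem(FALCAO2015_DEFAULT, 1.0, "LM", 0, 2.0)
        assert value == pytest.approx(17.40, abs=1e-12)

    def test_zero_slopes_give_constant_prediction(self):
        spec = NormalModelSpec(
            intercept=10.0,
            beta_dominance=0.0,
            beta_vessel=0.0,
            beta_log_distance=0.0,
            beta_bsa=0.0,
            ci_low={k: -1.0 if k != "intercept" else 9.0 for k in TERM_NAMES},
            ci_high={k: 1.0 if k != "intercept" else 11.0 for k in TERM_NAMES},
            adjusted_r2=0.0,
            n_bootstrap=1,
        )
        for d, v in ((1.0, "LM"), (40.0, "RCA"), (75.0, "LCX")):
            assert predict_eem(spec, d, v, 1, 1.8) == 10.0

    def test_out_of_range_prediction_warns_not_clamps(self):
        with pytest.warns(UserWarning, match="outside"):
            value = predict_eem(FALCAO2015_DEFAULT, 1.0, "LM", 0, 3.5)
        assert value == pytest.approx(12.20 + 3.5 * 2.60, abs=1e-12)

    @given(
        a=st.tuples(*[st.floats(-2, 2) for _ in range(4)]),
        b=st.tuples(*[st.floats(-2, 2) for _ in range(4)]),
    )
    def test_prediction_is_affine(self, a, b):
        spec = FALCAO2015_DEFAULT
        a, b = np.array(a), np.array(b)
        lhs = spec.linear_predictor(a) + spec.linear_predictor(b) - spec.linear_predictor(
            np.zeros(4)
        )
        rhs = spec.linear_predictor(a + b)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestSelectTrainingFrames:
    @staticmethod
    def cohort_from_burdens(burdens, lumens):
        n = len(burdens)
        lumen = np.asarray(lumens, dtype=float)
        eem = lumen / (1 - np.asarray(burdens, dtype=float) / 100.0)
        frames = pd.DataFrame(
            {
                "patient_id": "P001",
                "artery_id": "P001-LAD",
                "vessel": "LAD",
                "frame_index": np.arange(n),
                "distance_mm": 0.3 * (np.arange(n) + 1),
                "lumen_area_mm2": lumen,
                "eem_area_mm2": eem,
            }
        )
        patients = pd.DataFrame(
            {
                "patient_id": ["P001"],
                "weight_kg": [72.0],
                "height_cm": [161.6],
                "bsa_m2": [1.8],
                "dominance": ["right"],
                "dominance_indicator": [0],
            }
        )
        return Cohort(frames=frames, patients=patients)

    def test_burden_threshold_is_strict(self):
        cohort = self.cohort_from_burdens([10, 19.9, 20, 35], [8.0, 8.0, 8.0, 8.0])
        assert len(select_training_frames(cohort)) == 2

    def test_lumen_window_inclusive_bounds(self):
        cohort = self.cohort_from_burdens(
            [5, 5, 5, 5], [2.9, 3.1, 19.6, 19.7]
        )
        selected = select_training_frames(cohort)
        assert sorted(selected["lumen_area_mm2"]) == [3.1, 19.6]

    def test_empty_selection_advises_larger_input(self):
        cohort = self.cohort_from_burdens([50, 60], [5.0, 5.0])
        with pytest.raises(ValidationError, match="larger"):
            select_training_frames(cohort)

    def test_selected_fraction_tracks_low_burden_fraction(self, small_sim):
        from fvri.core import add_geometry

        training = select_training_frames(small_sim.cohort)
        burden = add_geometry(small_sim.frames)["plaque_burden_pct"]
        low_burden_frac = float((burden < 20).mean())
        assert len(training) / len(small_sim.frames) == pytest.approx(
            low_burden_frac, abs=0.03
        )


class TestModelSpec:
    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "model.json"
        FALCAO2015_DEFAULT.to_json(path)
        loaded = NormalModelSpec.from_json(path)
        assert loaded == FALCAO2015_DEFAULT

    def test_ci_must_bracket_coefficient(self):
        bad = json.loads(json.dumps(FALCAO2015_DEFAULT.to_dict()))
        bad["ci_low"]["bsa"] = 3.0  # above the 2.60 coefficient
        with pytest.raises(ValidationError, match="outside its CI"):
            NormalModelSpec.from_dict(bad)

    def test_packaged_coding_is_ordinal(self):
        assert FALCAO2015_DEFAULT.vessel_coding == DEFAULT_VESSEL_CODING
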