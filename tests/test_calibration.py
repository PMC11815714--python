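"""Range-error corrector: split, training, prediction, model selection."""

import dataclasses

import numpy as np
import pytest

from uwbid.calibration import (
    CalibrationDataset,
    TrainConfig,
    RangeCalibrator,
    load_model,
    predict,
    read_calibration_csv,
    rmse_1d,
    save_model,
    select_hidden_size,
    split_dataset,
    train,
    write_calibration_csv,
)
from uwbid.simulate import SimConfig, simulate_calibration_sweep


def biased_dataset(seed: int, n: int = 200) -> CalibrationDataset:
    rng = np.random.default_rng(seed)
    true = np.repeat(np.arange(1.0, 21.0), n // 20)
    measured = 1.002 * true + 0.15 + rng.normal(0.0, 0.02, true.size)
    return CalibrationDataset(np.maximum(measured, 0.0), true, split_seed=seed)


class TestSplit:
    def test_70_30_split_of_200(self):
        ds = biased_dataset(0)
        tr, te = split_dataset(ds, 0.7)
        assert len(tr) == 140 and len(te) == 60
        merged = np.sort(np.concatenate([tr.true, te.true]))
        assert np.array_equal(merged, np.sort(ds.true))

    def test_same_seed_reproduces_split(self):
        ds = biased_dataset(5, n=20)
        a = split_dataset(ds, 0.5)
        b = split_dataset(ds, 0.5)
        assert np.array_equal(a[0].measured, b[0].measured)

    def test_different_seed_permutes_membership(self):
        base = biased_dataset(1, n=20)
        other = CalibrationDataset(base.measured, base.true, split_seed=99)
        a, _ = split_dataset(base, 0.5)
        b, _ = split_dataset(other, 0.5)
        assert len(a) == len(b) == 10
        assert not np.array_equal(a.measured, b.measured)

    def test_too_small_dataset_raises(self):
        ds = CalibrationDataset([1.0], [1.0])
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset(ds, 0.5)


class TestTraining:
    def test_learns_identity_on_unbiased_data(self):
        rng = np.random.default_rng(0)
        true = rng.uniform(1.0, 20.0, 200)
        ds = CalibrationDataset(true, true, split_seed=0)
        tr, te = split_dataset(ds, 0.7)
        model = train(tr, 6, TrainConfig(seed=0))
        mse = float(np.mean((np.asarray(predict(model, te.measured)) - te.true) ** 2))
        assert mse < 1e-4
        assert predict(model, 7.0) == pytest.approx(7.0, abs=0.02)

    def test_corrects_injected_bias(self):
        ds = biased_dataset(42)
        tr, te = split_dataset(ds, 0.7)
        model = train(tr, 6, TrainConfig(seed=42))
        uncorrected = rmse_1d(te.measured, te.true)
        corrected = rmse_1d(predict(model, te.measured), te.true)
        assert corrected < 0.5 * uncorrected
        # inverse of the +0.15 m offset: 10.15 measured ~ 10.0 true
        assert predict(model, 10.15 + 0.002 * 10.0) == pytest.approx(10.0, abs=0.04)

    def test_error_reduction_across_seed_suite(self):
        """Bias magnitude >> noise s.d. must always be reduced."""
        for seed in range(10):
            ds = biased_dataset(seed)
            tr, te = split_dataset(ds, 0.7)
            model = train(tr, 6, TrainConfig(seed=seed))
            assert rmse_1d(predict(model, te.measured), te.true) < rmse_1d(
                te.measured, te.true
            )

    def test_divergence_raises_with_rate_in_message(self):
        ds = biased_dataset(0)
        tr, _ = split_dataset(ds, 0.7)
        # disable step rejection so the runaway rate actually overflows
        with pytest.raises(FloatingPointError, match="learning_rate"):
            train(
                tr,
                6,
                TrainConfig(
                    learning_rate=1e6, max_error_growth=1e300, lr_up=2.0, seed=0
                ),
            )

    def test_deterministic_given_seed(self):
        ds = biased_dataset(7)
        tr, _ = split_dataset(ds, 0.7)
        m1 = train(tr, 5, TrainConfig(seed=3))
        m2 = train(tr, 5, TrainConfig(seed=3))
        assert np.array_equal(m1.hidden_weights, m2.hidden_weights)
        assert m1.output_bias == m2.output_bias


class TestPredict:
    def test_finite_and_bounded_on_dense_grid(self):
        ds = biased_dataset(11)
        tr, _ = split_dataset(ds, 0.7)
        model = train(tr, 6, TrainConfig(seed=11))
        grid = np.linspace(0.0, 25.0, 2001)
        out = np.asarray(predict(model, grid))
        assert np.all(np.isfinite(out))
        assert np.all(out >= 0.0)
        # tanh network output is bounded by the denormalised saturation level
        bound = abs(model.output_norm[0]) + model.output_norm[1] * (
            np.abs(model.output_weights).sum() + abs(model.output_bias)
        )
        assert np.all(out <= bound + 1e-9)

    def test_continuity_on_grid(self):
        ds = biased_dataset(11)
        tr, _ = split_dataset(ds, 0.7)
        model = train(tr, 6, TrainConfig(seed=11))
        grid = np.linspace(0.0, 25.0, 5001)
        out = np.asarray(predict(model, grid))
        assert np.max(np.abs(np.diff(out))) < 0.1  # no jumps at 5 mm spacing


class TestRmse1d:
    def test_hand_examples(self):
        assert rmse_1d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        assert rmse_1d([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(
            np.sqrt(1.0 / 3.0)
        )
        assert rmse_1d([7.1], [7.0]) == pytest.approx(0.1)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=17)
            b = rng.normal(size=17)
            brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 17)
            assert rmse_1d(a, b) == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rmse_1d([1.0, 2.0], [1.0])


class TestHiddenSizeSelection:
    def test_sweep_produces_selection_table(self):
        ds = simulate_calibration_sweep(SimConfig(seed=2))
        best, table = select_hidden_size(ds, range(4, 10), TrainConfig(seed=2))
        assert list(table["hidden_nodes"]) == [4, 5, 6, 7, 8, 9]
        assert set(table.columns) == {"hidden_nodes", "train_rmse_m", "test_rmse_m"}
        assert best == int(table.loc[table["test_rmse_m"].idxmin(), "hidden_nodes"])

    def test_single_candidate(self):
        ds = biased_dataset(3)
        best, table = select_hidden_size(ds, [5], TrainConfig(seed=3))
        assert best == 5 and len(table) == 1

    def test_tie_breaks_to_smaller_width(self, monkeypatch):
        import uwbid.calibration as cal

        ds = biased_dataset(4)
        monkeypatch.setattr(
            cal, "rmse_1d", lambda p, a: 0.5
        )  # force identical scores
        best, _ = select_hidden_size(ds, [8, 4, 6], TrainConfig(max_epochs=1, seed=0))
        assert best == 4

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError, match="non-empty"):
            select_hidden_size(biased_dataset(0), [], TrainConfig(max_epochs=1))


class TestPersistence:
    def test_model_json_round_trip(self, tmp_path):
        ds = biased_dataset(9)
        tr, _ = split_dataset(ds, 0.7)
        model = train(tr, 4, TrainConfig(seed=9, max_epochs=500))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        grid = np.linspace(0.0, 22.0, 100)
        assert np.allclose(predict(back, grid), predict(model, grid))

    def test_dataset_csv_round_trip(self, tmp_path):
        ds = biased_dataset(1)
        path = tmp_path / "cal.csv"
        write_calibration_csv(ds, path)
        back = read_calibration_csv(path, split_seed=1)
        assert np.allclose(back.measured, ds.measured, atol=1e-8)
        assert np.allclose(back.true, ds.true, atol=1e-8)


def test_calibrator_wrapper_fit_predict():
    ds = biased_dataset(6)
    calib = RangeCalibrator(hidden_size=6, config=TrainConfig(seed=6)).fit(ds)
    _, te = split_dataset(ds, 0.7)
    assert rmse_1d(calib.predict(te.measured), te.true) < rmse_1d(te.measured, te.true)
    with pytest.raises(RuntimeError):
        RangeCalibrator().predict(5.0)
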