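"""Hierarchical-network construction, parameter counts, training basics."""

import numpy as np
import pandas as pd
import pytest

from filmcal import synthetic_film as sf
from filmcal.features import features_from_table
from filmcal.hnn import (HNNCalibration, HNNModel, SubnetSpec, TrainConfig,
                         build_hnn, count_params, default_subnet_specs,
                         predict_H, train_hnn)


def _noiseless_samples(mu_list=(100.0, 300.0), n_ages=1):
    config = sf.SimConfig(noise_sigma=0.0)
    rng = np.random.default_rng(0)
    lot = sf.default_lot()
    frames = [sf.simulate_calibration_film(mu, lot, 0.0, config, rng)
              for mu in mu_list]
    return features_from_table(pd.concat(frames, ignore_index=True))


class TestParameterCounts:
    @pytest.mark.parametrize("name,expected", [
        ("O1", 335), ("O2", 126), ("O3", 115), ("O4", 115),
        ("O5", 180), ("O6", 125), ("O7", 213),
    ])
    def test_each_subnet(self, name, expected):
        spec = next(s for s in default_subnet_specs() if s.name == name)
        assert spec.n_params == expected

    def test_total_is_1209(self):
        assert count_params(default_subnet_specs()) == 1209
        assert build_hnn(seed=0).n_params == 1209

    def test_trivial_linear_spec(self):
        spec = SubnetSpec("tiny", (1, 1), ("linear",))
        assert spec.n_params == 2


class TestBuild:
    def test_same_seed_same_initial_weights(self):
        a, b = build_hnn(seed=435), build_hnn(seed=435)
        for name in a.subnets:
            for wa, wb in zip(a.subnets[name].W, b.subnets[name].W):
                np.testing.assert_array_equal(wa, wb)

    def test_different_seed_different_weights(self):
        a, b = build_hnn(seed=1), build_hnn(seed=2)
        assert not np.array_equal(a.subnets["O1"].W[0], b.subnets["O1"].W[0])

    def test_initial_weights_uniform_in_range(self):
        m = build_hnn(seed=7)
        for net in m.subnets.values():
            for w in net.W:
                assert np.all(np.abs(w) <= 0.05)

    def test_topology_mismatch_rejected(self):
        specs = default_subnet_specs()
        bad = [SubnetSpec("O1", (1, 19, 10, 7, 1), ("selu",) * 3 + ("linear",))
               if s.name == "O1" else s for s in specs]
        with pytest.raises(ValueError, match="topology"):
            build_hnn(specs=bad)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            SubnetSpec("O3", (2, 10, 7, 1), ("tanh", "relu", "linear"))

    def test_untrained_model_refuses_to_predict(self):
        with pytest.raises(RuntimeError, match="untrained"):
            build_hnn(seed=0).predict(np.zeros((3, 10)))


class TestTraining:
    CFG = TrainConfig(epochs=40, seed=435)

    def test_training_is_seed_deterministic(self):
        feats = _noiseless_samples()
        r1 = HNNCalibration(feats).fit(self.CFG)
        r2 = HNNCalibration(feats).fit(self.CFG)
        for name in r1.model.subnets:
            for wa, wb in zip(r1.model.subnets[name].W,
                              r2.model.subnets[name].W):
                np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(r1.predict(feats), r2.predict(feats))

    def test_constant_dose_converges_to_constant(self):
        feats = _noiseless_samples().copy()
        feats["dose_cGy"] = 200.0
        res = HNNCalibration(feats).fit(TrainConfig(epochs=60, seed=435))
        pred = res.predict(feats)
        np.testing.assert_allclose(pred, 200.0, atol=2.0)

    def test_history_schema_and_loss_decreases(self):
        feats = _noiseless_samples()
        res = HNNCalibration(feats).fit(self.CFG)
        h = res.history
        assert list(h.columns) == ["epoch", "mse", "mae", "accuracy",
                                   "val_mse", "val_mae"]
        assert len(h) == self.CFG.epochs
        assert h["mse"].iloc[-1] < h["mse"].iloc[0]

    def test_functional_wrappers_round_trip(self):
        feats = _noiseless_samples()
        model = build_hnn(seed=435)
        train_hnn(model, feats, TrainConfig(epochs=10, seed=435))
        H = predict_H(model, feats)
        assert H.shape == (len(feats),)
        assert np.all(np.isfinite(H))

    def test_too_few_samples_rejected(self):
        feats = _noiseless_samples().iloc[:10]
        with pytest.raises(ValueError, match="batch"):
            HNNCalibration(feats).fit(self.CFG)


class TestConvergence:
    def test_noiseless_training_reaches_few_cGy_mae(self):
        """~2000 noiseless samples, default protocol: training MAE <= 3 cGy."""
        config = sf.SimConfig(noise_sigma=0.0)
        rng = np.random.default_rng(0)
        lot = sf.default_lot()
        frames = [sf.simulate_calibration_film(mu, lot, age, config, rng)
                  for age in (0.0, 4.0) for mu in (100.0, 200.0, 300.0, 400.0)]
        feats = features_from_table(pd.concat(frames, ignore_index=True))
        assert len(feats) > 1800
        res = HNNCalibration(feats).fit(TrainConfig(seed=435))
        assert res.final_mae <= 3.0
        assert res.history["val_mae"].iloc[-1] <= 3.0


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        feats = _noiseless_samples()
        res = HNNCalibration(feats).fit(TrainConfig(epochs=15, seed=435))
        path = tmp_path / "model.json"
        res.model.save(path)
        loaded = HNNModel.load(path)
        np.testing.assert_allclose(loaded.predict(feats), res.predict(feats),
                                   rtol=1e-12)
        assert loaded.n_params == 1209


class TestMonotonicity:
    def test_predictions_monotone_in_dose_on_noiseless_lot(self):
        feats = _noiseless_samples(mu_list=(100.0, 200.0, 300.0, 400.0))
        res = HNNCalibration(feats).fit(TrainConfig(epochs=150, seed=435))
        # probe on a clean dose grid spanning the training range
        config = sf.SimConfig(noise_sigma=0.0)
        rng = np.random.default_rng(1)
        lot = sf.default_lot()
        doses = np.linspace(feats.dose_cGy.min(), feats.dose_cGy.max(), 60)
        rows = {}
        for ch in "RGB":
            pre, post = sf.simulate_pv(doses, ch, lot, 0.0, rng)
            rows[f"{ch}_bpv"], rows[f"{ch}_ipv"] = pre, post
        grid = pd.DataFrame(rows)
        grid["dose_cGy"] = doses
        gf = features_from_table(grid)
        pred = res.predict(gf)
        assert np.all(np.diff(pred) > 0)
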