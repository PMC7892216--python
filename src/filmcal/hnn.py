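"""The seven-subnet hierarchical dose network.

Five leaf subnets each digest one input group — O1 the red-channel net
optical density, O2/O3/O4 the per-channel irradiated+background pixel-value
pairs, O5 the three inverse transmittances.  A combining subnet O6 merges
the three pixel-value subnets, and the head O7 merges O1, O5 and O6 into
the dose estimate H (cGy):

    O6 = f(O2, O3, O4)        O7 = f(O1, O5, O6)

Fixed topology (1209 trainable parameters in total):

    O1: 1-20-10-7-1   O2: 2-10-7-2-1   O3: 2-10-7-1   O4: 2-10-7-1
    O5: 3-15-7-1      O6: 3-10-7-1     O7: 3-20-6-1

The graph is trained end-to-end (a single mean-squared-error loss at O7)
with Adam, mini-batches of 20, 500 epochs, and 45% of the samples held
back for validation.  Intermediate subnet outputs carry no auxiliary
losses.  Because the background pixel values drift with film shelf age,
subnets O2–O4 give the network an age signal and let it compensate the
aging effect that defeats a fixed net-OD calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, FeatureVector
from .nnet import ACTIVATIONS, MLP, Adam

__all__ = [
    "SubnetSpec",
    "TrainConfig",
    "HNNModel",
    "HNNCalibration",
    "HNNResults",
    "default_subnet_specs",
    "build_hnn",
    "train_hnn",
    "predict_H",
    "count_params",
]


@dataclass(frozen=True)
class SubnetSpec:
    """Topology of one subnet: layer widths and per-layer activations."""

    name: str
    layer_sizes: tuple
    activations: tuple

    def __post_init__(self):
        if len(self.activations) != len(self.layer_sizes) - 1:
            raise ValueError(f"{self.name}: one activation per non-input layer")
        if self.layer_sizes[-1] != 1:
            raise ValueError(f"{self.name}: final layer must have size 1")
        for a in self.activations:
            if a not in ACTIVATIONS:
                raise ValueError(f"{self.name}: unknown activation {a!r}")

    @property
    def n_params(self) -> int:
        return sum(m * n + n for m, n in
                   zip(self.layer_sizes[:-1], self.layer_sizes[1:]))


#: Required layer widths for the seven subnets.
TOPOLOGY = {
    "O1": (1, 20, 10, 7, 1),
    "O2": (2, 10, 7, 2, 1),
    "O3": (2, 10, 7, 1),
    "O4": (2, 10, 7, 1),
    "O5": (3, 15, 7, 1),
    "O6": (3, 10, 7, 1),
    "O7": (3, 20, 6, 1),
}

# Hidden-layer activation per subnet.  The published architecture names
# selu/elu/relu/softplus/linear without mapping them to layers; this
# assignment is this package's choice and is configurable through the
# SubnetSpec list.  The background-PV subnets O2-O4 get *linear* hidden
# layers: their job is to extract the shelf-age proxy, which is linear in
# the pixel values, and a linear block extrapolates that proxy exactly to
# shelf ages beyond the training range (nonlinear blocks were measured to
# leave a systematic dose bias on aged films).  Every subnet's output
# layer is linear.
_DEFAULT_HIDDEN = {
    "O1": "selu", "O2": "linear", "O3": "linear", "O4": "linear",
    "O5": "softplus", "O6": "selu", "O7": "selu",
}

#: Feature-column indices feeding each leaf subnet (the five input groups).
GROUP_SLICES = {
    "O1": [0],          # r_nod
    "O2": [1, 2],       # r_ipv, r_bpv
    "O3": [3, 4],       # g_ipv, g_bpv
    "O4": [5, 6],       # b_ipv, b_bpv
    "O5": [7, 8, 9],    # r_it, g_it, b_it
}


def default_subnet_specs() -> list[SubnetSpec]:
    specs = []
    for name, sizes in TOPOLOGY.items():
        hidden = _DEFAULT_HIDDEN[name]
        acts = (hidden,) * (len(sizes) - 2) + ("linear",)
        specs.append(SubnetSpec(name=name, layer_sizes=sizes, activations=acts))
    return specs


def count_params(specs) -> int:
    """Analytic parameter count: sum over layers of fan_in*fan_out + fan_out."""
    return sum(s.n_params for s in specs)


@dataclass
class TrainConfig:
    """Training protocol for the hierarchical network."""

    batch_size: int = 20
    epochs: int = 500
    validation_split: float = 0.45
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 435
    #: standardise inputs and target inside fit (inverted at predict time);
    #: a numerical conditioning choice, not a feature redefinition.
    scale_inputs: bool = True

    def __post_init__(self):
        if not 0 < self.validation_split < 1:
            raise ValueError("validation_split must be in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


class HNNModel:
    """The wired seven-subnet graph with its weights.

    Leaf subnets read their feature-group slices; O6 consumes the scalar
    outputs of O2, O3, O4 and O7 consumes those of O1, O5, O6.  ``seed``
    fixes the uniform weight initialisation.
    """

    def __init__(self, specs=None, seed: int = 435):
        specs = list(specs) if specs is not None else default_subnet_specs()
        by_name = {s.name: s for s in specs}
        if set(by_name) != set(TOPOLOGY):
            raise ValueError("specs must name exactly O1..O7")
        for name, sizes in TOPOLOGY.items():
            if tuple(by_name[name].layer_sizes) != sizes:
                raise ValueError(
                    f"{name}: layer sizes {by_name[name].layer_sizes} do not "
                    f"match the fixed topology {sizes}")
        self.specs = [by_name[n] for n in TOPOLOGY]
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.subnets = {
            s.name: MLP(s.layer_sizes, s.activations, rng) for s in self.specs
        }
        self.trained = False
        # fitted scalers (identity until training sets them)
        self.x_mean = np.zeros(len(FEATURE_COLUMNS))
        self.x_scale = np.ones(len(FEATURE_COLUMNS))
        self.y_mean = 0.0
        self.y_scale = 1.0
        self.history: pd.DataFrame | None = None

    @property
    def n_params(self) -> int:
        return sum(net.n_params for net in self.subnets.values())

    # -- forward / backward over the DAG -------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        leaf = {n: self.subnets[n].forward(X[:, GROUP_SLICES[n]], cache)
                for n in ("O1", "O2", "O3", "O4", "O5")}
        in6 = np.hstack([leaf["O2"], leaf["O3"], leaf["O4"]])
        o6 = self.subnets["O6"].forward(in6, cache)
        in7 = np.hstack([leaf["O1"], leaf["O5"], o6])
        return self.subnets["O7"].forward(in7, cache)

    def _backward(self, grad_h: np.ndarray) -> dict:
        grads = {}
        dW, db, d_in7 = self.subnets["O7"].backward(grad_h)
        grads["O7"] = (dW, db)
        dW, db, d_in6 = self.subnets["O6"].backward(d_in7[:, 2:3])
        grads["O6"] = (dW, db)
        for i, name in enumerate(("O2", "O3", "O4")):
            dW, db, _ = self.subnets[name].backward(d_in6[:, i:i + 1])
            grads[name] = (dW, db)
        for col, name in ((0, "O1"), (1, "O5")):
            dW, db, _ = self.subnets[name].backward(d_in7[:, col:col + 1])
            grads[name] = (dW, db)
        return grads

    def _params_flat(self):
        out = []
        for name in TOPOLOGY:
            out.extend(self.subnets[name].params())
        return out

    def _grads_flat(self, grads):
        out = []
        for name in TOPOLOGY:
            dW, db = grads[name]
            out.extend(self.subnets[name].grads_in_order(dW, db))
        return out

    # -- prediction -----------------------------------------------------

    def predict(self, features) -> np.ndarray:
        """Dose estimates H (cGy), one per feature row."""
        if not self.trained:
            raise RuntimeError("model is untrained; call train first")
        X = _as_feature_matrix(features)
        Xs = (X - self.x_mean) / self.x_scale
        h = self._forward(Xs)
        return (h[:, 0] * self.y_scale + self.y_mean)

    # -- serialisation: JSON header + flat weight arrays ----------------

    def save(self, path) -> None:
        payload = {
            "format": "filmcal-hnn-1",
            "seed": self.seed,
            "trained": self.trained,
            "specs": [asdict(s) for s in self.specs],
            "scalers": {
                "x_mean": self.x_mean.tolist(),
                "x_scale": self.x_scale.tolist(),
                "y_mean": self.y_mean,
                "y_scale": self.y_scale,
            },
            "weights": {
                name: {
                    "W": [w.tolist() for w in net.W],
                    "b": [b.tolist() for b in net.b],
                }
                for name, net in self.subnets.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HNNModel":
        with open(path) as fh:
            payload = json.load(fh)
        specs = [SubnetSpec(name=s["name"],
                            layer_sizes=tuple(s["layer_sizes"]),
                            activations=tuple(s["activations"]))
                 for s in payload["specs"]]
        model = cls(specs=specs, seed=payload["seed"])
        for name, net in model.subnets.items():
            wdict = payload["weights"][name]
            net.W = [np.asarray(w, dtype=float) for w in wdict["W"]]
            net.b = [np.asarray(b, dtype=float) for b in wdict["b"]]
        sc = payload["scalers"]
        model.x_mean = np.asarray(sc["x_mean"], dtype=float)
        model.x_scale = np.asarray(sc["x_scale"], dtype=float)
        model.y_mean = float(sc["y_mean"])
        model.y_scale = float(sc["y_scale"])
        model.trained = bool(payload["trained"])
        return model


def _as_feature_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if isinstance(features, (list, tuple)) and features and \
            isinstance(features[0], FeatureVector):
        return np.vstack([f.as_array() for f in features])
    if isinstance(features, FeatureVector):
        return features.as_array()[None, :]
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected {len(FEATURE_COLUMNS)} feature columns")
    return X


class HNNCalibration:
    """Hierarchical-network dose calibration model.

    Parameters
    ----------
    features : DataFrame with the ten feature columns, list of
        FeatureVector, or (n, 10) array.
    dose : array-like of delivered doses (cGy); if ``features`` is a
        DataFrame containing ``dose_cGy`` it may be omitted.
    specs : optional list of SubnetSpec overriding the default activations.

    ``fit(config)`` trains the graph end-to-end and returns an
    :class:`HNNResults`.
    """

    def __init__(self, features, dose=None, specs=None):
        if dose is None:
            if not (isinstance(features, pd.DataFrame) and "dose_cGy" in features):
                raise ValueError("dose required unless features has dose_cGy")
            dose = features["dose_cGy"]
        self.X = _as_feature_matrix(features)
        self.y = np.asarray(dose, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("features and dose must have equal length")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("features and dose must be finite")
        self.specs = specs

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, specs=None) -> "HNNCalibration":
        return cls(frame, specs=specs)

    def fit(self, config: TrainConfig | None = None) -> "HNNResults":
        config = config or TrainConfig()
        n = self.y.size
        if n < config.batch_size:
            raise ValueError("need at least one full batch of samples")
        model = HNNModel(specs=self.specs, seed=config.seed)
        _train(model, self.X, self.y, config)
        return HNNResults(model=model, config=config,
                          n_samples=n, history=model.history)


def _train(model: HNNModel, X: np.ndarray, y: np.ndarray,
           config: TrainConfig) -> None:
    n = y.size
    rng = np.random.default_rng(config.seed)
    # reproducible hold-out: seeded shuffle, then the tail fraction
    perm = rng.permutation(n)
    n_val = int(np.floor(n * config.validation_split))
    train_idx, val_idx = perm[:n - n_val], perm[n - n_val:]

    if config.scale_inputs:
        model.x_mean = X[train_idx].mean(axis=0)
        model.x_scale = X[train_idx].std(axis=0)
        model.x_scale[model.x_scale == 0] = 1.0
        model.y_mean = float(y[train_idx].mean())
        model.y_scale = float(y[train_idx].std()) or 1.0
    Xs = (X - model.x_mean) / model.x_scale
    ys = (y - model.y_mean) / model.y_scale

    Xtr, ytr = Xs[train_idx], ys[train_idx]
    Xval, yval = Xs[val_idx], ys[val_idx]
    opt = Adam(model._params_flat(), lr=config.learning_rate)
    y2 = model.y_scale ** 2
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx.size)
        sq_sum = abs_sum = acc_sum = 0.0
        for start in range(0, order.size, config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb = Xtr[batch], ytr[batch]
            pred = model._forward(xb, cache=True)[:, 0]
            err = pred - yb
            if not np.all(np.isfinite(err)):
                raise FloatingPointError(
                    f"training loss became non-finite at epoch {epoch + 1}")
            grads = model._backward((2.0 / batch.size) * err[:, None])
            opt.step(model._grads_flat(grads))
            sq_sum += float(err @ err)
            abs_sum += float(np.abs(err).sum())
            acc_sum += float(np.count_nonzero(pred == yb))
        vpred = model._forward(Xval)[:, 0]
        verr = vpred - yval
        rows.append({
            "epoch": epoch + 1,
            "mse": sq_sum / order.size * y2,
            "mae": abs_sum / order.size * model.y_scale,
            # exact-match "accuracy": recorded for protocol completeness,
            # meaningless for regression
            "accuracy": acc_sum / order.size,
            "val_mse": float(verr @ verr) / max(verr.size, 1) * y2,
            "val_mae": float(np.abs(verr).mean()) * model.y_scale
            if verr.size else np.nan,
        })
    model.history = pd.DataFrame(rows)
    model.trained = True


@dataclass
class HNNResults:
    """Trained-network results: weights, history and diagnostics."""

    model: HNNModel
    config: TrainConfig
    n_samples: int
    history: pd.DataFrame = field(repr=False, default=None)

    def predict(self, features) -> np.ndarray:
        return self.model.predict(features)

    @property
    def final_mse(self) -> float:
        return float(self.history["mse"].iloc[-1])

    @property
    def final_mae(self) -> float:
        return float(self.history["mae"].iloc[-1])

    def summary(self) -> str:
        h = self.history.iloc[-1]
        lines = [
            "Hierarchical neural-network dose calibration",
            f"  subnets: {', '.join(TOPOLOGY)}  "
            f"({self.model.n_params} trainable parameters)",
            f"  training: n={self.n_samples}, batch={self.config.batch_size}, "
            f"epochs={self.config.epochs}, "
            f"validation split={self.config.validation_split}, "
            f"seed={self.config.seed}",
            f"  final MSE = {h['mse']:.3f} cGy^2   MAE = {h['mae']:.3f} cGy",
            f"  final val MSE = {h['val_mse']:.3f} cGy^2   "
            f"val MAE = {h['val_mae']:.3f} cGy",
        ]
        return "\n".join(lines)


# -- functional wrappers ------------------------------------------------

def build_hnn(specs=None, seed: int = 435) -> HNNModel:
    """Untrained seven-subnet graph with seeded uniform initial weights."""
    return HNNModel(specs=specs, seed=seed)


def train_hnn(model: HNNModel, samples, config: TrainConfig | None = None
              ) -> HNNModel:
    """Train a built graph on calibration samples (in place).

    ``samples`` may be a feature DataFrame with ``dose_cGy``, or a list of
    :class:`~filmcal.features.CalibrationSample`.
    """
    config = config or TrainConfig(seed=model.seed)
    if isinstance(samples, pd.DataFrame):
        X = _as_feature_matrix(samples)
        y = samples["dose_cGy"].to_numpy(dtype=float)
    else:
        samples = list(samples)
        if not samples:
            raise ValueError("empty sample list")
        X = np.vstack([s.features.as_array() for s in samples])
        y = np.array([s.dose for s in samples])
    if y.size < config.batch_size:
        raise ValueError("need at least one full batch of samples")
    _train(model, X, y, config)
    return model


def predict_H(model: HNNModel, features) -> np.ndarray:
    """Dose estimates H (cGy) from a trained graph."""
    return model.predict(features)
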