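"""3D convolutional threshold regressor.

The estimator maps a normalized N×N×N×C E-field tensor to the threshold
E-field magnitude (V/m, referenced to the grid centre / soma).  The
architecture is a stack of unpadded stride-1 Conv3D+ReLU layers, a flatten,
ReLU dense layers, and a single linear output unit.  Filter and dense-unit
counts shrink geometrically: layer i has round(first · r^(i−1)) units
(round-half-up).  With the best hyperparameters (4 conv layers of 3×3×3
kernels, 115 first-layer filters, 3 dense layers of 57 first-layer units,
r = 0.8) a 9×9×9 input produces conv feature maps with spatial edges
7, 5, 3 and 1.

Smaller inputs (N = 3, 5, 7) are handled two ways:

* ``variable``  — shrink the kernel to 2×2×2 and, for N = 3, use only two
  convolutional layers;
* ``constant``  — trilinearly upsample the input to 9×9×9 and keep the
  N = 9 architecture unchanged.

Training uses MSE loss, the Adam optimizer, Xavier-uniform initialization,
mini-batches (default 62), early stopping on the validation loss (patience
30 epochs) and learning-rate reduction by a factor of 5 on plateaus
(patience 15).  Everything is implemented directly on numpy arrays, which
keeps training deterministic for a fixed seed and fast enough for
desk-scale datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .geometry import GridSpec

__all__ = [
    "CNNConfig",
    "LayerPlan",
    "ArchitecturePlan",
    "TrainedEstimator",
    "plan_architecture",
    "train",
    "predict",
    "to_device_intensity",
    "random_search",
    "save_estimator",
    "load_estimator",
]


class CNNError(ValueError):
    pass


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters; defaults are the best set from the random search."""

    n_conv_layers: int = 4
    kernel: int = 3  # cubic, stride 1, no padding
    filters_1: int = 115
    n_dense_layers: int = 3
    dense_units_1: int = 57
    shrink_rate: float = 0.8
    batch_size: int = 62
    learning_rate: float = 1e-5
    activation: str = "relu"
    dropout_rate: float = 0.0  # available but off in the best set
    batch_norm: bool = False  # available but off in the best set
    max_epochs: int = 2000
    early_stop_patience: int = 30
    lr_plateau_patience: int = 15
    lr_reduction_factor: float = 5.0

    def conv_filters(self) -> list:
        return [_round_half_up(self.filters_1 * self.shrink_rate ** i)
                for i in range(self.n_conv_layers)]

    def dense_units(self) -> list:
        return [_round_half_up(self.dense_units_1 * self.shrink_rate ** i)
                for i in range(self.n_dense_layers)]


@dataclass(frozen=True)
class LayerPlan:
    name: str
    kind: str  # conv / flatten / dense / output
    out_shape: tuple
    n_params: int
    kernel: int = 0


@dataclass(frozen=True)
class ArchitecturePlan:
    layers: tuple
    input_shape: tuple  # (N, N, N, C) actually fed to the network
    adaptation: str  # variable / constant
    config: CNNConfig

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    @property
    def conv_edges(self) -> list:
        return [l.out_shape[0] for l in self.layers if l.kind == "conv"]


def plan_architecture(config: CNNConfig, N: int, channels: int = 3,
                      adaptation: str = "variable") -> ArchitecturePlan:
    """Resolve the layer plan for an input grid of N points per dimension."""
    if N not in (3, 5, 7, 9):
        raise CNNError(f"N must be one of 3,5,7,9, got {N}")
    if channels not in (3, 4):
        raise CNNError("channels must be 3 (Cartesian) or 4 (spherical)")
    if adaptation not in ("variable", "constant"):
        raise CNNError("adaptation must be 'variable' or 'constant'")

    kernel = config.kernel
    n_conv = config.n_conv_layers
    N_eff = N
    if adaptation == "constant":
        N_eff = 9  # inputs upsampled to the reference grid first
    elif N < 9:
        kernel = 2
        if N == 3:
            n_conv = 2

    filters = [_round_half_up(config.filters_1 * config.shrink_rate ** i)
               for i in range(n_conv)]
    dense = [_round_half_up(config.dense_units_1 * config.shrink_rate ** i)
             for i in range(config.n_dense_layers)]
    if any(f < 1 for f in filters) or any(d < 1 for d in dense):
        raise CNNError("shrink rate collapses a layer below one unit")

    layers = []
    edge, cin = N_eff, channels
    for i, f in enumerate(filters, start=1):
        edge = edge - (kernel - 1)
        if edge < 1:
            raise CNNError(
                f"conv layer {i} would reduce the spatial edge below 1 "
                f"(N={N_eff}, kernel={kernel}, layers={n_conv})"
            )
        n_params = kernel ** 3 * cin * f + f
        layers.append(LayerPlan(f"conv{i}", "conv", (edge, edge, edge, f), n_params, kernel))
        cin = f
    flat = edge ** 3 * cin
    layers.append(LayerPlan("flatten", "flatten", (flat,), 0))
    prev = flat
    for i, d in enumerate(dense, start=1):
        layers.append(LayerPlan(f"dense{i}", "dense", (d,), prev * d + d))
        prev = d
    layers.append(LayerPlan("output", "output", (1,), prev + 1))
    return ArchitecturePlan(tuple(layers), (N_eff, N_eff, N_eff, channels), adaptation, config)


# ---------------------------------------------------------------------------
# Network: forward/backward on numpy arrays
# ---------------------------------------------------------------------------

def _xavier_uniform(rng, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _init_weights(plan: ArchitecturePlan, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    W = {}
    cin = plan.input_shape[-1]
    for layer in plan.layers:
        if layer.kind == "conv":
            k, f = layer.kernel, layer.out_shape[-1]
            fan_in, fan_out = k ** 3 * cin, k ** 3 * f
            W[layer.name + "_w"] = _xavier_uniform(rng, fan_in, fan_out, (k, k, k, cin, f))
            W[layer.name + "_b"] = np.zeros(f, dtype=np.float32)
            cin = f
        elif layer.kind == "flatten":
            cin = layer.out_shape[0]
        else:  # dense / output
            d = layer.out_shape[0]
            W[layer.name + "_w"] = _xavier_uniform(rng, cin, d, (cin, d))
            W[layer.name + "_b"] = np.zeros(d, dtype=np.float32)
            cin = d
    return W


def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    """Unfold valid k³ patches: (B,D,D,D,C) → (B·o³, k³·C), o = D−k+1."""
    from numpy.lib.stride_tricks import sliding_window_view

    B, D = X.shape[0], X.shape[1]
    o = D - k + 1
    win = sliding_window_view(X, (k, k, k), axis=(1, 2, 3))  # B,o,o,o,C,k,k,k
    return np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
        B * o ** 3, k ** 3 * X.shape[-1]
    )


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 3D convolution (cross-correlation), stride 1, as a single GEMM."""
    k, f = W.shape[0], W.shape[-1]
    B, D = X.shape[0], X.shape[1]
    o = D - k + 1
    Xcol = _im2col(X, k)
    Y = Xcol @ W.reshape(-1, f) + b
    return Y.reshape(B, o, o, o, f), Xcol


def _conv_backward(X_shape, Xcol, W, dY):
    k, cin, f = W.shape[0], W.shape[3], W.shape[-1]
    B, o = dY.shape[0], dY.shape[1]
    dY_flat = dY.reshape(-1, f)
    dW = (Xcol.T @ dY_flat).reshape(W.shape)
    db = dY_flat.sum(axis=0)
    dXcol = (dY_flat @ W.reshape(-1, f).T).reshape(B, o, o, o, k, k, k, cin)
    dX = np.zeros(X_shape, dtype=dY.dtype)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                dX[:, dx:dx + o, dy:dy + o, dz:dz + o, :] += dXcol[:, :, :, :, dx, dy, dz, :]
    return dX, dW, db


def _forward(plan: ArchitecturePlan, W: dict, X: np.ndarray, keep_cache: bool = False):
    cache = []
    A = X
    for layer in plan.layers:
        if layer.kind == "conv":
            Z, Xcol = _conv_forward(A, W[layer.name + "_w"], W[layer.name + "_b"])
            if keep_cache:
                cache.append((layer, (A.shape, Xcol), Z))
            A = np.maximum(Z, 0.0)
        elif layer.kind == "flatten":
            if keep_cache:
                cache.append((layer, A.shape, None))
            A = A.reshape(A.shape[0], -1)
        elif layer.kind == "dense":
            Z = A @ W[layer.name + "_w"] + W[layer.name + "_b"]
            if keep_cache:
                cache.append((layer, A, Z))
            A = np.maximum(Z, 0.0)
        else:  # linear output
            Z = A @ W[layer.name + "_w"] + W[layer.name + "_b"]
            if keep_cache:
                cache.append((layer, A, Z))
            A = Z
    return (A, cache) if keep_cache else A


def _backward(plan: ArchitecturePlan, W: dict, cache, dOut: np.ndarray) -> dict:
    grads = {}
    dA = dOut
    for layer, A_in, Z in reversed(cache):
        if layer.kind == "output":
            grads[layer.name + "_w"] = A_in.T @ dA
            grads[layer.name + "_b"] = dA.sum(axis=0)
            dA = dA @ W[layer.name + "_w"].T
        elif layer.kind == "dense":
            dZ = dA * (Z > 0)
            grads[layer.name + "_w"] = A_in.T @ dZ
            grads[layer.name + "_b"] = dZ.sum(axis=0)
            dA = dZ @ W[layer.name + "_w"].T
        elif layer.kind == "flatten":
            dA = dA.reshape(A_in)  # A_in holds the pre-flatten shape
        else:  # conv
            dZ = dA * (Z > 0)
            X_shape, Xcol = A_in
            dX, dW, db = _conv_backward(X_shape, Xcol, W[layer.name + "_w"], dZ)
            grads[layer.name + "_w"] = dW
            grads[layer.name + "_b"] = db
            dA = dX
    return grads


class _Adam:
    def __init__(self, weights: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            weights[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Estimator container, training, prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedEstimator:
    plan: ArchitecturePlan
    weights: dict
    history: dict  # epoch, train_loss, val_loss, lr
    spec: GridSpec
    channels: str
    label_transform: str = "none"  # none | log
    label_mean: float = 0.0  # labels are standardized internally for Adam
    label_std: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def final_val_loss(self) -> float:
        return self.history["val_loss"][-1]


def _prepare_inputs(ds, plan: ArchitecturePlan) -> np.ndarray:
    """Dataset tensors → network input array, upsampling in constant mode."""
    X = ds.tensors
    N_in = plan.input_shape[0]
    if X.shape[1] != N_in:
        if plan.adaptation != "constant":
            raise CNNError(
                f"dataset grid N={X.shape[1]} does not match plan input N={N_in}"
            )
        from .geometry import FieldTensor, upsample_tensor

        up = [
            upsample_tensor(FieldTensor(t, ds.spec, ds.channels, ds.normalized, None),
                            N_in).values
            for t in X
        ]
        X = np.asarray(up)
    if X.shape[-1] != plan.input_shape[-1]:
        raise CNNError(
            f"dataset has {X.shape[-1]} channels ({ds.channels}); the plan expects "
            f"{plan.input_shape[-1]}"
        )
    return np.ascontiguousarray(X, dtype=np.float32)


def _transform_labels(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return y.astype(np.float32)
    if transform == "log":
        return np.log(y).astype(np.float32)
    raise CNNError(f"unknown label transform '{transform}'")


def _untransform(y: np.ndarray, transform: str) -> np.ndarray:
    return np.exp(y) if transform == "log" else y


def train(
    ds_train,
    ds_val,
    config: CNNConfig = CNNConfig(),
    seed: int = 0,
    adaptation: str = "variable",
    label_transform: str = "none",
    verbose: bool = False,
) -> TrainedEstimator:
    """Train the estimator with Adam, early stopping and LR-plateau scheduling.

    The weights giving the best validation loss are restored at the end, and
    the recorded final validation loss is re-evaluated on those weights.
    ``label_transform='log'`` fits log-thresholds (approximately optimizing
    relative error), recommended for heavy-tailed threshold distributions.
    """
    if ds_train.spec != ds_val.spec or ds_train.channels != ds_val.channels:
        raise CNNError("train and val datasets must share grid spec and channels")
    channels = 3 if ds_train.channels == "cartesian" else 4
    plan = plan_architecture(config, ds_train.spec.N, channels, adaptation)
    X_tr = _prepare_inputs(ds_train, plan)
    X_va = _prepare_inputs(ds_val, plan)
    y_tr = _transform_labels(ds_train.thresholds, label_transform)[:, None]
    y_va = _transform_labels(ds_val.thresholds, label_transform)[:, None]
    # standardize (transformed) labels so the output layer starts near scale
    mu = float(np.mean(y_tr))
    sd = float(max(np.std(y_tr), 1e-12))
    y_tr = ((y_tr - mu) / sd).astype(np.float32)
    y_va = ((y_va - mu) / sd).astype(np.float32)

    rng = np.random.default_rng(seed)
    W = _init_weights(plan, seed)
    opt = _Adam(W, config.learning_rate)
    n = len(y_tr)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    best_val, best_W, best_epoch = np.inf, None, -1
    plateau_wait, stop_wait = 0, 0

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        run_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            pred, cache = _forward(plan, W, Xb, keep_cache=True)
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            dOut = (2.0 / len(idx)) * resid.astype(np.float32)
            grads = _backward(plan, W, cache, dOut)
            opt.step(W, grads)
            run_loss += loss * len(idx)
            seen += len(idx)
        val_pred = _forward(plan, W, X_va)
        val_loss = float(np.mean((val_pred - y_va) ** 2))
        history["epoch"].append(epoch)
        history["train_loss"].append(run_loss / seen)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch}: train {run_loss / seen:.5g} val {val_loss:.5g} lr {opt.lr:.3g}")

        if val_loss < best_val:
            best_val = val_loss
            best_W = {k: v.copy() for k, v in W.items()}
            best_epoch = epoch
            plateau_wait, stop_wait = 0, 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.lr_plateau_patience:
                opt.lr /= config.lr_reduction_factor
                plateau_wait = 0
            if stop_wait >= config.early_stop_patience:
                break

    if best_W is not None:
        W = best_W
    final_val = float(np.mean((_forward(plan, W, X_va) - y_va) ** 2))
    history["val_loss"][-1] = final_val  # loss of the restored (served) weights
    return TrainedEstimator(
        plan, W, history, ds_train.spec, ds_train.channels, label_transform,
        mu, sd,
        provenance={
            "seed": seed,
            "config": asdict(config),
            "adaptation": adaptation,
            "n_train": int(n),
            "n_val": int(len(y_va)),
            "best_epoch": int(best_epoch),
            "waveform": ds_train.waveform,
            "adam": {"beta1": 0.9, "beta2": 0.999, "eps": 1e-7},
        },
    )


def predict(est: TrainedEstimator, tensors) -> np.ndarray:
    """Predict thresholds (V/m, soma-referenced) for a batch of tensors.

    Accepts a ThresholdDataset or a raw S×N×N×N×C array matching the
    training convention; batch-order invariant.
    """
    if hasattr(tensors, "tensors"):
        ds = tensors
        if ds.channels != est.channels:
            raise CNNError(
                f"dataset channels '{ds.channels}' do not match training "
                f"channels '{est.channels}'"
            )
        X = _prepare_inputs(ds, est.plan)
    else:
        X = np.asarray(tensors, dtype=np.float32)
        if X.ndim == 4:
            X = X[None]
        if X.shape[1] != est.plan.input_shape[0]:
            from .geometry import FieldTensor, upsample_tensor

            if est.plan.adaptation != "constant":
                raise CNNError("tensor N does not match the trained plan")
            spec = GridSpec(X.shape[1], est.spec.l)
            X = np.asarray([
                upsample_tensor(FieldTensor(t, spec, est.channels, True, None),
                                est.plan.input_shape[0]).values
                for t in X
            ], dtype=np.float32)
    out = _forward(est.plan, est.weights, X)[:, 0].astype(float)
    out = out * est.label_std + est.label_mean
    return _untransform(out, est.label_transform)


def to_device_intensity(threshold_Vm, soma_field_magnitude_per_unit) -> np.ndarray:
    """Convert V/m thresholds to stimulator intensity (A/μs).

    intensity = threshold / |E(soma)| per unit intensity.
    """
    thr = np.asarray(threshold_Vm, dtype=float)
    mag = np.asarray(soma_field_magnitude_per_unit, dtype=float)
    if np.any(mag <= 0):
        raise CNNError("soma field magnitude must be positive")
    return thr / mag


# ---------------------------------------------------------------------------
# Random hyperparameter search
# ---------------------------------------------------------------------------

#: search ranges (uniform; learning rate log-uniform)
SEARCH_RANGES = {
    "n_conv_layers": (2, 6),
    "kernel": (1, 3),
    "filters_1": (50, 121),
    "n_dense_layers": (1, 5),
    "dense_units_1": (50, 1000),
    "shrink_rate": (0.5, 0.9),
    "batch_size": (8, 128),
    "learning_rate": (1e-8, 1e-5),
}


def _sample_config(rng, ranges: dict, base: CNNConfig) -> CNNConfig:
    lo, hi = ranges["learning_rate"]
    return replace(
        base,
        n_conv_layers=int(rng.integers(ranges["n_conv_layers"][0], ranges["n_conv_layers"][1] + 1)),
        kernel=int(rng.integers(ranges["kernel"][0], ranges["kernel"][1] + 1)),
        filters_1=int(rng.integers(ranges["filters_1"][0], ranges["filters_1"][1] + 1)),
        n_dense_layers=int(rng.integers(ranges["n_dense_layers"][0], ranges["n_dense_layers"][1] + 1)),
        dense_units_1=int(rng.integers(ranges["dense_units_1"][0], ranges["dense_units_1"][1] + 1)),
        shrink_rate=float(rng.uniform(*ranges["shrink_rate"])),
        batch_size=int(rng.integers(ranges["batch_size"][0], ranges["batch_size"][1] + 1)),
        learning_rate=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
    )


def random_search(
    ds_train,
    ds_val,
    n_trials: int,
    budget_epochs: int = 50,
    train_fraction: float = 1 / 3,
    seed: int = 0,
    ranges: dict | None = None,
    base: CNNConfig = CNNConfig(),
    adaptation: str = "variable",
    label_transform: str = "none",
) -> list:
    """Random hyperparameter search on a fraction of the training data.

    Samples ``n_trials`` configurations from the tuning ranges, trains each
    for at most ``budget_epochs`` on ``train_fraction`` of the training set,
    and returns trial dicts ranked by final validation MSE.  Configurations
    whose conv stack would collapse the spatial edge below 1 are resampled
    (counted in each trial's ``n_resampled``).
    """
    if n_trials < 1:
        raise CNNError("n_trials must be ≥ 1")
    ranges = dict(SEARCH_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(train_fraction * len(ds_train))))
    sub_idx = rng.permutation(len(ds_train))[:n_sub]
    ds_sub = ds_train.subset(sub_idx, "train")
    channels = 3 if ds_train.channels == "cartesian" else 4
    results = []
    for trial in range(n_trials):
        n_resampled = 0
        while True:
            cfg = _sample_config(rng, ranges, base)
            cfg = replace(cfg, max_epochs=budget_epochs)
            try:
                plan_architecture(cfg, ds_train.spec.N, channels, adaptation)
                break
            except CNNError:
                n_resampled += 1
                if n_resampled > 1000:
                    raise
        est = train(ds_sub, ds_val, cfg, seed=seed + 7919 * trial,
                    adaptation=adaptation, label_transform=label_transform)
        results.append({
            "trial": trial,
            "config": cfg,
            "val_mse": est.final_val_loss,
            "n_resampled": n_resampled,
        })
    return sorted(results, key=lambda r: r["val_mse"])


# ---------------------------------------------------------------------------
# Persistence: directory with architecture/provenance JSON, npz weights, CSV
# ---------------------------------------------------------------------------

def save_estimator(est: TrainedEstimator, directory) -> None:
    import os

    os.makedirs(directory, exist_ok=True)
    arch = {
        "input_shape": list(est.plan.input_shape),
        "adaptation": est.plan.adaptation,
        "config": asdict(est.plan.config),
        "layers": [
            {"name": l.name, "kind": l.kind, "out_shape": list(l.out_shape),
             "n_params": l.n_params, "kernel": l.kernel}
            for l in est.plan.layers
        ],
        "spec": {"N": est.spec.N, "l": est.spec.l},
        "channels": est.channels,
        "label_transform": est.label_transform,
        "label_mean": est.label_mean,
        "label_std": est.label_std,
    }
    with open(os.path.join(directory, "architecture.json"), "w") as f:
        json.dump(arch, f, indent=1)
    with open(os.path.join(directory, "provenance.json"), "w") as f:
        json.dump(est.provenance, f, indent=1)
    np.savez(os.path.join(directory, "weights.npz"), **est.weights)
    import csv

    with open(os.path.join(directory, "history.csv"), "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch", "train_loss", "val_loss", "lr"])
        for row in zip(*(est.history[k] for k in ("epoch", "train_loss", "val_loss", "lr"))):
            w.writerow(row)


def load_estimator(directory) -> TrainedEstimator:
    import os

    with open(os.path.join(directory, "architecture.json")) as f:
        arch = json.load(f)
    with open(os.path.join(directory, "provenance.json")) as f:
        prov = json.load(f)
    config = CNNConfig(**arch["config"])
    spec = GridSpec(arch["spec"]["N"], arch["spec"]["l"])
    channels = arch["channels"]
    plan = plan_architecture(config, spec.N, 3 if channels == "cartesian" else 4,
                             arch["adaptation"])
    weights = dict(np.load(os.path.join(directory, "weights.npz")))
    import csv

    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    with open(os.path.join(directory, "history.csv")) as f:
        for row in csv.DictReader(f):
            history["epoch"].append(int(row["epoch"]))
            history["train_loss"].append(float(row["train_loss"]))
            history["val_loss"].append(float(row["val_loss"]))
            history["lr"].append(float(row["lr"]))
    return TrainedEstimator(plan, weights, history, spec, channels,
                            arch["label_transform"],
                            arch.get("label_mean", 0.0), arch.get("label_std", 1.0),
                            prov)
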