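"""CNN+LSTM models over dFC sequences, as scikit-learn style estimators.

The architecture: three 1D convolutions over the window axis with kernel
sizes 4, 8 and 16 windows and 32 channels each (edges are the input
channels), rectified and concatenated along the feature axis; dropout;
non-overlapping temporal max-pooling (kernel 5); a two-layer stacked LSTM
with 32 hidden units; the LSTM output sequence averaged over time; and an
affine head — two-way softmax for classification, a scalar for regression.

The LSTM cell follows the standard gate equations

    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    c~_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    C_t = i_t * c~_t + f_t * C_{t-1}
    h_t = o_t * tanh(C_t)

exposed directly by :func:`lstm_cell_step` for verification against the
vectorized stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, ChronnectomeNetwork, sigmoid, softmax

__all__ = [
    "ModelSpec",
    "LstmParams",
    "LstmState",
    "lstm_cell_step",
    "lstm_stack",
    "conv_bank",
    "temporal_maxpool",
    "temporal_average_head",
    "forward",
    "ChronnectomeClassifier",
    "ChronnectomeRegressor",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the CNN+LSTM."""

    n_edges: int
    conv_kernels: tuple[int, ...] = (4, 8, 16)
    conv_channels: int = 32
    pool_kernel: int = 5
    lstm_hidden: int = 32
    lstm_layers: int = 2
    dropout: float = 0.5
    head: str = "classification"      # or "regression"

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.conv_kernels):
            raise ValueError("conv kernels must be >= 1")
        if self.pool_kernel < 1 or self.lstm_hidden < 1 or self.lstm_layers < 1:
            raise ValueError("pool kernel, hidden size and layer count must be >= 1")
        if self.head not in ("classification", "regression"):
            raise ValueError("head must be 'classification' or 'regression'")

    @property
    def n_outputs(self) -> int:
        return 2 if self.head == "classification" else 1


@dataclass
class LstmParams:
    """Named LSTM weights: ``W_*`` input, ``U_*`` recurrent, ``b_*`` bias."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        h, f = np.atleast_2d(self.W_f).shape
        for name in ("W_i", "W_o", "W_c"):
            if np.atleast_2d(getattr(self, name)).shape != (h, f):
                raise ValueError(f"{name} shape mismatch")
        for name in ("U_f", "U_i", "U_o", "U_c"):
            if np.atleast_2d(getattr(self, name)).shape != (h, h):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_f", "b_i", "b_o", "b_c"):
            if np.atleast_1d(getattr(self, name)).shape != (h,):
                raise ValueError(f"{name} shape mismatch")


@dataclass
class LstmState:
    """Full state of one LSTM cell step: gates, candidate, cell and hidden."""

    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    c_tilde: np.ndarray
    c: np.ndarray
    h: np.ndarray


def lstm_cell_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   params: LstmParams) -> LstmState:
    """One LSTM cell update, written exactly as the gate equations."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=float))
    W = {k: np.atleast_2d(np.asarray(getattr(params, k), dtype=float))
         for k in ("W_f", "W_i", "W_o", "W_c", "U_f", "U_i", "U_o", "U_c")}
    b = {k: np.atleast_1d(np.asarray(getattr(params, k), dtype=float))
         for k in ("b_f", "b_i", "b_o", "b_c")}
    if W["W_f"].shape[1] != x_t.shape[0] or W["U_f"].shape[1] != h_prev.shape[0]:
        raise ValueError("input/hidden dimension mismatch with parameters")
    f = sigmoid(W["W_f"] @ x_t + W["U_f"] @ h_prev + b["b_f"])
    i = sigmoid(W["W_i"] @ x_t + W["U_i"] @ h_prev + b["b_i"])
    o = sigmoid(W["W_o"] @ x_t + W["U_o"] @ h_prev + b["b_o"])
    c_tilde = np.tanh(W["W_c"] @ x_t + W["U_c"] @ h_prev + b["b_c"])
    c = i * c_tilde + f * c_prev
    h = o * np.tanh(c)
    return LstmState(f=f, i=i, o=o, c_tilde=c_tilde, c=c, h=h)


def lstm_stack(sequence: np.ndarray, layer_params: list[LstmParams]) -> np.ndarray:
    """Stacked LSTM over a (T, F) sequence; returns top-layer outputs (T, H).

    Layer l consumes layer l-1's full output sequence; initial hidden and
    cell states are zero.  This is the reference (loop) implementation used
    both by the network and as its oracle.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be (T, F) with T >= 1")
    for params in layer_params:
        h_dim = np.atleast_2d(params.W_f).shape[0]
        h = np.zeros(h_dim)
        c = np.zeros(h_dim)
        outputs = np.empty((seq.shape[0], h_dim))
        for t in range(seq.shape[0]):
            state = lstm_cell_step(seq[t], h, c, params)
            h, c = state.h, state.c
            outputs[t] = h
        seq = outputs
    return seq


def conv_bank(net: ChronnectomeNetwork, dfc: np.ndarray) -> np.ndarray:
    """Rectified multi-scale conv features of one (W, E) dFC sequence."""
    from ._nn import conv1d_forward

    x = np.asarray(dfc, dtype=net.dtype)[None]
    if x.shape[2] != net.n_edges:
        raise ValueError(f"{x.shape[2]} edges, model expects {net.n_edges}")
    if x.shape[1] < max(net.conv_kernels):
        raise ValueError("fewer windows than the largest conv kernel")
    feats = []
    for k in net.conv_kernels:
        z, _ = conv1d_forward(x, net.params[f"conv{k}_w"], net.params[f"conv{k}_b"])
        feats.append(np.maximum(z, 0.0) if net.conv_activation == "relu" else z)
    return np.concatenate(feats, axis=2)[0]


def temporal_maxpool(features: np.ndarray, kernel: int) -> np.ndarray:
    """Non-overlapping temporal max-pooling of a (W, F) feature map."""
    from ._nn import maxpool_forward

    out, _ = maxpool_forward(np.asarray(features, dtype=float)[None], kernel)
    return out[0]


def temporal_average_head(outputs: np.ndarray, weight: np.ndarray,
                          bias: np.ndarray, apply_softmax: bool = False) -> np.ndarray:
    """Average LSTM outputs over time, then the affine head (optionally softmax)."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 2 or outputs.shape[0] < 1:
        raise ValueError("outputs must be (T, H) with T >= 1")
    h = outputs.mean(axis=0) @ np.atleast_2d(weight) + np.atleast_1d(bias)
    return softmax(h) if apply_softmax else h


def forward(net: ChronnectomeNetwork, batch: np.ndarray,
            apply_softmax: bool | None = None) -> np.ndarray:
    """Deterministic inference over a (B, W, E) batch (dropout off)."""
    out, _ = net.forward(np.asarray(batch), train=False)
    if apply_softmax is None:
        apply_softmax = net.n_outputs == 2
    return softmax(out) if apply_softmax else out[:, 0] if net.n_outputs == 1 else out


def _packed_to_named(net: ChronnectomeNetwork, layer: int) -> LstmParams:
    """Expose one packed LSTM layer as named gate matrices (gate order i,f,g,o)."""
    h = net.lstm_hidden
    wx = np.asarray(net.params[f"lstm{layer}_wx"], dtype=float)
    wh = np.asarray(net.params[f"lstm{layer}_wh"], dtype=float)
    b = np.asarray(net.params[f"lstm{layer}_b"], dtype=float)
    sl = {"i": slice(0, h), "f": slice(h, 2 * h), "g": slice(2 * h, 3 * h),
          "o": slice(3 * h, 4 * h)}
    return LstmParams(
        W_f=wx[:, sl["f"]].T, W_i=wx[:, sl["i"]].T, W_o=wx[:, sl["o"]].T,
        W_c=wx[:, sl["g"]].T,
        U_f=wh[:, sl["f"]].T, U_i=wh[:, sl["i"]].T, U_o=wh[:, sl["o"]].T,
        U_c=wh[:, sl["g"]].T,
        b_f=b[sl["f"]], b_i=b[sl["i"]], b_o=b[sl["o"]], b_c=b[sl["g"]],
    )


# ---------------------------------------------------------------------------
# estimators


class _BaseChronnectome(BaseEstimator):
    """Shared training machinery for the classifier and regressor."""

    def __init__(self, conv_kernels=(4, 8, 16), conv_channels=32, pool_kernel=5,
                 lstm_hidden=32, lstm_layers=2, dropout=0.5, dense_lstm=False,
                 learning_rate=1e-4, lr_decay=0.1, weight_decay=0.0, batch_size=64,
                 max_epochs=10, patience=3, min_delta=0.0, random_state=None,
                 dtype="float32", verbose=0):
        self.conv_kernels = conv_kernels
        self.conv_channels = conv_channels
        self.pool_kernel = pool_kernel
        self.lstm_hidden = lstm_hidden
        self.lstm_layers = lstm_layers
        self.dropout = dropout
        self.dense_lstm = dense_lstm
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # subclasses define
    _task = ""

    def _encode_targets(self, y):
        raise NotImplementedError

    def _encode_eval(self, y):
        return self._encode_targets(y)

    def _loss_and_grad(self, out, target):
        raise NotImplementedError

    def _check_X(self, X, fitted=False):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must have shape (n_runs, n_windows, n_edges)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if fitted and X.shape[2] != self.n_edges_:
            raise ValueError(
                f"X has {X.shape[2]} edges, model was fitted with {self.n_edges_}"
            )
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        """Optimize the network with Adam, per-epoch lr decay, early stopping.

        If a validation set is supplied, early stopping monitors its loss
        and the best-validation weights are restored; otherwise the training
        loss is monitored.  An epoch only counts as an improvement when it
        beats the previous best by ``min_delta``.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        target = self._encode_targets(y)
        rng = np.random.default_rng(self.random_state)
        n_outputs = 2 if self._task == "classification" else 1
        net = ChronnectomeNetwork(
            n_edges=X.shape[2],
            n_outputs=n_outputs,
            conv_kernels=tuple(self.conv_kernels),
            conv_channels=self.conv_channels,
            pool_kernel=self.pool_kernel,
            lstm_hidden=self.lstm_hidden,
            lstm_layers=self.lstm_layers,
            dropout=self.dropout,
            dense_lstm=self.dense_lstm,
            dtype=self.dtype,
            seed=int(rng.integers(2**31 - 1)),
        )
        drop_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
        opt = Adam(net.params, lr=self.learning_rate, weight_decay=self.weight_decay)

        have_val = X_val is not None and y_val is not None and len(y_val) > 0
        if have_val:
            X_val = self._check_X(X_val)
            val_target = self._encode_eval(np.asarray(y_val))

        n = X.shape[0]
        batch = min(self.batch_size, n)
        history = {"train_loss": [], "val_loss": [], "lr": []}
        best_loss = np.inf
        best_params = net.copy_params()
        wait = 0
        lr = float(self.learning_rate)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            opt.lr = lr
            losses = []
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                out, cache = net.forward(X[idx], train=True, dropout_rng=drop_rng)
                loss, dout = self._loss_and_grad(out, target[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"loss diverged (epoch {epoch}, lr {lr:g}); "
                        "reduce the learning rate"
                    )
                grads = net.backward(cache, dout)
                opt.step(net.params, grads)
                losses.append(float(loss))
            train_loss = float(np.mean(losses))
            if have_val:
                monitor = self._eval_loss(net, X_val, val_target)
            else:
                monitor = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(monitor if have_val else np.nan)
            history["lr"].append(lr)
            if self.verbose:
                print(f"epoch {epoch}: train {train_loss:.4f} "
                      f"monitor {monitor:.4f} lr {lr:g}")
            # a new best must beat the old one by min_delta: chance dips of
            # the monitored loss must not select (possibly overfit) weights
            if monitor < best_loss - max(self.min_delta, 1e-12):
                best_loss = monitor
                best_params = net.copy_params()
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
            lr *= self.lr_decay
        net.set_params_(best_params)
        self.net_ = net
        self.history_ = history
        self.n_edges_ = X.shape[2]
        self.n_windows_ = X.shape[1]
        return self

    def _eval_loss(self, net, X, target) -> float:
        losses = []
        weights = []
        for start in range(0, X.shape[0], 256):
            out, _ = net.forward(X[start : start + 256], train=False)
            loss, _ = self._loss_and_grad(out, target[start : start + 256])
            losses.append(float(loss))
            weights.append(out.shape[0])
        return float(np.average(losses, weights=weights))

    def _forward_eval(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._check_X(X, fitted=True)
        outs = []
        for start in range(0, X.shape[0], 256):
            out, _ = self.net_.forward(X[start : start + 256], train=False)
            outs.append(out)
        return np.concatenate(outs, axis=0)

    def lstm_layer_params(self, layer: int) -> LstmParams:
        """Named gate weights of a fitted LSTM layer (for inspection/oracles)."""
        check_is_fitted(self, "net_")
        return _packed_to_named(self.net_, layer)

    def save(self, path) -> None:
        """Single-file checkpoint: constructor params + learned weights."""
        import json

        check_is_fitted(self, "net_")
        meta = {
            "estimator": type(self).__name__,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "n_edges": int(self.n_edges_),
            "n_windows": int(self.n_windows_),
            "classes": getattr(self, "classes_", np.array([])).tolist(),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"w_{k}": v for k, v in self.net_.params.items()})

    @classmethod
    def load(cls, path):
        """Restore a checkpoint written by :meth:`save`."""
        import json

        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            weights = {k[2:]: archive[k] for k in archive.files if k.startswith("w_")}
        if meta["estimator"] != cls.__name__:
            raise ValueError(
                f"checkpoint holds a {meta['estimator']}, not a {cls.__name__}"
            )
        params = {k: (tuple(v) if k == "conv_kernels" else v)
                  for k, v in meta["params"].items()}
        est = cls(**params)
        net = ChronnectomeNetwork(
            n_edges=meta["n_edges"],
            n_outputs=2 if cls._task == "classification" else 1,
            conv_kernels=tuple(est.conv_kernels),
            conv_channels=est.conv_channels,
            pool_kernel=est.pool_kernel,
            lstm_hidden=est.lstm_hidden,
            lstm_layers=est.lstm_layers,
            dropout=est.dropout,
            dense_lstm=est.dense_lstm,
            dtype=est.dtype,
            seed=0,
        )
        net.set_params_(weights)
        est.net_ = net
        est.n_edges_ = meta["n_edges"]
        est.n_windows_ = meta["n_windows"]
        est.history_ = {}
        if meta["classes"]:
            est.classes_ = np.asarray(meta["classes"])
        return est


class ChronnectomeClassifier(ClassifierMixin, _BaseChronnectome):
    """Two-way CNN+LSTM classifier over dFC sequences.

    Parameters mirror the reference architecture: multi-scale kernels
    (4, 8, 16) with 32 channels, pool 5, two 32-unit LSTM layers, dropout
    0.5, Adam at ``learning_rate`` with multiplicative per-epoch
    ``lr_decay`` and early stopping with ``patience``.
    """

    _task = "classification"

    def _encode_targets(self, y):
        self.classes_, encoded = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"classifier supports exactly 2 classes, got {len(self.classes_)}"
            )
        return encoded

    def _encode_eval(self, y):
        encoded = np.searchsorted(self.classes_, y)
        if not np.array_equal(self.classes_[encoded], y):
            raise ValueError("validation labels outside the training classes")
        return encoded

    def _loss_and_grad(self, out, target):
        probs = softmax(out.astype(np.float64))
        n = out.shape[0]
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(n), target] + eps))
        dout = probs
        dout[np.arange(n), target] -= 1.0
        return loss, dout / n

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self._forward_eval(X).astype(np.float64))

    def decision_function(self, X) -> np.ndarray:
        out = self._forward_eval(X)
        return out[:, 1] - out[:, 0]

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class ChronnectomeRegressor(RegressorMixin, _BaseChronnectome):
    """Scalar-output CNN+LSTM regressor (squared-error loss) over dFC sequences."""

    _task = "regression"

    def _encode_targets(self, y):
        return np.asarray(y, dtype=float)

    def _loss_and_grad(self, out, target):
        pred = out[:, 0].astype(np.float64)
        resid = pred - target
        loss = np.mean(resid**2)
        dout = (2.0 * resid / len(resid))[:, None]
        return loss, dout

    def predict(self, X) -> np.ndarray:
        return self._forward_eval(X)[:, 0].astype(np.float64)
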