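"""A purely convolutional 1-D network for spectra, in numpy.

Architecture (fixed by design): three repetitions of
[valid convolution (64 filters, kernel width 3, softplus activation) ->
max-pool (size 2) -> dropout (rate 0.25)], then flatten, a 16-unit
fully-connected softplus layer, and a single sigmoid output node o in
(0, 1). Training minimizes binary cross-entropy with ADAM (learning rate
0.001, batch size 64). Spectra enter untransformed.

Interpretability: vanilla-gradient saliency maps do/dX_i, mapped through
the empirical CDF of the pooled score-derivatives of the test set.

The network and its backward pass (including the gradient with respect to
the input, needed for saliency) are implemented directly on numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .dataset import SpectralDataset
from .errors import DivergenceError, InsufficientDataError, InvalidConfigError

__all__ = [
    "TrainConfig",
    "SaliencyMap",
    "CNN1D",
    "CNNClassifier",
    "layer_lengths",
    "parameter_count",
    "min_input_length",
    "build_cnn",
    "vanilla_gradient_saliency",
]

N_BLOCKS = 3
N_FILTERS = 64
KERNEL = 3
POOL = 2
DROPOUT = 0.25
HIDDEN = 16


def layer_lengths(input_length: int, n_blocks: int = N_BLOCKS, kernel: int = KERNEL, pool: int = POOL) -> list[int]:
    """Sequence lengths through the conv/pool stack, starting at the input.

    Each block maps L -> L - (kernel-1) (valid convolution) -> L // pool.
    Raises when any stage would produce an empty sequence.
    """
    lengths = [input_length]
    L = input_length
    for b in range(n_blocks):
        L = L - (kernel - 1)
        if L < 1:
            raise InvalidConfigError(
                f"input length {input_length} too short for block {b + 1}; "
                f"minimum is {min_input_length(n_blocks, kernel, pool)}"
            )
        lengths.append(L)
        L = L // pool
        if L < 1:
            raise InvalidConfigError(
                f"input length {input_length} too short for block {b + 1}; "
                f"minimum is {min_input_length(n_blocks, kernel, pool)}"
            )
        lengths.append(L)
    return lengths


def min_input_length(n_blocks: int = N_BLOCKS, kernel: int = KERNEL, pool: int = POOL) -> int:
    """Smallest input length that survives the conv/pool stack."""
    L = 1
    for _ in range(n_blocks):
        L = L * pool + (kernel - 1)  # reverse of L -> (L - (k-1)) // pool
    return L


def parameter_count(input_length: int) -> int:
    """Trainable parameters of the fixed architecture for one input length."""
    lengths = layer_lengths(input_length)
    total = (KERNEL * 1 + 1) * N_FILTERS  # first conv: 1 input channel
    total += (N_BLOCKS - 1) * (KERNEL * N_FILTERS + 1) * N_FILTERS
    flat = lengths[-1] * N_FILTERS
    total += flat * HIDDEN + HIDDEN
    total += HIDDEN * 1 + 1
    return total


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: ADAM on binary cross-entropy."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 50
    early_stopping: bool = True
    validation_fraction: float = 0.1
    patience: int = 10
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise InvalidConfigError("batch_size must be >= 1")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")


def _softplus(z: np.ndarray) -> np.ndarray:
    # stable log(1 + e^z) = max(z, 0) + log1p(e^{-|z|})
    return np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


class CNN1D:
    """The fixed three-block convolutional classifier.

    Weights are created at construction from ``seed``; :meth:`fit` derives
    its own shuffling/dropout stream from the same seed, so two models
    built and trained identically produce bit-identical weights.
    """

    def __init__(self, input_length: int, seed: int = 0, dropout: float = DROPOUT,
                 dtype=np.float32):
        self.input_length = int(input_length)
        self.lengths = layer_lengths(self.input_length)
        self.seed = int(seed)
        self.dropout = float(dropout)
        self.dtype = np.dtype(dtype)
        self._init_params(attempt=0)
        self.loss_trace: list[float] = []

    def _init_params(self, attempt: int) -> None:
        """Glorot-uniform weights with two stabilizing choices: the dense
        softplus layer gets a small positive bias so its units start in
        the active regime, and the output layer starts at zero so the
        initial prediction is exactly 0.5. Spectra enter the network raw
        (all-positive, strongly correlated), so a confidently-wrong
        initial logit would push the hidden layer's common mode into
        negative softplus saturation, from which gradients cannot recover;
        the zero-init output removes that pressure."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0, attempt]))
        self.params = {}
        in_ch = 1
        for b in range(N_BLOCKS):
            # convolution weights are stored (KERNEL * in_ch, N_FILTERS) with
            # the kernel tap as the major axis, matching the im2col layout
            fan_in = KERNEL * in_ch
            limit = np.sqrt(6.0 / (fan_in + N_FILTERS))
            self.params[f"Wc{b}"] = rng.uniform(-limit, limit, size=(fan_in, N_FILTERS))
            self.params[f"bc{b}"] = np.zeros(N_FILTERS)
            in_ch = N_FILTERS
        flat = self.lengths[-1] * N_FILTERS
        limit = np.sqrt(6.0 / (flat + HIDDEN))
        self.params["Wd1"] = rng.uniform(-limit, limit, size=(flat, HIDDEN))
        self.params["bd1"] = np.full(HIDDEN, 0.5)
        self.params["Wd2"] = np.zeros((HIDDEN, 1))
        self.params["bd2"] = np.zeros(1)
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _im2col(a: np.ndarray, out_len: int) -> np.ndarray:
        """(B, L, C) -> (B, out_len, KERNEL*C), tap-major block layout."""
        return np.concatenate([a[:, t : t + out_len, :] for t in range(KERNEL)], axis=2)

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator | None):
        """Forward pass; returns (logits, cache) with everything backward needs."""
        B = X.shape[0]
        a = np.ascontiguousarray(X, dtype=self.dtype)[:, :, None]  # (B, L, 1)
        cache: dict = {"in_ch": [], "win": [], "sig": [], "pool_arg": [], "drop_mask": []}
        for b in range(N_BLOCKS):
            Lc = a.shape[1] - (KERNEL - 1)
            win = self._im2col(a, Lc)  # (B, Lc, K*C)
            pre = (win.reshape(B * Lc, -1) @ self.params[f"Wc{b}"]).reshape(B, Lc, N_FILTERS)
            pre += self.params[f"bc{b}"]
            # softplus and its derivative from one exponential:
            # e = exp(-|z|); softplus = max(z,0) + log1p(e); sigmoid = (z>=0 ? 1 : e)/(1+e)
            e = np.exp(-np.abs(pre))
            act = np.maximum(pre, 0) + np.log1p(e)
            Lp = Lc // POOL
            even = act[:, 0 : Lp * POOL : POOL]
            odd = act[:, 1 : Lp * POOL : POOL]
            arg = even >= odd  # True: the even (left) element won the pool
            pooled = np.where(arg, even, odd)
            if training and self.dropout > 0:
                mask = (
                    (rng.random(pooled.shape) >= self.dropout) / (1.0 - self.dropout)
                ).astype(self.dtype)
                out = pooled * mask
            else:
                mask = None
                out = pooled
            cache["in_ch"].append(a.shape[2])
            cache["win"].append(win)
            cache["sig"].append(np.where(pre >= 0, 1.0, e).astype(self.dtype) / (1.0 + e))
            cache["pool_arg"].append(arg)
            cache["drop_mask"].append(mask)
            a = out
        flat = a.reshape(B, -1)
        pre1 = flat @ self.params["Wd1"] + self.params["bd1"]
        h = _softplus(pre1)
        logits = (h @ self.params["Wd2"] + self.params["bd2"]).ravel()
        cache.update(flat=flat, pre1=pre1, h=h, block_out_shape=a.shape)
        return logits.astype(np.float64), cache

    def _backward(self, dlogits: np.ndarray, cache: dict):
        """Gradients of the scalar objective w.r.t. all parameters and the input."""
        grads: dict[str, np.ndarray] = {}
        dl = dlogits[:, None].astype(self.dtype)  # (B, 1)
        grads["Wd2"] = cache["h"].T @ dl
        grads["bd2"] = dl.sum(axis=0)
        dh = dl @ self.params["Wd2"].T
        dpre1 = dh * _sigmoid(cache["pre1"])
        grads["Wd1"] = cache["flat"].T @ dpre1
        grads["bd1"] = dpre1.sum(axis=0)
        dflat = dpre1 @ self.params["Wd1"].T
        da = dflat.reshape(cache["block_out_shape"])
        for b in reversed(range(N_BLOCKS)):
            if cache["drop_mask"][b] is not None:
                da = da * cache["drop_mask"][b]
            sig = cache["sig"][b]
            B, Lc, _ = sig.shape
            Lp = Lc // POOL
            arg = cache["pool_arg"][b]
            dact_full = np.zeros((B, Lc, N_FILTERS), dtype=self.dtype)
            dact_full[:, 0 : Lp * POOL : POOL] = np.where(arg, da, 0)
            dact_full[:, 1 : Lp * POOL : POOL] = np.where(arg, 0, da)
            dpre = dact_full * sig
            win = cache["win"][b]
            dpre_flat = dpre.reshape(B * Lc, N_FILTERS)
            grads[f"Wc{b}"] = win.reshape(B * Lc, -1).T @ dpre_flat
            grads[f"bc{b}"] = dpre.sum(axis=(0, 1))
            C = cache["in_ch"][b]
            dwin = (dpre_flat @ self.params[f"Wc{b}"].T).reshape(B, Lc, KERNEL * C)
            L_in = Lc + KERNEL - 1
            da = np.zeros((B, L_in, C), dtype=self.dtype)
            for t in range(KERNEL):
                da[:, t : t + Lc, :] += dwin[:, :, t * C : (t + 1) * C]
        return grads, da[:, :, 0]

    # -- public API --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Output score o in (0, 1) per spectrum (dropout off)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logits, _ = self._forward(X, training=False, rng=None)
        return _sigmoid(logits)

    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> "CNN1D":
        """Mini-batch ADAM on binary cross-entropy; returns self.

        With early stopping on, a ``validation_fraction`` split of the rows
        monitors the loss and the best weights are kept. The per-epoch
        training loss is stored in ``self.loss_trace``.

        Softplus networks on all-positive spectra can collapse into a dead
        constant-output state (every dense unit saturated on the negative
        side, so gradients vanish). When the fitted network's outputs are
        constant on the training data, the fit is restarted from a fresh
        seeded initialization, up to ``n_restarts`` times — the same
        restart strategy k-means uses for its non-convex objective.
        """
        config = config or TrainConfig()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(set(y.tolist())) < 2:
            raise InsufficientDataError("training needs both labels")
        for attempt in range(config.n_restarts + 1):
            if attempt:
                self._init_params(attempt)
            self._fit_once(X, y, config, attempt)
            # dead state: the hidden layer is constant across inputs, so the
            # whole network outputs one value regardless of the spectrum.
            # (A weakly discriminative but live network keeps input-dependent
            # hidden activity and is not restarted.)
            _, cache = self._forward(X[: min(len(X), 256)], training=False, rng=None)
            if float(cache["h"].std(axis=0).max()) > 1e-6:
                break
        return self

    def _fit_once(self, X: np.ndarray, y: np.ndarray, config: TrainConfig, attempt: int) -> "CNN1D":
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1, attempt]))
        n_val = int(round(config.validation_fraction * X.shape[0])) if config.early_stopping else 0
        if n_val > 0:
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X_tr, y_tr = X[tr_idx], y[tr_idx]
        else:
            X_tr, y_tr = X, y
            X_val = y_val = None
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = None
        stall = 0
        self.loss_trace = []
        for epoch in range(config.epochs):
            order = rng.permutation(X_tr.shape[0])
            epoch_loss = 0.0
            for start in range(0, X_tr.shape[0], config.batch_size):
                batch = order[start : start + config.batch_size]
                xb, yb = X_tr[batch], y_tr[batch]
                logits, cache = self._forward(xb, training=True, rng=rng)
                # BCE with logits: softplus(z) - y*z, averaged over the batch
                loss = float(np.mean(_softplus(logits) - yb * logits))
                epoch_loss += loss * batch.size
                dlogits = (_sigmoid(logits) - yb) / batch.size
                grads, _ = self._backward(dlogits, cache)
                step += 1
                for key, g in grads.items():
                    g = g.reshape(self.params[key].shape)
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**step)
                    vhat = v[key] / (1 - beta2**step)
                    self.params[key] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= X_tr.shape[0]
            if not np.isfinite(epoch_loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            self.loss_trace.append(epoch_loss)
            if X_val is not None and X_val.shape[0] > 0:
                val_logits, _ = self._forward(X_val, training=False, rng=None)
                val_loss = float(np.mean(_softplus(val_logits) - y_val * val_logits))
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = {k: p.copy() for k, p in self.params.items()}
                    stall = 0
                else:
                    stall += 1
                    if stall >= config.patience:
                        break
        if best_params is not None:
            self.params = best_params
        return self

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Vanilla gradients do/dX_i of the sigmoid output, dropout off."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        grads = np.empty_like(X)
        batch = 256
        for start in range(0, X.shape[0], batch):
            xb = X[start : start + batch]
            logits, cache = self._forward(xb, training=False, rng=None)
            do_dlogit = _sigmoid(logits) * (1.0 - _sigmoid(logits))
            _, dx = self._backward(do_dlogit, cache)
            grads[start : start + batch] = dx
        return grads


def build_cnn(input_length: int, seed: int = 0) -> CNN1D:
    """Construct the untrained fixed-architecture network."""
    return CNN1D(input_length, seed=seed)


@dataclass
class SaliencyMap:
    """Vanilla-gradient saliency of a test set.

    ``raw_gradients`` are do/dX_i per test spectrum; ``cdf_values`` the
    same derivatives mapped through the empirical CDF of the pooled
    derivative set (ties averaged, values in (0, 1)). ``mean``/``lo95``/
    ``hi95`` summarize the CDF values per wavenumber across spectra.
    """

    wavenumbers: np.ndarray
    raw_gradients: np.ndarray
    cdf_values: np.ndarray
    mean: np.ndarray = field(init=False)
    lo95: np.ndarray = field(init=False)
    hi95: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.cdf_values.mean(axis=0)
        n = self.cdf_values.shape[0]
        sem = self.cdf_values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(self.mean)
        self.lo95 = self.mean - 1.96 * sem
        self.hi95 = self.mean + 1.96 * sem


def vanilla_gradient_saliency(
    model: CNN1D,
    testset: SpectralDataset | np.ndarray,
    wavenumbers: np.ndarray | None = None,
    per_wavenumber_cdf: bool = False,
) -> SaliencyMap:
    """Saliency map of a trained network on a test set.

    The empirical CDF is taken over the pooled N_test x p derivatives by
    default (``per_wavenumber_cdf=True`` ranks within each wavenumber
    column instead). A constant derivative field maps to CDF value 0.5
    everywhere.
    """
    if isinstance(testset, SpectralDataset):
        X = testset.intensities
        wavenumbers = testset.wavenumbers
    else:
        X = np.atleast_2d(np.asarray(testset, dtype=float))
        if wavenumbers is None:
            wavenumbers = np.arange(X.shape[1], dtype=float)
    if X.shape[0] == 0:
        raise InsufficientDataError("saliency needs a non-empty test set")
    raw = model.input_gradient(X)
    if per_wavenumber_cdf:
        cdf = (rankdata(raw, axis=0) - 0.5) / raw.shape[0]
    else:
        cdf = ((rankdata(raw.ravel()) - 0.5) / raw.size).reshape(raw.shape)
    return SaliencyMap(wavenumbers=np.asarray(wavenumbers), raw_gradients=raw, cdf_values=cdf)


class CNNClassifier:
    """fit/scores wrapper so the network plugs into ``cross_validate``."""

    def __init__(self, epochs: int = 50, seed: int = 0, batch_size: int = 64,
                 learning_rate: float = 0.001, early_stopping: bool = True,
                 patience: int = 10):
        self.config = TrainConfig(
            learning_rate=learning_rate,
            batch_size=batch_size,
            epochs=epochs,
            early_stopping=early_stopping,
            patience=patience,
        )
        self.seed = seed
        self.model: CNN1D | None = None

    def fit(self, ds: SpectralDataset) -> "CNNClassifier":
        self.model = CNN1D(ds.n_points, seed=self.seed)
        self.model.fit(ds.intensities, ds.labels, self.config)
        return self

    def scores(self, ds: SpectralDataset) -> np.ndarray:
        return self.model.predict_proba(ds.intensities)
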