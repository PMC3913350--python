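"""Feed-forward MLP with Bayesian-regularized Levenberg-Marquardt training.

Small tanh/linear perceptrons trained by minimizing

    F = beta * E_D + alpha * E_W

where E_D is the sum of squared errors on min-max-scaled targets and E_W
the sum of squared weights and biases.  alpha and beta are re-estimated
each epoch by the MacKay evidence approximation with a Gauss-Newton
Hessian H = beta JtJ + alpha I:

    gamma = N_w - alpha * tr(H^-1)
    alpha <- gamma / (2 E_W)
    beta  <- (n - gamma) / (2 E_D)      (skipped while gamma >= n)

gamma is the effective number of parameters; the beta update is guarded
because these nets routinely carry more weights than training points.
Inputs and targets are scaled per feature to [-1, 1] using the training
split only, matching the operating range of the tanh layers.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

__all__ = [
    "MLPArchitecture",
    "AffineScaler",
    "MLPModel",
    "SupervisedSet",
    "TrainResult",
    "EvalResult",
    "ann1_architecture",
    "ann2_architecture",
    "forward",
    "loss",
    "train_bayes",
    "evaluate",
    "save_model",
    "load_model",
    "make_split",
    "loss_gradient",
    "model_to_dict",
    "model_from_dict",
]


@dataclasses.dataclass(frozen=True)
class MLPArchitecture:
    """Layer sizes plus activation names (tanh hidden, linear output)."""

    layer_sizes: tuple
    hidden_activation: str = "tanh"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 3:
            raise ValueError("need at least input, one hidden and output layer")
        if any(s <= 0 for s in sizes):
            raise ValueError("layer sizes must be strictly positive")
        if sizes[-1] != 1:
            raise ValueError("single-output networks only")
        if self.hidden_activation != "tanh" or self.output_activation != "linear":
            raise ValueError("only tanh hidden / linear output supported")
        object.__setattr__(self, "layer_sizes", sizes)

    @property
    def n_params(self) -> int:
        s = self.layer_sizes
        return sum(s[i + 1] * s[i] + s[i + 1] for i in range(len(s) - 1))


def ann1_architecture() -> MLPArchitecture:
    """6-10-3-1 net: transesterification conditions + triolein consumption -> ester."""
    return MLPArchitecture((6, 10, 3, 1))


def ann2_architecture() -> MLPArchitecture:
    """5-6-2-1 net: feed composition, initial state and day -> cumulative methane."""
    return MLPArchitecture((5, 6, 2, 1))


@dataclasses.dataclass(frozen=True)
class AffineScaler:
    """Per-feature affine map onto [-1, 1] fitted on the training split."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        if np.any(hi - lo <= 0):
            bad = np.nonzero(hi - lo <= 0)[0].tolist()
            raise ValueError(f"zero-range feature(s) {bad}: scaling not invertible")
        return cls(lo, hi)

    def scale(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(X, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def unscale(self, Xs: np.ndarray) -> np.ndarray:
        return (np.asarray(Xs, dtype=float) + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


@dataclasses.dataclass
class SupervisedSet:
    """Raw supervised samples with disjoint, covering train/test/validation splits."""

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray
    feature_names: tuple = ()
    meta: dict = dataclasses.field(default_factory=dict)  # per-row provenance arrays

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        idx = [np.asarray(s, dtype=int) for s in (self.train_idx, self.test_idx, self.val_idx)]
        self.train_idx, self.test_idx, self.val_idx = idx
        allidx = np.concatenate(idx)
        if len(np.unique(allidx)) != len(allidx) or len(allidx) != len(self.y):
            raise ValueError("splits must be disjoint and cover all rows")

    def subset(self, name: str) -> tuple:
        idx = {"train": self.train_idx, "test": self.test_idx, "validation": self.val_idx}[name]
        return self.X[idx], self.y[idx]


@dataclasses.dataclass
class MLPModel:
    architecture: MLPArchitecture
    weights: list  # per-layer (n_out, n_in) matrices
    biases: list  # per-layer (n_out,) vectors
    input_scale: AffineScaler
    output_scale: AffineScaler
    alpha: float = 0.0
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.architecture.layer_sizes
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[i + 1], sizes[i]) or b.shape != (sizes[i + 1],):
                raise ValueError(f"layer {i} weight/bias shape inconsistent with architecture")

    # --- parameter vector ---------------------------------------------------
    def get_flat(self) -> np.ndarray:
        parts = []
        for W, b in zip(self.weights, self.biases):
            parts.append(W.ravel())
            parts.append(b)
        return np.concatenate(parts)

    def set_flat(self, w: np.ndarray) -> None:
        pos = 0
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = w[pos : pos + W.size].reshape(W.shape)
            pos += W.size
            self.biases[i] = w[pos : pos + b.size].copy()
            pos += b.size

    # --- forward ------------------------------------------------------------
    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Propagate scaled inputs (n, p) to scaled outputs (n,)."""
        a = np.atleast_2d(Xs)
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W.T + b
            a = z if i == last else np.tanh(z)
        return a[:, 0]

    def forward(self, x: np.ndarray) -> float | np.ndarray:
        """Raw input(s) -> raw output; accepts one vector or a batch matrix."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.architecture.layer_sizes[0]:
            raise ValueError(
                f"expected {self.architecture.layer_sizes[0]} inputs, got {X.shape[1]}"
            )
        ys = self.forward_scaled(self.input_scale.scale(X))
        y = self.output_scale.unscale(ys[:, None])[:, 0]
        return float(y[0]) if single else y


def _init_params(arch: MLPArchitecture, seed: int) -> tuple:
    """Fan-in-scaled uniform initialization, seeded."""
    rng = np.random.default_rng(seed)
    sizes = arch.layer_sizes
    weights, biases = [], []
    for i in range(len(sizes) - 1):
        scale = 1.0 / np.sqrt(sizes[i])
        weights.append(rng.uniform(-0.5, 0.5, (sizes[i + 1], sizes[i])) * scale)
        biases.append(rng.uniform(-0.5, 0.5, sizes[i + 1]) * scale)
    return weights, biases


def _forward_pass(weights: list, biases: list, Xs: np.ndarray) -> list:
    """Return activations [a0, a1, ..., aL] for a scaled batch."""
    acts = [np.atleast_2d(Xs)]
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = acts[-1] @ W.T + b
        acts.append(z if i == last else np.tanh(z))
    return acts


def _jacobian(weights: list, biases: list, Xs: np.ndarray) -> tuple:
    """Jacobian d y_hat / d params, shape (n, N_w), plus predictions (n,).

    Backpropagation of the unit output sensitivity through the tanh stack,
    vectorized over the batch.
    """
    acts = _forward_pass(weights, biases, Xs)
    n = acts[0].shape[0]
    L = len(weights)
    # delta[l]: d y / d z_l, shape (n, size_{l+1})
    deltas = [None] * L
    deltas[L - 1] = np.ones((n, weights[L - 1].shape[0]))
    for l in range(L - 2, -1, -1):
        deltas[l] = (deltas[l + 1] @ weights[l + 1]) * (1.0 - acts[l + 1] ** 2)
    blocks = []
    for l in range(L):
        jw = np.einsum("ni,nj->nij", deltas[l], acts[l]).reshape(n, -1)
        blocks.append(jw)
        blocks.append(deltas[l])
    return np.concatenate(blocks, axis=1), acts[-1][:, 0]


def loss(model: MLPModel, Xs: np.ndarray, ys: np.ndarray) -> tuple:
    """Regularized objective on scaled pairs: (F, E_D, E_W)."""
    ys = np.asarray(ys, dtype=float).ravel()
    if len(ys) == 0:
        raise ValueError("loss requires a nonempty dataset")
    r = model.forward_scaled(Xs) - ys
    E_D = float(r @ r)
    w = model.get_flat()
    E_W = float(w @ w)
    return model.beta * E_D + model.alpha * E_W, E_D, E_W


def loss_gradient(model: MLPModel, Xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Analytic gradient of F with respect to the flat parameter vector."""
    J, yhat = _jacobian(model.weights, model.biases, np.atleast_2d(Xs))
    r = yhat - np.asarray(ys, dtype=float).ravel()
    return 2.0 * (model.beta * (J.T @ r) + model.alpha * model.get_flat())


@dataclasses.dataclass
class TrainResult:
    model: MLPModel
    history: list
    converged: bool
    evals: dict = dataclasses.field(default_factory=dict)

    @property
    def gamma(self) -> float:
        return self.history[-1]["gamma"] if self.history else float("nan")


def train_bayes(
    arch: MLPArchitecture,
    data: SupervisedSet,
    max_epochs: int = 300,
    seed: int = 0,
    tol: float = 1e-12,
    alpha0: float = 0.01,
    beta0: float = 1.0,
    mu0: float = 1e-3,
    fixed_hyper: bool = False,
) -> TrainResult:
    """Train an MLP by Bayesian-regularized Levenberg-Marquardt.

    ``fixed_hyper=True`` freezes (alpha0, beta0) as a plain weight-decay
    fallback.  Training is deterministic for a given seed.  Each accepted
    LM step strictly decreases F at the epoch's (alpha, beta); the
    evidence update between epochs may re-level F.
    """
    Xtr, ytr = data.subset("train")
    if len(ytr) == 0:
        raise ValueError("training split is empty")
    in_scale = AffineScaler.fit(Xtr)
    out_scale = AffineScaler.fit(ytr[:, None])
    Xs = in_scale.scale(Xtr)
    ys = out_scale.scale(ytr[:, None])[:, 0]

    weights, biases = _init_params(arch, seed)
    model = MLPModel(arch, weights, biases, in_scale, out_scale, alpha0, beta0, seed)
    w = model.get_flat()
    N_w = len(w)
    n = len(ys)
    alpha, beta = float(alpha0), float(beta0)
    mu = float(mu0)
    I = np.eye(N_w)
    history: list = []
    converged = False
    F_prev = np.inf

    for epoch in range(max_epochs):
        J, yhat = _jacobian(model.weights, model.biases, Xs)
        r = yhat - ys
        E_D = float(r @ r)
        E_W = float(w @ w)
        JtJ = J.T @ J
        gamma = float(N_w)
        if not fixed_hyper and epoch > 0:
            H = beta * JtJ + alpha * I
            try:
                Hinv_tr = float(np.trace(np.linalg.inv(H)))
            except np.linalg.LinAlgError:
                Hinv_tr = float(np.trace(np.linalg.inv(H + 1e-10 * I)))
            gamma = min(max(N_w - alpha * Hinv_tr, 0.0), float(N_w))
            alpha = min(max(gamma / max(2.0 * E_W, 1e-12), 1e-12), 1e12)
            if n > gamma:  # evidence beta update ill-posed while gamma >= n
                beta = min(max((n - gamma) / max(2.0 * E_D, 1e-12), 1e-12), 1e12)
        F = beta * E_D + alpha * E_W
        g = 2.0 * (beta * (J.T @ r) + alpha * w)
        A = 2.0 * (beta * JtJ + alpha * I)

        accepted = False
        F_new = F
        while mu <= 1e10:
            try:
                dw = np.linalg.solve(A + mu * I, -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_try = w + dw
            model.set_flat(w_try)
            r_try = model.forward_scaled(Xs) - ys
            E_D_try = float(r_try @ r_try)
            E_W_try = float(w_try @ w_try)
            F_try = beta * E_D_try + alpha * E_W_try
            if F_try < F:
                w = w_try
                F_new, E_D, E_W = F_try, E_D_try, E_W_try
                mu = max(mu * 0.1, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            model.set_flat(w)  # restore best parameters

        history.append(
            {
                "epoch": epoch,
                "F_pre": F,
                "F_post": F_new,
                "E_D": E_D,
                "E_W": E_W,
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "mu": mu,
                "grad_norm": float(np.max(np.abs(g))),
            }
        )
        if not accepted or np.max(np.abs(g)) < 1e-10:
            converged = True
            break
        if abs(F_prev - F_new) <= tol * (1.0 + F_new):
            converged = True
            break
        F_prev = F_new

    model.set_flat(w)
    model.alpha, model.beta = alpha, beta
    return TrainResult(model=model, history=history, converged=converged)


@dataclasses.dataclass
class EvalResult:
    rmse: float
    max_rel_err: float
    n: int
    n_rel: int  # points above the relative-error floor


def evaluate(
    model: MLPModel, data: SupervisedSet, subset: str, rel_floor: float = 1e-3
) -> EvalResult:
    """RMSE and maximum relative error of the model on one split.

    Relative errors are taken only over observations with |obs| > rel_floor
    (the metric is ill-conditioned where the measured quantity vanishes,
    e.g. cumulative production at start-up); all points enter the RMSE.
    """
    X, y = data.subset(subset)
    if len(y) == 0:
        raise ValueError(f"subset '{subset}' is empty")
    pred = np.atleast_1d(model.forward(X))
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    mask = np.abs(y) > rel_floor
    if mask.any():
        max_rel = float(np.max(np.abs(pred[mask] - y[mask]) / np.abs(y[mask])))
    else:
        max_rel = float("nan")
    return EvalResult(rmse, max_rel, len(y), int(mask.sum()))


# --- serialization ----------------------------------------------------------
def model_to_dict(model: MLPModel) -> dict:
    return {
        "layer_sizes": list(model.architecture.layer_sizes),
        "hidden_activation": model.architecture.hidden_activation,
        "output_activation": model.architecture.output_activation,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_lo": model.input_scale.lo.tolist(),
        "input_hi": model.input_scale.hi.tolist(),
        "output_lo": model.output_scale.lo.tolist(),
        "output_hi": model.output_scale.hi.tolist(),
        "alpha": model.alpha,
        "beta": model.beta,
        "seed": model.seed,
    }


def model_from_dict(d: dict) -> MLPModel:
    arch = MLPArchitecture(
        tuple(d["layer_sizes"]), d["hidden_activation"], d["output_activation"]
    )
    return MLPModel(
        architecture=arch,
        weights=[np.array(W, dtype=float) for W in d["weights"]],
        biases=[np.array(b, dtype=float) for b in d["biases"]],
        input_scale=AffineScaler(np.array(d["input_lo"]), np.array(d["input_hi"])),
        output_scale=AffineScaler(np.array(d["output_lo"]), np.array(d["output_hi"])),
        alpha=float(d["alpha"]),
        beta=float(d["beta"]),
        seed=int(d["seed"]),
    )


def save_model(path, model: MLPModel) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> MLPModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def forward(model: MLPModel, x: np.ndarray):
    """Functional alias for :meth:`MLPModel.forward`."""
    return model.forward(x)


def make_split(
    n: int, n_train: int, n_test: int, seed: int, forced_val: Sequence[int] = ()
) -> tuple:
    """Seeded random index split; ``forced_val`` rows always go to validation."""
    forced = np.asarray(sorted(forced_val), dtype=int)
    rng = np.random.default_rng(seed)
    rest = np.setdiff1d(np.arange(n), forced)
    perm = rng.permutation(rest)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train : n_train + n_test])
    val = np.sort(np.concatenate([forced, perm[n_train + n_test :]]))
    return train, test, val
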