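"""Feed-forward surrogate of the response surface with width selection.

A single-hidden-layer network (3 inputs - h tanh units - 1 affine output)
stands in for the quadratic polynomial as the objective handed to the genetic
optimizer.  Training mimics the classical MATLAB workflow: inputs mapped to
[-1, 1], output standardized, weights fitted by Levenberg-Marquardt (damped
Gauss-Newton on the training residuals) with early stopping at the epoch of
best validation MSE after six consecutive validation increases.

The hidden-layer width is chosen by the degree of approximation

    Da = c / [ (n_c/n) RMSE_c + (n_t/n) RMSE_t + |RMSE_c - RMSE_t| ],  c = 3,

where RMSE_c is over the calibration (training) subset and RMSE_t over the
held-out subset (validation plus test).  The weighted sum rewards overall
accuracy and the absolute-difference term penalizes widths that overfit the
calibration runs; larger Da is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import DesignMatrix, ResponseVector

__all__ = [
    "DataSplit",
    "TrainConfig",
    "SurrogateModel",
    "DaScore",
    "split_data",
    "train_network",
    "degree_of_approximation",
    "select_hidden_nodes",
]


@dataclass(frozen=True)
class DataSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split subsets overlap")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def split_data(n_runs: int,
               fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
               seed: int = 0) -> DataSplit:
    """Random disjoint train/validation/test indices with subset sizes by
    largest-remainder rounding (15 runs at 70/15/15 -> 11/2/2)."""
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ideal = fr * n_runs
    sizes = np.floor(ideal).astype(int)
    for _ in range(n_runs - sizes.sum()):
        k = int(np.argmax(ideal - sizes))
        sizes[k] += 1
    if np.any(sizes == 0):
        raise ValueError(f"subset of size 0 for n={n_runs}, fractions={fractions}")
    perm = np.random.default_rng(seed).permutation(n_runs)
    a, b = sizes[0], sizes[0] + sizes[1]
    return DataSplit(np.sort(perm[:a]), np.sort(perm[a:b]), np.sort(perm[b:]),
                     seed=seed)


@dataclass
class TrainConfig:
    max_epochs: int = 1000
    max_val_fail: int = 6       # consecutive validation-MSE increases allowed
    mu_init: float = 1e-3       # LM damping: x10 on failed step, /10 on success
    mu_max: float = 1e10
    output_init_scale: float = 0.1
    seed: int = 0


@dataclass
class SurrogateModel:
    hidden_nodes: int
    w1: np.ndarray              # (h, 3) input->hidden weights
    b1: np.ndarray              # (h,)
    w2: np.ndarray              # (h,) hidden->output weights
    b2: float
    x_center: np.ndarray        # input scaling: xs = (x - center) / half_range
    x_half_range: np.ndarray
    y_mean: float               # output standardization
    y_std: float
    split: DataSplit | None = None
    training_trace: dict[str, list[float]] = field(default_factory=dict)

    def _forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        return np.tanh(xs @ self.w1.T + self.b1) @ self.w2 + self.b2

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Predicted yield (original units) at coded points (n, 3) or (3,)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        xs = (p - self.x_center) / self.x_half_range
        return self._forward_scaled(xs) * self.y_std + self.y_mean


@dataclass
class DaScore:
    hidden_nodes: int
    rmse_calibration: float
    rmse_test: float
    n_c: int
    n_t: int
    c: float
    error_score: float
    da: float

    @property
    def n(self) -> int:
        return self.n_c + self.n_t


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, h, d):
    i = h * d
    return theta[:i].reshape(h, d), theta[i:i + h], theta[i + h:i + 2 * h], theta[-1]


def _nguyen_widrow_init(rng: np.random.Generator, h: int, d: int,
                        output_scale: float) -> np.ndarray:
    """Nguyen-Widrow hidden layer (unit directions scaled to 0.7 h^(1/d),
    biases spread evenly over the active range) with small random output
    weights, so the initial net is smooth and early LM epochs fit broad
    trends before any fine structure."""
    beta = 0.7 * h ** (1.0 / d)
    w1 = rng.normal(size=(h, d))
    w1 *= beta / np.linalg.norm(w1, axis=1, keepdims=True)
    b1 = beta * np.linspace(-1.0, 1.0, h) * np.sign(w1[:, 0])
    w2 = rng.normal(scale=output_scale, size=h)
    return np.concatenate([w1.ravel(), b1, w2, [0.0]])


def _residuals_and_jacobian(theta, xs, t, h, d):
    w1, b1, w2, b2 = _unpack(theta, h, d)
    z = xs @ w1.T + b1
    a = np.tanh(z)
    e = a @ w2 + b2 - t
    da = (1.0 - a * a) * w2            # (n, h)
    J = np.concatenate([
        (da[:, :, None] * xs[:, None, :]).reshape(len(xs), h * d),
        da,
        a,
        np.ones((len(xs), 1)),
    ], axis=1)
    return e, J


def train_network(split: DataSplit, design: DesignMatrix, y: ResponseVector,
                  hidden_nodes: int,
                  config: TrainConfig | None = None) -> SurrogateModel:
    """Levenberg-Marquardt training of a 3-h-1 network on the training subset,
    returning the weights from the epoch of lowest validation MSE."""
    if hidden_nodes < 1:
        raise ValueError("hidden_nodes must be >= 1")
    cfg = config or TrainConfig()
    X = np.asarray(design.runs, dtype=float)
    t_raw = np.asarray(y.values, dtype=float)
    if not np.all(np.isfinite(t_raw)):
        raise ValueError("responses must be finite")
    if len(t_raw) != len(X):
        raise ValueError("design/response length mismatch")

    # scaling fixed from the full dataset (deterministic, invertible)
    xmin, xmax = X.min(axis=0), X.max(axis=0)
    center = (xmax + xmin) / 2.0
    half = np.where(xmax > xmin, (xmax - xmin) / 2.0, 1.0)
    y_mean, y_std = float(t_raw.mean()), float(t_raw.std())
    if y_std == 0:
        y_std = 1.0
    xs_all = (X - center) / half
    ts_all = (t_raw - y_mean) / y_std

    h, d = hidden_nodes, X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    theta = _nguyen_widrow_init(rng, h, d, cfg.output_init_scale)

    tr, va = split.train, split.validation
    xs_tr, ts_tr = xs_all[tr], ts_all[tr]

    def mse(th, idx):
        w1, b1, w2, b2 = _unpack(th, h, d)
        pred = np.tanh(xs_all[idx] @ w1.T + b1) @ w2 + b2
        return float(np.mean((pred - ts_all[idx]) ** 2))

    trace: dict[str, list[float]] = {"train": [], "validation": [], "test": []}
    mu = cfg.mu_init
    # best-validation snapshot is taken over trained epochs only, never the
    # random initial weights
    best_theta, best_val, val_fail = None, np.inf, 0
    e, J = _residuals_and_jacobian(theta, xs_tr, ts_tr, h, d)
    sse = float(e @ e)

    for _ in range(cfg.max_epochs):
        JtJ, Jte = J.T @ J, J.T @ e
        stepped = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(len(theta)), -Jte)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + delta
            e_new, J_new = _residuals_and_jacobian(cand, xs_tr, ts_tr, h, d)
            sse_new = float(e_new @ e_new)
            if sse_new < sse:
                theta, e, J, sse = cand, e_new, J_new, sse_new
                mu = max(mu / 10.0, 1e-20)
                stepped = True
                break
            mu *= 10.0
        if not stepped:
            break
        trace["train"].append(sse / len(tr))
        trace["validation"].append(mse(theta, va))
        trace["test"].append(mse(theta, split.test))
        v = trace["validation"][-1]
        if v < best_val - 1e-15:
            best_val, best_theta, val_fail = v, theta.copy(), 0
        else:
            val_fail += 1
            if val_fail >= cfg.max_val_fail:
                break
        if sse / len(tr) < 1e-14:
            break
    if best_theta is None:
        best_theta = theta

    w1, b1, w2, b2 = _unpack(best_theta, h, d)
    return SurrogateModel(h, w1, b1, w2, float(b2), center, half,
                          y_mean, y_std, split=split, training_trace=trace)


def degree_of_approximation(model: SurrogateModel, design: DesignMatrix,
                            y: ResponseVector, c: float = 3.0) -> DaScore:
    """Degree-of-approximation score of a trained surrogate on its own split
    (calibration = training subset; test = validation plus test subsets)."""
    split = model.split
    if split is None:
        raise ValueError("model carries no data split")
    held = np.concatenate([split.validation, split.test])
    if len(split.train) == 0 or len(held) == 0:
        raise ValueError("empty calibration or test subset")
    t = np.asarray(y.values, dtype=float)
    pred = model.predict(design.runs)
    rmse_c = float(np.sqrt(np.mean((pred[split.train] - t[split.train]) ** 2)))
    rmse_t = float(np.sqrt(np.mean((pred[held] - t[held]) ** 2)))
    n_c, n_t = len(split.train), len(held)
    n = n_c + n_t
    err = (n_c / n) * rmse_c + (n_t / n) * rmse_t + abs(rmse_c - rmse_t)
    da = c / err if err > 0 else float("inf")
    return DaScore(model.hidden_nodes, rmse_c, rmse_t, n_c, n_t, c, err, da)


def select_hidden_nodes(design: DesignMatrix, y: ResponseVector,
                        widths=range(1, 16), seeds=range(10),
                        config: TrainConfig | None = None,
                        c: float = 3.0) -> tuple[int, dict[int, float]]:
    """Pick the hidden-layer width with the largest median Da over seeds.

    Each (width, seed) pair trains a fresh network on its own random 11/2/2
    split; ties go to the smaller width.  Returns the winner and the full
    median-Da trace for plotting.
    """
    widths = list(widths)
    if not widths:
        raise ValueError("empty width range")
    base = config or TrainConfig()
    trace: dict[int, float] = {}
    for h in widths:
        das = []
        for s in seeds:
            split = split_data(design.n_runs, seed=int(s))
            cfg = TrainConfig(**{**base.__dict__, "seed": int(s)})
            model = train_network(split, design, y, h, cfg)
            das.append(degree_of_approximation(model, design, y, c=c).da)
        trace[h] = float(np.median(das))
    best = max(trace, key=lambda h: (trace[h], -h))
    return best, trace
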