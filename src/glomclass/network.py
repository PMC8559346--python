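"""Shallow feed-forward network trained with scaled conjugate gradient.

One hidden layer with hyperbolic-tangent-sigmoid activation, a 2-unit
softmax output and mean cross-entropy loss.  Training uses Moller's scaled
conjugate gradient (SCG), a Hessian-free second-order method without line
searches: the curvature along the search direction is approximated by a
finite difference of gradients and regularised by an adaptive
Levenberg-Marquardt scale.

Early stopping monitors the validation loss with a sliding window: training
halts once the loss has failed to improve for ``window`` consecutive epochs
(one epoch = one SCG iteration over the full batch), and the weights of the
best validation epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


def tansig(x: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid activation."""
    return np.tanh(x)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class EarlyStopping:
    """Sliding-window validation-failure criterion.

    ``update`` returns True when the monitored loss has not strictly
    improved for ``window`` consecutive epochs.
    """

    def __init__(self, window: int = 6):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.best = np.inf
        self.best_epoch = -1
        self.failures = 0

    def update(self, loss: float, epoch: int) -> bool:
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.failures = 0
        else:
            self.failures += 1
        return self.failures >= self.window


class ShallowNet:
    """2-class shallow network: tansig hidden layer, softmax output."""

    def __init__(self, n_inputs: int, hidden_size: int, rng: np.random.Generator):
        if hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        self.n_inputs = n_inputs
        self.hidden_size = hidden_size
        # small symmetric init scaled by fan-in
        s1 = 1.0 / np.sqrt(n_inputs)
        s2 = 1.0 / np.sqrt(hidden_size)
        self.W1 = rng.uniform(-s1, s1, size=(n_inputs, hidden_size))
        self.b1 = np.zeros(hidden_size)
        self.W2 = rng.uniform(-s2, s2, size=(hidden_size, 2))
        self.b2 = np.zeros(2)

    # -- flat parameter vector ------------------------------------------------
    def get_weights(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def set_weights(self, w: np.ndarray) -> None:
        n, h = self.n_inputs, self.hidden_size
        o = 0
        self.W1 = w[o : o + n * h].reshape(n, h); o += n * h
        self.b1 = w[o : o + h].copy(); o += h
        self.W2 = w[o : o + h * 2].reshape(h, 2); o += h * 2
        self.b2 = w[o : o + 2].copy()

    # -- forward / loss / gradient -------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, 2); column 1 is the positive class."""
        H = tansig(X @ self.W1 + self.b1)
        return softmax(H @ self.W2 + self.b2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, dtype=float))

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        P = self.forward(X)
        return float(-(Y * np.log(np.clip(P, 1e-12, None))).sum() / len(X))

    def loss_grad(self, w: np.ndarray, X: np.ndarray, Y: np.ndarray):
        self.set_weights(w)
        H = tansig(X @ self.W1 + self.b1)
        P = softmax(H @ self.W2 + self.b2)
        n = len(X)
        loss = float(-(Y * np.log(np.clip(P, 1e-12, None))).sum() / n)
        dZ2 = (P - Y) / n
        gW2 = H.T @ dZ2
        gb2 = dZ2.sum(axis=0)
        dH = dZ2 @ self.W2.T * (1.0 - H**2)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return loss, grad


def scg_step_state(w0: np.ndarray):
    """Initial internal state of the SCG iteration."""
    return {
        "lambda": 1e-6,
        "lambda_bar": 0.0,
        "success": True,
        "p": None,
        "r": None,
    }


def train_scg(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    max_epochs: int = 1000,
    on_epoch: Callable[[int, np.ndarray], bool] | None = None,
    sigma0: float = 1e-5,
    grad_tol: float = 1e-8,
) -> np.ndarray:
    """Moller's scaled conjugate gradient minimisation.

    ``on_epoch(epoch, w)`` is called after every iteration; returning True
    stops training (used for validation-based early stopping).  Returns the
    final weight vector (the caller restores best-epoch weights itself).
    """
    w = w0.copy()
    f, g = fun_grad(w)
    r = -g
    p = r.copy()
    lam, lam_bar = 1e-6, 0.0
    success = True
    delta = 1.0
    n = len(w)
    for epoch in range(1, max_epochs + 1):
        p_norm2 = float(p @ p)
        if p_norm2 < 1e-300:
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_sigma = fun_grad(w + sigma * p)
            s = (g_sigma - g) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun_grad(w + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / mu**2 if mu != 0 else -1.0
        if comparison >= 0:  # successful step
            w = w + alpha * p
            f = f_new
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if epoch % n == 0:  # periodic restart along the gradient
                p = r_new.copy()
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            g = -r
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p_norm2
        lam = min(lam, 1e100)
        if on_epoch is not None and on_epoch(epoch, w):
            break
        if float(r @ r) < grad_tol**2:
            break
    return w


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def one_hot(y: np.ndarray) -> np.ndarray:
    """Binary targets {0, 1} to 2-column one-hot (column 1 = positive)."""
    y = np.asarray(y, dtype=int)
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def train_network(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hidden_size: int,
    rng: np.random.Generator,
    max_epochs: int = 1000,
    early_stop_window: int = 6,
) -> tuple[ShallowNet, TrainingHistory]:
    """Train one network with SCG and validation early stopping.

    Halts when the validation loss has not improved for
    ``early_stop_window`` consecutive epochs (or at ``max_epochs``) and
    restores the weights of the best validation epoch.  Deterministic for a
    fixed ``rng`` state.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training targets contain a single class")
    Y_train = one_hot(y_train)
    Y_val = one_hot(np.asarray(y_val, dtype=int))

    net = ShallowNet(X_train.shape[1], hidden_size, rng)
    history = TrainingHistory()
    stopper = EarlyStopping(early_stop_window)
    best_w = net.get_weights().copy()

    def fun_grad(w):
        return net.loss_grad(w, X_train, Y_train)

    def on_epoch(epoch: int, w: np.ndarray) -> bool:
        nonlocal best_w
        net.set_weights(w)
        vl = net.loss(X_val, Y_val)
        history.train_loss.append(net.loss(X_train, Y_train))
        history.val_loss.append(vl)
        stop = stopper.update(vl, epoch)
        if stopper.best_epoch == epoch:
            best_w = w.copy()
        history.stopped_epoch = epoch
        return stop

    final_w = train_scg(fun_grad, net.get_weights(), max_epochs, on_epoch)
    if history.val_loss and min(history.val_loss) <= net.loss(X_val, Y_val):
        net.set_weights(best_w)
    else:
        net.set_weights(final_w)
    history.best_epoch = stopper.best_epoch
    return net, history
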