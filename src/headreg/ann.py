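"""Feed-forward regression network on concatenated pair features.

A single-hidden-layer network (256 inputs -> 10 hyperbolic-tangent-sigmoid
hidden units -> 6 linear outputs) maps the concatenated MRI/CT feature
vector to the six registration parameters.  Three trainers are provided:

* ``levenberg_marquardt`` — damped Gauss-Newton on the sum-of-squares error,
* ``bayesian_regularization`` — Levenberg-Marquardt minimization of
  ``beta * E_D + alpha * E_W`` with MacKay's evidence rule re-estimating
  alpha and beta each accepted step (gamma = effective number of
  parameters),
* ``scaled_conjugate_gradient`` — Moller's SCG on the sum-of-squares error.

Features and targets are standardized to zero mean / unit variance inside
training (tanh saturation control) and the standardization is inverted at
prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

TRAINERS = ("bayesian_regularization", "levenberg_marquardt", "scaled_conjugate_gradient")


@dataclass(frozen=True)
class ANNConfig:
    n_input: int = 256
    n_hidden: int = 10
    n_output: int = 6
    trainer: str = "bayesian_regularization"
    max_epochs: int = 50
    mu_init: float = 1e-3
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    fixed_alpha: float | None = None  # freeze the regularization strength
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trainer not in TRAINERS:
            raise ValueError(f"unknown trainer {self.trainer!r}; choose from {TRAINERS}")
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer widths must be positive")


class ANNModel:
    """Trained 1-hidden-layer tanh network with standardization stats."""

    def __init__(self, w1, w2, x_mean, x_std, t_mean, t_std, cfg, history):
        self.w1 = w1  # (h, d+1)
        self.w2 = w2  # (o, h+1)
        self.x_mean, self.x_std = x_mean, x_std
        self.t_mean, self.t_std = t_mean, t_std
        self.cfg = cfg
        self.history = history

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, float))
        xs = (x - self.x_mean) / self.x_std
        y = _forward(self.w1, self.w2, xs)[0]
        out = y * self.t_std + self.t_mean
        return out[0] if np.asarray(features).ndim == 1 else out

    @property
    def weight_norm(self) -> float:
        return float(np.sqrt(np.sum(self.w1**2) + np.sum(self.w2**2)))


def _aug(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x, np.ones((x.shape[0], 1))], axis=1)


def _forward(w1, w2, x):
    h = np.tanh(_aug(x) @ w1.T)
    y = _aug(h) @ w2.T
    return y, h


def _pack(w1, w2):
    return np.concatenate([w1.ravel(), w2.ravel()])


def _unpack(w, shapes):
    (h, d1), (o, h1) = shapes
    return w[: h * d1].reshape(h, d1), w[h * d1 :].reshape(o, h1)


def _jacobian(w1, w2, x):
    """Residual Jacobian d y_{ik} / d w for every sample i and output k.

    Returns (r_flat layout helper) an array of shape (N * o, n_w) with the
    W1 block first, W2 block second.
    """
    n = x.shape[0]
    h = np.tanh(_aug(x) @ w1.T)  # (N, h)
    xa = _aug(x)  # (N, d+1)
    ha = _aug(h)  # (N, h+1)
    o = w2.shape[0]
    sech2 = 1.0 - h**2
    j_w1 = np.einsum("kj,ij,ia->ikja", w2[:, :-1], sech2, xa, optimize=True)
    j_w1 = j_w1.reshape(n * o, -1)
    j_w2 = np.einsum("kl,im->iklm", np.eye(o), ha, optimize=True).reshape(n * o, -1)
    return np.concatenate([j_w1, j_w2], axis=1), h


def _sse_and_residual(w1, w2, x, t):
    y, _ = _forward(w1, w2, x)
    r = (y - t).ravel()
    return float(r @ r), r


def _gradient(w1, w2, x, t):
    """Gradient of the SSE by backpropagation (no Jacobian materialized)."""
    y, h = _forward(w1, w2, x)
    dy = 2.0 * (y - t)  # (N, o)
    ha = _aug(h)
    g_w2 = dy.T @ ha
    dh = (dy @ w2[:, :-1]) * (1.0 - h**2)
    g_w1 = dh.T @ _aug(x)
    return _pack(g_w1, g_w2)


def _init_weights(cfg: ANNConfig, d: int):
    rng = np.random.default_rng(cfg.seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d + 1), size=(cfg.n_hidden, d + 1))
    w2 = rng.normal(0.0, 1.0 / np.sqrt(cfg.n_hidden + 1), size=(cfg.n_output, cfg.n_hidden + 1))
    return w1, w2


def _train_lm(x, t, cfg: ANNConfig, bayesian: bool):
    """Levenberg-Marquardt, optionally with Bayesian regularization."""
    w1, w2 = _init_weights(cfg, x.shape[1])
    shapes = (w1.shape, w2.shape)
    w = _pack(w1, w2)
    n_w = w.size
    n_res = t.size
    mu = cfg.mu_init
    alpha = 0.0 if cfg.fixed_alpha is None else cfg.fixed_alpha
    if bayesian and cfg.fixed_alpha is None:
        alpha = 0.01
    beta = 1.0
    history = {"objective": [], "alpha": [], "beta": [], "gamma": []}
    sse, r = _sse_and_residual(w1, w2, x, t)
    for epoch in range(cfg.max_epochs):
        J, _ = _jacobian(w1, w2, x)
        g = 2.0 * (beta * (J.T @ r) + alpha * w)
        if np.max(np.abs(g)) < cfg.grad_tol:
            break
        JtJ = J.T @ J
        Jtr = J.T @ r
        improved = False
        while mu <= cfg.mu_max:
            A = beta * JtJ + (alpha + mu) * np.eye(n_w)
            try:
                delta = sla.cho_solve(sla.cho_factor(A, check_finite=False),
                                      beta * Jtr + alpha * w, check_finite=False)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w - delta
            w1_new, w2_new = _unpack(w_new, shapes)
            sse_new, r_new = _sse_and_residual(w1_new, w2_new, x, t)
            obj_old = beta * sse + alpha * (w @ w)
            obj_new = beta * sse_new + alpha * (w_new @ w_new)
            if obj_new < obj_old:
                w, w1, w2, sse, r = w_new, w1_new, w2_new, sse_new, r_new
                mu = max(mu / 10.0, 1e-20)
                improved = True
                break
            mu *= 10.0
        if not improved:
            break
        gamma = float(n_w)
        if bayesian and cfg.fixed_alpha is None:
            # MacKay evidence update on F = beta*E_D + alpha*E_W;
            # tr(H^-1) = ||L^-T||_F^2 from the Cholesky factor of H
            H = 2.0 * beta * JtJ + 2.0 * alpha * np.eye(n_w)
            L = sla.cholesky(H, lower=True, check_finite=False)
            Linv, info = sla.lapack.dtrtri(L, lower=1)
            if info != 0:
                raise np.linalg.LinAlgError("triangular inverse failed in evidence update")
            tr_hinv = float(np.sum(Linv**2))
            gamma = n_w - 2.0 * alpha * tr_hinv
            ew = float(w @ w)
            alpha = gamma / (2.0 * ew) if ew > 1e-12 else alpha
            beta = (n_res - gamma) / (2.0 * sse) if sse > 1e-12 else beta
            alpha = float(np.clip(alpha, 0.0, 1e8))
            beta = float(np.clip(beta, 1e-8, 1e12))
        history["objective"].append(beta * sse + alpha * float(w @ w))
        history["alpha"].append(alpha)
        history["beta"].append(beta)
        history["gamma"].append(gamma)
    return w1, w2, history


def _train_scg(x, t, cfg: ANNConfig):
    """Moller's scaled conjugate gradient on the sum-of-squares error."""
    w1, w2 = _init_weights(cfg, x.shape[1])
    shapes = (w1.shape, w2.shape)
    w = _pack(w1, w2)

    def f(wv):
        a, b = _unpack(wv, shapes)
        return _sse_and_residual(a, b, x, t)[0]

    def grad(wv):
        a, b = _unpack(wv, shapes)
        return _gradient(a, b, x, t)

    sigma0, lam, lam_bar = 5e-5, 5e-7, 0.0
    r = -grad(w)
    p = r.copy()
    success = True
    fw = f(w)
    history = {"objective": [fw]}
    delta = 0.0
    for _ in range(cfg.max_epochs):
        if success:
            p2 = p @ p
            if p2 < 1e-300:
                break
            sigma = sigma0 / np.sqrt(p2)
            s = (grad(w + sigma * p) - grad(w)) / sigma
            delta = p @ s
        delta_reg = delta + (lam - lam_bar) * p2
        if delta_reg <= 0:
            lam_bar = 2.0 * (lam - delta_reg / p2)
            delta_reg = -delta + lam * p2
            lam = lam_bar
        mu_ = p @ r
        alpha_ = mu_ / delta_reg
        fw_new = f(w + alpha_ * p)
        comp = 2.0 * delta_reg * (fw - fw_new) / mu_**2 if mu_ != 0 else -1.0
        if comp >= 0:
            w = w + alpha_ * p
            r_new = -grad(w)
            fw = fw_new
            lam_bar = 0.0
            success = True
            beta_ = (r_new @ r_new - r_new @ r) / mu_
            p = r_new + beta_ * p
            r = r_new
            if comp >= 0.75:
                lam = max(lam / 4.0, 1e-300)
        else:
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam = lam + delta_reg * (1.0 - comp) / p2
        history["objective"].append(fw)
        if np.max(np.abs(r)) < cfg.grad_tol:
            break
    return (*_unpack(w, shapes), history)


def train_ann(features: np.ndarray, targets: np.ndarray, cfg: ANNConfig | None = None) -> ANNModel:
    """Fit the pair-feature regressor.

    ``features`` is (N, n_input), ``targets`` is (N, n_output) on the
    natural parameter scale.
    """
    cfg = cfg or ANNConfig()
    x = np.asarray(features, float)
    t = np.asarray(targets, float)
    if x.ndim != 2 or x.shape[1] != cfg.n_input:
        raise ValueError(f"features must be (N, {cfg.n_input}), got {x.shape}")
    if t.ndim != 2 or t.shape != (x.shape[0], cfg.n_output):
        raise ValueError(f"targets must be (N, {cfg.n_output}), got {t.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values in features or targets")
    if cfg.standardize:
        x_mean, x_std = x.mean(axis=0), x.std(axis=0)
        t_mean, t_std = t.mean(axis=0), t.std(axis=0)
        x_std = np.where(x_std > 1e-12, x_std, 1.0)
        t_std = np.where(t_std > 1e-12, t_std, 1.0)
    else:
        x_mean = np.zeros(x.shape[1]); x_std = np.ones(x.shape[1])
        t_mean = np.zeros(t.shape[1]); t_std = np.ones(t.shape[1])
    xs = (x - x_mean) / x_std
    ts = (t - t_mean) / t_std
    if cfg.trainer == "scaled_conjugate_gradient":
        w1, w2, history = _train_scg(xs, ts, cfg)
    else:
        bayesian = cfg.trainer == "bayesian_regularization" or cfg.fixed_alpha is not None
        w1, w2, history = _train_lm(xs, ts, cfg, bayesian=bayesian)
    return ANNModel(w1, w2, x_mean, x_std, t_mean, t_std, cfg, history)
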