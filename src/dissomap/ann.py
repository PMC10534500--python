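"""Dissolution-profile ANN: 2 inputs -> one tanh hidden layer -> 37 outputs.

The network maps (mean HPMC concentration in w/w %, HPMC particle size in
µm) to the 37 points of the dissolution profile.  It is trained with
Bayesian regularization: Levenberg-Marquardt steps on the objective

    F(w) = beta * E_D + alpha * E_W,
    E_D = sum of squared residuals,  E_W = sum of squared weights,

with the MacKay evidence updates of the hyperparameters after each accepted
step,

    gamma = N - 2 alpha tr(H^-1),   alpha = gamma / (2 E_W),
    beta = (n_res - gamma) / (2 E_D),

where H = 2 beta J'J + 2 alpha I is the Gauss-Newton Hessian and gamma the
effective number of parameters.  Training stops at the epoch cap, when the
objective-gradient infinity norm falls below tolerance, or when the LM
damping exceeds its ceiling (no descent direction left).

Because the network is tiny (<= 437 weights), the Jacobian normal equations
are assembled analytically in closed form; the expensive n_res x n_params
Jacobian is never materialized.

Model selection follows a restart protocol: for each hidden-layer width in
1-10, many independently initialized runs are trained and every trained
model is scored by the mean f2 similarity of its predictions on the
validation tablets (85% truncation applied); the best-scoring model wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .metrics import (
    DissolutionProfile,
    ProfilePair,
    dissolution_time_grid,
    f2_truncated,
)

__all__ = [
    "ANNModel",
    "BayesRegState",
    "SelectionResult",
    "NotFittedError",
    "TrainingFailedError",
    "build_ann",
    "train_bayesreg",
    "train_ensemble",
    "predict_profile",
    "ann_parameter_count",
]

logger = logging.getLogger(__name__)

N_OUTPUTS = 37
HIDDEN_RANGE = (1, 10)
PROFILE_CLAMP = (0.0, 110.0)


class NotFittedError(RuntimeError):
    """Prediction requested from an untrained model."""


class TrainingFailedError(RuntimeError):
    """The LM solver could not make progress (singular system)."""


def ann_parameter_count(n_hidden: int) -> int:
    """Weights + biases of a 2 -> n_hidden -> 37 network."""
    return 2 * n_hidden + n_hidden + N_OUTPUTS * n_hidden + N_OUTPUTS


@dataclass
class BayesRegState:
    """Hyperparameter trajectory of one Bayesian-regularization run."""

    alpha: list[float] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)
    gamma: list[float] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)
    termination: str = ""
    epochs_used: int = 0


class ANNModel:
    """One feedforward 2 -> h -> 37 network with affine input/output scalers."""

    def __init__(self, n_hidden: int, seed: int = 0):
        lo, hi = HIDDEN_RANGE
        if not lo <= n_hidden <= hi:
            raise ValueError(f"n_hidden must be in [{lo}, {hi}], got {n_hidden}")
        self.n_hidden = int(n_hidden)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        h = self.n_hidden
        self.w1 = rng.uniform(-0.5, 0.5, size=(h, 2))
        self.b1 = rng.uniform(-0.5, 0.5, size=h)
        self.w2 = rng.uniform(-0.5, 0.5, size=(N_OUTPUTS, h))
        self.b2 = rng.uniform(-0.5, 0.5, size=N_OUTPUTS)
        self.x_mean = np.zeros(2)
        self.x_std = np.ones(2)
        self.y_mean = np.zeros(N_OUTPUTS)
        self.y_std = np.ones(N_OUTPUTS)
        self.fitted = False

    # -- parameter vector <-> weights -------------------------------------
    @property
    def n_parameters(self) -> int:
        return ann_parameter_count(self.n_hidden)

    def get_params(self) -> np.ndarray:
        inp = np.concatenate([self.w1, self.b1[:, None]], axis=1).ravel()  # (j, [x1 x2 b])
        out = np.concatenate([self.w2, self.b2[:, None]], axis=1).ravel()  # (o, [w.. b])
        return np.concatenate([inp, out])

    def set_params(self, theta: np.ndarray) -> None:
        h = self.n_hidden
        inp = theta[: 3 * h].reshape(h, 3)
        self.w1 = inp[:, :2].copy()
        self.b1 = inp[:, 2].copy()
        out = theta[3 * h :].reshape(N_OUTPUTS, h + 1)
        self.w2 = out[:, :h].copy()
        self.b2 = out[:, h].copy()

    # -- forward ------------------------------------------------------------
    def hidden(self, xz: np.ndarray) -> np.ndarray:
        return np.tanh(xz @ self.w1.T + self.b1)

    def forward_scaled(self, xz: np.ndarray) -> np.ndarray:
        return self.hidden(xz) @ self.w2.T + self.b2

    def scale_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.x_mean) / self.x_std

    def unscale_y(self, yz: np.ndarray) -> np.ndarray:
        return yz * self.y_std + self.y_mean

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Profiles (n, 37) in % released for raw inputs (n, 2)."""
        if not self.fitted:
            raise NotFittedError("model has not been trained")
        x = np.atleast_2d(np.asarray(x, float))
        return np.clip(self.unscale_y(self.forward_scaled(self.scale_x(x))), *PROFILE_CLAMP)


def build_ann(n_hidden: int, seed: int = 0) -> ANNModel:
    """Randomly initialized 2 -> n_hidden -> 37 network, reproducible per seed."""
    return ANNModel(n_hidden, seed)


def _normal_equations(model: ANNModel, xz: np.ndarray, r: np.ndarray):
    """Closed-form J'J and J'r for residuals r = f(x) - y (standardized).

    Exploits the two-layer structure: the Jacobian w.r.t. output-side
    parameters is block sparse (one block per output neuron), and the
    input-side block is low-dimensional (3h columns).
    """
    h = model.n_hidden
    z = model.hidden(xz)  # (n, h)
    d = 1.0 - z**2  # tanh'
    xa = np.concatenate([xz, np.ones((xz.shape[0], 1))], axis=1)  # (n, 3)
    zt = np.concatenate([z, np.ones((z.shape[0], 1))], axis=1)  # (n, h+1)
    u = d[:, :, None] * xa[:, None, :]  # (n, h, 3)

    g_mat = model.w2.T @ model.w2  # (h, h)
    u2 = np.einsum("sji,skl->jikl", u, u, optimize=True)
    block_in = (g_mat[:, None, :, None] * u2).reshape(3 * h, 3 * h)

    p_mat = np.einsum("sji,sk->jik", u, zt, optimize=True)  # (h, 3, h+1)
    cross = np.einsum("oj,jik->jiok", model.w2, p_mat, optimize=True).reshape(
        3 * h, N_OUTPUTS * (h + 1)
    )

    z_gram = zt.T @ zt  # (h+1, h+1)
    block_out = np.kron(np.eye(N_OUTPUTS), z_gram)

    p = 3 * h + N_OUTPUTS * (h + 1)
    jtj = np.empty((p, p))
    jtj[: 3 * h, : 3 * h] = block_in
    jtj[: 3 * h, 3 * h :] = cross
    jtj[3 * h :, : 3 * h] = cross.T
    jtj[3 * h :, 3 * h :] = block_out

    rw2 = r @ model.w2  # (n, h)
    g_in = np.einsum("sji,sj->ji", u, rw2, optimize=True).ravel()
    g_out = (r.T @ zt).ravel()
    jtr = np.concatenate([g_in, g_out])
    return jtj, jtr


def train_bayesreg(
    model: ANNModel,
    x: np.ndarray,
    y: np.ndarray,
    max_epochs: int = 1000,
    grad_tol: float = 1e-7,
    mu0: float = 0.005,
    mu_max: float = 1e10,
    update_hyperparams: bool = True,
    alpha0: float = 0.0,
    beta0: float = 1.0,
) -> BayesRegState:
    """Train ``model`` in place on raw (n, 2) inputs and (n, 37) targets.

    Scalers are fit to the training data; optimization runs in standardized
    units.  With ``update_hyperparams=False`` and ``alpha0=0`` this reduces
    to plain Levenberg-Marquardt on the unregularized MSE.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("x must be (n, 2)")
    if y.shape != (x.shape[0], N_OUTPUTS):
        raise ValueError(f"y must be (n, {N_OUTPUTS})")
    n = x.shape[0]
    if n < max(model.n_parameters // 10, 2):
        logger.warning(
            "only %d samples for %d parameters; fit may be under-determined",
            n, model.n_parameters,
        )
    model.x_mean, model.x_std = x.mean(axis=0), np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    model.y_mean, model.y_std = y.mean(axis=0), np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
    xz = model.scale_x(x)
    yz = (y - model.y_mean) / model.y_std

    alpha, beta = float(alpha0), float(beta0)
    theta = model.get_params()
    n_res = yz.size
    state = BayesRegState()
    mu = mu0

    def objective(th: np.ndarray) -> tuple[float, np.ndarray]:
        model.set_params(th)
        r = model.forward_scaled(xz) - yz
        e_d = float(np.sum(r**2))
        return beta * e_d + alpha * float(np.sum(th**2)), r

    f_cur, r = objective(theta)
    termination = f"max_epochs ({max_epochs}) reached"
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        jtj, jtr = _normal_equations(model, xz, r)
        grad = 2.0 * beta * jtr + 2.0 * alpha * theta
        if np.max(np.abs(grad)) < grad_tol:
            termination = f"gradient below {grad_tol}"
            break
        h_mat = 2.0 * beta * jtj + 2.0 * alpha * np.eye(theta.size)
        accepted = False
        while mu <= mu_max:
            try:
                factor = cho_factor(h_mat + mu * np.eye(theta.size), lower=True)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            step = cho_solve(factor, -grad)
            f_new, r_new = objective(theta + step)
            if f_new < f_cur:
                theta = theta + step
                f_cur, r = f_new, r_new
                mu = max(mu * 0.1, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            model.set_params(theta)
            termination = f"damping exceeded mu_max ({mu_max:g})"
            break

        e_d = float(np.sum(r**2))
        e_w = float(np.sum(theta**2))
        if update_hyperparams:
            # evidence update at the new point
            jtj, _ = _normal_equations(model, xz, r)
            h_mat = 2.0 * beta * jtj + 2.0 * alpha * np.eye(theta.size)
            try:
                factor = cho_factor(h_mat + 1e-12 * np.eye(theta.size), lower=True)
                tr_hinv = float(np.trace(cho_solve(factor, np.eye(theta.size))))
            except np.linalg.LinAlgError:
                tr_hinv = float(np.trace(np.linalg.pinv(h_mat)))
            gamma = theta.size - 2.0 * alpha * tr_hinv
            gamma = float(np.clip(gamma, 1e-3, theta.size))
            alpha = gamma / max(2.0 * e_w, 1e-12)
            beta = max(n_res - gamma, 1e-3) / max(2.0 * e_d, 1e-12)
            f_cur = beta * e_d + alpha * float(np.sum(theta**2))
        else:
            gamma = float(theta.size)
        state.alpha.append(alpha)
        state.beta.append(beta)
        state.gamma.append(gamma)
        state.objective.append(f_cur)
        state.mse.append(e_d / n_res)

    model.set_params(theta)
    model.fitted = True
    state.termination = termination
    state.epochs_used = epoch if epoch else 0
    return state


def predict_profile(model: ANNModel, concentration: float, size: float) -> DissolutionProfile:
    """Predicted 37-point dissolution profile for one tablet's features."""
    released = model.predict(np.array([[concentration, size]]))[0]
    return DissolutionProfile(dissolution_time_grid(), released)


@dataclass
class SelectionResult:
    """Outcome of the restart ensemble: the winner plus the full score table."""

    best_model: ANNModel
    best_n_hidden: int
    best_run: int
    best_score: float
    scores: pd.DataFrame  # columns: n_hidden, run, seed, mean_f2, termination

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def train_ensemble(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    val_profiles: list[DissolutionProfile],
    runs: int = 100,
    hidden_range: range | None = None,
    master_seed: int = 0,
    max_epochs: int = 1000,
) -> SelectionResult:
    """Restart protocol over hidden widths; select by mean validation f2.

    ``val_profiles`` are the measured validation profiles (the f2 reference);
    predictions use the corresponding rows of ``x_val``.  A failed run scores
    -inf and is kept in the table with its error message.
    """
    hidden_range = hidden_range or range(HIDDEN_RANGE[0], HIDDEN_RANGE[1] + 1)
    if len(val_profiles) == 0:
        raise ValueError("validation set must be non-empty")
    x_val = np.asarray(x_val, float)
    if x_val.shape[0] != len(val_profiles):
        raise ValueError("x_val rows must match val_profiles")
    configs = [(h, run) for h in hidden_range for run in range(runs)]
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master_seed).spawn(len(configs))
    ]
    rows = []
    best = (-np.inf, None, None, None)  # score, model, h, run
    for (h, run), seed in zip(configs, seeds):
        model = build_ann(h, seed)
        try:
            state = train_bayesreg(model, x_train, y_train, max_epochs=max_epochs)
            preds = model.predict(x_val)
            scores = []
            for pred, ref in zip(preds, val_profiles):
                pair = ProfilePair(ref, DissolutionProfile(ref.times, pred))
                scores.append(f2_truncated(pair))
            mean_f2 = float(np.mean(scores))
            term = state.termination
        except Exception as exc:  # failed run: scored -inf, logged
            logger.warning("run (h=%d, run=%d) failed: %s", h, run, exc)
            mean_f2, term = -np.inf, f"failed: {exc}"
        rows.append({"n_hidden": h, "run": run, "seed": seed, "mean_f2": mean_f2,
                     "termination": term})
        if mean_f2 > best[0]:
            best = (mean_f2, model, h, run)
    if best[1] is None:
        raise TrainingFailedError("every ensemble run failed")
    table = pd.DataFrame(rows)
    return SelectionResult(best[1], best[2], best[3], best[0], table)
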