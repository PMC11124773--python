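"""The three loud-event classifiers: linear SVM, MLP, and their boosting ensemble.

* **Linear soft-margin SVM** - minimises ``1/2 w'w + C * sum(xi_n)`` subject
  to ``y_n (w'x_n + b) >= 1 - xi_n`` with C = 0.05 by default; the signed
  distance from the separating hyperplane is mapped to a class-1 posterior
  by Platt scaling, ``P(s) = 1 / (1 + exp(A s + B))``.
* **MLP** - one hidden layer of ``d + 2`` tanh units and a softmax output,
  trained on cross-entropy by Moller's scaled conjugate gradient (SCG),
  stopping at 2000 epochs or when the gradient norm falls below a
  tolerance.
* **Ensemble (ELM)** - AdaBoost.M1-style boosting over ten base learners,
  five linear SVMs and five MLPs, combined by ``alpha``-weighted voting;
  class 1 wins when its weighted confidence exceeds class 0's, exact ties
  fall back to class 0 (the conservative non-swallow default).

Labels are {0, 1} at the API surface (class 1 = swallow) and mapped to
{-1, +1} internally where the margin formulation needs signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.svm import SVC

__all__ = [
    "TrainingSet",
    "PlattCalibration",
    "LinearSvmModel",
    "MlpModel",
    "EnsembleModel",
    "PredictionResult",
    "train_linear_svm",
    "fit_platt",
    "train_mlp",
    "train_ensemble",
    "predict",
    "svm_primal_objective",
]


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix plus binary labels, validated for training."""

    x: np.ndarray  # (n, d)
    y: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y)
        if x.ndim != 2:
            raise ValueError("x must be a 2-D (n_samples, n_features) matrix")
        if y.shape != (x.shape[0],):
            raise ValueError("y length must match the number of rows of x")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be in {0, 1}")
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes to be present")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y.astype(np.int64))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]

    @property
    def y_signed(self) -> np.ndarray:
        """Labels mapped to {-1, +1} (class 1 -> +1)."""
        return np.where(self.y == 1, 1.0, -1.0)


@dataclass(frozen=True)
class PlattCalibration:
    """Sigmoid map from a classifier score to a class-1 posterior."""

    a: float
    b: float

    def probability(self, scores: np.ndarray) -> np.ndarray:
        z = self.a * np.asarray(scores, dtype=np.float64) + self.b
        # P = 1 / (1 + exp(z)), computed stably
        return np.exp(-np.logaddexp(0.0, z))


def fit_platt(
    scores: np.ndarray, labels: np.ndarray, regularize: bool = True
) -> PlattCalibration:
    """Fit the sigmoid ``P(s) = 1 / (1 + exp(A s + B))`` by maximum likelihood.

    ``regularize=True`` uses the soft targets ``(N+ + 1)/(N+ + 2)`` and
    ``1/(N- + 2)`` instead of hard 1/0 labels, the standard remedy against
    degenerate sigmoids when scores separate the classes perfectly.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt fitting requires scores from both classes")
    if regularize:
        t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    else:
        t = pos.astype(np.float64)

    def nll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = theta
        z = a * s + b
        nll = float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))
        dz = 1.0 - np.exp(-np.logaddexp(0.0, z)) - (1.0 - t)  # sigma(z) - (1 - t)
        return nll, np.array([np.dot(dz, s), np.sum(dz)])

    theta0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll_and_grad, theta0, jac=True, method="BFGS")
    return PlattCalibration(a=float(res.x[0]), b=float(res.x[1]))


@dataclass(frozen=True)
class LinearSvmModel:
    """Trained linear soft-margin SVM with its Platt calibration."""

    w: np.ndarray
    b: float
    c: float
    slack: np.ndarray  # per-training-sample xi_n, diagnostic
    platt: PlattCalibration

    @property
    def d(self) -> int:
        return len(self.w)

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float64) @ self.w + self.b


def svm_primal_objective(
    w: np.ndarray,
    b: float,
    x: np.ndarray,
    y_signed: np.ndarray,
    c: float,
    sample_weights: np.ndarray | None = None,
) -> float:
    """Primal objective ``1/2 w'w + sum(C_n xi_n)`` at the optimal slacks.

    For fixed (w, b) the optimal slack is the hinge ``max(0, 1 - y f(x))``,
    so this evaluates the soft-margin objective for any candidate solution
    (used both in training diagnostics and oracle comparisons).
    """
    margins = y_signed * (x @ w + b)
    xi = np.maximum(0.0, 1.0 - margins)
    cn = c if sample_weights is None else c * np.asarray(sample_weights)
    return float(0.5 * np.dot(w, w) + np.sum(cn * xi))


def _refine_svm_dual(
    x: np.ndarray,
    y_signed: np.ndarray,
    cn: np.ndarray,
    alpha0: np.ndarray,
    w0: np.ndarray,
    b0: float,
    max_pivots: int = 200,
    kkt_tol: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """Polish a near-optimal dual solution with an active-set QP method.

    The iterative solver stops at a small but nonzero KKT violation; this
    warm-started refinement solves the dual ``min 1/2 a'Qa - 1'a`` subject
    to ``y'a = 0, 0 <= a <= C_n`` exactly on the final active set, pivoting
    variables between the free set and the bounds until the KKT conditions
    hold.  The refined (w, b) is kept only when it lowers the primal
    objective, so the step can never hurt.
    """
    n = len(y_signed)
    xy = x * y_signed[:, None]
    q = xy @ xy.T
    alpha = np.clip(alpha0, 0.0, cn)
    # 0 = at lower bound, 1 = free, 2 = at upper bound
    status = np.where(alpha <= 1e-10, 0, np.where(alpha >= cn - 1e-10, 2, 1))
    beta = b0
    solved = False
    for _ in range(max_pivots):
        at_lo = status == 0
        at_hi = status == 2
        free = np.flatnonzero(status == 1)
        alpha[at_lo] = 0.0
        alpha[at_hi] = cn[at_hi]
        if len(free) == 0:
            # with no free variable, beta is only constrained to an interval
            g = q @ alpha - 1.0
            lows = np.concatenate([-g[at_lo & (y_signed > 0)], g[at_hi & (y_signed < 0)]])
            highs = np.concatenate([g[at_lo & (y_signed < 0)], -g[at_hi & (y_signed > 0)]])
            lo = lows.max() if len(lows) else -np.inf
            hi = highs.min() if len(highs) else np.inf
            if lo <= hi + kkt_tol:
                beta = float(np.clip(0.0, lo, hi)) if np.isfinite(lo) and np.isfinite(hi) else 0.0
                if np.isfinite(lo) and np.isfinite(hi):
                    beta = 0.5 * (lo + hi)
                solved = True
                break
            beta = 0.5 * (lo + hi)
            viol = np.where(at_lo, np.maximum(0.0, -(g + beta * y_signed)), 0.0)
            viol = np.where(at_hi, np.maximum(0.0, g + beta * y_signed), viol)
            status[int(np.argmax(viol))] = 1
            continue
        nf = len(free)
        yf = y_signed[free]
        bound_mask = at_lo | at_hi
        rhs = np.empty(nf + 1)
        rhs[:nf] = 1.0 - q[np.ix_(free, np.flatnonzero(bound_mask))] @ alpha[bound_mask]
        rhs[nf] = -float(y_signed[bound_mask] @ alpha[bound_mask])
        a_mat = np.zeros((nf + 1, nf + 1))
        a_mat[:nf, :nf] = q[np.ix_(free, free)]
        a_mat[:nf, nf] = yf
        a_mat[nf, :nf] = yf
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        target, beta = sol[:nf], float(sol[nf])
        cur = alpha[free]
        step = target - cur
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = np.where(step > 1e-15, (cn[free] - cur) / step, np.inf)
            t_lo = np.where(step < -1e-15, -cur / step, np.inf)
        t_block = np.minimum(t_hi, t_lo)
        blocker = int(np.argmin(t_block))
        if t_block[blocker] < 1.0 - 1e-12:
            alpha[free] = cur + t_block[blocker] * step
            status[free[blocker]] = 2 if t_hi[blocker] <= t_lo[blocker] else 0
            continue
        alpha[free] = target
        g = q @ alpha - 1.0
        kkt = g + beta * y_signed
        viol = np.where(at_lo, np.maximum(0.0, -kkt), 0.0)
        viol = np.where(at_hi, np.maximum(0.0, kkt), viol)
        worst = int(np.argmax(viol))
        if viol[worst] <= kkt_tol:
            solved = True
            break
        status[worst] = 1
    if not solved:
        return w0, b0
    w_new = (alpha * y_signed) @ x
    b_new = beta
    old = svm_primal_objective(w0, b0, x, y_signed, 1.0, cn)
    new = svm_primal_objective(w_new, b_new, x, y_signed, 1.0, cn)
    return (w_new, b_new) if new < old else (w0, b0)


def train_linear_svm(
    x: np.ndarray,
    y: np.ndarray,
    c: float = 0.05,
    sample_weights: np.ndarray | None = None,
    tol: float = 1e-6,
) -> LinearSvmModel:
    """Train the linear soft-margin SVM and its Platt calibration.

    ``sample_weights`` scale each sample's share of C (used by boosting);
    the calibration sigmoid is fitted on the training decision scores.
    The libsvm solution is polished by an exact active-set refinement.
    """
    data = TrainingSet(x, y)
    svc = SVC(kernel="linear", C=c, tol=tol, shrinking=True)
    svc.fit(data.x, data.y_signed, sample_weight=sample_weights)
    w = np.asarray(svc.coef_[0], dtype=np.float64)
    b = float(svc.intercept_[0])
    cn = np.full(data.n, c) if sample_weights is None else c * np.asarray(sample_weights)
    alpha0 = np.zeros(data.n)
    alpha0[svc.support_] = np.abs(svc.dual_coef_[0])
    w, b = _refine_svm_dual(data.x, data.y_signed, cn, alpha0, w, b)
    scores = data.x @ w + b
    slack = np.maximum(0.0, 1.0 - data.y_signed * scores)
    platt = fit_platt(scores, data.y)
    return LinearSvmModel(w=w, b=b, c=c, slack=slack, platt=platt)


# ---------------------------------------------------------------------------
# MLP trained by Moller's scaled conjugate gradient
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MlpModel:
    """One-hidden-layer tanh/softmax network for binary classification."""

    w1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h, 2)
    b2: np.ndarray  # (2,)
    epochs_run: int
    final_grad_norm: float

    @property
    def d(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w1.shape[1]

    def class1_probability(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        hidden = np.tanh(x @ self.w1 + self.b1)
        logits = hidden @ self.w2 + self.b2
        log_p = logits - logsumexp(logits, axis=1, keepdims=True)
        return np.exp(log_p[:, 1])


def _mlp_shapes(d: int, h: int) -> list[tuple[int, ...]]:
    return [(d, h), (h,), (h, 2), (2,)]


def _pack(arrays: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unpack(theta: np.ndarray, shapes: list[tuple[int, ...]]) -> list[np.ndarray]:
    out, i = [], 0
    for shape in shapes:
        size = int(np.prod(shape))
        out.append(theta[i : i + size].reshape(shape))
        i += size
    return out


def _mlp_loss_grad(
    theta: np.ndarray, x: np.ndarray, y_onehot: np.ndarray, shapes
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient by backprop."""
    w1, b1, w2, b2 = _unpack(theta, shapes)
    n = x.shape[0]
    z1 = x @ w1 + b1
    a1 = np.tanh(z1)
    z2 = a1 @ w2 + b2
    log_z = logsumexp(z2, axis=1, keepdims=True)
    loss = float(np.sum(y_onehot * (log_z - z2)) / n)
    p = np.exp(z2 - log_z)
    dz2 = (p - y_onehot) / n
    dw2 = a1.T @ dz2
    db2 = dz2.sum(axis=0)
    dz1 = (dz2 @ w2.T) * (1.0 - a1 * a1)
    dw1 = x.T @ dz1
    db1 = dz1.sum(axis=0)
    return loss, _pack([dw1, db1, dw2, db2])


def _scg_minimize(fun, theta0: np.ndarray, max_epochs: int, grad_tol: float):
    """Moller's scaled conjugate gradient on a full-batch objective.

    ``fun(theta)`` returns (loss, gradient).  One epoch is one SCG
    iteration (at most two gradient and one extra function evaluation).
    Returns (theta, epochs_run, final_grad_norm).
    """
    sigma0 = 1e-5
    lam, lam_bar = 1e-6, 0.0
    theta = theta0.copy()
    f, grad = fun(theta)
    r = -grad
    p = r.copy()
    success = True
    n_params = len(theta)
    delta = 0.0
    k = 0
    for k in range(1, max_epochs + 1):
        r_norm = float(np.linalg.norm(r))
        if r_norm < grad_tol:
            return theta, k - 1, r_norm
        p_sq = float(np.dot(p, p))
        if p_sq == 0.0:
            return theta, k - 1, r_norm
        if success:
            sigma = sigma0 / np.sqrt(p_sq)
            _, grad_plus = fun(theta + sigma * p)
            s = (grad_plus - grad) / sigma
            delta = float(np.dot(p, s))
        # scale the (approximate) Hessian towards positive definiteness
        delta += (lam - lam_bar) * p_sq
        if delta <= 0.0:
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar
        mu = float(np.dot(p, r))
        alpha = mu / delta
        theta_new = theta + alpha * p
        f_new, grad_new = fun(theta_new)
        comparison = 2.0 * delta * (f - f_new) / (mu * mu)
        if comparison >= 0.0:
            theta = theta_new
            f = f_new
            grad = grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()
            else:
                beta = (float(np.dot(r_new, r_new)) - float(np.dot(r_new, r))) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p_sq
        if not np.isfinite(lam) or lam > 1e100:
            return theta, k, float(np.linalg.norm(r))
    return theta, k, float(np.linalg.norm(r))


def train_mlp(
    x: np.ndarray,
    y: np.ndarray,
    hidden_size: int | None = None,
    max_epochs: int = 2000,
    grad_tol: float = 1e-6,
    seed: int = 0,
) -> MlpModel:
    """Train the tanh/softmax MLP with scaled conjugate gradient.

    The hidden layer defaults to ``d + 2`` units.  Training is
    deterministic for a fixed seed (which only controls the Glorot-uniform
    weight initialisation).
    """
    data = TrainingSet(x, y)
    h = hidden_size if hidden_size is not None else data.d + 2
    rng = np.random.default_rng(seed)
    shapes = _mlp_shapes(data.d, h)
    limit1 = np.sqrt(6.0 / (data.d + h))
    limit2 = np.sqrt(6.0 / (h + 2))
    theta0 = _pack(
        [
            rng.uniform(-limit1, limit1, size=(data.d, h)),
            np.zeros(h),
            rng.uniform(-limit2, limit2, size=(h, 2)),
            np.zeros(2),
        ]
    )
    y_onehot = np.eye(2)[data.y]
    fun = lambda th: _mlp_loss_grad(th, data.x, y_onehot, shapes)
    theta, epochs, grad_norm = _scg_minimize(fun, theta0, max_epochs, grad_tol)
    w1, b1, w2, b2 = _unpack(theta, shapes)
    return MlpModel(
        w1=w1, b1=b1, w2=w2, b2=b2, epochs_run=epochs, final_grad_norm=grad_norm
    )


# ---------------------------------------------------------------------------
# Boosting ensemble of SVMs and MLPs
# ---------------------------------------------------------------------------

#: Error floor used when a round classifies every weighted sample correctly.
EPSILON_MIN = 1e-6


@dataclass(frozen=True)
class EnsembleModel:
    """alpha-weighted vote over heterogeneous base learners."""

    learners: tuple
    alphas: np.ndarray
    round_errors: np.ndarray  # weighted error of each retained round

    @property
    def d(self) -> int:
        return self.learners[0].d

    def __post_init__(self) -> None:
        if len(self.learners) != len(self.alphas):
            raise ValueError("one alpha per learner required")


def _base_class1_probability(model, x: np.ndarray) -> np.ndarray:
    if isinstance(model, LinearSvmModel):
        return model.platt.probability(model.decision_scores(x))
    if isinstance(model, MlpModel):
        return model.class1_probability(x)
    raise TypeError(f"unsupported base learner {type(model).__name__}")


def _base_votes(model, x: np.ndarray) -> np.ndarray:
    """Base-learner decisions in {-1, +1} (probability ties -> class 0)."""
    p = _base_class1_probability(model, x)
    return np.where(p > 0.5, 1.0, -1.0)


def train_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    n_svm: int = 5,
    n_mlp: int = 5,
    svm_c: float = 0.05,
    mlp_max_epochs: int = 2000,
    mlp_grad_tol: float = 1e-6,
    seed: int = 0,
    learner_order: str = "alternate",
) -> EnsembleModel:
    """Boost ``n_svm`` linear SVMs and ``n_mlp`` MLPs into one ensemble.

    AdaBoost.M1 loop: each round trains the next base learner under the
    current sample distribution ``D_t`` (SVMs by per-sample C scaling,
    MLPs on a weighted resample of size n), computes the weighted error
    ``eps_t`` and vote weight ``alpha_t = ln((1 - eps_t) / eps_t) / 2``,
    and re-weights samples by ``exp(-alpha_t y h_t(x))``.  A round with
    ``eps_t >= 1/2`` is discarded and the distribution reset to uniform;
    a perfect round gets the capped alpha for ``eps = 1e-6`` and the loop
    continues to the fixed learner budget.  ``learner_order`` is
    "alternate" (SVM, MLP, SVM, ...) or "blocks" (all SVMs then all MLPs).
    """
    data = TrainingSet(x, y)
    if learner_order == "alternate":
        kinds: list[str] = []
        for i in range(max(n_svm, n_mlp) * 2):
            kind = "svm" if i % 2 == 0 else "mlp"
            if kinds.count(kind) < (n_svm if kind == "svm" else n_mlp):
                kinds.append(kind)
        kinds = kinds[: n_svm + n_mlp]
    elif learner_order == "blocks":
        kinds = ["svm"] * n_svm + ["mlp"] * n_mlp
    else:
        raise ValueError(f"unknown learner_order {learner_order!r}")

    rng = np.random.default_rng(seed)
    n = data.n
    dist = np.full(n, 1.0 / n)
    y_signed = data.y_signed
    learners: list = []
    alphas: list[float] = []
    errors: list[float] = []
    for kind in kinds:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if kind == "svm":
            model = train_linear_svm(
                data.x, data.y, c=svm_c, sample_weights=dist * n
            )
        else:
            idx = rng.choice(n, size=n, p=dist)
            # a resample can be single-class under an extreme distribution;
            # fall back to the full set in that rare degenerate case
            if len(np.unique(data.y[idx])) < 2:
                idx = np.arange(n)
            model = train_mlp(
                data.x[idx],
                data.y[idx],
                max_epochs=mlp_max_epochs,
                grad_tol=mlp_grad_tol,
                seed=sub_seed,
            )
        votes = _base_votes(model, data.x)
        eps = float(np.sum(dist[votes != y_signed]))
        if eps >= 0.5:
            dist = np.full(n, 1.0 / n)
            continue
        eps_eff = max(eps, EPSILON_MIN)
        alpha = 0.5 * np.log((1.0 - eps_eff) / eps_eff)
        learners.append(model)
        alphas.append(float(alpha))
        errors.append(eps)
        dist = dist * np.exp(-alpha * y_signed * votes)
        dist /= dist.sum()
    if not learners:
        raise RuntimeError("boosting retained no base learner (all rounds failed)")
    return EnsembleModel(
        learners=tuple(learners),
        alphas=np.asarray(alphas),
        round_errors=np.asarray(errors),
    )


# ---------------------------------------------------------------------------
# Unified prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionResult:
    """Score, class-1 posterior, and hard decision for one or more inputs."""

    score: np.ndarray
    probability: np.ndarray
    predicted_class: np.ndarray


def predict(model, x: np.ndarray) -> PredictionResult:
    """Predict with any trained model; accepts a vector or an (n, d) matrix.

    SVM score is the signed hyperplane distance with its Platt posterior;
    MLP score is the softmax class-1 probability margin ``p1 - p0``; the
    ensemble score is the signed alpha-weighted vote sum with confidence
    ``sum(alpha[h=+1]) / sum(alpha)``.  Probability ties resolve to
    class 0 (non-swallow).
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != model.d:
        raise ValueError(
            f"input dimension {x2.shape[1]} does not match model dimension {model.d}"
        )
    if isinstance(model, LinearSvmModel):
        score = model.decision_scores(x2)
        prob = model.platt.probability(score)
    elif isinstance(model, MlpModel):
        prob = model.class1_probability(x2)
        score = 2.0 * prob - 1.0
    elif isinstance(model, EnsembleModel):
        votes = np.stack([_base_votes(m, x2) for m in model.learners])
        score = model.alphas @ votes
        prob = (model.alphas @ (votes > 0)) / model.alphas.sum()
        cls = (score > 0).astype(np.int64)
        if squeeze:
            return PredictionResult(score[0], prob[0], cls[0])
        return PredictionResult(score, prob, cls)
    else:
        raise TypeError(f"unsupported model {type(model).__name__}")
    cls = (prob > 0.5).astype(np.int64)
    if squeeze:
        return PredictionResult(score[0], prob[0], cls[0])
    return PredictionResult(score, prob, cls)
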