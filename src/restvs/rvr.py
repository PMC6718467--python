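"""Relevance vector regression: sparse Bayesian linear modelling.

The model is y = Phi w + e with Phi = [1 | K], K a (linear) kernel between
subjects, a zero-mean Gaussian prior w_i ~ N(0, 1/alpha_i) with one precision
hyperparameter per basis function (including the bias), and Gaussian noise
e ~ N(0, sigma2 I).  Type-II maximum likelihood drives most alpha_i to
infinity, so only a few "relevance vectors" survive; their posterior mean
defines the predictor.  Hyperparameters follow the classic fixed-point
updates:

    Sigma  = (sigma2^-1 Phi' Phi + diag(alpha))^-1
    mu     = sigma2^-1 Sigma Phi' y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    sigma2  <- ||y - Phi mu||^2 / (n - sum_i gamma_i)

Basis functions with alpha above a pruning threshold are removed; iteration
stops when the largest |delta log alpha| falls below tolerance.  For the
linear kernel the kernel-space weights fold back to a weight per input
feature (here: per connectivity edge), which is what the downstream network
decomposition consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["KernelSpec", "RvrConfig", "RvrModel", "RVR", "RVRResults",
           "build_kernel", "fit_rvr_kernel", "predict", "primal_weights"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel construction: linear Gram matrix, optionally train-mean centred.

    Centring statistics always come from the training features only, so the
    same spec applied to held-out subjects never leaks their data.
    """

    kind: str = "linear"
    center: bool = True

    def __post_init__(self) -> None:
        if self.kind != "linear":
            raise ValueError(f"unsupported kernel kind {self.kind!r}")


@dataclass(frozen=True)
class RvrConfig:
    """Fitting controls for the evidence-maximisation loop."""

    max_iter: int = 1000
    tol: float = 1e-6
    prune_at: float = 1e12
    update_alpha: bool = True
    update_sigma2: bool = True
    alpha_init: float | None = None  # default 1/n^2
    sigma2_init: float | None = None  # default 0.1 * var(y)


def build_kernel(
    X_train: np.ndarray, X_other: np.ndarray, spec: KernelSpec = KernelSpec()
) -> np.ndarray:
    """m x n linear kernel between `X_other` rows and `X_train` rows.

    K = (X_other - xbar_train)(X_train - xbar_train)' when centring.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_other = np.asarray(X_other, dtype=float)
    if X_train.shape[1] != X_other.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X_other.shape[1]} vs {X_train.shape[1]}"
        )
    if spec.center:
        xbar = X_train.mean(axis=0)
        return (X_other - xbar) @ (X_train - xbar).T
    return X_other @ X_train.T


@dataclass
class RvrModel:
    """Fitted sparse-Bayesian state (kernel space).

    ``retained`` indexes the surviving basis functions: -1 is the bias, other
    entries are training-sample indices.  ``mu`` aligns with ``retained``.
    """

    alpha: np.ndarray
    sigma2: float
    mu: np.ndarray
    retained: np.ndarray
    n_train: int
    n_iter: int
    converged: bool
    final_delta: float
    evidence_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def retained_samples(self) -> np.ndarray:
        return self.retained[self.retained >= 0]

    @property
    def bias(self) -> float:
        hit = np.flatnonzero(self.retained == -1)
        return float(self.mu[hit[0]]) if hit.size else 0.0

    @property
    def sample_mu(self) -> np.ndarray:
        return self.mu[self.retained >= 0]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "sigma2": self.sigma2,
            "mu": self.mu.tolist(),
            "retained": self.retained.tolist(),
            "n_train": self.n_train,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def fit_rvr_kernel(K: np.ndarray, y: np.ndarray, config: RvrConfig = RvrConfig()) -> RvrModel:
    """Run the evidence-maximisation updates on a precomputed n x n kernel."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if K.shape != (n, n):
        raise ValueError(f"kernel must be {n}x{n}, got {K.shape}")

    Phi = np.hstack([np.ones((n, 1)), K])
    PhiTPhi = Phi.T @ Phi
    PhiTy = Phi.T @ y
    yTy = float(y @ y)

    var_y = float(y.var())
    sigma2 = config.sigma2_init if config.sigma2_init is not None else 0.1 * var_y
    if sigma2 <= 0:
        sigma2 = 1e-6
    sigma2_floor = max(1e-12 * var_y, 1e-30)
    alpha0 = config.alpha_init if config.alpha_init is not None else 1.0 / n**2

    active = np.arange(n + 1)  # 0 = bias, 1..n = samples
    alpha = np.full(n + 1, alpha0, dtype=float)
    log_alpha = np.log(alpha)
    evidence = []
    converged = False
    delta = np.inf
    it = 0
    eye_cache = np.eye(n + 1)
    for it in range(1, config.max_iter + 1):
        na = active.size
        A = PhiTPhi[np.ix_(active, active)] / sigma2
        A.flat[:: na + 1] += alpha[active]
        L = np.linalg.cholesky(A)
        Linv = solve_triangular(L, eye_cache[:na, :na], lower=True,
                                check_finite=False)
        Sigma = Linv.T @ Linv
        mu = Sigma @ PhiTy[active] / sigma2
        Sigma_diag = np.diag(Sigma)
        gamma = 1.0 - alpha[active] * Sigma_diag

        # log evidence at the current (alpha, sigma2), via the posterior
        logdetH = 2.0 * np.log(np.diag(L)).sum()
        quad = (yTy - PhiTy[active] @ mu) / sigma2
        logdetC = n * np.log(sigma2) - np.log(alpha[active]).sum() + logdetH
        evidence.append(-0.5 * (n * np.log(2 * np.pi) + logdetC + quad))

        if not (np.all(np.isfinite(mu)) and np.isfinite(sigma2)):
            raise FloatingPointError(
                f"non-finite updates at iteration {it} (sigma2={sigma2})"
            )

        if config.update_sigma2:
            resid = y - Phi[:, active] @ mu
            denom = max(n - gamma.sum(), 1e-12)
            sigma2 = max(float(resid @ resid) / denom, sigma2_floor)
        if config.update_alpha:
            mu2 = np.maximum(mu**2, 1e-300)
            new_alpha = np.maximum(gamma, 1e-12) / mu2
            keep = new_alpha <= config.prune_at
            if not keep.any():  # never drop every basis function
                keep[np.argmin(new_alpha)] = True
            delta = float(
                np.abs(np.log(new_alpha[keep]) - log_alpha[active][keep]).max()
            )
            alpha[active] = new_alpha
            log_alpha[active] = np.log(new_alpha)
            active = active[keep]
            if delta < config.tol:
                converged = True
                break
        else:
            # hyperparameters fixed: posterior is closed form, one pass is exact
            converged = True
            delta = 0.0
            break

    # final posterior aligned with the surviving basis
    A = PhiTPhi[np.ix_(active, active)] / sigma2
    A.flat[:: active.size + 1] += alpha[active]
    mu = np.linalg.solve(A, PhiTy[active]) / sigma2

    retained = active - 1  # bias becomes -1
    return RvrModel(
        alpha=alpha[active].copy(),
        sigma2=float(sigma2),
        mu=np.asarray(mu),
        retained=retained,
        n_train=n,
        n_iter=it,
        converged=converged,
        final_delta=delta,
        evidence_trace=np.asarray(evidence),
    )


def predict(model: RvrModel, K_test: np.ndarray) -> np.ndarray:
    """Predictions from kernel columns aligned with the retained samples."""
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    n_ret = int((model.retained >= 0).sum())
    if K_test.shape[1] != n_ret:
        raise ValueError(
            f"K_test has {K_test.shape[1]} columns, expected {n_ret} retained samples"
        )
    return model.bias + K_test @ model.sample_mu


def primal_weights(
    model: RvrModel, X_train: np.ndarray, spec: KernelSpec = KernelSpec()
) -> tuple[np.ndarray, float]:
    """Fold kernel-space weights back to feature space (linear kernel only).

    Returns ``(w, b)`` with predict(x) = w . x + b for any new x.
    """
    if spec.kind != "linear":
        raise ValueError("primal weights are only defined for the linear kernel")
    X_train = np.asarray(X_train, dtype=float)
    idx = model.retained_samples
    mu_s = model.sample_mu
    if idx.size == 0:
        return np.zeros(X_train.shape[1]), model.bias
    if spec.center:
        xbar = X_train.mean(axis=0)
        w = (X_train[idx] - xbar).T @ mu_s
        b = model.bias - float(w @ xbar)
    else:
        w = X_train[idx].T @ mu_s
        b = model.bias
    return w, b


class RVR:
    """Relevance vector regression model on feature rows.

    Parameters
    ----------
    endog : (n,) targets.
    exog : (n, d) feature matrix (e.g. vectorised connectivity edges).
    kernel : KernelSpec, default linear + train-mean centring.
    """

    def __init__(self, endog, exog, kernel: KernelSpec = KernelSpec()):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog row counts differ")
        self.kernel = kernel

    @classmethod
    def from_dataframe(cls, data, target: str, feature_cols=None, **kw) -> "RVR":
        feats = feature_cols or [c for c in data.columns if c != target]
        return cls(data[target].to_numpy(), data[feats].to_numpy(), **kw)

    def fit(self, config: RvrConfig = RvrConfig(), **overrides) -> "RVRResults":
        if overrides:
            config = RvrConfig(**{**config.__dict__, **overrides})
        K = build_kernel(self.exog, self.exog, self.kernel)
        state = fit_rvr_kernel(K, self.endog, config)
        return RVRResults(self, state)


class RVRResults:
    """Fitted RVR: posterior weights, noise level and retained basis."""

    def __init__(self, model: RVR, state: RvrModel):
        self.model = model
        self.state = state

    @property
    def params(self) -> np.ndarray:
        return self.state.mu

    @property
    def sigma2(self) -> float:
        return self.state.sigma2

    @property
    def alpha(self) -> np.ndarray:
        return self.state.alpha

    @property
    def retained(self) -> np.ndarray:
        return self.state.retained

    @property
    def n_relevance_vectors(self) -> int:
        return int((self.state.retained >= 0).sum())

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def predict(self, exog_new) -> np.ndarray:
        K = build_kernel(self.model.exog, np.atleast_2d(exog_new), self.model.kernel)
        return predict(self.state, K[:, self.state.retained_samples])

    def primal_weights(self) -> tuple[np.ndarray, float]:
        return primal_weights(self.state, self.model.exog, self.model.kernel)

    def to_json(self, path) -> None:
        """Serialise the fitted state (posterior, precisions, noise level,
        retained basis, centring statistics and retained training rows)."""
        import json

        s = self.state
        idx = s.retained_samples
        payload = {
            **s.to_dict(),
            "kernel": {"kind": self.model.kernel.kind,
                       "center": self.model.kernel.center},
            "train_mean": self.model.exog.mean(axis=0).tolist(),
            "retained_rows": self.model.exog[idx].tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def predict_from_json(path, exog_new) -> np.ndarray:
        """Predict with a serialised model without refitting."""
        import json

        with open(path) as fh:
            p = json.load(fh)
        X_new = np.atleast_2d(np.asarray(exog_new, dtype=float))
        rows = np.asarray(p["retained_rows"], dtype=float)
        mu = np.asarray(p["mu"])
        retained = np.asarray(p["retained"])
        bias = float(mu[retained == -1][0]) if (retained == -1).any() else 0.0
        if p["kernel"]["center"]:
            xbar = np.asarray(p["train_mean"])
            K = (X_new - xbar) @ (rows - xbar).T
        else:
            K = X_new @ rows.T
        return bias + K @ mu[retained >= 0]

    def summary(self) -> str:
        s = self.state
        lines = [
            "Relevance Vector Regression Results",
            "=" * 44,
            f"{'No. observations:':<28}{s.n_train}",
            f"{'Relevance vectors:':<28}{self.n_relevance_vectors}",
            f"{'Bias retained:':<28}{bool((s.retained == -1).any())}",
            f"{'Noise variance sigma2:':<28}{s.sigma2:.6g}",
            f"{'Iterations:':<28}{s.n_iter}",
            f"{'Converged:':<28}{s.converged}",
            f"{'Final max |dlog alpha|:':<28}{s.final_delta:.3g}",
            "-" * 44,
            f"{'basis':>8}  {'mu':>12}  {'alpha':>12}",
        ]
        for i, b in enumerate(s.retained):
            name = "bias" if b == -1 else f"x[{b}]"
            lines.append(f"{name:>8}  {s.mu[i]:>12.5g}  {s.alpha[i]:>12.5g}")
        return "\n".join(lines)
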