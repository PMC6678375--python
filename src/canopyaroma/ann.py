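"""Aroma prediction from canopy architecture with a Bayesian-regularized net.

Six canopy features (LAI, effective LAI, foliage projective cover, crown
cover, crown porosity, clumping index) predict six GC peak areas (phenethyl
acetate, 2-phenyl-2-butenal, isoamyl acetate, tetramethylpyrazine,
phenylacetaldehyde, 2,3-butanediol).  The model is a two-layer feedforward
network (tan-sigmoid hidden layer, linear output) trained by
Levenberg-Marquardt minimization of the regularized objective

    F(w) = beta * E_D + alpha * E_W,

with ``E_D`` the sum of squared errors, ``E_W`` the sum of squared weights,
and the hyperparameters ``alpha, beta`` re-estimated each epoch by the
MacKay evidence framework (Foresee-Hagan formulation): with Gauss-Newton
Hessian ``H = 2*beta*J'J + 2*alpha*I`` and effective parameter number
``gamma = N_w - 2*alpha*tr(H^-1)``,

    alpha <- gamma / (2 E_W),      beta <- (N - gamma) / (2 E_D).

Inputs and targets are min-max normalized to [-1, 1]; all reported R and
MSE values are on the normalized scale, pooled over samples x 6 targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AROMA_NAMES",
    "NormalizationSpec",
    "normalize_minmax",
    "split_data",
    "BayesRegNetRegressor",
    "StageScore",
    "FitReport",
    "pooled_score",
    "score_model",
    "fit_report",
    "train_br_ann",
    "select_architecture",
    "predict_aromas",
    "AROMA_SCALE_MAX",
]

AROMA_NAMES = [
    "phenethyl_acetate",
    "2_phenyl_2_butenal",
    "isoamyl_acetate",
    "tetramethylpyrazine",
    "phenylacetaldehyde",
    "2_3_butanediol",
]

#: Upper bound of the denormalized GC peak-area scale used on the maps.
AROMA_SCALE_MAX = 60_000.0


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationSpec:
    """Per-column min/max mapping a matrix onto [-1, 1].

    Fitted on training rows only and reused for test and prediction data.
    Constant columns cannot be scaled; they map to 0 (with a warning) and
    invert back to their constant value.
    """

    col_min: np.ndarray
    col_max: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "NormalizationSpec":
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values cannot be normalized")
        spec = cls(col_min=X.min(axis=0), col_max=X.max(axis=0))
        if np.any(spec.col_max == spec.col_min):
            warnings.warn("constant column(s): normalized to 0", stacklevel=2)
        return spec

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.col_max - self.col_min
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - self.col_min) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def inverse_transform(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.asarray(Xn, dtype=float)
        span = self.col_max - self.col_min
        return (Xn + 1.0) / 2.0 * span + self.col_min


def normalize_minmax(
    X: np.ndarray, spec: NormalizationSpec | None = None
) -> tuple[np.ndarray, NormalizationSpec]:
    """Min-max normalize to [-1, 1]; fits a spec when none is given."""
    spec = spec or NormalizationSpec.fit(X)
    return spec.transform(X), spec


def split_data(
    features: np.ndarray,
    targets: np.ndarray,
    train_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Random, reproducible row split into training and testing sets.

    The test size is ``round((1 - train_fraction) * n)`` with half-up
    rounding, so ties round toward training; 173 samples at 0.85 give
    147 training / 26 testing rows.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets must have equal row counts")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_test = int(np.floor((1.0 - train_fraction) * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return (X[train_idx], y[train_idx]), (X[test_idx], y[test_idx])


# ---------------------------------------------------------------------------
# the estimator

class BayesRegNetRegressor(BaseEstimator, RegressorMixin):
    """Two-layer feedforward regressor with Bayesian regularization.

    Parameters
    ----------
    hidden_size : int
        Neurons in the tan-sigmoid hidden layer (3, 5, 7 or 10 in the
        trimming assessment; 10 is the reference architecture).
    max_epochs : int
        Levenberg-Marquardt epoch budget.
    tol : float
        Convergence tolerance on the gradient infinity-norm and on the
        relative objective decrease.
    n_init : int
        Seeded restarts; the fit with the lowest final regularized
        objective is kept.  Training remains deterministic for a fixed
        ``random_state``.
    normalize : bool
        Min-max normalize inputs and targets to [-1, 1] internally (specs
        fitted on the training data and stored on the model).
    random_state : int
        Seed for weight initialization.

    Attributes
    ----------
    coefs_, intercepts_ : list of ndarray
        ``[W1 (H, n_in), W2 (n_out, H)]`` and ``[b1, b2]``.
    alpha_, beta_ : float
        Final regularization hyperparameters.
    gamma_ : float
        Effective number of parameters at convergence.
    x_spec_, y_spec_ : NormalizationSpec
        Stored input/target normalizations.
    n_epochs_ : int
        Epochs run by the selected restart.
    """

    def __init__(
        self,
        hidden_size: int = 10,
        max_epochs: int = 1000,
        tol: float = 1e-7,
        mu_init: float = 0.005,
        mu_inc: float = 10.0,
        mu_dec: float = 0.1,
        mu_max: float = 1e10,
        n_init: int = 3,
        normalize: bool = True,
        random_state: int = 0,
        fixed_alpha_beta: tuple[float, float] | None = None,
    ):
        self.hidden_size = hidden_size
        self.max_epochs = max_epochs
        self.tol = tol
        self.mu_init = mu_init
        self.mu_inc = mu_inc
        self.mu_dec = mu_dec
        self.mu_max = mu_max
        self.n_init = n_init
        self.normalize = normalize
        self.random_state = random_state
        # (alpha, beta) held constant instead of evidence updates; mainly
        # for studying the regularization path
        self.fixed_alpha_beta = fixed_alpha_beta

    # -- parameter vector helpers ------------------------------------------
    def _shapes(self, n_in: int, n_out: int):
        H = self.hidden_size
        return [(H, n_in), (H,), (n_out, H), (n_out,)]

    @staticmethod
    def _unpack(w: np.ndarray, shapes):
        parts, i = [], 0
        for s in shapes:
            n = int(np.prod(s))
            parts.append(w[i : i + n].reshape(s))
            i += n
        return parts

    @staticmethod
    def _forward(Xn, W1, b1, W2, b2):
        z = np.tanh(Xn @ W1.T + b1)
        return z @ W2.T + b2, z

    def _jacobian(self, Xn, z, W2):
        """Jacobian of flattened residuals w.r.t. the packed weight vector."""
        S, H = z.shape
        O = W2.shape[0]
        n_in = Xn.shape[1]
        g = 1.0 - z**2  # (S, H)
        wg = W2[None, :, :] * g[:, None, :]  # (S, O, H)
        J_W1 = (wg[:, :, :, None] * Xn[:, None, None, :]).reshape(S * O, H * n_in)
        J_b1 = wg.reshape(S * O, H)
        J_W2 = np.zeros((S, O, O, H))
        idx = np.arange(O)
        J_W2[:, idx, idx, :] = z[:, None, :]
        J_W2 = J_W2.reshape(S * O, O * H)
        J_b2 = np.zeros((S, O, O))
        J_b2[:, idx, idx] = 1.0
        J_b2 = J_b2.reshape(S * O, O)
        return np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=1)

    def _init_weights(self, rng, shapes) -> np.ndarray:
        parts = []
        for s in shapes:
            fan_in = s[1] if len(s) == 2 else 1
            parts.append(rng.uniform(-0.5, 0.5, size=int(np.prod(s))) / np.sqrt(fan_in))
        return np.concatenate(parts)

    def _train_once(self, Xn, Yn, w0):
        shapes = self._shapes(Xn.shape[1], Yn.shape[1])
        n_obs = Yn.size
        n_w = w0.size
        w = w0.copy()
        fixed = self.fixed_alpha_beta is not None
        alpha, beta = self.fixed_alpha_beta if fixed else (0.0, 1.0)
        mu = self.mu_init
        gamma = float(n_w)

        def residuals(wv):
            W1, b1, W2, b2 = self._unpack(wv, shapes)
            yhat, z = self._forward(Xn, W1, b1, W2, b2)
            return (yhat - Yn).ravel(), z, W2

        e, z, W2 = residuals(w)
        E_D = float(e @ e)
        E_W = float(w @ w)
        F = beta * E_D + alpha * E_W
        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            J = self._jacobian(Xn, z, W2)
            JtJ = J.T @ J
            grad = 2.0 * (beta * (J.T @ e) + alpha * w)
            if np.max(np.abs(grad)) < self.tol:
                break
            # damped Gauss-Newton step on F
            stepped = False
            while mu <= self.mu_max:
                A = 2.0 * beta * JtJ + (2.0 * alpha + mu) * np.eye(n_w)
                try:
                    delta = np.linalg.solve(A, -grad)
                except np.linalg.LinAlgError:
                    mu *= self.mu_inc
                    continue
                w_new = w + delta
                e_new, z_new, W2_new = residuals(w_new)
                E_D_new = float(e_new @ e_new)
                E_W_new = float(w_new @ w_new)
                F_new = beta * E_D_new + alpha * E_W_new
                if not np.isfinite(F_new):
                    raise FloatingPointError(
                        f"non-finite objective at epoch {epoch} "
                        f"(E_D={E_D_new:.3g}, E_W={E_W_new:.3g})"
                    )
                if F_new < F:
                    w, e, z, W2 = w_new, e_new, z_new, W2_new
                    E_D, E_W = E_D_new, E_W_new
                    F_prev, F = F, F_new
                    mu = max(mu * self.mu_dec, 1e-20)
                    stepped = True
                    break
                mu *= self.mu_inc
            if not stepped:
                break  # mu exhausted: local minimum of F
            # evidence-framework hyperparameter re-estimation
            if not fixed:
                H_full = 2.0 * beta * JtJ + 2.0 * alpha * np.eye(n_w)
                try:
                    tr_inv = float(np.trace(np.linalg.inv(H_full)))
                except np.linalg.LinAlgError:
                    tr_inv = 0.0
                gamma = float(np.clip(n_w - 2.0 * alpha * tr_inv, 1.0, min(n_w, n_obs)))
                alpha = gamma / (2.0 * max(E_W, 1e-12))
                beta = (n_obs - gamma) / (2.0 * max(E_D, 1e-12))
                beta = max(beta, 1e-12)
                F = beta * E_D + alpha * E_W
            if abs(F_prev - F_new) <= self.tol * max(F_prev, 1.0) and mu <= self.mu_init:
                break
        return {
            "w": w, "alpha": alpha, "beta": beta, "gamma": gamma,
            "E_D": E_D, "E_W": E_W, "F": F, "epochs": epoch, "shapes": shapes,
        }

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be 2-D with matching row counts")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("training data must be finite")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.normalize:
            self.x_spec_ = NormalizationSpec.fit(X)
            self.y_spec_ = NormalizationSpec.fit(y)
            Xn, Yn = self.x_spec_.transform(X), self.y_spec_.transform(y)
        else:
            self.x_spec_ = None
            self.y_spec_ = None
            Xn, Yn = X, y
        shapes = self._shapes(Xn.shape[1], Yn.shape[1])
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            w0 = self._init_weights(rng, shapes)
            result = self._train_once(Xn, Yn, w0)
            if best is None or result["F"] < best["F"]:
                best = result
        W1, b1, W2, b2 = self._unpack(best["w"], best["shapes"])
        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        self.alpha_ = best["alpha"]
        self.beta_ = best["beta"]
        self.gamma_ = best["gamma"]
        self.n_epochs_ = best["epochs"]
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def _predict_normalized(self, Xn: np.ndarray) -> np.ndarray:
        yhat, _ = self._forward(
            Xn, self.coefs_[0], self.intercepts_[0], self.coefs_[1], self.intercepts_[1]
        )
        return yhat

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        Xn = self.x_spec_.transform(X) if self.x_spec_ is not None else X
        Yn = self._predict_normalized(Xn)
        return self.y_spec_.inverse_transform(Yn) if self.y_spec_ is not None else Yn

    @property
    def weight_norm_(self) -> float:
        check_is_fitted(self, "coefs_")
        return float(
            np.sqrt(
                sum(float(np.sum(a**2)) for a in self.coefs_ + self.intercepts_)
            )
        )

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "coefs_")
        payload = {
            "params": self.get_params(),
            "coefs": [a.tolist() for a in self.coefs_],
            "intercepts": [a.tolist() for a in self.intercepts_],
            "alpha": self.alpha_,
            "beta": self.beta_,
            "gamma": self.gamma_,
            "x_spec": None
            if self.x_spec_ is None
            else {"min": self.x_spec_.col_min.tolist(), "max": self.x_spec_.col_max.tolist()},
            "y_spec": None
            if self.y_spec_ is None
            else {"min": self.y_spec_.col_min.tolist(), "max": self.y_spec_.col_max.tolist()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BayesRegNetRegressor":
        payload = json.loads(Path(path).read_text())
        model = cls(**payload["params"])
        model.coefs_ = [np.array(a) for a in payload["coefs"]]
        model.intercepts_ = [np.array(a) for a in payload["intercepts"]]
        model.alpha_ = payload["alpha"]
        model.beta_ = payload["beta"]
        model.gamma_ = payload["gamma"]
        for attr, spec in (("x_spec_", payload["x_spec"]), ("y_spec_", payload["y_spec"])):
            setattr(
                model,
                attr,
                None
                if spec is None
                else NormalizationSpec(np.array(spec["min"]), np.array(spec["max"])),
            )
        model.n_features_in_ = model.coefs_[0].shape[1]
        model.n_outputs_ = model.coefs_[1].shape[0]
        return model


# ---------------------------------------------------------------------------
# scoring

@dataclass
class StageScore:
    """Pooled fit statistics for one stage (training / testing / overall)."""

    stage: str
    samples: int
    observations: int
    r: float
    mse: float
    outlier_fraction: float
    degenerate: bool = False


@dataclass
class FitReport:
    training: StageScore
    testing: StageScore
    overall: StageScore
    per_size: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(s) for s in (self.training, self.testing, self.overall)])


def _pooled_stats(pred_n: np.ndarray, targ_n: np.ndarray, stage: str) -> StageScore:
    p, t = pred_n.ravel(), targ_n.ravel()
    n_samples = pred_n.shape[0]
    mse = float(np.mean((p - t) ** 2))
    degenerate = bool(np.std(p) == 0 or np.std(t) == 0)
    r = 0.0 if degenerate else float(np.corrcoef(p, t)[0, 1])
    # outliers: points outside the 95% prediction band of the pooled
    # predicted-vs-observed regression line
    if degenerate or len(p) < 3:
        outlier_fraction = 0.0
    else:
        import statsmodels.api as sm

        ols = sm.OLS(p, sm.add_constant(t)).fit()
        frame = ols.get_prediction(sm.add_constant(t)).summary_frame(alpha=0.05)
        outside = (p < frame["obs_ci_lower"].to_numpy()) | (
            p > frame["obs_ci_upper"].to_numpy()
        )
        outlier_fraction = float(outside.mean())
    return StageScore(
        stage=stage,
        samples=n_samples,
        observations=pred_n.size,
        r=r,
        mse=mse,
        outlier_fraction=outlier_fraction,
        degenerate=degenerate,
    )


def pooled_score(
    predictions: np.ndarray, targets: np.ndarray, stage: str = "overall"
) -> StageScore:
    """Pooled R / MSE / outlier fraction for prediction-target matrices."""
    return _pooled_stats(
        np.atleast_2d(np.asarray(predictions, dtype=float)),
        np.atleast_2d(np.asarray(targets, dtype=float)),
        stage,
    )


def score_model(
    model: BayesRegNetRegressor, features: np.ndarray, targets: np.ndarray, stage: str = "overall"
) -> StageScore:
    """Pooled R / MSE over samples x targets on the normalized scale."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    Xn = model.x_spec_.transform(X) if model.x_spec_ is not None else X
    yn = model.y_spec_.transform(y) if model.y_spec_ is not None else y
    pred_n = model._predict_normalized(Xn)
    return _pooled_stats(pred_n, yn, stage)


def fit_report(
    model: BayesRegNetRegressor,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
) -> FitReport:
    X_all = np.vstack([train[0], test[0]])
    y_all = np.vstack([train[1], test[1]])
    return FitReport(
        training=score_model(model, *train, stage="training"),
        testing=score_model(model, *test, stage="testing"),
        overall=score_model(model, X_all, y_all, stage="overall"),
    )


# ---------------------------------------------------------------------------
# thin functional wrappers

def train_br_ann(
    train: tuple[np.ndarray, np.ndarray],
    hidden_size: int = 10,
    seed: int = 0,
    max_epochs: int = 1000,
    tol: float = 1e-7,
) -> BayesRegNetRegressor:
    """Train one Bayesian-regularized network on a (features, targets) pair."""
    model = BayesRegNetRegressor(
        hidden_size=hidden_size, max_epochs=max_epochs, tol=tol, random_state=seed
    )
    return model.fit(*train)


def select_architecture(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    candidate_sizes: tuple[int, ...] = (3, 5, 7, 10),
    seed: int = 0,
    overfit_gap: float = 0.05,
    max_epochs: int = 1000,
    tie_tol: float = 1e-3,
) -> tuple[BayesRegNetRegressor, FitReport]:
    """Trimming assessment over hidden-layer sizes.

    One network is trained per candidate size; the winner has the highest
    test R among candidates whose |train MSE - test MSE| stays below the
    overfitting gap (all candidates if none qualify).  Candidates whose
    test R comes within ``tie_tol`` of the best are considered tied and
    the smallest network wins — the parsimony tie-break.
    """
    if not candidate_sizes:
        raise ValueError("candidate_sizes must be non-empty")
    per_size: dict[int, dict] = {}
    failures: dict[int, str] = {}
    for H in sorted(candidate_sizes):
        try:
            model = train_br_ann(train, hidden_size=H, seed=seed, max_epochs=max_epochs)
            report = fit_report(model, train, test)
            per_size[H] = {"model": model, "report": report}
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            failures[H] = str(exc)
    if not per_size:
        raise RuntimeError(f"all candidate sizes failed: {failures}")
    admissible = {
        H: v
        for H, v in per_size.items()
        if abs(v["report"].training.mse - v["report"].testing.mse) < overfit_gap
    } or per_size
    best_r = max(v["report"].testing.r for v in admissible.values())
    best_H = min(
        H for H, v in admissible.items() if v["report"].testing.r >= best_r - tie_tol
    )
    best = per_size[best_H]
    report = best["report"]
    report.per_size = {
        H: {
            "test_r": v["report"].testing.r,
            "test_mse": v["report"].testing.mse,
            "train_mse": v["report"].training.mse,
        }
        for H, v in per_size.items()
    }
    return best["model"], report


def predict_aromas(
    model: BayesRegNetRegressor,
    features: np.ndarray,
    clip_max: float = AROMA_SCALE_MAX,
) -> np.ndarray:
    """Predict denormalized GC peak areas, clamped to the map scale [0, 60e3].

    Feature rows outside the training min/max trigger an extrapolation
    warning but are still predicted.
    """
    X = np.asarray(features, dtype=float)
    if model.x_spec_ is not None:
        below = X < model.x_spec_.col_min
        above = X > model.x_spec_.col_max
        if np.any(below | above):
            warnings.warn(
                f"{int(np.any(below | above, axis=1).sum())} feature row(s) outside "
                "the training range: predictions are extrapolations",
                stacklevel=2,
            )
    return np.clip(model.predict(X), 0.0, clip_max)
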