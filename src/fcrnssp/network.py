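"""Fully complex-valued relaxation network (FCRN) classifier.

A single-hidden-layer network operating entirely on the complex plane:
inputs are unit-modulus complex features, the K hidden neurons apply
the hyperbolic secant to a random complex projection v_k . z + b_k,
and each of the n output neurons exponentiates a weighted sum of
hidden responses,

    y_hat_l = exp( sum_k  w_lk h_k ).

Class membership is coded as complex labels: the slot of the true
class carries the true-class code, all other slots the false-class
code (antipodal points on the unit circle by default).  Because the
output is an exponential, taking the principal logarithm of the coded
labels turns training into a single linear least-squares problem in
the output weights, solved in closed form (ridge-regularized) — a
projection solve rather than iterative epochs.  Both the magnitude and
the phase of the log-domain error enter the one objective

    min_W  sum_t || W h^t - log y^t ||^2  +  ridge ||W||^2 .

Hidden parameters are drawn once from the seed and never updated.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .chains import SS3_STATES
from .features import minmax_scale_sym, to_unit_circle

__all__ = [
    "FCRNClassifier",
    "sech",
    "encode_labels",
    "decode_labels",
    "DEFAULT_TRUE_CODE",
    "DEFAULT_FALSE_CODE",
    "K_MAX",
]

#: hard cap on hidden-layer width
K_MAX = 100

DEFAULT_TRUE_CODE = np.exp(1j * math.pi / 4)
DEFAULT_FALSE_CODE = np.exp(1j * 5 * math.pi / 4)

#: guard value replacing the (measure-zero) poles of complex sech
_SECH_CLIP = 1e30


def sech(u: np.ndarray) -> np.ndarray:
    """Complex hyperbolic secant 2/(e^u + e^-u), overflow-safe.

    Evaluated as 2 e^{-|Re u|-i Im u sign...}: concretely, with
    s = sign(Re u), sech(u) = 2 e^{-s u} / (1 + e^{-2 s u}), so every
    exponential has non-positive real part and cannot overflow.  The
    true poles of sech at u = i*pi*(k + 1/2) are replaced by a large
    finite value so downstream linear algebra never sees non-finite
    entries.
    """
    u = np.asarray(u, dtype=complex)
    s = np.where(u.real >= 0, 1.0, -1.0)
    eu = np.exp(-s * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * eu / (1.0 + eu * eu)
    bad = ~np.isfinite(out)
    if np.any(bad):
        out = np.where(bad, _SECH_CLIP + 0j, out)
    return out


def encode_labels(
    labels,
    true_code: complex = DEFAULT_TRUE_CODE,
    false_code: complex = DEFAULT_FALSE_CODE,
    classes=SS3_STATES,
) -> np.ndarray:
    """Code symbolic labels as complex (n_samples, n_classes) vectors."""
    labels = np.asarray(labels)
    classes = list(classes)
    idx = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        try:
            idx[i] = classes.index(lab)
        except ValueError:
            raise ValueError(f"unknown label {lab!r} at sample {i}") from None
    y = np.full((len(labels), len(classes)), false_code, dtype=complex)
    y[np.arange(len(labels)), idx] = true_code
    return y


def decode_labels(
    coded: np.ndarray,
    true_code: complex = DEFAULT_TRUE_CODE,
    classes=SS3_STATES,
) -> np.ndarray:
    """Inverse of encode_labels: nearest slot to the true code wins.

    Ties break by class order (H before E before C by default), which
    makes decoding deterministic on degenerate outputs.
    """
    coded = np.asarray(coded, dtype=complex)
    dist = np.abs(coded - true_code)
    return np.asarray(classes)[np.argmin(dist, axis=1)]


class FCRNClassifier(ClassifierMixin, BaseEstimator):
    """Complex-valued relaxation network for 3-state secondary structure.

    Accepts raw real-valued feature matrices; normalization to [-1, 1]
    (with fitted extrema) and the circular map to the unit circle are
    applied internally so a saved model carries everything needed for
    inference on new proteins.

    Parameters
    ----------
    n_hidden : int, default=100
        Hidden-layer width K; capped at 100.
    alpha : float, default=pi/2
        Circular-transform angle; must lie in (0, pi).
    ridge : float, default=1e-8
        Tikhonov term of the closed-form output-weight solve.
    projection_scale : float, default=0.2
        Magnitude of the random hidden projections relative to the
        1/sqrt(m) base scale.  Unit-modulus inputs give |v_k . z| of
        roughly this size, so a value well below pi/2 keeps the
        pre-activation near the bias point, inside the smooth region
        of sech and away from its imaginary-axis poles; the
        unit-circle biases spread the neurons over the activation
        curve and provide feature diversity.
    norm_mode : {'feature', 'vector', None}, default='feature'
        How inputs are scaled to [-1, 1].  None expects inputs already
        in [-1, 1].
    true_code, false_code : complex
        Class-coding constants (unit modulus, distinct).
    random_state : int or None
        Seed for the hidden projections and biases.

    Attributes
    ----------
    classes_ : ndarray — always ('H', 'E', 'C').
    hidden_v_ : complex ndarray (K, m) — projection vectors.
    hidden_b_ : complex ndarray (K,) — biases on the unit circle.
    output_weights_ : complex ndarray (n_classes, K) — w_lk.
    norm_min_, norm_max_ : ndarray (m,) or None — fitted extrema.
    """

    def __init__(
        self,
        n_hidden: int = 100,
        alpha: float = math.pi / 2,
        ridge: float = 1e-8,
        projection_scale: float = 0.2,
        norm_mode: str | None = "feature",
        true_code: complex = DEFAULT_TRUE_CODE,
        false_code: complex = DEFAULT_FALSE_CODE,
        random_state: int | None = None,
    ):
        self.n_hidden = n_hidden
        self.alpha = alpha
        self.ridge = ridge
        self.projection_scale = projection_scale
        self.norm_mode = norm_mode
        self.true_code = true_code
        self.false_code = false_code
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _to_complex(self, X: np.ndarray, fitting: bool) -> np.ndarray:
        """Real features -> unit-circle complex inputs, using fitted extrema."""
        X = np.asarray(X)
        if np.iscomplexobj(X):
            return X  # caller supplies ready-made circle inputs
        X = X.astype(float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.norm_mode is None:
            xn = X
        elif self.norm_mode == "vector":
            xn, _, _ = minmax_scale_sym(X, mode="vector")
        elif fitting:
            xn, self.norm_min_, self.norm_max_ = minmax_scale_sym(X, mode="feature")
        else:
            xn, _, _ = minmax_scale_sym(
                X, self.norm_min_, self.norm_max_, mode="feature"
            )
        return to_unit_circle(xn, self.alpha)

    def _hidden(self, Z: np.ndarray) -> np.ndarray:
        """Hidden responses h_k = sech(v_k . z + b_k) for a batch."""
        return sech(Z @ self.hidden_v_.T + self.hidden_b_)

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Draw hidden parameters from the seed and solve output weights.

        Training is single-shot: the ridge-regularized least-squares
        problem in the log-label domain is solved once via the normal
        equations; there are no epochs.
        """
        y = np.asarray(y)
        X = np.asarray(X)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        K = int(self.n_hidden)
        if not 1 <= K <= K_MAX:
            raise ValueError(f"n_hidden must be in [1, {K_MAX}], got {K}")
        if len(X) < K:
            raise ValueError(
                f"need at least n_hidden={K} training samples, got {len(X)}"
            )
        if abs(self.true_code - self.false_code) < 1e-12:
            raise ValueError("class codes must be distinct")

        self.classes_ = np.asarray(SS3_STATES)
        self.norm_min_ = self.norm_max_ = None  # set by _to_complex in feature mode
        Z = self._to_complex(X, fitting=True)
        m = Z.shape[1]
        self.n_features_in_ = m

        rng = np.random.default_rng(self.random_state)
        self.hidden_v_ = (
            rng.standard_normal((K, m)) + 1j * rng.standard_normal((K, m))
        ) * (self.projection_scale / math.sqrt(2 * m))
        self.hidden_b_ = np.exp(1j * rng.uniform(0, 2 * math.pi, size=K))

        H = self._hidden(Z)  # (T, K)
        Ylog = np.log(
            encode_labels(y, self.true_code, self.false_code, self.classes_)
        )  # principal branch; magnitude and phase of the coded labels
        G = H.conj().T @ H + self.ridge * np.eye(K)
        rhs = H.conj().T @ Ylog
        try:
            A = np.linalg.solve(G, rhs)  # (K, n_classes)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "normal equations are singular; increase ridge above 0"
            ) from None
        self.output_weights_ = A.T
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "output_weights_"):
            raise ValueError("FCRNClassifier is not fitted")

    def hidden_response(self, X) -> np.ndarray:
        """Hidden-layer responses for raw or complex inputs (n, K)."""
        self._check_fitted()
        return self._hidden(self._to_complex(np.asarray(X), fitting=False))

    def decision_function(self, X) -> np.ndarray:
        """Complex network outputs y_hat_l = exp(sum_k w_lk h_k), (n, 3)."""
        self._check_fitted()
        H = self.hidden_response(X)
        return np.exp(H @ self.output_weights_.T)

    def predict(self, X) -> np.ndarray:
        """Predicted 3-state symbols: nearest output to the true-class code."""
        yhat = self.decision_function(X)
        return decode_labels(yhat, self.true_code, self.classes_)

    def score(self, X, y) -> float:
        """Residue accuracy (Q3 / 100) on (X, y)."""
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize the fitted model as a self-describing JSON archive."""
        self._check_fitted()

        def c2ri(a: np.ndarray) -> list:
            a = np.asarray(a, dtype=complex)
            return [a.real.tolist(), a.imag.tolist()]

        doc = {
            "format": "fcrnssp-model",
            "version": 1,
            "m": int(self.n_features_in_),
            "n_classes": len(self.classes_),
            "n_hidden": int(self.n_hidden),
            "alpha": self.alpha,
            "ridge": self.ridge,
            "projection_scale": self.projection_scale,
            "norm_mode": self.norm_mode,
            "random_state": self.random_state,
            "classes": list(self.classes_),
            "true_code": [self.true_code.real, self.true_code.imag],
            "false_code": [self.false_code.real, self.false_code.imag],
            "hidden_v": c2ri(self.hidden_v_),
            "hidden_b": c2ri(self.hidden_b_),
            "output_weights": c2ri(self.output_weights_),
            "norm_min": None if self.norm_min_ is None else self.norm_min_.tolist(),
            "norm_max": None if self.norm_max_ is None else self.norm_max_.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "FCRNClassifier":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "fcrnssp-model":
            raise ValueError(f"{path}: not an fcrnssp model archive")

        def ri2c(pair: list) -> np.ndarray:
            return np.asarray(pair[0]) + 1j * np.asarray(pair[1])

        model = cls(
            n_hidden=doc["n_hidden"],
            alpha=doc["alpha"],
            ridge=doc["ridge"],
            projection_scale=doc["projection_scale"],
            norm_mode=doc["norm_mode"],
            true_code=complex(*doc["true_code"]),
            false_code=complex(*doc["false_code"]),
            random_state=doc["random_state"],
        )
        model.classes_ = np.asarray(doc["classes"])
        model.n_features_in_ = doc["m"]
        model.hidden_v_ = ri2c(doc["hidden_v"])
        model.hidden_b_ = ri2c(doc["hidden_b"])
        model.output_weights_ = ri2c(doc["output_weights"])
        model.norm_min_ = (
            None if doc["norm_min"] is None else np.asarray(doc["norm_min"])
        )
        model.norm_max_ = (
            None if doc["norm_max"] is None else np.asarray(doc["norm_max"])
        )
        return model
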