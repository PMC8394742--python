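"""Five one-class anomaly scorers with a unified scoring contract.

Each model trains on ADL feature vectors only and exposes
``score(matrix) -> vector`` where **larger means more anomalous** for
every kind, so a single threshold sweep serves them all:

- ``autoencoder`` — sparse single-hidden-layer autoencoder (logistic
  sigmoid encode/decode, loss = MSE + 0.001 L2 + KL sparsity); score is
  the mean squared reconstruction error.
- ``gmm`` — diagonal-covariance Gaussian mixture; score is the negative
  log-likelihood.
- ``ppnn`` — Parzen probabilistic neural network with window function
  f(u) = e^{u-1}; score is the negated mean window response.
- ``ocknn`` — distance to the k-th nearest training neighbor.
- ``ocsvm`` — nu one-class SVM; score is the negated decision function.

The hyperparameter grid (``default_grid``) enumerates: autoencoder hidden
sizes {6, 10, 12, 15}; GMM components {3, 5, 7}; OC-KNN distances
{euclidean, minkowski, chebychev, cosine} x k in {5, 10, 50}; OC-SVM
kernels {linear, cubic, quadratic, medium gaussian}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import OneClassSVM

from .datamodel import ValidationError

MODEL_KINDS = ("autoencoder", "gmm", "ppnn", "ocknn", "ocsvm")

OCKNN_METRICS = ("euclidean", "minkowski", "chebychev", "cosine")
OCSVM_KERNELS = ("linear", "cubic", "quadratic", "medium gaussian")


def _check_matrix(x, name="matrix") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {x.shape}")
    if x.size and not np.isfinite(x).all():
        raise ValidationError(f"{name} contains non-finite values")
    return x


class OCCModel:
    """Base class: a trained one-class scorer."""

    kind: str = ""

    def __init__(self, n_features: int, params: dict):
        self.n_features = int(n_features)
        self.params = dict(params)

    def _validate_query(self, x) -> np.ndarray:
        x = _check_matrix(x, "query matrix")
        if x.shape[0] and x.shape[1] != self.n_features:
            raise ValidationError(
                f"query has {x.shape[1]} features, model was trained "
                f"on {self.n_features}")
        return x

    def score(self, x) -> np.ndarray:
        """Anomaly scores, one per row; larger = more anomalous."""
        raise NotImplementedError


# ---------------------------------------------------------------------------
# autoencoder

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class AutoencoderOCC(OCCModel):
    """Sparse autoencoder scored by reconstruction MSE.

    Inputs are linearly rescaled per column into [0.1, 0.9] using training
    min/max (the convention of sigmoid-output autoencoders); queries use
    the same affine map, so far-out points reconstruct badly and score
    high.  Trained full-batch with Adam for at most ``epochs`` epochs on
    loss = MSE + l2 * 0.5 * sum(W^2) + beta * KL(rho || rho_hat).
    """

    kind = "autoencoder"

    def __init__(self, n_features, params, lo, span, weights):
        super().__init__(n_features, params)
        self.lo = lo
        self.span = span
        self.weights = weights   # (W1, b1, W2, b2)

    def _scale(self, x):
        return 0.1 + 0.8 * (x - self.lo) / self.span

    def _reconstruct(self, xs):
        w1, b1, w2, b2 = self.weights
        hidden = _sigmoid(xs @ w1.T + b1)
        return _sigmoid(hidden @ w2.T + b2)

    def score(self, x):
        x = self._validate_query(x)
        if x.shape[0] == 0:
            return np.empty(0)
        xs = self._scale(x)
        recon = self._reconstruct(xs)
        return np.mean((recon - xs) ** 2, axis=1)


def train_autoencoder(train_matrix, hidden_neurons: int, seed: int = 0, *,
                      epochs: int = 1000, l2: float = 0.001,
                      sparsity_weight: float = 1.0,
                      sparsity_target: float = 0.05,
                      lr: float = 0.01) -> AutoencoderOCC:
    """Train the sparse autoencoder; deterministic in ``seed``."""
    x = _check_matrix(train_matrix, "training matrix")
    if x.shape[0] < 2:
        raise ValidationError("autoencoder needs at least 2 training rows")
    if hidden_neurons < 1:
        raise ValueError("hidden_neurons must be >= 1")
    n, d = x.shape
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span = np.where(span < 1e-12, 1.0, span)
    xs = 0.1 + 0.8 * (x - lo) / span

    rng = np.random.default_rng(seed)
    h = hidden_neurons
    w1 = rng.normal(0, np.sqrt(1.0 / d), (h, d))
    b1 = np.zeros(h)
    w2 = rng.normal(0, np.sqrt(1.0 / h), (d, h))
    b2 = np.zeros(d)
    params_list = [w1, b1, w2, b2]
    m_t = [np.zeros_like(p) for p in params_list]
    v_t = [np.zeros_like(p) for p in params_list]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rho = sparsity_target

    for step in range(1, epochs + 1):
        w1, b1, w2, b2 = params_list
        hidden = _sigmoid(xs @ w1.T + b1)          # (n, h)
        out = _sigmoid(hidden @ w2.T + b2)         # (n, d)
        err = out - xs
        # dLoss/dout for MSE averaged over all entries
        d_out = (2.0 / (n * d)) * err * out * (1 - out)
        g_w2 = d_out.T @ hidden + l2 * w2
        g_b2 = d_out.sum(axis=0)
        d_hidden = d_out @ w2
        rho_hat = np.clip(hidden.mean(axis=0), 1e-6, 1 - 1e-6)
        d_rho = sparsity_weight * (-rho / rho_hat + (1 - rho) / (1 - rho_hat))
        d_hidden = d_hidden + d_rho / n
        d_act = d_hidden * hidden * (1 - hidden)
        g_w1 = d_act.T @ xs + l2 * w1
        g_b1 = d_act.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]
        for i, (p, g) in enumerate(zip(params_list, grads)):
            m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
            v_t[i] = beta2 * v_t[i] + (1 - beta2) * g * g
            m_hat = m_t[i] / (1 - beta1 ** step)
            v_hat = v_t[i] / (1 - beta2 ** step)
            params_list[i] = p - lr * m_hat / (np.sqrt(v_hat) + eps)

    model = AutoencoderOCC(d, {"hidden_neurons": hidden_neurons,
                               "seed": seed}, lo, span,
                           tuple(params_list))
    return model


# ---------------------------------------------------------------------------
# Gaussian mixture

class GMMOCC(OCCModel):
    """Diagonal-covariance Gaussian mixture scored by NLL per sample."""

    kind = "gmm"

    def __init__(self, n_features, params, gm: GaussianMixture):
        super().__init__(n_features, params)
        self.gm = gm

    def score(self, x):
        x = self._validate_query(x)
        if x.shape[0] == 0:
            return np.empty(0)
        return -self.gm.score_samples(x)


def train_gmm(train_matrix, n_components: int, seed: int = 0, *,
              reg_covar: float = 1e-6, tol: float = 1e-6,
              max_iter: int = 500) -> GMMOCC:
    """EM fit of a diagonal-covariance mixture (k-means++ init)."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = _check_matrix(train_matrix, "training matrix")
    if x.shape[0] < n_components:
        raise ValidationError(
            f"need at least {n_components} rows for {n_components} components")
    gm = GaussianMixture(
        n_components=n_components, covariance_type="diag",
        reg_covar=reg_covar, tol=tol, max_iter=max_iter,
        init_params="k-means++", n_init=1, random_state=seed)
    gm.fit(x)
    return GMMOCC(x.shape[1], {"n_components": n_components, "seed": seed}, gm)


# ---------------------------------------------------------------------------
# Parzen probabilistic neural network

class PPNNOCC(OCCModel):
    """Parzen window scorer with window function f(u) = e^{u-1}.

    likelihood(x) = mean_j exp(-||x - x_j||^2 / (2 sigma^2) - 1);
    the anomaly score is the negated likelihood.
    """

    kind = "ppnn"

    def __init__(self, n_features, params, train, sigma):
        super().__init__(n_features, params)
        self.train = train
        self.sigma = float(sigma)

    def likelihood(self, x):
        x = self._validate_query(x)
        if x.shape[0] == 0:
            return np.empty(0)
        d2 = cdist(x, self.train, "sqeuclidean")
        return np.exp(-d2 / (2 * self.sigma ** 2) - 1.0).mean(axis=1)

    def score(self, x):
        like = self.likelihood(x)
        return -like if like.size else like


def train_ppnn(train_matrix, bandwidth: float | None = None) -> PPNNOCC:
    """Fit the Parzen scorer.

    Default bandwidth is the median pairwise training distance divided by
    sqrt(2); a single-row training set falls back to sigma = 1 (the window
    response at the training point itself does not depend on sigma).
    """
    x = _check_matrix(train_matrix, "training matrix")
    if x.shape[0] < 1:
        raise ValidationError("ppnn needs at least 1 training row")
    if bandwidth is None:
        if x.shape[0] == 1:
            sigma = 1.0
        else:
            sigma = float(np.median(pdist(x))) / np.sqrt(2.0)
    else:
        sigma = float(bandwidth)
    if sigma <= 0:
        raise ValidationError("ppnn bandwidth is zero (degenerate training "
                              "set?); supply an explicit bandwidth")
    return PPNNOCC(x.shape[1], {"bandwidth": sigma}, x.copy(), sigma)


# ---------------------------------------------------------------------------
# one-class k-nearest neighbors

class KNNOCC(OCCModel):
    """Scores by the distance to the k-th nearest training row."""

    kind = "ocknn"

    def __init__(self, n_features, params, nn: NearestNeighbors, k: int):
        super().__init__(n_features, params)
        self.nn = nn
        self.k = int(k)

    def score(self, x):
        x = self._validate_query(x)
        if x.shape[0] == 0:
            return np.empty(0)
        dist, _ = self.nn.kneighbors(x, n_neighbors=self.k)
        return dist[:, -1]


def train_ocknn(train_matrix, metric: str, k: int) -> KNNOCC:
    """Index the training set under the chosen distance.

    ``minkowski`` uses exponent 3 (exponent 2 would duplicate euclidean,
    which the grid lists separately); ``chebychev`` is the L-infinity
    distance; ``cosine`` is 1 - cosine similarity.
    """
    x = _check_matrix(train_matrix, "training matrix")
    if metric not in OCKNN_METRICS:
        raise ValueError(f"metric must be one of {OCKNN_METRICS}")
    if k < 1 or k > x.shape[0]:
        raise ValueError(f"k={k} out of range for {x.shape[0]} training rows")
    kwargs = {}
    if metric == "minkowski":
        sk_metric = "minkowski"
        kwargs["p"] = 3
    elif metric == "chebychev":
        sk_metric = "chebyshev"
    elif metric == "cosine":
        sk_metric = "cosine"
        kwargs["algorithm"] = "brute"
    else:
        sk_metric = "euclidean"
    nn = NearestNeighbors(n_neighbors=k, metric=sk_metric, **kwargs)
    nn.fit(x)
    return KNNOCC(x.shape[1], {"metric": metric, "k": k}, nn, k)


# ---------------------------------------------------------------------------
# one-class SVM

class SVMOCC(OCCModel):
    """nu one-class SVM scored by the negated decision function."""

    kind = "ocsvm"

    def __init__(self, n_features, params, svm: OneClassSVM):
        super().__init__(n_features, params)
        self.svm = svm

    def score(self, x):
        x = self._validate_query(x)
        if x.shape[0] == 0:
            return np.empty(0)
        return -self.svm.decision_function(x)


def train_ocsvm(train_matrix, kernel: str, seed: int = 0, *,
                nu: float = 0.05) -> SVMOCC:
    """Fit a nu one-class SVM.

    ``cubic``/``quadratic`` are polynomial kernels (1 + x.y)^3 and
    (1 + x.y)^2; ``medium gaussian`` is an RBF with kernel scale sqrt(P)
    for P features, i.e. gamma = 1/P.
    """
    x = _check_matrix(train_matrix, "training matrix")
    if x.shape[0] < 2:
        raise ValidationError("ocsvm needs at least 2 training rows")
    if kernel not in OCSVM_KERNELS:
        raise ValueError(f"kernel must be one of {OCSVM_KERNELS}")
    p = x.shape[1]
    if kernel == "linear":
        svm = OneClassSVM(kernel="linear", nu=nu)
    elif kernel == "cubic":
        svm = OneClassSVM(kernel="poly", degree=3, gamma=1.0, coef0=1.0, nu=nu)
    elif kernel == "quadratic":
        svm = OneClassSVM(kernel="poly", degree=2, gamma=1.0, coef0=1.0, nu=nu)
    else:  # medium gaussian
        svm = OneClassSVM(kernel="rbf", gamma=1.0 / p, nu=nu)
    svm.fit(x)
    return SVMOCC(p, {"kernel": kernel, "nu": nu, "seed": seed}, svm)


# ---------------------------------------------------------------------------
# dispatch, grid, persistence

def train_model(kind: str, train_matrix, params: dict,
                seed: int = 0) -> OCCModel:
    """Train any model kind from a hyperparameter dict (see default_grid)."""
    if kind == "autoencoder":
        return train_autoencoder(train_matrix, params["hidden_neurons"], seed)
    if kind == "gmm":
        return train_gmm(train_matrix, params["n_components"], seed)
    if kind == "ppnn":
        return train_ppnn(train_matrix, params.get("bandwidth"))
    if kind == "ocknn":
        return train_ocknn(train_matrix, params["metric"], params["k"])
    if kind == "ocsvm":
        return train_ocsvm(train_matrix, params["kernel"], seed)
    raise ValueError(f"unknown model kind {kind!r}; "
                     f"expected one of {MODEL_KINDS}")


def default_grid(kind: str) -> list[dict]:
    """The hyperparameter grid, in deterministic enumeration order."""
    if kind == "autoencoder":
        return [{"hidden_neurons": h} for h in (6, 10, 12, 15)]
    if kind == "gmm":
        return [{"n_components": c} for c in (3, 5, 7)]
    if kind == "ppnn":
        return [{}]
    if kind == "ocknn":
        return [{"metric": m, "k": k}
                for m in OCKNN_METRICS for k in (5, 10, 50)]
    if kind == "ocsvm":
        return [{"kernel": k} for k in OCSVM_KERNELS]
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(kind: str, params: dict, train_matrix, seed: int,
               path: str | Path, normalizer=None) -> None:
    """Persist a model bundle as self-describing JSON.

    Stores the hyperparameters, seed and (small) training matrix;
    :func:`load_model` retrains deterministically, which keeps the bundle
    portable plain text at negligible cost for the matrix sizes this
    pipeline handles.
    """
    bundle = {
        "kind": kind,
        "params": params,
        "seed": int(seed),
        "train_matrix": np.asarray(train_matrix, dtype=float).tolist(),
    }
    if normalizer is not None:
        bundle["normalizer"] = {"mean": normalizer.mean_.tolist(),
                                "sd": normalizer.sd_.tolist()}
    Path(path).write_text(json.dumps(bundle, sort_keys=True))


def load_model(path: str | Path):
    """Load a bundle written by :func:`save_model`.

    Returns ``(model, normalizer_or_None)``.
    """
    from .features import Normalizer
    bundle = json.loads(Path(path).read_text())
    model = train_model(bundle["kind"], np.asarray(bundle["train_matrix"]),
                        bundle["params"], bundle["seed"])
    norm = None
    if "normalizer" in bundle:
        norm = Normalizer(mean_=np.asarray(bundle["normalizer"]["mean"]),
                          sd_=np.asarray(bundle["normalizer"]["sd"]))
    return model, norm
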