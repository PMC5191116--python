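"""Import vector machine: sparse greedy kernel logistic regression.

The classifier separates grape-bunch points from canopy points in the
128-dim feature space and — unlike a plain SVM — outputs genuine posterior
class probabilities, which the downstream graph-cut smoothing consumes as
unary energies.

Model: p(y=1 | x) = sigmoid(b + sum_s alpha_s k(x, x_s)) with an RBF kernel
over standardized features, the "import points" x_s being a small subset of
the training set chosen by greedy forward selection of the regularized
negative log-likelihood. Selection is accelerated by scoring a seeded
candidate subsample with the functional gradient and refining only the top
candidates with damped Newton steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

MAX_CANDIDATES_PER_STEP = 100
TOP_REFINE = 8


@dataclass
class TrainingSet:
    """Labeled feature vectors; labels in {0 = canopy, 1 = grape bunch}."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.ascontiguousarray(self.features, dtype=np.float64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must be (T,)")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def is_balanced(self, tol: float = 0.25) -> bool:
        n0, n1 = self.class_counts
        return abs(n0 - n1) <= tol * max(n0, n1)


@dataclass
class IvmModel:
    import_points: np.ndarray            # (S, d), standardized space
    weights: np.ndarray                  # (S + 1,): bias first
    gamma: float
    lam: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    prior: float                         # training fraction of class 1
    import_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))

    @property
    def n_import(self) -> int:
        return self.import_points.shape[0]

    @property
    def n_features(self) -> int:
        return self.feature_mean.shape[0]

    def save(self, path) -> None:
        """Serialize to a single JSON document (arrays as nested lists)."""
        doc = {
            "format": "vitis3d-ivm-1",
            "gamma": self.gamma,
            "lam": self.lam,
            "prior": self.prior,
            "import_points": self.import_points.tolist(),
            "weights": self.weights.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "import_indices": self.import_indices.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "IvmModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "vitis3d-ivm-1":
            raise ValueError("not a vitis3d IVM model file")
        return cls(
            import_points=np.asarray(doc["import_points"], dtype=np.float64),
            weights=np.asarray(doc["weights"], dtype=np.float64),
            gamma=float(doc["gamma"]),
            lam=float(doc["lam"]),
            feature_mean=np.asarray(doc["feature_mean"], dtype=np.float64),
            feature_scale=np.asarray(doc["feature_scale"], dtype=np.float64),
            prior=float(doc["prior"]),
            import_indices=np.asarray(doc["import_indices"], dtype=np.int64),
        )


def _standardize_fit(x: np.ndarray):
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale < 1e-12] = 1.0
    return mean, scale


def _rbf(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2) if a.shape[0] * b.shape[0] < 4_000_000 \
        else _rbf_blocked_d2(a, b)
    return np.exp(-gamma * d2)


def _rbf_blocked_d2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a * a).sum(axis=1)[:, None]
    bb = (b * b).sum(axis=1)[None, :]
    d2 = aa + bb - 2.0 * (a @ b.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator,
                           n_pairs: int = 2000) -> float:
    """gamma = 1 / median squared pairwise distance over a seeded subsample."""
    t = x.shape[0]
    i = rng.integers(0, t, size=n_pairs)
    j = rng.integers(0, t, size=n_pairs)
    keep = i != j
    d2 = ((x[i[keep]] - x[j[keep]]) ** 2).sum(axis=1)
    med = np.median(d2)
    if med <= 0:
        med = 1.0
    return 1.0 / med


def _objective(y, f, lam, alpha, k_ss):
    p = 1.0 / (1.0 + np.exp(-np.clip(f, -35, 35)))
    eps = 1e-12
    nll = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    return nll + lam * float(alpha @ k_ss @ alpha)


def _fit_weights(k_ts: np.ndarray, k_ss: np.ndarray, y: np.ndarray, lam: float,
                 w0: Optional[np.ndarray] = None, max_iter: int = 50,
                 tol: float = 1e-9):
    """Damped-Newton fit of (bias, alpha) for a fixed import set.

    Minimizes mean negative log-likelihood + lam * alpha' K_ss alpha.
    Returns (weights, objective).
    """
    t, s = k_ts.shape
    design = np.hstack([np.ones((t, 1)), k_ts])
    w = np.zeros(s + 1) if w0 is None else w0.copy()
    reg = np.zeros((s + 1, s + 1))
    reg[1:, 1:] = k_ss
    obj = _objective(y, design @ w, lam, w[1:], k_ss)
    for _ in range(max_iter):
        f = design @ w
        p = 1.0 / (1.0 + np.exp(-np.clip(f, -35, 35)))
        grad = design.T @ (p - y) / t + 2.0 * lam * (reg @ w)
        wdiag = np.maximum(p * (1 - p), 1e-10)
        hess = (design * wdiag[:, None]).T @ design / t + 2.0 * lam * reg
        hess[np.diag_indices_from(hess)] += 1e-10
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking line search on the damped Newton step
        lr = 1.0
        improved = False
        for _ in range(20):
            w_new = w - lr * step
            obj_new = _objective(y, design @ w_new, lam, w_new[1:], k_ss)
            if obj_new <= obj:
                improved = obj < obj_new + tol or obj - obj_new > 0
                w, prev, obj = w_new, obj, obj_new
                break
            lr *= 0.5
        else:
            break
        if prev - obj < tol:
            break
    return w, obj


def train_ivm(train: TrainingSet, gamma: Optional[float] = None, lam: float = 1e-3,
              max_import: int = 200, tol: float = 1e-4, seed: int = 0) -> IvmModel:
    """Greedy forward selection of import points for kernel logistic regression.

    Import points are added one at a time: a seeded random candidate
    subsample is scored by the magnitude of the functional gradient
    (correlation of the candidate's kernel column with the current
    residual), the best few candidates are refined with Newton refits, and
    the one with the lowest regularized negative log-likelihood is kept.
    Selection stops when the relative objective improvement falls below
    ``tol`` or ``max_import`` points were selected.
    """
    n0, n1 = train.class_counts
    if n0 < 10 or n1 < 10:
        raise ValueError("need at least 10 training points per class")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(seed)
    mean, scale = _standardize_fit(train.features)
    x = (train.features - mean) / scale
    y = train.labels.astype(np.float64)
    t = x.shape[0]
    if gamma is None:
        gamma = median_heuristic_gamma(x, rng)
    if gamma <= 0:
        raise ValueError("gamma must be positive")

    imports: list[int] = []
    k_ts = np.zeros((t, 0))
    k_ss = np.zeros((0, 0))
    w = np.zeros(1)
    # bias-only start: log-odds of the class prior
    prior = y.mean()
    w[0] = np.log(prior / (1 - prior)) if 0 < prior < 1 else 0.0
    obj = _objective(y, np.full(t, w[0]), lam, np.zeros(0), k_ss)
    obj_init = max(obj, 1e-12)

    while len(imports) < max_import:
        available = np.setdiff1d(np.arange(t), np.asarray(imports, dtype=np.int64))
        if available.size == 0:
            break
        n_cand = min(MAX_CANDIDATES_PER_STEP, available.size)
        cand = rng.choice(available, size=n_cand, replace=False)
        f = w[0] + (k_ts @ w[1:] if imports else 0.0)
        p = 1.0 / (1.0 + np.exp(-np.clip(f, -35, 35)))
        resid = p - y
        k_cand = _rbf(x, x[cand], gamma)          # (t, n_cand)
        scores = np.abs(k_cand.T @ resid)
        order = np.argsort(scores)[::-1][:TOP_REFINE]

        best = None
        for idx in order:
            c = int(cand[idx])
            k_col = k_cand[:, idx]
            k_ts_try = np.hstack([k_ts, k_col[:, None]])
            cross = k_col[imports] if imports else np.zeros(0)
            k_ss_try = np.zeros((len(imports) + 1, len(imports) + 1))
            k_ss_try[:-1, :-1] = k_ss
            k_ss_try[-1, :-1] = cross
            k_ss_try[:-1, -1] = cross
            k_ss_try[-1, -1] = 1.0
            w0 = np.append(w, 0.0)
            w_try, obj_try = _fit_weights(k_ts_try, k_ss_try, y, lam, w0, max_iter=4)
            if best is None or obj_try < best[0]:
                best = (obj_try, c, k_ts_try, k_ss_try, w_try)
        if best is None:
            break
        obj_new, c, k_ts_new, k_ss_new, w_new = best
        # improvement relative to the bias-only objective: near-zero
        # objectives on separable data do not drag selection on
        improvement = (obj - obj_new) / obj_init
        if imports and improvement < tol:
            break
        imports.append(c)
        k_ts, k_ss = k_ts_new, k_ss_new
        # full refit after each addition
        w, obj = _fit_weights(k_ts, k_ss, y, lam, w_new, max_iter=50)
        if not imports:
            break

    if not imports:  # pathological: force the best single candidate
        imports = [int(rng.integers(0, t))]
        k_ts = _rbf(x, x[imports], gamma)
        k_ss = np.ones((1, 1))
        w, obj = _fit_weights(k_ts, k_ss, y, lam)

    return IvmModel(
        import_points=x[np.asarray(imports)],
        weights=w,
        gamma=float(gamma),
        lam=float(lam),
        feature_mean=mean,
        feature_scale=scale,
        prior=float(prior),
        import_indices=np.asarray(imports, dtype=np.int64),
    )


def predict_proba(model: IvmModel, features, valid: Optional[np.ndarray] = None):
    """Posterior class probabilities, rows [p_canopy, p_bunch] summing to 1.

    Rows flagged invalid (or containing non-finite values) receive the
    training-prior posterior; the returned flag array marks them.

    Returns ``(posteriors (N, 2), prior_filled (N,))``.
    """
    x = np.asarray(getattr(features, "values", features), dtype=np.float64)
    if valid is None:
        valid = getattr(features, "valid", None)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {x.shape[1] if x.ndim == 2 else '?'} does not match "
            f"model width {model.n_features}")
    finite = np.isfinite(x).all(axis=1)
    ok = finite if valid is None else (np.asarray(valid, dtype=bool) & finite)
    xs = np.where(ok[:, None], x, 0.0)
    xs = (xs - model.feature_mean) / model.feature_scale
    k = _rbf(xs, model.import_points, model.gamma)
    f = model.weights[0] + k @ model.weights[1:]
    p1 = 1.0 / (1.0 + np.exp(-np.clip(f, -35, 35)))
    p1[~ok] = model.prior
    post = np.column_stack([1.0 - p1, p1])
    return post, ~ok


def assign_labels(posteriors: np.ndarray) -> np.ndarray:
    """Argmax class per row; exact ties go to class 0 (canopy)."""
    post = np.asarray(posteriors, dtype=np.float64)
    if post.ndim != 2 or post.shape[1] < 2:
        raise ValueError("posteriors must be (N, n_classes)")
    return (post[:, 1] > post[:, 0]).astype(np.int64) if post.shape[1] == 2 \
        else _argmax_first_tie(post)


def _argmax_first_tie(post: np.ndarray) -> np.ndarray:
    return np.argmax(post, axis=1).astype(np.int64)  # np.argmax takes first maximum
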