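"""Multivariate class modelling: PCA, PLS-DA, OPLS-DA, VIP, Q2, permutations.

The latent-variable machinery is implemented from first principles (NIPALS
with tricube-free classic deflation; O-PLS split of label-predictive and
label-orthogonal variation) so that variable-importance scores, the
cross-validated Q2 and the permutation null are exactly the quantities the
discriminant workflow defines, not a black box's approximations.

Conventions
-----------
* Input matrices are sample x feature, ideally autoscaled; models centre
  columns internally and remember the means for prediction.
* Component signs are fixed by making the largest-magnitude weight entry
  positive, so fits are reproducible across runs and libraries.
* VIP is normalised so that the mean squared VIP over features equals 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
DEFAULT_CV_FOLDS = 7       # sevenfold cross-validation
DEFAULT_N_PERM = 200       # label permutations for model validation


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray              # samples x components
    loadings: np.ndarray            # features x components
    explained_variance: np.ndarray  # fraction per component, non-increasing
    mean: np.ndarray


def fit_pca(matrix: np.ndarray, n_components: int) -> PCAResult:
    """Principal component analysis via SVD of the column-centred matrix."""
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise InvalidArgumentError(
            f"n_components must be in [1, {max_comp}] for a {n}x{p} matrix"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    # sign convention: largest-|loading| entry positive
    for a in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    ev = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAResult(scores=scores, loadings=loadings, explained_variance=ev, mean=mean)


# --------------------------------------------------------------------------
# PLS-DA / OPLS-DA
# --------------------------------------------------------------------------

@dataclass
class PermutationRecord:
    n_perm: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_r2y: float
    p_q2: float


@dataclass
class DAModelResult:
    """Fitted discriminant latent-variable model.

    Predictive blocks (``weights``/``scores``/``loadings``/``y_loadings``)
    always refer to the label-predictive components; the ``ortho_*`` blocks
    are filled only by OPLS-DA.
    """

    method: str                      # "plsda" | "oplsda"
    classes: list
    weights: np.ndarray              # features x A (normalised)
    scores: np.ndarray               # samples x A
    loadings: np.ndarray             # features x A
    y_loadings: np.ndarray           # classes x A
    x_mean: np.ndarray
    y_mean: np.ndarray
    r2x: float
    r2y: float
    ortho_weights: np.ndarray | None = None
    ortho_scores: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    q2: float | None = None
    vip: np.ndarray | None = None
    permutation: PermutationRecord | None = None
    feature_ids: list | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return 0 if self.ortho_weights is None else self.ortho_weights.shape[1]

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        """Continuous class-indicator predictions for new samples."""
        X = np.asarray(matrix, dtype=float) - self.x_mean
        if self.ortho_weights is not None:
            for a in range(self.n_orthogonal):
                t_o = X @ self.ortho_weights[:, a]
                X = X - np.outer(t_o, self.ortho_loadings[:, a])
        W, P, C = self.weights, self.loadings, self.y_loadings
        # regression coefficients B = W (P'W)^-1 C'
        B = W @ np.linalg.solve(P.T @ W, C.T)
        return X @ B + self.y_mean

    def predict_class(self, matrix: np.ndarray) -> list:
        yhat = self.predict(matrix)
        return [self.classes[i] for i in np.argmax(yhat, axis=1)]


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    labels = list(labels)
    classes = []
    for g in labels:
        if g not in classes:
            classes.append(g)
    Y = np.zeros((len(labels), len(classes)))
    for i, g in enumerate(labels):
        Y[i, classes.index(g)] = 1.0
    return Y, classes


def _fix_sign(w, t, p, q):
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        return -w, -t, -p, -q
    return w, t, p, q


def _nipals_component(X: np.ndarray, Y: np.ndarray):
    """One NIPALS PLS component on already-deflated X, Y."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if np.allclose(u, 0):
        u = Y[:, 0] + 1e-12
    t_old = None
    for it in range(NIPALS_MAX_ITER):
        w = X.T @ u / (u @ u)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise InvalidArgumentError("degenerate component: zero weight vector")
        w /= nw
        t = X @ w
        q = Y.T @ t / (t @ t)
        u = Y @ q / (q @ q)
        if t_old is not None and np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
            break
        t_old = t
    else:
        logger.warning("NIPALS did not converge in %d iterations", NIPALS_MAX_ITER)
    p = X.T @ t / (t @ t)
    return _fix_sign(w, t, p, q)


def fit_plsda(matrix: np.ndarray, labels, n_components: int) -> DAModelResult:
    """Partial least squares discriminant analysis (NIPALS, PLS2).

    Components maximise covariance between the intensity matrix and the
    one-hot class-membership matrix; both blocks are deflated per component.
    """
    X = np.asarray(matrix, dtype=float)
    Y, classes = _encode_labels(labels)
    if len(classes) < 2:
        raise InvalidArgumentError("PLS-DA needs >= 2 groups")
    if not 1 <= n_components <= min(X.shape):
        raise InvalidArgumentError(f"n_components must be in [1, {min(X.shape)}]")

    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xd, Yd = X - x_mean, Y - y_mean
    ssx_total = float((Xd**2).sum())
    ssy_total = float((Yd**2).sum())

    W = np.zeros((X.shape[1], n_components))
    T = np.zeros((X.shape[0], n_components))
    P = np.zeros((X.shape[1], n_components))
    C = np.zeros((Y.shape[1], n_components))
    for a in range(n_components):
        w, t, p, q = _nipals_component(Xd, Yd)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p, q
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, q)

    r2x = 1.0 - float((Xd**2).sum()) / ssx_total if ssx_total > 0 else 0.0
    r2y = 1.0 - float((Yd**2).sum()) / ssy_total if ssy_total > 0 else 0.0
    model = DAModelResult(
        method="plsda", classes=classes, weights=W, scores=T, loadings=P,
        y_loadings=C, x_mean=x_mean, y_mean=y_mean, r2x=r2x, r2y=r2y,
    )
    model.vip = compute_vip(model)
    return model


def fit_oplsda(matrix: np.ndarray, labels, n_orthogonal: int | str = 1,
               cv_seed: int = 0) -> DAModelResult:
    """Orthogonal PLS discriminant analysis for a two-group comparison.

    Splits variation into one label-predictive component and
    ``n_orthogonal`` label-orthogonal components removed from the matrix
    before the predictive fit. ``n_orthogonal="auto"`` adds orthogonal
    components while sevenfold cross-validated Q2 improves by more than
    0.01 (capped at 5).
    """
    X = np.asarray(matrix, dtype=float)
    Y, classes = _encode_labels(labels)
    if len(classes) != 2:
        raise InvalidArgumentError(
            "OPLS-DA is defined for exactly 2 groups; run pairwise comparisons for more"
        )
    if n_orthogonal == "auto":
        return _auto_oplsda(X, labels, cv_seed)
    if not isinstance(n_orthogonal, (int, np.integer)) or n_orthogonal < 0:
        raise InvalidArgumentError("n_orthogonal must be a non-negative integer or 'auto'")

    y = Y[:, 1]                     # single-response indicator of the 2nd class
    x_mean, y_mean1 = X.mean(axis=0), y.mean()
    Xd, yd = X - x_mean, y - y_mean1
    ssx_total = float((Xd**2).sum())
    ssy_total = float((yd**2).sum())

    n_feat = X.shape[1]
    Wo = np.zeros((n_feat, n_orthogonal))
    To = np.zeros((X.shape[0], n_orthogonal))
    Po = np.zeros((n_feat, n_orthogonal))
    kept = 0
    for a in range(n_orthogonal):
        w = Xd.T @ yd / (yd @ yd)
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:            # no label-orthogonal variation left
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Wo[:, kept], To[:, kept], Po[:, kept] = w_o, t_o, p_o
        Xd = Xd - np.outer(t_o, p_o)
        kept += 1
    Wo, To, Po = Wo[:, :kept], To[:, :kept], Po[:, :kept]

    # predictive component on the orthogonal-filtered matrix
    w = Xd.T @ yd / (yd @ yd)
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(yd @ t / (t @ t))
    w, t, p, q = _fix_sign(w, t, p, np.array([c]))
    c = float(q[0])

    resid_y = yd - t * c
    resid_x = Xd - np.outer(t, p)
    r2y = 1.0 - float((resid_y**2).sum()) / ssy_total if ssy_total > 0 else 0.0
    r2x = 1.0 - float((resid_x**2).sum()) / ssx_total if ssx_total > 0 else 0.0

    # store y-loadings for both indicator columns so predict() returns
    # one column per class (columns sum to the constant one-hot total)
    C = np.array([[-c], [c]])
    y_mean = np.array([1.0 - y_mean1, y_mean1])
    model = DAModelResult(
        method="oplsda", classes=classes, weights=w[:, None], scores=t[:, None],
        loadings=p[:, None], y_loadings=C, x_mean=x_mean, y_mean=y_mean,
        r2x=r2x, r2y=r2y,
        ortho_weights=Wo if kept else None,
        ortho_scores=To if kept else None,
        ortho_loadings=Po if kept else None,
    )
    model.vip = compute_vip(model)
    return model


def _auto_oplsda(X, labels, cv_seed: int, cap: int = 5, min_gain: float = 0.01):
    """Add orthogonal components while CV Q2 improves by > ``min_gain``."""
    best_k = 0
    best_q2 = cross_validate_q2(X, labels, {"method": "oplsda", "n_orthogonal": 0}, seed=cv_seed)
    for k in range(1, cap + 1):
        q2 = cross_validate_q2(X, labels, {"method": "oplsda", "n_orthogonal": k}, seed=cv_seed)
        if q2 > best_q2 + min_gain:
            best_q2, best_k = q2, k
        else:
            break
    model = fit_oplsda(X, labels, n_orthogonal=best_k)
    model.q2 = best_q2
    return model


def compute_vip(model: DAModelResult) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a w_{ja}^2 / sum_a SSY_a ) with normalised
    weight vectors, where SSY_a is the label variance captured by component
    a. The mean squared VIP equals 1, so sum(VIP^2) = number of features.
    For an OPLS model only the predictive component enters (VIP_pred).
    """
    if model.weights is None or model.weights.size == 0:
        raise InvalidArgumentError("model has no fitted components")
    W, T, C = model.weights, model.scores, model.y_loadings
    p, A = W.shape
    ssy = np.array([(C[:, a] @ C[:, a]) * (T[:, a] @ T[:, a]) for a in range(A)])
    if ssy.sum() == 0:
        return np.zeros(p)
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())
    return vip


# --------------------------------------------------------------------------
# Validation: cross-validated Q2 and label permutations
# --------------------------------------------------------------------------

def _fit_spec(X, labels, spec: dict) -> DAModelResult:
    method = spec.get("method", "plsda")
    if method == "plsda":
        return fit_plsda(X, labels, n_components=spec.get("n_components", 2))
    if method == "oplsda":
        return fit_oplsda(X, labels, n_orthogonal=spec.get("n_orthogonal", 1))
    raise InvalidArgumentError(f"unknown model spec method {method!r}")


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; each group dealt round-robin."""
    labels = np.asarray(labels, dtype=object)
    if k > len(labels):
        raise InvalidArgumentError(f"k={k} exceeds {len(labels)} samples")
    rng = np.random.default_rng(seed)
    assignment = np.zeros(len(labels), dtype=int)
    offset = 0
    for g in _unique(labels):
        idx = np.flatnonzero(labels == g)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            assignment[sample] = (i + offset) % k
        offset += len(idx)
    return [np.flatnonzero(assignment == f) for f in range(k)]


def _unique(values):
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def cross_validate_q2(matrix, labels, model_spec: dict,
                      k: int = DEFAULT_CV_FOLDS, seed: int = 0) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/TSS.

    Folds are stratified by group with seeded assignment (default k = 7).
    Held-out one-hot responses are predicted by models refit on the
    remaining samples; TSS accumulates squared deviations of the held-out
    responses from the training means.
    """
    X = np.asarray(matrix, dtype=float)
    Y, classes = _encode_labels(labels)
    labels = np.asarray(list(labels), dtype=object)
    press = tss = 0.0
    for test_idx in stratified_folds(labels, k, seed):
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
        train_labels = labels[train_idx]
        if len(set(train_labels)) < 2:
            raise InvalidArgumentError("a training fold lost all but one group; reduce k")
        model = _fit_spec(X[train_idx], train_labels, model_spec)
        yhat = model.predict(X[test_idx])
        # align class columns between fold model and global encoding
        col = [model.classes.index(c) if c in model.classes else None for c in classes]
        for j, cj in enumerate(col):
            y_true = Y[test_idx, j]
            pred = yhat[:, cj] if cj is not None else np.zeros(len(test_idx))
            press += float(((y_true - pred) ** 2).sum())
            train_mean = Y[train_idx, j].mean()
            tss += float(((y_true - train_mean) ** 2).sum())
    return 1.0 - press / tss if tss > 0 else float("nan")


def permutation_test(matrix, labels, model_spec: dict,
                     n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                     k: int = DEFAULT_CV_FOLDS) -> PermutationRecord:
    """Label-permutation validation of R2Y and Q2.

    Class labels are permuted ``n_perm`` times (default 200); the model and
    its cross-validated Q2 are refit each time. Empirical p-values use the
    add-one convention p = (1 + #{permuted >= observed}) / (n_perm + 1), so
    the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    rng = np.random.default_rng(seed)

    observed = _fit_spec(X, labels, model_spec)
    observed_q2 = cross_validate_q2(X, labels, model_spec, k=k, seed=seed)

    perm_r2y = np.zeros(n_perm)
    perm_q2 = np.zeros(n_perm)
    for b in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        perm_r2y[b] = _fit_spec(X, perm, model_spec).r2y
        perm_q2[b] = cross_validate_q2(X, perm, model_spec, k=k,
                                       seed=int(rng.integers(2**31)))
    p_r2y = (1 + int((perm_r2y >= observed.r2y).sum())) / (n_perm + 1)
    p_q2 = (1 + int((perm_q2 >= observed_q2).sum())) / (n_perm + 1)
    return PermutationRecord(
        n_perm=n_perm, observed_r2y=observed.r2y, observed_q2=observed_q2,
        permuted_r2y=perm_r2y, permuted_q2=perm_q2, p_r2y=p_r2y, p_q2=p_q2,
    )
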