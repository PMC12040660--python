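"""PLS-DA: univariate-response NIPALS partial least squares, VIP, CV selection.

Partial least squares regresses a dummy-coded class response (Target = 1,
Control = 0) on the centered spectral matrix by extracting latent
components sequentially: each component's weight vector is the
covariance direction ``w ∝ X'y`` (normalized), the score is ``t = Xw``,
and X is deflated by the rank-one term ``t p'`` before the next
component.  The regression coefficient vector is assembled as
``B = W (P'W)^-1 q`` and classification thresholds the continuous
prediction at 0.5.

Variable importance in projection (VIP) summarises each channel's
contribution across components:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),   SS_a = q_a^2 t_a't_a

with ``p`` the channel count and unit-norm weight columns, so the mean
squared VIP is 1 by construction.

Model-order selection uses k-fold cross-validation with folds drawn at
the *subject* level (all replicate spectra of a subject share a fold)
and stratified by group, scoring mean held-out spectrum-level accuracy;
ties prefer the smaller component count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, FitError, ParameterError

__all__ = [
    "PLSModel",
    "CVSelection",
    "VIPProfile",
    "fit_pls",
    "predict",
    "vip",
    "select_components",
    "stratified_subject_folds",
]

DECISION_THRESHOLD = 0.5  # Target iff score >= 0.5, the one place the coding lives
POSITIVE, NEGATIVE = "Target", "Control"


@dataclass
class PLSModel:
    """A fitted NIPALS PLS1 model.

    Attributes
    ----------
    x_mean, y_mean
        Training column means used for centering.
    W, P
        X-weights and X-loadings, shape (channels, A); W columns unit norm.
    T
        Training scores, shape (rows, A); columns mutually orthogonal.
    q
        Y-loadings, shape (A,).
    coef
        Regression coefficients ``W (P'W)^-1 q``, shape (channels,).
    n_components
        Number of latent components A.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    coef: np.ndarray
    n_components: int

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "T": self.T.tolist(),
            "q": self.q.tolist(),
            "coef": self.coef.tolist(),
            "n_components": self.n_components,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        return cls(
            x_mean=np.asarray(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            W=np.asarray(doc["W"], dtype=float),
            P=np.asarray(doc["P"], dtype=float),
            T=np.asarray(doc["T"], dtype=float),
            q=np.asarray(doc["q"], dtype=float),
            coef=np.asarray(doc["coef"], dtype=float),
            n_components=int(doc["n_components"]),
        )


@dataclass
class CVSelection:
    """Cross-validated component-count selection result."""

    grid: np.ndarray
    cv_accuracy: np.ndarray
    chosen_A: int
    k: int


@dataclass
class VIPProfile:
    """Per-channel variable importance; mean(vip^2) == 1."""

    axis: np.ndarray
    vip: np.ndarray


def _coef_from_decomposition(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Fit a centered univariate-response NIPALS PLS model with A components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise DataError(f"X has {n} rows but y has {len(y)} entries")
    if len(np.unique(y)) < 2:
        raise FitError("response contains a single class")
    if not 1 <= A <= min(n - 1, p):
        raise ParameterError(f"A must be in [1, {min(n - 1, p)}], got {A}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0.0 or not np.isfinite(nw):
            raise FitError(f"zero-variance covariance direction at component {a + 1}")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0.0:
            raise FitError(f"degenerate score vector at component {a + 1}")
        pa = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pa)
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
    coef = _coef_from_decomposition(W, P, q)
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, W=W, P=P, T=T, q=q, coef=coef, n_components=A
    )


def predict(model: PLSModel, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and hard labels for new spectra.

    ``score = y_mean + (Xnew - x_mean) @ coef``; label is Target iff the
    score is >= 0.5 (ties go to Target).
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != len(model.x_mean):
        raise DataError(
            f"channel mismatch: model has {len(model.x_mean)}, input has {Xnew.shape[1]}"
        )
    score = model.y_mean + (Xnew - model.x_mean) @ model.coef
    label = np.where(score >= DECISION_THRESHOLD, POSITIVE, NEGATIVE).astype(object)
    return score, label


def vip(model: PLSModel, axis: np.ndarray | None = None) -> VIPProfile:
    """Variable importance in projection of a fitted model."""
    p = model.W.shape[0]
    ss = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    denom = ss.sum()
    if denom == 0.0:
        raise FitError("model explains no response variance; VIP undefined")
    v = np.sqrt(p * (model.W**2 @ ss) / denom)
    if axis is None:
        axis = np.arange(p, dtype=float)
    return VIPProfile(axis=np.asarray(axis, dtype=float), vip=v)


def stratified_subject_folds(
    subject_ids: np.ndarray, y: np.ndarray, k: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Assign each row to one of k folds at the subject level.

    Subjects are shuffled within each class and dealt round-robin to
    folds, so folds are group-stratified and no subject straddles folds.
    Returns a per-row fold index array.
    """
    subject_ids = np.asarray(subject_ids, dtype=object)
    y = np.asarray(y, dtype=float)
    subj_class: dict[object, float] = {}
    order: list[object] = []
    for sid, yi in zip(subject_ids, y):
        if sid not in subj_class:
            subj_class[sid] = yi
            order.append(sid)
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if k > len(order):
        raise ParameterError(f"k = {k} exceeds number of subjects ({len(order)})")
    rng = np.random.default_rng(seed)
    fold_of: dict[object, int] = {}
    for cls in np.unique(y):
        members = [s for s in order if subj_class[s] == cls]
        perm = rng.permutation(len(members))
        for j, idx in enumerate(perm):
            fold_of[members[idx]] = j % k
    return np.array([fold_of[s] for s in subject_ids], dtype=int)


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    k: int = 7,
    grid: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> CVSelection:
    """Choose the component count by subject-grouped stratified k-fold CV.

    For every candidate A the mean held-out spectrum-level accuracy is
    computed (one NIPALS fit per fold at the largest candidate; smaller
    candidates reuse its truncated decomposition).  The accuracy-maximal
    A wins; ties break to the smallest A as an overfitting guard.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = stratified_subject_folds(subject_ids, y, k, seed)
    fold_ids = np.unique(folds)
    min_train = min(int(np.sum(folds != f)) for f in fold_ids)
    bound = min(min_train - 1, X.shape[1])
    if grid is None:
        grid = np.arange(1, min(15, bound) + 1)
    grid = np.sort(np.unique(np.asarray(grid, dtype=int)))
    if grid.size == 0:
        raise ParameterError("component grid is empty")
    if grid[0] < 1 or grid[-1] > bound:
        raise ParameterError(
            f"grid values must lie in [1, {bound}] given the fold sizes"
        )
    A_max = int(grid[-1])

    acc = np.zeros((len(fold_ids), len(grid)))
    for i, f in enumerate(fold_ids):
        tr, te = folds != f, folds == f
        model = fit_pls(X[tr], y[tr], A_max)
        Xc = X[te] - model.x_mean
        for j, A in enumerate(grid):
            coef = _coef_from_decomposition(model.W[:, :A], model.P[:, :A], model.q[:A])
            score = model.y_mean + Xc @ coef
            pred = (score >= DECISION_THRESHOLD).astype(float)
            acc[i, j] = float(np.mean(pred == y[te]))
    cv_accuracy = acc.mean(axis=0)
    chosen = int(grid[int(np.argmax(cv_accuracy))])  # argmax returns first max: smallest A
    return CVSelection(grid=grid, cv_accuracy=cv_accuracy, chosen_A=chosen, k=k)
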