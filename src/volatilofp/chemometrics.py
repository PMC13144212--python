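"""Fisher-ratio filtering, PCA, PLS-DA with Monte-Carlo CV, and chord export.

Feature filtering uses the Fisher ratio — per feature, the between-class mean
square over the within-class mean square, identical to the one-way ANOVA F
statistic — with the strict ``F > 6`` selection rule.  Classification is
PLS-DA: NIPALS PLS2 on the mean-centered matrix against 0/1 class-dummy
columns, predicting by argmax of the fitted class scores.  Validation follows
a Monte-Carlo scheme with repeated stratified random holdouts (default 10%
held out, 100 repetitions), with feature selection recomputed inside each
calibration split so the holdout never leaks into the filter.  Variable
importance in projection (VIP) summarizes each feature's contribution across
latent variables and satisfies mean(VIP²) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FisherResult",
    "PLSDAModel",
    "CVReport",
    "fisher_ratio",
    "select_features",
    "pca",
    "plsda_fit",
    "plsda_predict",
    "vip",
    "monte_carlo_cv",
    "chord_data",
]


@dataclass
class FisherResult:
    f: pd.Series            # per-feature Fisher ratio (one-way ANOVA F)
    p_value: pd.Series      # nominal ANOVA p-value (reported alongside)
    selected: pd.Series     # boolean, F strictly above the threshold
    threshold: float


def fisher_ratio(X: pd.DataFrame | np.ndarray, labels, threshold: float = 6.0) -> FisherResult:
    """Per-feature Fisher ratio between classes.

    F = between-class mean square / within-class mean square, computed
    feature-wise; equals the one-way ANOVA F statistic.  Features with zero
    within- and between-class variance get F = 0.
    """
    Xdf = pd.DataFrame(X)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two samples")
    n = Xdf.shape[0]
    k = classes.size
    grand = Xdf.mean(axis=0)
    ssb = pd.Series(0.0, index=Xdf.columns)
    ssw = pd.Series(0.0, index=Xdf.columns)
    for c in classes:
        sub = Xdf[y == c]
        ssb += len(sub) * (sub.mean(axis=0) - grand) ** 2
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = f.where(msw > 0, 0.0).astype(float)  # 0/0 guarded to 0
    pv = pd.Series(stats.f.sf(f, k - 1, n - k), index=Xdf.columns)
    return FisherResult(f=f, p_value=pv, selected=f > threshold, threshold=threshold)


def select_features(result: FisherResult, threshold: float | None = None) -> list:
    """Features with Fisher ratio strictly above the threshold (F > thr)."""
    thr = result.threshold if threshold is None else threshold
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    return result.f.index[result.f > thr].tolist()


def pca(
    X: pd.DataFrame | np.ndarray, n_components: int, mean_center: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component analysis by SVD of the (mean-centered) matrix.

    Returns (scores, loadings, explained-variance %).  Loadings are
    orthonormal columns; explained variance is non-increasing.
    """
    Xa = np.asarray(X, dtype=float)
    n, p = Xa.shape
    if not 1 <= n_components <= min(n - 1 if mean_center else n, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    Xc = Xa - Xa.mean(axis=0) if mean_center else Xa
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    ev = s**2
    explained_pct = 100.0 * ev[:n_components] / ev.sum()
    return scores, loadings, explained_pct


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 discriminant model on dummy-coded classes."""

    classes: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray     # W  (p × a), unit-norm columns
    x_loadings: np.ndarray  # P  (p × a)
    y_loadings: np.ndarray  # Q  (c × a)
    x_scores: np.ndarray    # T  (n × a)
    coef: np.ndarray        # B = W (PᵀW)⁻¹ Qᵀ, maps centered X → centered Y
    feature_names: list = field(default_factory=list)
    majority_class: object = None


def _dummy(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def plsda_fit(
    X: pd.DataFrame | np.ndarray, labels, n_lv: int = 3, *, max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSDAModel:
    """Fit PLS-DA by NIPALS PLS2 on mean-centered X and class dummies.

    ``n_lv`` latent variables (default 3) are extracted; successive X-scores
    are mutually orthogonal.  Deterministic given the data.
    """
    Xdf = pd.DataFrame(X)
    names = list(Xdf.columns)
    Xa = Xdf.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    n, p = Xa.shape
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    rank = min(n - 1, p)
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds matrix rank bound {rank}")
    Y = _dummy(y, classes)
    x_mean = Xa.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = Xa - x_mean
    F = Y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = E[:, int(np.argmax(E.var(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = E.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-15:
                break
            w_new /= norm
            t = E @ w_new
            q = F.T @ t / (t @ t)
            u_new = F @ q / (q @ q) if q @ q > 0 else t
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                u = u_new
                break
            w, u = w_new, u_new
        t = E @ w
        tt = t @ t
        if tt < 1e-15:
            raise ValueError(f"latent variable {a + 1} is degenerate (rank exhausted)")
        pvec = E.T @ t / tt
        q = F.T @ t / tt
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    counts = {c: int((y == c).sum()) for c in classes}
    majority = max(counts, key=counts.get)
    return PLSDAModel(
        classes=classes, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=Q, x_scores=T, coef=coef,
        feature_names=names, majority_class=majority,
    )


def plsda_predict(model: PLSDAModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict class labels: argmax over the fitted class-dummy columns.

    Exact ties go to the training majority class.
    """
    Xa = pd.DataFrame(X).to_numpy(dtype=float)
    Yhat = (Xa - model.x_mean) @ model.coef + model.y_mean
    out = []
    for row in Yhat:
        top = np.nonzero(row == row.max())[0]
        if top.size > 1:
            out.append(model.majority_class)
        else:
            out.append(model.classes[top[0]])
    return np.asarray(out)


def vip(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a ), where SSY_a is
    the Y-variance explained by component a.  mean(VIP²) = 1 by construction.
    """
    W = model.weights
    if W.size == 0:
        raise ValueError("model is not fitted")
    p, n_lv = W.shape
    ssy = np.array(
        [
            (model.x_scores[:, a] @ model.x_scores[:, a])
            * (model.y_loadings[:, a] @ model.y_loadings[:, a])
            for a in range(n_lv)
        ]
    )
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0), 1e-300)
    v = np.sqrt(p * (wnorm2 * ssy).sum(axis=1) / ssy.sum())
    return pd.Series(v, index=model.feature_names, name="vip")


@dataclass
class CVReport:
    """Monte-Carlo cross-validation outcome."""

    accuracies: np.ndarray
    holdout_fraction: float
    n_reps: int
    confusion: pd.DataFrame         # rows true class, columns predicted
    selected_per_rep: list

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.n_reps > 1 else 0.0


def _stratified_holdout(y: np.ndarray, holdout: float, rng: np.random.Generator):
    """Class-proportional random holdout indices (≥1 per class)."""
    test_idx = []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        n_hold = max(1, int(round(idx.size * holdout)))
        if n_hold >= idx.size:
            raise ValueError(f"class {c!r} too small for holdout fraction {holdout}")
        test_idx.extend(rng.permutation(idx)[:n_hold].tolist())
    test = np.array(sorted(test_idx))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def monte_carlo_cv(
    X: pd.DataFrame | np.ndarray,
    labels,
    holdout: float = 0.10,
    reps: int = 100,
    n_lv: int = 3,
    fisher_threshold: float | None = 6.0,
    seed: int = 0,
) -> CVReport:
    """Monte-Carlo cross-validated PLS-DA.

    Each repetition draws a stratified random holdout (default 10%,
    preserving class proportions), recomputes the Fisher-ratio selection on
    the calibration split only (pass ``fisher_threshold=None`` to skip
    filtering), fits PLS-DA on the calibration samples and scores accuracy
    on the holdout.  Deterministic under ``seed``.
    """
    if not 0 < holdout <= 0.5:
        raise ValueError("holdout must be in (0, 0.5]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    Xdf = pd.DataFrame(X)
    y = np.asarray(labels)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    accs = np.zeros(reps)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    selected_per_rep = []
    for r in range(reps):
        train, test = _stratified_holdout(y, holdout, rng)
        Xtr, ytr = Xdf.iloc[train], y[train]
        Xte, yte = Xdf.iloc[test], y[test]
        if fisher_threshold is not None:
            fres = fisher_ratio(Xtr, ytr, threshold=fisher_threshold)
            feats = select_features(fres)
            if not feats:  # nothing passes the filter: fall back to all features
                feats = list(Xdf.columns)
        else:
            feats = list(Xdf.columns)
        selected_per_rep.append(feats)
        lv = min(n_lv, len(feats), len(train) - 1)
        model = plsda_fit(Xtr[feats], ytr, n_lv=lv)
        pred = plsda_predict(model, Xte[feats])
        accs[r] = float(np.mean(pred == yte))
        for t, q in zip(yte, pred):
            conf.loc[t, q] += 1
    return CVReport(
        accuracies=accs, holdout_fraction=holdout, n_reps=reps,
        confusion=conf, selected_per_rep=selected_per_rep,
    )


def chord_data(
    percent: pd.DataFrame, groups, threshold_pct: float = 2.0
) -> pd.DataFrame:
    """Chord-diagram edge list: (group, feature, mean %) where mean % > 2.

    ``percent`` is the percent view of a feature matrix; ``groups`` assigns
    each sample a group label.  The threshold is strict ("exceeded 2%"): a
    group-mean share of exactly 2.0% produces no edge.
    """
    g = np.asarray(groups)
    rows = []
    for grp in pd.unique(g):
        means = percent[g == grp].mean(axis=0)
        for feat, m in means.items():
            if m > threshold_pct:
                rows.append({"group": grp, "feature": feat, "mean_percent": float(m)})
    return pd.DataFrame(rows, columns=["group", "feature", "mean_percent"])
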