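"""PCA screening and the PLS-DA model suite.

PLS-DA is fit by a NIPALS implementation on unit-variance-scaled features
with one-hot class encoding; model quality is reported as R2Y (goodness of
fit) and Q2 (goodness of prediction from seeded stratified cross-validation,
Q2 = 1 - PRESS/SSY).  Variable influence is the standard VIP score, whose
squares average to 1; variables with VIP >= 1 form the selected set and an
optional refit model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

__all__ = [
    "PLSDAModel",
    "ContrastSpec",
    "pca_screen",
    "plsda_fit",
    "plsda_predict",
    "vip_scores",
    "cross_validate",
    "run_model_suite",
    "default_contrasts",
]


def _one_hot(y: Sequence) -> tuple[np.ndarray, list]:
    labels = sorted(set(y))
    Y = np.column_stack([[1.0 if v == c else 0.0 for v in y] for c in labels])
    return Y, labels


def pca_screen(
    X: np.ndarray, n_components: int = 2, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD principal components with Hotelling-T2 outlier flags.

    Samples whose T2 over the retained components exceeds the
    ``(1 - alpha)`` F-distribution threshold are flagged.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA screening needs at least 3 samples")
    n_components = min(n_components, n - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    lam = scores.var(axis=0, ddof=1)
    lam = np.where(lam > 0, lam, np.inf)
    t2 = (scores ** 2 / lam).sum(axis=1)
    a = n_components
    crit = a * (n - 1) / (n - a) * f_dist.ppf(1 - alpha, a, n - a)
    return scores, pca.components_.T, t2 > crit


@dataclass
class PLSDAModel:
    """A fitted PLS-DA model for one class contrast."""

    n_components: int
    x_weights: np.ndarray  # p x a
    x_loadings: np.ndarray  # p x a
    x_scores: np.ndarray  # n x a
    y_loadings: np.ndarray  # k x a
    class_labels: list
    x_mean: np.ndarray
    y_mean: np.ndarray
    variable_ids: list[str]
    r2y: float
    q2: float | None = None
    vip: np.ndarray | None = None


def _nipals(X: np.ndarray, Y: np.ndarray, n_components: int,
            max_iter: int = 500, tol: float = 1e-12):
    """NIPALS PLS2 on centered X, Y. Returns W, T, P, Q (columns per component)."""
    n, p = X.shape
    k = Y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((k, n_components))
    Xa, Ya = X.copy(), Y.copy()
    for a in range(n_components):
        u = Ya[:, np.argmax(Ya.var(axis=0))].copy()
        if np.allclose(Ya, 0):
            break
        t_old = None
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xa @ w
            tt = t @ t
            if tt == 0:
                break
            q = Ya.T @ t / tt
            qq = q @ q
            if qq == 0:
                break
            u = Ya @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        if nw == 0 or tt == 0:
            break
        # sign convention: first nonzero weight element positive
        nz = np.flatnonzero(np.abs(w) > 1e-12)
        if len(nz) and w[nz[0]] < 0:
            w, t, q = -w, -t, -q
        p_a = Xa.T @ t / tt
        Xa = Xa - np.outer(t, p_a)
        Ya = Ya - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_a, q
    return W, T, P, Q


def plsda_fit(
    X: np.ndarray,
    y: Sequence,
    n_components: int = 2,
    variable_ids: list[str] | None = None,
) -> PLSDAModel:
    """Fit a PLS-DA model (X should already be unit-variance scaled)."""
    X = np.asarray(X, dtype=float)
    y = list(y)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"every class needs >= 2 samples, got {counts.to_dict()}"
        )
    Y, labels = _one_hot(y)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    W, T, P, Q = _nipals(Xc, Yc, n_components)
    ssy_total = (Yc ** 2).sum()
    resid = Yc - T @ Q.T
    r2y = 1.0 - (resid ** 2).sum() / ssy_total if ssy_total > 0 else 0.0
    model = PLSDAModel(
        n_components=n_components,
        x_weights=W, x_loadings=P, x_scores=T, y_loadings=Q,
        class_labels=labels, x_mean=x_mean, y_mean=y_mean,
        variable_ids=list(variable_ids) if variable_ids is not None
        else [f"v{i}" for i in range(X.shape[1])],
        r2y=float(r2y),
    )
    try:
        model.vip = vip_scores(model)
    except ValueError:  # degenerate fit with no explained Y variance
        model.vip = None
    return model


def plsda_predict(model: PLSDAModel, Xnew: np.ndarray) -> np.ndarray:
    """Predicted (continuous) class-membership matrix for new samples."""
    Xc = np.asarray(Xnew, dtype=float) - model.x_mean
    W, P, Q = model.x_weights, model.x_loadings, model.y_loadings
    a = np.flatnonzero((W ** 2).sum(axis=0) > 0)
    if len(a) == 0:
        return np.tile(model.y_mean, (Xc.shape[0], 1))
    W, P, Q = W[:, a], P[:, a], Q[:, a]
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return Xc @ B + model.y_mean


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection; mean of squared scores equals 1."""
    W, T, Q = model.x_weights, model.x_scores, model.y_loadings
    used = np.flatnonzero((W ** 2).sum(axis=0) > 0)
    if len(used) == 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    W, T, Q = W[:, used], T[:, used], Q[:, used]
    p = W.shape[0]
    ssy = (T ** 2).sum(axis=0) * (Q ** 2).sum(axis=0)  # explained Y variance per component
    if ssy.sum() == 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wn2 * ssy).sum(axis=1) / ssy.sum())


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    n_components: int = 2,
    n_folds: int = 7,
    seed: int = 0,
) -> tuple[float, float]:
    """(R2Y on the full fit, Q2 from seeded stratified k-fold CV).

    Q2 = 1 - PRESS / SSY over held-out folds.  If the smallest class has
    fewer members than ``n_folds`` the fold count drops to that size so that
    every fold keeps all classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=object)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples for CV")
    n_folds = int(min(n_folds, counts.min()))
    if n_folds < 2:
        raise ValueError("cannot stratify: a class has < 2 samples")
    full = plsda_fit(X, y, n_components)
    Y, _ = _one_hot(y)
    press = ssy = 0.0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        m = plsda_fit(X[train], y[train], n_components)
        Yhat = plsda_predict(m, X[test])
        press += ((Y[test] - Yhat) ** 2).sum()
        ssy += ((Y[test] - Y[train].mean(axis=0)) ** 2).sum()
    q2 = 1.0 - press / ssy
    return full.r2y, float(q2)


@dataclass
class ContrastSpec:
    """One PLS-DA contrast: a labeling of manifest rows (None = excluded)."""

    name: str
    label_fn: Callable[[pd.DataFrame], pd.Series]
    n_components: int = 2

    def labels(self, manifest: pd.DataFrame) -> pd.Series:
        lab = self.label_fn(manifest)
        lab.index = manifest["sample_id"]
        return lab.dropna()


def _tissue_label(*classes: str, rename: dict | None = None):
    def fn(manifest: pd.DataFrame) -> pd.Series:
        lab = manifest["tissue_class"].where(
            manifest["tissue_class"].isin(classes)
        )
        if rename:
            lab = lab.replace(rename)
        return lab
    return fn


def _grade_vs_normal(grades: tuple[str, ...]):
    def fn(manifest: pd.DataFrame) -> pd.Series:
        lab = pd.Series(np.nan, index=manifest.index, dtype=object)
        tumor = (manifest.tissue_class == "primary_tumor") & manifest.grade.isin(grades)
        lab[tumor] = manifest.grade[tumor] if len(grades) > 1 else grades[0]
        lab[manifest.tissue_class == "normal_si"] = "normal_si"
        return lab
    return fn


def default_contrasts() -> list[ContrastSpec]:
    """The seven-model suite: tumors vs normal SI (all / G1 / G2 / 3-class),
    metastases vs normal liver, primary vs metastases, and the 3-class
    primary / metastasis / normal-liver overview."""
    return [
        ContrastSpec("net_vs_normal_si",
                     _tissue_label("primary_tumor", "normal_si"), 2),
        ContrastSpec("g1_vs_normal_si", _grade_vs_normal(("G1",)), 2),
        ContrastSpec("g2_vs_normal_si", _grade_vs_normal(("G2",)), 2),
        ContrastSpec("g1_g2_normal_si", _grade_vs_normal(("G1", "G2")), 2),
        ContrastSpec("mets_vs_normal_liver",
                     _tissue_label("liver_metastasis", "normal_liver"), 2),
        ContrastSpec("primary_vs_mets",
                     _tissue_label("primary_tumor", "liver_metastasis"), 2),
        ContrastSpec("primary_mets_normal_liver",
                     _tissue_label("primary_tumor", "liver_metastasis",
                                   "normal_liver"), 3),
    ]


def run_model_suite(
    table: pd.DataFrame,
    manifest: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
    n_folds: int = 7,
    seed: int = 0,
    vip_threshold: float = 1.0,
    vip_refit: bool = True,
) -> dict[str, dict]:
    """Fit every contrast on a feature table (buckets or quantified panel).

    Each entry reports the full-variable model (R2Y, Q2, VIP-selected
    variables) and, when requested, a refit restricted to VIP >= threshold.
    Contrasts with an empty class are skipped with a warning.
    """
    contrasts = contrasts if contrasts is not None else default_contrasts()
    results: dict[str, dict] = {}
    for spec in contrasts:
        lab = spec.labels(manifest)
        lab = lab[lab.index.isin(table.index)]
        counts = lab.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            log.warning("contrast %s skipped: class counts %s",
                        spec.name, counts.to_dict())
            continue
        X = table.loc[lab.index].to_numpy(dtype=float)
        model = plsda_fit(X, lab.to_list(), spec.n_components,
                          variable_ids=list(table.columns))
        r2y, q2 = cross_validate(X, lab.to_list(), spec.n_components,
                                 n_folds, seed)
        model.q2 = q2
        selected = [v for v, s in zip(model.variable_ids, model.vip)
                    if s >= vip_threshold]
        entry = {
            "model": model,
            "r2y": r2y,
            "q2": q2,
            "n_components": spec.n_components,
            "classes": counts.to_dict(),
            "vip_selected": selected,
        }
        if vip_refit and len(selected) >= 1:
            keep = [v in selected for v in model.variable_ids]
            refit = plsda_fit(X[:, keep], lab.to_list(), spec.n_components,
                              variable_ids=selected)
            _, refit.q2 = cross_validate(X[:, keep], lab.to_list(),
                                         spec.n_components, n_folds, seed)
            entry["vip_refit"] = refit
        results[spec.name] = entry
    return results
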