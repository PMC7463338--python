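"""Discriminant analysis of principal components (DAPC).

The classifier reduces the individuals x (locus, allele) frequency matrix by
PCA (centred, unscaled by default) and fits linear discriminant axes that
maximize the between/within group variance ratio on the retained PC scores.
Group membership probabilities are Gaussian posteriors with the pooled
within-group covariance and uniform priors - the standard DAPC predictive
behaviour.  The estimator follows the scikit-learn fit/transform/predict_proba
protocol and composes with sklearn model selection.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.model_selection import StratifiedShuffleSplit

from .core import MISSING, GenotypeTable, MembershipMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Allele-frequency encoding
# ---------------------------------------------------------------------------

class AlleleEncoder(TransformerMixin, BaseEstimator):
    """Encode a GenotypeTable as an individuals x (locus, allele) matrix.

    Diploid entries are allele copies / 2 (0, 0.5, 1), haploid entries 0/1, so
    each locus's columns sum to 1 for a non-missing call.  Missing calls are
    imputed with the column mean of observed calls; for new data the fitted
    (training) means are used and alleles unseen in training are dropped.
    """

    def fit(self, table: GenotypeTable, y=None):
        cols: list[tuple[str, str]] = []
        for j, loc in enumerate(table.panel):
            for a in table.alleles_at(j):
                cols.append((loc.locus_id, a))
        if not cols:
            raise ValueError("table has no observed alleles")
        self.columns_ = cols
        X = self._raw(table)
        obs = ~np.isnan(X)
        means = np.zeros(X.shape[1])
        np.copyto(means, np.nanmean(np.where(obs, X, np.nan), axis=0))
        self.column_means_ = np.nan_to_num(means)
        return self

    def _raw(self, table: GenotypeTable) -> np.ndarray:
        col_idx = {c: k for k, c in enumerate(self.columns_)}
        lookup: dict[str, list[tuple[int, str]]] = {}
        for (lid, a), k in col_idx.items():
            lookup.setdefault(lid, []).append((k, a))
        n = table.n_individuals
        X = np.full((n, len(self.columns_)), np.nan)
        if any(all(c is MISSING for c in row) for row in table.calls):
            raise ValueError("an individual is missing at all loci")
        for j, loc in enumerate(table.panel):
            cols = lookup.get(loc.locus_id, [])
            if not cols:
                continue
            for i in range(n):
                c = table.calls[i, j]
                if c is MISSING:
                    continue
                for k, _a in cols:
                    X[i, k] = 0.0
                denom = float(loc.ploidy)
                for allele in c:
                    k = col_idx.get((loc.locus_id, allele))
                    if k is not None:
                        X[i, k] += 1.0 / denom
        return X

    def transform(self, table: GenotypeTable) -> np.ndarray:
        X = self._raw(table)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.column_means_, X.shape)[nan]
        return X


def encode(table: GenotypeTable) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """One-shot encoding of a table on its own allele dictionary."""
    enc = AlleleEncoder().fit(table)
    return enc.transform(table), enc.columns_


# ---------------------------------------------------------------------------
# DAPC estimator
# ---------------------------------------------------------------------------

class DAPC(ClassifierMixin, BaseEstimator):
    """PCA reduction followed by linear discriminant axes and Gaussian
    posteriors (pooled within-group covariance, uniform priors).

    Parameters
    ----------
    n_pcs : number of principal components retained (capped at the matrix
        rank and n - 1); None keeps everything up to the cap.
    scale : divide columns by their standard deviation before PCA.
    ridge : jitter added to a singular within-group scatter, logged when used.
    """

    def __init__(self, n_pcs: int | None = None, scale: bool = False,
                 ridge: float = 1e-8):
        self.n_pcs = n_pcs
        self.scale = scale
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        g = len(self.classes_)
        if g < 2:
            raise ValueError("need at least two groups")
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.scale_ = sd
            Xc = Xc / sd
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int((s > max(n, p) * np.finfo(float).eps * (s[0] if s.size else 1)).sum())
        cap = max(1, min(n - 1, rank))
        n_pcs = min(self.n_pcs or cap, cap)
        self.n_pcs_ = n_pcs
        self.pc_loadings_ = Vt[:n_pcs].T                      # (p, n_pcs)
        self.pc_eigenvalues_ = (s[:n_pcs] ** 2) / max(n - 1, 1)
        S = Xc @ self.pc_loadings_                            # PC scores

        M = np.vstack([S[yi == k].mean(axis=0) for k in range(g)])
        Sw = np.zeros((n_pcs, n_pcs))
        for k in range(g):
            D = S[yi == k] - M[k]
            Sw += D.T @ D
        Sw /= max(n - g, 1)
        counts = np.bincount(yi, minlength=g).astype(float)
        grand = (counts[:, None] * M).sum(axis=0) / n
        Sb = (counts[:, None] * (M - grand)).T @ (M - grand) / max(g - 1, 1)
        try:
            w, V = scipy.linalg.eigh(Sb, Sw)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            log.info("singular within-group scatter; ridge %g applied", self.ridge)
            w, V = scipy.linalg.eigh(Sb, Sw + self.ridge * np.eye(n_pcs))
        order = np.argsort(w)[::-1]
        n_da = min(g - 1, n_pcs)
        self.da_vectors_ = V[:, order[:n_da]]                 # v' Sw v = I
        self.discriminant_eigenvalues_ = w[order[:n_da]]
        self.means_da_ = M @ self.da_vectors_
        Z = S @ self.da_vectors_
        W = np.zeros((n_da, n_da))
        for k in range(g):
            D = Z[yi == k] - self.means_da_[k]
            W += D.T @ D
        self.within_cov_ = W / max(n - g, 1)
        return self

    # -- helpers -------------------------------------------------------
    def _pc_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xc = X - self.mean_
        if self.scale:
            Xc = Xc / self.scale_
        return Xc @ self.pc_loadings_

    def transform(self, X) -> np.ndarray:
        """Discriminant-space coordinates."""
        return self._pc_scores(X) @ self.da_vectors_

    def predict_proba(self, X) -> np.ndarray:
        Z = self.transform(X)
        cov = self.within_cov_
        try:
            cho = scipy.linalg.cho_factor(cov)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            cho = scipy.linalg.cho_factor(cov + self.ridge * np.eye(cov.shape[0]))
        logd = np.empty((Z.shape[0], len(self.classes_)))
        for k, mu in enumerate(self.means_da_):
            D = Z - mu
            logd[:, k] = -0.5 * np.einsum(
                "ij,ij->i", D, scipy.linalg.cho_solve(cho, D.T).T
            )
        logd -= logd.max(axis=1, keepdims=True)
        probs = np.exp(logd)
        probs /= probs.sum(axis=1, keepdims=True)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def membership(self, X, individuals: Sequence[str]) -> MembershipMatrix:
        return MembershipMatrix(
            pd.DataFrame(
                self.predict_proba(X), index=list(individuals),
                columns=list(self.classes_),
            )
        )


# ---------------------------------------------------------------------------
# Cluster search with BIC
# ---------------------------------------------------------------------------

def pc_scores(X: np.ndarray, n_pcs: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, Xc.shape[0] - 1 if Xc.shape[0] > 1 else 1, Vt.shape[0])
    return Xc @ Vt[:k].T


@dataclasses.dataclass
class FindClustersResult:
    bic: pd.Series                 # BIC(K); -inf sentinel for degenerate K=1
    labels: dict[int, np.ndarray]
    n_pcs: int

    @property
    def best_k(self) -> int:
        valid = self.bic.dropna()
        return int(valid.idxmin())


def _wss(S: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for k in np.unique(labels):
        D = S[labels == k] - S[labels == k].mean(axis=0)
        w += float((D**2).sum())
    return w


def find_clusters(
    X: np.ndarray,
    k_range: Sequence[int] = range(1, 11),
    method: str = "kmeans",
    n_pcs: int = 50,
    seed: int = 0,
) -> FindClustersResult:
    """Search the number of clusters on PC scores.

    ``ward`` cuts an agglomerative minimum-variance tree at K; ``kmeans`` uses
    restarted k-means.  BIC(K) = n ln(WSS_K / n) + K ln(n) is computed from
    the same labels for either method so the curves are comparable.  A
    degenerate WSS = 0 at K = 1 (all rows identical) returns -inf so K = 1 is
    selected; WSS = 0 at K > 1 is excluded from the curve.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if max(k_range) > n:
        raise ValueError("K cannot exceed the number of individuals")
    S = pc_scores(X, n_pcs)
    bic: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for K in k_range:
        if K == 1:
            lab = np.zeros(n, dtype=int)
        elif method == "ward":
            lab = AgglomerativeClustering(n_clusters=K, linkage="ward").fit_predict(S)
        elif method == "kmeans":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lab = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(S)
        else:
            raise ValueError(f"unknown method {method!r}")
        labels[K] = lab
        wss = _wss(S, lab)
        if wss <= 0:
            bic[K] = -np.inf if K == 1 else np.nan
        else:
            bic[K] = n * np.log(wss / n) + K * np.log(n)
    return FindClustersResult(pd.Series(bic, name="BIC"), labels, S.shape[1])


# ---------------------------------------------------------------------------
# PC-retention cross-validation
# ---------------------------------------------------------------------------

def xval_pc_retention(
    X: np.ndarray,
    y: Sequence,
    start_pcs: int = 300,
    grid: Sequence[int] | None = None,
    folds: int = 4,
    reps: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Stratified held-out assignment accuracy over a grid of PC counts,
    starting from ``start_pcs`` (capped at n - 1 and the column count).
    Returns the selected count (highest mean accuracy; ties -> fewest PCs)
    and the full accuracy curve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members to stratify")
    cap = min(start_pcs, X.shape[0] - 1, X.shape[1])
    if cap < start_pcs:
        log.info("start_pcs capped at %d", cap)
    if grid is None:
        grid = sorted({int(v) for v in np.geomspace(1, cap, num=min(8, cap))} | {cap})
    splitter = StratifiedShuffleSplit(
        n_splits=reps, test_size=max(1.0 / folds, len(classes) / len(y)),
        random_state=seed,
    )
    acc = {k: [] for k in grid}
    for train, test in splitter.split(X, y):
        for k in grid:
            model = DAPC(n_pcs=k).fit(X[train], y[train])
            acc[k].append(float((model.predict(X[test]) == y[test]).mean()))
    curve = pd.DataFrame(
        {"n_pcs": list(grid), "accuracy": [float(np.mean(acc[k])) for k in grid]}
    )
    best = curve.sort_values(["accuracy", "n_pcs"], ascending=[False, True])
    return int(best.iloc[0]["n_pcs"]), curve


# ---------------------------------------------------------------------------
# Membership post-processing
# ---------------------------------------------------------------------------

def redistribute_membership(m, floor: float = 0.05):
    """Zero membership coefficients below ``floor`` and redistribute their
    mass proportionally over the surviving coefficients, so each row still
    sums to one.  If everything but the maximum falls below the floor the row
    becomes an indicator of the maximum.  Idempotent."""
    if isinstance(m, MembershipMatrix):
        return MembershipMatrix(redistribute_membership(m.df, floor))
    if isinstance(m, pd.DataFrame):
        out = m.copy()
        out.loc[:, :] = redistribute_membership(m.to_numpy(dtype=float), floor)
        return out
    V = np.array(m, dtype=float)
    one_row = V.ndim == 1
    if one_row:
        V = V[None, :]
    for i in range(V.shape[0]):
        row = V[i]
        imax = int(row.argmax())
        drop = row < floor
        drop[imax] = False
        row[drop] = 0.0
        tot = row.sum()
        if tot <= 0 or (row[imax] < floor):
            if row[imax] < floor:
                log.warning("row %d: all coefficients below floor; using argmax", i)
            row[:] = 0.0
            row[imax] = 1.0
        else:
            row /= tot
    return V[0] if one_row else V


# ---------------------------------------------------------------------------
# Hierarchical (two-level) workflow
# ---------------------------------------------------------------------------

def hierarchical_dapc(
    table: GenotypeTable,
    k_range: Sequence[int] = range(1, 11),
    method: str = "kmeans",
    n_pcs: int = 50,
    min_size: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-level cluster search: find clusters on the full table, then repeat
    within each top-level group (groups smaller than ``min_size`` pass through
    unsplit).  Returns per-individual (group, cluster) labels and the BIC
    curves of every search."""
    enc = AlleleEncoder().fit(table)
    X = enc.transform(table)
    top = find_clusters(X, k_range=k_range, method=method, n_pcs=n_pcs, seed=seed)
    top_labels = top.labels[top.best_k]
    detail = {"top": top}
    rows = []
    for g in np.unique(top_labels):
        idx = np.where(top_labels == g)[0]
        inds = [table.individuals[i] for i in idx]
        if len(idx) < max(min_size, 2):
            log.info("group %s below min size; left unsplit", g)
            sub_labels = np.zeros(len(idx), dtype=int)
        else:
            sub_tab = table.subset(individuals=inds)
            sub_X = AlleleEncoder().fit(sub_tab).transform(sub_tab)
            sub_krange = [k for k in k_range if k <= len(idx) - 1] or [1]
            sub = find_clusters(
                sub_X, k_range=sub_krange, method=method, n_pcs=n_pcs, seed=seed
            )
            detail[f"group{g}"] = sub
            sub_labels = sub.labels[sub.best_k]
        for ind, c in zip(inds, sub_labels):
            rows.append(
                {"individual": ind, "group": int(g), "cluster": f"{g}.{c}"}
            )
    df = pd.DataFrame(rows).set_index("individual").loc[table.individuals]
    return df, detail
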