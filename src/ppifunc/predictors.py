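"""Function-prediction classifiers.

Every predictor returns a *prediction table*: a pandas DataFrame whose rows
are test proteins, columns are GO terms, and entries are posterior
probabilities P(protein, term) in [0, 1]. When a posterior is undefined —
a protein with no training neighbours, no hits, zero total edge weight —
the whole row is exactly 0, signalling "this method cannot say anything
about this protein" (such rows count against coverage).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import AnnotationTable

__all__ = [
    "naive_predict",
    "gba_predict",
    "gba_weighted",
    "similarity_transfer",
    "combine",
    "knn_predict",
    "label_matrix",
    "ridge_fit_predict",
]


def _label_bool(train: AnnotationTable, proteins: Sequence[str], terms: Sequence[str]) -> np.ndarray:
    """Boolean protein x term membership matrix."""
    tidx = {t: j for j, t in enumerate(terms)}
    Y = np.zeros((len(proteins), len(terms)), dtype=bool)
    for i, p in enumerate(proteins):
        for t in train.annotations.get(p, ()):
            j = tidx.get(t)
            if j is not None:
                Y[i, j] = True
    return Y


def naive_predict(
    train: AnnotationTable, test: Sequence[str], terms: Sequence[str]
) -> pd.DataFrame:
    """Frequency baseline: P(p, t) = training frequency of t, for every p.

    Every test protein receives the same row, which makes this the
    "Bayesian marginal" baseline with coverage 1 by construction.
    """
    train_proteins = sorted(train.proteins)
    if not train_proteins:
        raise ValueError("naive_predict requires a non-empty training set")
    freq = np.array(
        [train.term_count.get(t, 0) / len(train_proteins) for t in terms]
    )
    return pd.DataFrame(
        np.tile(freq, (len(test), 1)), index=list(test), columns=list(terms)
    )


def gba_predict(
    g: nx.Graph,
    train: AnnotationTable,
    test: Sequence[str],
    terms: Sequence[str],
) -> pd.DataFrame:
    """Guilt-by-association on a binary graph.

    P(p, t) is the fraction of p's training-set neighbours annotated with t.
    Proteins with no training neighbour get an all-zero row.
    """
    train_proteins = sorted(train.proteins)
    Y = _label_bool(train, train_proteins, terms).astype(float)
    pos = {p: i for i, p in enumerate(train_proteins)}
    P = np.zeros((len(test), len(terms)))
    for i, p in enumerate(test):
        if p not in g:
            continue
        nbr = [pos[n] for n in g.neighbors(p) if n in pos]
        if nbr:
            P[i] = Y[nbr].sum(axis=0) / len(nbr)
    return pd.DataFrame(P, index=list(test), columns=list(terms))


def gba_weighted(
    g: nx.Graph,
    train: AnnotationTable,
    test: Sequence[str],
    terms: Sequence[str],
) -> pd.DataFrame:
    """Weighted GBA: neighbours vote with their edge weight.

    P(p, t) = sum_n w(p,n)·1[t in T(n)] / sum_n w(p,n); a zero total weight
    yields an all-zero row. On a 0/1-weighted graph this reduces to
    :func:`gba_predict`.
    """
    train_proteins = sorted(train.proteins)
    Y = _label_bool(train, train_proteins, terms).astype(float)
    pos = {p: i for i, p in enumerate(train_proteins)}
    P = np.zeros((len(test), len(terms)))
    for i, p in enumerate(test):
        if p not in g:
            continue
        idx, w = [], []
        for n in g.neighbors(p):
            j = pos.get(n)
            if j is not None:
                idx.append(j)
                w.append(g[p][n].get("weight", 1.0))
        tot = float(np.sum(w))
        if tot > 0:
            P[i] = (np.asarray(w) @ Y[idx]) / tot
    return pd.DataFrame(P, index=list(test), columns=list(terms))


def similarity_transfer(
    identity: Mapping[tuple[str, str], float],
    train: AnnotationTable,
    test: Sequence[str],
    terms: Sequence[str],
) -> pd.DataFrame:
    """Annotation transfer by maximum sequence identity (BLAST-style).

    P(p, t) = max identity over training hits of p annotated with t; absent
    pairs are treated as "no hit" and contribute 0. Identities must be
    fractions in [0, 1].
    """
    hits: dict[str, list[tuple[str, float]]] = {p: [] for p in test}
    train_set = train.proteins
    for (a, b), v in identity.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"identity for ({a},{b}) is {v}, must be in [0,1]")
        for query, hit in ((a, b), (b, a)):
            if query in hits and hit in train_set:
                hits[query].append((hit, v))
    tidx = {t: j for j, t in enumerate(terms)}
    P = np.zeros((len(test), len(terms)))
    for i, p in enumerate(test):
        for hit, v in hits[p]:
            for t in train.annotations[hit]:
                j = tidx.get(t)
                if j is not None and v > P[i, j]:
                    P[i, j] = v
    return pd.DataFrame(P, index=list(test), columns=list(terms))


def combine(p1: pd.DataFrame, p2: pd.DataFrame) -> pd.DataFrame:
    """Noisy-OR fusion of two classifiers: P = 1 - (1-P1)(1-P2).

    High whenever at least one component is confident; 0 is the identity
    element and 1 is absorbing.
    """
    if not (p1.index.equals(p2.index) and p1.columns.equals(p2.columns)):
        raise ValueError("prediction tables must share rows and columns")
    return 1.0 - (1.0 - p1) * (1.0 - p2)


def label_matrix(
    train: AnnotationTable, proteins: Sequence[str], terms: Sequence[str]
) -> np.ndarray:
    """{-1, +1} label matrix Y: +1 iff the protein carries the term."""
    return np.where(_label_bool(train, proteins, terms), 1.0, -1.0)


def knn_predict(
    train_embeddings: pd.DataFrame,
    train: AnnotationTable,
    test_embeddings: pd.DataFrame,
    k: int,
    terms: Sequence[str],
    metric: str = "euclidean",
) -> pd.DataFrame:
    """k-nearest-neighbour vote in embedding space.

    P(p, t) = fraction of the k nearest training proteins (Euclidean by
    default, cosine optionally) annotated with t. Distance ties at the k-th
    neighbour break by training-protein row order, which is deterministic.
    """
    n_train = len(train_embeddings)
    if not 1 <= k <= n_train:
        raise ValueError(f"k={k} must be in [1, {n_train}]")
    Xtr = train_embeddings.to_numpy(dtype=float)
    Xte = test_embeddings.to_numpy(dtype=float)
    if metric == "euclidean":
        d2 = (
            (Xte**2).sum(1)[:, None] - 2 * Xte @ Xtr.T + (Xtr**2).sum(1)[None, :]
        )
        dist = np.sqrt(np.maximum(d2, 0.0))
    elif metric == "cosine":
        nte = np.linalg.norm(Xte, axis=1, keepdims=True)
        ntr = np.linalg.norm(Xtr, axis=1, keepdims=True)
        nte[nte == 0] = 1.0
        ntr[ntr == 0] = 1.0
        dist = 1.0 - (Xte / nte) @ (Xtr / ntr).T
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    Y = _label_bool(train, list(train_embeddings.index), terms).astype(float)
    P = Y[order].mean(axis=1)
    return pd.DataFrame(P, index=list(test_embeddings.index), columns=list(terms))


def ridge_fit_predict(
    X_train: np.ndarray,
    Y: np.ndarray,
    lam: float,
    X_test: np.ndarray,
    center: bool = True,
) -> np.ndarray:
    """Multi-output ridge with the closed-form solution, squashed by a sigmoid.

    W* = (XᵀX + λI)⁻¹ XᵀY with Y in {-1, +1}; predictions are s(X_test W*)
    with s(a) = 1/(1+e^{-a}). No intercept; features are mean-centered by
    default (training mean applied to both sets). Predictions are not
    post-processed, so they may be inconsistent with the GO hierarchy.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if center:
        mu = X_train.mean(axis=0)
        X_train = X_train - mu
        X_test = X_test - mu
    d = X_train.shape[1]
    A = X_train.T @ X_train + lam * np.eye(d)
    try:
        W = np.linalg.solve(A, X_train.T @ np.asarray(Y, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"normal equations are singular ({exc}); use lambda > 0"
        ) from exc
    return 1.0 / (1.0 + np.exp(-(X_test @ W)))


def ridge_predict_table(
    train_embeddings: pd.DataFrame,
    train: AnnotationTable,
    test_embeddings: pd.DataFrame,
    lam: float,
    terms: Sequence[str],
    center: bool = True,
) -> pd.DataFrame:
    """DataFrame wrapper around :func:`ridge_fit_predict`."""
    Y = label_matrix(train, list(train_embeddings.index), terms)
    P = ridge_fit_predict(
        train_embeddings.to_numpy(float), Y, lam, test_embeddings.to_numpy(float),
        center=center,
    )
    return pd.DataFrame(P, index=list(test_embeddings.index), columns=list(terms))


def write_predictions(pred: pd.DataFrame, path, decimals: int = 2) -> None:
    """Serialize as CAFA-style protein<TAB>term<TAB>score (non-zero entries)."""
    with open(path, "w") as fh:
        fh.write("protein\tterm\tscore\n")
        for p in pred.index:
            row = pred.loc[p]
            for t in pred.columns:
                s = row[t]
                if s > 0:
                    fh.write(f"{p}\t{t}\t{s:.{decimals}f}\n")
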