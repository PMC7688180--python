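"""CAFA-style protein-centric evaluation and cross-validation machinery.

Fmax is the maximum, over a decision-threshold grid, of the harmonic mean of
protein-averaged precision and recall; Smin is the minimum Euclidean norm of
(remaining uncertainty, misinformation) measured in information-content
bits. Prediction Advantage expresses a classifier's loss reduction relative
to the naive frequency baseline. Both metrics use the threshold grid
0.01, 0.02, ..., 1.00.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationTable

__all__ = [
    "THRESHOLDS",
    "FoldSpec",
    "fmax",
    "smin",
    "coverage",
    "prediction_advantage",
    "make_folds",
    "filter_fold_terms",
    "tune_hyperparameters",
    "compare_methods",
]

#: CAFA decision-threshold grid.
THRESHOLDS = np.round(np.arange(1, 101) / 100.0, 2)


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold with an inner 80/20 tuning split."""

    index: int
    train: tuple[str, ...]
    test: tuple[str, ...]
    inner_train: tuple[str, ...]
    inner_val: tuple[str, ...]


def _truth_matrix(
    pred: pd.DataFrame, truth: AnnotationTable, exclude_terms: frozenset[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    terms = [t for t in pred.columns if t not in exclude_terms]
    P = pred[terms].to_numpy(dtype=float)
    Y = np.zeros_like(P, dtype=bool)
    tidx = {t: j for j, t in enumerate(terms)}
    for i, p in enumerate(pred.index):
        if p not in truth.annotations:
            raise ValueError(f"protein {p} missing from the truth table")
        for t in truth.annotations[p]:
            j = tidx.get(t)
            if j is not None:
                Y[i, j] = True
    return P, Y, terms


def fmax(
    pred: pd.DataFrame,
    truth: AnnotationTable,
    exclude_terms: frozenset[str] = frozenset(),
) -> tuple[float, float]:
    """Protein-centric Fmax and its optimal threshold.

    At each threshold tau, precision is averaged over proteins with at least
    one prediction >= tau, recall over *all* test proteins; thresholds at
    which no protein has a prediction are skipped. Ties prefer the smallest
    tau. Root terms can be excluded via ``exclude_terms`` (they are
    trivially predicted).
    """
    if len(pred) == 0:
        raise ValueError("empty test set")
    P, Y, _ = _truth_matrix(pred, truth, exclude_terms)
    n_true = Y.sum(axis=1)
    best_f, best_tau = 0.0, float(THRESHOLDS[0])
    for tau in THRESHOLDS:
        B = P >= tau
        n_pred = B.sum(axis=1)
        covered = n_pred > 0
        if not covered.any():
            continue
        tp = (B & Y).sum(axis=1)
        pr = float(np.mean(tp[covered] / n_pred[covered]))
        with np.errstate(invalid="ignore", divide="ignore"):
            rc_each = np.where(n_true > 0, tp / np.maximum(n_true, 1), 0.0)
        rc = float(np.mean(rc_each))
        if pr + rc > 0:
            f = 2 * pr * rc / (pr + rc)
            if f > best_f:
                best_f, best_tau = f, float(tau)
    return best_f, best_tau


def smin(
    pred: pd.DataFrame,
    truth: AnnotationTable,
    ic: Mapping[str, float],
    exclude_terms: frozenset[str] = frozenset(),
) -> tuple[float, float]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold grid.

    ru(tau) is the mean, over test proteins, of the summed IC of true terms
    missed at tau; mi(tau) of the summed IC of false-positive terms.
    """
    P, Y, terms = _truth_matrix(pred, truth, exclude_terms)
    missing = [t for t in terms if t not in ic]
    if missing:
        raise ValueError(f"missing information content for terms: {missing}")
    w = np.array([ic[t] for t in terms])
    best_s, best_tau = np.inf, float(THRESHOLDS[0])
    for tau in THRESHOLDS:
        B = P >= tau
        ru = float(np.mean(((~B) & Y) @ w))
        mi = float(np.mean((B & (~Y)) @ w))
        s = float(np.hypot(ru, mi))
        if s < best_s:
            best_s, best_tau = s, float(tau)
    return best_s, best_tau


def coverage(pred: pd.DataFrame) -> float:
    """Fraction of test proteins with at least one non-zero posterior."""
    if len(pred) == 0:
        return 0.0
    return float((pred.to_numpy() > 0).any(axis=1).mean())


def prediction_advantage(loss_c: float, loss_naive: float) -> float:
    """PA = 1 - L_c / L_naive, with L = 1 - Fmax as the classification loss."""
    if loss_naive <= 0:
        raise ValueError("naive loss must be positive for PA to be defined")
    return 1.0 - loss_c / loss_naive


def make_folds(
    proteins: Sequence[str], k: int = 5, seed: int = 0
) -> list[FoldSpec]:
    """Seeded shuffle + contiguous k-way partition; inner 80/20 split recorded.

    Fold sizes differ by at most one; folds partition the protein set.
    """
    proteins = sorted(proteins)
    if k > len(proteins):
        raise ValueError(f"k={k} exceeds the number of proteins ({len(proteins)})")
    rng = np.random.default_rng(seed)
    order = [proteins[i] for i in rng.permutation(len(proteins))]
    bounds = np.linspace(0, len(order), k + 1).astype(int)
    folds = []
    for i in range(k):
        test = tuple(order[bounds[i] : bounds[i + 1]])
        train = tuple(p for p in order if p not in set(test))
        cut = int(round(0.8 * len(train)))
        folds.append(
            FoldSpec(
                index=i,
                train=train,
                test=test,
                inner_train=train[:cut],
                inner_val=train[cut:],
            )
        )
    return folds


def filter_fold_terms(fold: FoldSpec, annots: AnnotationTable) -> list[str]:
    """Terms with at least one positive example in both train and test."""
    in_train: set[str] = set()
    for p in fold.train:
        in_train |= annots.annotations.get(p, frozenset())
    in_test: set[str] = set()
    for p in fold.test:
        in_test |= annots.annotations.get(p, frozenset())
    return sorted(in_train & in_test)


def tune_hyperparameters(
    grid: Sequence[Mapping],
    fold: FoldSpec,
    evaluate: Callable[[Mapping, Sequence[str], Sequence[str]], float],
) -> tuple[Mapping, float]:
    """Pick the grid point maximising Fmax on the fold's inner validation set.

    ``evaluate(config, inner_train, inner_val)`` must return the validation
    Fmax. Ties break in favour of the earliest grid point. The caller
    retrains the winner on the full training set.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best_cfg, best_score = None, -np.inf
    for cfg in grid:
        score = evaluate(cfg, fold.inner_train, fold.inner_val)
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, best_score


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        # degenerate variance: identical vectors are indistinguishable,
        # a constant non-zero shift is unambiguously significant
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return np.inf if diff.mean() > 0 else -np.inf, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def compare_methods(
    per_fold_scores: Mapping[str, Sequence[float]],
    test: str = "t",
) -> pd.DataFrame:
    """All-pairs method comparison with Benjamini-Hochberg FDR adjustment.

    ``test='t'`` runs a paired t-test on the per-fold scores; ``'ranksum'``
    runs the Wilcoxon rank-sum test (used for unpaired per-protein bins).
    The BH family is the full set of pairwise comparisons.
    """
    methods = sorted(per_fold_scores)
    lengths = {m: len(per_fold_scores[m]) for m in methods}
    if test == "t" and len(set(lengths.values())) > 1:
        raise ValueError(f"paired test needs equal-length vectors, got {lengths}")
    rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            a = np.asarray(per_fold_scores[m1], dtype=float)
            b = np.asarray(per_fold_scores[m2], dtype=float)
            if test == "t":
                t, p = _paired_t(a, b)
            elif test == "ranksum":
                t, p = stats.ranksums(a, b)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {"method_a": m1, "method_b": m2, "statistic": float(t), "p": float(p)}
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
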