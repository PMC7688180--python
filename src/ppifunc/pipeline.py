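"""Experiment orchestration: cross-validated runs, the data-source
combination sweep, and the edge-downsampling robustness study.

Every run is a pure function of (inputs, config, seeds): the same call with
the same arguments produces identical tables, and every metric row can be
re-derived from the persisted prediction tables with the evaluation module
alone.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import evaluation, network, predictors
from .embeddings import node2vec_embed
from .evaluation import (
    FoldSpec,
    coverage,
    filter_fold_terms,
    fmax,
    make_folds,
    prediction_advantage,
    smin,
)
from .network import (
    enumerate_source_combinations,
    integrate_sources,
    threshold_top_half,
    union_binary,
    downsample_uniform,
    downsample_degree_biased,
)
from .ontology import AnnotationTable, Ontology, information_content
from .predictors import (
    combine,
    gba_predict,
    gba_weighted,
    knn_predict,
    naive_predict,
    ridge_predict_table,
    similarity_transfer,
    write_predictions,
)

__all__ = ["run_experiment", "run_combination_sweep", "run_downsampling",
           "DEFAULT_NODE2VEC_GRID"]

#: Modest default tuning grid for the embedding classifiers. The reference
#: node2vec grid (d in {64,128}, p,q in {0.25,1,4}, r=10, l=80) is available
#: through configuration; this default keeps desk-scale experiments quick.
DEFAULT_NODE2VEC_GRID: tuple[dict, ...] = tuple(
    {"d": 32, "p": p, "q": q, "classifier": clf, "param": prm}
    for p, q in [(1.0, 1.0)]
    for clf, prm in [("knn", 1), ("knn", 5), ("ridge", 1.0), ("ridge", 10.0)]
)


def _predict_embedding(
    emb: pd.DataFrame,
    train: AnnotationTable,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    terms: Sequence[str],
    classifier: str,
    param,
) -> pd.DataFrame:
    tr = emb.loc[[p for p in train_ids if p in emb.index]]
    te = emb.reindex(list(test_ids)).fillna(0.0)
    if classifier == "knn":
        k = int(min(param, len(tr)))
        return knn_predict(tr, train, te, k, terms)
    if classifier == "ridge":
        return ridge_predict_table(tr, train, te, float(param), terms)
    raise ValueError(f"unknown embedding classifier {classifier!r}")


def _fold_predictions(
    name: str,
    g: nx.Graph,
    train: AnnotationTable,
    fold: FoldSpec,
    terms: Sequence[str],
    identity: Mapping[tuple[str, str], float] | None,
    embeddings: Mapping[tuple, pd.DataFrame],
    grid: Sequence[Mapping],
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Predictions for one classifier on one fold; returns (table, log)."""
    test = list(fold.test)
    log: dict = {}
    if name == "naive":
        return naive_predict(train, test, terms), log
    if name == "gba":
        return gba_predict(g, train, test, terms), log
    if name == "gba_weighted":
        return gba_weighted(g, train, test, terms), log
    if name == "similarity":
        if identity is None:
            raise ValueError("similarity classifier needs an identity table")
        return similarity_transfer(identity, train, test, terms), log
    if name == "node2vec":
        def evaluate(cfg, inner_train, inner_val):
            emb = embeddings[(cfg["d"], cfg["p"], cfg["q"])]
            inner_annots = train.subset(inner_train)
            inner_terms = sorted(
                set(itertools.chain.from_iterable(
                    inner_annots.annotations.values()))
                & set(
                    itertools.chain.from_iterable(
                        train.annotations.get(p, frozenset()) for p in inner_val
                    )
                )
            )
            if not inner_terms:
                return 0.0
            pred = _predict_embedding(
                emb, inner_annots, inner_train, inner_val, inner_terms,
                cfg["classifier"], cfg["param"],
            )
            truth = train.subset(list(inner_val) + list(inner_train))
            return fmax(pred, truth)[0]

        best, best_score = evaluation.tune_hyperparameters(grid, fold, evaluate)
        log = {"config": dict(best), "val_fmax": best_score}
        emb = embeddings[(best["d"], best["p"], best["q"])]
        pred = _predict_embedding(
            emb, train, fold.train, test, terms, best["classifier"], best["param"]
        )
        return pred, log
    if name.startswith("fusion:"):
        parts = name.split(":", 1)[1].split("+")
        p1, l1 = _fold_predictions(parts[0], g, train, fold, terms, identity,
                                   embeddings, grid, seed)
        p2, l2 = _fold_predictions(parts[1], g, train, fold, terms, identity,
                                   embeddings, grid, seed)
        return combine(p1, p2), {"a": l1, "b": l2}
    raise ValueError(f"unknown classifier {name!r}")


def run_experiment(
    g: nx.Graph,
    annots: AnnotationTable,
    onto: Ontology,
    classifiers: Sequence[str] = ("naive", "gba"),
    k_folds: int = 5,
    seed: int = 0,
    identity: Mapping[tuple[str, str], float] | None = None,
    grid: Sequence[Mapping] = DEFAULT_NODE2VEC_GRID,
    folds: Sequence[FoldSpec] | None = None,
    network_name: str = "network",
    outdir: str | Path | None = None,
    exclude_roots: bool = True,
) -> pd.DataFrame:
    """Cross-validated evaluation of ``classifiers`` on one network.

    Returns one row per (network, classifier, fold) with Fmax, its
    threshold, Smin, coverage, and the Prediction Advantage against the
    naive baseline computed on the same fold. Root terms are excluded from
    scoring by default (they are trivially predicted). Prediction tables
    are written under ``outdir`` when given.
    """
    if folds is None:
        folds = make_folds(sorted(annots.proteins), k=k_folds, seed=seed)
    needs_emb = any(c == "node2vec" or "node2vec" in c for c in classifiers)
    embeddings: dict[tuple, pd.DataFrame] = {}
    if needs_emb:
        for key in {(c["d"], c["p"], c["q"]) for c in grid}:
            d, p, q = key
            embeddings[key] = node2vec_embed(g, d=d, p=p, q=q, seed=seed)
    roots = onto.roots if exclude_roots else frozenset()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for fold in folds:
        train = annots.subset(fold.train)
        truth = annots  # full table covers the test proteins
        terms = filter_fold_terms(fold, annots)
        ic = information_content(train, onto)
        naive_pred = naive_predict(train, list(fold.test), terms)
        naive_f, _ = fmax(naive_pred, truth, exclude_terms=roots)
        for name in classifiers:
            pred, log = _fold_predictions(
                name, g, train, fold, terms, identity, embeddings, grid, seed
            )
            f, tau = fmax(pred, truth, exclude_terms=roots)
            # IC may miss rare test-only terms; they were filtered per fold
            s, _ = smin(pred, truth, ic, exclude_terms=roots)
            pa = (
                prediction_advantage(1.0 - f, 1.0 - naive_f)
                if naive_f < 1.0
                else 0.0
            )
            rows.append(
                {
                    "network": network_name,
                    "classifier": name,
                    "fold": fold.index,
                    "fmax": f,
                    "tau": tau,
                    "smin": s,
                    "coverage": coverage(pred),
                    "pa": pa,
                    "n_terms": len(terms),
                    "log": repr(log) if log else "",
                }
            )
            if outdir is not None:
                safe = name.replace(":", "_").replace("+", "_")
                write_predictions(
                    pred, outdir / f"{network_name}.{safe}.fold{fold.index}.tsv"
                )
    df = pd.DataFrame(rows)
    if outdir is not None:
        df.to_csv(outdir / f"{network_name}.report.tsv", sep="\t", index=False)
    return df


def run_combination_sweep(
    exp_graph: nx.Graph,
    sources: Sequence[network.SourceScoreTable],
    annots: AnnotationTable,
    onto: Ontology,
    prior: float = 0.041,
    k_folds: int = 5,
    seed: int = 0,
    classifier: str = "gba",
) -> pd.DataFrame:
    """Evaluate every non-empty subset of evidence channels added to the
    experimental graph (2^k - 1 rows, mean over folds).

    All subsets share one fold assignment so their per-fold scores are
    paired for downstream t-tests. For each subset the channel scores are
    probabilistically integrated, thresholded to the top half of non-zero
    scores, OR-ed with the experimental edges, and scored with GBA.
    """
    by_name = {t.source: t for t in sources}
    combos = enumerate_source_combinations(sorted(by_name))
    folds = make_folds(sorted(annots.proteins), k=k_folds, seed=seed)
    rows = []
    for combo in combos:
        tables = [by_name[n] for n in combo]
        merged = tables[0] if len(tables) == 1 else integrate_sources(
            tables, prior=prior
        )
        g = union_binary(exp_graph, threshold_top_half(merged))
        g = network.restrict_to_annotated(g, annots.proteins)
        rep = run_experiment(
            g, annots, onto, classifiers=(classifier,), folds=folds, seed=seed,
            network_name="+".join(combo),
        )
        rows.append(
            {
                "subset": "+".join(combo),
                "n_sources": len(combo),
                "fmax": rep["fmax"].mean(),
                "smin": rep["smin"].mean(),
                "coverage": rep["coverage"].mean(),
            }
        )
    return pd.DataFrame(rows)


def run_downsampling(
    g: nx.Graph,
    annots: AnnotationTable,
    onto: Ontology,
    fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75),
    strategies: Sequence[str] = ("uniform", "degree"),
    n_seeds: int = 3,
    seed: int = 0,
    k_folds: int = 5,
    classifier: str = "gba",
) -> pd.DataFrame:
    """Edge-removal robustness study: full factorial over strategy x
    fraction x seed, re-running cross-validation on each stripped graph."""
    samplers = {"uniform": downsample_uniform, "degree": downsample_degree_biased}
    unknown = set(strategies) - set(samplers)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}")
    rows = []
    for strategy in strategies:
        for f in fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0,1]")
            for s in range(n_seeds):
                sub_seed = seed + 1000 * s
                h = samplers[strategy](g, f, seed=sub_seed)
                rep = run_experiment(
                    h, annots, onto, classifiers=(classifier,),
                    k_folds=k_folds, seed=seed,
                    network_name=f"{strategy}_f{f}_s{s}",
                )
                rows.append(
                    {
                        "strategy": strategy,
                        "fraction": f,
                        "seed": sub_seed,
                        "fmax": rep["fmax"].mean(),
                        "smin": rep["smin"].mean(),
                        "coverage": rep["coverage"].mean(),
                    }
                )
    return pd.DataFrame(rows)
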