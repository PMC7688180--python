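"""Synthetic ontology / annotation / network / score generator.

Produces coupled fixtures with the statistical structure the analysis
assumes: a rooted GO-like DAG, propagated per-protein term sets with a
realistic frequency skew (shallow terms common, deep terms rare), an
undirected interaction network whose edge probability grows with shared
specific function, several noisy per-source association score channels, and
a pairwise sequence-identity surrogate correlated with shared function.

Functional association between two proteins is measured as the Jaccard
similarity of their non-root propagated term sets; the network generator
plants the guilt-by-association signal by wiring proteins with probability
``q0 + q1 * J(i, j)``. All randomness flows from one root seed through
named substreams, so each artifact can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .network import SourceScoreTable, STRING_CHANNELS, _pair
from .ontology import AnnotationTable, Ontology

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_ontology",
    "gen_annotations",
    "gen_network",
    "gen_source_scores",
    "gen_identity",
    "simulate",
    "write_obo",
    "write_gaf",
]

_SUBSTREAMS = {
    "ontology": 1,
    "annotations": 2,
    "network": 3,
    "sources": 4,
    "identity": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[stream],))
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``q0`` is the background edge rate, ``q1`` the functional-coupling
    strength (``q1 = 0`` disables the guilt-by-association signal entirely,
    yielding an Erdos-Renyi graph). ``noise_sd`` blurs the per-source
    association scores; ``dropout`` is the per-pair probability that a
    source simply has no measurement.
    """

    seed: int
    n_proteins: int = 150
    n_terms: int = 40
    branching: int = 2
    annotation_rate: float = 0.5
    q0: float = 0.01
    q1: float = 0.6
    n_sources: int = 4
    noise_sd: float = 0.1
    dropout: float = 0.5
    identity_noise_sd: float = 0.1
    identity_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("annotation_rate", "q0", "q1", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0,1]")
        if self.q0 + self.q1 > 1.0:
            raise ValueError("q0 + q1 must not exceed 1")


@dataclass
class SimTruth:
    """Everything the generator knows: inputs plus the planted ground truth."""

    config: SimConfig
    ontology: Ontology
    annotations: AnnotationTable
    network: nx.Graph
    sources: list[SourceScoreTable] = field(default_factory=list)
    identity: dict[tuple[str, str], float] = field(default_factory=dict)


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def gen_ontology(n_terms: int, branching: int = 2, seed: int = 0) -> Ontology:
    """Single-root random DAG: term i draws 1 to ``branching`` parents
    uniformly among earlier terms, so the graph is acyclic by construction."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = _rng(seed, "ontology")
    parents: dict[str, frozenset[str]] = {_term_id(0): frozenset()}
    for i in range(1, n_terms):
        n_par = 1 + int(rng.random() < 0.25) if branching > 1 else 1
        pool = rng.choice(i, size=min(n_par, i), replace=False)
        parents[_term_id(i)] = frozenset(_term_id(int(j)) for j in pool)
    namespace = {t: "BP" for t in parents}
    return Ontology(parents=parents, namespace=namespace)


def gen_annotations(
    n_proteins: int,
    onto: Ontology,
    annotation_rate: float = 0.5,
    seed: int = 0,
) -> AnnotationTable:
    """Sample 1-3 leaf terms per protein with depth-weighted probabilities.

    A leaf at depth D is drawn with weight 2^(-D/2) times a per-leaf
    popularity factor, so shallower (more general) terms end up more
    frequent than deep ones after propagation — the skew real GO corpora
    show. ``annotation_rate`` sets how often a protein carries more than
    one direct term.
    """
    rng = _rng(seed, "annotations")
    children = onto.children_map()
    leaves = sorted(t for t, ch in children.items() if not ch)
    depth = {t: onto.depth(t) for t in leaves}
    pop = rng.gamma(shape=1.0, scale=1.0, size=len(leaves))
    w = np.array([2.0 ** (-depth[t] / 2.0) for t in leaves]) * pop
    w /= w.sum()
    raw: dict[str, set[str]] = {}
    for i in range(n_proteins):
        n_direct = 1 + int(rng.binomial(2, annotation_rate))
        picks = rng.choice(len(leaves), size=min(n_direct, len(leaves)),
                           replace=False, p=w)
        raw[f"P{i:04d}"] = {leaves[int(j)] for j in picks}
    closed = {
        p: frozenset().union(*(onto.ancestors(t) for t in ts))
        for p, ts in raw.items()
    }
    return AnnotationTable({p: frozenset(ts) for p, ts in closed.items()})


def _jaccard_matrix(
    annots: AnnotationTable, proteins: Sequence[str], roots: frozenset[str]
) -> np.ndarray:
    terms = sorted(annots.terms - roots)
    tidx = {t: j for j, t in enumerate(terms)}
    M = np.zeros((len(proteins), len(terms)), dtype=bool)
    for i, p in enumerate(proteins):
        for t in annots.annotations[p]:
            j = tidx.get(t)
            if j is not None:
                M[i, j] = True
    inter = (M.astype(float) @ M.T.astype(float))
    sizes = M.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
    return J


def gen_network(
    annots: AnnotationTable,
    onto: Ontology,
    q0: float = 0.01,
    q1: float = 0.6,
    seed: int = 0,
) -> nx.Graph:
    """Plant edges with probability ``q0 + q1 * Jaccard(non-root term sets)``."""
    if q0 + q1 > 1.0:
        raise ValueError("q0 + q1 must not exceed 1")
    rng = _rng(seed, "network")
    proteins = sorted(annots.proteins)
    J = _jaccard_matrix(annots, proteins, onto.roots)
    g = nx.Graph()
    g.add_nodes_from(proteins)
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)
    probs = q0 + q1 * J[iu, ju]
    draws = rng.random(len(iu)) < probs
    for a, b in zip(iu[draws], ju[draws]):
        g.add_edge(proteins[int(a)], proteins[int(b)], weight=1.0)
    return g


def gen_source_scores(
    truth_network: nx.Graph,
    n_sources: int = 4,
    noise_sd: float = 0.1,
    dropout: float = 0.5,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[SourceScoreTable]:
    """Noisy evidence channels: clip01(0.8·edge + N(0, sd)) with dropout.

    Each source observes every protein pair independently; scores that clip
    to zero (or drop out) are absent, matching the sparse-score convention.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rng = _rng(seed, "sources")
    if names is None:
        usable = [c for c in STRING_CHANNELS if c not in ("database", "database_transferred")]
        names = [usable[i % len(usable)] + ("" if i < len(usable) else f"_{i}")
                 for i in range(n_sources)]
    proteins = sorted(truth_network.nodes)
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)
    edge = np.array(
        [truth_network.has_edge(proteins[int(a)], proteins[int(b)])
         for a, b in zip(iu, ju)],
        dtype=float,
    )
    tables = []
    for s in range(n_sources):
        raw = np.clip(0.8 * edge + rng.normal(0.0, noise_sd, size=len(edge)), 0, 1)
        keep = (rng.random(len(edge)) >= dropout) & (raw > 0)
        scores = {
            _pair(proteins[int(a)], proteins[int(b)]): float(v)
            for a, b, v in zip(iu[keep], ju[keep], raw[keep])
        }
        tables.append(SourceScoreTable(names[s], scores))
    return tables


def gen_identity(
    annots: AnnotationTable,
    onto: Ontology,
    noise_sd: float = 0.1,
    fraction: float = 0.3,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Sequence-identity surrogate: clip01(0.3 + 0.5·J + noise) on a random
    subset of pairs (absent pairs mean "no BLAST hit")."""
    rng = _rng(seed, "identity")
    proteins = sorted(annots.proteins)
    J = _jaccard_matrix(annots, proteins, onto.roots)
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < fraction
    vals = np.clip(
        0.3 + 0.5 * J[iu[keep], ju[keep]] + rng.normal(0, noise_sd, int(keep.sum())),
        0.0,
        1.0,
    )
    return {
        _pair(proteins[int(a)], proteins[int(b)]): float(v)
        for a, b, v in zip(iu[keep], ju[keep], vals)
    }


def simulate(config: SimConfig) -> SimTruth:
    """Generate the full coupled dataset from one root seed."""
    onto = gen_ontology(config.n_terms, config.branching, config.seed)
    annots = gen_annotations(
        config.n_proteins, onto, config.annotation_rate, config.seed
    )
    net = gen_network(annots, onto, config.q0, config.q1, config.seed)
    sources = gen_source_scores(
        net, config.n_sources, config.noise_sd, config.dropout, config.seed
    )
    identity = gen_identity(
        annots, onto, config.identity_noise_sd, config.identity_fraction,
        config.seed,
    )
    return SimTruth(
        config=config,
        ontology=onto,
        annotations=annots,
        network=net,
        sources=sources,
        identity=identity,
    )


def write_obo(onto: Ontology, path) -> None:
    """Write a minimal OBO 1.2 file readable by the package's own parser."""
    ns_long = {"BP": "biological_process", "MF": "molecular_function",
               "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(onto.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            fh.write(f"namespace: {ns_long.get(onto.namespace[t], onto.namespace[t])}\n")
            for p in sorted(onto.parents[t]):
                fh.write(f"is_a: {p} ! {p}\n")


def write_gaf(
    annots: AnnotationTable, path, evidence: str = "IDA", direct_only: bool = False
) -> None:
    """Write propagated (or direct) annotations as a GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for p in sorted(annots.annotations):
            for t in sorted(annots.annotations[p]):
                cols = [
                    "SIM", p, p, "involved_in", t, "SIM:0000001", evidence, "",
                    "P", p, "", "protein", "taxon:0", "20200101", "SIM", "", "",
                ]
                fh.write("\t".join(cols) + "\n")
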