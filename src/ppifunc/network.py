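"""Building, integrating, restricting and downsampling PPI networks.

Networks are undirected :class:`networkx.Graph` objects whose edges carry a
``weight`` attribute in [0, 1] (binary graphs have every weight equal to 1).
Per-source association scores (STRING-style evidence channels) live in
:class:`SourceScoreTable` objects and are thresholded or probabilistically
integrated into networks.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SourceScoreTable",
    "STRING_CHANNELS",
    "DEFAULT_EXCLUDED_CHANNELS",
    "read_experimental_edges",
    "read_string_scores",
    "read_score_table",
    "write_edges",
    "threshold_median",
    "threshold_top_half",
    "threshold_fixed",
    "integrate_sources",
    "union_binary",
    "add_weighted",
    "restrict_to_annotated",
    "downsample_uniform",
    "downsample_degree_biased",
    "enumerate_source_combinations",
    "prune_redundant_sources",
]

#: STRING evidence channels, in the database's column naming.
STRING_CHANNELS = (
    "neighborhood",
    "neighborhood_transferred",
    "cooccurence",
    "database",
    "database_transferred",
    "experiments_transferred",
    "fusion",
    "homology",
    "coexpression",
    "coexpression_transferred",
    "textmining",
    "textmining_transferred",
)

#: "database" channels are derived partly from GO annotations themselves and
#: would leak label information into the network; excluded by default.
DEFAULT_EXCLUDED_CHANNELS = frozenset({"database", "database_transferred"})


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class SourceScoreTable:
    """Sparse symmetric pairwise scores for one named evidence channel.

    Scores are probabilities in (0, 1]; zero scores are simply absent.
    """

    source: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for (a, b), s in self.scores.items():
            if a == b:
                continue
            if not 0.0 < s <= 1.0:
                raise ValueError(
                    f"score for ({a},{b}) is {s}, must be in (0,1]"
                )
            clean[_pair(a, b)] = s
        self.scores = clean

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.scores.get(_pair(a, b), default)

    def restrict(self, proteins: Iterable[str]) -> "SourceScoreTable":
        keep = set(proteins)
        return SourceScoreTable(
            self.source,
            {p: s for p, s in self.scores.items() if p[0] in keep and p[1] in keep},
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"protein_a\tprotein_b\t{self.source}\n")
            for (a, b), s in sorted(self.scores.items()):
                fh.write(f"{a}\t{b}\t{s:.6g}\n")


def _empty_binary(nodes: Iterable[str] = ()) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    return g


def _binary_from_pairs(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    g = nx.Graph()
    for a, b in pairs:
        if a != b:
            g.add_edge(a, b, weight=1.0)
    return g


def is_binary(g: nx.Graph) -> bool:
    return all(d.get("weight", 1.0) == 1.0 for _, _, d in g.edges(data=True))


def read_experimental_edges(
    path,
    physical_only: bool = True,
    col_a: str = "Official Symbol Interactor A",
    col_b: str = "Official Symbol Interactor B",
    col_type: str = "Experimental System Type",
) -> nx.Graph:
    """Read a BIOGRID TAB-style TSV into a binary interaction graph.

    Rows whose experimental system type is ``genetic`` are dropped when
    ``physical_only`` (the default, matching the physical-interaction-only
    network construction). Self-interactions are dropped; duplicate pairs in
    either order collapse to a single undirected edge.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in (col_a, col_b, col_type) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if physical_only:
        df = df[df[col_type].str.lower() != "genetic"]
    return _binary_from_pairs(zip(df[col_a], df[col_b]))


def read_string_scores(
    path,
    exclude: frozenset[str] = DEFAULT_EXCLUDED_CHANNELS,
) -> list[SourceScoreTable]:
    """Read a STRING protein.links.detailed-style table.

    One column per evidence channel, raw scores on the 0-1000 scale (divided
    by 1000 on read); zero entries are dropped. Channels in ``exclude`` are
    skipped.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=None)
    id_cols = list(df.columns[:2])
    tables = []
    for col in df.columns[2:]:
        if col in exclude:
            continue
        sub = df[df[col] > 0]
        scores = {
            _pair(str(a), str(b)): min(1.0, float(s) / 1000.0)
            for a, b, s in zip(sub[id_cols[0]], sub[id_cols[1]], sub[col])
            if a != b
        }
        tables.append(SourceScoreTable(col, scores))
    return tables


def read_score_table(path, source: str | None = None) -> SourceScoreTable:
    """Read a generic 3-column ``a<TAB>b<TAB>score`` table (scores in [0,1])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    name = source or str(df.columns[2])
    scores = {
        _pair(str(a), str(b)): float(s)
        for a, b, s in df.itertuples(index=False)
        if a != b and s > 0
    }
    return SourceScoreTable(name, scores)


def write_edges(g: nx.Graph, path) -> None:
    """Write a graph as protein_a<TAB>protein_b<TAB>weight TSV."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tweight\n")
        for a, b in sorted(_pair(a, b) for a, b in g.edges()):
            w = g[a][b].get("weight", 1.0)
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def read_edges(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", comment="#")
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        if a != b:
            g.add_edge(str(a), str(b), weight=float(w))
    return g


def threshold_median(scores: SourceScoreTable) -> nx.Graph:
    """Binary graph of pairs scoring strictly above the non-zero median."""
    if not scores.scores:
        warnings.warn(f"{scores.source}: empty score table, empty graph")
        return _empty_binary()
    med = float(np.median(list(scores.scores.values())))
    return _binary_from_pairs(p for p, s in scores.scores.items() if s > med)


def threshold_top_half(scores: SourceScoreTable) -> nx.Graph:
    """Binary graph of the ceil(n/2) highest-scoring pairs (cutoff ties kept)."""
    if not scores.scores:
        return _empty_binary()
    vals = sorted(scores.scores.values(), reverse=True)
    cutoff = vals[math.ceil(len(vals) / 2) - 1]
    return _binary_from_pairs(p for p, s in scores.scores.items() if s >= cutoff)


def threshold_fixed(scores: SourceScoreTable, cut: float) -> nx.Graph:
    """Binary graph of pairs with score >= ``cut`` (boundary inclusive)."""
    return _binary_from_pairs(p for p, s in scores.scores.items() if s >= cut)


def integrate_sources(
    tables: Sequence[SourceScoreTable],
    prior: float = 0.041,
    name: str = "combined",
) -> SourceScoreTable:
    """STRING-style probabilistic integration of several evidence channels.

    Each score is first corrected for the random-interaction prior,
    ``s' = max(0, (s - prior) / (1 - prior))``, the corrected scores are
    combined as one minus the product of their complements, and the prior is
    added back: ``combined = (1 - prod(1 - s_i')) * (1 - prior) + prior``.
    Pairs present in at least one table get a score; others are absent.
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior must be in [0,1), got {prior}")
    pairs: set[tuple[str, str]] = set()
    for t in tables:
        pairs.update(t.scores)
    out: dict[tuple[str, str], float] = {}
    for p in pairs:
        prod = 1.0
        for t in tables:
            s = t.scores.get(p, 0.0)
            s_corr = max(0.0, (s - prior) / (1.0 - prior))
            prod *= 1.0 - s_corr
        out[p] = (1.0 - prod) * (1.0 - prior) + prior
    return SourceScoreTable(name, out)


def union_binary(g1: nx.Graph, g2: nx.Graph) -> nx.Graph:
    """Element-wise logical OR of two binary adjacency structures."""
    if not (is_binary(g1) and is_binary(g2)):
        raise TypeError("union_binary requires binary graphs; use add_weighted")
    g = _empty_binary(itertools.chain(g1.nodes, g2.nodes))
    for a, b in itertools.chain(g1.edges, g2.edges):
        g.add_edge(a, b, weight=1.0)
    return g


def add_weighted(exp: nx.Graph, pred: SourceScoreTable) -> nx.Graph:
    """Weighted graph: experimental edges weigh 1, predicted pairs their score.

    A pair present in both keeps the maximum (i.e. 1).
    """
    g = nx.Graph()
    g.add_nodes_from(exp.nodes)
    for a, b in exp.edges:
        g.add_edge(a, b, weight=1.0)
    for (a, b), s in pred.scores.items():
        if not g.has_edge(a, b):
            g.add_edge(a, b, weight=s)
    return g


def restrict_to_annotated(
    g: nx.Graph, annotated: Iterable[str], keep_unannotated: bool = False
) -> nx.Graph:
    """Restrict the node set to annotated proteins.

    Annotated proteins with no surviving interaction are kept as degree-0
    nodes, so they still count against coverage. With ``keep_unannotated``
    the graph is returned with its full node set (used when learning
    embeddings on the whole interactome).
    """
    if keep_unannotated:
        return g.copy()
    keep = set(annotated)
    h = nx.Graph()
    h.add_nodes_from(keep)
    for a, b, d in g.edges(data=True):
        if a in keep and b in keep:
            h.add_edge(a, b, **d)
    return h


def _n_remove(f: float, n_edges: int) -> int:
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"remove fraction must be in [0,1], got {f}")
    # round half away from zero
    return int(math.floor(f * n_edges + 0.5))


def downsample_uniform(g: nx.Graph, remove_fraction: float, seed: int) -> nx.Graph:
    """Remove ``round(f*|E|)`` edges uniformly at random (nodes retained)."""
    edges = sorted((_pair(a, b) for a, b in g.edges()))
    k = _n_remove(remove_fraction, len(edges))
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(len(edges), size=k, replace=False)) if k else set()
    h = g.copy()
    h.remove_edges_from(e for i, e in enumerate(edges) if i in drop)
    return h


def downsample_degree_biased(
    g: nx.Graph, remove_fraction: float, seed: int
) -> nx.Graph:
    """Remove edges preferentially around low-degree nodes.

    Edges are removed one at a time; at each draw an edge (u, v) is sampled
    with probability proportional to 1/min(deg(u), deg(v)) using the degrees
    of the *current* (partially stripped) graph. This mimics study bias:
    poorly-characterised proteins lose their few interactions first.
    """
    edges = sorted((_pair(a, b) for a, b in g.edges()))
    k = _n_remove(remove_fraction, len(edges))
    rng = np.random.default_rng(seed)
    h = g.copy()
    remaining = list(edges)
    for _ in range(k):
        deg = dict(h.degree())
        w = np.array([1.0 / min(deg[a], deg[b]) for a, b in remaining])
        idx = rng.choice(len(remaining), p=w / w.sum())
        a, b = remaining.pop(int(idx))
        h.remove_edge(a, b)
    return h


def enumerate_source_combinations(sources: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    if not sources:
        raise ValueError("at least one source is required")
    names = sorted(sources)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, size))
    return out


def prune_redundant_sources(
    tables: Sequence[SourceScoreTable], experimental: nx.Graph
) -> list[SourceScoreTable]:
    """Drop channels whose thresholded edges are all already experimental."""
    exp_edges = {_pair(a, b) for a, b in experimental.edges()}
    kept = []
    for t in tables:
        edges = {_pair(a, b) for a, b in threshold_top_half(t).edges()}
        if edges - exp_edges:
            kept.append(t)
    return kept
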