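"""Gene Ontology parsing, annotation filtering, ancestor propagation and IC.

The prediction pipeline works on *propagated* annotation sets: whenever a
protein is annotated with a GO term it is also annotated with every ancestor
of that term, so annotation sets are closed under the is_a hierarchy. All
downstream classifiers and the Smin metric rely on that closure.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import obonet
from Bio.UniProt import GOA

__all__ = [
    "Ontology",
    "AnnotationTable",
    "GafRecord",
    "EXPERIMENTAL_EVIDENCE_CODES",
    "parse_obo",
    "read_gaf",
    "filter_evidence",
    "propagate",
    "information_content",
]

#: Experimental + curated evidence codes retained by default (IEA and other
#: automatic assignments are excluded to avoid circularity with sequence data).
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "IBA", "IBD", "IKR", "IRD", "TAS"}
)

_NAMESPACE_MAP = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


class OboFormatError(ValueError):
    """Raised when the OBO file cannot be parsed or validates badly."""


@dataclass(frozen=True)
class Ontology:
    """A rooted DAG of GO terms connected by is_a edges.

    ``parents`` maps every term to its (possibly empty) set of direct is_a
    parents. Terms with no parents are roots; one root per namespace in a
    standard GO release.
    """

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def root_of(self, namespace: str) -> str:
        roots = [t for t in self.roots if self.namespace.get(t) == namespace]
        if len(roots) != 1:
            raise ValueError(
                f"expected exactly one {namespace} root, found {sorted(roots)}"
            )
        return roots[0]

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        if term not in self.parents:
            raise KeyError(term)
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parents[t])
        return frozenset(seen)

    def children_map(self) -> dict[str, set[str]]:
        ch: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                ch[p].add(t)
        return ch

    def depth(self, term: str) -> int:
        """Shortest is_a distance to a root (roots have depth 0)."""
        d, frontier = 0, {term}
        while frontier:
            if any(not self.parents[t] for t in frontier):
                return d
            frontier = {p for t in frontier for p in self.parents[t]}
            d += 1
        raise ValueError(f"{term} does not reach a root")  # pragma: no cover

    def validate(self) -> None:
        g = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        g.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OboFormatError(f"cyclic is_a relationship: {cycle}")
        roots = self.roots
        for t in self.parents:
            if not (self.ancestors(t) & roots):
                raise OboFormatError(f"term {t} does not reach a root")


class GafRecord(NamedTuple):
    """One line of a GAF 2.x annotation file (the fields we use)."""

    protein: str
    term: str
    evidence: str
    qualifiers: tuple[str, ...] = ()

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifiers


@dataclass
class AnnotationTable:
    """Protein -> propagated GO-term sets, with term counts and optional IC.

    Invariants: each term set is closed under ancestry; ``term_count[t]``
    equals the number of proteins carrying ``t``.
    """

    annotations: dict[str, frozenset[str]]
    term_count: Counter = field(default_factory=Counter)
    ic: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.term_count:
            self.term_count = Counter(
                t for terms in self.annotations.values() for t in terms
            )

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.annotations)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.term_count)

    def __contains__(self, protein: str) -> bool:
        return protein in self.annotations

    def __getitem__(self, protein: str) -> frozenset[str]:
        return self.annotations[protein]

    def subset(self, proteins: Iterable[str]) -> "AnnotationTable":
        """Restrict to ``proteins`` (recomputes term counts; drops IC)."""
        keep = {p: ts for p, ts in self.annotations.items() if p in set(proteins)}
        return AnnotationTable(keep)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for p in sorted(self.annotations):
                for t in sorted(self.annotations[p]):
                    fh.write(f"{p}\t{t}\n")


def parse_obo(path) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Obsolete terms are dropped and only is_a edges are retained. Raises
    :class:`OboFormatError` on malformed stanzas or cyclic is_a relations.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise OboFormatError(f"cannot parse OBO file {path}: {exc}") from exc
    parents: dict[str, frozenset[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        # obonet stores `child is_a parent` as an edge child->parent keyed "is_a"
        ps = frozenset(
            parent
            for _, parent, key in graph.out_edges(term, keys=True)
            if key == "is_a" and parent in graph
        )
        parents[term] = ps
        ns = data.get("namespace", "biological_process")
        namespace[term] = _NAMESPACE_MAP.get(ns, ns)
    onto = Ontology(parents=parents, namespace=namespace)
    onto.validate()
    return onto


def read_gaf(path) -> list[GafRecord]:
    """Read a GAF 2.x file (comment lines start with ``!``)."""
    records: list[GafRecord] = []
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            records.append(
                GafRecord(
                    protein=rec["DB_Object_ID"],
                    term=rec["GO_ID"],
                    evidence=rec["Evidence"],
                    qualifiers=tuple(q for q in rec.get("Qualifier", []) if q),
                )
            )
    return records


def filter_evidence(
    records: Iterable[GafRecord],
    allowed: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES,
    drop_negated: bool = True,
) -> list[GafRecord]:
    """Keep records whose evidence code is in ``allowed``, preserving order.

    NOT-qualified (negative) annotations are dropped by default.
    """
    return [
        r
        for r in records
        if r.evidence in allowed and not (drop_negated and r.negated)
    ]


def records_to_raw(records: Iterable[GafRecord]) -> dict[str, set[str]]:
    """Collapse GAF records into a protein -> direct-term-set mapping."""
    raw: dict[str, set[str]] = {}
    for r in records:
        raw.setdefault(r.protein, set()).add(r.term)
    return raw


def propagate(
    raw: Mapping[str, Iterable[str]],
    onto: Ontology,
    namespace: str | None = "BP",
) -> AnnotationTable:
    """Propagate direct annotations to all is_a ancestors.

    Terms are restricted to ``namespace`` (``None`` keeps all namespaces);
    proteins whose closed set is empty after restriction are dropped.
    Raises ``ValueError`` listing any term IDs absent from the ontology.
    """
    unknown = sorted(
        {t for ts in raw.values() for t in ts if t not in onto.parents}
    )
    if unknown:
        raise ValueError(f"unknown term IDs: {unknown}")
    closed: dict[str, frozenset[str]] = {}
    cache: dict[str, frozenset[str]] = {}
    for protein, terms in raw.items():
        acc: set[str] = set()
        for t in terms:
            if t not in cache:
                anc = onto.ancestors(t)
                if namespace is not None:
                    anc = frozenset(
                        a for a in anc if onto.namespace.get(a) == namespace
                    )
                cache[t] = anc
            acc |= cache[t]
        if acc:
            closed[protein] = frozenset(acc)
    return AnnotationTable(closed)


def information_content(
    annots: AnnotationTable, onto: Ontology, namespace: str = "BP"
) -> dict[str, float]:
    """Per-term information content in bits.

    ``ic[t] = -log2(term_count[t] / term_count[root])`` where the denominator
    is the number of proteins annotated with the namespace root (after
    propagation, every annotated protein). The root has 0 bits; rarer terms
    carry more bits; IC is anti-monotone along is_a edges.
    """
    root = onto.root_of(namespace)
    n_root = annots.term_count.get(root, 0)
    if n_root == 0:
        raise ValueError(f"no protein is annotated with the {namespace} root")
    ic: dict[str, float] = {}
    for t, c in annots.term_count.items():
        if c <= 0:
            continue
        ic[t] = max(0.0, -math.log2(c / n_root))
    ic[root] = 0.0
    return ic
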