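import pytest

from ppifunc.ontology import AnnotationTable, Ontology


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000002 ! b
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: a
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001 ! a

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000001 ! a

[Term]
id: GO:0000004
name: d
namespace: biological_process
is_a: GO:0000002 ! b
is_a: GO:0000003 ! c
"""


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


@pytest.fixture
def diamond_obo(tmp_path):
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return path


@pytest.fixture
def chain_ontology():
    return Ontology(
        parents={
            "GO:0000001": frozenset(),
            "GO:0000002": frozenset({"GO:0000001"}),
            "GO:0000003": frozenset({"GO:0000002"}),
        },
        namespace={t: "BP" for t in ("GO:0000001", "GO:0000002", "GO:0000003")},
    )


@pytest.fixture
def diamond_ontology():
    return Ontology(
        parents={
            "GO:0000001": frozenset(),
            "GO:0000002": frozenset({"GO:0000001"}),
            "GO:0000003": frozenset({"GO:0000001"}),
            "GO:0000004": frozenset({"GO:0000002", "GO:0000003"}),
        },
        namespace={t: "BP" for t in
                   ("GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004")},
    )


def make_annotations(mapping):
    """Shorthand: dict of protein -> iterable of terms (already closed)."""
    return AnnotationTable({p: frozenset(ts) for p, ts in mapping.items()})
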