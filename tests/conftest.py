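import numpy as np
import pytest

from funcdiv.ontology import parse_obo
from funcdiv.simulate import simulate_study

# minimal organelle DAG for the shared-function worked example:
# gene1 annotated to "organelle envelope", gene2 to "intracellular
# membrane-bound organelle"; their most specific shared functions are
# "membrane-bound organelle" and "intracellular organelle".
ORGANELLE_OBO = """\
format-version: 1.2
ontology: test

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0043226
name: organelle
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0043227
name: membrane-bound organelle
namespace: cellular_component
is_a: GO:0043226

[Term]
id: GO:0043229
name: intracellular organelle
namespace: cellular_component
is_a: GO:0043226

[Term]
id: GO:0043231
name: intracellular membrane-bound organelle
namespace: cellular_component
is_a: GO:0043227
is_a: GO:0043229

[Term]
id: GO:0031967
name: organelle envelope
namespace: cellular_component
relationship: part_of GO:0043227
relationship: part_of GO:0043229
"""


@pytest.fixture(scope="session")
def organelle_graph():
    return parse_obo(ORGANELLE_OBO)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(seed=7)


def random_dag(rng: np.random.Generator, n_terms: int = 12, namespace: str = "biological_process"):
    """Small random rooted DAG (layered attachment) for oracle-based tests."""
    from funcdiv.ontology import OntologyGraph, OntologyTerm

    terms = {}
    parents = {}
    ids = [f"GO:{i:07d}" for i in range(n_terms)]
    for i, tid in enumerate(ids):
        terms[tid] = OntologyTerm(id=tid, name=f"t{i}", namespace=namespace)
        if i == 0:
            parents[tid] = ()
        else:
            k = 1 + (rng.random() < 0.3)
            choices = rng.choice(i, size=min(k, i), replace=False)
            parents[tid] = tuple(
                (ids[c], "is_a" if rng.random() < 0.8 else "part_of") for c in choices
            )
    return OntologyGraph(terms=terms, parents=parents)


def random_corpus(rng: np.random.Generator, graph, n_genes: int = 20):
    """Random annotation set over a toy DAG."""
    from funcdiv.annotations import AnnotationRecord, AnnotationSet

    term_ids = sorted(graph.terms)
    records = []
    for g in range(n_genes):
        for t in rng.choice(term_ids, size=rng.integers(1, 4), replace=False):
            records.append(
                AnnotationRecord(
                    gene=f"g{g}", term=str(t), evidence="IDA",
                    namespace=graph.terms[str(t)].namespace,
                )
            )
    return AnnotationSet(records=tuple(records))
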