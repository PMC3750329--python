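import numpy as np
import pytest

from genoanat import (
    AnnotationVolume,
    ExpressionVolumeSet,
    OntologyTerm,
    OntologyTree,
    SyntheticSpec,
    generate_atlas,
)


def make_chain_tree(depth: int) -> OntologyTree:
    """Root -> single child -> ... down to `depth`."""
    terms = [OntologyTerm(id=1, acronym="root", name="root", level=0, parent_id=None)]
    for lvl in range(1, depth + 1):
        terms.append(OntologyTerm(id=lvl + 1, acronym=f"c{lvl}", name=f"chain {lvl}",
                                  level=lvl, parent_id=lvl))
    return OntologyTree(terms)


def make_random_tree(rng: np.random.Generator, n_terms: int = 60,
                     max_children: int = 4) -> OntologyTree:
    """Random tree grown by attaching each new term to a random existing one."""
    terms = [OntologyTerm(id=1, acronym="root", name="root", level=0, parent_id=None)]
    levels = {1: 0}
    for tid in range(2, n_terms + 2):
        parent = int(rng.choice(list(levels)))
        lvl = levels[parent] + 1
        levels[tid] = lvl
        terms.append(OntologyTerm(id=tid, acronym=f"t{tid}", name=f"term {tid}",
                                  level=lvl, parent_id=parent))
    return OntologyTree(terms)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_atlas():
    """A small but fully structured synthetic atlas shared across tests."""
    return generate_atlas(SyntheticSpec(dims=(14, 12, 8), n_genes=60, seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_atlas):
    return small_atlas.build_dataset()


@pytest.fixture
def tiny_tree():
    """Root + two level-1 branches; one branch continues to level 6."""
    terms = [
        OntologyTerm(id=1, acronym="root", name="root", level=0, parent_id=None),
        OntologyTerm(id=2, acronym="brain", name="brain", level=1, parent_id=1),
        OntologyTerm(id=3, acronym="sp", name="spinal cord", level=1, parent_id=1),
        OntologyTerm(id=4, acronym="b2", name="brain l2", level=2, parent_id=2),
        OntologyTerm(id=5, acronym="b3", name="brain l3", level=3, parent_id=4),
        OntologyTerm(id=6, acronym="b4", name="brain l4", level=4, parent_id=5),
        OntologyTerm(id=7, acronym="b5", name="brain l5", level=5, parent_id=6),
        OntologyTerm(id=8, acronym="b6", name="brain l6", level=6, parent_id=7),
        OntologyTerm(id=9, acronym="sp2", name="sp l2", level=2, parent_id=3),
        OntologyTerm(id=10, acronym="sp3", name="sp l3", level=3, parent_id=9),
        OntologyTerm(id=11, acronym="sp4", name="sp l4", level=4, parent_id=10),
        OntologyTerm(id=12, acronym="sp5", name="sp l5", level=5, parent_id=11),
    ]
    return OntologyTree(terms)


def blobs(rng, n_per, centers, sd=1.0):
    """Isotropic Gaussian blobs; returns (X, labels)."""
    centers = np.asarray(centers, dtype=float)
    X = np.concatenate([
        c + sd * rng.standard_normal((n_per, centers.shape[1])) for c in centers
    ])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y
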