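import pytest

from motifquad import FixtureSpec, Graph, generate


@pytest.fixture
def directed_path5() -> Graph:
    return generate(FixtureSpec(kind="path", n=5, directed=True))


@pytest.fixture
def undirected_k4() -> Graph:
    return generate(FixtureSpec(kind="complete", n=4, directed=False))


@pytest.fixture
def star5_undirected() -> Graph:
    """Star with 4 leaves (5 vertices), centre is vertex 0."""
    return generate(FixtureSpec(kind="star", n=5, directed=False))


def er_graph(n: int, p: float, directed: bool, seed: int) -> Graph:
    kind = "er_directed" if directed else "er_undirected"
    return generate(FixtureSpec(kind=kind, n=n, p=p, seed=seed))
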