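import networkx as nx
import pytest

from citefronts import PublicationRecord


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint triangles: the canonical separable community fixture."""
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    )


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(4)


@pytest.fixture
def path3() -> nx.Graph:
    return nx.path_graph(3)


@pytest.fixture
def single_edge() -> nx.Graph:
    return nx.Graph([("u", "v")])


@pytest.fixture
def small_corpus() -> list[PublicationRecord]:
    """Six papers, two citation-linked groups plus one isolate."""
    return [
        PublicationRecord("p1", 2010, "T lymphocyte responses in tumor immunity",
                          "Checkpoint blockade rejuvenates exhausted T cells.", []),
        PublicationRecord("p2", 2012, "Immune checkpoint inhibitors in melanoma",
                          "PD-1 blockade extends survival.", ["p1"]),
        PublicationRecord("p3", 2015, "CAR T cell therapy for leukemia",
                          "Engineered immune receptors redirect T lymphocytes.", ["p1", "p2"]),
        PublicationRecord("p4", 2008, "Gut microbiota and mucosal immunity",
                          "Commensal bacteria shape intestinal T cells.", []),
        PublicationRecord("p5", 2011, "Probiotics in inflammatory bowel disease",
                          "Intestinal microbiota modulate colitis.", ["p4"]),
        PublicationRecord("p6", 1999, "Innate immunity of macrophages",
                          "Phagocytes respond to pathogens.", []),
    ]
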