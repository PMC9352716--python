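import pytest

from disorient.dnt import StreetGraph


@pytest.fixture()
def toy_graph():
    """Six-node street graph with an original route H-A-L and detour L-D-H.

    A and D are intersections (degree 3+); S and T are dead-end branches so a
    wrong turn has somewhere to go. Edge D-A allows a detour walk to cut back
    onto the original route.
    """
    g = StreetGraph()
    coords = {"H": (0, 0), "A": (1, 0), "L": (2, 0),
              "D": (1.2, 1), "S": (1.2, 2), "T": (1, -1)}
    for n, (x, y) in coords.items():
        g.add_node(n, x, y)
    g.add_edge("H", "A", 0.5)
    g.add_edge("A", "L", 0.5)
    g.add_edge("L", "D", 0.5)
    g.add_edge("D", "H", 0.7)
    g.add_edge("D", "S", 0.2)
    g.add_edge("A", "T", 0.2)
    g.add_edge("D", "A", 0.5)
    g.validate()
    return g


ORIGINAL_ROUTE = ["H", "A", "L"]
DETOUR_ROUTE = ["L", "D", "H"]


@pytest.fixture()
def toy_routes():
    return list(ORIGINAL_ROUTE), list(DETOUR_ROUTE)
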