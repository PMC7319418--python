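import numpy as np
import pytest

from damcap.synthetic import CatchmentScenario, generate_terrain


@pytest.fixture(scope="session")
def small_scenario():
    return CatchmentScenario(grid_shape=(64, 64), seed=1)


@pytest.fixture(scope="session")
def small_terrain(small_scenario):
    return generate_terrain(small_scenario)


@pytest.fixture(scope="session")
def small_flow_grid(small_terrain):
    from damcap.terrain import build_flow_grid

    return build_flow_grid(small_terrain.dtm, list(small_terrain.network["geometry"]))


def graph_strahler_orders(lines, outlet):
    """Independent graph-based Strahler oracle on the vector network.

    Treats the network as a tree rooted at the outlet and applies the
    Strahler combination rule recursively; returns one order per line.
    """
    import networkx as nx

    g = nx.Graph()
    for i, line in enumerate(lines):
        a = tuple(np.round(line.coords[0], 6))
        b = tuple(np.round(line.coords[-1], 6))
        g.add_edge(a, b, idx=i)
    order = {}

    def visit(node, parent):
        child_orders = []
        for nbr in g.neighbors(node):
            if nbr == parent:
                continue
            o = visit(nbr, node)
            order[g[node][nbr]["idx"]] = o
            child_orders.append(o)
        if not child_orders:
            return 1
        m = max(child_orders)
        return m + 1 if child_orders.count(m) >= 2 else m

    visit(tuple(np.round(outlet, 6)), None)
    return np.array([order[i] for i in range(len(lines))])
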