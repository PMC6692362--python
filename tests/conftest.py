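import networkx as nx
import numpy as np
import pytest

from vasculotopo.synthetic_data import GroundTruthGraph, PhantomSpec


def tube_truth(polylines_radii, domain_um, spacing_um=(5.0, 3.25, 3.25)):
    """Ground-truth graph from explicit (polyline, radius) tubes."""
    spec = PhantomSpec(
        mode="custom", domain_size_um=tuple(domain_um), voxel_spacing_um=spacing_um, seed=0
    )
    g = nx.MultiGraph()
    for i, (pts, r) in enumerate(polylines_radii):
        pts = np.asarray(pts, float)
        g.add_node(2 * i, pos_um=pts[0])
        g.add_node(2 * i + 1, pos_um=pts[-1])
        g.add_edge(2 * i, 2 * i + 1, polyline=pts, radius_um=float(r))
    return GroundTruthGraph(g, spec)


@pytest.fixture(scope="session")
def straight_tube():
    """Axis-aligned cylinder: radius 8 um, length 340 um."""
    from vasculotopo.synthetic_data import voxelize

    truth = tube_truth([([[50.0, 100.0, 30.0], [50.0, 100.0, 370.0]], 8.0)], (100, 200, 400))
    return truth, voxelize(truth)


@pytest.fixture(scope="session")
def clearance_tree():
    """Binary-tree phantom satisfying the round-trip preconditions: tube
    radius >= 1.5 voxels and generous inter-segment clearance."""
    from vasculotopo.synthetic_data import clearance_tree_phantom, voxelize

    truth = clearance_tree_phantom(seed=7)
    return truth, voxelize(truth)


@pytest.fixture(scope="session")
def bridge_graph():
    """Two 5-cliques joined by a single edge."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    return g


@pytest.fixture(scope="session")
def healthy_mini():
    """Small healthy-like phantom run through voxelization and extraction."""
    import vasculotopo as vt

    truth = vt.generate_network(vt.healthy_like(seed=11, domain_size_um=(300.0, 300.0, 300.0)))
    vol = vt.voxelize(truth)
    skel, graph = vt.extract_graph(vol)
    return truth, vol, skel, graph
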