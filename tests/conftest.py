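import pytest

from icuaccess.catchment import BlockGroup, Facility, build_catchments, no_access_set
from icuaccess.network import RoadNetwork
from icuaccess.synthetic import RegionConfig, generate_region

from shapely.geometry import Point


def small_config(seed: int, **overrides) -> RegionConfig:
    """A fast region: 150 block groups, 6 facilities, 10x10 grid."""
    params = dict(
        seed=seed,
        extent_km=200.0,
        n_urban_centers=2,
        n_block_groups=150,
        n_facilities=6,
        grid_size=10,
    )
    params.update(overrides)
    return RegionConfig(**params)


@pytest.fixture
def region_factory():
    def make(seed: int, **overrides):
        return generate_region(small_config(seed, **overrides))

    return make


def line_network(n_nodes: int, edge_minutes: float = 30.0, speed: float = 60.0) -> RoadNetwork:
    """Path graph 0-1-...-(n-1); each edge takes ``edge_minutes``."""
    net = RoadNetwork()
    length = edge_minutes * speed / 60.0
    for i in range(n_nodes):
        net.add_node(i, float(i * length), 0.0)
    for i in range(n_nodes - 1):
        net.add_edge(i, i + 1, length, speed)
    return net


def point_block_group(bg_id, x, y, pop, **kw):
    defaults = dict(pop_by_group={}, urbanization="Rural", region_code="R1")
    defaults.update(kw)
    return BlockGroup(id=bg_id, geometry=Point(x, y), pop_total=pop, **defaults)


@pytest.fixture
def toy_region():
    """Hand-checkable region: 3 facilities / 5 block groups on a line.

    Nodes 0..4 joined by 30-minute edges.  Facilities at nodes 0, 2, 4
    with 10, 5, 20 beds; block groups at every node with adult
    populations 1000, 2000, 3000, 4000, 0 (the last is excluded as
    unpopulated).  At T=60 the catchments are: F1 -> {bg0,bg1,bg2},
    F2 -> {bg0..bg3}, F3 -> {bg2,bg3}.
    """
    net = line_network(5)
    xs = [net.coords(i)[0] for i in range(5)]
    facilities = [
        Facility("F1", xs[0], 0.0, 10, "R1"),
        Facility("F2", xs[2], 0.0, 5, "R1"),
        Facility("F3", xs[4], 0.0, 20, "R1"),
    ]
    pops = [1000, 2000, 3000, 4000, 0]
    block_groups = [
        point_block_group(f"bg{i}", xs[i], 0.0, pops[i]) for i in range(5)
    ]
    return net, facilities, block_groups


def group_no_access_pct(region, threshold=60.0):
    """Per-race-group percentage of adults in no-access block groups."""
    index = build_catchments(region.network, region.facilities, region.block_groups, threshold)
    na = no_access_set(index, region.block_groups)
    groups = {}
    for bg in region.block_groups:
        if not bg.populated:
            continue
        for g, n in bg.pop_by_group.items():
            tot, cnt = groups.get(g, (0, 0))
            groups[g] = (tot + n, cnt + (n if bg.id in na else 0))
    return {g: 100.0 * cnt / tot for g, (tot, cnt) in groups.items() if tot > 0}
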