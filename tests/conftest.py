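"""Shared fixtures: tiny hand-built road networks and a seeded synthetic city."""

from __future__ import annotations

import math

import networkx as nx
import pytest

from medaccess import BlindZoneSpec, CityConfig, RoadNetwork, generate_city


def make_network(nodes: dict, edges: list[tuple], road_class: str = "local") -> RoadNetwork:
    """Build a RoadNetwork from {node: (x, y)} and [(u, v)] with one class."""
    from medaccess import ROAD_SPEED_KMH

    g = nx.Graph()
    for n, xy in nodes.items():
        g.add_node(n, pos=tuple(map(float, xy)))
    speed = ROAD_SPEED_KMH[road_class]
    for u, v in edges:
        length = math.dist(nodes[u], nodes[v])
        g.add_edge(
            u, v,
            length_m=length,
            road_class=road_class,
            speed_kmh=speed,
            time_min=length / 1000.0 / speed * 60.0,
        )
    return RoadNetwork(g)


@pytest.fixture(scope="session")
def city_config() -> CityConfig:
    return CityConfig(
        seed=7,
        blind_zone_spec=(BlindZoneSpec((10_000.0, 2_000.0), 1000.0, 20, "community"),),
    )


@pytest.fixture(scope="session")
def city(city_config):
    """One seeded synthetic city shared across tests (read-only)."""
    return generate_city(city_config)
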