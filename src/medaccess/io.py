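"""Readers and writers for the pipeline's on-disk artifact formats.

Vector features travel as GeoJSON FeatureCollections (planar coordinates in
meters; no CRS member), rasters as ESRI ASCII grids, road graphs additionally
as a node/edge CSV pair so they can be rebuilt without geometry parsing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic_city import (
    AdminUnit,
    Facility,
    FacilitySet,
    PopulationGrid,
    ResidentialArea,
    RoadNetwork,
)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _point_feature(xy: tuple[float, float], properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [float(xy[0]), float(xy[1])]},
        "properties": properties,
    }


def write_residential_geojson(path: str | Path, residential: Sequence[ResidentialArea]) -> None:
    feats = [
        _point_feature(a.location, {"id": a.id, "households": a.households, "truth_blind": a.truth_blind})
        for a in residential
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def read_residential_geojson(path: str | Path) -> list[ResidentialArea]:
    data = json.loads(Path(path).read_text())
    return [
        ResidentialArea(
            f["properties"]["id"],
            tuple(f["geometry"]["coordinates"]),
            f["properties"]["households"],
            f["properties"].get("truth_blind", False),
        )
        for f in data["features"]
    ]


def write_facilities_geojson(path: str | Path, facilities: FacilitySet) -> None:
    feats = [
        _point_feature(
            f.location,
            {
                "id": f.id,
                "tier": f.tier,
                "beds": f.beds,
                "service_radius_m": f.service_radius_m,
                "capacity_persons": f.capacity_persons,
            },
        )
        for f in facilities
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def read_facilities_geojson(path: str | Path) -> FacilitySet:
    data = json.loads(Path(path).read_text())
    return FacilitySet(
        [
            Facility(
                p["id"], p["tier"], tuple(f["geometry"]["coordinates"]),
                beds=p["beds"],
                service_radius_m=p.get("service_radius_m"),
                capacity_persons=p.get("capacity_persons"),
            )
            for f in data["features"]
            for p in [f["properties"]]
        ]
    )


def write_road_geojson(path: str | Path, network: RoadNetwork) -> None:
    pos = network.node_positions()
    feats = []
    for u, v, d in network.graph.edges(data=True):
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(pos[u]), list(pos[v])],
                },
                "properties": {
                    "u": u, "v": v,
                    "length_m": d["length_m"],
                    "road_class": d["road_class"],
                    "speed_kmh": d["speed_kmh"],
                },
            }
        )
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def write_road_csvs(nodes_path: str | Path, edges_path: str | Path, network: RoadNetwork) -> None:
    pos = network.node_positions()
    pd.DataFrame(
        [{"node": n, "x": xy[0], "y": xy[1]} for n, xy in pos.items()]
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [
            {
                "u": u, "v": v,
                "length_m": d["length_m"],
                "road_class": d["road_class"],
                "speed_kmh": d["speed_kmh"],
            }
            for u, v, d in network.graph.edges(data=True)
        ]
    ).to_csv(edges_path, index=False)


def read_road_csvs(nodes_path: str | Path, edges_path: str | Path) -> RoadNetwork:
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(int(row.node), pos=(float(row.x), float(row.y)))
    for row in edges.itertuples(index=False):
        g.add_edge(
            int(row.u), int(row.v),
            length_m=float(row.length_m),
            road_class=str(row.road_class),
            speed_kmh=float(row.speed_kmh),
            time_min=float(row.length_m) / 1000.0 / float(row.speed_kmh) * 60.0,
        )
    return RoadNetwork(g)


def write_admin_geojson(path: str | Path, units: Sequence[AdminUnit]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(u.polygon),
            "properties": {"id": u.id, "population": u.population, "beds": u.beds},
        }
        for u in units
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def read_admin_geojson(path: str | Path) -> list[AdminUnit]:
    data = json.loads(Path(path).read_text())
    return [
        AdminUnit(
            f["properties"]["id"],
            shape(f["geometry"]),
            f["properties"]["population"],
            f["properties"]["beds"],
        )
        for f in data["features"]
    ]


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    origin: tuple[float, float],
    cell_size_m: float,
    nodata: float = -9999.0,
) -> None:
    """ESRI ASCII grid; ``values`` row 0 is the southern row (written last)."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\n"
        f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size_m}\nNODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in values[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> PopulationGrid:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for line in lines[:6]:
        k, v = line.split()
        hdr[k.lower()] = float(v)
    n_cols, n_rows = int(hdr["ncols"]), int(hdr["nrows"])
    vals = np.array([[float(v) for v in line.split()] for line in lines[6 : 6 + n_rows]])
    return PopulationGrid(
        (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"], n_rows, n_cols, vals[::-1]
    )


def write_geojson_polygons(path: str | Path, rings: Sequence[list], properties: Sequence[dict]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [[list(p) for p in ring]]},
            "properties": props,
        }
        for ring, props in zip(rings, properties)
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))
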