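"""Synthetic region generator: road network, ICU facilities, block groups.

Emulates the statistical structure the accessibility analysis assumes,
without any real data:

* a handful of urban centers on a square planar extent (km), with block
  groups and facilities concentrated near them and a sparse uniform rural
  periphery;
* a perturbed-grid road network of low-speed local roads, with high-speed
  corridors along the grid paths linking consecutive urban centers, so
  isochrones are anisotropic;
* adult population (>= 15 y) per block group with per-race/ethnicity
  counts; Hispanic is an overlapping ethnicity drawn independently of the
  racial composition, and a residual share of the population belongs to
  untabulated categories, so per-group counts deliberately do not sum to
  the total;
* a ``disparity_knob`` in [0, 1]: at 0, racial composition is independent
  of geography; at 1, the designated minority groups are concentrated in
  block groups far from any facility, so access disparities are
  recoverable by construction;
* six urbanization classes assigned by population-density quantile.

All positions are drawn in unit coordinates and scaled by ``extent_km``:
the same seed at a larger extent gives a geometrically similar region with
proportionally longer drive times, so coverage at a fixed drive-time
threshold shrinks as the extent grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .catchment import BlockGroup, Facility
from .network import RoadNetwork

__all__ = [
    "RegionConfig",
    "SyntheticRegion",
    "generate_region",
    "write_region",
    "read_region",
    "regions_equal",
    "DEFAULT_GROUPS",
    "URBANIZATION_LABELS",
]

DEFAULT_GROUPS = ("ai_an", "asian", "black", "hispanic", "pacific_islander", "white")

# density quantiles, lowest to highest
URBANIZATION_LABELS = (
    "Rural",
    "Semirural",
    "Suburban Periphery",
    "Metro Cities",
    "Urban Periphery",
    "Principle Urban Centers",
)
# cumulative quantile cutpoints between the six classes (bottom -> top)
DEFAULT_URBANIZATION_CUTS = (0.25, 0.40, 0.75, 0.85, 0.95)

# baseline national-ish composition shares; the remainder is the
# untabulated "other/multiracial" share that is generated but not labelled
BASE_RACE_SHARES = {
    "ai_an": 0.013,
    "asian": 0.060,
    "black": 0.125,
    "pacific_islander": 0.004,
    "white": 0.720,
}
HISPANIC_FRACTION = 0.18


class ConfigurationError(ValueError):
    """A RegionConfig bound was violated."""


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of one synthetic region.

    ``disparity_knob`` controls how strongly minority composition
    correlates with distance from facilities (0 = independent, 1 =
    strongly concentrated far away).  ``urban_speed_kmh`` is the speed of
    the corridor roads linking urban centers; ``rural_speed_kmh`` that of
    ordinary grid roads.
    """

    seed: int = 0
    extent_km: float = 300.0
    n_urban_centers: int = 3
    n_block_groups: int = 400
    n_facilities: int = 12
    beds_per_facility_range: tuple[int, int] = (2, 20)
    urban_speed_kmh: float = 90.0
    rural_speed_kmh: float = 50.0
    grid_size: int = 14
    race_group_names: tuple[str, ...] = DEFAULT_GROUPS
    overlapping_group: str = "hispanic"
    minority_groups: tuple[str, ...] = ("ai_an", "pacific_islander")
    disparity_knob: float = 0.0
    n_regions: int = 4
    urban_fraction: float = 0.7
    zero_pop_fraction: float = 0.02
    mean_adults_per_block_group: float = 1300.0
    urbanization_cuts: tuple[float, ...] = DEFAULT_URBANIZATION_CUTS

    def validate(self) -> None:
        lo, hi = self.beds_per_facility_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"beds_per_facility_range lower bound must be >= 1 and <= upper, got {(lo, hi)}"
            )
        if self.extent_km <= 0:
            raise ConfigurationError(f"extent_km must be > 0, got {self.extent_km}")
        if self.n_block_groups < self.n_facilities:
            raise ConfigurationError(
                f"n_block_groups ({self.n_block_groups}) must be >= n_facilities "
                f"({self.n_facilities})"
            )
        if self.n_facilities < 0 or self.n_block_groups < 1 or self.n_urban_centers < 1:
            raise ConfigurationError("counts must be non-negative (>=1 block group and center)")
        if not 0.0 <= self.disparity_knob <= 1.0:
            raise ConfigurationError(
                f"disparity_knob must be in [0, 1], got {self.disparity_knob}"
            )
        if self.urban_speed_kmh <= 0 or self.rural_speed_kmh <= 0:
            raise ConfigurationError("speeds must be > 0")
        if self.grid_size < 2:
            raise ConfigurationError("grid_size must be >= 2")


@dataclass
class SyntheticRegion:
    """A generated region plus the generative truth labels per block group.

    ``truth`` columns: blockgroup_id, urban_core (bool), dist_to_facility_km
    (euclidean, NaN when there are no facilities), z (distance percentile
    rank in [0, 1] used for the composition gradient).
    """

    config: RegionConfig
    network: RoadNetwork
    facilities: list[Facility]
    block_groups: list[BlockGroup]
    truth: pd.DataFrame


def _unit_positions(rng: np.random.Generator, cfg: RegionConfig):
    """All random draws in unit coordinates; one fixed draw order."""
    centers = rng.uniform(0.1, 0.9, size=(cfg.n_urban_centers, 2))

    k = cfg.grid_size
    gx, gy = np.meshgrid(np.linspace(0, 1, k), np.linspace(0, 1, k))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    jitter = rng.uniform(-0.2, 0.2, size=grid.shape) / (k - 1)
    nodes = np.clip(grid + jitter, 0.0, 1.0)

    fac_centers = rng.integers(0, cfg.n_urban_centers, size=cfg.n_facilities)
    fac_pos = np.clip(
        centers[fac_centers] + rng.normal(0, 0.04, size=(cfg.n_facilities, 2)), 0.0, 1.0
    )

    n_urban = int(round(cfg.urban_fraction * cfg.n_block_groups))
    bg_centers = rng.integers(0, cfg.n_urban_centers, size=n_urban)
    urban_pos = centers[bg_centers] + rng.normal(0, 0.055, size=(n_urban, 2))
    rural_pos = rng.uniform(0, 1, size=(cfg.n_block_groups - n_urban, 2))
    bg_pos = np.clip(np.vstack([urban_pos, rural_pos]), 0.0, 1.0)
    return centers, nodes, fac_pos, bg_pos


def _build_network(cfg: RegionConfig, unit_nodes: np.ndarray, centers: np.ndarray) -> RoadNetwork:
    k = cfg.grid_size
    net = RoadNetwork()
    xy = unit_nodes * cfg.extent_km
    for i in range(k * k):
        net.add_node(i, xy[i, 0], xy[i, 1])

    def length(u, v):
        return float(np.hypot(xy[u, 0] - xy[v, 0], xy[u, 1] - xy[v, 1]))

    for r in range(k):
        for c in range(k):
            u = r * k + c
            if c + 1 < k:
                net.add_edge(u, u + 1, length(u, u + 1), cfg.rural_speed_kmh)
            if r + 1 < k:
                net.add_edge(u, u + k, length(u, u + k), cfg.rural_speed_kmh)

    # high-speed corridors along grid paths between consecutive urban centers
    center_xy = centers * cfg.extent_km
    center_nodes = []
    for cx, cy in center_xy:
        d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        center_nodes.append(int(np.argmin(d2)))
    for a, b in zip(center_nodes, center_nodes[1:]):
        path = nx.shortest_path(net.graph, a, b, weight="length_km")
        for u, v in zip(path, path[1:]):
            e = net.graph.edges[u, v]
            net.add_edge(u, v, e["length_km"], cfg.urban_speed_kmh)
    return net


def _race_probabilities(cfg: RegionConfig, z: np.ndarray) -> np.ndarray:
    """Per-block-group multinomial probabilities over race groups + 'other'.

    ``z`` is the distance-to-facility percentile rank.  With knob d, the
    designated minority groups get weight exp(4 d (z - 1/2)) and white
    exp(-1.5 d (z - 1/2)); at d=0 every block group shares the baseline.
    """
    race_labels = [g for g in cfg.race_group_names if g != cfg.overlapping_group]
    base = np.array([BASE_RACE_SHARES.get(g, 0.02) for g in race_labels])
    other = max(0.0, 1.0 - base.sum())
    d = cfg.disparity_knob
    n = z.size
    probs = np.empty((n, len(race_labels) + 1))
    for idx, g in enumerate(race_labels):
        if g in cfg.minority_groups:
            w = np.exp(4.0 * d * (z - 0.5))
        elif g == "white":
            w = np.exp(-1.5 * d * (z - 0.5))
        else:
            w = np.ones(n)
        probs[:, idx] = base[idx] * w
    probs[:, -1] = other
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def generate_region(config: RegionConfig) -> SyntheticRegion:
    """Deterministically generate a region from its config (seed included)."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    centers, unit_nodes, fac_unit, bg_unit = _unit_positions(rng, cfg)
    network = _build_network(cfg, unit_nodes, centers)

    def region_code(x_km: float) -> str:
        band = min(cfg.n_regions - 1, int(x_km / cfg.extent_km * cfg.n_regions))
        return f"R{band + 1}"

    lo, hi = cfg.beds_per_facility_range
    beds = rng.integers(lo, hi + 1, size=cfg.n_facilities)
    facilities = []
    for i in range(cfg.n_facilities):
        x, y = fac_unit[i] * cfg.extent_km
        facilities.append(
            Facility(
                id=f"F{i:03d}",
                x_km=float(x),
                y_km=float(y),
                adult_icu_beds=int(beds[i]),
                region_code=region_code(float(x)),
            )
        )

    bg_xy = bg_unit * cfg.extent_km

    # distance-to-facility truth and its percentile rank (composition driver)
    if cfg.n_facilities > 0:
        fac_xy = fac_unit * cfg.extent_km
        d = np.sqrt(
            ((bg_xy[:, None, :] - fac_xy[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        order = np.argsort(np.argsort(d))
        z = order / max(1, cfg.n_block_groups - 1)
    else:
        d = np.full(cfg.n_block_groups, np.nan)
        z = np.full(cfg.n_block_groups, 0.5)

    # density score -> urbanization class by quantile
    center_xy = centers * cfg.extent_km
    sigma = cfg.extent_km / 12.0
    dc2 = ((bg_xy[:, None, :] - center_xy[None, :, :]) ** 2).sum(axis=2)
    density = np.exp(-dc2 / (2 * sigma**2)).sum(axis=1)
    dens_rank = np.argsort(np.argsort(density)) / max(1, cfg.n_block_groups - 1)
    cuts = np.asarray(cfg.urbanization_cuts)
    urb_idx = np.searchsorted(cuts, dens_rank, side="right")
    urban_core = dens_rank >= cuts[-1]

    pops = rng.poisson(cfg.mean_adults_per_block_group, size=cfg.n_block_groups)
    zero_mask = rng.uniform(size=cfg.n_block_groups) < cfg.zero_pop_fraction
    pops = np.where(zero_mask, 0, pops)

    race_labels = [g for g in cfg.race_group_names if g != cfg.overlapping_group]
    probs = _race_probabilities(cfg, z)

    block_groups: list[BlockGroup] = []
    half = 0.5  # 1 km square footprint around each centroid
    for j in range(cfg.n_block_groups):
        x, y = float(bg_xy[j, 0]), float(bg_xy[j, 1])
        total = int(pops[j])
        counts = rng.multinomial(total, probs[j])
        pop_by_group = {g: int(counts[idx]) for idx, g in enumerate(race_labels)}
        if cfg.overlapping_group in cfg.race_group_names:
            pop_by_group[cfg.overlapping_group] = int(rng.binomial(total, HISPANIC_FRACTION))
        geometry = Polygon(
            [(x - half, y - half), (x + half, y - half), (x + half, y + half), (x - half, y + half)]
        )
        block_groups.append(
            BlockGroup(
                id=f"BG{j:04d}",
                geometry=geometry,
                pop_total=total,
                pop_by_group=pop_by_group,
                urbanization=URBANIZATION_LABELS[urb_idx[j]],
                region_code=region_code(x),
            )
        )

    truth = pd.DataFrame(
        {
            "blockgroup_id": [bg.id for bg in block_groups],
            "urban_core": urban_core,
            "dist_to_facility_km": d,
            "z": z,
        }
    )
    return SyntheticRegion(
        config=cfg,
        network=network,
        facilities=facilities,
        block_groups=block_groups,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# file round trip


class RegionParseError(ValueError):
    """A region file is malformed; the message names file and record."""


def write_region(region: SyntheticRegion, directory) -> dict[str, Path]:
    """Write a region to its on-disk file set; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    fac = pd.DataFrame(
        [
            {
                "id": f.id,
                "x_km": f.x_km,
                "y_km": f.y_km,
                "adult_icu_beds": f.adult_icu_beds,
                "region_code": f.region_code,
            }
            for f in region.facilities
        ],
        columns=["id", "x_km", "y_km", "adult_icu_beds", "region_code"],
    )
    paths["facilities"] = directory / "facilities.csv"
    fac.to_csv(paths["facilities"], index=False)

    ids, xy = region.network.node_array()
    nodes = pd.DataFrame({"id": ids, "x_km": xy[:, 0], "y_km": xy[:, 1]})
    paths["nodes"] = directory / "network_nodes.csv"
    nodes.to_csv(paths["nodes"], index=False)

    edges = pd.DataFrame(
        [
            {"u": u, "v": v, "length_km": d["length_km"], "speed_kmh": d["speed_kmh"]}
            for u, v, d in sorted(region.network.graph.edges(data=True))
        ],
        columns=["u", "v", "length_km", "speed_kmh"],
    )
    paths["edges"] = directory / "network_edges.csv"
    edges.to_csv(paths["edges"], index=False)

    features = []
    for bg in region.block_groups:
        props = {
            "id": bg.id,
            "region_code": bg.region_code,
            "urbanization": bg.urbanization,
            "pop_total": bg.pop_total,
        }
        for g, n in bg.pop_by_group.items():
            props[f"pop_{g}"] = n
        features.append(
            {"type": "Feature", "geometry": mapping(bg.geometry), "properties": props}
        )
    paths["block_groups"] = directory / "block_groups.geojson"
    with open(paths["block_groups"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    paths["truth"] = directory / "truth.csv"
    region.truth.to_csv(paths["truth"], index=False)

    paths["config"] = directory / "region_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(asdict(region.config), fh, indent=1, sort_keys=True)
    return paths


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RegionParseError(f"{path}: missing column(s) {missing}")


def read_region(directory) -> SyntheticRegion:
    """Read a region file set back; inverse of :func:`write_region`."""
    directory = Path(directory)

    cfg_path = directory / "region_config.json"
    config = None
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = json.load(fh)
        for key in (
            "beds_per_facility_range",
            "race_group_names",
            "minority_groups",
            "urbanization_cuts",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        config = RegionConfig(**raw)

    fac_path = directory / "facilities.csv"
    fac = pd.read_csv(fac_path, float_precision="round_trip")
    _require_columns(fac, ["id", "x_km", "y_km", "adult_icu_beds", "region_code"], fac_path)
    facilities = []
    for i, row in fac.iterrows():
        try:
            facilities.append(
                Facility(
                    id=str(row["id"]),
                    x_km=float(row["x_km"]),
                    y_km=float(row["y_km"]),
                    adult_icu_beds=int(row["adult_icu_beds"]),
                    region_code=str(row["region_code"]),
                )
            )
        except ValueError as exc:
            raise RegionParseError(f"{fac_path}: record {i}: {exc}") from exc

    nodes_path = directory / "network_nodes.csv"
    nodes = pd.read_csv(nodes_path, float_precision="round_trip")
    _require_columns(nodes, ["id", "x_km", "y_km"], nodes_path)
    edges_path = directory / "network_edges.csv"
    edges = pd.read_csv(edges_path, float_precision="round_trip")
    _require_columns(edges, ["u", "v", "length_km", "speed_kmh"], edges_path)
    network = RoadNetwork()
    for _, row in nodes.iterrows():
        network.add_node(int(row["id"]), float(row["x_km"]), float(row["y_km"]))
    for i, row in edges.iterrows():
        try:
            network.add_edge(
                int(row["u"]), int(row["v"]), float(row["length_km"]), float(row["speed_kmh"])
            )
        except ValueError as exc:
            raise RegionParseError(f"{edges_path}: record {i}: {exc}") from exc

    bg_path = directory / "block_groups.geojson"
    try:
        with open(bg_path) as fh:
            collection = json.load(fh)
    except json.JSONDecodeError as exc:
        raise RegionParseError(f"{bg_path}: invalid JSON: {exc}") from exc
    block_groups = []
    for i, feature in enumerate(collection.get("features", [])):
        props = feature.get("properties", {})
        try:
            pop_by_group = {
                k[len("pop_"):]: int(v)
                for k, v in props.items()
                if k.startswith("pop_") and k != "pop_total"
            }
            block_groups.append(
                BlockGroup(
                    id=str(props["id"]),
                    geometry=shape(feature["geometry"]),
                    pop_total=int(props["pop_total"]),
                    pop_by_group=pop_by_group,
                    urbanization=str(props["urbanization"]),
                    region_code=str(props["region_code"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise RegionParseError(f"{bg_path}: feature {i}: {exc}") from exc

    truth_path = directory / "truth.csv"
    truth = (
        pd.read_csv(truth_path)
        if truth_path.exists()
        else pd.DataFrame(
            columns=["blockgroup_id", "urban_core", "dist_to_facility_km", "z"]
        )
    )
    if config is None:
        config = RegionConfig(n_block_groups=len(block_groups), n_facilities=len(facilities))
    return SyntheticRegion(
        config=config,
        network=network,
        facilities=facilities,
        block_groups=block_groups,
        truth=truth,
    )


def regions_equal(a: SyntheticRegion, b: SyntheticRegion) -> bool:
    """Field-wise equality on everything used downstream."""
    if a.facilities != b.facilities:
        return False
    if sorted(a.network.graph.nodes(data=True)) != sorted(b.network.graph.nodes(data=True)):
        return False
    ea = {tuple(sorted((u, v))): d for u, v, d in a.network.graph.edges(data=True)}
    eb = {tuple(sorted((u, v))): d for u, v, d in b.network.graph.edges(data=True)}
    if ea != eb:
        return False
    if len(a.block_groups) != len(b.block_groups):
        return False
    for x, y in zip(a.block_groups, b.block_groups):
        if (
            x.id != y.id
            or x.pop_total != y.pop_total
            or x.pop_by_group != y.pop_by_group
            or x.urbanization != y.urbanization
            or x.region_code != y.region_code
            or not x.geometry.equals_exact(y.geometry, tolerance=0.0)
        ):
            return False
    return True
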