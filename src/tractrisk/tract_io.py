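"""Reading, writing and validation of tract-level inputs.

Three kinds of input describe a study region:

* a covariate table — one row per census tract with an identifier,
  socioeconomic covariates, household totals and event (outlet) counts;
* spatial structure — either polygon geometries (GeoJSON), from which a
  queen-contiguity neighbor graph is derived, or a precomputed adjacency
  list in the plain-text GAL format;
* optionally, point locations of events to be assigned to tracts.

All structures are aligned by tract identifier and validated on
construction (unique ids, non-negative integer counts, symmetric
zero-diagonal adjacency).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "TractTable",
    "AdjacencyGraph",
    "OutletPoints",
    "read_tract_table",
    "build_queen_adjacency",
    "read_gal",
    "write_gal",
    "read_geojson_polygons",
    "write_geojson_polygons",
    "read_outlet_points",
    "assign_points_to_tracts",
]


@dataclass
class TractTable:
    """Per-tract covariates, household totals and event counts.

    Attributes
    ----------
    tract_id : array of str
        Unique tract identifiers, in row order.
    x : (n, C) float array
        Socioeconomic covariates; may contain NaN before missing-value
        filtering.
    households : (n,) int array
        Households per tract (the Poisson offset is built from these).
    counts : (n,) int array
        Event counts per tract.
    covariate_names : list of str
    missing_mask : (n,) bool array
        True where the row has at least one missing covariate cell.
    """

    tract_id: np.ndarray
    x: np.ndarray
    households: np.ndarray
    counts: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tract_id = np.asarray(self.tract_id, dtype=str)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.households = np.asarray(self.households)
        self.counts = np.asarray(self.counts)
        if len(set(self.tract_id.tolist())) != self.n:
            dupes = pd.Series(self.tract_id).value_counts()
            dupes = dupes[dupes > 1].index.tolist()
            raise ValueError(f"duplicated tract_id values: {dupes}")
        for name, arr in (("households", self.households), ("counts", self.counts)):
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name} must be integer-valued")
                arr = np.round(arr).astype(np.int64)
            setattr(self, name, arr.astype(np.int64))
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.n_covariates)]
        if len(self.covariate_names) != self.n_covariates:
            raise ValueError("covariate_names length does not match x columns")

    @property
    def n(self) -> int:
        return len(self.tract_id)

    @property
    def n_covariates(self) -> int:
        return self.x.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.x).any(axis=1)

    def subset(self, keep: np.ndarray) -> "TractTable":
        """Row subset by boolean mask or index array."""
        return TractTable(
            tract_id=self.tract_id[keep],
            x=self.x[keep],
            households=self.households[keep],
            counts=self.counts[keep],
            covariate_names=list(self.covariate_names),
        )


@dataclass
class AdjacencyGraph:
    """Symmetric binary neighbor structure over tracts.

    ``neighbors[i]`` is the sorted integer index array of tracts adjacent
    to tract i; ``degrees[i]`` its cardinality.  Islands (degree 0) are
    allowed and warned about at construction.
    """

    ids: np.ndarray
    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=str)
        self.neighbors = [np.asarray(sorted(set(int(j) for j in nb)), dtype=np.int64)
                          for nb in self.neighbors]
        n = self.n
        if len(self.neighbors) != n:
            raise ValueError("neighbor list length != number of ids")
        for i, nb in enumerate(self.neighbors):
            if np.any(nb == i):
                raise ValueError(f"self-neighbor at tract {self.ids[i]}")
            if np.any(nb < 0) or np.any(nb >= n):
                raise ValueError(f"neighbor index out of range at tract {self.ids[i]}")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.ids[i]} lists {self.ids[j]} "
                        "but not vice versa"
                    )
        isl = self.islands
        if len(isl):
            warnings.warn(
                f"{len(isl)} island tract(s) with no neighbors: "
                f"{self.ids[isl][:10].tolist()}",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    @property
    def islands(self) -> np.ndarray:
        return np.where(self.degrees == 0)[0]

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def edge_array(self) -> np.ndarray:
        """(n_edges, 2) array of index pairs with i < j."""
        pairs = [(i, int(j)) for i, nb in enumerate(self.neighbors) for j in nb if i < j]
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def sparse_matrix(self):
        """Binary adjacency as a scipy CSR matrix."""
        from scipy import sparse

        e = self.edge_array()
        if len(e) == 0:
            return sparse.csr_matrix((self.n, self.n))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def connected_components(self) -> list[np.ndarray]:
        """Index arrays of connected components (islands are singletons)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edge_array()))
        return [np.array(sorted(c), dtype=np.int64) for c in nx.connected_components(g)]

    def greedy_coloring(self) -> np.ndarray:
        """Proper node coloring (no two neighbors share a color).

        Used by the sampler to update non-adjacent spatial effects in
        parallel blocks.
        """
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edge_array()))
        col = nx.greedy_color(g, strategy="largest_first")
        return np.array([col[i] for i in range(self.n)], dtype=np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencyGraph):
            return NotImplemented
        return (
            self.ids.tolist() == other.ids.tolist()
            and all(a.tolist() == b.tolist() for a, b in zip(self.neighbors, other.neighbors))
        )


@dataclass
class OutletPoints:
    """Event point locations in decimal-degree longitude/latitude."""

    point_id: np.ndarray
    longitude: np.ndarray
    latitude: np.ndarray
    store_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.point_id = np.asarray(self.point_id, dtype=str)
        self.longitude = np.asarray(self.longitude, dtype=float)
        self.latitude = np.asarray(self.latitude, dtype=float)
        if not (np.isfinite(self.longitude).all() and np.isfinite(self.latitude).all()):
            raise ValueError("non-finite coordinates")
        if np.any(np.abs(self.longitude) > 180) or np.any(np.abs(self.latitude) > 90):
            raise ValueError("coordinates outside valid longitude/latitude ranges")

    @property
    def n(self) -> int:
        return len(self.point_id)


def read_tract_table(
    path,
    id_column: str = "tract_id",
    covariate_columns: list[str] | None = None,
    households_column: str = "households",
    counts_column: str = "counts",
) -> TractTable:
    """Read a per-tract covariate/count table from a CSV file.

    Rows with missing covariate cells are retained and flagged via
    ``TractTable.missing_mask``; filtering is a separate, reported step.

    Raises
    ------
    KeyError
        If a mapped column is absent.
    ValueError
        On non-numeric covariate cells (naming row and column) or
        duplicated tract identifiers.
    """
    df = pd.read_csv(path, dtype={id_column: str})
    if covariate_columns is None:
        reserved = {id_column, households_column, counts_column}
        covariate_columns = [c for c in df.columns if c not in reserved]
    for col in [id_column, households_column, counts_column, *covariate_columns]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    x = np.empty((len(df), len(covariate_columns)))
    for j, col in enumerate(covariate_columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric covariate cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        x[:, j] = vals.to_numpy()
    return TractTable(
        tract_id=df[id_column].to_numpy(),
        x=x,
        households=df[households_column].to_numpy(),
        counts=df[counts_column].to_numpy(),
        covariate_names=list(covariate_columns),
    )


def _check_polygons(polygons: dict[str, BaseGeometry]) -> None:
    for tid, geom in polygons.items():
        if geom is None or geom.is_empty:
            raise ValueError(f"empty geometry for tract {tid}")
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for tract {tid}")


def build_queen_adjacency(polygons: dict[str, BaseGeometry]) -> AdjacencyGraph:
    """Queen-contiguity graph: tracts are neighbors iff their boundaries
    share at least one point.

    Parameters
    ----------
    polygons : dict mapping tract_id -> shapely geometry

    Returns
    -------
    AdjacencyGraph with ids in the dict's insertion order.
    """
    _check_polygons(polygons)
    ids = list(polygons)
    geoms = [polygons[t] for t in ids]
    tree = STRtree(geoms)
    neighbors: list[set[int]] = [set() for _ in ids]
    for i, geom in enumerate(geoms):
        for j in tree.query(geom, predicate="intersects"):
            j = int(j)
            if j != i:
                neighbors[i].add(j)
                neighbors[j].add(i)
    return AdjacencyGraph(ids=np.array(ids, dtype=str),
                          neighbors=[np.array(sorted(s)) for s in neighbors])


def write_gal(graph: AdjacencyGraph, path) -> None:
    """Write an adjacency graph in the plain-text GAL dialect.

    Header line: number of nodes.  Then, per node, a line with the node
    id and its degree followed by a line listing neighbor ids.
    """
    with open(path, "w") as fh:
        fh.write(f"{graph.n}\n")
        for i, nb in enumerate(graph.neighbors):
            fh.write(f"{graph.ids[i]} {len(nb)}\n")
            fh.write(" ".join(graph.ids[j] for j in nb) + "\n")


def read_gal(path, symmetrize: bool = False) -> AdjacencyGraph:
    """Read a GAL adjacency file.

    The header may be a bare node count or the common
    ``0 n shapefile key`` form; both are accepted.  Asymmetric listings
    are an error unless ``symmetrize=True``, in which case the union of
    the two directions is taken.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln.strip() for ln in tokens if ln.strip()]
    if not lines:
        raise ValueError(f"empty GAL file: {path}")
    header = lines[0].split()
    n = int(header[1]) if len(header) > 1 else int(header[0])
    ids: list[str] = []
    raw: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise ValueError(f"truncated GAL file: {path}")
        node_id, degree = lines[pos].split()[:2]
        degree = int(degree)
        nb: list[str] = []
        if degree > 0:
            pos += 1
            nb = lines[pos].split()
            if len(nb) != degree:
                raise ValueError(
                    f"GAL degree mismatch for node {node_id}: "
                    f"declared {degree}, listed {len(nb)}"
                )
        ids.append(node_id)
        raw[node_id] = nb
        pos += 1
    index = {t: i for i, t in enumerate(ids)}
    neighbors = [[index[j] for j in raw[t]] for t in ids]
    if symmetrize:
        sym = [set(nb) for nb in neighbors]
        for i, nb in enumerate(neighbors):
            for j in nb:
                sym[j].add(i)
        neighbors = [sorted(s) for s in sym]
    # AdjacencyGraph.__post_init__ enforces symmetry otherwise
    return AdjacencyGraph(ids=np.array(ids, dtype=str),
                          neighbors=[np.array(nb, dtype=np.int64) for nb in neighbors])


def read_geojson_polygons(path, id_property: str = "tract_id") -> dict[str, BaseGeometry]:
    """Read tract polygons from a GeoJSON FeatureCollection keyed by a
    feature property."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    polygons: dict[str, BaseGeometry] = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise KeyError(f"feature missing property {id_property!r}")
        tid = str(props[id_property])
        if tid in polygons:
            raise ValueError(f"duplicated tract_id in GeoJSON: {tid}")
        polygons[tid] = shapely_shape(feat["geometry"])
    return polygons


def write_geojson_polygons(
    polygons: dict[str, BaseGeometry],
    path,
    id_property: str = "tract_id",
    properties: dict[str, dict] | None = None,
) -> None:
    """Write polygons (optionally with per-tract properties) as GeoJSON."""
    feats = []
    for tid, geom in polygons.items():
        props = {id_property: tid}
        if properties is not None:
            props.update(properties.get(tid, {}))
        feats.append({"type": "Feature", "properties": props,
                      "geometry": shapely_mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_outlet_points(
    path,
    id_column: str = "point_id",
    longitude_column: str = "longitude",
    latitude_column: str = "latitude",
    store_type_column: str | None = None,
) -> OutletPoints:
    """Read event point coordinates from CSV."""
    df = pd.read_csv(path)
    for col in (longitude_column, latitude_column):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    pid = (df[id_column].astype(str).to_numpy() if id_column in df.columns
           else np.arange(len(df)).astype(str))
    st = (df[store_type_column].astype(str).to_numpy()
          if store_type_column and store_type_column in df.columns else None)
    return OutletPoints(point_id=pid,
                        longitude=df[longitude_column].to_numpy(),
                        latitude=df[latitude_column].to_numpy(),
                        store_type=st)


def assign_points_to_tracts(
    points: OutletPoints,
    polygons: dict[str, BaseGeometry],
) -> tuple[pd.Series, list[str]]:
    """Assign each point to the tract polygon containing it.

    Points on a shared boundary count as inside; if a point falls inside
    two or more polygons it is assigned to the lowest tract_id (logged).
    Coordinates are treated as planar.

    Returns
    -------
    counts : pandas Series indexed by tract_id (all tracts, zeros kept)
    unassigned : list of point ids contained by no polygon
    """
    _check_polygons(polygons)
    from shapely.geometry import Point

    ids = list(polygons)
    geoms = [polygons[t] for t in ids]
    tree = STRtree(geoms)
    counts = pd.Series(0, index=pd.Index(ids, name="tract_id"), dtype=np.int64)
    unassigned: list[str] = []
    for k in range(points.n):
        pt = Point(points.longitude[k], points.latitude[k])
        hits = sorted(ids[int(j)] for j in tree.query(pt, predicate="intersects"))
        if not hits:
            unassigned.append(points.point_id[k])
            continue
        if len(hits) > 1:
            logger.info(
                "point %s on boundary of %s; assigned to %s",
                points.point_id[k], hits, hits[0],
            )
        counts[hits[0]] += 1
    return counts, unassigned
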