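"""Areal data handling: polygons, contiguity, event aggregation, standardization.

The modelling unit is a small area (e.g. a census dissemination area). This
module turns raw inputs — a polygon layer, point events or pre-aggregated
counts, population tables — into the two containers the model consumes:

* :class:`AreaTable` — per-area observed and expected counts for the two
  outcomes, plus standardized ratios (observed/expected, the crude relative
  risks).
* :class:`AdjacencyStructure` — the 0–1 contiguity relation between areas
  (queen by default: any shared boundary point makes a neighbour pair),
  with neighbour counts, connected components and islands.

Expected counts come from indirect standardization: region-wide reference
rates (optionally stratified by sex and age group) applied to each area's
population, so that expected totals match observed totals by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
import shapely

logger = logging.getLogger("scsm")

N_OUTCOMES = 2


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyStructure:
    """Symmetric 0–1 contiguity relation over ``n`` areas.

    ``edges`` holds each unordered neighbour pair once as ``(i, j)`` with
    ``i < j``. ``neighbor_counts[i]`` is the number of neighbours of area i,
    ``components`` partitions the areas into connected components, and
    ``islands`` lists areas with no neighbours.
    """

    area_ids: list
    edges: np.ndarray  # (m, 2) int, i < j
    n: int = 0
    neighbor_counts: np.ndarray = field(default=None, repr=False)
    components: list = field(default=None, repr=False)
    islands: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.n = len(self.area_ids)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            if np.any(lo == hi):
                raise ValueError("self-neighbour pair in edge list")
            self.edges = np.column_stack([lo, hi])
            # drop duplicate pairs
            self.edges = np.unique(self.edges, axis=0)
        counts = np.zeros(self.n, dtype=np.int64)
        for col in (0, 1):
            np.add.at(counts, self.edges[:, col], 1)
        self.neighbor_counts = counts
        adj = self.sparse()
        n_comp, labels = connected_components(adj, directed=False)
        self.components = [np.flatnonzero(labels == c) for c in range(n_comp)]
        self.islands = np.flatnonzero(counts == 0)

    # -- constructors -------------------------------------------------------

    @classmethod
    def grid(cls, nrows: int, ncols: int, rule: str = "queen") -> "AdjacencyStructure":
        """Regular-lattice contiguity; stands in for polygon layers in tests
        and simulations."""
        if nrows < 1 or ncols < 1:
            raise ValueError("grid dimensions must be positive")
        idx = np.arange(nrows * ncols).reshape(nrows, ncols)
        pairs = []
        if rule == "queen":
            offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
        elif rule == "rook":
            offsets = [(0, 1), (1, 0)]
        else:
            raise ValueError(f"unknown contiguity rule: {rule!r}")
        for dr, dc in offsets:
            r0 = slice(max(0, -dr), nrows - max(0, dr))
            r1 = slice(max(0, dr), nrows + min(0, dr) or None)
            c0 = slice(max(0, -dc), ncols - max(0, dc))
            c1 = slice(max(0, dc), ncols + min(0, dc) or None)
            a = idx[r0, c0].ravel()
            b = idx[r1, c1].ravel()
            pairs.append(np.column_stack([a, b]))
        edges = np.concatenate(pairs) if pairs else np.empty((0, 2), dtype=np.int64)
        ids = [f"g{r:03d}_{c:03d}" for r in range(nrows) for c in range(ncols)]
        return cls(area_ids=ids, edges=edges)

    # -- views --------------------------------------------------------------

    def sparse(self) -> csr_matrix:
        """Symmetric CSR adjacency matrix W (0–1, zero diagonal)."""
        if self.edges.size:
            i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            data = np.ones(len(i))
        else:
            i = j = np.array([], dtype=np.int64)
            data = np.array([])
        return csr_matrix((data, (i, j)), shape=(self.n, self.n))

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()

    @property
    def n_components(self) -> int:
        return len(self.components)

    def pairwise_diff_sum(self, x: np.ndarray) -> float:
        """Sum over neighbour pairs of (x_i - x_j)^2 (each pair once)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"field has shape {x.shape}, expected ({self.n},)")
        if not self.edges.size:
            return 0.0
        d = x[self.edges[:, 0]] - x[self.edges[:, 1]]
        return float(d @ d)

    # -- I/O ----------------------------------------------------------------

    def to_edge_csv(self, path) -> None:
        df = pd.DataFrame({
            "area_i": [self.area_ids[i] for i in self.edges[:, 0]],
            "area_j": [self.area_ids[j] for j in self.edges[:, 1]],
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_edge_csv(cls, path, area_ids: list) -> "AdjacencyStructure":
        df = pd.read_csv(path, dtype=str)
        pos = {a: k for k, a in enumerate(area_ids)}
        edges = np.array(
            [[pos[a], pos[b]] for a, b in zip(df["area_i"], df["area_j"])],
            dtype=np.int64,
        ).reshape(-1, 2)
        return cls(area_ids=list(area_ids), edges=edges)


def load_polygons_geojson(path, id_field: str = "area_id"):
    """Read a GeoJSON FeatureCollection; returns (area_ids, geometries, properties)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ids, geoms, props = [], [], []
    for k, feat in enumerate(gj["features"]):
        p = feat.get("properties") or {}
        if id_field not in p:
            raise ValueError(f"feature {k} lacks the configured id field {id_field!r}")
        ids.append(str(p[id_field]))
        geoms.append(_shapely_shape(feat["geometry"]))
        props.append(p)
    return ids, geoms, props


def build_adjacency(polygons, area_ids=None, rule: str = "queen") -> AdjacencyStructure:
    """Contiguity structure from polygons.

    ``rule='queen'``: areas touching in at least one boundary point (corner
    touches included) are neighbours. ``rule='rook'``: the shared boundary
    must have positive length.
    """
    if isinstance(polygons, dict):
        area_ids = list(polygons.keys())
        geoms = list(polygons.values())
    else:
        geoms = list(polygons)
        if area_ids is None:
            area_ids = [str(k) for k in range(len(geoms))]
        area_ids = [str(a) for a in area_ids]
    if not geoms:
        raise ValueError("no polygons supplied")
    if len(set(area_ids)) != len(area_ids):
        dupes = sorted({a for a in area_ids if area_ids.count(a) > 1})
        raise ValueError(f"duplicate area_id(s): {dupes}")
    for aid, g in zip(area_ids, geoms):
        if not isinstance(g, BaseGeometry) or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for area {aid!r}")
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule: {rule!r}")

    tree = STRtree(geoms)
    cand_i, cand_j = tree.query(geoms, predicate="intersects")
    pairs = set()
    for i, j in zip(cand_i, cand_j):
        if i >= j:
            continue
        if rule == "queen":
            pairs.add((int(i), int(j)))
        else:
            inter = geoms[i].intersection(geoms[j])
            if inter.length > 0:
                pairs.add((int(i), int(j)))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    adj = AdjacencyStructure(area_ids=area_ids, edges=edges)
    if adj.islands.size:
        logger.warning(
            "SCSM-W01 islands (no neighbours): %s",
            [area_ids[k] for k in adj.islands],
        )
    return adj


# ---------------------------------------------------------------------------
# Point events
# ---------------------------------------------------------------------------

@dataclass
class PointEvents:
    """Point event coordinates in the polygon layer's CRS, with optional
    sex / age-group stratum labels."""

    x: np.ndarray
    y: np.ndarray
    sex: np.ndarray | None = None
    age_group: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y lengths differ")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("event coordinates must be finite")

    def __len__(self):
        return self.x.size

    @classmethod
    def from_csv(cls, path) -> "PointEvents":
        df = pd.read_csv(path)
        return cls(
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            sex=df["sex"].to_numpy() if "sex" in df else None,
            age_group=df["age_group"].to_numpy() if "age_group" in df else None,
        )


def count_points_in_areas(events: PointEvents, polygons, area_ids=None):
    """Assign each event to at most one area by a closed-boundary
    point-in-polygon test; ties (points on shared boundaries) go to the
    lowest area_id. Returns ``(counts, n_unassigned)``.
    """
    if isinstance(polygons, dict):
        area_ids = list(polygons.keys())
        geoms = list(polygons.values())
    else:
        geoms = list(polygons)
        if area_ids is None:
            area_ids = [str(k) for k in range(len(geoms))]
        area_ids = [str(a) for a in area_ids]
    if not geoms:
        raise ValueError("empty polygon set")

    counts = np.zeros(len(geoms), dtype=np.int64)
    if len(events) == 0:
        return counts, 0
    pts = shapely.points(events.x, events.y)
    tree = STRtree(geoms)
    pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
    order = np.argsort([area_ids[j] for j in poly_idx], kind="stable")
    assigned: dict[int, int] = {}
    for k in order:
        p, g = int(pt_idx[k]), int(poly_idx[k])
        if p not in assigned:
            assigned[p] = g
    for g in assigned.values():
        counts[g] += 1
    n_unassigned = len(events) - len(assigned)
    if n_unassigned:
        logger.warning("SCSM-W02 %d event(s) fell outside all polygons", n_unassigned)
    return counts, n_unassigned


# ---------------------------------------------------------------------------
# Indirect standardization
# ---------------------------------------------------------------------------

def expected_counts_population(observed_total: float, area_population: np.ndarray) -> np.ndarray:
    """Expected counts proportional to residential population.

    ``e_i = (sum O / sum pop) * pop_i``, so expected and observed totals match
    exactly. Areas with zero population get ``e_i = 0`` and are flagged for
    exclusion downstream.
    """
    pop = np.asarray(area_population, dtype=float)
    if np.any(pop < 0):
        raise ValueError("area populations must be non-negative")
    total_pop = pop.sum()
    if total_pop <= 0:
        raise ValueError("total population is zero")
    e = observed_total * pop / total_pop
    if np.any(pop == 0):
        logger.warning(
            "SCSM-W03 %d area(s) have zero population (expected count 0; "
            "excluded from modelling)", int((pop == 0).sum()),
        )
    return e


def expected_counts_stratified(
    stratum_observed_totals: np.ndarray,
    stratum_area_populations: np.ndarray,
) -> np.ndarray:
    """Indirect standardization over (sex × age-group) strata.

    Reference rate per stratum = region-wide observed total / region-wide
    population in that stratum; ``e_i = sum_s rate_s * pop_is``. Conserves
    the observed total.
    """
    O_s = np.asarray(stratum_observed_totals, dtype=float)
    P = np.asarray(stratum_area_populations, dtype=float)  # (n_areas, n_strata)
    if P.ndim != 2 or P.shape[1] != O_s.size:
        raise ValueError("stratum tables are inconsistent")
    pop_s = P.sum(axis=0)
    bad = (pop_s == 0) & (O_s > 0)
    if np.any(bad):
        raise ValueError(
            f"stratum {np.flatnonzero(bad).tolist()} has observed events but zero population"
        )
    rates = np.divide(O_s, pop_s, out=np.zeros_like(O_s), where=pop_s > 0)
    return P @ rates


def standardized_ratio(observed: np.ndarray, expected: np.ndarray, area_ids=None) -> np.ndarray:
    """SR_i = O_i / e_i, the crude relative risk."""
    O = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if np.any(e <= 0):
        k = int(np.flatnonzero(e <= 0)[0])
        name = area_ids[k] if area_ids is not None else k
        raise ValueError(f"non-positive expected count for area {name!r}")
    return O / e


# ---------------------------------------------------------------------------
# AreaTable
# ---------------------------------------------------------------------------

@dataclass
class AreaTable:
    """Per-area observed and expected counts for the two outcomes.

    ``observed`` and ``expected`` have shape (n_areas, 2): column 0 is
    outcome 1 (e.g. offenders), column 1 is outcome 2 (e.g. offenses).
    """

    area_ids: list
    observed: np.ndarray
    expected: np.ndarray
    population: np.ndarray | None = None

    def __post_init__(self):
        self.area_ids = [str(a) for a in self.area_ids]
        self.observed = np.asarray(self.observed)
        self.expected = np.asarray(self.expected, dtype=float)
        n = len(self.area_ids)
        if self.observed.shape != (n, N_OUTCOMES) or self.expected.shape != (n, N_OUTCOMES):
            raise ValueError("observed/expected must have shape (n_areas, 2)")
        if np.any(self.observed < 0) or not np.allclose(self.observed, np.round(self.observed)):
            raise ValueError("observed counts must be non-negative integers")
        self.observed = np.round(self.observed).astype(np.int64)
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=float)

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def validate_for_model(self) -> None:
        if np.any(self.expected <= 0):
            bad = [self.area_ids[k] for k in np.flatnonzero((self.expected <= 0).any(axis=1))]
            raise ValueError(f"non-positive expected counts for area(s) {bad}")

    def drop_unmodellable(self) -> tuple["AreaTable", list]:
        """Remove areas with any non-positive expected count (e.g. zero
        population); returns the reduced table and the excluded ids."""
        keep = (self.expected > 0).all(axis=1)
        excluded = [self.area_ids[k] for k in np.flatnonzero(~keep)]
        if excluded:
            logger.warning("SCSM-W04 excluding %d area(s) with e<=0: %s",
                           len(excluded), excluded)
        sub = AreaTable(
            area_ids=[a for a, k in zip(self.area_ids, keep) if k],
            observed=self.observed[keep],
            expected=self.expected[keep],
            population=None if self.population is None else self.population[keep],
        )
        return sub, excluded

    def standardized_ratios(self) -> np.ndarray:
        return np.column_stack([
            standardized_ratio(self.observed[:, k], self.expected[:, k], self.area_ids)
            for k in range(N_OUTCOMES)
        ])

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        sr = self.standardized_ratios()
        df = pd.DataFrame({
            "area_id": self.area_ids,
            "observed_1": self.observed[:, 0],
            "observed_2": self.observed[:, 1],
            "expected_1": self.expected[:, 0],
            "expected_2": self.expected[:, 1],
            "sr_1": sr[:, 0],
            "sr_2": sr[:, 1],
        })
        if self.population is not None:
            df["population"] = self.population
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AreaTable":
        df = pd.read_csv(path, dtype={"area_id": str})
        return cls(
            area_ids=df["area_id"].tolist(),
            observed=df[["observed_1", "observed_2"]].to_numpy(),
            expected=df[["expected_1", "expected_2"]].to_numpy(),
            population=df["population"].to_numpy() if "population" in df else None,
        )
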