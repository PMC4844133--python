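"""Pairwise weight matrices for network autocorrelation models.

Four kinds of matrix enter the analysis:

* a socio-linguistic *affinity* matrix, derived from language-phylogeny and
  colonial divergence times (years) via the linear transform
  ``(max(D) - D_ij) / max(D)``;
* a spatial *proximity* affinity, the same transform applied to great-circle
  distances between country centroids;
* a language *adjacency* (1 where two countries' majority languages diverged
  less than a mutual-intelligibility threshold, by default 1000 years),
  row-normalized;
* a spatial adjacency (shared land border, supplied as data, never computed
  from geometry), row-normalized.

Affinity entries are expected correlations in [0, 1] with unit diagonal;
row-normalized adjacencies have row sums of exactly 0 (isolates) or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: tolerance inside which a distance equal to the adjacency threshold counts
#: as "not less than" (deterministic strict inequality)
THRESHOLD_TOL = 1e-9

AFFINITY = "affinity"
ROW_NORMALIZED = "row_normalized_adjacency"

#: canonical matrix labels, in the field's shorthand
SOL_AFF = "SoL_aff"
S_PROX = "S_prox"
L_ADJ = "L_adj"
S_ADJ = "S_adj"
ALL_LABELS = (SOL_AFF, S_PROX, L_ADJ, S_ADJ)


class InputError(ValueError):
    """Raised for malformed or out-of-range user input."""


class DegenerateInputError(ValueError):
    """Raised when an input is valid in type but unusable (e.g. all-zero distances)."""


@dataclass(frozen=True)
class NodeSet:
    """An ordered set of country identifiers with optional centroids.

    Parameters
    ----------
    ids
        Unique country identifiers, order defines matrix row/column order.
    coords
        Optional mapping id -> (lat, lon) in decimal degrees.
    language_id
        Optional mapping id -> language label.
    """

    ids: tuple[str, ...]
    coords: Mapping[str, tuple[float, float]] | None = None
    language_id: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        if len(set(ids)) != len(ids):
            raise InputError("node ids must be unique")
        object.__setattr__(self, "ids", ids)
        if self.coords is not None:
            for nid, (lat, lon) in self.coords.items():
                if not (abs(lat) <= 90 and abs(lon) <= 180):
                    raise InputError(f"coordinate out of range for node {nid!r}: ({lat}, {lon})")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, keep: Sequence[str]) -> np.ndarray:
        pos = {nid: i for i, nid in enumerate(self.ids)}
        try:
            return np.array([pos[k] for k in keep], dtype=int)
        except KeyError as exc:
            raise InputError(f"unknown node id {exc.args[0]!r}") from None


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances over a NodeSet.

    ``units`` is ``"years"`` for socio-linguistic divergence times or ``"km"``
    for great-circle distances.
    """

    nodes: NodeSet
    values: np.ndarray
    units: str = "years"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if v.shape != (n, n):
            raise InputError(f"distance matrix shape {v.shape} does not match {n} nodes")
        if not np.allclose(v, v.T, atol=1e-8):
            raise InputError("distance matrix must be symmetric")
        if (v < 0).any():
            raise InputError("distances must be nonnegative")
        if not np.allclose(np.diag(v), 0.0):
            raise InputError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class WeightMatrix:
    """A square autocorrelation weight matrix.

    ``kind`` is either :data:`AFFINITY` (distance-derived expected
    correlations) or :data:`ROW_NORMALIZED` (row-normalized binary adjacency).
    """

    nodes: NodeSet
    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if v.shape != (n, n):
            raise InputError(f"weight matrix shape {v.shape} does not match {n} nodes")
        if self.kind not in (AFFINITY, ROW_NORMALIZED):
            raise InputError(f"unknown weight-matrix kind {self.kind!r}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.nodes)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float,
                 radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between two points given in decimal degrees."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (abs(lat) <= 90 and abs(lon) <= 180):
            raise InputError(f"coordinate out of range: ({lat}, {lon})")
    if radius <= 0:
        raise InputError("radius must be positive")
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return float(2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def spatial_distance_matrix(nodes: NodeSet, radius: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between node centroids.

    Centroid overrides (e.g. population-weighted points for very large
    countries) are simply supplied in ``nodes.coords`` by the caller.
    """
    if nodes.coords is None:
        raise InputError("nodes carry no coordinates")
    missing = [nid for nid in nodes.ids if nid not in nodes.coords]
    if missing:
        raise InputError(f"missing coordinates for node(s): {missing}")
    lat = np.radians([nodes.coords[nid][0] for nid in nodes.ids])
    lon = np.radians([nodes.coords[nid][1] for nid in nodes.ids])
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return DistanceMatrix(nodes=nodes, values=d, units="km")


def distance_to_affinity(d: DistanceMatrix, label: str = "") -> WeightMatrix:
    """Expected-correlation affinity ``(max(D) - D_ij) / max(D)``.

    The transform maps the zero diagonal to 1 and the maximally distant pair
    to 0, and is invariant to rescaling the distances.
    """
    dmax = float(d.values.max())
    if dmax <= 0:
        raise DegenerateInputError("all distances are zero; affinity transform undefined")
    w = (dmax - d.values) / dmax
    return WeightMatrix(nodes=d.nodes, values=w, kind=AFFINITY, label=label)


def adjacency_from_distance(d: DistanceMatrix, threshold: float) -> np.ndarray:
    """Binary adjacency: 1 where ``D_ij < threshold`` (strictly) and i != j.

    Distances within :data:`THRESHOLD_TOL` of the threshold count as *not*
    less than it, so the boundary is deterministic under floating-point noise.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    a = (d.values < threshold - THRESHOLD_TOL).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


def row_normalize(a: np.ndarray, nodes: NodeSet, label: str = "") -> WeightMatrix:
    """Divide each nonzero row by its sum; isolate (all-zero) rows stay zero."""
    a = np.asarray(a, dtype=float)
    if (a < 0).any():
        raise InputError("adjacency entries must be nonnegative")
    sums = a.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sums > 0, a / np.where(sums > 0, sums, 1.0), 0.0)
    return WeightMatrix(nodes=nodes, values=w, kind=ROW_NORMALIZED, label=label)


def subset_weights(w: WeightMatrix, keep: Sequence[str]) -> WeightMatrix:
    """Restrict a weight matrix to a subset of nodes.

    Affinity matrices are sliced as-is: the transform is *not* recomputed on
    the subset, so affinities stay comparable across time bins that retain
    different country sets. Row-normalized adjacencies are sliced and then
    re-normalized, since dropping a node changes its neighbors' weights.
    """
    keep = list(keep)
    if not keep:
        raise InputError("keep must be a nonempty subset of nodes")
    idx = w.nodes.index_of(keep)
    sub_nodes = NodeSet(
        ids=tuple(keep),
        coords={k: w.nodes.coords[k] for k in keep if k in w.nodes.coords} if w.nodes.coords else None,
        language_id={k: w.nodes.language_id[k] for k in keep if k in w.nodes.language_id}
        if w.nodes.language_id else None,
    )
    vals = w.values[np.ix_(idx, idx)]
    if w.kind == ROW_NORMALIZED:
        # slicing breaks the row-sum invariant; rebuild it
        return row_normalize(vals, sub_nodes, label=w.label)
    return WeightMatrix(nodes=sub_nodes, values=vals, kind=AFFINITY, label=w.label)


# ---------------------------------------------------------------------------
# CSV I/O — labeled square matrices (row labels == column labels)

def read_square_csv(path: str | Path, units: str = "years") -> DistanceMatrix:
    """Read a labeled square distance matrix CSV (header row + row labels)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise InputError("row labels do not match column labels")
    nodes = NodeSet(ids=tuple(df.index))
    return DistanceMatrix(nodes=nodes, values=df.to_numpy(dtype=float), units=units)


def read_adjacency_csv(path: str | Path) -> tuple[NodeSet, np.ndarray]:
    """Read a labeled binary adjacency matrix CSV (e.g. shared borders)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise InputError("row labels do not match column labels")
    a = df.to_numpy(dtype=float)
    if not np.isin(a, (0.0, 1.0)).all():
        raise InputError("adjacency matrix entries must be 0 or 1")
    return NodeSet(ids=tuple(df.index)), a


def read_centroids_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a key-value CSV of centroids/overrides with columns id, lat, lon."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("id", "lat", "lon"):
        if needed not in cols:
            raise InputError(f"centroid file missing column {needed!r}")
    return {
        str(r[cols["id"]]): (float(r[cols["lat"]]), float(r[cols["lon"]]))
        for _, r in df.iterrows()
    }


def write_weight_csv(w: WeightMatrix, path: str | Path) -> None:
    """Write a weight matrix as a labeled CSV, rows ordered by node id order."""
    df = pd.DataFrame(w.values, index=list(w.nodes.ids), columns=list(w.nodes.ids))
    df.to_csv(path, float_format="%.12g")


def read_weight_csv(path: str | Path, kind: str, label: str = "") -> WeightMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    nodes = NodeSet(ids=tuple(df.index))
    return WeightMatrix(nodes=nodes, values=df.to_numpy(dtype=float), kind=kind, label=label)
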