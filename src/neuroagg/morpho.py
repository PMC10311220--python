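"""Sholl profiles, branch morphometrics, and zone densities for traced arbors.

An arbor is a rooted tree of 3-D points with SWC semantics: the root is
the soma, every other node points at its parent, and an edge is the
straight segment between a node and its parent.  Sholl analysis counts
exact circle-segment intersection points at increasing radii from the
soma.  Branch morphometrics follow hand-scoring conventions for
astrocytes: main branches originate at the soma (junction-free stubs
below a length floor are excluded), a junction is an internal branch
point whose side process is at least 5 um, and total process length
sums every traced segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Arbor",
    "ShollParams",
    "ShollProfile",
    "MorphometryParams",
    "MorphometricsResult",
    "ZoneSpec",
    "ZoneDensityResult",
    "sholl_profile",
    "branch_morphometrics",
    "zone_density",
    "read_swc",
    "write_swc",
]


@dataclass
class Arbor:
    """Rooted tree of 3-D points (SWC semantics) with a soma node.

    ``ids``/``parents`` are per-node SWC identifiers (parent -1 for the
    root), ``xyz`` the coordinates in micrometres, ``types`` the SWC
    type codes (only the soma's matters), ``radii`` per-node radii.
    """

    ids: np.ndarray
    xyz: np.ndarray
    parents: np.ndarray
    types: Optional[np.ndarray] = None
    radii: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        n = self.ids.size
        if self.xyz.shape != (n, 3) or self.parents.size != n:
            raise ValueError("ids, xyz and parents must agree in length")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if self.types is None:
            self.types = np.full(n, 3, dtype=int)
        if self.radii is None:
            self.radii = np.ones(n, dtype=float)
        roots = np.flatnonzero(self.parents == -1)
        if roots.size != 1:
            raise ValueError("arbor must have exactly one root (the soma)")
        self._root_index = int(roots[0])
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("node ids must be unique")
        for p in self.parents:
            if p != -1 and int(p) not in self._index:
                raise ValueError(f"parent id {p} does not resolve")
        # acyclicity: walk each node to the root, bounded by n steps
        for k in range(n):
            steps, cur = 0, k
            while self.parents[cur] != -1:
                cur = self._index[int(self.parents[cur])]
                steps += 1
                if steps > n:
                    raise ValueError("arbor contains a cycle")

    @property
    def soma_index(self) -> int:
        return self._root_index

    @property
    def soma_id(self) -> int:
        return int(self.ids[self._root_index])

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self._root_index]

    @property
    def n_nodes(self) -> int:
        return int(self.ids.size)

    def edges(self) -> np.ndarray:
        """(n_edges, 2) array of (parent_index, child_index)."""
        child = np.flatnonzero(self.parents != -1)
        parent = np.array([self._index[int(p)] for p in self.parents[child]])
        return np.column_stack([parent, child])

    def children_map(self) -> Dict[int, List[int]]:
        cm: Dict[int, List[int]] = {k: [] for k in range(self.n_nodes)}
        for p, c in self.edges():
            cm[int(p)].append(int(c))
        return cm


@dataclass
class ShollParams:
    step: float = 5.0
    r_max: Optional[float] = None  # default: max node distance from soma

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.r_max is not None and self.r_max < self.step:
            raise ValueError("r_max must be >= step")


@dataclass
class ShollProfile:
    radii: np.ndarray
    crossings: np.ndarray


@dataclass
class MorphometryParams:
    min_junction_branch: float = 5.0
    min_main_branch: float = 10.0

    def __post_init__(self) -> None:
        if self.min_junction_branch <= 0 or self.min_main_branch <= 0:
            raise ValueError("length thresholds must be positive")


@dataclass
class MorphometricsResult:
    n_main_branches: int
    longest_main_branch: float
    total_process_length: float
    n_junctions: int


@dataclass
class ZoneSpec:
    """Annular analysis zones around a circular aggregate.

    Band edges are distances from the aggregate *perimeter*, so a band
    (inner, outer) is the annulus radius+inner .. radius+outer around
    the centre.
    """

    aggregate_center: Tuple[float, float] = (0.0, 0.0)
    aggregate_radius: float = 250.0
    bands: Sequence[Tuple[float, float]] = ((50.0, 200.0), (200.0, 400.0), (400.0, 600.0))

    def __post_init__(self) -> None:
        if self.aggregate_radius <= 0:
            raise ValueError("aggregate_radius must be positive")
        prev = -np.inf
        for inner, outer in self.bands:
            if not inner < outer:
                raise ValueError("each band needs inner < outer")
            if inner < prev:
                raise ValueError("bands must be non-overlapping and increasing")
            prev = outer


@dataclass
class ZoneDensityResult:
    table: pd.DataFrame  # columns: inner_um, outer_um, count, area_mm2, density_per_mm2
    n_unassigned: int


def sholl_profile(arbor: Arbor, params: ShollParams | None = None) -> ShollProfile:
    """Exact circle-crossing counts at radii step, 2*step, ... from the soma.

    For each radius the intersection points of the circle (sphere in 3-D
    coordinates, evaluated on the tree's own geometry) with every edge
    segment are solved exactly; coincident points -- a tangency, or a
    vertex on the circle shared by its incident edges -- count once.
    Radii beyond the arbor's extent report zero; a soma-only arbor
    yields an all-zero profile.
    """
    params = params or ShollParams()
    center = arbor.soma_xyz
    dists = np.linalg.norm(arbor.xyz - center, axis=1)
    r_max = params.r_max if params.r_max is not None else float(dists.max())
    n_radii = int(np.floor(r_max / params.step + 1e-9))
    radii = params.step * np.arange(1, max(n_radii, 0) + 1)
    edges = arbor.edges()
    crossings = np.zeros(radii.size, dtype=int)
    if edges.size == 0 or radii.size == 0:
        return ShollProfile(radii, crossings)

    p1 = arbor.xyz[edges[:, 0]] - center
    p2 = arbor.xyz[edges[:, 1]] - center
    v = p2 - p1
    a = np.einsum("ij,ij->i", v, v)
    b = 2.0 * np.einsum("ij,ij->i", p1, v)
    d2 = np.einsum("ij,ij->i", p1, p1)

    t_eps = 1e-9
    for k, r in enumerate(radii):
        c = d2 - r * r
        points: set = set()
        disc = b * b - 4.0 * a * c
        scale = np.maximum(b * b, np.abs(4.0 * a * c)) + 1.0
        for e in np.flatnonzero((disc > -1e-12 * scale) & (a > 0)):
            if disc[e] <= 1e-12 * scale[e]:
                roots = [-b[e] / (2.0 * a[e])]  # tangency: double root, one point
            else:
                sq = np.sqrt(disc[e])
                roots = [(-b[e] - sq) / (2.0 * a[e]), (-b[e] + sq) / (2.0 * a[e])]
            for t in roots:
                if -t_eps <= t <= 1.0 + t_eps:
                    pt = p1[e] + t * v[e]
                    points.add(tuple(np.round(pt, 6)))
        crossings[k] = len(points)
    return ShollProfile(radii, crossings)


def _subtree_depths(arbor: Arbor) -> Tuple[np.ndarray, Dict[int, List[int]], np.ndarray]:
    """Max path length from each node to a terminal of its subtree.

    Returns (depths, children map, edge length to parent per node).
    Iterative post-order so deep tracings don't hit the recursion limit.
    """
    cm = arbor.children_map()
    n = arbor.n_nodes
    edge_len = np.zeros(n)
    for p, c in arbor.edges():
        edge_len[c] = np.linalg.norm(arbor.xyz[c] - arbor.xyz[p])
    depths = np.zeros(n)
    order: List[int] = []
    stack = [arbor.soma_index]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(cm[node])
    for node in reversed(order):
        kids = cm[node]
        if kids:
            depths[node] = max(edge_len[c] + depths[c] for c in kids)
    return depths, cm, edge_len


def branch_morphometrics(
    arbor: Arbor, params: MorphometryParams | None = None
) -> MorphometricsResult:
    """Main-branch counts and lengths, junction count, total process length.

    Main branches are the subtrees rooted at soma children, measured
    from the soma to their farthest terminal; a candidate is excluded
    when it bears no qualifying junction and its extent is below
    ``min_main_branch``.  A junction is a non-soma node with >= 2
    children whose side path (second-longest child path, measured to the
    farthest terminal of that side subtree) is at least
    ``min_junction_branch``.  Total process length sums every traced
    segment, including excluded stubs.
    """
    params = params or MorphometryParams()
    depths, cm, edge_len = _subtree_depths(arbor)
    soma = arbor.soma_index

    # qualifying junctions per node
    junction_nodes = []
    for node in range(arbor.n_nodes):
        if node == soma:
            continue
        kids = cm[node]
        if len(kids) >= 2:
            paths = sorted((edge_len[c] + depths[c] for c in kids), reverse=True)
            if paths[1] >= params.min_junction_branch:
                junction_nodes.append(node)
    junction_set = set(junction_nodes)

    # junctions per main-branch subtree
    n_main = 0
    longest = 0.0
    for child in cm[soma]:
        extent = edge_len[child] + depths[child]
        has_junction = False
        stack = [child]
        while stack:
            node = stack.pop()
            if node in junction_set:
                has_junction = True
                break
            stack.extend(cm[node])
        if has_junction or extent >= params.min_main_branch:
            n_main += 1
            longest = max(longest, extent)

    total = float(edge_len.sum())
    return MorphometricsResult(
        n_main_branches=n_main,
        longest_main_branch=float(longest),
        total_process_length=total,
        n_junctions=len(junction_nodes),
    )


def zone_density(points: np.ndarray, spec: ZoneSpec | None = None) -> ZoneDensityResult:
    """Cell densities in annular zones around a circular aggregate.

    Each point is assigned by its distance to the aggregate perimeter,
    d = |point - center| - radius; band membership is inner <= d < outer.
    Densities are counts over the analytic annulus area in mm^2.  Points
    inside the aggregate (d < 0) or outside all bands are unassigned
    (the former with a warning).
    """
    spec = spec or ZoneSpec()
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    center = np.asarray(spec.aggregate_center, dtype=float)
    if points.size:
        d = np.linalg.norm(points - center, axis=1) - spec.aggregate_radius
    else:
        d = np.empty(0)
    if np.any(d < 0):
        warnings.warn(
            f"{int(np.sum(d < 0))} point(s) fall inside the aggregate; left unassigned",
            stacklevel=2,
        )
    rows = []
    assigned = np.zeros(d.size, dtype=bool)
    for inner, outer in spec.bands:
        in_band = (d >= inner) & (d < outer)
        assigned |= in_band
        r_in = spec.aggregate_radius + inner
        r_out = spec.aggregate_radius + outer
        area_mm2 = np.pi * (r_out**2 - r_in**2) / 1e6
        count = int(in_band.sum())
        rows.append(
            {
                "inner_um": inner,
                "outer_um": outer,
                "count": count,
                "area_mm2": area_mm2,
                "density_per_mm2": count / area_mm2,
            }
        )
    return ZoneDensityResult(
        table=pd.DataFrame(rows), n_unassigned=int(d.size - assigned.sum())
    )


def read_swc(path) -> Arbor:
    """Read a standard 7-column SWC file (id, type, x, y, z, radius, parent)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(parts)
    if not rows:
        raise ValueError("empty SWC file")
    arr = np.array(rows, dtype=float)
    return Arbor(
        ids=arr[:, 0].astype(int),
        types=arr[:, 1].astype(int),
        xyz=arr[:, 2:5],
        radii=arr[:, 5],
        parents=arr[:, 6].astype(int),
    )


def write_swc(arbor: Arbor, path) -> None:
    """Write an arbor as standard SWC with fixed 6-decimal formatting."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(arbor.n_nodes):
            fh.write(
                f"{arbor.ids[k]} {arbor.types[k]} "
                f"{arbor.xyz[k, 0]:.6f} {arbor.xyz[k, 1]:.6f} {arbor.xyz[k, 2]:.6f} "
                f"{arbor.radii[k]:.6f} {arbor.parents[k]}\n"
            )
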