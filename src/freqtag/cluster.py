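"""Sensor-space cluster-mass permutation tests.

Electrode-wise t-tests are thresholded (per tail), supra-threshold
electrodes are grouped into connected components of a triangulation-derived
adjacency graph (Delaunay on the 2-D projected montage), components smaller
than ``min_size`` electrodes are discarded, and each surviving cluster's
mass (summed t) is ranked against the permutation distribution of the
*maximum* cluster mass over the scalp (strong family-wise error control).
Paired designs permute by sign-flipping within-subject difference maps;
independent designs by reshuffling group labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps
from scipy.spatial import Delaunay, QhullError

from .design import InvalidParameterError
from .layout import SensorLayout

__all__ = ["AdjacencyGraph", "Cluster", "ClusterResult", "build_adjacency", "cluster_mass_test"]


class DegenerateLayoutError(ValueError):
    """Layout positions unsuitable for triangulation."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric electrode neighbourhood structure."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]  # i < j, unique

    @property
    def matrix(self) -> np.ndarray:
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            m[i, j] = m[j, i] = True
        return m

    def neighbour_lists(self) -> list[np.ndarray]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(n), dtype=int) for n in nbrs]

    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d


def build_adjacency(layout: SensorLayout | np.ndarray) -> AdjacencyGraph:
    """Neighbours via Delaunay triangulation of the projected positions
    (edges = triangle sides), the standard triangulation method for scalp
    montages."""
    pos = layout.positions2d if isinstance(layout, SensorLayout) else np.asarray(layout, float)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 3:
        raise DegenerateLayoutError("need >= 3 two-dimensional positions")
    if len(np.unique(pos.round(12), axis=0)) != len(pos):
        raise DegenerateLayoutError("duplicate electrode positions")
    try:
        tri = Delaunay(pos)
    except QhullError as err:
        raise DegenerateLayoutError(f"triangulation failed: {err}") from err
    if tri.simplices.size == 0:
        raise DegenerateLayoutError("collinear positions admit no triangulation")
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return AdjacencyGraph(n_nodes=len(pos), edges=tuple(sorted(edges)))


@dataclass(frozen=True)
class Cluster:
    electrodes: tuple[int, ...]
    mass: float
    p: float
    sign: int  # +1 or -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_perm: int
    t_map: np.ndarray
    threshold: float
    tail: str
    cluster_alpha: float

    def significant(self, cluster_alpha: float | None = None) -> list[Cluster]:
        a = self.cluster_alpha if cluster_alpha is None else cluster_alpha
        return [c for c in self.clusters if c.p <= a]


def _components(mask: np.ndarray, nbrs: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of the supra-threshold electrode subgraph."""
    comps: list[np.ndarray] = []
    seen = np.zeros(len(mask), dtype=bool)
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in nbrs[node]:
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(np.array(sorted(comp), dtype=int))
    return comps


def _cluster_masses(
    t_map: np.ndarray,
    thr: float,
    tails: tuple[int, ...],
    min_size: int,
    nbrs: list[np.ndarray],
) -> list[tuple[np.ndarray, float, int]]:
    out = []
    for sign in tails:
        mask = t_map > thr if sign > 0 else t_map < -thr
        if np.count_nonzero(mask) < min_size:
            continue
        for comp in _components(mask, nbrs):
            if len(comp) >= min_size:
                out.append((comp, float(t_map[comp].sum()), sign))
    return out


def _paired_t_maps(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t-maps of sign-flipped difference maps (perms x elec)."""
    n = diffs.shape[0]
    msq = (diffs**2).mean(axis=0)  # invariant under sign flips
    means = signs @ diffs / n
    var = (msq - means**2) * n / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return means / np.sqrt(var / n)


def _independent_t_maps(x: np.ndarray, member: np.ndarray, n1: int) -> np.ndarray:
    """Pooled-variance two-sample t-maps for permuted group labels.

    ``member``: perms x subjects boolean, True = group 1, each row summing
    to ``n1``."""
    n = x.shape[0]
    n2 = n - n1
    tot = x.sum(axis=0)
    tot2 = (x**2).sum(axis=0)
    s1 = member.astype(float) @ x
    ss1 = member.astype(float) @ (x**2)
    s2, ss2 = tot - s1, tot2 - ss1
    m1, m2 = s1 / n1, s2 / n2
    sse = (ss1 - n1 * m1**2) + (ss2 - n2 * m2**2)
    var_p = np.maximum(sse / (n - 2), np.finfo(float).tiny)
    return (m1 - m2) / np.sqrt(var_p * (1.0 / n1 + 1.0 / n2))


def cluster_mass_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: AdjacencyGraph,
    design: Literal["paired", "independent"] = "paired",
    tail: Literal["one", "two"] = "one",
    alpha: float = 0.05,
    cluster_alpha: float | None = None,
    min_size: int = 4,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster-mass permutation test of electrode maps ``a`` vs ``b``.

    ``a``/``b`` are subjects x electrodes (matched order for paired
    designs; two independent groups otherwise).  ``alpha`` is the
    per-electrode, per-tail threshold level; one-tailed tests look for
    positive (a > b) clusters only, two-tailed tests track positive and
    negative clusters separately at ``alpha`` per tail (e.g. 0.025 each).
    Cluster p = (1 + #{null max-mass >= |mass|}) / (n_perm + 1).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if not (0 < alpha <= 0.5):
        raise InvalidParameterError("alpha must be in (0, 0.5]")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise InvalidParameterError("inputs must be subjects x electrodes with equal electrodes")
    if a.shape[1] != adjacency.n_nodes:
        raise InvalidParameterError("electrode count does not match adjacency graph")
    if cluster_alpha is None:
        cluster_alpha = alpha
    rng = rng if rng is not None else np.random.default_rng()
    tails: tuple[int, ...] = (1,) if tail == "one" else (1, -1)
    nbrs = adjacency.neighbour_lists()

    if design == "paired":
        if a.shape[0] != b.shape[0]:
            raise InvalidParameterError("paired design needs matched subject counts")
        diffs = a - b
        n = diffs.shape[0]
        df = n - 1
        thr = float(sps.t.ppf(1 - alpha, df))
        t_obs = _paired_t_maps(diffs, np.ones((1, n)))[0]
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_null = _paired_t_maps(diffs, signs)
    elif design == "independent":
        n1, n2 = a.shape[0], b.shape[0]
        if min(n1, n2) < 2:
            raise InvalidParameterError("independent design needs >= 2 subjects per group")
        x = np.vstack([a, b])
        n = n1 + n2
        df = n - 2
        thr = float(sps.t.ppf(1 - alpha, df))
        obs_member = np.zeros((1, n), dtype=bool)
        obs_member[0, :n1] = True
        t_obs = _independent_t_maps(x, obs_member, n1)[0]
        member = np.zeros((n_perm, n), dtype=bool)
        for p in range(n_perm):
            member[p, rng.permutation(n)[:n1]] = True
        t_null = _independent_t_maps(x, member, n1)
    else:
        raise InvalidParameterError("design must be 'paired' or 'independent'")

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        masses = _cluster_masses(t_null[p], thr, tails, min_size, nbrs)
        if masses:
            null_max[p] = max(abs(m) for _, m, _ in masses)

    clusters = []
    for comp, mass, sign in _cluster_masses(t_obs, thr, tails, min_size, nbrs):
        p_val = (1 + int(np.sum(null_max >= abs(mass)))) / (n_perm + 1)
        clusters.append(Cluster(electrodes=tuple(int(i) for i in comp), mass=mass, p=p_val, sign=sign))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters=clusters,
        n_perm=n_perm,
        t_map=t_obs,
        threshold=thr,
        tail=tail,
        cluster_alpha=float(cluster_alpha),
    )
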