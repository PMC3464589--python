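"""Voxel co-expression: correlation pairs, thresholding, networks, modules.

Two probes are compared by the Pearson correlation of their expression
energies over the voxels of a brain domain (whole brain or a single
region).  The cumulative pair-frequency curve over rho typically follows a
negative sigmoid; the working threshold rho_T sits in its right flattened
tail, formalized here as the smallest grid value (>= a floor of 0.8, the
smallest threshold used in practice) whose survivor fraction drops below a
target.  Networks use strict rho > rho_T edges; modules come from average-
linkage clustering of region-level profiles at distance 1 - rho.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .expression import ExpressionVolume, RegionOntology

logger = logging.getLogger(__name__)


@dataclass
class CorrelationPair:
    probe_a: str
    probe_b: str
    rho: float
    domain: str = "brain"

    def __post_init__(self) -> None:
        if self.probe_b < self.probe_a:
            self.probe_a, self.probe_b = self.probe_b, self.probe_a
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| > 1")


@dataclass
class ExpressionModule:
    module_id: int
    probe_ids: list[str]
    focal_regions: list[int] = field(default_factory=list)


def pearson(u, v) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(u) == 0 or np.std(v) == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def correlate_pairs(volumes: list[ExpressionVolume], ontology: RegionOntology,
                    domain: int | str = "brain",
                    level: str = "fine") -> list[CorrelationPair]:
    """All unordered probe pairs with rho over the domain's voxels.

    Pairs with undefined rho (constant vector) are dropped and logged.
    """
    mask = ontology.mask(domain, level)
    if not mask.any():
        raise ValueError(f"domain {domain!r} has no voxels")
    if len(volumes) < 2:
        raise ValueError("need at least two probes")
    vecs = np.stack([v.energy[mask] for v in volumes])
    ids = [v.probe_id for v in volumes]
    sd = vecs.std(axis=1)
    keep = sd > 0
    dropped = [i for i, k in zip(ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant probes in domain %r", len(dropped), domain)
    r = np.corrcoef(vecs[keep])
    kept_ids = [i for i, k in zip(ids, keep) if k]
    dom = str(domain)
    return [
        CorrelationPair(kept_ids[i], kept_ids[j], float(r[i, j]), dom)
        for i, j in combinations(range(len(kept_ids)), 2)
    ]


def select_threshold(rhos, q_target: float = 0.01, grid_step: float = 0.05,
                     floor: float = 0.8):
    """Pick rho_T from the survivor-fraction curve.

    Returns ``(rho_T, curve)`` where ``curve`` is a list of
    ``(grid value, fraction of pairs with rho >= value)`` for inspection.
    rho_T is the smallest grid multiple >= ``floor`` whose survivor
    fraction is <= ``q_target``; if none qualifies, ``1 - grid_step`` is
    returned with a warning.
    """
    rhos = np.asarray(rhos, dtype=float)
    if rhos.size == 0:
        raise ValueError("empty rho vector")
    if not 0 < q_target < 1:
        raise ValueError("q_target must be in (0, 1)")
    grid = np.arange(np.ceil(floor / grid_step) * grid_step, 1.0,
                     grid_step).round(10)
    curve = [(float(g), float(np.mean(rhos >= g))) for g in grid]
    for g, frac in curve:
        if frac <= q_target:
            return g, curve
    warnings.warn(
        "no grid value reaches the target survivor fraction; using 1 - grid_step",
        stacklevel=2,
    )
    return float(round(1.0 - grid_step, 10)), curve


def build_network(pairs: list[CorrelationPair], rho_t: float,
                  min_clique: int = 3) -> tuple[nx.Graph, list[set], list[list[str]]]:
    """Graph of pairs with rho strictly above rho_T.

    Returns the graph, its connected components (as node sets) and maximal
    cliques of size >= ``min_clique``.
    """
    g = nx.Graph()
    for p in pairs:
        if p.rho > rho_t:
            g.add_edge(p.probe_a, p.probe_b, rho=p.rho, domain=p.domain)
    comps = [set(c) for c in nx.connected_components(g)]
    cliques = [sorted(c) for c in nx.find_cliques(g) if len(c) >= min_clique]
    return g, comps, sorted(cliques)


def detect_modules(profiles, cut_k: int | None = None,
                   cut_height: float | None = 0.5) -> list[ExpressionModule]:
    """Agglomerative modules of correlated region-level profiles.

    ``profiles`` is a probes x regions DataFrame of mean energies.  Average
    linkage on distance 1 - rho; cut either at ``cut_k`` clusters or at
    ``cut_height``.  Constant-profile probes are excluded with a warning.
    Each module's focal regions are the region(s) with the highest
    module-mean energy.
    """
    sd = profiles.std(axis=1)
    const = profiles.index[sd == 0]
    if len(const):
        logger.warning("excluding %d constant-profile probes", len(const))
        profiles = profiles.drop(index=const)
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 non-constant probes")
    d = pdist(profiles.to_numpy(dtype=float), metric="correlation")
    z = average(d)
    if cut_k is not None:
        lab = fcluster(z, t=cut_k, criterion="maxclust")
    else:
        lab = fcluster(z, t=cut_height, criterion="distance")
    modules = []
    for m in sorted(set(lab)):
        probes = [p for p, l in zip(profiles.index, lab) if l == m]
        mean_profile = profiles.loc[probes].mean(axis=0)
        focal = mean_profile.idxmax()
        modules.append(ExpressionModule(int(m), probes, [focal]))
    return modules
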