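"""Spatial eigenfunction bases: dbMEM (PCNM) and asymmetric eigenvector maps.

dbMEM encodes geographic proximity: Euclidean distances between
Cartesian-projected sites are truncated at the longest minimum-spanning-tree
edge, Gower-centred and eigen-decomposed (the classical PCNM construction).
AEM encodes directed, current-driven connectivity: every edge of the directed
connectivity graph that lies on a path from an upstream origin to a site
contributes to that site's row of a sites-by-edges matrix, which is
weighted, centred and decomposed by SVD.

Both constructions are exposed as sklearn-style transformers whose fitted
``basis_`` is the sites x eigenfunctions matrix, and as thin module-level
functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from ._utils import EARTH_RADIUS_M, fix_sign
from .connectivity import ConnectivityMatrix
from .sites import SiteTable

ORIGIN = "__origin__"


def project_xy(sites: SiteTable) -> pd.DataFrame:
    """Local Cartesian projection about the site centroid, in metres.

    y = R dlat; x = R cos(lat_site) dlon, i.e. eastings are measured along
    each site's own parallel (so east-west distances stay exact at every
    latitude), which keeps pairwise Euclidean distances within 1% of the
    great-circle distance over a few-degree domain.
    """
    lon0 = sites.lon.mean()
    lat0 = sites.lat.mean()
    x = EARTH_RADIUS_M * np.cos(np.radians(sites.lat)) * np.radians(sites.lon - lon0)
    y = EARTH_RADIUS_M * np.radians(sites.lat - lat0)
    return pd.DataFrame({"x": x, "y": y}, index=pd.Index(sites.site_ids, name="site_id"))


@dataclass
class EigenBasis:
    """Sites x eigenfunctions matrix with eigenvalues, in decreasing order."""

    site_ids: list[str]
    basis: np.ndarray        # (n_sites, n_functions)
    eigenvalues: np.ndarray  # decreasing
    kind: str                # "dbMEM" | "AEM"
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.basis.shape != (len(self.site_ids), self.eigenvalues.size):
            raise ValueError("basis shape must be (n_sites, n_eigenvalues)")
        if self.eigenvalues.size > 1 and np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be in decreasing order")

    @property
    def n_functions(self) -> int:
        return self.eigenvalues.size

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{self.kind}{k + 1}" for k in range(self.n_functions)]
        return pd.DataFrame(self.basis, index=self.site_ids, columns=cols)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} eigenvalues={','.join(f'{v:.10g}' for v in self.eigenvalues)}\n")
            self.to_dataframe().to_csv(fh, index_label="site_id")


class DistanceBasedMEM(BaseEstimator):
    """dbMEM via the PCNM construction.

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree) are replaced by 4x the threshold; the
    resulting matrix is Gower-centred (-D*^2/2, double-centred) and
    eigen-decomposed.  Eigenvectors with eigenvalue > ``tol`` x the largest
    are retained and scaled by sqrt(eigenvalue).
    """

    def __init__(self, truncation: float | None = None, tol: float = 1e-8):
        self.truncation = truncation
        self.tol = tol

    def fit(self, xy, y=None) -> "DistanceBasedMEM":
        if isinstance(xy, pd.DataFrame):
            site_ids = list(xy.index)
            coords = xy.to_numpy(dtype=float)
        else:
            coords = np.asarray(xy, dtype=float)
            site_ids = [f"s{i}" for i in range(coords.shape[0])]
        n = coords.shape[0]
        if n < 3:
            raise ValueError("need at least 3 sites")
        D = squareform(pdist(coords))
        if np.any(D[np.triu_indices(n, 1)] == 0):
            raise ValueError("duplicate site coordinates")

        if self.truncation is None:
            mst = minimum_spanning_tree(D).toarray()
            t = float(mst.max())
        else:
            t = float(self.truncation)
        self.truncation_ = t

        Dstar = np.where(D > t, 4.0 * t, D)
        np.fill_diagonal(Dstar, 0.0)
        A = -0.5 * Dstar**2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        self.gower_trace_ = float(np.trace(G))

        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        keep = evals > self.tol * evals.max()
        evals, evecs = evals[keep], evecs[:, keep]
        basis = fix_sign(evecs) * np.sqrt(evals)[None, :]

        self.eigenvalues_ = evals
        self.basis_ = basis
        self.site_ids_ = site_ids
        self.result_ = EigenBasis(
            site_ids=site_ids,
            basis=basis,
            eigenvalues=evals,
            kind="dbMEM",
            meta={"truncation": t},
        )
        return self

    def fit_transform(self, xy, y=None) -> np.ndarray:
        return self.fit(xy).basis_


def dbmem(xy, truncation: float | None = None) -> EigenBasis:
    """PCNM-style dbMEM basis from site coordinates (metres)."""
    return DistanceBasedMEM(truncation=truncation).fit(xy).result_


# ---------------------------------------------------------------------------
# Directed connectivity graph and AEM
# ---------------------------------------------------------------------------


def graph_from_connectivity(C: ConnectivityMatrix, threshold: float = 0.0) -> nx.DiGraph:
    """Directed graph of connectivity links above ``threshold``.

    Off-diagonal entries C[i, j] > threshold become edges i -> j with weight
    C[i, j].  Sites with no incoming edge are fed by a virtual origin node
    with unit weight, so every node is reachable from upstream (required by
    the AEM construction).
    """
    ids = C.site_ids
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    n_real = 0
    for i, src in enumerate(ids):
        for j, dst in enumerate(ids):
            if i != j and C.probabilities[i, j] > threshold:
                g.add_edge(src, dst, weight=float(C.probabilities[i, j]))
                n_real += 1
    orphans = [v for v in ids if g.in_degree(v) == 0]
    if n_real == 0:
        import warnings

        warnings.warn("all-zero connectivity: AEM graph is a star from the origin only")
    g.add_node(ORIGIN)
    for v in orphans:
        g.add_edge(ORIGIN, v, weight=1.0)
    return g


class AEMTransformer(BaseEstimator):
    """Asymmetric eigenvector maps from a directed, weighted graph.

    Builds the sites x edges incidence matrix E (E[i, e] = 1 when edge e lies
    on at least one directed path from the origin to site i), multiplies each
    column by its edge weight, centres columns, and takes the SVD; the AEMs
    are the left singular vectors with singular value above ``tol``, with
    eigenvalues the squared singular values.

    ``include_origin_edges`` keeps the virtual-origin feed edges as columns
    of E (so sites differ by how they attach to the upstream source); setting
    it False drops them, which removes contrasts that reflect nothing but the
    arbitrary origin attachment (useful when several unconnected sites are
    fed directly by the origin).
    """

    def __init__(self, tol: float = 1e-8, include_origin_edges: bool = True):
        self.tol = tol
        self.include_origin_edges = include_origin_edges

    def fit(self, graph: nx.DiGraph, y=None) -> "AEMTransformer":
        if ORIGIN not in graph:
            raise ValueError("graph must contain the virtual origin node")
        sites = [v for v in graph.nodes if v != ORIGIN]
        reachable = nx.descendants(graph, ORIGIN)
        unreachable = [v for v in sites if v not in reachable]
        if unreachable:
            raise ValueError(f"sites unreachable from the origin: {unreachable}")

        edges = [
            (u, v, w)
            for u, v, w in graph.edges(data="weight")
            if self.include_origin_edges or u != ORIGIN
        ]
        # edge (u, v) lies on an origin->i path  iff  u is origin or reachable
        # from origin, and i is v or a descendant of v
        desc = {v: nx.descendants(graph, v) | {v} for v in graph.nodes}
        from_origin = reachable | {ORIGIN}
        E = np.zeros((len(sites), len(edges)))
        weights = np.empty(len(edges))
        for e, (u, v, w) in enumerate(edges):
            weights[e] = w
            if u in from_origin:
                for i, s in enumerate(sites):
                    if s in desc[v]:
                        E[i, e] = 1.0
        Ew = E * weights[None, :]
        Ec = Ew - Ew.mean(axis=0, keepdims=True)

        U, s, _ = np.linalg.svd(Ec, full_matrices=False)
        keep = s > self.tol * max(s.max(), 1.0) if s.size else np.array([], dtype=bool)
        U, s = U[:, keep], s[keep]
        basis = fix_sign(U)

        self.site_ids_ = sites
        self.edges_ = [(u, v) for u, v, _ in edges]
        self.nodes_to_edges_ = E
        self.basis_ = basis
        self.eigenvalues_ = s**2
        self.result_ = EigenBasis(
            site_ids=sites,
            basis=basis,
            eigenvalues=s**2,
            kind="AEM",
            meta={"n_edges": len(edges)},
        )
        return self

    def fit_transform(self, graph, y=None) -> np.ndarray:
        return self.fit(graph).basis_


def aem(graph: nx.DiGraph) -> EigenBasis:
    """AEM basis from a directed connectivity graph with a virtual origin."""
    return AEMTransformer().fit(graph).result_
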