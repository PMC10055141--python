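"""Connectome container, dynamics normalization and graph-theoretic quantities.

The controlled network is a weighted, undirected, connected structural
connectome. This module holds its in-memory representation and the
graph measures used downstream: the stabilized dynamics matrix, the
Laplacian pseudoinverse and effective-resistance (resistance distance)
matrix, random-walk commute times, network variance of a distribution
over nodes, and per-node predictors (degree, strength, participation
coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Connectome",
    "NormalizedSystem",
    "ResistanceMatrix",
    "normalize_adjacency",
    "effective_resistance",
    "commute_time",
    "map_to_distribution",
    "network_variance",
    "node_predictors",
]

_SYM_TOL = 1e-12


@dataclass
class Connectome:
    """Weighted undirected connectome with optional geometry.

    Parameters
    ----------
    adjacency
        N x N symmetric nonnegative weight matrix with zero diagonal
        (arbitrary streamline-density units).
    node_labels
        N region names.
    coords_euclidean
        N x 3 region centroids in mm (required by geometry-preserving
        nulls and distance-based statistics).
    coords_spherical
        N x 3 unit vectors on the sphere (required by spin tests).
    hemisphere
        N labels in {"left", "right"} (required by spin tests).
    """

    adjacency: np.ndarray
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]
    coords_euclidean: np.ndarray | None = None
    coords_spherical: np.ndarray | None = None
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("adjacency must be symmetric within 1e-12")
        a = 0.5 * (a + a.T)
        if np.any(np.diag(a) != 0.0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if np.any(a < 0.0):
            raise ValueError("adjacency weights must be nonnegative")
        self.adjacency = a
        n = a.shape[0]
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match adjacency size")
        n_comp, labels = connected_components(a > 0, directed=False)
        if n_comp > 1:
            comps = [np.flatnonzero(labels == k).tolist() for k in range(n_comp)]
            raise ValueError(
                f"graph is disconnected into {n_comp} components: {comps}"
            )
        for name in ("coords_euclidean", "coords_spherical"):
            c = getattr(self, name)
            if c is not None:
                c = np.asarray(c, dtype=float)
                if c.shape != (n, 3):
                    raise ValueError(f"{name} must be N x 3")
                setattr(self, name, c)
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere, dtype=object)
            if self.hemisphere.shape != (n,):
                raise ValueError("hemisphere must have one label per node")
            bad = set(self.hemisphere) - {"left", "right"}
            if bad:
                raise ValueError(f"hemisphere labels must be left/right, got {bad}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def strength(self) -> np.ndarray:
        """Weighted degree of each node."""
        return self.adjacency.sum(axis=1)

    @property
    def degree(self) -> np.ndarray:
        """Binary degree of each node."""
        return (self.adjacency > 0).sum(axis=1)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangular edges as (m x 2 index array, m weights)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] > 0
        edges = np.column_stack([iu[mask], ju[mask]])
        return edges, self.adjacency[edges[:, 0], edges[:, 1]]

    def with_adjacency(self, adjacency: np.ndarray) -> "Connectome":
        """Copy of this connectome with a replaced weight matrix."""
        return Connectome(
            adjacency=adjacency,
            node_labels=list(self.node_labels),
            coords_euclidean=None
            if self.coords_euclidean is None
            else self.coords_euclidean.copy(),
            coords_spherical=None
            if self.coords_spherical is None
            else self.coords_spherical.copy(),
            hemisphere=None if self.hemisphere is None else self.hemisphere.copy(),
        )


@dataclass
class NormalizedSystem:
    """Stabilized linear dynamics A_norm = A/(lambda_max + c) - I."""

    a_norm: np.ndarray
    c: float
    lambda_max: float

    @property
    def n_nodes(self) -> int:
        return self.a_norm.shape[0]


@dataclass
class ResistanceMatrix:
    """Effective-resistance distances and the Laplacian pseudoinverse."""

    omega: np.ndarray
    laplacian_pinv: np.ndarray


def normalize_adjacency(connectome: Connectome, c: float = 0.0) -> NormalizedSystem:
    """Stabilize the adjacency for linear dynamics.

    Divides the weight matrix by (lambda_max + c) and subtracts the
    identity, so the spectrum is shifted into the stable half-plane:
    with c = 0 the dominant mode is marginally stable (eigenvalue 0)
    and with c > 0 all modes decay.

    Parameters
    ----------
    connectome
        The network to control.
    c
        Nonnegative stabilization constant. The default 0 keeps the
        dominant mode; ``c = 0.01 * lambda_max`` is a common decaying
        alternative.
    """
    if c < 0:
        raise ValueError("c must be nonnegative")
    a = connectome.adjacency
    lam = float(np.linalg.eigvalsh(a)[-1])
    if lam + c <= 0:
        raise ValueError(
            "lambda_max + c must be positive; a zero adjacency with c = 0 "
            "cannot be normalized (division by zero)"
        )
    a_norm = a / (lam + c) - np.eye(a.shape[0])
    return NormalizedSystem(a_norm=a_norm, c=float(c), lambda_max=lam)


def laplacian(connectome: Connectome) -> np.ndarray:
    """Weighted graph Laplacian L = diag(strength) - A."""
    a = connectome.adjacency
    return np.diag(a.sum(axis=1)) - a


def effective_resistance(
    connectome: Connectome, eig_cutoff: float = 1e-10
) -> ResistanceMatrix:
    """Resistance distance between every node pair.

    omega[i, j] = (e_i - e_j)' Q (e_i - e_j) with Q the Moore-Penrose
    pseudoinverse of the Laplacian. The pseudoinverse is formed by
    eigendecomposition, discarding eigenvalues below ``eig_cutoff``
    relative to the largest (one such mode exists for a connected
    graph: the constant vector).
    """
    lap = laplacian(connectome)
    evals, evecs = np.linalg.eigh(lap)
    thresh = eig_cutoff * evals[-1]
    keep = evals > thresh
    n_null = int((~keep).sum())
    if n_null != 1:
        # connectivity is enforced on construction, so this indicates a
        # numerically near-disconnected graph
        warnings.warn(
            f"Laplacian null space has dimension {n_null}; "
            "graph may be numerically near-disconnected",
            RuntimeWarning,
            stacklevel=2,
        )
    inv = np.zeros_like(evals)
    inv[keep] = 1.0 / evals[keep]
    q = (evecs * inv) @ evecs.T
    d = np.diag(q)
    omega = d[:, None] + d[None, :] - 2.0 * q
    omega = np.maximum(omega, 0.0)
    np.fill_diagonal(omega, 0.0)
    return ResistanceMatrix(omega=0.5 * (omega + omega.T), laplacian_pinv=q)


def commute_time(connectome: Connectome) -> np.ndarray:
    """Mean round-trip time of a random walker between node pairs.

    Equals vol(G) * omega with vol(G) the sum of node strengths; kept
    as an independent cross-check on the resistance computation.
    """
    res = effective_resistance(connectome)
    vol = float(connectome.strength.sum())
    return vol * res.omega


def map_to_distribution(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rescale a regional map to a probability distribution over nodes.

    Shifts the minimum to 0 and divides by the sum; undefined for a
    constant map.
    """
    v = np.asarray(values, dtype=float)
    shifted = v - v.min()
    total = shifted.sum()
    if total == 0:
        raise ValueError("constant map cannot be converted to a distribution")
    return shifted / total


def network_variance(resistance: ResistanceMatrix, p: np.ndarray) -> float:
    """Variance of a node distribution measured with resistance distances.

    var(p) = 1/2 * sum_ij p(i) p(j) omega[i, j]; large when most mass
    sits on nodes that are hard to reach by diffusion. Effective
    resistance plays the role of squared distance (the convention of
    the measure's source).
    """
    p = np.asarray(p, dtype=float)
    omega = resistance.omega
    if p.shape[0] != omega.shape[0]:
        raise ValueError(
            f"distribution has {p.shape[0]} entries but omega is {omega.shape}"
        )
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability distribution over nodes")
    return float(0.5 * p @ omega @ p)


def participation_coefficient(
    adjacency: np.ndarray, module_assignment: np.ndarray
) -> np.ndarray:
    """Weighted participation coefficient P_i = 1 - sum_m (k_im / k_i)^2.

    Nodes with zero strength get P = 0 by convention.
    """
    a = np.asarray(adjacency, dtype=float)
    modules = np.asarray(module_assignment)
    strength = a.sum(axis=1)
    p = np.zeros(a.shape[0])
    ok = strength > 0
    for m in np.unique(modules):
        k_im = a[:, modules == m].sum(axis=1)
        p[ok] += (k_im[ok] / strength[ok]) ** 2
    out = np.zeros(a.shape[0])
    out[ok] = 1.0 - p[ok]
    return out


def node_predictors(
    connectome: Connectome,
    module_assignment: np.ndarray,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-node architectural predictors.

    Returns a table indexed by node label with binary degree, strength,
    weighted participation coefficient over the supplied module
    assignment, and any extra annotation columns passed through
    unchanged (e.g. a cortical-hierarchy gradient).
    """
    modules = np.asarray(module_assignment)
    if modules.shape[0] != connectome.n_nodes:
        raise ValueError("module_assignment must cover every node")
    strength = connectome.strength
    table = pd.DataFrame(
        {
            "degree": connectome.degree,
            "strength": strength,
            "participation": participation_coefficient(connectome.adjacency, modules),
        },
        index=pd.Index(connectome.node_labels, name="node"),
    )
    if np.any(strength == 0):
        table["isolated"] = strength == 0
        warnings.warn(
            "isolated nodes present; their participation is set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    if annotations is not None:
        ann = annotations.copy()
        ann.index = table.index
        table = pd.concat([table, ann], axis=1)
    return table
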