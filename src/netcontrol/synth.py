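"""Synthetic connectomes, state maps and annotation maps.

The generators emulate the statistical signatures the analysis relies
on, without any neuroimaging download: a two-hemisphere geometric
connectome (~68 nodes at ~27% density with exponentially
distance-decaying connection probability and weight, hence a negative
weight-length correlation), spatially autocorrelated state maps with
tunable mean/SD (heat-kernel diffusion of white noise over the
connectome graph), nonnegative receptor-like maps, and disease-like
Cohen's d maps confined to (-0.6, 0.9) so the derived control gains
stay positive. Small closed-form fixture graphs are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.sparse.csgraph import minimum_spanning_tree

from .graph import Connectome

__all__ = [
    "SynthConfig",
    "synth_connectome",
    "synth_state_maps",
    "synth_annotation_maps",
    "synth_modules",
    "fixture_graphs",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study conditions.

    n_nodes and target_density default to the 68-region cortical
    parcellation at 27% consensus edge density; decay_length (mm) sets
    the exponential distance decay of connection probability and
    weight; smoothness is the heat-kernel diffusion time used for the
    regional maps.
    """

    n_nodes: int = 68
    target_density: float = 0.27
    decay_length: float = 30.0
    smoothness: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.target_density <= 1):
            raise ValueError("target_density must be in (0, 1]")
        if self.n_nodes < 4:
            raise ValueError("need at least 4 nodes")


def _cap_points(rng: np.random.Generator, n: int, center: np.ndarray, max_angle: float):
    """Uniform points on the spherical cap of half-angle max_angle around center."""
    # sample z uniform on [cos(max_angle), 1] around +x then rotate
    z = rng.uniform(np.cos(max_angle), 1.0, size=n)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    r = np.sqrt(1 - z**2)
    pts = np.column_stack([z, r * np.cos(phi), r * np.sin(phi)])
    if center[0] < 0:
        pts[:, 0] *= -1
    return pts


def synth_connectome(config: SynthConfig) -> Connectome:
    """Geometric two-hemisphere connectome with weight-length decay.

    Nodes sit on two lateralized spherical caps (providing Euclidean
    and unit-sphere coordinates plus hemisphere labels). A minimum
    spanning tree over Euclidean distance guarantees connectivity;
    remaining edges are sampled without replacement with probability
    proportional to exp(-d / decay_length) until the target density is
    met. Weights decay exponentially with length, with lognormal
    scatter.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    n_left = n // 2
    sphere = np.vstack(
        [
            _cap_points(rng, n_left, np.array([-1.0, 0, 0]), np.deg2rad(75)),
            _cap_points(rng, n - n_left, np.array([1.0, 0, 0]), np.deg2rad(75)),
        ]
    )
    hemisphere = np.array(["left"] * n_left + ["right"] * (n - n_left), dtype=object)
    coords = sphere * 60.0  # mm-scale brain radius
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    n_pairs = n * (n - 1) // 2
    m_target = int(round(config.target_density * n_pairs))
    if m_target < n - 1:
        raise ValueError(
            f"target density {config.target_density} gives {m_target} edges, "
            f"fewer than the {n - 1} needed for connectivity"
        )
    mst = minimum_spanning_tree(d).toarray()
    iu, ju = np.triu_indices(n, k=1)
    in_mst = (mst[iu, ju] > 0) | (mst[ju, iu] > 0)
    remaining = m_target - int(in_mst.sum())
    free = np.flatnonzero(~in_mst)
    probs = np.exp(-d[iu[free], ju[free]] / config.decay_length)
    probs /= probs.sum()
    chosen = rng.choice(free, size=remaining, replace=False, p=probs)
    edge_mask = in_mst.copy()
    edge_mask[chosen] = True
    a = np.zeros((n, n))
    ei, ej = iu[edge_mask], ju[edge_mask]
    w = 100.0 * np.exp(-d[ei, ej] / config.decay_length) * np.exp(
        rng.normal(0.0, 0.4, size=len(ei))
    )
    a[ei, ej] = w
    a[ej, ei] = w
    labels = [f"{h[0].upper()}{i:03d}" for i, h in enumerate(hemisphere)]
    return Connectome(
        adjacency=a,
        node_labels=labels,
        coords_euclidean=coords,
        coords_spherical=sphere,
        hemisphere=hemisphere,
    )


def _heat_kernel(connectome: Connectome, smoothness: float) -> np.ndarray:
    """exp(-s * L_norm) with the symmetric normalized Laplacian."""
    a = connectome.adjacency
    s = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.where(s > 0, s, 1.0))
    l_norm = np.eye(len(s)) - (inv_sqrt[:, None] * a * inv_sqrt[None, :])
    if smoothness == 0:
        return np.eye(len(s))
    return expm(-smoothness * l_norm)


def synth_state_maps(
    connectome: Connectome,
    k_maps: int = 20,
    smoothness: float = 2.0,
    mean_range: tuple[float, float] = (0.5, 2.0),
    sd_range: tuple[float, float] = (0.5, 1.5),
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spatially autocorrelated state maps with drawn mean and SD.

    White noise per node is diffused over the connectome graph with a
    heat kernel (parameter ``smoothness``; 0 gives i.i.d. maps), then
    each map is affinely rescaled to a mean drawn from ``mean_range``
    and an SD drawn from ``sd_range``.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be nonnegative")
    rng = np.random.default_rng(seed)
    n = connectome.n_nodes
    kernel = _heat_kernel(connectome, smoothness)
    raw = kernel @ rng.standard_normal((n, k_maps))
    means = rng.uniform(*mean_range, size=k_maps)
    sds = rng.uniform(*sd_range, size=k_maps)
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=0)
    maps = raw * sds + means
    return pd.DataFrame(
        maps,
        index=pd.Index(connectome.node_labels, name="node"),
        columns=[f"term_{j:02d}" for j in range(k_maps)],
    )


def synth_annotation_maps(
    connectome: Connectome,
    kind: str,
    n_maps: int = 3,
    smoothness: float = 2.0,
    seed: int | np.random.Generator | None = None,
    hub_concentrated: bool = False,
) -> pd.DataFrame:
    """Receptor-like (nonnegative) or disease-like (Cohen's d) maps.

    Receptor maps are smooth and min-max scaled to [0, scale] with a
    drawn positive scale. Disease maps are smooth, zero-centred with
    SD ~0.25 and clipped to [-0.6, 0.9], mirroring the envelope of
    reported cortical-thickness effect sizes, so 1 + d gains stay
    positive. ``hub_concentrated`` makes each map a monotone function
    of node strength (plus tiny jitter), placing its largest values on
    the strongest hubs — useful for spatial-specificity checks.
    """
    if kind not in ("receptor", "disease"):
        raise ValueError("kind must be 'receptor' or 'disease'")
    rng = np.random.default_rng(seed)
    n = connectome.n_nodes
    if hub_concentrated:
        strength = connectome.adjacency.sum(axis=1)
        base = np.tile(
            (strength - strength.mean()) / strength.std(), (n_maps, 1)
        ).T
        base = base + 1e-6 * rng.standard_normal((n, n_maps))
    else:
        kernel = _heat_kernel(connectome, smoothness)
        base = kernel @ rng.standard_normal((n, n_maps))
        base = (base - base.mean(axis=0)) / base.std(axis=0, ddof=0)
    if kind == "receptor":
        scale = rng.uniform(1.0, 10.0, size=n_maps)
        lo = base.min(axis=0)
        span = base.max(axis=0) - lo
        maps = (base - lo) / span * scale
        prefix = "receptor"
    else:
        maps = np.clip(base * 0.25, -0.6, 0.9)
        prefix = "disorder"
    return pd.DataFrame(
        maps,
        index=pd.Index(connectome.node_labels, name="node"),
        columns=[f"{prefix}_{j:02d}" for j in range(n_maps)],
    )


def synth_modules(
    connectome: Connectome, n_modules: int = 4, seed: int | None = 0
) -> np.ndarray:
    """Spatially contiguous module assignment via k-means on coordinates."""
    from scipy.cluster.vq import kmeans2

    coords = connectome.coords_euclidean
    if coords is None:
        raise ValueError("module assignment from geometry needs coordinates")
    _, labels = kmeans2(coords, n_modules, seed=seed, minit="++")
    return labels


def _circle_coords(n: int, radius: float = 10.0) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])


def fixture_graphs() -> dict[str, Connectome]:
    """Named unit-weight graphs with closed-form graph quantities.

    triangle (resistance 2/3 everywhere), 4-node path (endpoint
    resistance 3), 4-node ring, 4-node star (no degree-preserving
    swap exists), and the complete graph K4.
    """
    def from_edges(n, edges):
        a = np.zeros((n, n))
        for i, j in edges:
            a[i, j] = a[j, i] = 1.0
        return Connectome(adjacency=a, coords_euclidean=_circle_coords(n))

    return {
        "triangle": from_edges(3, [(0, 1), (1, 2), (0, 2)]),
        "path4": from_edges(4, [(0, 1), (1, 2), (2, 3)]),
        "ring4": from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)]),
        "star4": from_edges(4, [(0, 1), (0, 2), (0, 3)]),
        "k4": from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)]),
    }
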