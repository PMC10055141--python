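"""Topological, geometric and spatial null models.

Three surrogate families calibrate the empirical results against
chance:

* degree-preserving (Maslov-Sneppen) rewiring, with weights travelling
  on their edges so the weight multiset is preserved exactly;
* geometry-preserving rewiring, which additionally keeps the binned
  edge-length histogram within a tolerance and reassigns weights
  within distance bins to approximately preserve the weight-length
  relationship;
* spin surrogates for regional maps: mirrored per-hemisphere random
  rotations of the spherical node coordinates with nearest-neighbour
  value reassignment, preserving the value distribution and spatial
  autocorrelation while randomizing anatomical placement.

Plus the z-score / empirical-p machinery used to compare them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import special_ortho_group

from .energy import transition_energy_matrix
from .graph import Connectome

__all__ = [
    "NullEnsemble",
    "maslov_sneppen_rewire",
    "geometry_preserving_rewire",
    "spin_surrogates",
    "rotate_map",
    "null_zscore",
    "empirical_vs_null_energy",
    "permutation_domain_test",
    "morans_i",
]


@dataclass
class NullEnsemble:
    """A family of surrogates with the seeds and parameters that made them."""

    kind: str
    members: list | np.ndarray
    seeds: list[int] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def _edge_arrays(connectome: Connectome):
    edges, weights = connectome.edge_list()
    return edges.copy(), weights.copy()


def _rebuild(connectome: Connectome, edges: np.ndarray, weights: np.ndarray):
    n = connectome.n_nodes
    a = np.zeros((n, n))
    a[edges[:, 0], edges[:, 1]] = weights
    a[edges[:, 1], edges[:, 0]] = weights
    return connectome.with_adjacency(a)


def maslov_sneppen_rewire(
    connectome: Connectome,
    n_swap_per_edge: int = 10,
    seed: int | np.random.Generator | None = None,
    max_attempt_factor: int = 100,
    return_stats: bool = False,
):
    """Degree-preserving rewired surrogate.

    Repeatedly swaps edge pairs (a-b, c-d) -> (a-d, c-b), rejecting
    self-loops and multi-edges, until ``n_swap_per_edge`` swaps per
    edge are accepted. Weights stay attached to their edges, so both
    the binary degree sequence and the weight multiset are preserved
    exactly. Graphs admitting no valid swap (e.g. stars, complete
    graphs) are returned unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    edges, weights = _edge_arrays(connectome)
    m = len(edges)
    n = connectome.n_nodes
    exists = connectome.adjacency > 0
    target = n_swap_per_edge * m
    max_attempts = max_attempt_factor * target
    accepted = attempts = 0
    while accepted < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        if exists[a, d] or exists[c, b]:
            continue
        exists[a, b] = exists[b, a] = False
        exists[c, d] = exists[d, c] = False
        exists[a, d] = exists[d, a] = True
        exists[c, b] = exists[b, c] = True
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        accepted += 1
    if accepted == 0:
        warnings.warn(
            "no valid degree-preserving swap found; returning the input "
            "topology (swap count 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    out = _rebuild(connectome, edges, weights)
    if return_stats:
        return out, {"accepted_swaps": accepted, "attempts": attempts}
    return out


def _edge_lengths(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    diff = coords[edges[:, 0]] - coords[edges[:, 1]]
    return np.linalg.norm(diff, axis=1)


def _length_bins(lengths: np.ndarray, n_bins: int, min_per_bin: int = 5):
    """Quantile bin edges over observed edge lengths, merging thin bins."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges_ = np.unique(np.quantile(lengths, qs))
    while len(edges_) > 2:
        counts, _ = np.histogram(lengths, bins=edges_)
        if counts.min() >= min_per_bin:
            break
        k = int(np.argmin(counts))
        edges_ = np.delete(edges_, k + 1 if k < len(counts) - 1 else k)
        warnings.warn(
            "distance bin with too few edges merged with its neighbour",
            RuntimeWarning,
            stacklevel=3,
        )
    edges_[0] -= 1e-9
    edges_[-1] += 1e-9
    return edges_


def geometry_preserving_rewire(
    connectome: Connectome,
    n_bins: int = 10,
    n_swap_per_edge: int = 10,
    tol: float = 0.2,
    seed: int | np.random.Generator | None = None,
    max_attempt_factor: int = 100,
    return_stats: bool = False,
):
    """Degree-preserving rewiring that also preserves wiring geometry.

    Swaps are accepted only while every distance-bin edge count stays
    within ``tol`` (fractionally) of the empirical histogram; after the
    topology is randomized, the original weights are reassigned within
    distance bins by length rank, approximately preserving the
    weight-length relationship. Degree sequence and weight multiset
    are preserved exactly.
    """
    if connectome.coords_euclidean is None:
        raise ValueError("geometry-preserving rewiring requires Euclidean coordinates")
    rng = np.random.default_rng(seed)
    coords = connectome.coords_euclidean
    edges, weights = _edge_arrays(connectome)
    m = len(edges)
    lengths = _edge_lengths(coords, edges)
    bin_edges = _length_bins(lengths, n_bins)
    ref_counts, _ = np.histogram(lengths, bins=bin_edges)
    lo = np.floor(ref_counts * (1 - tol)).astype(int)
    hi = np.ceil(ref_counts * (1 + tol)).astype(int)
    counts = ref_counts.copy()
    edge_bin = np.digitize(lengths, bin_edges) - 1
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    exists = connectome.adjacency > 0
    target = n_swap_per_edge * m
    max_attempts = max_attempt_factor * target
    accepted = attempts = 0
    nb = len(ref_counts)
    while accepted < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if exists[a, d] or exists[c, b]:
            continue
        b1 = min(nb - 1, max(0, np.digitize(dist[a, d], bin_edges) - 1))
        b2 = min(nb - 1, max(0, np.digitize(dist[c, b], bin_edges) - 1))
        new_counts = counts.copy()
        new_counts[edge_bin[e1]] -= 1
        new_counts[edge_bin[e2]] -= 1
        new_counts[b1] += 1
        new_counts[b2] += 1
        if np.any(new_counts < lo) or np.any(new_counts > hi):
            continue
        counts = new_counts
        exists[a, b] = exists[b, a] = False
        exists[c, d] = exists[d, c] = False
        exists[a, d] = exists[d, a] = True
        exists[c, b] = exists[b, c] = True
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        edge_bin[e1] = b1
        edge_bin[e2] = b2
        accepted += 1
    if accepted == 0:
        warnings.warn(
            "no geometry-compatible swap found; returning the input topology",
            RuntimeWarning,
            stacklevel=2,
        )
    # weight reassignment: within each distance bin, hand the original
    # weights (ordered by original edge length) to the new edges ordered
    # by length, so short edges keep getting the weights short edges had
    new_lengths = _edge_lengths(coords, edges)
    new_bin = np.clip(np.digitize(new_lengths, bin_edges) - 1, 0, nb - 1)
    orig_bin = np.clip(np.digitize(lengths, bin_edges) - 1, 0, nb - 1)
    new_weights = np.empty(m)
    pool_w: list[np.ndarray] = []
    pool_len: list[np.ndarray] = []
    for k in range(nb):
        sel = orig_bin == k
        order = np.argsort(lengths[sel])
        pool_w.append(weights[sel][order])
        pool_len.append(lengths[sel][order])
    used = np.zeros(nb, dtype=int)
    # process bins independently; spill into neighbouring bins when the
    # surrogate has more edges in a bin than the original did
    for k in range(nb):
        sel = np.flatnonzero(new_bin == k)
        sel = sel[np.argsort(new_lengths[sel])]
        for idx in sel:
            kk = k
            if used[kk] >= len(pool_w[kk]):
                order = np.argsort(np.abs(np.arange(nb) - k))
                for cand in order:
                    if used[cand] < len(pool_w[cand]):
                        kk = cand
                        break
            new_weights[idx] = pool_w[kk][used[kk]]
            used[kk] += 1
    out = _rebuild(connectome, edges, new_weights)
    if return_stats:
        return out, {
            "accepted_swaps": accepted,
            "attempts": attempts,
            "bin_edges": bin_edges,
            "ref_counts": ref_counts,
            "final_counts": counts,
        }
    return out


def _mirror(rotation: np.ndarray) -> np.ndarray:
    m = np.diag([-1.0, 1.0, 1.0])
    return m @ rotation @ m


def rotate_map(
    values: np.ndarray,
    coords_spherical: np.ndarray,
    hemisphere: np.ndarray,
    rotation: np.ndarray,
    bijective: bool = False,
) -> np.ndarray:
    """Apply one spherical rotation to a regional map.

    The rotation acts on the left hemisphere; its mirror image (about
    the x = 0 plane) acts on the right. Each original parcel receives
    the value of the nearest rotated parcel of the same hemisphere
    (great-circle distance). With ``bijective=True`` a one-to-one
    assignment (minimizing total distance) is used instead, so the
    surrogate is an exact permutation of the original values.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for hemi, rot in (("left", rotation), ("right", _mirror(rotation))):
        idx = np.flatnonzero(hemisphere == hemi)
        if idx.size == 0:
            continue
        pts = coords_spherical[idx]
        rotated = pts @ rot.T
        # cosine similarity: nearest on the great circle = largest dot
        sim = pts @ rotated.T
        if bijective:
            rows, cols = linear_sum_assignment(-sim)
            out[idx[rows]] = values[idx[cols]]
        else:
            nearest = np.argmax(sim, axis=1)
            out[idx] = values[idx[nearest]]
    return out


def spin_surrogates(
    values: np.ndarray | pd.Series,
    coords_spherical: np.ndarray,
    hemisphere: np.ndarray,
    n_rot: int = 10000,
    seed: int | np.random.Generator | None = None,
    bijective: bool = False,
) -> NullEnsemble:
    """Spatially constrained surrogates of a regional map.

    Each member applies one uniformly random 3D rotation (mirrored
    across hemispheres) and nearest-parcel reassignment; the value
    distribution and spatial autocorrelation are approximately
    preserved while anatomical placement is randomized.
    """
    if coords_spherical is None or hemisphere is None:
        raise ValueError(
            "spin surrogates need unit-sphere coordinates and hemisphere "
            "labels; without them use a value-permutation null instead"
        )
    vals = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    members = np.empty((n_rot, vals.shape[0]))
    seeds = []
    for r in range(n_rot):
        rot = special_ortho_group.rvs(3, random_state=rng)
        members[r] = rotate_map(vals, coords_spherical, hemisphere, rot, bijective)
        seeds.append(r)
    return NullEnsemble(
        kind="spin",
        members=members,
        seeds=seeds,
        provenance={"n_rot": n_rot, "bijective": bijective},
    )


def null_zscore(empirical: float, null_values) -> tuple[float, float]:
    """z-score and percentile of an empirical value within a null sample."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 2:
        raise ValueError("need at least 2 null values")
    if nulls.size < 20:
        warnings.warn(
            f"only {nulls.size} null values; z-score will be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    sd = nulls.std(ddof=1)
    if sd == 0:
        raise ValueError("null distribution has zero standard deviation")
    z = float((empirical - nulls.mean()) / sd)
    pct = float(100.0 * np.mean(nulls < empirical))
    return z, pct


def empirical_vs_null_energy(
    connectome: Connectome,
    states: pd.DataFrame,
    null_kind: str = "degree_preserving",
    n_nulls: int = 500,
    seed: int | np.random.Generator | None = None,
    T: float = 1.0,
    rho: float = 1.0,
    c: float = 0.0,
    n_steps: int = 1000,
    null_params: dict | None = None,
) -> dict:
    """Mean all-to-all transition energy: empirical vs rewired surrogates.

    Recomputes the full transition-energy matrix on each surrogate
    connectome and compares its mean against the empirical one. The
    one-sided empirical p tests the hypothesis that the empirical
    connectome supports cheaper transitions than the nulls
    (p = (#{null <= empirical} + 1) / (n_nulls + 1)).
    """
    rng = np.random.default_rng(seed)
    null_params = dict(null_params or {})
    tem = transition_energy_matrix(
        connectome, states, T=T, rho=rho, c=c, n_steps=n_steps
    )
    empirical = float(tem.energies.mean())
    rewire = {
        "degree_preserving": maslov_sneppen_rewire,
        "geometry_preserving": geometry_preserving_rewire,
    }
    if null_kind not in rewire:
        raise ValueError(f"unknown null kind {null_kind!r}")
    null_means = np.empty(n_nulls)
    for i in range(n_nulls):
        surr = rewire[null_kind](connectome, seed=rng, **null_params)
        t_null = transition_energy_matrix(
            surr, states, T=T, rho=rho, c=c, n_steps=n_steps
        )
        null_means[i] = t_null.energies.mean()
    z, pct = null_zscore(empirical, null_means)
    p = (int(np.sum(null_means <= empirical)) + 1) / (n_nulls + 1)
    return {
        "null_kind": null_kind,
        "empirical_mean_energy": empirical,
        "null_mean_energies": null_means,
        "z": z,
        "percentile": pct,
        "p_one_sided": p,
        "n_nulls": n_nulls,
    }


def permutation_domain_test(
    net_scores: pd.Series,
    domain_labels: pd.Series | dict,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Is a cognitive domain's median net asymmetry larger than chance?

    Terms without a domain label are excluded. For each domain the
    statistic is the median net score of its terms; the null draws
    equally sized subsets by permuting domain labels among the labeled
    terms. One-sided p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    labels = pd.Series(domain_labels)
    labels = labels.reindex(net_scores.index).dropna()
    scores = net_scores.loc[labels.index].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    n_labeled = len(scores)
    for domain, members in labels.groupby(labels):
        size = len(members)
        if size < 2:
            warnings.warn(
                f"domain {domain!r} has fewer than 2 terms; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        observed = float(np.median(net_scores.loc[members.index]))
        null = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(n_labeled, size=size, replace=False)
            null[b] = np.median(scores[pick])
        p = (int(np.sum(null >= observed)) + 1) / (n_perm + 1)
        rows.append(
            {"domain": domain, "n_terms": size, "median_net_score": observed, "p": p}
        )
    return pd.DataFrame(rows).set_index("domain")


def morans_i(values: np.ndarray, coords: np.ndarray) -> float:
    """Moran's I spatial autocorrelation with inverse-distance weights."""
    v = np.asarray(values, dtype=float)
    z = v - v.mean()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    n = len(v)
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("constant map has undefined Moran's I")
    return float(n / w.sum() * (z @ w @ z) / denom)
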