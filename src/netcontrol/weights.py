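"""Heterogeneous control-input weightings from annotation maps.

Control authority need not be uniform across regions: receptor
density maps (nonnegative PET tracer densities) and disease maps
(Cohen's d cortical-thickness abnormalities) modulate the diagonal of
the input matrix B. Receptor maps are min-max scaled and added to the
uniform gains (gains in [1, 2]); disease maps are added directly
(gain 1 + d, positive as long as d > -1). Each empirical weighting is
scored against spin-rotated counterparts of its source map, which
preserve the gain distribution and spatial autocorrelation while
randomizing anatomical placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import transition_energy_matrix
from .graph import Connectome
from .nulls import null_zscore, spin_surrogates

__all__ = [
    "InputWeighting",
    "uniform_inputs",
    "disease_inputs",
    "receptor_inputs",
    "disease_target_zscores",
    "receptor_facilitation",
]


@dataclass
class InputWeighting:
    """Per-node diagonal control gains and how they were built."""

    b_diag: np.ndarray
    scheme: str
    source_map_name: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.b_diag, dtype=float)
        if np.any(b < 0) or not np.any(b > 0):
            raise ValueError(
                "gains must be nonnegative with at least one positive entry"
            )
        self.b_diag = b


def uniform_inputs(n_nodes: int) -> InputWeighting:
    """Whole-brain uniform control (B = I)."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    return InputWeighting(b_diag=np.ones(n_nodes), scheme="uniform")


def disease_inputs(
    cohens_d_map: np.ndarray | pd.Series, name: str = ""
) -> InputWeighting:
    """Gains 1 + d from a cortical-abnormality effect-size map.

    Regions with thinning (d < 0) inject less control input, thickened
    regions more; any d <= -1 would give a non-positive gain and is
    rejected.
    """
    d = np.asarray(cohens_d_map, dtype=float)
    if np.any(d <= -1):
        raise ValueError(
            "Cohen's d values must exceed -1 so that all gains 1 + d stay positive"
        )
    if isinstance(cohens_d_map, pd.Series) and not name:
        name = str(cohens_d_map.name)
    return InputWeighting(b_diag=1.0 + d, scheme="disease", source_map_name=name)


def receptor_inputs(
    density_map: np.ndarray | pd.Series, name: str = ""
) -> InputWeighting:
    """Gains 1 + min-max-scaled density, so gains lie in [1, 2]."""
    v = np.asarray(density_map, dtype=float)
    rng_ = v.max() - v.min()
    if rng_ == 0:
        raise ValueError("constant receptor map: min-max scaling is degenerate")
    scaled = (v - v.min()) / rng_
    if isinstance(density_map, pd.Series) and not name:
        name = str(density_map.name)
    return InputWeighting(b_diag=1.0 + scaled, scheme="receptor", source_map_name=name)


def _mean_energy_to_targets(
    connectome: Connectome,
    states: pd.DataFrame,
    b_diag: np.ndarray,
    T: float,
    rho: float,
    c: float,
    n_steps: int,
) -> np.ndarray:
    """Mean energy to reach each target from all other states (off-diag col mean)."""
    tem = transition_energy_matrix(
        connectome, states, T=T, rho=rho, c=c, b_diag=b_diag, n_steps=n_steps
    )
    e = tem.energies
    k = e.shape[0]
    return (e.sum(axis=0) - np.diag(e)) / (k - 1)


def disease_target_zscores(
    connectome: Connectome,
    states_reduced: pd.DataFrame,
    disease_maps: pd.DataFrame,
    n_rot: int = 100,
    seed: int | np.random.Generator | None = None,
    T: float = 1.0,
    rho: float = 1.0,
    c: float = 0.0,
    n_steps: int = 1000,
) -> pd.DataFrame:
    """How each disorder's abnormality layout reshapes reach costs.

    For every disorder the empirical gain map (1 + d) and one gain map
    per spin surrogate of the d-map are pushed through the transition
    solver on the reduced state set; for each target state the
    statistic is the mean energy to reach it from every other state,
    z-scored against the surrogate distribution. Negative z: the
    empirical abnormality layout makes that target cheaper to reach
    than random layouts with the same value distribution.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for disorder in disease_maps.columns:
        dmap = disease_maps[disorder].to_numpy(dtype=float)
        ens = spin_surrogates(
            dmap,
            connectome.coords_spherical,
            connectome.hemisphere,
            n_rot=n_rot,
            seed=rng,
        )
        emp = _mean_energy_to_targets(
            connectome,
            states_reduced,
            disease_inputs(dmap).b_diag,
            T,
            rho,
            c,
            n_steps,
        )
        nulls = np.empty((n_rot, len(emp)))
        for r in range(n_rot):
            nulls[r] = _mean_energy_to_targets(
                connectome,
                states_reduced,
                disease_inputs(ens.members[r]).b_diag,
                T,
                rho,
                c,
                n_steps,
            )
        zs = np.empty(len(emp))
        for j in range(len(emp)):
            sd_j = nulls[:, j].std(ddof=1)
            # floating-point jitter between identical runs is not variation
            if sd_j <= 1e-9 * max(1.0, abs(nulls[:, j].mean())):
                warnings.warn(
                    f"degenerate null distribution for {disorder!r} target "
                    f"{states_reduced.columns[j]!r} (constant map?)",
                    RuntimeWarning,
                    stacklevel=2,
                )
                zs[j] = np.nan
            else:
                zs[j], _ = null_zscore(emp[j], nulls[:, j])
        rows[disorder] = zs
    return pd.DataFrame(rows, index=states_reduced.columns).T


def receptor_facilitation(
    connectome: Connectome,
    states_reduced: pd.DataFrame,
    receptor_maps: pd.DataFrame,
    n_rot: int = 100,
    seed: int | np.random.Generator | None = None,
    T: float = 1.0,
    rho: float = 1.0,
    c: float = 0.0,
    n_steps: int = 1000,
    return_per_transition: bool = False,
):
    """Percentage of transitions facilitated by each receptor layout.

    For each receptor the empirical gain map and each spin surrogate's
    gain map yield full transition-energy matrices on the reduced state
    set. A (source -> target, surrogate) comparison counts as
    facilitated when the empirical energy is strictly lower. The main
    table pools comparisons within target state (receptors x targets,
    in percent); ``return_per_transition`` also yields, per receptor,
    the source x target percentage table over surrogates.
    """
    rng = np.random.default_rng(seed)
    k = states_reduced.shape[1]
    off = ~np.eye(k, dtype=bool)
    per_target = {}
    per_transition = {}
    for receptor in receptor_maps.columns:
        vmap = receptor_maps[receptor].to_numpy(dtype=float)
        ens = spin_surrogates(
            vmap,
            connectome.coords_spherical,
            connectome.hemisphere,
            n_rot=n_rot,
            seed=rng,
        )
        emp = transition_energy_matrix(
            connectome,
            states_reduced,
            T=T,
            rho=rho,
            c=c,
            b_diag=receptor_inputs(vmap).b_diag,
            n_steps=n_steps,
        ).energies
        wins = np.zeros((k, k))
        for r in range(n_rot):
            surr = transition_energy_matrix(
                connectome,
                states_reduced,
                T=T,
                rho=rho,
                c=c,
                b_diag=receptor_inputs(ens.members[r]).b_diag,
                n_steps=n_steps,
            ).energies
            wins += (emp < surr).astype(float)
        # pool (source, surrogate) comparisons within each target column
        per_target[receptor] = (
            100.0 * (wins * off).sum(axis=0) / ((k - 1) * n_rot)
        )
        per_transition[receptor] = pd.DataFrame(
            100.0 * wins / n_rot,
            index=states_reduced.columns,
            columns=states_reduced.columns,
        )
    table = pd.DataFrame(per_target, index=states_reduced.columns).T
    if return_per_transition:
        return table, per_transition
    return table
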