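"""End-to-end orchestration of the transition-energy analysis.

Three entry points mirror the stages of the study: the all-pairs
transition analysis (energy matrix, asymmetry, variability,
indirect-transition and distance statistics), the null-network
comparison, and the perturbation analysis (disease z-scores and
receptor facilitation on a reduced state set). Each run resolves a
single seeded generator hierarchy, writes its outputs as labeled CSVs
plus a JSON summary, and stores the resolved configuration beside
them so any stage can be rerun independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .energy import (
    euclidean_state_distance,
    indirect_transition_fraction,
    source_target_variability,
    transition_asymmetry,
    transition_energy_matrix,
)
from .graph import Connectome, normalize_adjacency
from .nulls import empirical_vs_null_energy, permutation_domain_test
from .synth import SynthConfig, synth_annotation_maps, synth_connectome, synth_state_maps
from .weights import disease_target_zscores, receptor_facilitation

__all__ = [
    "RunConfig",
    "load_inputs",
    "run_transition_analysis",
    "run_null_comparison",
    "run_perturbation_analysis",
]

log = logging.getLogger("netcontrol")


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Defaults reproduce the main study settings: horizon T = 1, input
    weight rho = 1, stabilization c = 0, uniform control inputs, full
    state set. Paths may be omitted when ``synthetic`` is set, in
    which case the generators provide all inputs.
    """

    connectome: str | None = None
    coords: str | None = None
    states: str | None = None
    receptors: str | None = None
    diseases: str | None = None
    domains: str | None = None
    synthetic: bool = False
    n_nodes: int = 68
    target_density: float = 0.27
    k_maps: int = 20
    smoothness: float = 2.0
    T: float = 1.0
    rho: float = 1.0
    c: float = 0.0
    normalize_states: bool = False
    n_steps: int = 1000
    n_nulls: int = 50
    n_rot: int = 100
    n_perm: int = 1000
    reduced_state_count: int = 25
    seed: int = 0
    out: str = "netcontrol_out"

    def dump(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def load_inputs(config: RunConfig):
    """Resolve the connectome and state set, synthetic or from disk."""
    rng = np.random.default_rng(config.seed)
    if config.synthetic or config.connectome is None:
        syn = SynthConfig(
            n_nodes=config.n_nodes,
            target_density=config.target_density,
            smoothness=config.smoothness,
            seed=int(rng.integers(2**31)),
        )
        conn = synth_connectome(syn)
        states = synth_state_maps(
            conn,
            k_maps=config.k_maps,
            smoothness=config.smoothness,
            seed=int(rng.integers(2**31)),
        )
    else:
        conn = nio.read_connectome(config.connectome, config.coords)
        if config.states is None:
            raise ValueError("states table required when a connectome file is given")
        states = nio.read_maps(config.states, conn.node_labels)
    return conn, states


def _log_system(conn: Connectome, config: RunConfig) -> None:
    system = normalize_adjacency(conn, c=config.c)
    log.info(
        "connectome: %d nodes, density %.3f, lambda_max %.4g",
        conn.n_nodes,
        (conn.adjacency > 0).sum() / (conn.n_nodes * (conn.n_nodes - 1)),
        system.lambda_max,
    )


def run_transition_analysis(config: RunConfig) -> dict:
    """All-pairs transition energies and the derived statistics."""
    outdir = Path(config.out)
    config.dump(outdir)
    conn, states = load_inputs(config)
    _log_system(conn, config)
    tem = transition_energy_matrix(
        conn,
        states,
        T=config.T,
        rho=config.rho,
        c=config.c,
        n_steps=config.n_steps,
        normalize_states=config.normalize_states,
    )
    asym, net = transition_asymmetry(tem)
    variability = source_target_variability(tem)
    frac, pairs = indirect_transition_fraction(tem)
    dist = euclidean_state_distance(states)
    k = len(tem.term_labels)
    off = ~np.eye(k, dtype=bool)
    from scipy.stats import spearmanr

    r_dist, p_dist = spearmanr(dist.to_numpy()[off], tem.energies[off])
    nio.matrix_to_csv(tem.energies, tem.term_labels, outdir / "transition_energy.csv")
    nio.matrix_to_csv(asym, tem.term_labels, outdir / "asymmetry.csv")
    net.to_csv(outdir / "net_asymmetry.csv")
    pairs.to_csv(outdir / "indirect_transitions.csv", index=False)
    summary = {
        "parameters": {
            "T": config.T,
            "rho": config.rho,
            "c": config.c,
            "normalize_states": config.normalize_states,
            "n_steps": config.n_steps,
            "seed": config.seed,
        },
        "n_states": k,
        "n_transitions": k * k,
        "mean_energy": float(tem.energies.mean()),
        "indirect_transition_fraction": frac,
        "distance_energy_spearman_r": float(r_dist),
        "distance_energy_spearman_p": float(p_dist),
        "variability": {
            key: variability[key]
            for key in (
                "mean_sd_across_targets",
                "mean_sd_across_sources",
                "t",
                "cohens_d",
                "df",
                "degenerate",
            )
        },
        "net_asymmetry": {str(kk): float(v) for kk, v in net.items()},
    }
    if config.domains is not None:
        dom = pd.read_csv(config.domains, index_col=0).iloc[:, 0]
        dtest = permutation_domain_test(
            net, dom, n_perm=config.n_perm, seed=config.seed
        )
        dtest.to_csv(outdir / "domain_permutation.csv")
        summary["domain_permutation_p"] = {
            str(d): float(p) for d, p in dtest["p"].items()
        }
    with open(outdir / "transition_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    summary["tem"] = tem
    summary["net_scores"] = net
    return summary


def run_null_comparison(config: RunConfig) -> dict:
    """Empirical vs rewired-null mean transition energy, both null kinds."""
    outdir = Path(config.out)
    config.dump(outdir)
    conn, states = load_inputs(config)
    _log_system(conn, config)
    report: dict = {}
    for kind in ("degree_preserving", "geometry_preserving"):
        res = empirical_vs_null_energy(
            conn,
            states,
            null_kind=kind,
            n_nulls=config.n_nulls,
            seed=config.seed,
            T=config.T,
            rho=config.rho,
            c=config.c,
            n_steps=config.n_steps,
        )
        np.savetxt(
            outdir / f"null_means_{kind}.csv",
            res["null_mean_energies"],
            delimiter=",",
            header="mean_energy",
            comments="",
        )
        report[kind] = {
            "empirical_mean_energy": res["empirical_mean_energy"],
            "z": res["z"],
            "p_one_sided": res["p_one_sided"],
            "null_mean": float(res["null_mean_energies"].mean()),
            "n_nulls": res["n_nulls"],
        }
        log.info("%s null: z = %.3f, p = %.4f", kind, res["z"], res["p_one_sided"])
    with open(outdir / "null_comparison.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _reduced_states(states: pd.DataFrame, count: int, seed: int) -> pd.DataFrame:
    if states.shape[1] <= count:
        return states
    rng = np.random.default_rng(seed)
    cols = sorted(rng.choice(states.shape[1], size=count, replace=False))
    return states.iloc[:, cols]


def run_perturbation_analysis(config: RunConfig) -> dict:
    """Disease z-score and receptor facilitation tables (reduced states)."""
    outdir = Path(config.out)
    config.dump(outdir)
    conn, states = load_inputs(config)
    _log_system(conn, config)
    reduced = _reduced_states(states, config.reduced_state_count, config.seed)
    rng = np.random.default_rng(config.seed)
    if config.synthetic or config.diseases is None:
        diseases = synth_annotation_maps(
            conn, "disease", n_maps=3, seed=int(rng.integers(2**31))
        )
    else:
        diseases = nio.read_maps(config.diseases, conn.node_labels)
    if config.synthetic or config.receptors is None:
        receptors = synth_annotation_maps(
            conn, "receptor", n_maps=3, seed=int(rng.integers(2**31))
        )
    else:
        receptors = nio.read_maps(config.receptors, conn.node_labels)
    zs = disease_target_zscores(
        conn,
        reduced,
        diseases,
        n_rot=config.n_rot,
        seed=config.seed,
        T=config.T,
        rho=config.rho,
        c=config.c,
        n_steps=config.n_steps,
    )
    fac = receptor_facilitation(
        conn,
        reduced,
        receptors,
        n_rot=config.n_rot,
        seed=config.seed + 1,
        T=config.T,
        rho=config.rho,
        c=config.c,
        n_steps=config.n_steps,
    )
    zs.to_csv(outdir / "disease_target_zscores.csv")
    fac.to_csv(outdir / "receptor_facilitation.csv")
    manifest = {
        "n_reduced_states": reduced.shape[1],
        "n_rot": config.n_rot,
        "disorders": list(zs.index),
        "receptors": list(fac.index),
        "mean_abs_disease_z": float(np.nanmean(np.abs(zs.to_numpy()))),
        "mean_receptor_facilitation_pct": float(fac.to_numpy().mean()),
    }
    with open(outdir / "perturbation_summary.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"disease_z": zs, "receptor_facilitation": fac, "manifest": manifest}
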