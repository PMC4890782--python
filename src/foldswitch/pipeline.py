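"""End-to-end pipeline: contacts -> simulate -> wham -> landscape -> cluster.

Every stage writes plain-text artifacts (TSV/JSON) into the run directory,
each embedding the config hash and seed for provenance; stages already on
disk are reused when ``resume`` is set.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from foldswitch.analysis import (
    centroid_graph,
    cluster_conformations,
    superposition_vector,
    transition_flux,
)
from foldswitch.config import RunConfig
from foldswitch.contacts import consensus_from_tsv, consensus_map, consensus_to_tsv
from foldswitch.sbm import SbmParams
from foldswitch.sampling import parallel_tempering, temperature_ladder
from foldswitch.structures import (
    FixtureSpec,
    Structure,
    fixture_sequence,
    generate_fixture_set,
    read_structure,
)
from foldswitch.thermo import (
    basin_stats,
    burn_in_slice,
    free_energy_landscape,
    heat_capacity,
    landscape_to_tsv,
    wham_reweight,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_fold_structures(cfg: RunConfig) -> tuple[list[Structure], list[Structure], str]:
    if cfg.fixture_length > 0:
        spec_a = FixtureSpec(length=cfg.fixture_length, topology="helix-bundle",
                             n_conformers=3, jitter_sd=0.25, seed=cfg.seed)
        spec_b = FixtureSpec(length=cfg.fixture_length, topology="hairpin-sheet",
                             n_conformers=3, jitter_sd=0.25, seed=cfg.seed + 1)
        seq = cfg.sequence or fixture_sequence(cfg.fixture_length)
        return generate_fixture_set(spec_a), generate_fixture_set(spec_b), seq
    strs_a = [read_structure(p) for p in cfg.structures_A]
    strs_b = [read_structure(p) for p in cfg.structures_B]
    return strs_a, strs_b, cfg.sequence


def _write_snapshots(rs, sequence: str, path: Path, prov: str) -> None:
    """Wide TSV of snapshot torsions (one row per recorded conformation)."""
    L = len(sequence)
    rows = []
    for rung, traj in enumerate(rs.trajectories):
        for rec, conf in enumerate(traj.snapshots or []):
            row = {"rung": rung, "record": rec,
                   "Q_A": traj.Q_A[rec], "Q_B": traj.Q_B[rec]}
            row.update({f"phi_{i}": conf.phi[i] for i in range(L)})
            row.update({f"psi_{i}": conf.psi[i] for i in range(L)})
            row.update({f"chi_{i}": conf.chi[i] for i in range(L)})
            rows.append(row)
    with path.open("w") as fh:
        fh.write(f"# {prov} sequence={sequence}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def load_snapshots(rundir: str | Path):
    """(conformations, Q_A, Q_B, rung) from a run directory's snapshots.tsv."""
    from foldswitch.sampling import Conformation

    path = Path(rundir) / "snapshots.tsv"
    meta = dict(tok.split("=") for tok in path.open().readline().lstrip("# ").split())
    seq = meta["sequence"]
    L = len(seq)
    df = pd.read_csv(path, sep="\t", comment="#")
    confs = [
        Conformation(seq,
                     [row[f"phi_{i}"] for i in range(L)],
                     [row[f"psi_{i}"] for i in range(L)],
                     [row[f"chi_{i}"] for i in range(L)])
        for _, row in df.iterrows()
    ]
    return confs, df["Q_A"].to_numpy(), df["Q_B"].to_numpy(), df["rung"].to_numpy()


def run_pipeline(cfg: RunConfig, outdir: str | Path, resume: bool = False) -> Path:
    """Run all stages; returns the artifact directory."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    prov = cfg.provenance()

    # -- stage: contacts ----------------------------------------------------
    try:
        map_paths = (outdir / "consensus_A.tsv", outdir / "consensus_B.tsv")
        strs_a, strs_b, sequence = _load_fold_structures(cfg)
        if resume and all(p.exists() for p in map_paths):
            map_a = consensus_from_tsv(map_paths[0])
            map_b = consensus_from_tsv(map_paths[1])
        else:
            map_a = consensus_map(strs_a, cfg.cutoff, cfg.min_seq_sep,
                                  cfg.gly_policy, fold_label="A")
            map_b = consensus_map(strs_b, cfg.cutoff, cfg.min_seq_sep,
                                  cfg.gly_policy, fold_label="B")
            consensus_to_tsv(map_a, map_paths[0])
            consensus_to_tsv(map_b, map_paths[1])
    except Exception as exc:                       # noqa: BLE001
        raise StageError("contacts", exc) from exc

    # -- stage: simulate ----------------------------------------------------
    try:
        params = SbmParams(eps_B=cfg.eps_B, eps_ratio=cfg.eps_ratio, w=cfg.w)
        ladder = temperature_ladder(cfg.t_min, cfg.t_max, cfg.n_replicas)
        rs = parallel_tempering(sequence, (map_a, map_b), params, ladder,
                                n_cycles=cfg.n_cycles,
                                exchange_interval=cfg.exchange_interval,
                                seed=cfg.seed, transferable=cfg.transferable_model,
                                record_stride=cfg.record_stride,
                                record_snapshots=True)
        for k, traj in enumerate(rs.trajectories):
            arr = traj.arrays()
            df = pd.DataFrame({"cycle" if name == "cycles" else name: arr[name]
                               for name in traj.FIELDS})
            path = outdir / f"traj_rung{k}.tsv"
            with path.open("w") as fh:
                fh.write(f"# {prov} T={traj.T}\n")
                df.to_csv(fh, sep="\t", index=False)
        _write_snapshots(rs, sequence, outdir / "snapshots.tsv", prov)
    except Exception as exc:                       # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # -- stage: wham + landscape + basins ------------------------------------
    try:
        keep = {T: np.asarray(t.E_total)[burn_in_slice(len(t), cfg.burn_in)]
                for T, t in zip(rs.ladder, rs.trajectories)}
        cv = heat_capacity(keep)
        pd.DataFrame({"T": cv.temperatures, "C_V": cv.C_V}).to_csv(
            outdir / "cv.tsv", sep="\t", index=False)
        samples = wham_reweight(rs, cv.T_m, cfg.burn_in)
        landscape = free_energy_landscape(samples, (cfg.grid, cfg.grid))
        landscape_to_tsv(landscape, outdir / "landscape.tsv")
        stats = basin_stats(samples)
        (outdir / "basins.json").write_text(json.dumps({
            "provenance": prov, "T_m": cv.T_m, "P_A": stats.P_A,
            "P_B": stats.P_B, "dF": stats.dF, "degenerate": stats.degenerate,
        }, indent=2))
    except Exception as exc:                       # noqa: BLE001
        raise StageError("wham", exc) from exc

    # -- stage: cluster + flux ----------------------------------------------
    try:
        ref_a, ref_b = strs_a[0], strs_b[0]
        snaps, q_a, q_b = [], [], []
        for traj in rs.trajectories:
            keep_slice = burn_in_slice(len(traj), cfg.burn_in)
            snaps.extend(traj.snapshots[keep_slice])
            q_a.extend(traj.Q_A[keep_slice])
            q_b.extend(traj.Q_B[keep_slice])
        vectors = np.array([superposition_vector(c, ref_a, ref_b) for c in snaps])
        k = min(cfg.k_clusters, len(vectors))
        clustering = cluster_conformations(vectors, k=k, seed=cfg.seed)
        pd.DataFrame({"conformation": np.arange(len(vectors)),
                      "cluster": clustering.assignments,
                      "Q_A": q_a, "Q_B": q_b}).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False)
        edges = centroid_graph(clustering, cfg.graph_threshold)
        pd.DataFrame(edges, columns=["a", "b", "rmsd_sm"]).to_csv(
            outdir / "centroid_graph.tsv", sep="\t", index=False)
        traj0 = rs.trajectories[0]
        flux = transition_flux(np.asarray(traj0.Q_A), np.asarray(traj0.Q_B))
        (outdir / "flux.json").write_text(json.dumps({
            "provenance": prov, "states": flux.states,
            "counts": flux.counts.tolist(),
            "two_way_GA_U": flux.two_way("G_A", "U"),
            "two_way_GB_U": flux.two_way("G_B", "U"),
        }, indent=2))
    except Exception as exc:                       # noqa: BLE001
        raise StageError("cluster", exc) from exc

    return outdir
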