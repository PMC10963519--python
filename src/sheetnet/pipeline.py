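"""End-to-end orchestration: config handling, stage execution, reports.

A pipeline run loads (or generates) one or more systems, prepares frames
(equilibration cut, alignment), and produces conformational, contact,
network, rigidity and conservation reports as plain CSV/JSON/GraphML
files, together with a manifest recording parameters and output hashes so
deterministic stages can be re-run byte-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformation, conservation, contacts, mechanics, netcomm, synthgen, traj_io
from .synthgen import GroundTruth, SheetSpec

log = logging.getLogger("sheetnet.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "sheetnet_out",
    "temperature": 300.0,
    "equilibration_frames": 0,
    "node_selection": {
        "exclude_chains": [],
        "exclude_restrained": True,
        "fit_on_restrained": True,
        "include_ligands": True,
        "ligand_atoms": {"GTP": "PB", "GDP": "PB"},
    },
    "cluster": {"cutoff_nm": 0.15, "linkage": "average", "stride": 1, "max_frames": 4000},
    "contacts": {"cutoff_nm": 0.45, "group_a_chains": None, "group_b_chains": None},
    "interactions": {
        "saltbridge_dist_nm": 0.55,
        "hbond_dist_nm": 0.35,
        "hbond_angle_deg": 130.0,
        "hydrophobic_dist_nm": 0.40,
        "stability_threshold": 0.75,
    },
    "network": {
        "contact_cutoff_nm": 0.45,
        "contact_fraction": 0.75,
        "knn_k": 5,
        "min_frames": 100,
    },
    "mechanics": {"exclude_within": 0},
    "conservation": {"msa": None, "gap_flag_threshold": 0.5, "reference": 0},
    "systems": [],
}


def demo_config(
    output_dir,
    seed: int = 5,
    n_frames: int = 2000,
    with_msa: bool = True,
) -> dict:
    """The packaged two-system study configuration.

    A uniform sheet (homophilic lateral interfaces only) and a seam-bearing
    sheet whose central lateral column is weakly coupled (0.2 vs 0.7, with
    0.9 longitudinal bonds), both 2 x 6 blocks with the four corner blocks
    position-restrained.  With ``with_msa`` a small synthetic alignment
    (one column per bead of a monomer block) is generated alongside so the
    conservation stage has input.
    """
    from . import synthgen

    output_dir = Path(output_dir)
    corners = [[0, 0], [0, 5], [1, 0], [1, 5]]
    sheet = {
        "n_rows": 2,
        "n_cols": 6,
        "coupling_long": 0.9,
        "coupling_lat": 0.7,
        "n_frames": n_frames,
        "restrained_blocks": corners,
    }
    seam = dict(sheet, coupling_seam=0.2, seam_col=2)
    overrides: dict = {
        "seed": seed,
        "output_dir": str(output_dir),
        "cluster": {"stride": max(1, n_frames // 200)},
        "systems": [
            {"name": "uniform", "generate": {"sheet": sheet}},
            {"name": "seam", "generate": {"sheet": seam}},
        ],
    }
    if with_msa:
        msa_path = output_dir / "inputs" / "toy_msa.fasta"
        msa_path.parent.mkdir(parents=True, exist_ok=True)
        profiles = [
            {"A": 1.0},
            {"A": 0.5, "F": 0.5},
            {l: 1 / 6 for l in "AFSKDG"},
            {"K": 0.7, "R": 0.3},
            {"D": 0.6, "G": 0.4},
        ]
        synthgen.gen_toy_msa(
            synthgen.MSASpec(
                n_sequences=400,
                column_profiles=profiles,
                seed=_stage_seed(seed, "msa"),
            ),
            msa_path,
        )
        overrides["conservation"] = {"msa": str(msa_path)}
    return _deep_update(DEFAULT_CONFIG, overrides)


def _deep_update(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (extra or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULT_CONFIG, user)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def validate_config(config: dict) -> None:
    if not config.get("systems"):
        raise ValueError("config lists no systems")
    for sysconf in config["systems"]:
        if "name" not in sysconf:
            raise ValueError("every system needs a 'name'")
        if "generate" in sysconf:
            continue
        if "topology" not in sysconf:
            raise ValueError(f"system {sysconf['name']}: missing 'topology'")
        if not Path(sysconf["topology"]).exists():
            raise FileNotFoundError(
                f"system {sysconf['name']}: topology {sysconf['topology']} not found"
            )
        for t in sysconf.get("trajectories", []):
            if not Path(t).exists():
                raise FileNotFoundError(
                    f"system {sysconf['name']}: trajectory {t} not found"
                )
    msa = config["conservation"]["msa"]
    if msa is not None and not Path(msa).exists():
        raise FileNotFoundError(f"conservation MSA {msa} not found")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def simulate_system(sysconf: dict, outdir: Path, root_seed: int):
    """Materialise a generated system to PDB + DCD (+ ground-truth JSON)."""
    gen = sysconf["generate"]
    name = sysconf["name"]
    outdir.mkdir(parents=True, exist_ok=True)
    pdb = outdir / f"{name}.pdb"
    dcd = outdir / f"{name}.dcd"
    if "sheet" in gen:
        opts = dict(gen["sheet"])
        opts.setdefault("seed", _stage_seed(root_seed, f"simulate:{name}"))
        if "restrained_blocks" in opts:
            opts["restrained_blocks"] = [tuple(b) for b in opts["restrained_blocks"]]
        spec = SheetSpec(**opts)
        system, truth = synthgen.gen_toy_sheet(spec)
        truth.to_json(outdir / f"{name}.groundtruth.json")
    elif "two_state" in gen:
        opts = dict(gen["two_state"])
        opts.setdefault("seed", _stage_seed(root_seed, f"simulate:{name}"))
        system, states = synthgen.gen_two_state_ensemble(**opts)
        np.savetxt(outdir / f"{name}.states.txt", states, fmt="%d")
    else:
        raise ValueError(f"system {name}: unknown generate block {sorted(gen)}")
    traj_io.write_system(system, pdb, dcd)
    return pdb, dcd


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _prepare_system(config: dict, sysconf: dict, outdir: Path):
    name = sysconf["name"]
    if "generate" in sysconf:
        pdb, dcd = simulate_system(sysconf, outdir / "inputs", config["seed"])
        trajectories = [dcd]
        truth_path = outdir / "inputs" / f"{name}.groundtruth.json"
        truth = GroundTruth.from_json(truth_path) if truth_path.exists() else None
    else:
        pdb = Path(sysconf["topology"])
        trajectories = [Path(t) for t in sysconf.get("trajectories", [])]
        truth = None
        sidecar = pdb.with_suffix(".groundtruth.json")
        if sidecar.exists():
            truth = GroundTruth.from_json(sidecar)

    system = traj_io.load_system(pdb, trajectories)
    cut = int(sysconf.get("equilibration_frames", config["equilibration_frames"]))
    if cut:
        system = traj_io.concat_equilibrated(system, cut)

    nodeconf = config["node_selection"]
    exclude = set(nodeconf["exclude_chains"])
    if truth is not None and nodeconf["exclude_restrained"]:
        exclude |= set(truth.restrained_chains)
    ligand_atoms = dict(nodeconf["ligand_atoms"]) if nodeconf["include_ligands"] else {}
    nodes = traj_io.select_nodes(system, exclude_chains=exclude, ligand_atoms=ligand_atoms)
    # position-restrained chains are the static scaffold: fitting on them
    # pins the lab frame without biasing the mobile residues' displacement
    # statistics; lacking restraints, fit on the analysis nodes themselves
    restrained = set(truth.restrained_chains) if truth is not None else set()
    if restrained and nodeconf.get("fit_on_restrained", True):
        fit = system.atoms.index[system.atoms["chain"].isin(restrained)].to_numpy()
    else:
        fit = nodes.atom_indices
    system = traj_io.align_frames(system, fit, reference="mean")
    return name, system, nodes, truth


def _contact_groups(config: dict, system, nodes, truth):
    """Atom index groups for the lateral-interface contact analysis."""
    conf = config["contacts"]
    atoms = system.atoms
    if conf["group_a_chains"] and conf["group_b_chains"]:
        ga = atoms.index[atoms["chain"].isin(conf["group_a_chains"])].to_numpy()
        gb = atoms.index[atoms["chain"].isin(conf["group_b_chains"])].to_numpy()
        return ga, gb
    if truth is not None:
        rows = sorted({r for r, _ in truth.block_grid})
        if len(rows) >= 2:
            included = set(nodes.labels["chain"])
            row_chains = {
                r: [
                    c for (rr, _), c in zip(truth.block_grid, truth.block_chains)
                    if rr == r and c in included
                ]
                for r in rows[:2]
            }
            ga = atoms.index[atoms["chain"].isin(row_chains[rows[0]])].to_numpy()
            gb = atoms.index[atoms["chain"].isin(row_chains[rows[1]])].to_numpy()
            if ga.size and gb.size:
                return ga, gb
    return None, None


ALL_STAGES = ("conformation", "contacts", "network", "mechanics", "conservation")


def run_pipeline(config: dict, outdir=None, stages=None) -> dict:
    """Execute the requested stages for every configured system.

    ``stages`` is a subset of :data:`ALL_STAGES` (default: all).  Returns
    a results dict with per-system reports; all tabular outputs are also
    written under ``outdir`` together with ``manifest.json``.
    """
    stages = set(ALL_STAGES if stages is None else stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
    validate_config(config)
    outdir = Path(outdir if outdir is not None else config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"systems": {}, "outputs": []}

    def emit(df: pd.DataFrame, relpath: str) -> None:
        path = outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
        results["outputs"].append(relpath)

    geometry = contacts.InteractionGeometry(
        saltbridge_dist=config["interactions"]["saltbridge_dist_nm"],
        hbond_dist=config["interactions"]["hbond_dist_nm"],
        hbond_angle_deg=config["interactions"]["hbond_angle_deg"],
        hydrophobic_dist=config["interactions"]["hydrophobic_dist_nm"],
    )

    contact_tables: dict[str, contacts.ContactTable] = {}
    interaction_sets: list[list[contacts.InteractionRecord]] = []
    ranked_lists: dict[str, np.ndarray] = {}
    networks, reports, profiles = {}, {}, []

    for sysconf in config["systems"]:
        name, system, nodes, truth = _prepare_system(config, sysconf, outdir)
        log.info("system %s: %d frames, %d nodes", name, system.n_frames, len(nodes))
        res: dict = {"n_frames": system.n_frames, "n_nodes": len(nodes)}
        emit(nodes.labels, f"{name}/nodes.csv")

        # conformational stability
        if "conformation" in stages:
            rs = conformation.rmsd_series(system, nodes.atom_indices)
            emit(rs.to_frame(), f"{name}/rmsd.csv")
            cl = conformation.cluster_frames(
                system,
                nodes.atom_indices,
                cutoff=config["cluster"]["cutoff_nm"],
                method=config["cluster"]["linkage"],
                stride=config["cluster"]["stride"],
                max_frames=config["cluster"]["max_frames"],
            )
            emit(
                pd.DataFrame({"frame": cl.frames, "cluster": cl.labels}),
                f"{name}/clusters.csv",
            )
            res["n_clusters"] = cl.n_clusters

        # contacts and typed interactions across the lateral interface
        ga, gb = (
            _contact_groups(config, system, nodes, truth)
            if "contacts" in stages
            else (None, None)
        )
        if ga is not None:
            table = contacts.contact_frequency(
                system, ga, gb, cutoff=config["contacts"]["cutoff_nm"]
            )
            contact_tables[name] = table
            emit(table.pairs, f"{name}/contact_pairs.csv")
            emit(table.marginals, f"{name}/contact_marginals.csv")
            records = contacts.classify_interactions(
                system, ga, gb, geometry=geometry, interface="lateral"
            )
            interaction_sets.append(records)
            emit(
                pd.DataFrame(
                    [
                        (r.kind, *r.res_i, *r.res_j, r.frequency, r.interface)
                        for r in records
                    ],
                    columns=[
                        "kind", "chain_i", "resid_i", "resname_i",
                        "chain_j", "resid_j", "resname_j", "frequency", "interface",
                    ],
                ),
                f"{name}/interactions.csv",
            )

        # dynamical network + centrality
        if "network" not in stages:
            if "mechanics" in stages:
                profile = mechanics.force_constant_profile(
                    system,
                    nodes,
                    temperature=config["temperature"],
                    exclude_within=config["mechanics"]["exclude_within"],
                )
                profiles.append(profile)
                emit(profile.per_residue, f"{name}/force_constants.csv")
            results["systems"][name] = res
            res["truth"] = truth
            continue
        net = netcomm.build_network(
            system,
            nodes,
            contact_cutoff=config["network"]["contact_cutoff_nm"],
            contact_fraction=config["network"]["contact_fraction"],
            knn_k=config["network"]["knn_k"],
            seed=_stage_seed(config["seed"], f"network:{name}"),
            min_frames=config["network"]["min_frames"],
        )
        report = netcomm.betweenness_centrality(net)
        networks[name], reports[name] = net, report
        net.write_graphml(outdir / f"{name}/network.graphml")
        results["outputs"].append(f"{name}/network.graphml")
        emit(
            pd.DataFrame(
                {
                    "node": report.degree.index,
                    "degree": report.degree.to_numpy(),
                    "betweenness": report.node_betweenness.to_numpy(),
                }
            ),
            f"{name}/node_centrality.csv",
        )
        ids = net.nodes.node_ids()
        edge_df = pd.DataFrame(
            [
                (ids[i], ids[j], net.weights[i, j], b)
                for (i, j), b in sorted(
                    report.edge_betweenness.items(), key=lambda kv: -kv[1]
                )
            ],
            columns=["node_i", "node_j", "weight", "betweenness"],
        )
        emit(edge_df, f"{name}/edge_centrality.csv")
        ranked_lists[name] = edge_df["betweenness"].to_numpy()
        res["n_edges"] = len(edge_df)
        res["knee"] = netcomm.knee_threshold(ranked_lists[name])

        # rigidity
        if "mechanics" in stages:
            profile = mechanics.force_constant_profile(
                system,
                nodes,
                temperature=config["temperature"],
                exclude_within=config["mechanics"]["exclude_within"],
            )
            profiles.append(profile)
            emit(profile.per_residue, f"{name}/force_constants.csv")

        results["systems"][name] = res
        res["truth"] = truth

    # cross-system reports -------------------------------------------------
    names = list(results["systems"])
    if ranked_lists:
        threshold = netcomm.shared_knee_threshold(list(ranked_lists.values()))
        results["shared_knee_threshold"] = threshold
        for name in names:
            te = netcomm.top_edges(networks[name], reports[name], threshold)
            emit(te, f"{name}/top_edges.csv")
            results["systems"][name]["top_edges"] = te
            emit(
                netcomm.chain_centrality_summary(
                    networks[name], reports[name], threshold
                ),
                f"{name}/chain_centrality.csv",
            )

    if len(contact_tables) >= 2:
        ref_name = names[0]
        for name in names[1:]:
            if name in contact_tables:
                diff = contacts.contact_difference(
                    contact_tables[name], contact_tables[ref_name]
                )
                emit(diff, f"{name}/contact_difference_vs_{ref_name}.csv")
                results["systems"][name]["contact_difference"] = diff
    if interaction_sets:
        stable = contacts.stable_interactions(
            interaction_sets, threshold=config["interactions"]["stability_threshold"]
        )
        emit(stable, "stable_interactions.csv")
        results["stable_interactions"] = stable

    agg = None
    if profiles:
        agg = mechanics.aggregate_profiles(profiles)
        emit(agg, "force_constants_aggregate.csv")
        results["force_constants"] = agg

    msa_path = config["conservation"]["msa"]
    if msa_path and "conservation" in stages:
        msa = conservation.read_msa(msa_path)
        prof = conservation.stereochemical_entropy_profile(
            msa, gap_flag_threshold=config["conservation"]["gap_flag_threshold"]
        )
        emit(prof.per_column, "conservation.csv")
        ne_by_pos = prof.ne_by_reference_position(
            msa, config["conservation"]["reference"]
        )
        k_series = (
            mechanics.ForceConstantProfile(
                per_residue=agg.rename(columns={"k_mean": "k"}),
                temperature=config["temperature"],
            ).k_series()
            if agg is not None
            else pd.Series(dtype=float)
        )
        # residues map onto alignment positions by their order within the
        # chain (position p of every chain follows reference position p)
        if agg is not None:
            chain_pos = agg.groupby("chain").cumcount() + 1
            ne_series = pd.Series(
                {
                    nid: ne_by_pos.get(int(p), np.nan)
                    for nid, p in zip(k_series.index, chain_pos)
                }
            ).dropna()
        else:
            ne_series = pd.Series(dtype=float)
        if len(ne_series):
            summary = mechanics.rigid_set_conservation(k_series, ne_series)
            results["rigid_set"] = summary
            with open(outdir / "rigid_set.json", "w") as fh:
                json.dump(summary, fh, indent=1)
            results["outputs"].append("rigid_set.json")

    manifest = {
        "config": _jsonable(config),
        "outputs": {
            rel: _sha256(outdir / rel) for rel in results["outputs"]
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
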