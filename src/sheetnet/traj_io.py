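"""Topology/trajectory I/O, node selection and frame preparation.

Files are read and written through MDAnalysis (PDB topology, DCD/XTC
trajectories).  Internally everything is in nm; MDAnalysis works in
angstroms, so readers multiply by 0.1 and writers by 10.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .system import MolecularSystem, NodeSelection, kabsch_rotation

NM_PER_ANGSTROM = 0.1


def _quiet_mda():
    import MDAnalysis as mda

    return mda


def write_system(
    system: MolecularSystem,
    pdb_path,
    traj_path=None,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write the first frame as PDB and, optionally, all frames as a
    DCD/XTC trajectory (format chosen from the file suffix)."""
    mda = _quiet_mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    atoms = system.atoms
    n_atoms = len(atoms)
    res_key = atoms[["chain", "resid"]].astype(str).agg(":".join, axis=1)
    res_codes, res_uniques = pd.factorize(res_key)
    n_res = len(res_uniques)
    first_atom = pd.Series(np.arange(n_atoms)).groupby(res_codes).min()

    seg_key = atoms["chain"].to_numpy()
    seg_codes, seg_uniques = pd.factorize(pd.Series(seg_key))
    res_seg = seg_codes[first_atom.to_numpy()]

    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_res,
        n_segments=len(seg_uniques),
        atom_resindex=res_codes,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].to_list())
    u.add_TopologyAttr("elements", atoms["element"].to_list())
    u.add_TopologyAttr("resids", atoms["resid"].to_numpy()[first_atom.to_numpy()])
    u.add_TopologyAttr("resnames", atoms["resname"].to_numpy()[first_atom.to_numpy()])
    u.add_TopologyAttr("chainIDs", atoms["chain"].to_list())
    u.add_TopologyAttr("segids", [str(s) for s in seg_uniques])
    u.add_TopologyAttr("occupancies", np.ones(n_atoms))
    u.add_TopologyAttr(
        "tempfactors",
        np.zeros(n_atoms) if bfactors is None else np.asarray(bfactors, dtype=float),
    )
    coords_ang = np.asarray(system.coords, dtype=np.float32) / NM_PER_ANGSTROM
    u.load_new(coords_ang, format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))
        if traj_path is not None:
            with mda.Writer(str(traj_path), n_atoms=n_atoms) as writer:
                for _ in u.trajectory:
                    writer.write(u.atoms)


def load_system(topology, trajectories=None) -> MolecularSystem:
    """Load a PDB topology plus zero or more trajectory files.

    Frames are ordered replica by replica in the order the trajectory
    paths are given; replica boundaries are recorded on the returned
    system.  With no trajectories the single PDB model is the only frame.
    """
    mda = _quiet_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology))
    atoms = pd.DataFrame(
        {
            "name": u.atoms.names,
            "element": [
                (e if e else n[0])
                for e, n in zip(
                    getattr(u.atoms, "elements", [""] * len(u.atoms)), u.atoms.names
                )
            ],
            "resid": u.atoms.resids,
            "resname": u.atoms.resnames,
            "chain": getattr(u.atoms, "chainIDs", u.atoms.segids),
        }
    )
    n_atoms = len(atoms)
    if trajectories is None or len(trajectories) == 0:
        coords = u.atoms.positions[None, :, :] * NM_PER_ANGSTROM
        return MolecularSystem(atoms, coords.astype(np.float64))

    stacks, boundaries, start = [], [], 0
    for path in trajectories:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ur = mda.Universe(str(topology), str(path))
        if len(ur.atoms) != n_atoms:
            raise ValueError(
                f"trajectory {path} has {len(ur.atoms)} atoms, topology has {n_atoms}"
            )
        frames = np.array(
            [ur.atoms.positions.copy() for _ in ur.trajectory], dtype=np.float64
        )
        if frames.shape[0] == 0:
            raise ValueError(f"trajectory {path} contains no frames")
        stacks.append(frames * NM_PER_ANGSTROM)
        boundaries.append((start, start + frames.shape[0]))
        start += frames.shape[0]
    return MolecularSystem(atoms, np.concatenate(stacks, axis=0), boundaries)


def select_nodes(
    system: MolecularSystem,
    exclude_chains=(),
    ligand_atoms: dict[str, str] | None = None,
    representative: str = "CA",
) -> NodeSelection:
    """One node per residue of every non-excluded chain.

    Amino-acid residues are represented by their ``CA`` atom (or
    ``representative``); residues whose name appears in ``ligand_atoms``
    (e.g. ``{"GTP": "PB"}``) use the mapped atom instead.  Node order is a
    pure function of the topology: (chain, resid) sorted.
    """
    ligand_atoms = ligand_atoms or {}
    exclude = set(exclude_chains)
    present = set(system.atoms["chain"].unique())
    missing = exclude - present
    if missing:
        raise ValueError(f"excluded chains not in system: {sorted(missing)}")

    atoms = system.atoms.reset_index().rename(columns={"index": "atom_index"})
    atoms = atoms[~atoms["chain"].isin(exclude)]
    indices, rows = [], []
    grouped = atoms.groupby(["chain", "resid"], sort=True)
    for (chain, resid), grp in grouped:
        resname = grp["resname"].iloc[0]
        want = ligand_atoms.get(resname, representative)
        hit = grp[grp["name"] == want]
        if hit.empty:
            raise ValueError(
                f"residue {chain}:{resid}:{resname} lacks representative atom {want!r}"
            )
        indices.append(int(hit["atom_index"].iloc[0]))
        rows.append((chain, resid, resname, want))
    labels = pd.DataFrame(rows, columns=["chain", "resid", "resname", "name"])
    return NodeSelection(
        atom_indices=np.asarray(indices, dtype=int),
        labels=labels,
        excluded_chains=frozenset(exclude),
    )


def concat_equilibrated(
    system: MolecularSystem, equil_frames_per_replica: int
) -> MolecularSystem:
    """Drop the first ``equil_frames_per_replica`` frames of each replica
    and concatenate the remainders."""
    cut = int(equil_frames_per_replica)
    if cut < 0:
        raise ValueError("equilibration cut must be non-negative")
    pieces, boundaries, start = [], [], 0
    for a, b in system.replica_boundaries:
        if b - a <= cut:
            raise ValueError(
                f"equilibration cut {cut} >= replica length {b - a} for replica ({a}, {b})"
            )
        pieces.append(system.coords[a + cut : b])
        boundaries.append((start, start + (b - a - cut)))
        start += b - a - cut
    return system.with_coords(np.concatenate(pieces, axis=0), boundaries)


def _check_fit_selection(ref_points: np.ndarray) -> None:
    if ref_points.shape[0] == 0:
        raise ValueError("fit selection is empty")
    if ref_points.shape[0] >= 3:
        centred = ref_points - ref_points.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        if svals[1] < 1e-10:
            raise ValueError("fit selection is degenerate (collinear points)")


def align_frames(
    system: MolecularSystem,
    fit_indices: np.ndarray,
    reference: int | str = "mean",
) -> MolecularSystem:
    """Least-squares superpose every frame onto a reference over the fit
    atoms, applying the rigid transform to all atoms.

    ``reference`` is a frame index, or ``"mean"`` for the two-pass
    procedure: fit everything to frame 0, take the mean structure of the
    fit atoms, then fit the original frames onto that mean.
    """
    fit_indices = np.asarray(fit_indices, dtype=int)
    coords = system.coords

    def _fit_to(target_fit: np.ndarray) -> np.ndarray:
        mobile_fit = coords[:, fit_indices, :]
        _check_fit_selection(target_fit)
        mc = mobile_fit.mean(axis=1, keepdims=True)
        tc = target_fit.mean(axis=0, keepdims=True)
        rot = kabsch_rotation(mobile_fit - mc, target_fit[None, :, :] - tc)
        return (
            np.einsum("fni,fij->fnj", coords - mc, np.swapaxes(rot, -1, -2))
            + tc[None, :, :]
        )

    if reference == "mean":
        pass1 = _fit_to(coords[0, fit_indices, :])
        mean_fit = pass1[:, fit_indices, :].mean(axis=0)
        aligned = _fit_to(mean_fit)
    else:
        aligned = _fit_to(coords[int(reference), fit_indices, :])
    return system.with_coords(aligned, list(system.replica_boundaries))
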