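"""Shared in-memory containers and rigid-body geometry helpers.

All coordinates are stored in nanometres.  File writers convert to
angstroms where a format (PDB, DCD) expects them; see :mod:`sheetnet.traj_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every atom table must carry (plus an implicit 0-based row index)
ATOM_COLUMNS = ("name", "element", "resid", "resname", "chain")


@dataclass
class MolecularSystem:
    """Topology (atom table) plus an ordered stack of coordinate frames.

    Parameters
    ----------
    atoms
        One row per atom with columns ``name``, ``element``, ``resid``,
        ``resname``, ``chain``.  Residue ids follow PDB convention
        (1-based, unique within a chain).
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    replica_boundaries
        Half-open frame ranges ``(start, stop)`` marking independent
        replicas; defaults to a single replica spanning all frames.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    replica_boundaries: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"atom table length {len(self.atoms)}"
            )
        self.atoms = self.atoms.reset_index(drop=True)
        if self.replica_boundaries is None:
            self.replica_boundaries = [(0, self.n_frames)]
        cov = sum(b - a for a, b in self.replica_boundaries)
        if cov != self.n_frames:
            raise ValueError("replica boundaries do not tile the trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def with_coords(
        self,
        coords: np.ndarray,
        replica_boundaries: list[tuple[int, int]] | None = None,
    ) -> "MolecularSystem":
        """Same topology, new frames."""
        return MolecularSystem(self.atoms, coords, replica_boundaries)

    def residues(self) -> pd.DataFrame:
        """Unique residues in (chain, resid) order of first appearance."""
        res = self.atoms[["chain", "resid", "resname"]].drop_duplicates()
        return res.reset_index(drop=True)


@dataclass(frozen=True)
class NodeSelection:
    """One representative atom per included residue.

    ``labels`` carries one row per node (``chain``, ``resid``, ``resname``,
    ``name`` of the representative atom) aligned with ``atom_indices``.
    """

    atom_indices: np.ndarray
    labels: pd.DataFrame
    excluded_chains: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def node_ids(self) -> list[str]:
        """Stable human-readable node identifiers, e.g. ``A:5:TUA``."""
        return [
            f"{r.chain}:{r.resid}:{r.resname}" for r in self.labels.itertuples()
        ]


def node_coordinates(system: MolecularSystem, nodes: NodeSelection) -> np.ndarray:
    """(n_frames, n_nodes, 3) coordinate stack of the node atoms."""
    return system.coords[:, nodes.atom_indices, :]


# ---------------------------------------------------------------------------
# rigid-body superposition (Kabsch), batched over leading dimensions
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrices mapping centred ``mobile`` onto centred
    ``target``; both ``(..., n, 3)``.  Returns ``(..., 3, 3)``."""
    h = np.einsum("...ni,...nj->...ij", mobile, target)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("...ij,...jk->...ik", u, vt))
    flip = np.ones(u.shape[:-2] + (3,))
    flip[..., -1] = np.sign(det)
    return np.einsum("...ij,...j,...jk->...ki", u, flip, vt)


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` (shapes
    ``(..., n, 3)``): optimal translation + rotation, no scaling."""
    mc = mobile.mean(axis=-2, keepdims=True)
    tc = target.mean(axis=-2, keepdims=True)
    rot = kabsch_rotation(mobile - mc, target - tc)
    return np.einsum("...ni,...ij->...nj", mobile - mc, np.swapaxes(rot, -1, -2)) + tc


def rmsd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Coordinate RMSD between matching point sets ``(..., n, 3)``."""
    d = a - b
    return np.sqrt(np.einsum("...ni,...ni->...", d, d) / a.shape[-2])


def fitted_rmsd(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """RMSD after optimal superposition."""
    return rmsd(superpose(mobile, target), target)
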