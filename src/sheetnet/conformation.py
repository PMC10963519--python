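"""Conformational descriptors: RMSD series, RMSF profiles and
hierarchical clustering of trajectory frames.

Frame-frame distances use the coordinate RMSD after optimal pairwise
superposition over the chosen selection, mirroring the usual practice of
clustering a trajectory on the RMSD of a structural core (here: the
selection the caller supplies, e.g. the Calpha atoms of a central dimer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .system import MolecularSystem, fitted_rmsd


@dataclass
class RmsdSeries:
    values: np.ndarray  # per-frame RMSD vs reference, nm
    reference_frame: int
    selection_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)), "rmsd_nm": self.values})


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-analysed-frame cluster id, contiguous from 1
    frames: np.ndarray  # trajectory frame index of each analysed frame
    cutoff: float  # nm
    linkage_method: str

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def rmsd_series(
    system: MolecularSystem, selection: np.ndarray, reference: int = 0
) -> RmsdSeries:
    """RMSD of the selection vs a fixed reference frame, each frame
    optimally superposed onto the reference over the same selection."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    sel = system.coords[:, selection, :]
    ref = sel[reference]
    vals = fitted_rmsd(sel, ref[None, :, :])
    return RmsdSeries(values=vals, reference_frame=reference, selection_size=selection.size)


def rmsf_profile(system: MolecularSystem, selection: np.ndarray) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    Assumes frames are already aligned; for an isotropic Gaussian with
    per-axis sigma the RMSF converges to sigma*sqrt(3).
    """
    if system.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = system.coords[:, np.asarray(selection, dtype=int), :]
    dev = sel - sel.mean(axis=0, keepdims=True)
    return np.sqrt(np.einsum("fni,fni->n", dev, dev) / sel.shape[0])


def pairwise_rmsd_matrix(
    system: MolecularSystem, selection: np.ndarray, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric zero-diagonal matrix of pairwise fitted RMSDs over the
    strided frames; returns (matrix, analysed frame indices)."""
    selection = np.asarray(selection, dtype=int)
    frames = np.arange(0, system.n_frames, stride)
    sel = system.coords[frames][:, selection, :]
    f = len(frames)
    ii, jj = np.triu_indices(f, k=1)
    vals = fitted_rmsd(sel[ii], sel[jj])
    mat = np.zeros((f, f))
    mat[ii, jj] = vals
    mat[jj, ii] = vals
    return mat, frames


def cluster_frames(
    system: MolecularSystem,
    selection: np.ndarray,
    cutoff: float = 0.15,
    method: str = "average",
    stride: int = 1,
    max_frames: int = 4000,
) -> ClusterAssignment:
    """Agglomerative clustering of frames on the pairwise fitted-RMSD
    matrix, cut at ``cutoff`` (nm).

    The pairwise matrix is O(F^2); ``stride`` subsamples frames and
    ``max_frames`` guards against accidental quadratic blow-ups.
    """
    if system.n_frames < 2:
        raise ValueError("clustering needs at least 2 frames")
    n_eff = (system.n_frames + stride - 1) // stride
    if n_eff > max_frames:
        raise ValueError(
            f"{n_eff} frames exceed the pairwise-matrix guard ({max_frames}); "
            "increase stride or max_frames"
        )
    mat, frames = pairwise_rmsd_matrix(system, selection, stride)
    condensed = squareform(mat, checks=False)
    z = linkage(condensed, method=method)
    raw = fcluster(z, t=cutoff, criterion="distance")
    # relabel contiguously from 1 in order of first appearance
    order = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order) + 1
        labels[i] = order[lab]
    return ClusterAssignment(labels=labels, frames=frames, cutoff=cutoff, linkage_method=method)
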