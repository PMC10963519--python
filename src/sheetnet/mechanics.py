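"""Per-residue rigidity (force-constant) profiles.

A residue's effective force constant is obtained from the fluctuation of
its mean distance to all other network nodes:

    d_i(t) = <||r_i(t) - r_j(t)||>_{j != i}
    k_i    = 3 kB T / Var(d_i)

so residues whose average distance to the rest of the structure barely
fluctuates are mechanically rigid (large k_i).  The 3 kB T numerator is
the convention of the mean-distance-fluctuation rigidity method; note it
refers to the scalar distance coordinate, so for an isotropic harmonic
probe with per-axis variance kB T / k measured against a one-sided anchor
cloud the profile reads 3k (see the package methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import MolecularSystem, NodeSelection, node_coordinates

KB = 0.0083144621  # kJ mol^-1 K^-1


@dataclass
class ForceConstantProfile:
    per_residue: pd.DataFrame  # chain, resid, resname, k (kJ mol^-1 nm^-2), mean_d, var_d
    temperature: float

    def k_series(self) -> pd.Series:
        idx = [
            f"{r.chain}:{r.resid}:{r.resname}" for r in self.per_residue.itertuples()
        ]
        return pd.Series(self.per_residue["k"].to_numpy(), index=idx, name="k")


def _pairwise_mean_distances(coords: np.ndarray, exclude_within: int, chains, resids):
    """(n_frames, n_nodes) series of each node's mean distance to the
    other nodes, optionally excluding sequence neighbours within
    ``exclude_within`` residues on the same chain."""
    f, n, _ = coords.shape
    mask = ~np.eye(n, dtype=bool)
    if exclude_within > 0:
        same_chain = chains[:, None] == chains[None, :]
        close = np.abs(resids[:, None] - resids[None, :]) <= exclude_within
        mask &= ~(same_chain & close)
    denom = mask.sum(axis=1)
    if np.any(denom == 0):
        raise ValueError("a node has no distance partners after exclusion")
    out = np.empty((f, n))
    chunk = max(1, int(2e7 // (n * n)))  # bound the (frames, n, n) workspace
    for a in range(0, f, chunk):
        b = min(a + chunk, f)
        diff = coords[a:b, :, None, :] - coords[a:b, None, :, :]
        dist = np.sqrt(np.einsum("fijk,fijk->fij", diff, diff))
        out[a:b] = (dist * mask[None, :, :]).sum(axis=2) / denom[None, :]
    return out


def mean_distance_series(
    system: MolecularSystem,
    nodes: NodeSelection,
    target: int,
    exclude_within: int = 0,
) -> np.ndarray:
    """Per-frame mean distance of node ``target`` to all other nodes."""
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    if system.n_frames < 2:
        raise ValueError("need at least 2 frames")
    coords = node_coordinates(system, nodes)
    chains = pd.factorize(nodes.labels["chain"])[0]
    resids = nodes.labels["resid"].to_numpy()
    return _pairwise_mean_distances(coords, exclude_within, chains, resids)[:, target]


def force_constant_profile(
    system: MolecularSystem,
    nodes: NodeSelection,
    temperature: float = 300.0,
    exclude_within: int = 0,
) -> ForceConstantProfile:
    """Force constant per node from mean-distance fluctuations.

    Zero-variance nodes (static residues) get ``k = inf`` and are flagged;
    they are excluded from any downstream ranking.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    coords = node_coordinates(system, nodes)
    chains = pd.factorize(nodes.labels["chain"])[0]
    resids = nodes.labels["resid"].to_numpy()
    d = _pairwise_mean_distances(coords, exclude_within, chains, resids)
    var = d.var(axis=0)
    with np.errstate(divide="ignore"):
        k = np.where(var > 0, 3.0 * KB * temperature / np.where(var > 0, var, 1.0), np.inf)
    table = nodes.labels[["chain", "resid", "resname"]].copy()
    table["k"] = k
    table["mean_d"] = d.mean(axis=0)
    table["var_d"] = var
    table["zero_variance"] = var == 0
    return ForceConstantProfile(per_residue=table, temperature=temperature)


def aggregate_profiles(profiles: list[ForceConstantProfile]) -> pd.DataFrame:
    """Mean and min-max envelope of per-residue force constants across
    systems (residues matched on chain:resid labels)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    base = profiles[0].per_residue[["chain", "resid", "resname"]].copy()
    stack = np.stack([p.per_residue["k"].to_numpy() for p in profiles])
    base["k_mean"] = stack.mean(axis=0)
    base["k_min"] = stack.min(axis=0)
    base["k_max"] = stack.max(axis=0)
    return base


def rigid_set_conservation(
    k: pd.Series, conservation: pd.Series
) -> dict[str, float]:
    """Median conservation entropy within the mechanically rigid set.

    The rigid set holds residues with ``k`` strictly above the median of
    the finite profile; both series must share residue labels.  Returns
    the rigid-set median NE and the overall median NE for comparison.
    """
    common = k.index.intersection(conservation.index)
    if len(common) == 0:
        raise ValueError("force-constant and conservation labels do not overlap")
    kk = k.loc[common]
    ne = conservation.loc[common]
    finite = np.isfinite(kk.to_numpy())
    kk, ne = kk[finite], ne[finite]
    med_k = float(np.median(kk))
    rigid = kk > med_k
    return {
        "median_k": med_k,
        "n_rigid": int(rigid.sum()),
        "median_ne_rigid": float(np.median(ne[rigid])) if rigid.any() else float("nan"),
        "median_ne_all": float(np.median(ne)),
    }
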