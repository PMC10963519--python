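"""Contact frequencies and geometric non-covalent interaction typing.

A contact between two residues exists in a frame when any heavy-atom pair
is within a distance cutoff (default 0.45 nm).  Interactions are typed
geometrically with conventional profiler criteria: salt bridges by
charged-group centroid distance, hydrogen bonds by donor-acceptor
heavy-atom distance (plus a D-H...A angle when hydrogens exist in the
topology), hydrophobic contacts by apolar-carbon pair distance.  All
thresholds are parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .system import MolecularSystem

log = logging.getLogger(__name__)


@dataclass
class InteractionGeometry:
    """Geometric criteria for interaction typing (all distances in nm)."""

    saltbridge_dist: float = 0.55
    hbond_dist: float = 0.35
    hbond_angle_deg: float = 130.0
    hydrophobic_dist: float = 0.40
    his_protonated: bool = False


POSITIVE_GROUPS = {"LYS": ["NZ"], "ARG": ["NH1", "NH2"]}
HIS_POSITIVE = {"HIS": ["ND1", "NE2"], "HSP": ["ND1", "NE2"]}
NEGATIVE_GROUPS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
#: nucleotide phosphates count as negative groups
PHOSPHATE_RESNAMES = {"GTP", "GDP", "ATP", "ADP"}
HYDROPHOBIC_RESNAMES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

STANDARD_RESNAMES = (
    set(POSITIVE_GROUPS) | set(HIS_POSITIVE) | set(NEGATIVE_GROUPS)
    | HYDROPHOBIC_RESNAMES | PHOSPHATE_RESNAMES
    | {"GLY", "SER", "THR", "CYS", "ASN", "GLN", "TUA", "TUB", "PRB", "ANC"}
)


@dataclass
class ContactTable:
    """Per-residue-pair contact frequencies plus per-residue marginals."""

    pairs: pd.DataFrame  # chain_i, resid_i, resname_i, chain_j, ..., frequency
    marginals: pd.DataFrame  # chain, resid, resname, frequency (contact w/ any partner)
    cutoff: float
    group_a: str = "A"
    group_b: str = "B"
    n_frames: int = 0


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # hydrogen_bond | salt_bridge | hydrophobic
    res_i: tuple  # (chain, resid, resname)
    res_j: tuple
    atoms_i: tuple
    atoms_j: tuple
    frequency: float
    interface: str = ""
    distance_only: bool = False  # hydrogen bonds without angle check

    def key(self) -> tuple:
        return (self.kind, self.res_i, self.res_j)


def _heavy(system: MolecularSystem, indices: np.ndarray) -> np.ndarray:
    elements = system.atoms["element"].to_numpy()
    return np.asarray([i for i in indices if elements[i].upper() != "H"], dtype=int)


def _residue_keys(system: MolecularSystem, indices: np.ndarray) -> list[tuple]:
    sub = system.atoms.iloc[indices]
    return list(zip(sub["chain"], sub["resid"], sub["resname"]))


def contact_frequency(
    system: MolecularSystem,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 0.45,
    labels: tuple[str, str] = ("A", "B"),
) -> ContactTable:
    """Contact frequency for every residue pair across two disjoint atom
    groups, plus each residue's marginal frequency of touching any partner."""
    idx_a = _heavy(system, np.asarray(group_a, dtype=int))
    idx_b = _heavy(system, np.asarray(group_b, dtype=int))
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("contact groups must be non-empty (heavy atoms)")
    if set(idx_a) & set(idx_b):
        raise ValueError("contact groups must be disjoint")

    nf = system.n_frames
    keys_a = _residue_keys(system, idx_a)
    keys_b = _residue_keys(system, idx_b)
    counts: dict[tuple, int] = {}
    marg_counts: dict[tuple, int] = {}
    for f in range(nf):
        ta = cKDTree(system.coords[f, idx_a, :])
        tb = cKDTree(system.coords[f, idx_b, :])
        seen, touched = set(), set()
        for ia, hits in enumerate(ta.query_ball_tree(tb, r=cutoff)):
            if hits:
                touched.add(keys_a[ia])
            for ib in hits:
                seen.add((keys_a[ia], keys_b[ib]))
                touched.add(keys_b[ib])
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
        for key in touched:
            marg_counts[key] = marg_counts.get(key, 0) + 1

    rows = [
        ka + kb + (c / nf,) for (ka, kb), c in sorted(counts.items()) if ka != kb
    ]
    pairs = pd.DataFrame(
        rows,
        columns=[
            "chain_i", "resid_i", "resname_i",
            "chain_j", "resid_j", "resname_j", "frequency",
        ],
    )
    all_keys = sorted(set(keys_a) | set(keys_b))
    marginals = pd.DataFrame(
        [(k[0], k[1], k[2], marg_counts.get(k, 0) / nf) for k in all_keys],
        columns=["chain", "resid", "resname", "frequency"],
    )
    return ContactTable(
        pairs=pairs, marginals=marginals, cutoff=cutoff,
        group_a=labels[0], group_b=labels[1], n_frames=nf,
    )


# ---------------------------------------------------------------------------
# typed interactions
# ---------------------------------------------------------------------------

def _charged_atoms(system: MolecularSystem, indices: np.ndarray, geometry: InteractionGeometry):
    """(positive, negative) lists of (residue_key, atom_indices)."""
    atoms = system.atoms
    pos_defs = dict(POSITIVE_GROUPS)
    if geometry.his_protonated:
        pos_defs.update(HIS_POSITIVE)
    pos, neg = [], []
    sub = atoms.iloc[indices]
    for (chain, resid), grp in sub.groupby(
        [sub["chain"], sub["resid"]], sort=True
    ):
        resname = grp["resname"].iloc[0]
        key = (chain, resid, resname)
        if resname in pos_defs:
            hit = grp.index[grp["name"].isin(pos_defs[resname])].to_numpy()
            if hit.size:
                pos.append((key, hit))
        if resname in NEGATIVE_GROUPS:
            hit = grp.index[grp["name"].isin(NEGATIVE_GROUPS[resname])].to_numpy()
            if hit.size:
                neg.append((key, hit))
        if resname in PHOSPHATE_RESNAMES:
            mask = (grp["element"].str.upper() == "P") | grp["name"].str.match(
                r"O[0-9]"
            )
            hit = grp.index[mask].to_numpy()
            if hit.size:
                neg.append((key, hit))
    return pos, neg


def _polar_atoms(system: MolecularSystem, indices: np.ndarray) -> np.ndarray:
    sub = system.atoms.iloc[indices]
    mask = sub["element"].str.upper().isin(["N", "O"])
    return sub.index[mask].to_numpy()


def _apolar_carbons(system: MolecularSystem, indices: np.ndarray) -> np.ndarray:
    sub = system.atoms.iloc[indices]
    mask = (
        (sub["element"].str.upper() == "C")
        & ~sub["name"].isin(BACKBONE_NAMES)
        & sub["resname"].isin(HYDROPHOBIC_RESNAMES)
    )
    return sub.index[mask].to_numpy()


def _hydrogens_near(system: MolecularSystem, donor_idx: int) -> np.ndarray:
    """Hydrogens of the donor's residue within covalent range (0.12 nm)
    of the donor heavy atom, evaluated on frame 0 geometry."""
    atoms = system.atoms
    row = atoms.iloc[donor_idx]
    same_res = atoms.index[
        (atoms["chain"] == row["chain"])
        & (atoms["resid"] == row["resid"])
        & (atoms["element"].str.upper() == "H")
    ].to_numpy()
    if same_res.size == 0:
        return same_res
    d = np.linalg.norm(
        system.coords[0, same_res, :] - system.coords[0, donor_idx, :], axis=1
    )
    return same_res[d <= 0.12]


def classify_interactions(
    system: MolecularSystem,
    group_a: np.ndarray,
    group_b: np.ndarray,
    geometry: InteractionGeometry | None = None,
    interface: str = "",
) -> list[InteractionRecord]:
    """Frame-by-frame geometric detection of salt bridges, hydrogen bonds
    and hydrophobic contacts between two atom groups, aggregated into
    per-pair frequencies.

    Residues with names outside the known set are skipped with a warning.
    Hydrogen-bond detection degrades to distance-only when the topology
    contains no hydrogens.
    """
    geometry = geometry or InteractionGeometry()
    idx_a = np.asarray(group_a, dtype=int)
    idx_b = np.asarray(group_b, dtype=int)
    nf = system.n_frames

    unknown = sorted(
        set(system.atoms.iloc[np.concatenate([idx_a, idx_b])]["resname"])
        - STANDARD_RESNAMES
    )
    if unknown:
        log.warning("skipping residues with unknown names: %s", unknown)
        warnings.warn(f"unknown residue names skipped: {unknown}", stacklevel=2)
        keep = ~system.atoms["resname"].isin(unknown)
        idx_a = idx_a[keep.to_numpy()[idx_a]]
        idx_b = idx_b[keep.to_numpy()[idx_b]]

    has_h = (system.atoms["element"].str.upper() == "H").any()
    records: list[InteractionRecord] = []

    # --- salt bridges: charged-group centroid distance
    pos_a, neg_a = _charged_atoms(system, idx_a, geometry)
    pos_b, neg_b = _charged_atoms(system, idx_b, geometry)
    for plist, nlist in ((pos_a, neg_b), (pos_b, neg_a)):
        for pkey, pidx in plist:
            pc = system.coords[:, pidx, :].mean(axis=1)
            for nkey, nidx in nlist:
                nc = system.coords[:, nidx, :].mean(axis=1)
                hits = np.linalg.norm(pc - nc, axis=1) <= geometry.saltbridge_dist
                if hits.any():
                    ri, rj = sorted([pkey, nkey])
                    ai = tuple(system.atoms.iloc[pidx]["name"]) if ri == pkey else tuple(system.atoms.iloc[nidx]["name"])
                    aj = tuple(system.atoms.iloc[nidx]["name"]) if ri == pkey else tuple(system.atoms.iloc[pidx]["name"])
                    records.append(
                        InteractionRecord(
                            kind="salt_bridge", res_i=ri, res_j=rj,
                            atoms_i=ai, atoms_j=aj,
                            frequency=float(hits.mean()), interface=interface,
                        )
                    )

    # --- hydrogen bonds: N/O donor-acceptor distance (+ angle if H present)
    pol_a = _polar_atoms(system, idx_a)
    pol_b = _polar_atoms(system, idx_b)
    res_a = _residue_keys(system, pol_a) if pol_a.size else []
    res_b = _residue_keys(system, pol_b) if pol_b.size else []
    hb_counts: dict[tuple, np.ndarray] = {}
    for ia, da in enumerate(pol_a):
        for ib, ab in enumerate(pol_b):
            if res_a[ia] == res_b[ib]:
                continue
            d = np.linalg.norm(
                system.coords[:, da, :] - system.coords[:, ab, :], axis=1
            )
            ok = d <= geometry.hbond_dist
            if not ok.any():
                continue
            if has_h:
                ok = ok & _hbond_angle_ok(system, da, ab, geometry)
                if not ok.any():
                    continue
            key = (res_a[ia], res_b[ib], system.atoms.iloc[da]["name"], system.atoms.iloc[ab]["name"])
            hb_counts[key] = hb_counts.get(key, np.zeros(nf, dtype=bool)) | ok
    for (ri, rj, an_i, an_j), ok in hb_counts.items():
        records.append(
            InteractionRecord(
                kind="hydrogen_bond", res_i=ri, res_j=rj,
                atoms_i=(an_i,), atoms_j=(an_j,),
                frequency=float(ok.mean()), interface=interface,
                distance_only=not has_h,
            )
        )

    # --- hydrophobic: apolar carbon pairs
    apo_a = _apolar_carbons(system, idx_a)
    apo_b = _apolar_carbons(system, idx_b)
    hp_counts: dict[tuple, np.ndarray] = {}
    hp_atoms: dict[tuple, tuple] = {}
    keys_aa = _residue_keys(system, apo_a) if apo_a.size else []
    keys_bb = _residue_keys(system, apo_b) if apo_b.size else []
    for ia, ca in enumerate(apo_a):
        for ib, cb in enumerate(apo_b):
            if keys_aa[ia] == keys_bb[ib]:
                continue
            d = np.linalg.norm(
                system.coords[:, ca, :] - system.coords[:, cb, :], axis=1
            )
            ok = d <= geometry.hydrophobic_dist
            if not ok.any():
                continue
            key = (keys_aa[ia], keys_bb[ib])
            hp_counts[key] = hp_counts.get(key, np.zeros(nf, dtype=bool)) | ok
            hp_atoms.setdefault(
                key,
                (system.atoms.iloc[ca]["name"], system.atoms.iloc[cb]["name"]),
            )
    for (ri, rj), ok in hp_counts.items():
        an_i, an_j = hp_atoms[(ri, rj)]
        records.append(
            InteractionRecord(
                kind="hydrophobic", res_i=ri, res_j=rj,
                atoms_i=(an_i,), atoms_j=(an_j,),
                frequency=float(ok.mean()), interface=interface,
            )
        )
    return records


def _hbond_angle_ok(
    system: MolecularSystem, donor: int, acceptor: int, geometry: InteractionGeometry
) -> np.ndarray:
    """Per-frame D-H...A angle criterion over the donor's hydrogens
    (any hydrogen passing counts)."""
    hyds = _hydrogens_near(system, donor)
    nf = system.n_frames
    if hyds.size == 0:
        return np.ones(nf, dtype=bool)  # donor has no H: distance-only
    ok = np.zeros(nf, dtype=bool)
    for h in hyds:
        hd = system.coords[:, donor, :] - system.coords[:, h, :]
        ha = system.coords[:, acceptor, :] - system.coords[:, h, :]
        cosang = np.einsum("fi,fi->f", hd, ha) / (
            np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1) + 1e-30
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok |= ang >= geometry.hbond_angle_deg
    return ok


def stable_interactions(
    records_per_system: list[list[InteractionRecord]],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Interactions whose mean frequency across systems is strictly greater
    than ``threshold``; an interaction missing from a system counts as 0."""
    n_sys = len(records_per_system)
    freq: dict[tuple, np.ndarray] = {}
    meta: dict[tuple, InteractionRecord] = {}
    for s, records in enumerate(records_per_system):
        for rec in records:
            arr = freq.setdefault(rec.key(), np.zeros(n_sys))
            arr[s] = max(arr[s], rec.frequency)
            meta.setdefault(rec.key(), rec)
    rows = []
    for key, arr in sorted(freq.items()):
        mean = arr.mean()
        if mean > threshold:
            rec = meta[key]
            rows.append(
                (rec.kind, *rec.res_i, *rec.res_j, mean, rec.interface)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "chain_i", "resid_i", "resname_i",
            "chain_j", "resid_j", "resname_j", "mean_frequency", "interface",
        ],
    )


def contact_difference(table_x: ContactTable, table_ref: ContactTable) -> pd.DataFrame:
    """Per-residue signed marginal-frequency difference (x - ref);
    residues absent from one table count as frequency 0."""
    mx = table_x.marginals.set_index(["chain", "resid"])
    mr = table_ref.marginals.set_index(["chain", "resid"])
    idx = mx.index.union(mr.index)
    fx = mx["frequency"].reindex(idx, fill_value=0.0)
    fr = mr["frequency"].reindex(idx, fill_value=0.0)
    resnames = mx["resname"].reindex(idx).fillna(mr["resname"].reindex(idx))
    out = pd.DataFrame(
        {
            "chain": [i[0] for i in idx],
            "resid": [i[1] for i in idx],
            "resname": resnames.to_numpy(),
            "difference": (fx - fr).to_numpy(),
        }
    )
    return out.sort_values(["chain", "resid"]).reset_index(drop=True)
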