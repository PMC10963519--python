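"""Stereochemically sensitive conservation scoring of alignment columns.

Residues are pooled into six stereochemical classes before computing the
per-column Shannon entropy, so exchanges within a class (e.g. Leu -> Val)
do not count as divergence:

    aliphatic {A V L I M C}   aromatic {F W Y H}   polar {S T N Q}
    basic     {K R}           acidic   {D E}       special {G P}

The normalized entropy NE = H / ln(6) lies in [0, 1]: 0 for a fully
conserved column, 1 for a column populated evenly by all six classes.
Gaps are excluded from the counts (not a seventh class); columns with a
high gap fraction are flagged unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.SeqUtils import seq1

STEREO_CLASSES: dict[str, str] = {}
for _cls, _letters in {
    "aliphatic": "AVLIMC",
    "aromatic": "FWYH",
    "polar": "STNQ",
    "basic": "KR",
    "acidic": "DE",
    "special": "GP",
}.items():
    for _l in _letters:
        STEREO_CLASSES[_l] = _cls

CLASS_NAMES = ("aliphatic", "aromatic", "polar", "basic", "acidic", "special")
AMBIGUOUS = set("BZXJUO")
GAP_CHARS = set("-.")

MAX_ENTROPY = np.log(len(CLASS_NAMES))


@dataclass
class MSA:
    sequences: list[str]
    ids: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, j: int) -> str:
        return "".join(seq[j] for seq in self.sequences)

    def reference_positions(self, ref: int | str = 0) -> list[int]:
        """Alignment column of each non-gap position of the reference
        sequence, in order (position p of the reference maps to
        ``reference_positions(ref)[p]``)."""
        if isinstance(ref, str):
            ref = self.ids.index(ref)
        seq = self.sequences[ref]
        return [j for j, c in enumerate(seq) if c not in GAP_CHARS]


@dataclass
class ConservationProfile:
    per_column: pd.DataFrame  # column, ne, gap_fraction, n_counted, flagged
    gap_flag_threshold: float

    def ne_by_reference_position(self, msa: MSA, ref: int | str = 0) -> pd.Series:
        cols = msa.reference_positions(ref)
        ne = self.per_column["ne"].to_numpy()
        return pd.Series(
            [ne[j] for j in cols], index=np.arange(1, len(cols) + 1), name="ne"
        )


def read_msa(path) -> MSA:
    """Read a FASTA alignment; enforces equal lengths and uppercases."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as err:
        raise ValueError(f"not a valid alignment: {err}") from err
    seqs = [str(rec.seq).upper() for rec in aln]
    if not seqs or not seqs[0]:
        raise ValueError("empty alignment")
    return MSA(sequences=seqs, ids=[rec.id for rec in aln])


def stereochemical_entropy_profile(
    msa: MSA, gap_flag_threshold: float = 0.5
) -> ConservationProfile:
    """Per-column normalized stereochemical entropy.

    All-gap columns get NE = NaN and are flagged; ambiguity codes are
    excluded from the counts with a warning.
    """
    n_seq = len(msa.sequences)
    rows = []
    saw_ambiguous = 0
    for j in range(msa.n_columns):
        col = msa.column(j)
        counts = dict.fromkeys(CLASS_NAMES, 0)
        n_gap = 0
        for c in col:
            if c in GAP_CHARS:
                n_gap += 1
            elif c in AMBIGUOUS:
                saw_ambiguous += 1
            elif c in STEREO_CLASSES:
                counts[STEREO_CLASSES[c]] += 1
            else:
                saw_ambiguous += 1
        total = sum(counts.values())
        gap_fraction = n_gap / n_seq
        if total == 0:
            ne = np.nan
        else:
            p = np.array([v for v in counts.values() if v > 0], dtype=float) / total
            ne = float(-(p * np.log(p)).sum() / MAX_ENTROPY)
        rows.append(
            (
                j, ne, gap_fraction, total,
                gap_fraction > gap_flag_threshold or total == 0,
                *[counts[c] for c in CLASS_NAMES],
            )
        )
    if saw_ambiguous:
        warnings.warn(
            f"{saw_ambiguous} ambiguous/unknown residue codes excluded from "
            "conservation counts"
        )
    per_column = pd.DataFrame(
        rows,
        columns=["column", "ne", "gap_fraction", "n_counted", "flagged", *CLASS_NAMES],
    )
    return ConservationProfile(per_column=per_column, gap_flag_threshold=gap_flag_threshold)


#: B-factor written for residues that cannot be mapped onto the alignment
UNMAPPED_SENTINEL = -1.0


def annotate_structure(
    profile: ConservationProfile,
    system,
    msa: MSA,
    chain_reference: dict[str, int | str],
    pdb_path=None,
):
    """Map per-column NE onto structure residues chain by chain.

    ``chain_reference`` maps a chain id to the alignment record whose
    ungapped sequence the chain follows residue-for-residue.  Residues
    whose name disagrees with the reference letter get the sentinel value;
    the mismatch count is returned.  NE is scaled by 100 into the
    B-factor column (PDB carries two decimals) when ``pdb_path`` is given.

    Returns (per-atom B-factor array, mismatch count).
    """
    from .traj_io import write_system

    atoms = system.atoms
    bfac = np.full(len(atoms), UNMAPPED_SENTINEL)
    mismatches = 0
    ne = profile.per_column["ne"].to_numpy()
    for chain, ref in chain_reference.items():
        ref_idx = msa.ids.index(ref) if isinstance(ref, str) else ref
        ungapped = [
            c for c in msa.sequences[ref_idx] if c not in GAP_CHARS
        ]
        cols = msa.reference_positions(ref_idx)
        sub = atoms[atoms["chain"] == chain]
        resids = sub["resid"].drop_duplicates().to_numpy()
        for pos, resid in enumerate(resids):
            res_atoms = sub.index[sub["resid"] == resid]
            if pos >= len(ungapped):
                mismatches += 1
                continue
            resname = atoms.loc[res_atoms[0], "resname"]
            letter = seq1(resname.capitalize()) if len(resname) == 3 else "X"
            if letter.upper() != ungapped[pos]:
                mismatches += 1
                continue
            val = ne[cols[pos]]
            bfac[res_atoms] = val * 100.0 if np.isfinite(val) else UNMAPPED_SENTINEL
    if pdb_path is not None:
        write_system(system, pdb_path, bfactors=bfac)
    return bfac, mismatches
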