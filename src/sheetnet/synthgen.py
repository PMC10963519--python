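"""Synthetic systems with analytically known statistical structure.

Every downstream stage of the package (correlation networks, centrality,
contacts, rigidity, conservation) is exercised on data produced here, where
the designed correlation matrix, contact geometry, fluctuation amplitudes
and alignment-column compositions are known exactly.

The flagship generator, :func:`gen_toy_sheet`, emulates a patch of a
filament wall: a grid of monomer blocks (protofilament analogs) whose
rigid-body displacements are multivariate Gaussian with stronger coupling
along a filament than between filaments, an optional seam-like column where
the lateral coupling is weakened, and position-restrained corner blocks
that do not move at all.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .system import MolecularSystem

KB = 0.0083144621  # Boltzmann constant, kJ mol^-1 K^-1

#: eigenvalue tolerance for the positive-semi-definiteness check
PSD_TOL = 1e-10


class NotPositiveSemiDefinite(ValueError):
    """Raised when a requested correlation design is not realisable."""


def _check_correlation_matrix(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < -PSD_TOL:
        raise NotPositiveSemiDefinite(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {evals.min():.3e})"
        )
    return corr


def _correlated_normal(
    corr: np.ndarray, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_frames, N, 3) unit-variance Gaussian samples; each spatial axis is
    an independent draw with the given N x N correlation matrix."""
    evals, evecs = np.linalg.eigh(corr)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal(size=(n_frames, 3, corr.shape[0]))
    # result[f, n, a] = sum_k factor[n, k] * z[f, a, k]
    return np.einsum("fak,nk->fna", z, factor)


def _single_bead_atoms(n: int, resname: str = "GLY") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": ["CA"] * n,
            "element": ["C"] * n,
            "resid": np.arange(1, n + 1),
            "resname": [resname] * n,
            "chain": ["A"] * n,
        }
    )


def gen_correlated_ensemble(
    correlation_matrix: np.ndarray,
    n_frames: int,
    seed: int,
    fluctuation_sigma: float = 0.05,
    spacing: float = 2.0,
) -> MolecularSystem:
    """Single-bead residues on a line whose displacement series realise a
    designed correlation matrix.

    Each spatial axis of each bead's displacement is multivariate normal
    with the given correlation matrix; the three axes are independent.
    Rejects non-PSD designs with :class:`NotPositiveSemiDefinite`.
    """
    corr = _check_correlation_matrix(correlation_matrix)
    n = corr.shape[0]
    rng = np.random.default_rng(seed)
    base = np.zeros((n, 3))
    base[:, 0] = np.arange(n) * spacing
    disp = _correlated_normal(corr, n_frames, rng) * fluctuation_sigma
    coords = base[None, :, :] + disp
    return MolecularSystem(_single_bead_atoms(n), coords)


def gen_harmonic_ensemble(
    force_constant: float,
    temperature: float,
    n_frames: int,
    seed: int,
    n_anchors: int = 20,
    anchor_distance: float = 5.0,
) -> MolecularSystem:
    """One probe bead Boltzmann-sampled from an isotropic harmonic well
    (per-axis variance ``kB*T/k``) plus a static anchor cloud.

    The anchor cloud sits to one side of the probe (centred
    ``anchor_distance`` nm away along +x with a 0.2 nm spread) so that the
    probe's mean distance to the anchors responds linearly, with unit
    gradient, to its displacement along x.  That makes the Boltzmann
    statistics of the mean-distance coordinate analytic: its variance is
    the per-axis positional variance ``kB*T/k``.
    """
    if force_constant <= 0:
        raise ValueError("force_constant must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature / force_constant)
    probe = rng.standard_normal(size=(n_frames, 1, 3)) * sigma
    anchor_rng = np.random.default_rng(12345)  # geometry fixed across seeds
    anchors = anchor_rng.standard_normal(size=(n_anchors, 3)) * 0.2
    anchors[:, 0] += anchor_distance
    coords = np.concatenate(
        [probe, np.broadcast_to(anchors, (n_frames, n_anchors, 3))], axis=1
    )
    n = n_anchors + 1
    atoms = _single_bead_atoms(n)
    atoms.loc[0, "resname"] = "PRB"
    atoms.loc[1:, "resname"] = "ANC"
    return MolecularSystem(atoms, coords)


# ---------------------------------------------------------------------------
# toy filament-wall sheet
# ---------------------------------------------------------------------------

@dataclass
class SheetSpec:
    """Design of a toy wall sheet.

    The sheet is a ``n_rows x n_cols`` grid of monomer blocks.  Each row is
    a protofilament analog running along the column axis: neighbours within
    a row, ``(r, c)-(r, c+1)``, are longitudinally coupled with
    ``coupling_long`` (the intra-filament analog); neighbours across rows,
    ``(r, c)-(r+1, c)``, are laterally coupled with ``coupling_lat``.  If
    ``seam_col`` is set, lateral bonds in that lattice column use
    ``coupling_seam`` instead, mimicking the seam discontinuity, and the
    facing beads across those weak interfaces are pulled back to
    ``seam_gap_nm`` so the weakened mechanical coupling is accompanied by a
    loosened contact.

    Couplings are the relative bond stiffnesses of the harmonic
    displacement network that generates the block fluctuations; the
    correlation matrix they imply is computed by
    :func:`implied_block_correlation` and recorded in the ground truth.
    """

    n_rows: int = 2
    n_cols: int = 6
    beads_per_monomer: int = 5
    lattice_spacing: float = 1.0  # nm between block centres
    coupling_long: float = 0.9
    coupling_lat: float = 0.7
    coupling_seam: float = 0.7
    seam_col: int | None = None
    restrained_blocks: list[tuple[int, int]] = field(default_factory=list)
    fluctuation_sigma: float = 0.05  # nm, per-axis block displacement
    n_frames: int = 1000
    seed: int = 0
    contact_gap_nm: float = 0.20  # rest gap between facing arm beads
    seam_gap_nm: float = 0.395  # widened gap at weak lateral interfaces

    def __post_init__(self) -> None:
        for name in ("coupling_long", "coupling_lat", "coupling_seam"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.seam_col is not None and not (0 <= self.seam_col < self.n_cols):
            raise ValueError("seam_col outside grid")
        for r, c in self.restrained_blocks:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"restrained block {(r, c)} outside grid")
        if self.beads_per_monomer < 1:
            raise ValueError("beads_per_monomer must be >= 1")


@dataclass
class GroundTruth:
    """Designed statistics recorded alongside a generated sheet."""

    spec: SheetSpec
    block_chains: list[str]  # chain id of block (r, c), row-major
    block_grid: list[tuple[int, int]]  # (row, col) per block, row-major
    correlation: np.ndarray  # implied block-displacement correlations
    contact_pairs: list[tuple[int, int]]  # adjacent block index pairs
    weak_interfaces: list[tuple[int, int]]  # lateral pairs with weakened bond
    restrained_chains: list[str]

    def to_json(self, path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "block_chains": self.block_chains,
            "block_grid": [list(g) for g in self.block_grid],
            "correlation": self.correlation.tolist(),
            "contact_pairs": [list(p) for p in self.contact_pairs],
            "weak_interfaces": [list(p) for p in self.weak_interfaces],
            "restrained_chains": self.restrained_chains,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            spec=SheetSpec(**{
                **d["spec"],
                "restrained_blocks": [tuple(b) for b in d["spec"]["restrained_blocks"]],
            }),
            block_chains=d["block_chains"],
            block_grid=[tuple(g) for g in d["block_grid"]],
            correlation=np.asarray(d["correlation"]),
            contact_pairs=[tuple(p) for p in d["contact_pairs"]],
            weak_interfaces=[tuple(p) for p in d["weak_interfaces"]],
            restrained_chains=d["restrained_chains"],
        )


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _sheet_bonds(spec: SheetSpec):
    """Bond list [(block_a, block_b, coupling, lateral?)], row-major blocks."""
    def idx(r, c):
        return r * spec.n_cols + c

    bonds = []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            if c + 1 < spec.n_cols:
                bonds.append((idx(r, c), idx(r, c + 1), spec.coupling_long, False))
            if r + 1 < spec.n_rows:
                coup = (
                    spec.coupling_seam
                    if spec.seam_col is not None and c == spec.seam_col
                    else spec.coupling_lat
                )
                bonds.append((idx(r, c), idx(r + 1, c), coup, True))
    return bonds


def implied_block_correlation(spec: SheetSpec) -> np.ndarray:
    """Correlation matrix implied by the bond design.

    The couplings act as relative spring constants of a harmonic
    displacement network over the blocks: the block-displacement
    covariance is the inverse of the grounded graph Laplacian (restrained
    blocks are rigid anchors that ground their neighbours; without any
    restraint the rigid-translation zero mode is projected out, the
    standard Gaussian-network pseudo-inverse), and the correlation is its
    diagonal normalization.  Being the equilibrium Gaussian of a
    bead-spring lattice it is positive semi-definite by construction; a
    weak seam spring lowers the correlation across exactly that
    interface, and stiffer bonds carry systematically higher neighbour
    correlations.  Restrained blocks get zero off-diagonal rows/columns.
    """
    n = spec.n_rows * spec.n_cols
    restrained = {r * spec.n_cols + c for r, c in spec.restrained_blocks}
    free = [i for i in range(n) if i not in restrained]
    pos = {b: i for i, b in enumerate(free)}
    lap = np.zeros((len(free), len(free)))
    for a, b, coup, _ in _sheet_bonds(spec):
        ia, ib = pos.get(a), pos.get(b)
        if ia is not None:
            lap[ia, ia] += coup
        if ib is not None:
            lap[ib, ib] += coup
        if ia is not None and ib is not None:
            lap[ia, ib] -= coup
            lap[ib, ia] -= coup
    if restrained:
        cov = np.linalg.inv(lap)
    else:
        evals, evecs = np.linalg.eigh(lap)
        keep = evals > 1e-10
        cov = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    d = np.sqrt(np.diag(cov))
    sub = cov / np.outer(d, d)
    corr = np.eye(n)
    corr[np.ix_(free, free)] = sub
    return corr


def _block_bead_offsets(spec: SheetSpec) -> np.ndarray:
    """Local bead offsets within a block: a central bead plus four arm
    beads pointing at the lattice neighbours; extras stack along z."""
    arm = spec.lattice_spacing / 2.0 - spec.contact_gap_nm / 2.0
    canonical = np.array(
        [
            [0.0, 0.0, 0.0],
            [arm, 0.0, 0.0],
            [-arm, 0.0, 0.0],
            [0.0, arm, 0.0],
            [0.0, -arm, 0.0],
        ]
    )
    k = spec.beads_per_monomer
    if k <= 5:
        return canonical[:k]
    extra = np.zeros((k - 5, 3))
    extra[:, 2] = 0.15 * (np.arange(k - 5) + 1)
    return np.vstack([canonical, extra])


def gen_toy_sheet(spec: SheetSpec) -> tuple[MolecularSystem, GroundTruth]:
    """Generate a toy wall sheet and its ground truth.

    Blocks move as rigid units (their per-axis displacement series follow
    :func:`implied_block_correlation`, scaled by ``fluctuation_sigma``)
    plus small independent per-bead jitter (``sigma/10``) so residue-level
    and block-level correlations agree.  Restrained blocks have exactly
    zero displacement.  Facing arm beads of adjacent blocks rest within
    ``contact_gap_nm`` of each other, far inside a conventional heavy-atom
    contact cutoff, while non-adjacent blocks stay well outside it.
    """
    n_blocks = spec.n_rows * spec.n_cols
    if n_blocks > len(_CHAIN_IDS):
        raise ValueError("sheet too large for single-character chain ids")
    corr = implied_block_correlation(spec)
    try:
        _check_correlation_matrix(corr)
    except NotPositiveSemiDefinite as err:
        raise NotPositiveSemiDefinite(
            f"implied block correlation for this sheet design is invalid: {err}"
        ) from err

    grid = [(r, c) for r in range(spec.n_rows) for c in range(spec.n_cols)]
    chains = [_CHAIN_IDS[i] for i in range(n_blocks)]
    restrained = {(r, c) for r, c in spec.restrained_blocks}
    restrained_idx = [i for i, g in enumerate(grid) if g in restrained]

    rng = np.random.default_rng(spec.seed)
    disp = _correlated_normal(corr, spec.n_frames, rng) * spec.fluctuation_sigma
    disp[:, restrained_idx, :] = 0.0

    offsets = _block_bead_offsets(spec)
    k = spec.beads_per_monomer

    # widen the rest gap across weak lateral interfaces by retracting the
    # facing arm beads (arms 3/4 point along +/-y, the lateral axis)
    retract = (spec.seam_gap_nm - spec.contact_gap_nm) / 2.0
    weak_pairs: list[tuple[int, int]] = []
    block_offsets = [offsets.copy() for _ in range(n_blocks)]
    if spec.seam_col is not None and retract > 0 and k >= 4:
        for a, b, coup, lateral in _sheet_bonds(spec):
            if lateral and coup == spec.coupling_seam and spec.coupling_seam < spec.coupling_lat:
                # block a is at row r, block b at row r+1: a's +y arm (index 3)
                # and b's -y arm (index 4) face each other
                block_offsets[a][3, 1] -= retract
                if k >= 5:
                    block_offsets[b][4, 1] += retract
                weak_pairs.append((a, b))

    centres = np.array(
        [[c * spec.lattice_spacing, r * spec.lattice_spacing, 0.0] for r, c in grid]
    )
    coords = np.empty((spec.n_frames, n_blocks * k, 3))
    names, elements, resids, resnames, chain_col = [], [], [], [], []
    for i, (r, c) in enumerate(grid):
        base = centres[i] + block_offsets[i]
        jitter = rng.standard_normal(size=(spec.n_frames, k, 3)) * (
            spec.fluctuation_sigma / 10.0
        )
        if i in restrained_idx:
            jitter[:] = 0.0
        coords[:, i * k : (i + 1) * k, :] = (
            base[None, :, :] + disp[:, i : i + 1, :] + jitter
        )
        resname = "TUA" if c % 2 == 0 else "TUB"  # alternating monomer labels
        names += ["CA"] * k
        elements += ["C"] * k
        # step-2 residue numbering: beads of one block are spatial, not
        # sequence, neighbours, so none may look covalently bonded
        resids += [1 + 2 * b for b in range(k)]
        resnames += [resname] * k
        chain_col += [chains[i]] * k

    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resid": resids,
            "resname": resnames,
            "chain": chain_col,
        }
    )
    system = MolecularSystem(atoms, coords)

    contact_pairs = sorted(
        (min(a, b), max(a, b)) for a, b, _, _ in _sheet_bonds(spec)
    )
    truth = GroundTruth(
        spec=spec,
        block_chains=chains,
        block_grid=grid,
        correlation=corr,
        contact_pairs=contact_pairs,
        weak_interfaces=sorted(weak_pairs),
        restrained_chains=[chains[i] for i in restrained_idx],
    )
    return system, truth


def gen_two_state_ensemble(
    displacement: float,
    n_frames_per_state: int,
    seed: int,
    sigma: float = 0.02,
    n_beads: int = 8,
    spacing: float = 0.8,
) -> tuple[MolecularSystem, np.ndarray]:
    """Two-conformation ensemble for clustering tests.

    The first ``n_frames_per_state`` frames fluctuate tightly (``sigma``)
    about conformation A; the remainder about A deformed internally by
    ``displacement``: alternating bead quadruplets move ``+d/2``/``-d/2``
    along z in a ``+ - - +`` pattern whose zeroth and first moments vanish,
    so the deformation cannot be removed by superposition.

    Returns the system and the designed per-frame state labels (0/1).
    """
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    rng = np.random.default_rng(seed)
    base = np.zeros((n_beads, 3))
    base[:, 0] = np.arange(n_beads) * spacing
    pattern = np.array([1.0, -1.0, -1.0, 1.0])
    signs = np.resize(pattern, n_beads)
    shifted = base.copy()
    shifted[:, 2] += signs * displacement / 2.0
    n = n_frames_per_state
    coords = np.empty((2 * n, n_beads, 3))
    coords[:n] = base
    coords[n:] = shifted
    coords += rng.standard_normal(size=coords.shape) * sigma
    states = np.repeat([0, 1], n)
    return MolecularSystem(_single_bead_atoms(n_beads), coords), states


# ---------------------------------------------------------------------------
# toy multiple sequence alignments
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MSASpec:
    """Design of a synthetic alignment: one target composition per column.

    ``column_profiles`` is a list of dicts mapping amino-acid letters to
    probabilities (each summing to 1 over letters); ``gap_fractions``
    (optional, default 0) gives the per-column gap probability, applied
    before the letter draw.
    """

    n_sequences: int
    column_profiles: list[dict[str, float]]
    gap_fractions: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_fractions is None:
            self.gap_fractions = [0.0] * len(self.column_profiles)
        if len(self.gap_fractions) != len(self.column_profiles):
            raise ValueError("gap_fractions length must match column_profiles")
        for j, prof in enumerate(self.column_profiles):
            total = sum(prof.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"column {j} profile sums to {total}, not 1")
            for aa in prof:
                if aa not in AMINO_ACIDS:
                    raise ValueError(f"unknown amino acid letter {aa!r}")
        for g in self.gap_fractions:
            if not (0.0 <= g < 1.0):
                raise ValueError("gap fractions must lie in [0, 1)")


def gen_toy_msa(spec: MSASpec, path) -> None:
    """Write a FASTA alignment sampling each column independently from its
    profile; realised compositions converge to the design as n grows."""
    rng = np.random.default_rng(spec.seed)
    n, width = spec.n_sequences, len(spec.column_profiles)
    cols = []
    for j, prof in enumerate(spec.column_profiles):
        letters = np.array(list(prof.keys()))
        probs = np.array(list(prof.values()), dtype=float)
        probs = probs / probs.sum()
        col = rng.choice(letters, size=n, p=probs)
        gap = rng.random(n) < spec.gap_fractions[j]
        col = np.where(gap, "-", col)
        cols.append(col)
    matrix = np.stack(cols, axis=1)
    with open(path, "w") as fh:
        for i in range(n):
            fh.write(f">seq{i:05d}\n{''.join(matrix[i])}\n")
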