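import numpy as np
import pandas as pd
import pytest

from sheetnet import SheetSpec, gen_toy_sheet
from sheetnet.system import MolecularSystem


def make_system(coords, resnames=None, names=None, elements=None, chains=None,
                resids=None):
    """Small helper to assemble a MolecularSystem from raw arrays."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "name": names if names is not None else ["CA"] * n,
            "element": elements if elements is not None else ["C"] * n,
            "resid": resids if resids is not None else np.arange(1, n + 1),
            "resname": resnames if resnames is not None else ["GLY"] * n,
            "chain": chains if chains is not None else ["A"] * n,
        }
    )
    return MolecularSystem(atoms, coords)


CORNERS = [(0, 0), (0, 3), (1, 0), (1, 3)]


@pytest.fixture(scope="session")
def small_sheet():
    """2x4 sheet, corners restrained, enough frames for contact gating."""
    spec = SheetSpec(
        n_rows=2, n_cols=4, n_frames=400, seed=7,
        restrained_blocks=list(CORNERS),
    )
    system, truth = gen_toy_sheet(spec)
    return system, truth


@pytest.fixture(scope="session")
def seam_sheet():
    spec = SheetSpec(
        n_rows=2, n_cols=6, n_frames=400, seed=9,
        coupling_long=0.9, coupling_lat=0.7, coupling_seam=0.2, seam_col=2,
        restrained_blocks=[(0, 0), (0, 5), (1, 0), (1, 5)],
    )
    system, truth = gen_toy_sheet(spec)
    return system, truth
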