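import numpy as np
import pytest

from sheetnet import synthgen
from sheetnet.synthgen import (
    KB,
    MSASpec,
    NotPositiveSemiDefinite,
    SheetSpec,
    gen_correlated_ensemble,
    gen_harmonic_ensemble,
    gen_toy_msa,
    gen_toy_sheet,
    gen_two_state_ensemble,
    implied_block_correlation,
)


def _pearson(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestCorrelatedEnsemble:
    def test_independent_beads_stay_uncorrelated(self):
        sys_ = gen_correlated_ensemble(np.eye(4), n_frames=5000, seed=1)
        disp = sys_.coords - sys_.coords.mean(axis=0)
        for i in range(4):
            for j in range(i + 1, 4):
                for ax in range(3):
                    assert abs(_pearson(disp[:, i, ax], disp[:, j, ax])) < 0.05

    def test_designed_pairwise_correlation_realised(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        sys_ = gen_correlated_ensemble(corr, n_frames=5000, seed=2)
        disp = sys_.coords - sys_.coords.mean(axis=0)
        for ax in range(3):
            assert _pearson(disp[:, 0, ax], disp[:, 1, ax]) == pytest.approx(0.8, abs=0.05)

    def test_seed_determinism_bitwise(self):
        a = gen_correlated_ensemble(np.eye(3), 200, seed=5)
        b = gen_correlated_ensemble(np.eye(3), 200, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(NotPositiveSemiDefinite):
            gen_correlated_ensemble(bad, 100, seed=0)

    def test_axes_independent(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        sys_ = gen_correlated_ensemble(corr, 5000, seed=3)
        disp = sys_.coords - sys_.coords.mean(axis=0)
        assert abs(_pearson(disp[:, 0, 0], disp[:, 0, 1])) < 0.05


class TestHarmonicEnsemble:
    def test_boltzmann_per_axis_variance(self):
        sys_ = gen_harmonic_ensemble(748.3, 300.0, 50000, seed=1)
        var = sys_.coords[:, 0, :].var(axis=0)
        expected = KB * 300.0 / 748.3
        assert np.all(np.abs(var - expected) / expected < 0.05)

    def test_doubling_k_halves_variance(self):
        a = gen_harmonic_ensemble(400.0, 300.0, 30000, seed=2)
        b = gen_harmonic_ensemble(800.0, 300.0, 30000, seed=2)
        ratio = a.coords[:, 0, :].var() / b.coords[:, 0, :].var()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_anchors_static_and_deterministic(self):
        a = gen_harmonic_ensemble(500.0, 300.0, 100, seed=3)
        b = gen_harmonic_ensemble(500.0, 300.0, 100, seed=3)
        assert np.array_equal(a.coords, b.coords)
        assert np.ptp(a.coords[:, 1:, :], axis=0).max() == 0.0

    @pytest.mark.parametrize("k,temp", [(-1.0, 300.0), (100.0, 0.0)])
    def test_invalid_parameters_rejected(self, k, temp):
        with pytest.raises(ValueError):
            gen_harmonic_ensemble(k, temp, 10, seed=0)


class TestToySheet:
    def test_ground_truth_marks_single_weak_interface(self, seam_sheet):
        _, truth = seam_sheet
        assert len(truth.weak_interfaces) == 1
        (a, b) = truth.weak_interfaces[0]
        assert truth.block_grid[a][1] == truth.spec.seam_col
        assert truth.block_grid[b][1] == truth.spec.seam_col

    def test_restrained_blocks_never_move(self, small_sheet):
        system, truth = small_sheet
        for chain in truth.restrained_chains:
            idx = system.atoms.index[system.atoms["chain"] == chain].to_numpy()
            assert np.ptp(system.coords[:, idx, :], axis=0).max() == 0.0

    def test_contact_geometry_matches_adjacency(self, small_sheet):
        # brute-force distance check over all frames: adjacent blocks have
        # a bead pair within the contact cutoff in every frame, while
        # non-adjacent blocks never come close
        system, truth = small_sheet
        cutoff = 0.45
        chains = truth.block_chains
        by_chain = {
            c: system.atoms.index[system.atoms["chain"] == c].to_numpy()
            for c in chains
        }
        adjacent = set(truth.contact_pairs)
        n_blocks = len(chains)
        for a in range(n_blocks):
            for b in range(a + 1, n_blocks):
                ia, ib = by_chain[chains[a]], by_chain[chains[b]]
                d = np.linalg.norm(
                    system.coords[:, ia, None, :] - system.coords[:, None, ib, :],
                    axis=-1,
                )
                dmin = d.min(axis=(1, 2))
                if (a, b) in adjacent:
                    assert (dmin <= cutoff).all()
                else:
                    assert (dmin > cutoff).all()

    def test_block_correlation_realised_as_designed(self):
        spec = SheetSpec(n_rows=2, n_cols=3, n_frames=5000, seed=4, beads_per_monomer=1)
        system, truth = gen_toy_sheet(spec)
        disp = system.coords - system.coords.mean(axis=0)
        n = len(truth.block_chains)
        for i in range(n):
            for j in range(i + 1, n):
                for ax in range(3):
                    r = _pearson(disp[:, i, ax], disp[:, j, ax])
                    assert r == pytest.approx(truth.correlation[i, j], abs=0.05)

    def test_implied_correlation_is_psd_and_rank_ordered(self):
        spec = SheetSpec(
            n_rows=2, n_cols=6, coupling_long=0.9, coupling_lat=0.7,
            coupling_seam=0.2, seam_col=2,
            restrained_blocks=[(0, 0), (0, 5), (1, 0), (1, 5)],
        )
        corr = implied_block_correlation(spec)
        assert np.linalg.eigvalsh(corr).min() > -1e-10
        # the weak lateral pair carries the lowest lateral correlation
        nc = spec.n_cols
        lat = {c: corr[0 * nc + c, 1 * nc + c] for c in range(1, 5)}
        assert min(lat, key=lat.get) == spec.seam_col

    def test_out_of_grid_spec_rejected(self):
        with pytest.raises(ValueError):
            SheetSpec(n_rows=2, n_cols=4, seam_col=9)
        with pytest.raises(ValueError):
            SheetSpec(n_rows=2, n_cols=4, restrained_blocks=[(5, 0)])
        with pytest.raises(ValueError):
            SheetSpec(coupling_lat=1.2)


class TestTwoStateEnsemble:
    def test_state_assignment_recorded(self):
        system, states = gen_two_state_ensemble(0.5, 50, seed=1)
        assert states.tolist() == [0] * 50 + [1] * 50
        assert system.n_frames == 100

    def test_zero_displacement_collapses_states(self):
        system, _ = gen_two_state_ensemble(0.0, 50, seed=2, sigma=0.02)
        mid = system.coords[:50].mean(axis=0) - system.coords[50:].mean(axis=0)
        assert np.abs(mid).max() < 0.02

    def test_deformation_survives_superposition(self):
        from sheetnet.system import fitted_rmsd

        system, _ = gen_two_state_ensemble(0.5, 20, seed=3, sigma=0.0)
        r = fitted_rmsd(system.coords[0], system.coords[-1])
        assert r == pytest.approx(0.25, abs=0.01)


class TestToyMSA:
    def test_pure_column_and_gap_fraction(self, tmp_path):
        spec = MSASpec(
            n_sequences=200,
            column_profiles=[{"A": 1.0}, {"A": 0.5, "F": 0.5}],
            gap_fractions=[0.0, 0.2],
            seed=1,
        )
        path = tmp_path / "toy.fasta"
        gen_toy_msa(spec, path)
        lines = [l.strip() for l in path.read_text().splitlines() if not l.startswith(">")]
        col0 = [l[0] for l in lines]
        col1 = [l[1] for l in lines]
        assert set(col0) == {"A"}
        gap_frac = col1.count("-") / len(col1)
        assert gap_frac == pytest.approx(0.2, abs=0.08)

    def test_uniform_class_composition(self, tmp_path):
        letters = ["A", "F", "S", "K", "D", "G"]
        spec = MSASpec(
            n_sequences=600,
            column_profiles=[{l: 1 / 6 for l in letters}],
            seed=2,
        )
        path = tmp_path / "u.fasta"
        gen_toy_msa(spec, path)
        col = [
            l[0] for l in path.read_text().splitlines() if l and not l.startswith(">")
        ]
        for letter in letters:
            assert col.count(letter) == pytest.approx(100, abs=35)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            MSASpec(n_sequences=5, column_profiles=[{"A": 0.5}])
        with pytest.raises(ValueError):
            MSASpec(n_sequences=5, column_profiles=[{"A": 1.0}], gap_fractions=[1.5])

    def test_seed_determinism(self, tmp_path):
        spec = MSASpec(n_sequences=30, column_profiles=[{"A": 0.5, "K": 0.5}] * 4, seed=9)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        gen_toy_msa(spec, p1)
        gen_toy_msa(spec, p2)
        assert p1.read_text() == p2.read_text()
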