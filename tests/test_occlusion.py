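"""Occlusion: masking, the K statistic, aggregation, site calls, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plinet.encoding import encode_protein, encode_smiles
from plinet.occlusion import (
    OcclusionConfig,
    aggregate_to_residues,
    call_sites,
    evaluate_sites,
    mask_window,
    occlusion_scan,
    residue_mask,
    track_auprc,
)

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"  # 56 residues


@pytest.fixture()
def protein():
    return encode_protein(SEQ, max_len=64)


@pytest.fixture()
def ligand():
    return encode_smiles("CCO", max_len=16)


class TestMaskWindow:
    def test_masked_columns_zeroed(self, protein):
        masked = mask_window(protein, 0, 15)
        assert masked.matrix[:, :15].sum() == 0
        assert masked.matrix.sum() == protein.matrix.sum() - 15

    def test_nonmasked_columns_unchanged(self, protein):
        masked = mask_window(protein, 10, 5)
        assert np.array_equal(masked.matrix[:, :10], protein.matrix[:, :10])
        assert np.array_equal(masked.matrix[:, 15:], protein.matrix[:, 15:])

    def test_idempotent(self, protein):
        once = mask_window(protein, 3, 7)
        twice = mask_window(once, 3, 7)
        assert np.array_equal(once.matrix, twice.matrix)

    def test_input_not_mutated(self, protein):
        before = protein.matrix.copy()
        mask_window(protein, 0, 15)
        assert np.array_equal(protein.matrix, before)

    def test_out_of_range_raises(self, protein):
        with pytest.raises(ValueError):
            mask_window(protein, protein.true_length - 3, 15)


class TestOcclusionScan:
    def test_window_count(self, protein, ligand):
        cfg = OcclusionConfig(window=15, stride=1)
        result = occlusion_scan(lambda Xp, Xl: np.full(len(Xp), 0.5),
                                protein, ligand, 1.0, cfg)
        assert result.n_windows == (protein.true_length - 15) // 1 + 1

    def test_constant_predictor_all_k_equal_below_one(self, protein, ligand):
        """Prediction independent of input: K = |p-v| / (|p-v| + eps) < 1."""
        cfg = OcclusionConfig(window=15, epsilon=1e-6)
        result = occlusion_scan(lambda Xp, Xl: np.full(len(Xp), 0.3),
                                protein, ligand, 1.0, cfg)
        expected = abs(0.3 - 1.0) / (abs(0.3 - 1.0) + 1e-6)
        assert np.allclose(result.k_values, expected)
        assert (result.k_values < 1).all()

    def test_masked_prediction_equals_value_gives_zero(self, protein, ligand):
        """p_ij = v_i makes the numerator (hence K) exactly zero."""
        def predictor(Xp, Xl):
            # unmasked input predicts 0.2; any masked input predicts 1.0 = v
            full = Xp.sum(axis=(1, 2)) == protein.true_length
            return np.where(full, 0.2, 1.0)
        result = occlusion_scan(predictor, protein, ligand, 1.0, OcclusionConfig())
        assert np.allclose(result.k_values, 0.0)

    def test_motif_destruction_scores_high(self, ligand):
        """A predictor keyed on an intact WWW motif: windows covering the
        motif get K ~ 1/eps-scale, others K ~ 1 (direct hand evaluation)."""
        seq = "A" * 20 + "WWW" + "A" * 20
        penc = encode_protein(seq, max_len=48)
        from plinet.encoding import protein_vocabulary
        w_row = protein_vocabulary().index("W")

        def predictor(Xp, Xl):
            intact = (Xp[:, w_row, 20:23].sum(axis=1) == 3)
            return intact.astype(float)

        eps = 1e-6
        cfg = OcclusionConfig(window=15, epsilon=eps)
        result = occlusion_scan(predictor, penc, ligand, 1.0, cfg)
        covers = (result.starts <= 22) & (result.starts + 15 > 20)
        # K = |0-1| / (|1-1| + eps) = 1/eps for motif-destroying windows
        assert np.allclose(result.k_values[covers], 1 / eps)
        # K = |1-1| / eps = 0 for untouched windows
        assert np.allclose(result.k_values[~covers], 0.0)

    def test_short_protein_whole_mask_with_warning(self, ligand):
        penc = encode_protein("MKT", max_len=16)
        with pytest.warns(UserWarning, match="shorter than window"):
            result = occlusion_scan(lambda Xp, Xl: np.ones(len(Xp)),
                                    penc, ligand, 1.0, OcclusionConfig(window=15))
        assert result.n_windows == 1

    def test_scan_does_not_mutate_inputs(self, protein, ligand):
        bp, bl = protein.matrix.copy(), ligand.matrix.copy()
        occlusion_scan(lambda Xp, Xl: np.zeros(len(Xp)), protein, ligand, 1.0)
        assert np.array_equal(protein.matrix, bp)
        assert np.array_equal(ligand.matrix, bl)

    def test_k_matches_direct_recomputation(self, protein, ligand, rng):
        """K recomputed straight from the definition on the raw predictions."""
        table = rng.random(1024)
        predictor = lambda Xp, Xl: table[np.arange(len(Xp))] + Xp.sum(axis=(1, 2)) / 100
        cfg = OcclusionConfig(window=9, stride=2, epsilon=1e-6)
        result = occlusion_scan(predictor, protein, ligand, 0.7, cfg)
        brute = np.abs(result.p_masked - 0.7) / (np.abs(result.p_unmasked - 0.7) + 1e-6)
        assert np.allclose(result.k_values, brute, atol=1e-12)


class TestAggregate:
    def _result(self, k_values, window, length, stride=1):
        from plinet.occlusion import OcclusionResult
        starts = np.arange(0, length - window + 1, stride)
        return OcclusionResult(starts=starts, k_values=np.asarray(k_values, float),
                               p_unmasked=0.5, p_masked=np.zeros(len(starts)),
                               binding_value=1.0, window=window, stride=stride,
                               true_length=length)

    def test_window_one_equals_raw_in_both_modes(self):
        k = np.arange(1, 11, dtype=float)
        result = self._result(k, window=1, length=10)
        assert np.array_equal(aggregate_to_residues(result, "center"), k)
        assert np.array_equal(aggregate_to_residues(result, "mean_over_covering"), k)

    def test_constant_k_constant_track(self):
        result = self._result(np.full(8, 2.5), window=3, length=10)
        track = aggregate_to_residues(result, "mean_over_covering")
        assert np.allclose(track, 2.5)

    def test_single_high_window_center_mode(self):
        k = np.ones(8)
        k[4] = 9.0
        result = self._result(k, window=3, length=10)
        track = aggregate_to_residues(result, "center")
        assert track[5] == 9.0  # center of window starting at 4
        assert np.sum(track == 9.0) == 1

    def test_uncovered_residues_neutral(self):
        result = self._result([3.0], window=3, length=10, stride=10)
        track = aggregate_to_residues(result, "mean_over_covering")
        assert np.allclose(track[3:], 1.0)


class TestCallSites:
    def test_kr_zero_calls_everything(self, rng):
        track = rng.random(30)
        assert call_sites(track, 0) == [(0, 30)]

    def test_kr_100_only_maximal(self):
        track = np.array([1.0, 2.0, 5.0, 2.0])
        assert call_sites(track, 100) == [(2, 3)]

    def test_uniform_track_all_called(self):
        # percentile of a constant track equals that constant; >= calls all
        assert call_sites(np.full(10, 1.0), 90) == [(0, 10)]

    def test_runs_merged(self):
        track = np.array([9, 9, 0, 0, 9, 9, 9, 0], dtype=float)
        assert call_sites(track, 60) == [(0, 2), (4, 7)]

    @settings(max_examples=30)
    @given(st.integers(0, 2 ** 30))
    def test_monotone_shrinkage_in_kr(self, seed):
        track = np.random.default_rng(seed).random(40)
        called = [residue_mask(call_sites(track, kr), 40).sum()
                  for kr in (0, 25, 50, 75, 100)]
        assert all(a >= b for a, b in zip(called, called[1:]))


class TestEvaluateSites:
    def test_perfect_prediction(self):
        truth = [[(5, 15)]]
        out = evaluate_sites([[(5, 15)]], truth, [40])
        assert out["precision"] == 1.0 and out["recall"] == 1.0

    def test_call_everything(self):
        truth = [[(5, 15)]]
        out = evaluate_sites([[(0, 40)]], truth, [40])
        assert out["recall"] == 1.0
        assert np.isclose(out["precision"], 10 / 40)
        assert np.isclose(out["random_baseline"], 10 / 40)

    def test_kr_curve_shape(self, rng):
        tracks = [rng.random(40) for _ in range(3)]
        truth = [[(0, 10)], [(10, 20)], [(30, 40)]]
        out = evaluate_sites(None, truth, [40, 40, 40],
                             kr_grid=[0, 50, 95], tracks=tracks)
        assert len(out["curve"]) == 3
        recalls = [row["recall"] for row in out["curve"]]
        assert recalls[0] == 1.0  # Kr=0 calls every residue

    def test_dilation_widens_truth(self):
        out = evaluate_sites([[(3, 5)]], [[(5, 7)]], [20], dilate_truth=2)
        assert out["precision"] == 1.0  # dilated truth now covers [3, 9)


def test_track_auprc_separates_signal_from_noise(rng):
    track = np.full(50, 1.0)
    track[20:28] = 5.0
    assert track_auprc(track, [(20, 28)]) == 1.0
    shuffled = rng.permutation(track)
    assert track_auprc(track, [(20, 28)]) >= track_auprc(shuffled, [(20, 28)])
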