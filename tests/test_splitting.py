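"""Identity, clustering, fold assignment, ratio enforcement, binarization."""

import numpy as np
import pandas as pd
import pytest
from Bio import Align

from plinet.splitting import (
    TargetClustering,
    add_fold_column,
    binarize_affinity,
    cluster_targets,
    drop_floor_values,
    enforce_ratio,
    global_identity,
    make_folds,
)


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("MKTAYIAK", "MKTAYIAK") == 100.0

    def test_hand_alignment(self):
        assert global_identity("AAAA", "AAAT") == 75.0

    def test_symmetry(self):
        a, b = "MKWVTFISLLFLFSSAYS", "MKWVTALSLLFAFSSAYS"
        assert np.isclose(global_identity(a, b), global_identity(b, a))

    def test_gap_in_alignment_length_denominator(self):
        # best alignment of AAAA vs AA uses 2 gaps: 2 matches / 4 columns
        assert global_identity("AAAA", "AA") == 50.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            global_identity("", "AAA")

    def test_score_matches_biopython_global_aligner(self, rng):
        """NW scores agree with Biopython's PairwiseAligner (independent
        implementation of the same scoring scheme)."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        from plinet.splitting import _nw_matrices
        for _ in range(25):
            a = "".join(rng.choice(aa, size=rng.integers(3, 25)))
            b = "".join(rng.choice(aa, size=rng.integers(3, 25)))
            S, _P = _nw_matrices(a, b, 1.0, 0.0, -1.0)
            assert np.isclose(S[len(a), len(b)], aligner.score(a, b))


class TestClusterTargets:
    def test_all_identical_single_cluster(self):
        seqs = {f"P{i}": "MKTAYIAKQRQISFVK" for i in range(4)}
        assert cluster_targets(seqs, 80).n_clusters == 1

    def test_two_families_separate(self):
        fam_a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        fam_b = "GSHMWNSNLPQHVTSAGDDVRPYTGWWNAVHQA"
        seqs = {"A1": fam_a, "A2": fam_a[:-2] + "GG", "B1": fam_b, "B2": fam_b[:-2] + "AA"}
        clustering = cluster_targets(seqs, 80)
        assert clustering.n_clusters == 2
        assert clustering.assignments["A1"] == clustering.assignments["A2"]
        assert clustering.assignments["B1"] == clustering.assignments["B2"]
        assert clustering.assignments["A1"] != clustering.assignments["B1"]

    def test_transitive_chain_merges(self):
        # A~B and B~C above threshold, A~C below: single linkage joins all
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"  # 32 residues
        a = base
        b = base[:28] + "GGGG"                      # 87.5% to a
        c = base[:24] + "GGGGGGGG"                  # 87.5% to b, 75% to a
        assert global_identity(a, b) > 80
        assert global_identity(b, c) > 80
        assert global_identity(a, c) <= 80
        clustering = cluster_targets({"A": a, "B": b, "C": c}, 80)
        assert clustering.n_clusters == 1

    def test_threshold_extremes(self):
        # a shared first residue keeps every pairwise identity > 0
        seqs = {"A": "AMKT", "B": "AGSH", "C": "AHWW"}
        assert cluster_targets(seqs, 0).n_clusters == 1      # everything joins
        assert cluster_targets(seqs, 100.0).n_clusters == 3  # strict > 100 never

    def test_threshold_tie_is_strict(self):
        # exactly 75% identity with threshold 75 -> no edge
        clustering = cluster_targets({"A": "AAAA", "B": "AAAT"}, 75.0)
        assert clustering.n_clusters == 2


class TestMakeFolds:
    def test_equal_clusters_balanced(self):
        clustering = TargetClustering({f"P{i}": i for i in range(9)}, 80)
        folds = make_folds(clustering, k=3, seed=0)
        counts = pd.Series(folds).value_counts()
        assert sorted(counts) == [3, 3, 3]

    def test_no_protein_level_leakage(self):
        assignments = {f"P{i}": i % 4 for i in range(12)}
        clustering = TargetClustering(assignments, 80)
        folds = make_folds(clustering, k=3, seed=1)
        for pid, cid in assignments.items():
            same_cluster = [q for q, c in assignments.items() if c == cid]
            assert len({folds[q] for q in same_cluster}) == 1
        fold_sets = [set(p for p, f in folds.items() if f == j) for j in range(3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (fold_sets[i] & fold_sets[j])

    def test_skewed_weights_greedy_bound(self):
        clustering = TargetClustering({f"P{i}": i for i in range(8)}, 80)
        weights = {f"P{i}": w for i, w in enumerate([50, 30, 20, 10, 5, 5, 5, 5])}
        folds = make_folds(clustering, k=2, seed=0, weights=weights)
        loads = pd.Series({p: weights[p] for p in folds}).groupby(pd.Series(folds)).sum()
        assert loads.max() / loads.min() < 2


def _toy_manifest():
    rows = []
    for i in range(100):
        rows.append((f"P{i % 10}", f"Lp{i}", "d1", "classification", 1))
    for i in range(1000):
        rows.append((f"P{i % 10}", f"Ln{i}", "d1", "classification", 0))
    return pd.DataFrame(rows, columns=["protein_id", "ligand_id", "dataset", "task", "label"])


class TestEnforceRatio:
    def test_downsamples_to_ratio(self):
        out = enforce_ratio(_toy_manifest(), 3.0, seed=0)
        assert (out.label == 1).sum() == 100
        assert (out.label == 0).sum() == 300

    def test_insufficient_negatives_unchanged_with_warning(self):
        manifest = _toy_manifest().iloc[:150]  # 100 pos, 50 neg
        with pytest.warns(UserWarning):
            out = enforce_ratio(manifest, 3.0, seed=0)
        assert len(out) == 150

    def test_seeded_determinism(self):
        a = enforce_ratio(_toy_manifest(), 3.0, seed=5)
        b = enforce_ratio(_toy_manifest(), 3.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_positives_never_touched(self):
        manifest = _toy_manifest()
        out = enforce_ratio(manifest, 0.5, seed=0)
        pos_ids = set(manifest[manifest.label == 1].ligand_id)
        assert set(out[out.label == 1].ligand_id) == pos_ids


class TestBinarizeAffinity:
    def test_above_threshold_positive(self):
        assert binarize_affinity([6.5])[0] == 1

    def test_tie_is_negative(self):
        assert binarize_affinity([6.0])[0] == 0

    def test_micromolar_anchor(self):
        assert -np.log10(1e-6) == 6.0

    def test_alternative_threshold(self):
        assert binarize_affinity([12.2], threshold=12.1)[0] == 1
        assert binarize_affinity([12.0], threshold=12.1)[0] == 0


def test_drop_floor_values():
    df = pd.DataFrame({
        "protein_id": list("ABCD"), "ligand_id": list("abcd"),
        "dataset": ["d"] * 4, "task": ["regression"] * 3 + ["classification"],
        "label": [5.0, 6.2, 5.0, 1],
    })
    out = drop_floor_values(df, 5.0)
    assert len(out) == 2  # regression rows at the floor removed, others kept
    assert set(out.protein_id) == {"B", "D"}


def test_add_fold_column_rejects_unassigned():
    df = _toy_manifest().head(5)
    with pytest.raises(ValueError, match="without a fold"):
        add_fold_column(df, {"P0": 0})
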