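"""Occlusion interpretability: sliding-window masking of the protein input.

A window of ``window`` residues (default 15, stride 1) is zeroed out of the
protein one-hot matrix while the ligand matrix is left unchanged; the model
is re-run and the importance of the masked region is

    K_ij = |p_ij - v_i| / (|p_i - v_i| + eps)

where ``v_i`` is the real binding value, ``p_i`` the unmasked prediction
and ``p_ij`` the prediction with window ``j`` masked.  K > 1 marks a region
whose removal hurts the prediction (important), K close to 1 an irrelevant
region, K < 1 candidate noise.  Window K values are aggregated into a
per-residue track (window center by default; the mean over covering
windows is provided because pooling can shift the signal by a few
residues), thresholded at the Kr-th percentile of the track to call
binding-site intervals, and scored against ground-truth intervals at
residue level.

All intervals are 0-based, half-open (BED convention).  Masking uses
all-zero columns — identical to padding and to the unknown-token policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from .encoding import LigandEncoding, ProteinEncoding

__all__ = [
    "OcclusionConfig",
    "OcclusionResult",
    "mask_window",
    "occlusion_scan",
    "aggregate_to_residues",
    "call_sites",
    "residue_mask",
    "evaluate_sites",
    "track_auprc",
]


@dataclass
class OcclusionConfig:
    window: int = 15
    stride: int = 1
    epsilon: float = 1e-6
    kr: float = 90.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not (0 <= self.kr <= 100):
            raise ValueError("Kr must lie in [0, 100]")


@dataclass
class OcclusionResult:
    """Per-window K values for one protein-ligand sample."""

    starts: np.ndarray          # window start residues (0-based)
    k_values: np.ndarray        # K per window
    p_unmasked: float           # p_i
    p_masked: np.ndarray        # p_ij per window
    binding_value: float        # v_i
    window: int
    stride: int
    true_length: int

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def mask_window(encoding: ProteinEncoding, start: int, window: int) -> ProteinEncoding:
    """Zero columns ``[start, start + window)``; all others bit-identical.

    Pure: returns a new encoding, the input is never mutated.
    """
    if start < 0 or window < 1:
        raise ValueError("start must be >= 0 and window >= 1")
    if start + window > encoding.true_length:
        raise ValueError(
            f"window [{start}, {start + window}) extends past true_length "
            f"{encoding.true_length}")
    out = encoding.copy()
    out.matrix[:, start : start + window] = 0.0
    return out


def occlusion_scan(
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray],
    protein: ProteinEncoding,
    ligand: LigandEncoding,
    binding_value: float,
    config: OcclusionConfig | None = None,
) -> OcclusionResult:
    """Slide a mask along the protein and score each window with K.

    ``predict`` maps batches ``(Xp (B, 20, L), Xl (B, 64, L'))`` to a
    vector of predictions; all masked variants are evaluated in one batch.
    Windows that would extend past the true sequence length are skipped;
    a protein shorter than the window gets a single whole-sequence mask
    (with a warning).
    """
    if config is None:
        config = OcclusionConfig()
    L = protein.true_length
    if L < config.window:
        warnings.warn(
            f"protein length {L} shorter than window {config.window}; "
            "masking the whole sequence once")
        starts = np.array([0])
        widths = [L]
    else:
        starts = np.arange(0, L - config.window + 1, config.stride)
        widths = [config.window] * len(starts)
    masked = np.stack([
        mask_window(protein, int(s), int(w)).matrix for s, w in zip(starts, widths)
    ])
    Xl = np.broadcast_to(ligand.matrix, (len(starts),) + ligand.matrix.shape)
    p_i = float(predict(protein.matrix[None], ligand.matrix[None])[0])
    p_ij = np.asarray(predict(masked, np.ascontiguousarray(Xl)), dtype=float)
    k = np.abs(p_ij - binding_value) / (abs(p_i - binding_value) + config.epsilon)
    return OcclusionResult(
        starts=starts, k_values=k, p_unmasked=p_i, p_masked=p_ij,
        binding_value=float(binding_value), window=config.window,
        stride=config.stride, true_length=L,
    )


def aggregate_to_residues(result: OcclusionResult, mode: str = "center") -> np.ndarray:
    """Turn window K values into a per-residue importance track.

    ``center`` assigns each window's K to its center residue; ``mean_over_
    covering`` averages K over every window covering a residue.  Residues
    covered by no window keep the neutral value 1.
    """
    if mode not in ("center", "mean_over_covering"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    track = np.ones(result.true_length)
    if mode == "center":
        centers = result.starts + result.window // 2
        centers = np.clip(centers, 0, result.true_length - 1)
        track[centers] = result.k_values
    else:
        total = np.zeros(result.true_length)
        count = np.zeros(result.true_length)
        for start, k in zip(result.starts, result.k_values):
            end = min(start + result.window, result.true_length)
            total[start:end] += k
            count[start:end] += 1
        covered = count > 0
        track[covered] = total[covered] / count[covered]
    return track


def call_sites(track: np.ndarray, kr: float) -> list[tuple[int, int]]:
    """Threshold a K track at its Kr-th percentile and merge runs.

    ``K_threshold`` is the Kr-th percentile of the track values; residues
    with K >= K_threshold are called and maximal runs are returned as
    0-based half-open intervals.  Kr = 0 calls every residue; Kr = 100
    calls only maximal-K residues.
    """
    track = np.asarray(track, dtype=float)
    if not (0 <= kr <= 100):
        raise ValueError("Kr must lie in [0, 100]")
    k_threshold = np.percentile(track, kr)
    mask = track >= k_threshold
    intervals: list[tuple[int, int]] = []
    start = None
    for i, hit in enumerate(mask):
        if hit and start is None:
            start = i
        elif not hit and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(mask)))
    return intervals


def residue_mask(intervals: Sequence[tuple[int, int]], length: int,
                 dilate: int = 0) -> np.ndarray:
    """Boolean per-residue mask from 0-based half-open intervals.

    ``dilate`` widens each interval by that many residues on both sides —
    the optional shift tolerance for pooling-induced translation.
    """
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        lo = max(0, int(start) - dilate)
        hi = min(length, int(end) + dilate)
        mask[lo:hi] = True
    return mask


def evaluate_sites(
    predicted: Sequence[Sequence[tuple[int, int]]] | None,
    truth: Sequence[Sequence[tuple[int, int]]],
    lengths: Sequence[int],
    kr_grid: Sequence[float] | None = None,
    tracks: Sequence[np.ndarray] | None = None,
    dilate_truth: int = 0,
) -> dict:
    """Residue-level precision/recall, averaged over samples.

    Two call styles: pass per-sample ``predicted`` intervals for a single
    operating point, or pass per-sample K ``tracks`` plus a ``kr_grid`` to
    sweep Kr and produce a precision-recall curve.  The random-guess
    baseline is the mean truth-residue fraction.
    """
    truth_masks = [residue_mask(t, L, dilate=dilate_truth) for t, L in zip(truth, lengths)]
    baseline = float(np.mean([m.mean() for m in truth_masks]))

    def _pr(pred_masks):
        precisions, recalls = [], []
        for pm, tm in zip(pred_masks, truth_masks):
            tp = np.sum(pm & tm)
            precisions.append(tp / pm.sum() if pm.sum() else np.nan)
            recalls.append(tp / tm.sum() if tm.sum() else np.nan)
        return (float(np.nanmean(precisions)) if precisions else np.nan,
                float(np.nanmean(recalls)) if recalls else np.nan)

    out: dict = {"random_baseline": baseline}
    if predicted is not None:
        pred_masks = [residue_mask(p, L) for p, L in zip(predicted, lengths)]
        out["precision"], out["recall"] = _pr(pred_masks)
    if tracks is not None and kr_grid is not None:
        rows = []
        for kr in kr_grid:
            pred_masks = [residue_mask(call_sites(tr, kr), L)
                          for tr, L in zip(tracks, lengths)]
            p, r = _pr(pred_masks)
            rows.append({"kr": float(kr), "precision": p, "recall": r})
        out["curve"] = rows
    return out


def track_auprc(track: np.ndarray, truth_intervals: Sequence[tuple[int, int]],
                dilate: int = 0) -> float:
    """Area under the precision-recall curve of a K track vs truth residues."""
    truth = residue_mask(truth_intervals, len(track), dilate=dilate)
    if truth.all() or not truth.any():
        return np.nan
    return float(average_precision_score(truth.astype(int), np.asarray(track)))
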