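"""Gated-saliency importance scores and seqlet summaries.

For cell-type-specific interpretation the workflow is: sample test examples
whose label vector is positive for exactly one track (mutually exclusive
labels), take the gradient of that track's pre-sigmoid output with respect
to the one-hot input (saliency), gate the gradient by the observed
nucleotide — the gradient of unobserved bases is set exactly to zero — and
summarise high-importance stretches as seqlets.  Importance arrays can be
exported (with their one-hot sequences and a JSON manifest) for external
motif-discovery tooling; a small PWM matcher is included for synthetic-data
checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ImportanceTrack",
    "Seqlet",
    "sample_exclusive_bins",
    "saliency",
    "gate_importance",
    "extract_seqlets",
    "export_importance",
    "load_importance",
    "match_pwm",
]


@dataclass(frozen=True)
class ImportanceTrack:
    sequence_id: str
    importance: np.ndarray      # (L, 4); exactly zero off the observed base
    target_feature: str


@dataclass(frozen=True)
class Seqlet:
    sequence_id: str
    start: int
    end: int
    summed_importance: float


def sample_exclusive_bins(
    labels: np.ndarray, n: int = 2000, seed: int = 0
) -> dict[int, np.ndarray]:
    """Per-feature index sets of examples with exactly one positive label.

    Sampling is without replacement and deterministic given the seed; if a
    feature has fewer than ``n`` exclusive examples, all of them are
    returned (with a warning when it has none).
    """
    import warnings

    rng = np.random.default_rng(seed)
    exclusive = labels.sum(axis=1) == 1
    groups: dict[int, np.ndarray] = {}
    for f in range(labels.shape[1]):
        eligible = np.flatnonzero(exclusive & (labels[:, f] == 1))
        if len(eligible) == 0:
            warnings.warn(f"feature {f}: no mutually exclusive examples")
            groups[f] = eligible
            continue
        k = min(n, len(eligible))
        groups[f] = np.sort(rng.choice(eligible, size=k, replace=False))
    return groups


def saliency(model, onehot: np.ndarray, feature_index: int) -> np.ndarray:
    """Gradient of the target track's pre-sigmoid output wrt the input.

    ``onehot`` is a single (L, 4) matrix; the result has the same shape and
    is finite everywhere.
    """
    x = onehot[None]
    logits = model.forward(x, train=False)
    if not 0 <= feature_index < logits.shape[1]:
        raise IndexError(f"feature index {feature_index} out of range")
    dy = np.zeros_like(logits)
    dy[0, feature_index] = 1.0
    grad = model.backward(dy)[0]
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite saliency gradient")
    return grad


def gate_importance(gradient: np.ndarray, onehot: np.ndarray,
                    sequence_id: str = "", target_feature: str = "") -> ImportanceTrack:
    """Keep the gradient of the observed nucleotide only (elementwise gate)."""
    if gradient.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {gradient.shape} vs {onehot.shape}")
    return ImportanceTrack(sequence_id, gradient * onehot, target_feature)


def extract_seqlets(track: ImportanceTrack, window: int = 8,
                    threshold_sd: float = 2.0) -> list[Seqlet]:
    """Greedy non-overlapping high-importance windows.

    Per-position importance (sum over bases) is summed over sliding windows;
    windows whose sum exceeds ``threshold_sd`` standard deviations above the
    mean window sum are reported greedily by descending sum, skipping
    overlaps.
    """
    if window < 4:
        raise ValueError("seqlet window must be >= 4")
    per_pos = track.importance.sum(axis=1)
    if len(per_pos) < window:
        return []
    sums = np.convolve(per_pos, np.ones(window), mode="valid")
    thr = sums.mean() + threshold_sd * sums.std()
    if sums.std() == 0:
        return []
    order = np.argsort(-sums, kind="stable")
    chosen: list[Seqlet] = []
    for i in order:
        if sums[i] <= thr:
            break
        if all(i + window <= s.start or s.end <= i for s in chosen):
            chosen.append(Seqlet(track.sequence_id, int(i), int(i + window),
                                 float(sums[i])))
    return sorted(chosen, key=lambda s: -s.summed_importance)


def export_importance(tracks: list[ImportanceTrack], onehots: list[np.ndarray],
                      path: str | Path) -> None:
    """Write importance + one-hot arrays with a JSON manifest (lossless)."""
    if not tracks:
        raise ValueError("no importance tracks to export")
    if len(tracks) != len(onehots):
        raise ValueError("tracks and one-hot sequences must align")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "importance.npy", np.stack([t.importance for t in tracks]))
    np.save(path / "onehot.npy", np.stack(onehots))
    manifest = {
        "sequence_ids": [t.sequence_id for t in tracks],
        "target_features": [t.target_feature for t in tracks],
        "n": len(tracks),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_importance(path: str | Path) -> tuple[list[ImportanceTrack], np.ndarray]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    imp = np.load(path / "importance.npy")
    onehot = np.load(path / "onehot.npy")
    tracks = [
        ImportanceTrack(sid, imp[i], feat)
        for i, (sid, feat) in enumerate(zip(manifest["sequence_ids"],
                                            manifest["target_features"]))
    ]
    return tracks, onehot


def match_pwm(candidate: np.ndarray, reference: np.ndarray,
              max_offset: int = 3) -> float:
    """Best Pearson correlation of aligned, trimmed PWM columns over offsets.

    A convenience matcher for synthetic-data checks: both matrices are
    (width, 4); the candidate is slid against the reference over offsets in
    ±``max_offset`` and the best correlation over the overlapping columns
    (flattened) is returned.
    """
    best = -1.0
    w_c, w_r = len(candidate), len(reference)
    for off in range(-max_offset, max_offset + 1):
        lo_c, lo_r = max(0, -off), max(0, off)
        span = min(w_c - lo_c, w_r - lo_r)
        if span < 4:
            continue
        a = candidate[lo_c : lo_c + span].ravel()
        b = reference[lo_r : lo_r + span].ravel()
        if a.std() == 0 or b.std() == 0:
            continue
        best = max(best, float(np.corrcoef(a, b)[0, 1]))
    return best
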