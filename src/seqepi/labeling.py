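"""Genome binning, peak-overlap labeling, splitting and one-hot encoding.

The labeling pipeline converts a genome plus per-feature peak files into
training examples: the genome is tiled into consecutive 200-bp bins, a bin
is labeled positive for a feature when at least 50% of the bin is covered by
the union of that feature's peaks, bins with no positive feature are
discarded, held-out chromosomes (chr7/chr8 by convention) form the test set,
and each retained bin is extended symmetrically to a 1-kb window and one-hot
encoded.  Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinLabelMatrix",
    "DatasetSplit",
    "EncodedDataset",
    "bin_genome",
    "label_bins",
    "filter_positive",
    "chromosomal_split",
    "extend_and_extract",
    "one_hot_encode",
    "one_hot_decode",
    "merge_intervals",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lowercase


@dataclass
class BinLabelMatrix:
    """Sorted non-overlapping bins with a binary feature-label matrix."""

    bins: pd.DataFrame                 # columns chrom, start, end
    labels: np.ndarray                 # (n_bins, n_features) int8
    feature_names: list[str]

    def __post_init__(self):
        if len(self.bins) != len(self.labels):
            raise ValueError("bins and labels must have the same length")
        if self.labels.ndim != 2 or self.labels.shape[1] != len(self.feature_names):
            raise ValueError("label matrix width must match feature names")


@dataclass
class DatasetSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    test_chroms: set[str] = field(default_factory=set)


def bin_genome(chrom_sizes: dict[str, int], bin_length: int = 200) -> pd.DataFrame:
    """Tile each chromosome into consecutive bins; drop the trailing partial bin."""
    if bin_length <= 0:
        raise ValueError("bin length must be positive")
    frames = []
    for chrom, size in chrom_sizes.items():
        n = size // bin_length
        if n == 0:
            continue
        starts = np.arange(n) * bin_length
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + bin_length,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent half-open intervals; returns sorted arrays."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [int(s[0])], [int(e[0])]
    for a, b in zip(s[1:], e[1:]):
        if a <= me[-1]:
            me[-1] = max(me[-1], int(b))
        else:
            ms.append(int(a))
            me.append(int(b))
    return np.array(ms), np.array(me)


def _covered_length(points_lo, points_hi, ms, me):
    """bp of [lo, hi) covered by merged intervals (vectorised over bins)."""
    if len(ms) == 0:
        return np.zeros(len(points_lo), dtype=int)
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def cov(x):
        k = np.searchsorted(ms, x, side="right")
        out = cum[k].astype(int)
        inside = k > 0
        prev = np.maximum(k - 1, 0)
        out -= np.maximum(me[prev] - x, 0) * inside
        return out

    return cov(points_hi) - cov(points_lo)


def label_bins(
    bins: pd.DataFrame,
    peak_sets: dict[str, pd.DataFrame],
    min_overlap_fraction: float = 0.5,
) -> BinLabelMatrix:
    """Binary bin × feature labels from union peak coverage.

    ``label[b, f] = 1`` iff the union of feature *f*'s peaks covers at least
    ``min_overlap_fraction`` of bin *b* (the boundary case counts: covering
    exactly half of a 200-bp bin is positive).  Peaks on chromosomes absent
    from the bin set are ignored with a warning.
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValueError("min overlap fraction must be in (0, 1]")
    feature_names = list(peak_sets)
    labels = np.zeros((len(bins), len(feature_names)), dtype=np.int8)
    known_chroms = set(bins["chrom"].unique())
    chrom_groups = {c: idx.to_numpy() for c, idx in bins.groupby("chrom").groups.items()}

    for f, name in enumerate(feature_names):
        peaks = peak_sets[name]
        if (peaks["end"] <= peaks["start"]).any():
            raise ValueError(f"feature {name}: invalid peak interval")
        unknown = set(peaks["chrom"].unique()) - known_chroms
        if unknown:
            warnings.warn(
                f"feature {name}: peaks on unknown chromosome(s) "
                f"{sorted(unknown)} ignored"
            )
        for chrom, grp in peaks.groupby("chrom"):
            if chrom not in chrom_groups:
                continue
            ms, me = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
            idx = chrom_groups[chrom]
            lo = bins["start"].to_numpy()[idx]
            hi = bins["end"].to_numpy()[idx]
            covered = _covered_length(lo, hi, ms, me)
            need = min_overlap_fraction * (hi - lo)
            labels[idx[covered >= need], f] = 1
    return BinLabelMatrix(bins.reset_index(drop=True), labels, feature_names)


def filter_positive(matrix: BinLabelMatrix) -> BinLabelMatrix:
    """Keep only bins with at least one positive feature label."""
    keep = matrix.labels.any(axis=1)
    return BinLabelMatrix(
        matrix.bins.loc[keep].reset_index(drop=True),
        matrix.labels[keep],
        list(matrix.feature_names),
    )


def chromosomal_split(
    matrix: BinLabelMatrix,
    test_chroms: set[str] | None = None,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> DatasetSplit:
    """Hold out whole chromosomes for test; split the rest train/validation."""
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation fraction must be in (0, 1)")
    test_chroms = {"chr7", "chr8"} if test_chroms is None else set(test_chroms)
    is_test = matrix.bins["chrom"].isin(test_chroms).to_numpy()
    rest = np.flatnonzero(~is_test)
    if len(rest) == 0:
        raise ValueError(
            "no bins outside the test chromosomes — nothing to train on"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(rest)
    n_val = max(1, int(round(validation_fraction * len(rest))))
    return DatasetSplit(
        train=np.sort(perm[n_val:]),
        validation=np.sort(perm[:n_val]),
        test=np.flatnonzero(is_test),
        test_chroms=test_chroms,
    )


def one_hot_encode(sequence: str) -> np.ndarray:
    """L × 4 one-hot (columns A, C, G, T); N/ambiguity codes give zero rows."""
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    out = np.zeros((len(sequence), 4))
    valid = codes >= 0
    out[np.flatnonzero(valid), codes[valid]] = 1.0
    return out


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; zero rows decode to 'N'."""
    bases = np.array(list("ACGT"))
    idx = matrix.argmax(axis=1)
    out = np.where(matrix.sum(axis=1) > 0, bases[idx], "N")
    return "".join(out)


@dataclass
class EncodedDataset:
    """One-hot examples plus labels and a bin/split manifest."""

    x: np.ndarray                      # (n, window, 4)
    y: np.ndarray                      # (n, n_features)
    manifest: pd.DataFrame             # chrom, start, end, split
    feature_names: list[str]

    def split_arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero((self.manifest["split"] == split).to_numpy())
        return self.x[idx], self.y[idx]

    def save(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "X.npy", self.x.astype(np.float32))
        np.save(path / "Y.npy", self.y.astype(np.int8))
        manifest = self.manifest.copy()
        manifest.to_csv(path / "manifest.tsv", sep="\t", index=False)
        (path / "features.txt").write_text("\n".join(self.feature_names) + "\n")

    @classmethod
    def load(cls, path) -> "EncodedDataset":
        from pathlib import Path

        path = Path(path)
        return cls(
            x=np.load(path / "X.npy").astype(float),
            y=np.load(path / "Y.npy").astype(np.int8),
            manifest=pd.read_csv(path / "manifest.tsv", sep="\t"),
            feature_names=(path / "features.txt").read_text().split(),
        )


def extend_and_extract(
    matrix: BinLabelMatrix,
    genome: dict[str, str],
    split: DatasetSplit | None = None,
    window: int = 1000,
) -> EncodedDataset:
    """Extend each bin symmetrically to ``window`` bp and one-hot encode it.

    Bins whose extended window would leave the chromosome are dropped (their
    count is logged); no padding is ever introduced, so every example is a
    real genomic sequence.
    """
    bin_len = int(matrix.bins["end"].iloc[0] - matrix.bins["start"].iloc[0]) \
        if len(matrix.bins) else 0
    if window < bin_len:
        raise ValueError("window must be at least the bin length")
    if (window - bin_len) % 2 != 0:
        raise ValueError("window minus bin length must be even")
    pad = (window - bin_len) // 2

    split_of = np.full(len(matrix.bins), "", dtype=object)
    if split is not None:
        split_of[split.train] = "train"
        split_of[split.validation] = "validation"
        split_of[split.test] = "test"
    else:
        split_of[:] = "all"

    xs, ys, rows = [], [], []
    dropped = 0
    chroms = matrix.bins["chrom"].to_numpy()
    starts = matrix.bins["start"].to_numpy()
    ends = matrix.bins["end"].to_numpy()
    for i in range(len(matrix.bins)):
        lo, hi = int(starts[i]) - pad, int(ends[i]) + pad
        seq = genome.get(chroms[i])
        if seq is None or lo < 0 or hi > len(seq):
            dropped += 1
            continue
        xs.append(one_hot_encode(str(seq[lo:hi])))
        ys.append(matrix.labels[i])
        rows.append((chroms[i], int(starts[i]), int(ends[i]), split_of[i]))
    if dropped:
        logger.info("extend_and_extract: dropped %d boundary bins", dropped)
    x = np.stack(xs) if xs else np.empty((0, window, 4))
    y = np.array(ys, dtype=np.int8) if ys else np.empty((0, len(matrix.feature_names)), dtype=np.int8)
    manifest = pd.DataFrame(rows, columns=["chrom", "start", "end", "split"])
    return EncodedDataset(x, y, manifest, list(matrix.feature_names))
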