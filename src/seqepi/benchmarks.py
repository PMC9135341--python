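"""Desk-scale synthetic benchmark studies.

These functions define the package's reference study conditions — the
synthetic data sizes, motif vocabulary, model widths and training settings
used by the test suite and the acceptance script.  They are deliberately
small enough to run on one CPU core in minutes while preserving the
statistical structure of the full-scale problem:

* **single-motif study** — one epigenomic track driven by one strong motif;
  2,000 training and up to 500 held-out-chromosome test examples of 400 bp;
  used for learnability, variant-effect recovery and saliency checks.
* **transfer study** — a 10-track reference compendium whose tasks are
  built from an 8-motif vocabulary, and a 3-track target set sharing that
  vocabulary but only ~1,000 training examples; the meta-feature extractor
  is pre-trained on the reference set and the joint model is fine-tuned on
  the target set, against a from-scratch baseline.

All randomness flows from the caller's seed.  The motif vocabulary of the
transfer study is fixed (its own internal seed) so reference and target
tasks share determinants by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from seqepi import labeling as lab
from seqepi import synthetic as syn
from seqepi.models import (
    JointModel,
    JointModelSpec,
    MetaFeat,
    MetaFeatSpec,
    ResNetEncoderSpec,
    build_joint,
    build_metafeat,
)
from seqepi.training import (
    TrainConfig,
    TrainHistory,
    evaluate_model,
    pretrain_metafeat,
    train_joint,
)

__all__ = [
    "WINDOW",
    "desk_metafeat_spec",
    "desk_joint_spec",
    "SingleMotifStudy",
    "make_single_motif_data",
    "train_single_motif_model",
    "make_variant_study",
    "run_transfer_comparison",
]

WINDOW = 400        # bp; covers the full span of any peak overlapping the bin
BIN = 200
PEAK_LENGTH = 200
VAL_FRACTION = 0.15

# The single-track study plants one wide (18 bp) motif instance per peak, so
# a lone instance carries all the evidence; the transfer study spreads the
# load over two 12-bp instances per peak and an 8-motif vocabulary.
SINGLE_MOTIF_WIDTH = 18
TRANSFER_MOTIF_WIDTH = 12
SINGLE_CHANNELS = (64, 64, 96)
TRANSFER_CHANNELS = (32, 48, 64)


def desk_metafeat_spec(n_meta: int,
                       channels: tuple[int, int, int] = TRANSFER_CHANNELS) -> MetaFeatSpec:
    """Scaled-down extractor: same topology, reduced widths, kernel 11
    (comparable to the motif widths at this scale)."""
    return MetaFeatSpec(channels=channels, kernel=11, pool=4, hidden=64,
                        n_meta=n_meta, input_length=WINDOW)


def desk_joint_spec(n_meta: int, n_out: int,
                    channels: tuple[int, int, int] = TRANSFER_CHANNELS) -> JointModelSpec:
    return JointModelSpec(
        metafeat=desk_metafeat_spec(n_meta, channels),
        encoder=ResNetEncoderSpec(
            stem_channels=8, block_channels=(8, 8, 12, 12, 16, 16, 24, 24),
            block_kernel=7, hidden=32, n_target=n_out, input_length=WINDOW,
        ),
        head_hidden=(48, 24),
        n_out=n_out,
        input_length=WINDOW,
    )


def _encode(tasks, chroms, motifs, seed, implants):
    rng = np.random.default_rng(seed)
    genome = syn.generate_genome(
        syn.SyntheticGenomeSpec(chromosomes=chroms, seed=seed))
    peaks, truth = syn.generate_task_peaks(
        genome, tasks, motifs, rng, motifs_per_peak=implants)
    gstr = syn.genome_to_strings(genome)
    bins = lab.bin_genome({c: len(s) for c, s in gstr.items()}, BIN)
    matrix = lab.label_bins(bins, peaks)
    return genome, gstr, peaks, truth, matrix


@dataclass
class SingleMotifStudy:
    genome: dict[str, np.ndarray]
    genome_str: dict[str, str]
    motifs: dict[str, syn.MotifModel]
    peaks: dict[str, pd.DataFrame]
    truth: syn.SyntheticTruth
    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray


def make_single_motif_data(seed: int, n_peaks: int = 850,
                           n_train: int = 2000, n_test: int = 500) -> SingleMotifStudy:
    """One strong motif, one track; test examples from a held-out chromosome.

    Each peak carries exactly one instance of a wide, information-rich
    motif, so disrupting the instance removes the peak's entire sequence
    evidence (variant effects are never buffered by a second instance).
    The single-track dataset keeps label-negative bins (the track's
    negatives), unlike the multi-track pipeline where bins with no positive
    feature are discarded.
    """
    rng = np.random.default_rng(seed)
    motif = syn.random_motif("m0", SINGLE_MOTIF_WIDTH, rng)
    task = syn.TaskSpec("track0", ("m0",), n_peaks=n_peaks,
                        peak_length=PEAK_LENGTH)
    genome, gstr, peaks, truth, matrix = _encode(
        [task], (("chr1", 400_000), ("chr7", 130_000)), {"m0": motif}, seed,
        implants=1)
    split = lab.chromosomal_split(matrix, {"chr7"}, VAL_FRACTION, seed)
    ds = lab.extend_and_extract(matrix, gstr, split=split, window=WINDOW)
    x_tr, y_tr = ds.split_arrays("train")
    x_va, y_va = ds.split_arrays("validation")
    x_te, y_te = ds.split_arrays("test")
    sub = np.random.default_rng(seed + 100)
    if len(x_tr) > n_train:
        idx = sub.choice(len(x_tr), n_train, replace=False)
        x_tr, y_tr = x_tr[idx], y_tr[idx]
    if len(x_te) > n_test:
        idx = sub.choice(len(x_te), n_test, replace=False)
        x_te, y_te = x_te[idx], y_te[idx]
    return SingleMotifStudy(genome, gstr, {"m0": motif}, peaks, truth,
                            x_tr, y_tr, x_va, y_va, x_te, y_te)


def train_single_motif_model(
    study: SingleMotifStudy, seed: int,
    pretrain_epochs: int = 12, joint_epochs: int = 8,
) -> tuple[JointModel, MetaFeat, TrainHistory, pd.DataFrame]:
    """Two-phase training on the single-motif track; returns the joint
    model, the pre-trained extractor, the joint history and test metrics."""
    meta = build_metafeat(desk_metafeat_spec(n_meta=1, channels=SINGLE_CHANNELS),
                          rng=np.random.default_rng(seed))
    cfg1 = TrainConfig(phase="pretrain", batch_size=32, learning_rate=3e-3,
                       epochs=pretrain_epochs, patience=pretrain_epochs, seed=seed)
    meta, _ = pretrain_metafeat(meta, study.x_train, study.y_train,
                                study.x_val, study.y_val, cfg1)
    model = build_joint(desk_joint_spec(n_meta=1, n_out=1, channels=SINGLE_CHANNELS),
                        rng=np.random.default_rng(seed))
    cfg2 = TrainConfig(phase="joint", batch_size=32, learning_rate=3e-3,
                       momentum=0.9, epochs=joint_epochs, patience=joint_epochs,
                       seed=seed)
    model, history = train_joint(model, study.x_train, study.y_train,
                                 study.x_val, study.y_val, cfg2, pretrained=meta)
    metrics = evaluate_model(model, study.x_test, study.y_test, ["track0"])
    return model, meta, history, metrics


def make_variant_study(
    study: SingleMotifStudy, model: JointModel, seed: int,
    n_functional: int = 200, n_neutral: int = 200,
    depth: int = 100, imbalance_scale: float = 1.0,
) -> dict:
    """Variants on the single-motif genome, scored with the trained model.

    Returns the variant table, planted truth, scored effect table and
    binomial allelic read counts.
    """
    from seqepi.variants import score_variant_table

    rng = np.random.default_rng(seed)
    variants = syn.generate_variants(
        study.genome, study.truth, study.motifs, study.peaks,
        n_functional=n_functional, n_neutral=n_neutral, rng=rng)
    # the genome strings must reflect the (unmodified) implanted genome
    effects, report = score_variant_table(
        model, variants, study.genome_str, feature_names=["track0"],
        window=WINDOW)
    asc = syn.generate_asc_counts(study.truth, rng, depth=depth,
                                  imbalance_scale=imbalance_scale)
    truth_table = pd.DataFrame(
        [(v.variant_id, v.is_functional, v.effect_sign, v.effect_magnitude)
         for v in study.truth.variants],
        columns=["id", "is_functional", "effect_sign", "effect_magnitude"])
    return {"variants": variants, "truth": truth_table, "effects": effects,
            "skipped": report, "asc": asc}


def run_transfer_comparison(seed: int, pretrain_epochs: int = 15,
                            joint_epochs: int = 8) -> dict:
    """Pre-trained versus from-scratch joint model on a low-data target set.

    Reference: 10 tracks (8 single-motif + 2 composite) over an 8-motif
    vocabulary, ~2,300 training examples.  Target: 3 two-motif tracks from
    the same vocabulary, capped at 1,000 training examples.  Returns the
    paired mean test AUPRC of both fits.
    """
    vocab_rng = np.random.default_rng(777)
    motifs = {f"m{i}": syn.random_motif(f"m{i}", TRANSFER_MOTIF_WIDTH, vocab_rng)
              for i in range(8)}
    ref_tasks = [syn.TaskSpec(f"ref{i}", (f"m{i}",), n_peaks=280,
                              peak_length=PEAK_LENGTH) for i in range(8)]
    ref_tasks += [syn.TaskSpec("ref8", ("m0", "m4"), n_peaks=280,
                               peak_length=PEAK_LENGTH),
                  syn.TaskSpec("ref9", ("m1", "m5"), n_peaks=280,
                               peak_length=PEAK_LENGTH)]
    tgt_tasks = [syn.TaskSpec(f"tgt{j}", (f"m{2 * j}", f"m{2 * j + 1}"),
                              n_peaks=550, peak_length=PEAK_LENGTH)
                 for j in range(3)]

    def encode_filtered(tasks, chroms, data_seed):
        _, gstr, peaks, _, matrix = _encode(tasks, chroms, motifs, data_seed,
                                            implants=2)
        matrix = lab.filter_positive(matrix)
        split = lab.chromosomal_split(matrix, {"chr7"}, VAL_FRACTION, data_seed)
        return lab.extend_and_extract(matrix, gstr, split=split, window=WINDOW)

    ref = encode_filtered(ref_tasks, (("chr1", 1_500_000), ("chr7", 80_000)), seed)
    tgt = encode_filtered(tgt_tasks, (("chr1", 700_000), ("chr7", 260_000)), seed + 50)
    x_r, y_r = ref.split_arrays("train")
    x_rv, y_rv = ref.split_arrays("validation")
    x_t, y_t = tgt.split_arrays("train")
    x_tv, y_tv = tgt.split_arrays("validation")
    x_te, y_te = tgt.split_arrays("test")
    sub = np.random.default_rng(seed + 100)
    if len(x_t) > 1000:
        idx = sub.choice(len(x_t), 1000, replace=False)
        x_t, y_t = x_t[idx], y_t[idx]
    if len(x_te) > 500:
        idx = sub.choice(len(x_te), 500, replace=False)
        x_te, y_te = x_te[idx], y_te[idx]

    meta = build_metafeat(desk_metafeat_spec(n_meta=10),
                          rng=np.random.default_rng(seed))
    cfg1 = TrainConfig(phase="pretrain", batch_size=32, learning_rate=3e-3,
                       epochs=pretrain_epochs, patience=pretrain_epochs, seed=seed)
    meta, _ = pretrain_metafeat(meta, x_r, y_r, x_rv, y_rv, cfg1)

    spec = desk_joint_spec(n_meta=10, n_out=3)
    out: dict = {"n_target_train": len(x_t), "n_target_test": len(x_te)}
    for label, pre in (("transfer", meta), ("scratch", None)):
        model = build_joint(spec, rng=np.random.default_rng(seed))
        cfg2 = TrainConfig(phase="joint", batch_size=32, learning_rate=3e-3,
                           momentum=0.9, epochs=joint_epochs,
                           patience=joint_epochs, seed=seed)
        model, _ = train_joint(model, x_t, y_t, x_tv, y_tv, cfg2, pretrained=pre)
        table = evaluate_model(model, x_te, y_te)
        macro = table[table["feature"].str.startswith("macro")]
        out[f"{label}_auprc"] = float(macro["auprc"].iloc[0])
        out[f"{label}_auroc"] = float(macro["auroc"].iloc[0])
    return out
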