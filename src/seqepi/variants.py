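"""Allele-difference variant-effect scoring.

A single-nucleotide variant is scored by building two 1-kb sequences that
differ only at, and are centred on, the variant position, predicting the
per-track accessibility probabilities A_ref and A_alt for both, and taking
their disparity: the absolute difference |A_ref − A_alt| (the default
ranking score), the absolute log-odds difference, and the signed effect
log(A_ref/A_alt) used for direction analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from seqepi.labeling import one_hot_encode
from seqepi.models import predict

__all__ = [
    "VariantRecord",
    "VariantEffect",
    "RefMismatchError",
    "build_allele_sequences",
    "score_variant",
    "score_variant_table",
    "rank_variants",
    "read_variant_table",
]

logger = logging.getLogger(__name__)

_PROB_CLAMP = 1e-6


class RefMismatchError(ValueError):
    """The genome base at the variant position does not match the ref allele."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int                    # 0-based
    ref: str
    alt: str
    id: str

    def __post_init__(self):
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"{self.id}: alleles must be single bases in ACGT")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.id}: negative position")


@dataclass(frozen=True)
class VariantEffect:
    variant_id: str
    abs_diff: np.ndarray        # |A_ref − A_alt| per track, in [0, 1]
    log_odds_diff: np.ndarray   # |logit(A_ref) − logit(A_alt)| per track
    signed: np.ndarray          # log(A_ref / A_alt) per track
    a_ref: np.ndarray
    a_alt: np.ndarray


def build_allele_sequences(
    variant: VariantRecord, genome: dict[str, str], window: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot matrices for both alleles, centred at the variant.

    Both sequences span ``[pos − window/2, pos + window/2)`` so the variant
    base sits at offset ``window // 2`` and they differ nowhere else.
    Variants closer than ``window/2`` to a chromosome end cannot be centred
    and raise ``ValueError``.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    seq = genome.get(variant.chrom)
    if seq is None:
        raise KeyError(f"{variant.id}: chromosome {variant.chrom} not in genome")
    if variant.pos < half or variant.pos + half > len(seq):
        raise ValueError(
            f"{variant.id}: position {variant.pos} is within {half} bp of a "
            f"chromosome end"
        )
    ref_base = str(seq[variant.pos]).upper()
    if ref_base != variant.ref:
        raise RefMismatchError(
            f"{variant.id}: genome has {ref_base!r} at {variant.chrom}:"
            f"{variant.pos}, expected ref {variant.ref!r}"
        )
    core = str(seq[variant.pos - half : variant.pos + half]).upper()
    alt_seq = core[:half] + variant.alt + core[half + 1 :]
    return one_hot_encode(core), one_hot_encode(alt_seq)


def score_variant(model, ref_onehot: np.ndarray, alt_onehot: np.ndarray,
                  variant_id: str = "") -> VariantEffect:
    """Disparity of predicted profiles between the two alleles."""
    probs = predict(model, np.stack([ref_onehot, alt_onehot]))
    a_ref, a_alt = probs[0], probs[1]
    pr = np.clip(a_ref, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    pa = np.clip(a_alt, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    return VariantEffect(
        variant_id=variant_id,
        abs_diff=np.abs(a_ref - a_alt),
        log_odds_diff=np.abs(np.log(pr / (1 - pr)) - np.log(pa / (1 - pa))),
        signed=np.log(pr / pa),
        a_ref=a_ref,
        a_alt=a_alt,
    )


def score_variant_table(
    model,
    variants: pd.DataFrame,
    genome: dict[str, str],
    feature_names: list[str] | None = None,
    window: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every variant in a (chrom, pos0, ref, alt, id) table.

    Returns the effect table (one row per variant, one column group per
    track) and a sidecar report of skipped variants with reasons.  A
    reference-allele mismatch is an error; boundary-violating variants are
    skipped and reported.
    """
    rows, skipped = [], []
    for rec in variants.itertuples(index=False):
        variant = VariantRecord(str(rec.chrom), int(rec.pos0), str(rec.ref),
                                str(rec.alt), str(rec.id))
        try:
            ref_oh, alt_oh = build_allele_sequences(variant, genome, window=window)
        except RefMismatchError:
            raise
        except (ValueError, KeyError) as exc:
            logger.warning("skipping %s: %s", variant.id, exc)
            skipped.append((variant.id, str(exc)))
            continue
        eff = score_variant(model, ref_oh, alt_oh, variant_id=variant.id)
        rows.append((variant.id, variant.chrom, variant.pos, eff))

    n_feat = rows[0][3].abs_diff.size if rows else (
        len(feature_names) if feature_names else 0)
    names = feature_names if feature_names is not None else \
        [f"feature{i}" for i in range(n_feat)]
    data = []
    for vid, chrom, pos, eff in rows:
        row = {"id": vid, "chrom": chrom, "pos0": pos}
        for f, name in enumerate(names):
            row[f"abs_diff.{name}"] = eff.abs_diff[f]
            row[f"log_odds_diff.{name}"] = eff.log_odds_diff[f]
            row[f"signed.{name}"] = eff.signed[f]
            row[f"a_ref.{name}"] = eff.a_ref[f]
            row[f"a_alt.{name}"] = eff.a_alt[f]
        data.append(row)
    effects = pd.DataFrame(data)
    report = pd.DataFrame(skipped, columns=["id", "reason"])
    return effects, report


def rank_variants(effects: pd.DataFrame, feature: str, k: int,
                  score: str = "abs_diff") -> pd.DataFrame:
    """Top-k variants by descending score; ties broken by id lexicographically."""
    col = f"{score}.{feature}"
    if col not in effects.columns:
        raise KeyError(f"unknown feature or score column {col!r}")
    if k > len(effects):
        raise ValueError(f"k={k} exceeds table size {len(effects)}")
    ordered = effects.sort_values([col, "id"], ascending=[False, True],
                                  kind="stable")
    return ordered.head(k).reset_index(drop=True)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read variants from TSV (chrom, pos0, ref, alt, id) or VCF.

    VCF positions are 1-based and converted to 0-based on read; only
    single-base SNVs are retained.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf",):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, pos1, vid, ref, alt = parts[:5]
                if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
                    rows.append((chrom, int(pos1) - 1, ref, alt, vid))
        return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt", "id"])
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
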