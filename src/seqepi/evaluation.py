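"""Validation statistics for predicted functional variants.

Covers the four analyses used to validate allele-difference scores:

* enrichment of allele-specific chromatin accessibility (ASC) variants in
  top-ranked versus control variants (Fisher exact test);
* concordance between observed allelic imbalance log(R_ref/R_alt) and the
  predicted signed effect log(A_ref/A_alt) (Spearman correlation and a
  sign-agreement curve over score cutoffs);
* comparison of evolutionary-constraint scores (GERP/PhyloP-style) between
  top and control variants (Wilcoxon rank-sum test);
* mean minor allele frequency within score bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AscRecord",
    "EnrichmentResult",
    "asc_enrichment",
    "allelic_imbalance_concordance",
    "constraint_comparison",
    "maf_by_score_bins",
    "select_top_and_control",
    "COARSE_SCORE_BINS",
    "FINE_SCORE_BINS",
]

# The two default score-bin edge sets used for the MAF analysis.  The second
# (fine-grained, low-score) set is encoded as 0–0.01, 0.01–0.02, ..., 0.04–1.0.
COARSE_SCORE_BINS = (0.0, 0.05, 0.1, 0.15, 0.2, 1.0)
FINE_SCORE_BINS = (0.0, 0.01, 0.02, 0.03, 0.04, 1.0)


@dataclass(frozen=True)
class AscRecord:
    variant_id: str
    ref_count: int
    alt_count: int
    significant: bool

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_count + self.alt_count == 0:
            raise ValueError("total read count must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    fold_enrichment: float      # proportion ratio (headline number)
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def asc_enrichment(top_ids, control_ids, asc_ids) -> EnrichmentResult:
    """Fisher exact enrichment of ASC variants among top-ranked variants.

    Builds the 2×2 table (top vs control) × (ASC vs not).  Overlap between
    top and control is removed from the control side with a warning.  The
    fold enrichment is the ratio of ASC proportions; the odds ratio and a
    two-sided Fisher exact p-value are also reported.
    """
    top = set(top_ids)
    control = set(control_ids)
    overlap = top & control
    if overlap:
        warnings.warn(f"removing {len(overlap)} variants from control that "
                      f"also appear in the top set")
        control -= overlap
    if not control:
        raise ValueError("control set is empty")
    asc = set(asc_ids)
    a = len(top & asc)
    b = len(top) - a
    c = len(control & asc)
    d = len(control) - c
    table = ((a, b), (c, d))
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    prop_top = a / len(top) if top else 0.0
    prop_ctrl = c / len(control)
    fold = prop_top / prop_ctrl if prop_ctrl > 0 else float("inf")
    return EnrichmentResult(float(fold), float(odds_ratio), float(p), table)


def allelic_imbalance_concordance(
    asc: pd.DataFrame,
    signed_effects: pd.DataFrame,
    cutoffs: np.ndarray | None = None,
    score_column: str = "score",
) -> tuple[float, pd.DataFrame]:
    """Spearman rho of observed vs predicted allelic imbalance, plus a
    sign-agreement curve.

    ``asc`` has columns (id, ref_count, alt_count); ``signed_effects`` has
    (id, signed) and optionally a ranking score column used for the cutoff
    curve (defaults to |signed| when absent).  Records with a zero count on
    either allele are excluded with a warning (log-ratio undefined).  With
    fewer than 3 usable records the correlation is undefined (NaN).
    """
    merged = asc.merge(signed_effects, on="id")
    zero = (merged["ref_count"] == 0) | (merged["alt_count"] == 0)
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} records with a zero "
                      f"allele count")
        merged = merged.loc[~zero]
    observed = np.log(merged["ref_count"].to_numpy(float)
                      / merged["alt_count"].to_numpy(float))
    predicted = merged["signed"].to_numpy(float)
    if score_column in merged.columns:
        score = merged[score_column].to_numpy(float)
    else:
        score = np.abs(predicted)
    if len(merged) < 3:
        warnings.warn("fewer than 3 usable records; correlation undefined")
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(observed, predicted).statistic)
    if cutoffs is None:
        cutoffs = np.quantile(score, np.linspace(0.0, 0.9, 10)) if len(score) \
            else np.array([0.0])
    rows = []
    for cut in np.asarray(cutoffs, dtype=float):
        mask = score >= cut
        n = int(mask.sum())
        agree = float(np.mean(np.sign(observed[mask]) == np.sign(predicted[mask]))) \
            if n else float("nan")
        rows.append((cut, n, agree))
    curve = pd.DataFrame(rows, columns=["cutoff", "n", "sign_agreement"])
    return rho, curve


def constraint_comparison(
    top_ids, control_ids, annotations: pd.DataFrame
) -> dict:
    """Two-sided Wilcoxon rank-sum test on constraint scores.

    ``annotations`` maps variant id → constraint score (columns id,
    constraint).  Unannotated variants are dropped; exact enumeration is
    used for small tie-free groups (both n ≤ 50), the tie-corrected normal
    approximation otherwise.
    """
    lookup = annotations.set_index("id")["constraint"]
    top = lookup.reindex(list(top_ids)).dropna().to_numpy(float)
    control = lookup.reindex(list(control_ids)).dropna().to_numpy(float)
    if len(top) == 0 or len(control) == 0:
        raise ValueError("a group is empty after dropping unannotated variants")
    combined = np.concatenate([top, control])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(top) <= 50 and len(control) <= 50 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(top, control, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_top": float(np.median(top)),
        "median_control": float(np.median(control)),
        "n_top": len(top),
        "n_control": len(control),
    }


def maf_by_score_bins(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    edges: tuple[float, ...] = COARSE_SCORE_BINS,
) -> pd.DataFrame:
    """Per-score-bin count and mean minor allele frequency.

    ``scores`` has columns (id, score) with scores in [0, 1]; ``annotations``
    has (id, maf).  Bins are left-closed right-open except the last, which
    is closed.
    """
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    s = scores["score"].to_numpy(float)
    if (s < 0).any() or (s > 1).any():
        raise ValueError("variant scores must lie in [0, 1]")
    merged = scores.merge(annotations, on="id")
    s = merged["score"].to_numpy(float)
    maf = merged["maf"].to_numpy(float)
    if (maf < 0).any() or (maf > 0.5).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    idx = np.digitize(s, edges[1:-1], right=False)  # 0 .. n_bins-1; last bin closed
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        rows.append((
            edges[b], edges[b + 1], int(mask.sum()),
            float(maf[mask].mean()) if mask.any() else float("nan"),
        ))
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n", "mean_maf"])


def select_top_and_control(
    effects: pd.DataFrame,
    feature: str,
    peaks: pd.DataFrame,
    top_n: int = 10000,
    control_n: int = 100000,
    seed: int = 0,
    score: str = "abs_diff",
) -> tuple[list[str], list[str]]:
    """Top-N scored in-peak variants plus a seeded uniform control sample.

    ``effects`` needs columns (id, chrom, pos0, {score}.{feature}); the
    candidate pool is restricted to variants inside the feature's peak
    regions.  Controls are sampled without replacement from the in-peak pool
    (top variants excluded).  Requested counts larger than the pool are
    truncated with a warning.
    """
    from seqepi.variants import rank_variants

    in_peak = np.zeros(len(effects), dtype=bool)
    pos = effects["pos0"].to_numpy(int)
    chroms = effects["chrom"].to_numpy()
    for chrom, grp in peaks.groupby("chrom"):
        on_chrom = chroms == chrom
        for s_, e_ in zip(grp["start"], grp["end"]):
            in_peak |= on_chrom & (pos >= s_) & (pos < e_)
    pool = effects.loc[in_peak].reset_index(drop=True)
    if len(pool) == 0:
        raise ValueError("no variants fall inside the feature's peak regions")
    k = min(top_n, len(pool))
    if k < top_n:
        warnings.warn(f"only {len(pool)} in-peak variants; top truncated to {k}")
    top = rank_variants(pool, feature, k, score=score)["id"].tolist()
    rest = sorted(set(pool["id"]) - set(top))
    m = min(control_n, len(rest))
    if m < control_n:
        warnings.warn(f"control truncated to {m} variants")
    rng = np.random.default_rng(seed)
    control = [rest[i] for i in rng.choice(len(rest), size=m, replace=False)] \
        if m else []
    return top, control
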