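"""Credible-set SNP prioritization from fine-mapping PIPs and variant scores.

A fine-mapped SNP is called a candidate causal variant when it satisfies all
three criteria:

(i)   posterior inclusion probability above a threshold (default PIP > 0.1);
(ii)  its score reaches the genome-wide top percentile (default top 1%) of a
      background score distribution in at least one cell type;
(iii) its score is the maximum among all SNPs of its locus's credible set in
      at least one cell type (ties at the maximum qualify every tied SNP).

The developmental-stage call (F / A / FA) is the set of stages — fetal or
adult — of the cell types in which the candidate is the credible-set
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeMeta",
    "CandidateCall",
    "genomewide_percentile_thresholds",
    "select_candidates",
    "classify_stage",
    "annotate_candidates",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class CellTypeMeta:
    name: str
    stage: str                  # "F" (fetal) or "A" (adult)
    assay: str = ""

    def __post_init__(self):
        if self.stage not in ("F", "A"):
            raise ValueError(f"cell type {self.name}: stage must be 'F' or 'A'")


@dataclass
class CandidateCall:
    variant_id: str
    locus_id: str
    pip: float
    top_percentile_cell_types: list[str] = field(default_factory=list)
    credible_set_max_cell_types: list[str] = field(default_factory=list)
    stage: str = ""
    annotations: dict = field(default_factory=dict)


def genomewide_percentile_thresholds(
    background: pd.DataFrame, cell_types: list[str], percentile: float = 0.01
) -> pd.Series:
    """Per-cell-type score threshold at the top ``percentile`` of background.

    With n background variants the threshold is the k-th largest score where
    ``k = max(1, floor(percentile × n))``; scores at or above it are "top".
    """
    if len(background) < 100:
        raise ValueError("background table needs at least 100 variants")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    n = len(background)
    k = max(1, int(np.floor(percentile * n)))
    out = {}
    for ct in cell_types:
        vals = background[ct].to_numpy(float)
        out[ct] = float(np.partition(vals, n - k)[n - k])
    return pd.Series(out, name="threshold")


def select_candidates(
    credible: pd.DataFrame,
    thresholds: pd.Series,
    pip_min: float = 0.1,
) -> list[CandidateCall]:
    """Apply the three selection criteria to a credible-set score table.

    ``credible`` has columns (locus, id, pip) plus one score column per cell
    type named in ``thresholds``.  A single-SNP locus trivially satisfies
    the within-locus-maximum criterion in every cell type.
    """
    cell_types = list(thresholds.index)
    missing = [c for c in ["locus", "id", "pip", *cell_types]
               if c not in credible.columns]
    if missing:
        raise ValueError(f"credible-set table is missing columns {missing}")
    locus_max = credible.groupby("locus")[cell_types].transform("max")
    calls = []
    for i in credible.sort_values("id").index:
        row = credible.loc[i]
        if not row["pip"] > pip_min:
            continue
        top_cts = [ct for ct in cell_types if row[ct] >= thresholds[ct]]
        max_cts = [ct for ct in cell_types if row[ct] >= locus_max.loc[i, ct]]
        if top_cts and max_cts:
            calls.append(CandidateCall(
                variant_id=str(row["id"]),
                locus_id=str(row["locus"]),
                pip=float(row["pip"]),
                top_percentile_cell_types=top_cts,
                credible_set_max_cell_types=max_cts,
            ))
    return calls


def classify_stage(candidate: CandidateCall,
                   cell_type_meta: dict[str, CellTypeMeta]) -> str:
    """F, A, or FA from the stages of the candidate's credible-set-max cell types."""
    stages = {cell_type_meta[ct].stage
              for ct in candidate.credible_set_max_cell_types}
    if not stages:
        raise RuntimeError(
            f"{candidate.variant_id}: no credible-set-max cell types — the "
            f"candidate cannot have passed selection"
        )
    call = "FA" if stages == {"F", "A"} else stages.pop()
    candidate.stage = call
    return call


def annotate_candidates(
    candidates: list[CandidateCall],
    annotation_tables: dict[str, pd.DataFrame],
) -> list[CandidateCall]:
    """Left-join annotation flags (eQTL, contact-map target, gene, ...).

    Each table is keyed by variant id; a variant absent from a table is
    recorded as ``None`` (absent), never as negative.  The candidate list
    length is preserved.
    """
    for name, table in annotation_tables.items():
        indexed = table.set_index("id")
        value_col = [c for c in indexed.columns][0] if len(indexed.columns) else None
        for cand in candidates:
            if cand.variant_id in indexed.index and value_col is not None:
                cand.annotations[name] = indexed.loc[cand.variant_id, value_col]
            else:
                cand.annotations[name] = None
    return candidates


def candidates_to_frame(candidates: list[CandidateCall]) -> pd.DataFrame:
    """Flatten candidate calls into an output table (headers kept if empty)."""
    if not candidates:
        return pd.DataFrame(columns=["id", "locus", "pip", "stage",
                                     "top_percentile_cell_types",
                                     "credible_set_max_cell_types"])
    rows = []
    for c in candidates:
        row = {
            "id": c.variant_id,
            "locus": c.locus_id,
            "pip": c.pip,
            "stage": c.stage,
            "top_percentile_cell_types": ",".join(c.top_percentile_cell_types),
            "credible_set_max_cell_types": ",".join(c.credible_set_max_cell_types),
        }
        row.update(c.annotations)
        rows.append(row)
    return pd.DataFrame(rows)
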