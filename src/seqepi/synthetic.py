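"""Synthetic genomes, motif-implanted peak sets, variants, and allelic counts.

This module generates the statistical structure the modelling pipeline
assumes, so every downstream stage is testable without external data:

* an i.i.d. background genome;
* per-task peak sets in which every peak carries at least one planted motif
  from the task's motif subset — tasks that share motifs therefore share
  sequence determinants, the structure transfer learning exploits;
* functional variants that substitute the highest-information column of a
  planted motif with its least-probable base, and neutral variants in peak
  background;
* allelic ATAC-style read counts whose imbalance tracks motif disruption,
  with a Benjamini–Hochberg significance flag from a two-sided exact
  binomial test.

The signed *true effect* of a variant is defined on the ref-over-alt scale:
``sign(log pwm[col, ref] − log pwm[col, alt])`` — positive when the
alternative allele weakens the motif — and its magnitude is the absolute
log-probability difference (natural log).  With that convention the expected
allelic imbalance ``log(R_ref/R_alt)`` and the model's signed prediction
``log(A_ref/A_alt)`` share the truth's sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binomtest, false_discovery_control

__all__ = [
    "MotifModel",
    "SyntheticGenomeSpec",
    "TaskSpec",
    "Placement",
    "VariantTruth",
    "SyntheticTruth",
    "generate_genome",
    "generate_task_peaks",
    "generate_variants",
    "generate_asc_counts",
    "random_motif",
    "write_fasta",
    "write_bed",
]

BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
EDGE_MARGIN = 500  # bp kept clear of chromosome ends for peaks and variants


@dataclass(frozen=True)
class MotifModel:
    """A named position weight matrix (width × 4, rows sum to 1)."""

    name: str
    pwm: np.ndarray

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=float)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[1] != 4 or pwm.shape[0] < 4:
            raise ValueError("pwm must have shape (width >= 4, 4)")
        if (pwm < 0).any() or (pwm > 1).any():
            raise ValueError("pwm entries must lie in [0, 1]")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chromosomes: tuple[tuple[str, int], ...]
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        for name, length in self.chromosomes:
            if length < 2000:
                raise ValueError(f"chromosome {name}: length {length} < 2000")
        if not np.isclose(sum(self.background), 1.0):
            raise ValueError("background frequencies must sum to 1")


@dataclass(frozen=True)
class TaskSpec:
    name: str
    motif_names: tuple[str, ...]
    n_peaks: int
    peak_length: int
    stage: str = "F"

    def __post_init__(self):
        object.__setattr__(self, "motif_names", tuple(self.motif_names))
        if not self.motif_names:
            raise ValueError(f"task {self.name}: motif subset is empty")
        if self.n_peaks < 1:
            raise ValueError(f"task {self.name}: peak count must be >= 1")
        if self.stage not in ("F", "A"):
            raise ValueError("stage must be 'F' or 'A'")


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int
    motif_name: str
    strand: str
    task_names: tuple[str, ...]


@dataclass(frozen=True)
class VariantTruth:
    variant_id: str
    is_functional: bool
    effect_sign: int
    effect_magnitude: float


@dataclass
class SyntheticTruth:
    placements: list[Placement] = field(default_factory=list)
    variants: list[VariantTruth] = field(default_factory=list)


def generate_genome(spec: SyntheticGenomeSpec) -> dict[str, np.ndarray]:
    """Chromosome name → base-index array (0=A,1=C,2=G,3=T), i.i.d. background."""
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.background, dtype=float)
    return {name: rng.choice(4, size=length, p=p)
            for name, length in spec.chromosomes}


def genome_to_strings(genome: dict[str, np.ndarray]) -> dict[str, str]:
    return {name: "".join(BASES[seq]) for name, seq in genome.items()}


def random_motif(name: str, width: int, rng: np.random.Generator,
                 dominance: float = 0.97) -> MotifModel:
    """A sharp random PWM: one dominant base per column at probability
    ``dominance``, the rest spread evenly (a strong, information-rich motif)."""
    if width < 4:
        raise ValueError("motif width must be >= 4")
    if not 0.25 < dominance < 1.0:
        raise ValueError("dominance must be in (0.25, 1)")
    pwm = np.full((width, 4), (1.0 - dominance) / 3.0)
    dominant = rng.integers(0, 4, size=width)
    pwm[np.arange(width), dominant] = dominance
    return MotifModel(name, pwm)


def _sample_nonoverlapping(rng: np.random.Generator, low: int, high: int,
                           length: int, n: int, max_tries: int = 10000) -> list[int]:
    """Greedy rejection sampling of n non-overlapping starts in [low, high)."""
    taken: list[int] = []
    tries = 0
    while len(taken) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping intervals")
        s = int(rng.integers(low, high - length + 1))
        if all(s + length <= t or t + length <= s for t in taken):
            taken.append(s)
    return taken


def generate_task_peaks(
    genome: dict[str, np.ndarray],
    tasks: list[TaskSpec],
    motifs: dict[str, MotifModel],
    rng: np.random.Generator,
    motifs_per_peak: int | tuple[int, int] = 1,
    both_strands: bool = False,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Implant motif instances into the genome and return per-task peak sets.

    Peaks are sampled without overlap across all tasks (so each genomic
    region belongs to one task's peak file), kept ``EDGE_MARGIN`` bp clear of
    chromosome ends; each peak receives ``motifs_per_peak`` sampled instances
    (an int, or an inclusive ``(low, high)`` range drawn per peak) of motifs
    from the task's subset, written into the genome in place.  Returns
    ``{task name: DataFrame(chrom, start, end, name)}`` and the truth.
    """
    for task in tasks:
        for m in task.motif_names:
            if m not in motifs:
                raise ValueError(f"task {task.name}: unknown motif {m!r}")
            if task.peak_length < motifs[m].width:
                raise ValueError(f"task {task.name}: peak length < motif width")
    chrom_names = list(genome)
    lengths = {c: len(genome[c]) for c in chrom_names}
    # chromosomes are chosen proportionally to their placeable length
    weights = np.array([max(lengths[c] - 2 * EDGE_MARGIN, 0) for c in chrom_names],
                       dtype=float)
    if weights.sum() <= 0:
        raise RuntimeError("no chromosome has room for peaks")
    weights /= weights.sum()
    truth = SyntheticTruth()
    peak_tables: dict[str, pd.DataFrame] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    for task in tasks:
        rows = []
        for i in range(task.n_peaks):
            placed = False
            for _ in range(10000):
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
                lo, hi = EDGE_MARGIN, lengths[chrom] - EDGE_MARGIN - task.peak_length
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + task.peak_length
                if all(end <= s or e <= start for s, e in occupied[chrom]):
                    occupied[chrom].append((start, end))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"task {task.name}: could not fit peak {i} inside the genome "
                    f"with a {EDGE_MARGIN} bp margin"
                )
            rows.append((chrom, start, end, f"{task.name}_peak{i}"))
            if isinstance(motifs_per_peak, tuple):
                n_implants = int(rng.integers(motifs_per_peak[0],
                                              motifs_per_peak[1] + 1))
            else:
                n_implants = motifs_per_peak
            for _ in range(n_implants):
                motif = motifs[task.motif_names[int(rng.integers(len(task.motif_names)))]]
                pos = start + int(rng.integers(0, task.peak_length - motif.width + 1))
                strand = "+"
                pwm = motif.pwm
                if both_strands and rng.random() < 0.5:
                    strand = "-"
                    pwm = pwm[::-1, ::-1]
                sampled = np.array([rng.choice(4, p=col) for col in pwm])
                genome[chrom][pos : pos + motif.width] = sampled
                truth.placements.append(
                    Placement(chrom, pos, motif.name, strand, (task.name,))
                )
        peak_tables[task.name] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return peak_tables, truth


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def generate_variants(
    genome: dict[str, np.ndarray],
    truth: SyntheticTruth,
    motifs: dict[str, MotifModel],
    peak_tables: dict[str, pd.DataFrame],
    n_functional: int,
    n_neutral: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Functional (motif-disrupting) and neutral (peak-background) SNVs.

    Functional variants hit the highest-information column of a sampled
    placement, substituting the genome base there with the column's
    least-probable base (that differs from the reference).  Neutral variants
    fall inside peaks but outside every placement.  All variants sit at
    least ``EDGE_MARGIN`` bp from chromosome ends.  Truth records are
    appended to ``truth.variants``; the returned table has columns
    (chrom, pos0, ref, alt, id).
    """
    forward = [p for p in truth.placements if p.strand == "+"]
    if n_functional > len(forward):
        raise RuntimeError(
            f"need {n_functional} functional variants but only "
            f"{len(forward)} forward-strand motif placements exist"
        )
    rows = []
    chosen = rng.choice(len(forward), size=n_functional, replace=False) if n_functional else []
    for k, idx in enumerate(chosen):
        pl = forward[int(idx)]
        pwm = motifs[pl.motif_name].pwm
        info = np.sum(pwm * np.log2(np.clip(pwm, 1e-12, 1)), axis=1) + 2.0
        col = int(np.argmax(info))
        pos = pl.start + col
        ref_idx = int(genome[pl.chrom][pos])
        order = np.argsort(pwm[col])          # ascending probability
        alt_idx = int(order[0]) if int(order[0]) != ref_idx else int(order[1])
        logodds = np.log(np.clip(pwm[col], 1e-12, None))
        signed = logodds[ref_idx] - logodds[alt_idx]   # >0: alt weakens the motif
        vid = f"func{k}"
        rows.append((pl.chrom, pos, BASES[ref_idx], BASES[alt_idx], vid))
        truth.variants.append(
            VariantTruth(vid, True, int(np.sign(signed)), float(abs(signed)))
        )

    placement_ivs: dict[str, list[tuple[int, int]]] = {}
    for pl in truth.placements:
        w = motifs[pl.motif_name].width
        placement_ivs.setdefault(pl.chrom, []).append((pl.start, pl.start + w))
    all_peaks = pd.concat(peak_tables.values(), ignore_index=True)
    used = {(r[0], r[1]) for r in rows}
    for k in range(n_neutral):
        for _ in range(10000):
            row = all_peaks.iloc[int(rng.integers(len(all_peaks)))]
            pos = int(rng.integers(row.start, row.end))
            if _in_any(pos, placement_ivs.get(row.chrom, [])) or (row.chrom, pos) in used:
                continue
            if pos < EDGE_MARGIN or pos >= len(genome[row.chrom]) - EDGE_MARGIN:
                continue
            ref_idx = int(genome[row.chrom][pos])
            alt_idx = int(rng.choice([i for i in range(4) if i != ref_idx]))
            vid = f"neut{k}"
            rows.append((row.chrom, pos, BASES[ref_idx], BASES[alt_idx], vid))
            truth.variants.append(VariantTruth(vid, False, 0, 0.0))
            used.add((row.chrom, pos))
            break
        else:
            raise RuntimeError("could not place a neutral variant in peak background")
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt", "id"])


def generate_asc_counts(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    depth: int = 100,
    imbalance_scale: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Binomial allelic read counts whose imbalance tracks the planted effect.

    ``ref_count ~ Binomial(depth, p)`` with
    ``logit(p) = imbalance_scale × effect_magnitude × effect_sign`` for
    functional variants and ``p = 0.5`` for neutral ones.  The significance
    flag comes from a two-sided exact binomial test, Benjamini–Hochberg
    corrected at the given FDR.
    """
    if depth < 10:
        raise ValueError("read depth must be >= 10")
    if not truth.variants:
        return pd.DataFrame(columns=["id", "ref_count", "alt_count", "significant"])
    rows = []
    for v in truth.variants:
        p = expit(imbalance_scale * v.effect_magnitude * v.effect_sign) \
            if v.is_functional else 0.5
        ref = int(rng.binomial(depth, p))
        rows.append((v.variant_id, ref, depth - ref))
    pvals = [binomtest(r, r + a, 0.5).pvalue for _, r, a in rows]
    qvals = false_discovery_control(pvals, method="bh")
    return pd.DataFrame(
        [(vid, r, a, bool(q <= fdr)) for (vid, r, a), q in zip(rows, qvals)],
        columns=["id", "ref_count", "alt_count", "significant"],
    )


def write_fasta(genome: dict[str, np.ndarray], path, width: int = 80) -> None:
    """Uppercase single-record-per-chromosome FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            s = "".join(BASES[seq])
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_bed(table: pd.DataFrame, path) -> None:
    """BED3+name, 0-based half-open."""
    table[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )
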