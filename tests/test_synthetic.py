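"""Synthetic data generator: determinism, planted truth, allelic counts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from seqepi import synthetic as syn


def _toy_setup(seed=0, n_peaks=10, implants=1, width=8):
    rng = np.random.default_rng(seed)
    genome = syn.generate_genome(syn.SyntheticGenomeSpec(
        chromosomes=(("chrA", 20_000), ("chrB", 12_000)), seed=seed))
    motif = syn.random_motif("m0", width, rng)
    task = syn.TaskSpec("t0", ("m0",), n_peaks=n_peaks, peak_length=120)
    peaks, truth = syn.generate_task_peaks(
        genome, [task], {"m0": motif}, rng, motifs_per_peak=implants)
    return genome, motif, task, peaks, truth, rng


class TestGenerateGenome:
    def test_degenerate_background_yields_constant_sequence(self):
        spec = syn.SyntheticGenomeSpec(chromosomes=(("c", 2000),),
                                       background=(1.0, 0.0, 0.0, 0.0))
        genome = syn.generate_genome(spec)
        assert len(genome["c"]) == 2000
        assert (genome["c"] == 0).all()    # all 'A'

    def test_same_seed_reproduces_sequences(self):
        spec = syn.SyntheticGenomeSpec(chromosomes=(("c", 5000),), seed=42)
        g1, g2 = syn.generate_genome(spec), syn.generate_genome(spec)
        assert np.array_equal(g1["c"], g2["c"])

    def test_uniform_background_frequencies_within_binomial_bound(self):
        spec = syn.SyntheticGenomeSpec(chromosomes=(("c", 100_000),), seed=7)
        seq = syn.generate_genome(spec)["c"]
        freqs = np.bincount(seq, minlength=4) / len(seq)
        assert np.all((freqs > 0.24) & (freqs < 0.26))

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="2000"):
            syn.SyntheticGenomeSpec(chromosomes=(("c", 1999),))


class TestGenerateTaskPeaks:
    def test_single_peak_single_motif_placement_inside_peak(self):
        genome, motif, task, peaks, truth, _ = _toy_setup(n_peaks=1)
        assert len(truth.placements) == 1
        pl = truth.placements[0]
        peak = peaks["t0"].iloc[0]
        assert peak.chrom == pl.chrom
        assert peak.start <= pl.start and pl.start + motif.width <= peak.end

    def test_empty_motif_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            syn.TaskSpec("t", (), n_peaks=1, peak_length=100)

    def test_every_placement_inside_a_peak_of_its_task(self):
        genome, motif, task, peaks, truth, _ = _toy_setup(n_peaks=10, implants=2)
        table = peaks["t0"]
        for pl in truth.placements:
            hits = table[(table.chrom == pl.chrom)
                         & (table.start <= pl.start)
                         & (table.end >= pl.start + motif.width)]
            assert len(hits) >= 1

    def test_shared_motif_subsets_give_similar_hit_rates(self):
        """Two tasks with identical subsets share sequence determinants:
        per-bp placement rates inside peaks agree over replicates."""
        rates = {"a": [], "b": []}
        for rep in range(30):
            rng = np.random.default_rng(rep)
            genome = syn.generate_genome(syn.SyntheticGenomeSpec(
                chromosomes=(("c", 40_000),), seed=rep))
            motifs = {"m0": syn.random_motif("m0", 8, rng)}
            tasks = [syn.TaskSpec("a", ("m0",), 8, 120),
                     syn.TaskSpec("b", ("m0",), 8, 120)]
            _, truth = syn.generate_task_peaks(genome, tasks, motifs, rng)
            for t in ("a", "b"):
                n = sum(1 for p in truth.placements if t in p.task_names)
                rates[t].append(n / (8 * 120))
        assert np.mean(rates["a"]) == pytest.approx(np.mean(rates["b"]), rel=0.05)

    def test_peak_too_small_for_motif_rejected(self):
        genome = syn.generate_genome(syn.SyntheticGenomeSpec(
            chromosomes=(("c", 20_000),), seed=0))
        rng = np.random.default_rng(0)
        motifs = {"m0": syn.random_motif("m0", 16, rng)}
        task = syn.TaskSpec("t", ("m0",), 1, peak_length=10)
        with pytest.raises(ValueError, match="peak length"):
            syn.generate_task_peaks(genome, [task], motifs, rng)


class TestGenerateVariants:
    def test_functional_variants_overlap_placements_by_interval_oracle(self):
        from intervaltree import IntervalTree

        genome, motif, task, peaks, truth, rng = _toy_setup(n_peaks=20)
        table = syn.generate_variants(genome, truth, {"m0": motif}, peaks,
                                      n_functional=15, n_neutral=15, rng=rng)
        trees = {}
        for pl in truth.placements:
            trees.setdefault(pl.chrom, IntervalTree()).addi(
                pl.start, pl.start + motif.width)
        truth_by_id = {v.variant_id: v for v in truth.variants}
        for row in table.itertuples():
            inside = row.chrom in trees and bool(trees[row.chrom][row.pos0])
            assert inside == truth_by_id[row.id].is_functional

    def test_disruption_has_positive_ref_over_alt_sign(self):
        """Substituting toward the least-probable base weakens the motif:
        log-odds(ref) - log-odds(alt) > 0 whenever ref is the likelier base."""
        genome, motif, task, peaks, truth, rng = _toy_setup(n_peaks=20)
        table = syn.generate_variants(genome, truth, {"m0": motif}, peaks,
                                      n_functional=15, n_neutral=0, rng=rng)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        info = np.sum(motif.pwm * np.log2(np.clip(motif.pwm, 1e-12, 1)), axis=1) + 2
        col = int(np.argmax(info))
        for v, row in zip(truth.variants, table.itertuples()):
            p_ref = motif.pwm[col, base_idx[row.ref]]
            p_alt = motif.pwm[col, base_idx[row.alt]]
            assert v.effect_sign == np.sign(np.log(p_ref) - np.log(p_alt))
            if p_ref > p_alt:
                assert v.effect_sign > 0

    def test_zero_functional_gives_all_neutral(self):
        genome, motif, task, peaks, truth, rng = _toy_setup(n_peaks=5)
        syn.generate_variants(genome, truth, {"m0": motif}, peaks,
                              n_functional=0, n_neutral=8, rng=rng)
        assert all(not v.is_functional for v in truth.variants)
        assert all(v.effect_sign == 0 for v in truth.variants)

    def test_ref_allele_matches_genome(self):
        genome, motif, task, peaks, truth, rng = _toy_setup(n_peaks=10)
        table = syn.generate_variants(genome, truth, {"m0": motif}, peaks,
                                      n_functional=5, n_neutral=5, rng=rng)
        for row in table.itertuples():
            assert syn.BASES[genome[row.chrom][row.pos0]] == row.ref

    def test_insufficient_placements_rejected(self):
        genome, motif, task, peaks, truth, rng = _toy_setup(n_peaks=2)
        with pytest.raises(RuntimeError, match="placements"):
            syn.generate_variants(genome, truth, {"m0": motif}, peaks,
                                  n_functional=50, n_neutral=0, rng=rng)


class TestGenerateAscCounts:
    def test_neutral_variant_mean_ref_count_near_half_depth(self):
        truth = syn.SyntheticTruth(variants=[
            syn.VariantTruth(f"v{i}", False, 0, 0.0) for i in range(1000)])
        table = syn.generate_asc_counts(truth, np.random.default_rng(0),
                                        depth=100)
        assert 47 <= table["ref_count"].mean() <= 53

    def test_zero_imbalance_scale_keeps_all_probabilities_half(self):
        truth = syn.SyntheticTruth(variants=[
            syn.VariantTruth(f"v{i}", True, 1, 5.0) for i in range(2000)])
        table = syn.generate_asc_counts(truth, np.random.default_rng(1),
                                        depth=50, imbalance_scale=0.0)
        # mean ref fraction indistinguishable from 0.5
        assert table["ref_count"].mean() / 50 == pytest.approx(0.5, abs=0.01)

    def test_strong_variant_flagged_significant_with_high_power(self):
        p = expit(4.0)                     # strongly imbalanced
        flags = []
        rng = np.random.default_rng(2)
        for _ in range(200):
            truth = syn.SyntheticTruth(variants=[
                syn.VariantTruth("v", True, 1, 4.0)])
            flags.append(bool(
                syn.generate_asc_counts(truth, rng, depth=100,
                                        imbalance_scale=1.0)["significant"][0]))
        assert np.mean(flags) > 0.9

    def test_direction_law_expected_log_ratio_sign(self):
        """E[log(R_ref/R_alt)] carries the true effect sign (500 replicates)."""
        rng = np.random.default_rng(3)
        for sign in (1, -1):
            truth = syn.SyntheticTruth(variants=[
                syn.VariantTruth(f"v{i}", True, sign, 1.5) for i in range(500)])
            t = syn.generate_asc_counts(truth, rng, depth=100)
            ok = (t["ref_count"] > 0) & (t["alt_count"] > 0)
            logratio = np.log(t.loc[ok, "ref_count"] / t.loc[ok, "alt_count"])
            assert np.sign(logratio.mean()) == sign

    def test_low_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            syn.generate_asc_counts(syn.SyntheticTruth(),
                                    np.random.default_rng(0), depth=5)


class TestWriters:
    def test_fasta_and_bed_deterministic_and_wellformed(self, tmp_path):
        genome, motif, task, peaks, truth, rng = _toy_setup()
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        syn.write_fasta(genome, f1)
        syn.write_fasta(genome, f2)
        assert f1.read_bytes() == f2.read_bytes()
        text = f1.read_text()
        assert text.startswith(">chrA\n")
        assert set(text.replace("\n", "").replace(">chrAchrB", "")) <= set("ACGT>chrAB")
        bed = tmp_path / "t0.bed"
        syn.write_bed(peaks["t0"], bed)
        reread = pd.read_csv(bed, sep="\t", header=None,
                             names=["chrom", "start", "end", "name"])
        assert len(reread) == len(peaks["t0"])
        assert (reread["end"] > reread["start"]).all()

    def test_pwm_row_sums_validated(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError, match="sum"):
            syn.MotifModel("bad", bad)
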