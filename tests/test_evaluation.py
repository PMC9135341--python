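"""Validation statistics against enumeration / definitional oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import rankdata

from seqepi.evaluation import (
    COARSE_SCORE_BINS,
    FINE_SCORE_BINS,
    allelic_imbalance_concordance,
    asc_enrichment,
    constraint_comparison,
    maf_by_score_bins,
    select_top_and_control,
)


def _fisher_exact_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x, exact=True)
                * comb(n - col1, row1 - x, exact=True)) / comb(n, row1, exact=True)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestAscEnrichment:
    def _ids(self, n, prefix):
        return [f"{prefix}{i}" for i in range(n)]

    def test_odds_ratio_closed_form(self):
        top = self._ids(100, "t")
        control = self._ids(1000, "c")
        asc = top[:10] + control[:10]
        res = asc_enrichment(top, control, asc)
        assert res.odds_ratio == pytest.approx(11.0)
        assert res.table == ((10, 90), (10, 990))
        assert res.fold_enrichment == pytest.approx((10 / 100) / (10 / 1000))

    def test_equal_proportions_give_unit_fold(self):
        top = self._ids(50, "t")
        control = self._ids(200, "c")
        asc = top[:5] + control[:20]       # 10% in both groups
        res = asc_enrichment(top, control, asc)
        assert res.fold_enrichment == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        (2, 3, 3, 2), (1, 4, 2, 8), (5, 5, 5, 5), (0, 6, 3, 3), (4, 1, 1, 9),
    ])
    def test_fisher_p_matches_hypergeometric_enumeration(self, table):
        a, b, c, d = table
        top = self._ids(a + b, "t")
        control = self._ids(c + d, "c")
        asc = top[:a] + control[:c]
        res = asc_enrichment(top, control, asc)
        assert res.p_value == pytest.approx(
            _fisher_exact_enumeration(a, b, c, d), rel=1e-9)

    def test_overlap_removed_with_warning(self):
        top = self._ids(20, "v")
        control = self._ids(30, "v")       # first 20 overlap
        with pytest.warns(UserWarning, match="removing"):
            res = asc_enrichment(top, control, ["v0"])
        assert res.table[1][0] + res.table[1][1] == 10

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            asc_enrichment(["a"], ["a"], [])


class TestAllelicImbalanceConcordance:
    def _frames(self, ref, alt, signed):
        asc = pd.DataFrame({"id": [f"v{i}" for i in range(len(ref))],
                            "ref_count": ref, "alt_count": alt})
        eff = pd.DataFrame({"id": [f"v{i}" for i in range(len(ref))],
                            "signed": signed})
        return asc, eff

    def test_perfect_agreement_gives_unit_rho_and_full_sign_curve(self):
        ref = [80, 70, 30, 20]
        alt = [20, 30, 70, 80]
        signed = [math.log(r / a) for r, a in zip(ref, alt)]
        rho, curve = allelic_imbalance_concordance(*self._frames(ref, alt, signed))
        assert rho == pytest.approx(1.0)
        assert (curve["sign_agreement"] == 1.0).all()

    def test_perfect_disagreement_gives_negative_rho(self):
        ref = [80, 70, 30, 20]
        alt = [20, 30, 70, 80]
        signed = [-math.log(r / a) for r, a in zip(ref, alt)]
        rho, curve = allelic_imbalance_concordance(*self._frames(ref, alt, signed))
        assert rho == pytest.approx(-1.0)
        assert (curve["sign_agreement"] == 0.0).all()

    def test_rho_matches_rank_then_correlate_oracle(self):
        rng = np.random.default_rng(8)
        ref = rng.integers(1, 100, 20)
        alt = rng.integers(1, 100, 20)
        signed = rng.normal(size=20)
        rho, _ = allelic_imbalance_concordance(*self._frames(ref, alt, signed))
        obs = np.log(ref / alt)
        r1, r2 = rankdata(obs), rankdata(signed)
        oracle = np.corrcoef(r1, r2)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_rho_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        ref = rng.integers(1, 100, 15)
        alt = rng.integers(1, 100, 15)
        signed = rng.normal(size=15)
        rho1, _ = allelic_imbalance_concordance(*self._frames(ref, alt, signed))
        rho2, _ = allelic_imbalance_concordance(
            *self._frames(ref, alt, np.exp(signed)))
        assert rho1 == pytest.approx(rho2, rel=1e-12)

    def test_zero_counts_excluded_with_warning(self):
        asc, eff = self._frames([10, 0, 5], [5, 10, 0], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            rho, curve = allelic_imbalance_concordance(asc, eff)
        assert np.isnan(rho)               # only 1 usable record


class TestConstraintComparison:
    def _annotations(self, ids, scores):
        return pd.DataFrame({"id": ids, "constraint": scores})

    def test_identical_groups_give_null_p(self):
        ids = [f"v{i}" for i in range(40)]
        scores = list(range(20)) * 2
        res = constraint_comparison(ids[:20], ids[20:],
                                    self._annotations(ids, scores))
        assert res["p_value"] > 0.9

    def test_shifted_group_detected_at_n_200_vs_permutation_oracle(self):
        rng = np.random.default_rng(11)
        top_scores = rng.normal(10, 1, 200)
        ctrl_scores = rng.normal(0, 1, 200)
        ids = [f"t{i}" for i in range(200)] + [f"c{i}" for i in range(200)]
        ann = self._annotations(ids, np.concatenate([top_scores, ctrl_scores]))
        res = constraint_comparison(ids[:200], ids[200:], ann)
        assert res["p_value"] < 0.01
        assert res["median_top"] > res["median_control"]

    def test_tiny_groups_match_exhaustive_rank_enumeration(self):
        """3 vs 3 exact p equals enumeration over all rank assignments."""
        top, ctrl = [9.0, 7.0, 5.0], [6.0, 2.0, 1.0]
        ids = ["a", "b", "c", "d", "e", "f"]
        ann = self._annotations(ids, top + ctrl)
        res = constraint_comparison(ids[:3], ids[3:], ann)
        # enumerate U statistics over all C(6,3) label assignments
        pooled = top + ctrl
        u_obs = sum(1 for x in top for y in ctrl if x > y)
        us = []
        for comb_ids in itertools.combinations(range(6), 3):
            grp = [pooled[i] for i in comb_ids]
            rest = [pooled[i] for i in range(6) if i not in comb_ids]
            us.append(sum(1 for x in grp for y in rest if x > y))
        n_extreme = sum(1 for u in us
                        if abs(u - 4.5) >= abs(u_obs - 4.5) - 1e-12)
        assert res["p_value"] == pytest.approx(n_extreme / len(us), rel=1e-9)

    def test_all_unannotated_rejected(self):
        ann = self._annotations(["x"], [1.0])
        with pytest.raises(ValueError):
            constraint_comparison(["a"], ["b"], ann)


class TestMafByScoreBins:
    def test_all_zero_scores_fall_in_first_bin(self):
        scores = pd.DataFrame({"id": ["a", "b"], "score": [0.0, 0.0]})
        ann = pd.DataFrame({"id": ["a", "b"], "maf": [0.1, 0.3]})
        out = maf_by_score_bins(scores, ann, COARSE_SCORE_BINS)
        assert out.iloc[0]["n"] == 2
        assert out["n"].sum() == 2

    def test_boundary_score_lands_in_right_open_bins(self):
        scores = pd.DataFrame({"id": ["a", "b"], "score": [0.04, 0.06]})
        ann = pd.DataFrame({"id": ["a", "b"], "maf": [0.1, 0.2]})
        out = maf_by_score_bins(scores, ann, COARSE_SCORE_BINS)
        assert out.iloc[0]["n"] == 1 and out.iloc[1]["n"] == 1

    def test_means_match_group_by_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        n = 100
        ids = [f"v{i}" for i in range(n)]
        s = rng.random(n)
        maf = rng.random(n) * 0.5
        scores = pd.DataFrame({"id": ids, "score": s})
        ann = pd.DataFrame({"id": ids, "maf": maf})
        for edges in (COARSE_SCORE_BINS, FINE_SCORE_BINS):
            out = maf_by_score_bins(scores, ann, edges)
            e = np.asarray(edges)
            assign = np.clip(np.searchsorted(e[1:-1], s, side="right"), 0,
                             len(e) - 2)
            for b in range(len(e) - 1):
                grp = maf[assign == b]
                if len(grp):
                    assert out.iloc[b]["mean_maf"] == pytest.approx(grp.mean())
                    assert out.iloc[b]["n"] == len(grp)

    def test_score_outside_unit_interval_rejected(self):
        scores = pd.DataFrame({"id": ["a"], "score": [1.2]})
        ann = pd.DataFrame({"id": ["a"], "maf": [0.1]})
        with pytest.raises(ValueError, match="0, 1"):
            maf_by_score_bins(scores, ann)


class TestSelectTopAndControl:
    def _effects(self, n, rng, n_in_peak=None):
        # first n_in_peak variants inside the peak [0, 6000), rest outside
        n_in = n if n_in_peak is None else n_in_peak
        pos = np.concatenate([
            rng.choice(6_000, size=n_in, replace=False),
            rng.choice(np.arange(6_000, 10_000), size=n - n_in, replace=False),
        ])
        return pd.DataFrame({
            "id": [f"v{i}" for i in range(n)],
            "chrom": "chr1",
            "pos0": pos,
            "abs_diff.f": rng.random(n),
        })

    def _peaks(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [6000],
                             "name": ["p"]})

    def test_sizes_and_in_peak_membership(self, rng):
        eff = self._effects(50, rng, n_in_peak=35)
        top, control = select_top_and_control(eff, "f", self._peaks(),
                                              top_n=10, control_n=20, seed=0)
        assert len(top) == 10 and len(control) == 20
        pos = eff.set_index("id")["pos0"]
        for vid in top + control:
            assert 0 <= pos[vid] < 6000     # interval-membership oracle
        assert not set(top) & set(control)

    def test_same_seed_reproduces_control_sample(self, rng):
        eff = self._effects(60, rng)
        _, c1 = select_top_and_control(eff, "f", self._peaks(), 5, 20, seed=3)
        _, c2 = select_top_and_control(eff, "f", self._peaks(), 5, 20, seed=3)
        assert c1 == c2

    def test_truncation_warns(self, rng):
        eff = self._effects(20, rng, n_in_peak=20)
        with pytest.warns(UserWarning, match="truncated"):
            top, control = select_top_and_control(eff, "f", self._peaks(),
                                                  top_n=10, control_n=1000,
                                                  seed=0)
        assert len(control) <= 10
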