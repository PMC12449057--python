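"""Paired comparison statistics: pairing, Wilcoxon, Cohen's d, influence."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from fibos.compare import (
    compare_structures,
    flag_influential,
    pair_residues,
    paired_stats,
    sd_influence,
    wilcoxon_signed_rank_p,
)
from fibos.metrics import ResiduePacking


def rows(osps, names=None, start=1):
    names = names or ["ALA"] * len(osps)
    return [ResiduePacking("A", start + i, "", nm, 1, 1.0, 1.0, float(v))
            for i, (v, nm) in enumerate(zip(osps, names))]


def exhaustive_signflip_p(diffs):
    """Independent oracle: enumerate all 2^n equiprobable sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [ranks[np.array(signs, bool)].sum()
            for signs in itertools.product([0, 1], repeat=n)]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs + 1e-12)
    p_ge = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairing:
    def test_identical_lists_pair_completely(self):
        res = pair_residues(rows([0.1, 0.2, 0.3]), rows([0.1, 0.2, 0.3]))
        assert len(res.pairs) == 3
        assert all(p.diff == 0 for p in res.pairs)
        assert res.unmatched_a == res.unmatched_b == []

    def test_missing_residue_is_reported(self):
        a = rows([0.1, 0.2, 0.3])
        b = [a[0], a[2]]
        b = rows([0.1, 0.3])
        b[1] = ResiduePacking("A", 3, "", "ALA", 1, 1.0, 1.0, 0.3)
        res = pair_residues(a, b)
        assert len(res.pairs) == 2
        assert res.unmatched_a == [("A", 2, "", "ALA")]

    def test_name_mismatch_excluded_and_reported(self):
        a = rows([0.1, 0.2], names=["ALA", "GLY"])
        b = rows([0.1, 0.2], names=["ALA", "SER"])
        res = pair_residues(a, b)
        assert len(res.pairs) == 1
        assert res.unmatched_a == [("A", 2, "", "GLY")]
        assert res.unmatched_b == [("A", 2, "", "SER")]

    def test_zero_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            pair_residues(rows([0.1]), rows([0.1], start=9))

    def test_pairs_ordered_by_sequence(self):
        a = rows([0.1, 0.2, 0.3])
        res = pair_residues(list(reversed(a)), a)
        assert [p.res_seq for p in res.pairs] == [1, 2, 3]


class TestWilcoxon:
    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(st.integers(0, 10**9), st.integers(2, 10))
    def test_exact_p_matches_signflip_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(size=n), 2)  # rounding forces occasional ties
        if rng.random() < 0.3:
            d[rng.integers(0, n)] = 0.0
        assert wilcoxon_signed_rank_p(d) == pytest.approx(
            exhaustive_signflip_p(d), abs=1e-12
        )

    def test_six_positive_diffs(self):
        # W+ hits its maximum; two-sided p = 2/2^6
        assert wilcoxon_signed_rank_p(np.arange(1.0, 7.0)) == pytest.approx(0.03125)

    def test_all_zero_diffs_convention(self):
        assert wilcoxon_signed_rank_p(np.zeros(5)) == 1.0

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1.0, size=60)
        ours = wilcoxon_signed_rank_p(d)
        ref = scipy.stats.wilcoxon(d, correction=False, method="approx").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)


class TestPairedStats:
    def test_cohens_d_hand_computed(self):
        pairs = pair_residues(rows([0.0] * 4), rows([1, 2, 3, 4])).pairs
        _, d = paired_stats(pairs)
        assert d == pytest.approx(2.5 / np.std([1, 2, 3, 4], ddof=1))
        assert d == pytest.approx(1.9364916731)

    def test_identity_convention(self):
        pairs = pair_residues(rows([0.1, 0.2, 0.3]), rows([0.1, 0.2, 0.3])).pairs
        assert paired_stats(pairs) == (1.0, 0.0)

    def test_swapping_sides_negates_d_keeps_p(self):
        rng = np.random.default_rng(2)
        a = rows(rng.uniform(0.1, 0.5, 12))
        b = rows(rng.uniform(0.1, 0.5, 12))
        p_ab, d_ab = paired_stats(pair_residues(a, b).pairs)
        p_ba, d_ba = paired_stats(pair_residues(b, a).pairs)
        assert p_ab == pytest.approx(p_ba)
        assert d_ab == pytest.approx(-d_ba)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            paired_stats(pair_residues(rows([0.1]), rows([0.2])).pairs)


class TestInfluence:
    def test_identical_sides_give_zero_scores(self):
        pairs = pair_residues(rows([0.1, 0.4, 0.3]), rows([0.1, 0.4, 0.3])).pairs
        assert np.allclose(sd_influence(pairs), 0.0)

    def test_single_outlier_has_maximum_score(self):
        a = rows([0.3] * 10)
        b = rows([0.3] * 9 + [0.9])
        scores = sd_influence(pair_residues(a, b).pairs)
        assert np.argmax(scores) == 9

    def test_scores_nondegenerate_when_sd_gap_nonzero(self):
        rng = np.random.default_rng(1)
        a = rows(rng.uniform(0.1, 0.3, 8))
        b = rows(rng.uniform(0.1, 0.5, 8))
        pairs = pair_residues(a, b).pairs
        osp_a = np.array([p.osp_a for p in pairs])
        osp_b = np.array([p.osp_b for p in pairs])
        assert osp_b.std(ddof=1) != osp_a.std(ddof=1)
        assert np.abs(sd_influence(pairs)).sum() > 0

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            sd_influence(pair_residues(rows([0.1, 0.2]), rows([0.3, 0.1])).pairs)

    def test_analytic_mode_ranks_like_jackknife(self):
        rng = np.random.default_rng(9)
        a = rows(rng.uniform(0.1, 0.4, 15))
        b = rows(rng.uniform(0.1, 0.4, 15))
        pairs = pair_residues(a, b).pairs
        jk = sd_influence(pairs, mode="jackknife")
        an = sd_influence(pairs, mode="analytic")
        # same residue ordering at the top; scales differ by design
        assert np.argmax(jk) == np.argmax(an)
        assert scipy.stats.spearmanr(jk, an).statistic > 0.9

    def test_removing_flagged_residues_shrinks_sd_gap(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.15, 0.35, 30)
        shifted = base.copy()
        shifted[7] = 0.9
        pairs = pair_residues(rows(base), rows(shifted)).pairs
        scores = sd_influence(pairs)
        flagged = flag_influential(scores)
        assert flagged.any()
        keep = [p for p, f in zip(pairs, flagged) if not f]
        gap = lambda ps: (np.std([p.osp_b for p in ps], ddof=1)
                          - np.std([p.osp_a for p in ps], ddof=1))
        assert abs(gap(keep)) <= abs(gap(pairs))


class TestFlagging:
    def test_equal_scores_flag_nothing(self):
        assert not flag_influential(np.full(20, 0.37)).any()

    def test_single_extreme_among_nulls(self):
        scores = np.zeros(51)
        scores[17] = 1.0
        flags = flag_influential(scores)
        assert flags[17] and flags.sum() == 1

    def test_threshold_monotone_in_k(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=100)
        counts = [flag_influential(scores, mad_k=k).sum() for k in (1, 3, 10, 1e9)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            flag_influential(np.array([0.1, np.inf, 0.2]))


class TestCompareStructures:
    def test_report_symmetry(self):
        rng = np.random.default_rng(12)
        a = rows(rng.uniform(0.2, 0.6, 9))
        b = rows(rng.uniform(0.2, 0.7, 9))
        fwd = compare_structures(a, b)
        rev = compare_structures(b, a)
        assert fwd.cohens_d == pytest.approx(-rev.cohens_d)
        assert fwd.sd_gap == pytest.approx(-rev.sd_gap)
        assert fwd.wilcoxon_p == pytest.approx(rev.wilcoxon_p)

    def test_report_dict_is_json_ready(self):
        import json

        a = rows([0.1, 0.2, 0.3, 0.4])
        b = rows([0.1, 0.25, 0.28, 0.4])
        report = compare_structures(a, b, id_a="exp", id_b="model")
        payload = json.loads(json.dumps(report.to_dict()))
        assert payload["n_pairs"] == 4
        assert payload["id_a"] == "exp"
        assert 0 < payload["wilcoxon_p"] <= 1
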