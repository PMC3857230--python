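import itertools
import math

import numpy as np
import pytest
from scipy import stats

from chromnet.features import (
    bh_fdr,
    enrichment_table,
    fisher_enrichment,
    label_by_overlap,
    log2_ratio,
    mean_signal,
)
from chromnet.io import FeatureTrack, Fragment, FragmentSet, SignalTrack


@pytest.fixture
def one_fragment():
    return FragmentSet([Fragment("f1", "chrI", 100, 200)])


class TestLabelByOverlap:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((150, 160), True),    # contained
            ((200, 210), False),   # half-open adjacency: no shared base
            ((199, 205), True),    # 1 bp overlap satisfies non-zero criterion
            ((50, 100), False),    # ends exactly where the fragment starts
        ],
    )
    def test_non_zero_overlap_criterion(self, one_fragment, interval, expected):
        track = FeatureTrack("t", [("chrI", *interval)])
        assert label_by_overlap(one_fragment, track)["f1"] is expected

    def test_tss_containment_mode(self, one_fragment):
        inside = FeatureTrack("genes", [("chrI", 150, 400)])
        assert label_by_overlap(one_fragment, inside, mode="tss")["f1"] is True
        upstream = FeatureTrack("genes", [("chrI", 50, 400)])
        assert label_by_overlap(one_fragment, upstream, mode="tss")["f1"] is False

    def test_unknown_chromosome_intervals_skipped(self, one_fragment):
        track = FeatureTrack("t", [("chrX", 150, 160)])
        assert label_by_overlap(one_fragment, track)["f1"] is False

    def test_idempotent_and_order_invariant(self, one_fragment):
        ivs = [("chrI", 10, 20), ("chrI", 150, 160), ("chrI", 300, 400)]
        a = label_by_overlap(one_fragment, FeatureTrack("t", ivs))
        b = label_by_overlap(one_fragment, FeatureTrack("t", ivs[::-1]))
        assert a == b == label_by_overlap(one_fragment, FeatureTrack("t", ivs))


class TestMeanSignal:
    def test_unweighted_mean_of_overlapping_values(self, one_fragment):
        track = SignalTrack("s", [("chrI", 90, 150, 30.0), ("chrI", 150, 250, 50.0)])
        assert mean_signal(one_fragment, track)["f1"] == pytest.approx(40.0)

    def test_no_overlap_is_missing(self, one_fragment):
        track = SignalTrack("s", [("chrI", 500, 600, 30.0)])
        assert math.isnan(mean_signal(one_fragment, track)["f1"])

    def test_spanning_interval_contributes_to_both_fragments(self):
        frags = FragmentSet(
            [Fragment("f1", "chrI", 0, 100), Fragment("f2", "chrI", 100, 200)]
        )
        track = SignalTrack("s", [("chrI", 50, 150, 7.0)])
        values = mean_signal(frags, track)
        assert values["f1"] == 7.0 and values["f2"] == 7.0


class TestLog2Ratio:
    def test_fourfold_enrichment(self):
        out = log2_ratio({"f": 8.0}, {"f": 2.0}, pseudocount=0.0, libsize_normalize=False)
        assert out["f"] == pytest.approx(2.0)

    def test_identical_libraries_give_zero(self):
        chip = {f"f{i}": float(i + 1) for i in range(5)}
        out = log2_ratio(chip, dict(chip), pseudocount=0.0)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_zero_chip_with_pseudocount(self):
        out = log2_ratio({"f": 0.0}, {"f": 4.0}, pseudocount=0.5, libsize_normalize=False)
        assert out["f"] == pytest.approx(math.log2(0.5 / 4.5))

    def test_library_size_normalization(self):
        # chip library twice as deep; equal relative coverage -> ratio 0
        chip = {"f1": 20.0, "f2": 20.0}
        control = {"f1": 10.0, "f2": 10.0}
        out = log2_ratio(chip, control, pseudocount=0.0, libsize_normalize=True)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_empty_libraries_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio({"f": 0.0}, {"f": 0.0})


def exact_two_tailed_fisher(a, b, c, d):
    """Enumeration oracle: sum hypergeometric probabilities of all tables
    with the observed margins whose probability <= the observed table's."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    observed = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= observed * (1 + 1e-7)))


class TestFisher:
    def _result(self, a, b, c, d):
        labels, membership = {}, {}
        counts = {(True, True): a, (True, False): b, (False, True): c, (False, False): d}
        i = 0
        for (in_com, has), k in counts.items():
            for _ in range(k):
                labels[f"n{i}"] = has
                membership[f"n{i}"] = in_com
                i += 1
        return fisher_enrichment(labels, membership)

    def test_balanced_table_is_one(self):
        assert self._result(5, 5, 5, 5).p == pytest.approx(1.0)

    def test_perfect_association(self):
        result = self._result(10, 0, 0, 10)
        assert result.p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_row_swap_symmetry(self):
        assert self._result(3, 7, 8, 2).p == pytest.approx(self._result(8, 2, 3, 7).p)

    def test_zero_margin_flagged(self):
        result = self._result(0, 0, 6, 4)
        assert result.p == 1.0 and result.degenerate

    def test_counts_and_odds_ratio(self):
        result = self._result(4, 2, 1, 8)
        assert result.counts == (4, 2, 1, 8)
        assert result.odds_ratio == pytest.approx(16.0)

    @pytest.mark.parametrize("total", [12, 20])
    def test_matches_enumeration_oracle(self, total):
        for a, b, c in itertools.product(range(total + 1), repeat=3):
            d = total - a - b - c
            if d < 0 or min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert self._result(a, b, c, d).p == pytest.approx(
                exact_two_tailed_fisher(a, b, c, d), abs=1e-9
            ), (a, b, c, d)


class TestBH:
    def test_step_up_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_bounds_and_monotonicity(self):
        ps = [0.9, 0.001, 0.2, 0.04, 0.04, 0.5]
        qs = bh_fdr(ps)
        assert all(p <= q <= 1 for p, q in zip(ps, qs))
        order = np.argsort(ps)
        assert all(
            qs[order[i]] <= qs[order[i + 1]] + 1e-12 for i in range(len(ps) - 1)
        )

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def test_enrichment_table_corrects_factor_family_only():
    rng = np.random.default_rng(0)
    frag_ids = [f"n{i}" for i in range(60)]
    membership = {"c0": {f: i < 20 for i, f in enumerate(frag_ids)}}
    feature_labels = {
        "centromeres": {f: i % 5 == 0 for i, f in enumerate(frag_ids)},
        "factor_a": {f: bool(rng.integers(2)) for f in frag_ids},
        "factor_b": {f: bool(rng.integers(2)) for f in frag_ids},
    }
    results = enrichment_table(
        membership, feature_labels, fdr_families=["factor_a", "factor_b"]
    )
    by_name = {r.feature: r for r in results}
    assert by_name["centromeres"].fdr is None
    assert by_name["factor_a"].fdr is not None and by_name["factor_a"].fdr >= by_name["factor_a"].p
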