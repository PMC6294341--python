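"""Two-stage consensus aggregation: hand counts, thresholds, oracle parity."""

import numpy as np
import pandas as pd
import pytest

from synergyseq import (
    ConsensusSignature,
    aggregate_cell_line,
    build_tcs,
    consensus_signatures,
    filter_low_support,
    filter_time,
    high_confidence,
)
from synergyseq.consensus import CellLineAggregate

from conftest import make_profiles, sample_meta


def agg_from_dirs(compound, line, dirs):
    return CellLineAggregate(
        compound_id=compound,
        cell_line=line,
        direction=pd.Series(dirs, index=[f"G{i:04d}" for i in range(len(dirs))]),
        n_samples=3,
    )


class TestFilterTime:
    def test_mixed_times_keeps_only_24h(self):
        meta = sample_meta(n=2, time_h=24.0) + sample_meta(n=2, time_h=6.0, start=2)
        pps = make_profiles(np.zeros((3, 4)), meta)
        out = filter_time(pps, 24.0)
        assert out.n_samples == 2
        assert (out.samples["time_h"] == 24.0).all()

    def test_all_matching_is_identity(self):
        pps = make_profiles(np.ones((2, 3)), sample_meta(n=3))
        out = filter_time(pps, 24.0)
        pd.testing.assert_frame_equal(out.z, pps.z)

    def test_none_matching_warns_not_raises(self):
        pps = make_profiles(np.ones((2, 2)), sample_meta(n=2, time_h=6.0))
        with pytest.warns(UserWarning, match="empty"):
            out = filter_time(pps, 24.0)
        assert out.n_samples == 0


class TestAggregateCellLine:
    def test_hand_count_two_of_five_up(self):
        # gene A: z = (1.5, 1.2, 0.1, -0.3, 0.2): 2/5 = 40% > 20% up
        z = np.array([[1.5, 1.2, 0.1, -0.3, 0.2]])
        agg = aggregate_cell_line(make_profiles(z, sample_meta(n=5)))
        assert agg.direction.iloc[0] == 1
        assert agg.n_samples == 5

    def test_all_subthreshold_gives_zero(self):
        z = np.full((4, 5), 0.5)
        agg = aggregate_cell_line(make_profiles(z, sample_meta(n=5)))
        assert (agg.direction == 0).all()

    def test_exactly_twenty_percent_excluded(self):
        # 1/5 = 20% is NOT > 20%
        z = np.array([[1.5, 0.0, 0.0, 0.0, 0.0]])
        agg = aggregate_cell_line(make_profiles(z, sample_meta(n=5)))
        assert agg.direction.iloc[0] == 0

    def test_tie_between_directions_is_zero(self):
        z = np.array([[2.0, 2.0, -2.0, -2.0, 0.0]])
        agg = aggregate_cell_line(make_profiles(z, sample_meta(n=5)))
        assert agg.direction.iloc[0] == 0

    def test_mixed_groups_rejected(self):
        meta = sample_meta(compound="a", n=1) + sample_meta(compound="b", n=1, start=1)
        with pytest.raises(ValueError, match="one \\(compound, cell_line\\)"):
            aggregate_cell_line(make_profiles(np.zeros((2, 2)), meta))


class TestBuildTcs:
    def test_four_lines_up_scores_plus_four(self):
        aggs = [agg_from_dirs("c", f"L{i}", [1]) for i in range(4)]
        aggs += [agg_from_dirs("c", f"L{i + 4}", [0]) for i in range(2)]
        tcs = build_tcs(aggs)
        assert tcs.score.iloc[0] == 4
        assert tcs.n_cell_lines == 6

    def test_one_of_six_lines_fails_thirty_percent(self):
        aggs = [agg_from_dirs("c", "L0", [1])] + [
            agg_from_dirs("c", f"L{i + 1}", [0]) for i in range(5)
        ]
        assert build_tcs(aggs).score.iloc[0] == 0

    def test_exactly_thirty_percent_excluded(self):
        # 3/10 = 30% is NOT > 30%
        aggs = [agg_from_dirs("c", f"L{i}", [1 if i < 3 else 0]) for i in range(10)]
        assert build_tcs(aggs).score.iloc[0] == 0

    def test_single_line_passes_through(self):
        agg = agg_from_dirs("c", "L0", [1, 0, -1])
        tcs = build_tcs([agg])
        assert list(tcs.score) == [1, 0, -1]

    def test_duplicate_cell_lines_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_tcs([agg_from_dirs("c", "L0", [1]), agg_from_dirs("c", "L0", [1])])

    def test_opposing_lines_cancel_in_signed_count(self):
        aggs = [agg_from_dirs("c", f"L{i}", [1]) for i in range(4)]
        aggs += [agg_from_dirs("c", f"L{i + 4}", [-1]) for i in range(2)]
        assert build_tcs(aggs).score.iloc[0] == 2  # 4 up - 2 down, 4/6 > 30%


class TestHighConfidence:
    def test_half_of_six_keeps_abs_score_three(self):
        score = pd.Series([3, -3, 2, -2], index=list("abcd"))
        tcs = ConsensusSignature(compound_id="c", score=score, n_cell_lines=6)
        sig = high_confidence(tcs, 0.5)
        assert list(sig.values) == [1, -1, 0, 0]

    def test_full_score_all_survive(self):
        score = pd.Series([6, -6, 6], index=list("abc"))
        tcs = ConsensusSignature(compound_id="c", score=score, n_cell_lines=6)
        assert high_confidence(tcs).support == 3

    def test_support_never_grows(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            score = pd.Series(rng.integers(-4, 5, 15), index=range(15))
            tcs = ConsensusSignature(compound_id="c", score=score, n_cell_lines=4)
            assert high_confidence(tcs).support <= tcs.support


class TestFilterLowSupport:
    def make_tcs(self, compound, support, G=200):
        score = pd.Series(0, index=range(G))
        score.iloc[:support] = 1
        return ConsensusSignature(compound_id=compound, score=score, n_cell_lines=6)

    def make_ref(self, support, G=200):
        vals = pd.Series(0, index=range(G))
        vals.iloc[:support] = 1
        from synergyseq import SignedSignature

        return SignedSignature(values=vals, role="reference")

    def test_fifty_percent_rule_keeps_at_or_above(self):
        ref = self.make_ref(84)
        cohort = [self.make_tcs("a", 42), self.make_tcs("b", 41), self.make_tcs("c", 100)]
        kept = filter_low_support(cohort, ref, 0.5)
        assert [t.compound_id for t in kept] == ["a", "c"]

    def test_zero_fraction_is_identity(self):
        ref = self.make_ref(10)
        cohort = [self.make_tcs("a", 1), self.make_tcs("b", 2)]
        assert len(filter_low_support(cohort, ref, 0.0)) == 2

    def test_all_below_warns_empty(self):
        ref = self.make_ref(100)
        with pytest.warns(UserWarning, match="empty"):
            out = filter_low_support([self.make_tcs("a", 3)], ref, 0.5)
        assert out == []

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty support"):
            filter_low_support([self.make_tcs("a", 3)], self.make_ref(0), 0.5)


def naive_tcs(z_by_line: dict, z_threshold=1.0, sample_fraction=0.2, cell_fraction=0.3):
    """Triple-loop reference implementation over {line: G x n array}."""
    lines = list(z_by_line)
    G = next(iter(z_by_line.values())).shape[0]
    dirs = {}
    for line, z in z_by_line.items():
        n = z.shape[1]
        d = np.zeros(G, dtype=int)
        for g in range(G):
            up = sum(1 for s in range(n) if z[g, s] > z_threshold)
            down = sum(1 for s in range(n) if z[g, s] < -z_threshold)
            if up > down and up / n > sample_fraction:
                d[g] = 1
            elif down > up and down / n > sample_fraction:
                d[g] = -1
        dirs[line] = d
    N = len(lines)
    score = np.zeros(G, dtype=int)
    for g in range(G):
        n_up = sum(1 for line in lines if dirs[line][g] == 1)
        n_down = sum(1 for line in lines if dirs[line][g] == -1)
        if max(n_up, n_down) / N > cell_fraction:
            score[g] = n_up - n_down
    return score


class TestOracleAndProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        G = int(rng.integers(5, 21))
        n_lines = int(rng.integers(1, 5))
        z_by_line, meta, blocks = {}, [], []
        for li in range(n_lines):
            n = int(rng.integers(1, 7))
            z_by_line[f"L{li}"] = rng.normal(0, 1.5, (G, n))
            meta += [("c", f"L{li}", 10.0, "uM", 24.0, f"r{li}_{s}") for s in range(n)]
            blocks.append(z_by_line[f"L{li}"])
        pps = make_profiles(np.hstack(blocks), meta)
        tcs = consensus_signatures(pps)["c"]
        np.testing.assert_array_equal(tcs.score.to_numpy(), naive_tcs(z_by_line))

    def test_sample_and_line_order_invariance(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1.5, (12, 18))
        meta = []
        for li in range(3):
            meta += [("c", f"L{li}", 10.0, "uM", 24.0, f"r{li}_{s}") for s in range(6)]
        pps = make_profiles(z, meta)
        ref = consensus_signatures(pps)["c"].score
        perm = rng.permutation(18)
        shuffled = pps.subset_samples(pps.samples.index[perm])
        out = consensus_signatures(shuffled)["c"].score
        pd.testing.assert_series_equal(ref, out)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1.5, (30, 10))
        pps = make_profiles(z, sample_meta(n=10))
        supports = []
        for thr in (0.5, 1.0, 1.5, 2.0):
            agg = aggregate_cell_line(pps, z_threshold=thr)
            supports.append(int((agg.direction != 0).sum()))
        assert supports == sorted(supports, reverse=True)
        supports = []
        for frac in (0.1, 0.2, 0.4, 0.6):
            agg = aggregate_cell_line(pps, sample_fraction=frac)
            supports.append(int((agg.direction != 0).sum()))
        assert supports == sorted(supports, reverse=True)

    def test_score_bounded_by_cell_lines(self):
        rng = np.random.default_rng(8)
        meta = []
        for li in range(4):
            meta += [("c", f"L{li}", 10.0, "uM", 24.0, f"r{li}_{s}") for s in range(3)]
        pps = make_profiles(rng.normal(0, 2, (20, 12)), meta)
        tcs = consensus_signatures(pps)["c"]
        assert tcs.score.abs().max() <= 4
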