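import itertools

import numpy as np
import pandas as pd
import pytest

from tadremodel import (
    PWM,
    border_heatmap,
    cluster_occupancy,
    count_pwm_sites,
    group_signal_test,
    pausing_index,
)
from tadremodel.genome import GenomicInterval
from tadremodel.tad_analysis import Border
from tadremodel.track_analysis import (
    _BASE_INDEX,
    interval_mean,
    reverse_complement,
)


def border(pos, chrom="c"):
    return Border(GenomicInterval(chrom, pos, pos + 100), pos // 100,
                  -1.0, 0.2, 1e-4, "strong")


def track_from_values(values, step=100, chrom="c"):
    starts = np.arange(len(values)) * step
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + step, "value": values})


class TestBorderHeatmap:
    def test_constant_positive_track_all_ones(self):
        track = track_from_values(np.full(200, 3.0))
        mat = border_heatmap(track, [border(10_000)], dialect="chip")
        np.testing.assert_allclose(mat.values, 1.0)

    def test_outlier_clipped_to_q95(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, 200)
        vals[100] = 500.0  # extreme outlier at the border
        track = track_from_values(vals)
        mat = border_heatmap(track, [border(10_000)], dialect="chip")
        assert mat.values.max() == 1.0
        # the outlier column is tied with other clipped values, not dominant
        assert (mat.values == 1.0).sum() >= 2

    def test_nascent_dialect_spans_minus_one_to_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 200)
        track = track_from_values(vals)
        mat = border_heatmap(track, [border(10_000)], dialect="nascent")
        assert mat.values.min() >= -1.0 and mat.values.max() <= 1.0
        assert mat.values.min() < -0.5 and mat.values.max() > 0.5

    def test_chip_and_dnase_bounded_zero_one(self):
        rng = np.random.default_rng(2)
        track = track_from_values(rng.normal(1, 2, 300))
        for dialect in ("chip", "dnase"):
            mat = border_heatmap(track, [border(10_000), border(20_000)],
                                 dialect=dialect)
            assert mat.values.min() >= 0.0 and mat.values.max() <= 1.0

    def test_rows_ordered_by_reference_signal(self):
        vals = np.zeros(400)
        vals[200:250] = 10.0  # strong signal near 22.5 kb only
        ref = track_from_values(vals)
        track = track_from_values(np.ones(400))
        mat = border_heatmap(track, [border(10_000), border(22_000)],
                             reference_track=ref)
        assert mat.borders[0].position.start == 22_000

    def test_empty_track_warns_all_zero(self):
        track = track_from_values(np.zeros(5))
        with pytest.warns(UserWarning, match="empty"):
            mat = border_heatmap(track, [border(50_000)])
        assert (mat.values == 0).all()

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            border_heatmap(track_from_values(np.ones(100)), [border(1000)],
                           dialect="atac")


class TestClusterOccupancy:
    def heatmap_for(self, values):
        track = track_from_values(values)
        return border_heatmap(track, [border(10_000)], dialect="chip")

    def test_all_negative_window_is_no_signal(self):
        mats = {"d1": self.heatmap_for(np.full(250, -2.0)),
                "d2": self.heatmap_for(np.full(250, 5.0))}
        calls = {(c.dataset): c.occupancy_class
                 for c in cluster_occupancy(mats)}
        assert calls["d1"] == "no"

    def test_first_quartile_above_cutoff_is_extra_high(self):
        low = self.heatmap_for(np.full(250, 1.0))
        high = self.heatmap_for(np.full(250, 100.0))
        calls = {c.dataset: c.occupancy_class
                 for c in cluster_occupancy({"low": low, "high": high})}
        assert calls["high"] == "extra_high"
        assert calls["low"] == "low"

    def test_all_zero_window_falls_through_to_low(self):
        mats = {"zero": self.heatmap_for(np.zeros(250)),
                "pos": self.heatmap_for(np.full(250, 4.0))}
        calls = {c.dataset: c.occupancy_class
                 for c in cluster_occupancy(mats)}
        assert calls["zero"] == "low"

    def test_classes_exhaustive_and_unique(self):
        rng = np.random.default_rng(3)
        mats = {f"d{k}": self.heatmap_for(rng.normal(k - 2, 3, 250))
                for k in range(6)}
        calls = cluster_occupancy(mats)
        assert len(calls) == 6
        valid = {"no", "extra_low", "low", "medium", "high", "extra_high"}
        assert {c.occupancy_class for c in calls} <= valid


class TestPausingIndex:
    genes = pd.DataFrame({
        "gene_id": ["plus", "minus"],
        "chrom": ["c", "c"],
        "start": [10_000, 30_000],
        "end": [12_000, 32_000],
        "strand": ["+", "-"],
    })

    def test_uniform_signal_index_one(self):
        track = track_from_values(np.full(400, 5.0))
        idx = pausing_index(track, self.genes)
        assert idx["plus"] == pytest.approx(1.0)
        assert idx["minus"] == pytest.approx(1.0)

    def test_promoter_enrichment_ratio(self):
        vals = np.full(400, 2.0)
        vals[97:101] = 10.0  # covers [9700, 10100): the + promoter region
        track = track_from_values(vals)
        idx = pausing_index(track, self.genes)
        assert idx["plus"] > 2.0

    def test_zero_body_discarded(self):
        vals = np.zeros(400)
        vals[96:101] = 8.0  # promoter-only signal
        track = track_from_values(vals)
        idx = pausing_index(track, self.genes)
        assert "minus" not in idx

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 3.0, 400)
        t1 = track_from_values(vals)
        t2 = track_from_values(vals * 17.0)
        i1 = pausing_index(t1, self.genes)
        i2 = pausing_index(t2, self.genes)
        pd.testing.assert_series_equal(i1, i2)


class TestPwm:
    @pytest.fixture
    def pwm(self, rng):
        counts = rng.integers(0, 30, (7, 4))
        return PWM.from_counts(counts)

    def brute_count(self, seq, pwm, tf):
        thr = pwm.score_threshold(tf)
        total = 0
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - len(pwm) + 1):
                win = s[i:i + len(pwm)]
                if any(b not in _BASE_INDEX for b in win):
                    continue
                sc = sum(pwm.matrix[k, _BASE_INDEX[b]]
                         for k, b in enumerate(win))
                if sc >= thr:
                    total += 1
        return total

    def test_consensus_found_at_full_threshold(self, pwm):
        consensus = "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))
        seq = "TTTTT" + consensus + "TTTTT"
        assert count_pwm_sites(seq, pwm, threshold_fraction=1.0) >= 1

    def test_matches_brute_force_on_random_sequences(self, pwm, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 1000))
            for tf in (0.8, 0.85, 0.9):
                assert count_pwm_sites(seq, pwm, threshold_fraction=tf) \
                    == self.brute_count(seq, pwm, tf)

    def test_lower_threshold_counts_at_least_as_many(self, pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        c85 = count_pwm_sites(seq, pwm, threshold_fraction=0.85)
        c95 = count_pwm_sites(seq, pwm, threshold_fraction=0.95)
        assert c85 >= c95

    def test_windows_with_n_skipped(self, pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq_n = seq[:50] + "N" * 100 + seq[150:]
        assert count_pwm_sites(seq_n, pwm, threshold_fraction=0.5) \
            == self.brute_count(seq_n, pwm, 0.5)

    def test_region_flank_clipping(self, pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 6000))
        region = GenomicInterval("c", 2900, 3100)
        got = count_pwm_sites(seq, pwm, region=region, flank=2000,
                              threshold_fraction=0.8)
        window = seq[900:5100]
        assert got == self.brute_count(window, pwm, 0.8)


class TestGroupSignalTest:
    def test_identical_small_groups_p_one(self):
        assert group_signal_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_separated_groups_exact_enumeration(self):
        # all 252 splits of ranks 1..10: only the 2 extreme orderings are
        # as extreme as observed
        p = group_signal_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_matches_brute_force_enumeration(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 6)
        pooled = np.concatenate([a, b])
        n_a = len(a)

        def ustat(x, y):
            return sum((xi > yi) + 0.5 * (xi == yi)
                       for xi in x for yi in y)

        obs = ustat(a, b)
        m = len(pooled)
        count = 0
        total = 0
        for comb in itertools.combinations(range(m), n_a):
            xa = pooled[list(comb)]
            xb = pooled[[i for i in range(m) if i not in comb]]
            u = ustat(xa, xb)
            # two-sided: as or more extreme in either direction
            if min(u, n_a * len(b) - u) <= min(obs, n_a * len(b) - obs):
                count += 1
            total += 1
        assert group_signal_test(a, b) == pytest.approx(count / total)

    def test_large_groups_use_approximation(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(0.1, 1, 500)
        p = group_signal_test(a, b)
        assert 0 < p <= 1

    def test_all_tied_values_p_one(self):
        assert group_signal_test([2, 2, 2], [2, 2]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_signal_test([], [1, 2])


def test_interval_mean_counts_uncovered_as_zero():
    track = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [50],
                          "value": [10.0]})
    assert interval_mean(track, "c", 0, 100) == pytest.approx(5.0)
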