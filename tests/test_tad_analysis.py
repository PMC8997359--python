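import math

import numpy as np
import pandas as pd
import pytest

from tadremodel import (
    Border,
    annotate_direct,
    balance,
    call_borders,
    classify_borders,
    insulation_score,
    intersect_status,
    proportion_test,
    robust_borders,
    simulate_matrix,
)
from tadremodel.genome import GenomicInterval
from tadremodel.synthetic import PlantedBorder, SyntheticSpec
from tadremodel.tad_analysis import status_counts

from conftest import dense_to_matrix


def make_border(pos, strength="strong", chrom="chr1", width=1000,
                delta=0.5, pvalue=1e-4):
    iv = GenomicInterval(chrom, pos, pos + width)
    return Border(iv, pos // width, -1.0, delta, pvalue, strength)


# ---------------------------------------------------------------------------
# insulation score
# ---------------------------------------------------------------------------

class TestInsulationScore:
    def test_matches_brute_force_diamond(self, rng):
        """Raw diamond means equal a double-loop computation exactly."""
        n = 120
        a = rng.poisson(25, (n, n)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        m = dense_to_matrix(a, weights=np.ones(n))
        track = insulation_score(m, window_sizes=(4000, 7000))
        for wbp, w in [(4000, 4), (7000, 7)]:
            brute = np.full(n, np.nan)
            for i in range(w, n - w):
                vals = [a[r, c] for r in range(i - w, i)
                        for c in range(i + 1, i + 1 + w)]
                brute[i] = sum(vals) / len(vals)
            got = track.raw[wbp]
            ok = np.isfinite(brute)
            assert np.isfinite(got[ok]).all()
            np.testing.assert_allclose(got[ok], brute[ok], atol=1e-10)

    def test_translation_invariant_matrix_flat_score(self):
        n = 100
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        a = 1000.0 / (1 + d)
        m = dense_to_matrix(a, weights=np.ones(n))
        track = insulation_score(m, window_sizes=(5000, 10000))
        interior = track.score[15:-15]
        assert np.nanstd(interior) < 1e-6

    def test_planted_border_is_global_minimum(self, rng):
        n = 100
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        lam = 2000.0 / (1 + d)
        cross = (np.add.outer((np.arange(n) >= 50).astype(int),
                              (np.arange(n) >= 50).astype(int)) == 1)
        lam[cross] /= 3
        a = rng.poisson(lam)
        a = np.triu(a) + np.triu(a, 1).T
        m = dense_to_matrix(a.astype(float), weights=np.ones(n))
        track = insulation_score(m, window_sizes=(5000, 10000))
        assert abs(int(np.nanargmin(track.score)) - 50) <= 1

    def test_identical_windows_average_to_themselves(self, decay_matrix):
        t1 = insulation_score(decay_matrix, window_sizes=(6000,))
        t2 = insulation_score(decay_matrix, window_sizes=(6000, 6000))
        np.testing.assert_allclose(t1.score, t2.score, equal_nan=True)


# ---------------------------------------------------------------------------
# border calling
# ---------------------------------------------------------------------------

def _planted_spec(seed, depth=3.0, n_borders=8):
    positions = (np.linspace(250_000, 2_250_000, n_borders) // 5000 * 5000)
    return SyntheticSpec(
        genome={"chr1": 2_500_000}, resolution=5000,
        borders=[PlantedBorder("chr1", int(p), depth) for p in positions],
        depth=600_000, seed=seed)


class TestCallBorders:
    def test_flat_track_yields_no_borders(self):
        n = 80
        a = np.full((n, n), 12.0)
        m = balance(dense_to_matrix(a))
        track = insulation_score(m, window_sizes=(5000, 10000))
        assert call_borders(track, m) == []

    def test_planted_borders_recovered_with_delta_tiers(self):
        m, truth = simulate_matrix(_planted_spec(5))
        m = balance(m)
        borders = call_borders(insulation_score(m), m)
        called = np.array([b.bin for b in borders])
        for tb in truth.borders["bin"]:
            assert np.min(np.abs(called - tb)) <= 1
        for b in borders:
            assert b.delta >= 0.04
            assert (b.strength == "strong") == (b.delta >= 0.08)
            assert 0 <= b.pvalue <= 0.01

    def test_raising_strong_threshold_never_adds_strong_borders(self):
        m, _ = simulate_matrix(_planted_spec(6))
        m = balance(m)
        track = insulation_score(m)
        counts = []
        for thr in (0.08, 0.5, 2.0, 5.0):
            borders = call_borders(track, m, delta_strong=thr)
            counts.append(sum(1 for b in borders if b.strength == "strong"))
        assert counts == sorted(counts, reverse=True)

    def test_min_tad_rule_keeps_larger_delta(self):
        m, _ = simulate_matrix(_planted_spec(7))
        m = balance(m)
        track = insulation_score(m)
        borders = call_borders(track, m, min_tad=100_000)
        mids = [b.midpoint for b in borders]
        assert all(b - a >= 100_000 for a, b in zip(mids, mids[1:]))


# ---------------------------------------------------------------------------
# robustness filter and classification
# ---------------------------------------------------------------------------

class TestRobustBorders:
    def test_identical_lists_all_robust(self):
        full = [make_border(10_000), make_border(50_000, "weak")]
        assert robust_borders(full, list(full)) == full

    def test_strength_class_must_match(self):
        full = [make_border(10_000, "strong")]
        down = [make_border(10_000, "weak")]
        assert robust_borders(full, down) == []

    def test_match_tolerance_boundary(self):
        full = [make_border(10_000)]
        near = [make_border(12_000)]
        far = [make_border(12_001)]
        assert robust_borders(full, near, match_tol=2000) == full
        assert robust_borders(full, far, match_tol=2000) == []


class TestClassifyBorders:
    def test_identical_strong_lists_all_maintained(self):
        wt = [make_border(p) for p in (10_000, 50_000, 90_000)]
        comps = classify_borders(wt, [make_border(p) for p in
                                      (10_000, 50_000, 90_000)])
        assert {c.status for c in comps} == {"maintained"}
        assert len(comps) == 3

    def test_shifted_border_is_fuzzy_with_shift(self):
        wt = [make_border(50_000)]
        kd = [make_border(51_500)]
        (c,) = classify_borders(wt, kd, same_tol=600)
        assert c.status == "fuzzy"
        assert c.shift == 1500

    def test_lost_and_new(self):
        wt = [make_border(50_000)]
        kd = [make_border(60_000)]
        comps = classify_borders(wt, kd, same_tol=600)
        assert status_counts(comps) == {"lost": 1, "new": 1}

    def test_strong_to_weak_is_weakened(self):
        wt = [make_border(50_000)]
        kd = [make_border(50_000, "weak")]
        (c,) = classify_borders(wt, kd)
        assert c.status == "weakened"

    def test_statuses_partition_wt_strong_set(self, rng):
        wt = [make_border(int(p)) for p in
              np.sort(rng.choice(np.arange(10, 400), 25, replace=False) * 1000)]
        kd = [make_border(int(p + rng.integers(-3, 4) * 1000))
              for p in rng.choice([b.position.start for b in wt], 15,
                                  replace=False)]
        kd = sorted(kd, key=lambda b: b.bin)
        kd = [b for i, b in enumerate(kd)
              if i == 0 or b.bin != kd[i - 1].bin]
        comps = classify_borders(wt, kd, same_tol=600)
        wt_statuses = [c for c in comps if c.wt_border is not None]
        assert len(wt_statuses) == len(wt)
        assert {id(c.wt_border) for c in wt_statuses} == {id(b) for b in wt}

    def test_overlapping_input_borders_rejected(self):
        wt = [make_border(50_000), make_border(50_000)]
        with pytest.raises(ValueError, match="overlapping"):
            classify_borders(wt, [])


class TestIntersectStatus:
    def _comps(self, statuses):
        out = []
        for i, s in enumerate(statuses):
            wt = make_border(10_000 + 20_000 * i) if s != "new" else None
            kd = make_border(11_000 + 20_000 * i) if s != "lost" else None
            from tadremodel.tad_analysis import BorderComparison
            out.append(BorderComparison(wt, kd, s))
        return out

    def test_self_intersection_is_identity(self):
        a = self._comps(["maintained", "lost", "new"])
        common = intersect_status(a, a)
        assert len(common["maintained"]) == 1
        assert len(common["lost"]) == 1
        assert len(common["new"]) == 1
        assert common["discordant"] == []

    def test_discordant_status_in_neither_set(self):
        a = self._comps(["maintained"])
        b = self._comps(["fuzzy"])
        common = intersect_status(a, b)
        assert common["maintained"] == [] and common["lost"] == []
        assert len(common["discordant"]) == 1

    def test_disjoint_new_borders_empty(self):
        a = self._comps(["new"])
        b = self._comps(["new"])
        b[0].kd_border = make_border(500_000)
        assert intersect_status(a, b)["new"] == []


class TestAnnotateDirect:
    peaks = {"BEAF-32": pd.DataFrame({"chrom": ["chr1"], "start": [9_000],
                                      "end": [10_500]}),
             "Cp190": pd.DataFrame({"chrom": ["chr1"], "start": [9_500],
                                    "end": [11_000]})}

    def test_overlapping_peak_direct(self):
        calls = annotate_direct([make_border(10_000)], self.peaks)
        assert calls[0].direct
        assert set(calls[0].bound_proteins) == {"BEAF-32", "Cp190"}

    def test_peak_outside_vicinity_indirect(self):
        calls = annotate_direct([make_border(100_000)], self.peaks,
                                vicinity=5000)
        assert not calls[0].direct

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="unknown protein"):
            annotate_direct([make_border(10_000)],
                            {"CTCF": self.peaks["Cp190"]})


# ---------------------------------------------------------------------------
# Fisher exact oracle
# ---------------------------------------------------------------------------

def brute_force_fisher(k1, n1, k2, n2):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    total_k = k1 + k2

    def prob(x):
        return (math.comb(n1, x) * math.comb(n2, total_k - x)
                / math.comb(n1 + n2, total_k))

    support = [x for x in range(0, total_k + 1)
               if x <= n1 and total_k - x <= n2]
    p_obs = prob(k1)
    return sum(prob(x) for x in support if prob(x) <= p_obs * (1 + 1e-9))


class TestProportionTest:
    def test_equal_proportions_p_one(self):
        assert proportion_test(5, 10, 5, 10) == pytest.approx(1.0)
        assert proportion_test(1, 2, 1, 2) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        got = proportion_test(10, 10, 0, 10)
        assert got == pytest.approx(brute_force_fisher(10, 10, 0, 10),
                                    rel=1e-9)

    @pytest.mark.parametrize("k1,n1,k2,n2", [
        (3, 8, 6, 9), (0, 5, 5, 5), (2, 10, 7, 10), (4, 6, 1, 7),
    ])
    def test_matches_enumeration_small_tables(self, k1, n1, k2, n2):
        assert proportion_test(k1, n1, k2, n2) == pytest.approx(
            brute_force_fisher(k1, n1, k2, n2), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(-1, 5, 2, 5)
        with pytest.raises(ValueError):
            proportion_test(6, 5, 2, 5)
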