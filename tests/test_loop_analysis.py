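import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tadremodel import (
    GenomicInterval,
    Loop,
    annotate_loops,
    apa,
    balance,
    call_loops,
    compare_loops,
    deg_at_loops,
    simulate_matrix,
)
from tadremodel.loop_analysis import (
    LoopComparison,
    _kernels,
    loops_to_bedpe,
    poisson_sf,
)
from tadremodel.synthetic import PlantedLoop, SyntheticSpec

RES = 2000


def make_loop(pos1, pos2, chrom="c", fdr=1e-3, observed=20.0):
    return Loop(GenomicInterval(chrom, pos1, pos1 + RES),
                GenomicInterval(chrom, pos2, pos2 + RES),
                observed, 4.0, 4.0, 4.0, 4.0, fdr)


@pytest.fixture(scope="module")
def planted():
    anchors = [(200_000, 350_000), (500_000, 650_000), (800_000, 1_050_000),
               (1_200_000, 1_400_000), (1_500_000, 1_800_000)]
    spec = SyntheticSpec(
        genome={"c": 2_000_000}, resolution=RES,
        loops=[PlantedLoop("c", a, b, 5.0) for a, b in anchors],
        depth=4_000_000, seed=42)
    m, truth = simulate_matrix(spec)
    return balance(m), truth


class TestKernels:
    def test_footprints_disjoint_from_peak(self):
        k = _kernels(10, 5)
        ii, jj = np.mgrid[-10:11, -10:11]
        peak = np.maximum(np.abs(ii), np.abs(jj)) <= 5
        for name, kern in k.items():
            assert not (kern.astype(bool) & peak).any(), name
            assert kern[10, 10] == 0, name

    def test_donut_excludes_center_cross(self):
        k = _kernels(10, 5)["donut"].astype(bool)
        assert not k[10, :].any() and not k[:, 10].any()


def test_poisson_sf_matches_scipy():
    obs = np.arange(0, 30, dtype=float)
    mu = np.full_like(obs, 4.5)
    got = poisson_sf(obs, mu)
    want = stats.poisson.sf(obs - 1, mu)
    np.testing.assert_allclose(got, want, rtol=1e-10)


class TestCallLoops:
    def test_planted_peaks_recovered_within_one_bin(self, planted):
        m, truth = planted
        called = call_loops(m)
        tb = truth.loops[["bin1", "bin2"]].to_numpy()
        for i, j in tb:
            best = min(max(abs(L.anchor1.start // RES - i),
                           abs(L.anchor2.start // RES - j)) for L in called)
            assert best <= 1

    def test_null_matrix_rarely_yields_loops(self):
        hits = 0
        for seed in range(10):
            m, _ = simulate_matrix(SyntheticSpec(
                genome={"c": 1_000_000}, resolution=RES,
                depth=1_000_000, seed=900 + seed))
            hits += len(call_loops(balance(m))) > 0
        assert hits <= 1

    def test_nearby_significant_pixels_merge(self, planted):
        m, _ = planted
        called = call_loops(m, merge_dist=20_000)
        # no two calls within the merge distance of each other
        for a in called:
            for b in called:
                if a is b:
                    continue
                d = max(abs(a.anchor1.midpoint - b.anchor1.midpoint),
                        abs(a.anchor2.midpoint - b.anchor2.midpoint))
                assert d > 20_000

    def test_incompatible_resolution_rejected(self, planted):
        m, _ = planted
        with pytest.raises(ValueError, match="multiple"):
            call_loops(m, resolution=3000)


class TestCompareLoops:
    def test_identical_lists_maintained(self):
        wt = [make_loop(100_000, 300_000), make_loop(500_000, 700_000)]
        comps = compare_loops(wt, list(wt))
        assert [c.status for c in comps] == ["maintained", "maintained"]

    def test_one_shared_anchor_is_partial(self):
        wt = [make_loop(100_000, 300_000)]
        kd = [make_loop(100_000, 340_000)]
        (c,) = compare_loops(wt, kd)
        assert c.status == "partial"

    def test_no_nearby_anchors_lost(self):
        wt = [make_loop(100_000, 300_000)]
        kd = [make_loop(600_000, 800_000)]
        (c,) = compare_loops(wt, kd)
        assert c.status == "lost"

    def test_statuses_partition_wt(self):
        wt = [make_loop(p, p + 200_000) for p in
              (100_000, 400_000, 700_000, 1_000_000)]
        kd = [make_loop(100_000, 300_000), make_loop(400_000, 640_000)]
        comps = compare_loops(wt, kd)
        assert len(comps) == len(wt)
        counts = pd.Series([c.status for c in comps]).value_counts()
        assert counts.sum() == len(wt)


class TestApa:
    def test_flat_matrix_center_score_near_one(self, rng):
        from conftest import dense_to_matrix
        n = 500
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        a = rng.poisson(2000 / (1 + d)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        m = dense_to_matrix(a, resolution=RES, chrom="c",
                            weights=np.ones(n))
        loops = [make_loop(100 * RES, 300 * RES),
                 make_loop(200 * RES, 420 * RES)]
        _, score = apa(m, loops, halfwidth=10)
        assert abs(score - 1.0) < 0.25

    def test_planted_loops_score_beats_shifted_decoys(self, planted):
        m, truth = planted
        loops = [make_loop(int(r.pos1), int(r.pos2))
                 for r in truth.loops.itertuples()]
        _, score = apa(m, loops)
        decoys = [make_loop(int(r.pos1) + 10 * RES, int(r.pos2) + 10 * RES)
                  for r in truth.loops.itertuples()]
        _, decoy_score = apa(m, decoys)
        assert score >= 2.0
        assert score > decoy_score

    def test_no_eligible_loops_raises(self, planted):
        m, _ = planted
        near_diag = [make_loop(500_000, 520_000)]
        with pytest.raises(ValueError, match="no loops"):
            apa(m, near_diag, halfwidth=15)


class TestAnnotateLoops:
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2"],
        "chrom": ["c", "c"],
        "start": [101_000, 300_000],
        "end": [105_000, 320_000],
        "strand": ["+", "-"],
    })
    enhancers = pd.DataFrame({"chrom": ["c"], "start": [200_000],
                              "end": [202_000]})

    def annotate_one(self, pos1, pos2):
        (ann,) = annotate_loops([make_loop(pos1, pos2)], self.genes,
                                self.enhancers)
        return ann

    def test_promoter_window_upstream_of_plus_strand_tss(self):
        ann = self.annotate_one(100_000, 300_000)
        assert ann.end1_class == "P"  # anchor covers [100k,102k): TSS-1kb hit
        # minus-strand gene: TSS at end-1; promoter [320000, 321000)
        assert ann.end2_class == "G"

    def test_enhancer_then_gene_then_other_precedence(self):
        ann = self.annotate_one(200_000, 304_000)
        assert ann.end1_class == "E"
        assert ann.end2_class == "G"
        ann = self.annotate_one(500_000, 700_000)
        assert (ann.end1_class, ann.end2_class) == ("O", "O")

    def test_unordered_pair(self):
        ann = self.annotate_one(200_000, 304_000)
        assert ann.pair == ("E", "G")

    def test_missing_strand_rejected(self):
        bad = self.genes.assign(strand=".")
        with pytest.raises(ValueError, match="strand"):
            annotate_loops([make_loop(100_000, 300_000)], bad, self.enhancers)


class TestDegAtLoops:
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(6)],
        "chrom": ["c"] * 6,
        "start": [101_000, 103_000, 301_000, 303_000, 501_000, 503_000],
        "end": [102_000, 104_000, 302_000, 304_000, 502_000, 504_000],
        "strand": ["+"] * 6,
    })

    def comps(self):
        return [LoopComparison(make_loop(100_000, 302_000), "maintained",
                               make_loop(100_000, 302_000)),
                LoopComparison(make_loop(500_000, 700_000), "lost")]

    def test_no_degs_gives_p_one(self):
        deg = pd.DataFrame({"gene_id": self.genes["gene_id"],
                            "status": ["not-DE"] * 6})
        out = deg_at_loops(self.comps(), self.genes, deg)
        assert out["maintained"]["fraction"] == 0
        assert out["lost"]["fraction"] == 0
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_all_deg_at_lost_only_significant_direction(self):
        status = ["not-DE"] * 6
        # genes at the lost-loop anchors (promoters just upstream)
        deg = pd.DataFrame({"gene_id": self.genes["gene_id"], "status": status})
        deg.loc[deg["gene_id"].isin(["g4", "g5"]), "status"] = "up"
        out = deg_at_loops(self.comps(), self.genes, deg)
        assert out["lost"]["fraction"] > out["maintained"]["fraction"]


def test_bedpe_export_schema():
    df = loops_to_bedpe([make_loop(100_000, 300_000)])
    assert list(df.columns) == ["chrom1", "start1", "end1", "chrom2",
                                "start2", "end2", "name", "fdr"]
    assert df.loc[0, "start2"] == 300_000
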