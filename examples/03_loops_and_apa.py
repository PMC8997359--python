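"""Call chromatin loops with the donut filter and aggregate them (APA).

Plants six focal 5x-enriched contact peaks at 2-kb resolution, calls loops
at FDR 0.05 with HiCCUPS-style local filters, and quantifies aggregate
enrichment with an APA center score (mean observed/expected at the loop
pixel relative to its lower-left background corner).
"""
from tadremodel import (
    PlantedLoop,
    SyntheticSpec,
    balance,
    call_loops,
    simulate_matrix,
)
from tadremodel.loop_analysis import apa

anchors = [(200_000, 350_000), (500_000, 650_000), (800_000, 1_050_000),
           (1_200_000, 1_400_000), (1_500_000, 1_800_000),
           (400_000, 550_000)]
spec = SyntheticSpec(
    genome={"chr2L": 2_000_000}, resolution=2000,
    loops=[PlantedLoop("chr2L", a, b, 5.0) for a, b in anchors],
    depth=4_000_000, seed=2)
matrix, truth = simulate_matrix(spec)
balanced = balance(matrix)

loops = call_loops(balanced, fdr=0.05)
print(f"called {len(loops)} loops from {len(anchors)} planted peaks:")
for L in loops:
    print(f"  {L.chrom}:{L.anchor1.start:,} <-> {L.anchor2.start:,}  "
          f"obs={L.observed:.1f} donut-exp={L.expected_donut:.1f} "
          f"q={L.fdr:.1e}")

apa_matrix, score = apa(balanced, loops)
print(f"APA center score = {score:.2f}")
print("(1.0 would mean no aggregate enrichment; planted 5x loops give a "
      "score well above 2 even after binning attenuation)")
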