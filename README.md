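# tadremodel

Comparative Hi-C analysis of chromatin architecture across conditions:
TAD-border detection and robustness, maintained/lost/fuzzy/new border
classification between a wild type and architectural-protein knockdowns,
chromatin-loop calling and comparison, A/B compartment strength, and the
association between TAD reorganization and differential gene expression.

The package is aimed at regulatory-genomics analysts who want the full
knockdown-comparison workflow — the kind used to dissect the roles of
*Drosophila* insulator proteins such as BEAF-32, Cp190, and Chro at TAD
borders — as a tested, seedable library rather than a chain of separate
command-line tools. Every analysis step has a synthetic-data counterpart
with machine-readable planted truth, so the whole pipeline can be
exercised and validated end to end without any external download.

## The statistics at the core

**TAD-separation score.** For bin *i* and window *w*, the score is the
mean corrected contact count in the diamond `{(a, b) : i−w ≤ a < i < b ≤
i+w}`, z-scored per chromosome and averaged over windows (10/20/30 kb by
default). Borders are local minima with prominence δ ≥ 0.04 (weak) or
δ ≥ 0.08 (strong) whose inter-domain contacts are depleted relative to the
flanking intra-domain triangles (one-sided rank-sum test on
distance-normalized contacts, BH-adjusted p ≤ 0.01), with a 5-kb minimum
TAD width. A border is *robust* if recovered at the same strength after
20% binomial down-sampling; robust strong WT borders are then scored
against a knockdown as maintained, weakened, fuzzy (moved ≤ 2 kb), lost,
or new.

**Loops.** Focal peaks at 2-kb resolution where the corrected count
exceeds four local expectations (donut, horizontal, vertical, lower-left;
window 10, peak width 5) with per-filter Poisson tails at BH-FDR 0.05,
enrichment factors 1.75 (donut/lower-left) and 1.5 (horizontal/vertical),
merging within 20 kb — the HiCCUPS scheme with direct Poisson tails.
Aggregate peak analysis (APA) reports the mean O/E submatrix around loop
pixels and its center-over-corner score.

**Compartments.** Per chromosome, the leading eigenvector of the Pearson
correlation of the O/E map at 10-kb bins, sign-oriented by GC content
(A = positive, B = negative). The saddle ranks bins into 30 eigenvector
percentile groups (trimmed to [2.5%, 97.5%]); compartment strength is the
homotypic/heterotypic ratio of 10x10 corner means.

**Expression association.** The genome is segmented by the union of WT
and knockdown borders; segments are classed by how far their WT TAD's
borders moved (conserved-two / conserved-one / knockdown-specific /
fuzzy). DEG enrichment in reorganized TADs is tested by uniform
within-chromosome region permutation, p = (1 + #{null ≥ obs})/(1 + N).

## Worked example

```bash
python examples/01_simulate_and_call_borders.py
```

```
simulated 1000915 contacts over 1000 bins
called 15 borders (15 strong) versus 15 planted
15 strong borders sit within one 5-kb bin of a planted border
  border at chr2L:  295,000  delta=5.61  adj. p=4.39e-11  strong
  border at chr2L:  610,000  delta=5.45  adj. p=4.39e-11  strong
  border at chr2L:  920,000  delta=5.00  adj. p=4.39e-11  strong
```

A 5-Mb chromosome is simulated with 15 borders whose insulation depth is
2.5 (contacts crossing a border are reduced 2.5-fold); all 15 are
recovered within one bin, each with a large score prominence (`delta`)
and a tiny adjusted separation p-value. The other scripts in `examples/`
walk through condition-pair classification, loop calling and APA,
compartments and saddle strength, the DEG permutation test, border-signal
heatmaps/occupancy/PWM scanning, and the full pipeline:

```bash
tadremodel run --config examples/demo_config.yaml
```

which prints a summary like

```
beaf32_kd: {'lost': 5, 'maintained': 6, 'new': 1} of 11 WT robust strong
borders; DEG association p = 0.002
loops: {'lost': 3, 'maintained': 2} (APA 4.67)
compartments: strength WT 2.25 vs KD 2.23, switching 0.0%
```

— the border ledger per knockdown, loop status counts, compartment
strengths, and the permutation p-value testing whether differentially
expressed genes concentrate in reorganized TADs.

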