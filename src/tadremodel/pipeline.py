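"""Configuration-driven end-to-end comparison of WT against knockdowns.

The runner simulates (or loads) contact matrices, calls borders with the
down-sampling robustness filter, classifies borders across conditions,
calls and compares loops, computes compartments and saddle strengths, and
tests the DEG/TAD-reorganization association — writing BED/BEDPE/TSV/JSON
outputs plus a summary report, deterministically for a given config.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartment_analysis as comp
from . import contact_matrix as cm
from . import expression_association as ea
from . import loop_analysis as la
from . import synthetic as syn
from . import tad_analysis as ta
from .genome import write_bed, write_bedgraph

log = logging.getLogger("tadremodel")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_KNOWN_KEYS = {
    "name", "genome", "resolution", "depth", "seed", "n_borders",
    "border_depth", "n_loops", "loop_enrichment", "loop_resolution",
    "loop_depth", "compartment_blocks", "checkerboard_factor",
    "compartment_resolution", "compartment_depth", "knockdowns",
    "delta_weak", "delta_strong", "border_pvalue", "min_tad",
    "downsample_fraction", "fuzzy_tol", "loop_fdr", "saddle_bins",
    "n_perm", "deg_padj", "deg_log2fc", "genes_per_tad", "deg_odds",
    "seeds", "outdir",
}
_REQUIRED_SEEDS = ("simulation", "downsample", "permutation", "expression")


@dataclass
class RunConfig:
    """All pipeline parameters, with the study's defaults."""

    name: str = "demo"
    genome: dict[str, int] = field(default_factory=lambda: {"chrS": 4_000_000})
    resolution: int = 5000
    depth: float = 1_000_000.0
    n_borders: int = 12
    border_depth: float = 3.0
    n_loops: int = 6
    loop_enrichment: float = 5.0
    loop_resolution: int = 2000
    loop_depth: float = 4_000_000.0
    compartment_blocks: int = 20
    checkerboard_factor: float = 3.0
    compartment_resolution: int = 10_000
    compartment_depth: float = 2_000_000.0
    knockdowns: dict[str, dict] = field(default_factory=dict)
    delta_weak: float = ta.DELTA_WEAK
    delta_strong: float = ta.DELTA_STRONG
    border_pvalue: float = ta.BORDER_PVALUE
    min_tad: int = ta.MIN_TAD
    downsample_fraction: float = 0.8
    fuzzy_tol: int = ta.FUZZY_TOL
    loop_fdr: float = la.LOOP_FDR
    saddle_bins: int = comp.SADDLE_BINS
    n_perm: int = ea.N_PERM
    deg_padj: float = ea.DEG_PADJ
    deg_log2fc: float = ea.DEG_LOG2FC
    genes_per_tad: int = 3
    deg_odds: float = 5.0
    seeds: dict[str, int] = field(default_factory=dict)
    outdir: str = "tadremodel_run"

    def validate(self) -> None:
        missing = [k for k in _REQUIRED_SEEDS if k not in self.seeds]
        if missing:
            raise ValueError(f"config must set explicit seeds for: {missing}")
        if not (0 < self.downsample_fraction <= 1):
            raise ValueError("downsample_fraction must be in (0, 1]")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------

def _border_layout(cfg: RunConfig, rng: np.random.Generator
                   ) -> list[syn.PlantedBorder]:
    borders = []
    for chrom, size in cfg.genome.items():
        slots = np.linspace(0.08 * size, 0.92 * size, cfg.n_borders)
        jitter = rng.integers(-3, 4, cfg.n_borders) * cfg.resolution
        for p in np.sort(slots + jitter):
            pos = int(round(p / cfg.resolution)) * cfg.resolution
            borders.append(syn.PlantedBorder(chrom, pos, cfg.border_depth))
    return borders


def _loop_layout(cfg: RunConfig, rng: np.random.Generator
                 ) -> list[syn.PlantedLoop]:
    loops = []
    for chrom, size in cfg.genome.items():
        for k in range(cfg.n_loops):
            a = int(size * (0.1 + 0.75 * k / max(cfg.n_loops, 1)))
            a = (a // cfg.loop_resolution) * cfg.loop_resolution
            span = int(rng.integers(50, 150)) * cfg.loop_resolution
            loops.append(syn.PlantedLoop(chrom, a, min(a + span,
                                                       size - cfg.loop_resolution),
                                         cfg.loop_enrichment))
    return loops


def _call_robust(m: cm.ContactMatrix, cfg: RunConfig, seed: int
                 ) -> list[ta.Border]:
    bal = cm.balance(m)
    track = ta.insulation_score(bal)
    full = ta.call_borders(track, bal, cfg.delta_weak, cfg.delta_strong,
                           cfg.border_pvalue, cfg.min_tad)
    ds = cm.downsample(m, cfg.downsample_fraction, seed)
    dbal = cm.balance(ds)
    dtrack = ta.insulation_score(dbal)
    dborders = ta.call_borders(dtrack, dbal, cfg.delta_weak, cfg.delta_strong,
                               cfg.border_pvalue, cfg.min_tad)
    return ta.robust_borders(full, dborders, cfg.fuzzy_tol)


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic WT-versus-knockdowns comparison.

    Returns the summary dict (also written as summary.json). A failure in
    one knockdown comparison is logged and does not abort the others.
    """
    cfg.validate()
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log.info("run %s (config %s)", cfg.name, chash)
    summary: dict = {"name": cfg.name, "config_hash": chash,
                     "knockdowns": {}}
    sim_seed = cfg.seeds["simulation"]
    layout_rng = np.random.default_rng(sim_seed)
    borders = _border_layout(cfg, layout_rng)
    loops = _loop_layout(cfg, layout_rng)

    # ---- TAD-scale WT/KD pairs -------------------------------------
    base = syn.SyntheticSpec(genome=cfg.genome, resolution=cfg.resolution,
                             borders=borders, depth=cfg.depth, seed=sim_seed)
    if not cfg.knockdowns:
        cfg.knockdowns = {"kd1": {"delete": 3, "shift": 3, "shift_bp": 10000}}
    edit_rng = np.random.default_rng(sim_seed + 1)
    for kname, spec_edits in cfg.knockdowns.items():
        try:
            summary["knockdowns"][kname] = _run_one_knockdown(
                cfg, base, kname, spec_edits, edit_rng, out)
        except Exception:  # noqa: BLE001 - isolate per-comparison failures
            log.exception("comparison %s failed; continuing", kname)
            summary["knockdowns"][kname] = {"error": "failed"}

    # ---- loops ------------------------------------------------------
    log.info("loop stage: resolution %d, FDR %g", cfg.loop_resolution,
             cfg.loop_fdr)
    lspec = syn.SyntheticSpec(genome=cfg.genome,
                              resolution=cfg.loop_resolution,
                              loops=loops, depth=cfg.loop_depth,
                              seed=sim_seed + 2)
    wt_lm, kd_lm, wt_lt, _ = syn.simulate_condition_pair(
        lspec, [syn.LoopEdit(L.chrom, L.pos1, L.pos2)
                for L in loops[: len(loops) // 2]])
    wt_loops = la.call_loops(cm.balance(wt_lm), resolution=cfg.loop_resolution,
                             fdr=cfg.loop_fdr)
    kd_loops = la.call_loops(cm.balance(kd_lm), resolution=cfg.loop_resolution,
                             fdr=cfg.loop_fdr)
    comparisons = la.compare_loops(wt_loops, kd_loops,
                                   anchor_tol=cfg.loop_resolution)
    la.loops_to_bedpe(wt_loops).to_csv(out / "wt_loops.bedpe", sep="\t",
                                       index=False, header=False)
    loop_counts = {}
    for c in comparisons:
        loop_counts[c.status] = loop_counts.get(c.status, 0) + 1
    apa_score = None
    if wt_loops:
        try:
            _, apa_score = la.apa(cm.balance(wt_lm), wt_loops,
                                  resolution=cfg.loop_resolution)
        except ValueError:
            pass
    summary["loops"] = {"wt_total": len(wt_loops), "kd_total": len(kd_loops),
                        "status_counts": loop_counts,
                        "apa_center_score": apa_score}

    # ---- compartments ------------------------------------------------
    log.info("compartment stage: resolution %d", cfg.compartment_resolution)
    cspec = syn.SyntheticSpec(genome=cfg.genome,
                              resolution=cfg.compartment_resolution,
                              compartment_blocks=cfg.compartment_blocks,
                              checkerboard_factor=cfg.checkerboard_factor,
                              depth=cfg.compartment_depth, seed=sim_seed + 3)
    wt_cm, wt_ct = syn.simulate_matrix(cspec)
    kd_cm, _ = syn.simulate_matrix(
        syn.SyntheticSpec(genome=cfg.genome,
                          resolution=cfg.compartment_resolution,
                          compartment_blocks=cfg.compartment_blocks,
                          checkerboard_factor=cfg.checkerboard_factor,
                          depth=cfg.compartment_depth, seed=sim_seed + 4))
    wt_track = comp.compartment_eigenvector(cm.balance(wt_cm), wt_ct.gc,
                                            cfg.compartment_resolution)
    kd_track = comp.compartment_eigenvector(cm.balance(kd_cm), wt_ct.gc,
                                            cfg.compartment_resolution)
    _, switch_frac = comp.detect_switches(wt_track, kd_track)
    strength_wt = comp.saddle(cm.balance(wt_cm), wt_track,
                              n_bins=cfg.saddle_bins).strength
    strength_kd = comp.saddle(cm.balance(kd_cm), kd_track,
                              n_bins=cfg.saddle_bins).strength
    write_bedgraph(wt_track.to_bedgraph_frame(), out / "wt_eigenvector.bedgraph")
    summary["compartments"] = {"switch_fraction": switch_frac,
                               "strength_wt": strength_wt,
                               "strength_kd": strength_kd}

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("summary written to %s", summary_path)
    return summary


def _run_one_knockdown(cfg: RunConfig, base: syn.SyntheticSpec, kname: str,
                       spec_edits: dict, edit_rng: np.random.Generator,
                       out: Path) -> dict:
    log.info("border stage for %s: edits %s", kname, spec_edits)
    borders = base.borders
    n_del = int(spec_edits.get("delete", 0))
    n_shift = int(spec_edits.get("shift", 0))
    shift_bp = int(spec_edits.get("shift_bp", 10_000))
    idx = edit_rng.permutation(len(borders))
    edits: list[syn.BorderEdit] = []
    for i in idx[:n_del]:
        b = borders[i]
        edits.append(syn.BorderEdit(b.chrom, b.pos, "delete"))
    for i in idx[n_del:n_del + n_shift]:
        b = borders[i]
        edits.append(syn.BorderEdit(b.chrom, b.pos, "shift", delta=shift_bp))
    wt_m, kd_m, wt_truth, _ = syn.simulate_condition_pair(
        base, edits, same_tol=cfg.resolution, fuzzy_tol=cfg.fuzzy_tol)
    ds_seed = cfg.seeds["downsample"]
    wt_borders = _call_robust(wt_m, cfg, ds_seed)
    kd_borders = _call_robust(kd_m, cfg, ds_seed + 1)
    comparisons = ta.classify_borders(wt_borders, kd_borders,
                                      fuzzy_tol=cfg.fuzzy_tol)
    counts = ta.status_counts(comparisons)
    ledger = pd.DataFrame(
        [(c.status,
          c.wt_border.chrom if c.wt_border else c.kd_border.chrom,
          c.wt_border.midpoint if c.wt_border else -1,
          c.kd_border.midpoint if c.kd_border else -1,
          c.shift if c.shift is not None else -1)
         for c in comparisons],
        columns=["status", "chrom", "wt_pos", "kd_pos", "shift"])
    ledger.to_csv(out / f"{kname}_border_ledger.tsv", sep="\t", index=False)
    write_bed(ta.borders_to_bed(wt_borders), out / f"{kname}_wt_borders.bed")

    # expression association: DEGs planted into reorganized TADs
    genes, deg = syn.simulate_expression(wt_truth, cfg.genome,
                                         cfg.genes_per_tad, cfg.deg_odds,
                                         cfg.seeds["expression"],
                                         padj_thresh=cfg.deg_padj,
                                         log2fc_thresh=cfg.deg_log2fc)
    deg = ea.apply_deg_thresholds(deg, cfg.deg_padj, cfg.deg_log2fc)
    classes = ea.classify_tad_regions(
        wt_borders, kd_borders, cfg.genome, fuzzy_tol=cfg.fuzzy_tol,
        same_tol=cfg.resolution)
    targets = ea.regions_frame(classes)
    targets = targets[targets["class"].isin(["kd_specific", "conserved_one"])]
    de_ids = set(deg.loc[deg["status"] != "not-DE", "gene_id"])
    deg_regions = genes[genes["gene_id"].isin(de_ids)][["chrom", "start", "end"]]
    universe = pd.DataFrame([(c, 0, s) for c, s in cfg.genome.items()],
                            columns=["chrom", "start", "end"])
    if len(deg_regions) and len(targets):
        perm = ea.permutation_overlap_test(deg_regions, targets, universe,
                                           n_perm=cfg.n_perm,
                                           seed=cfg.seeds["permutation"])
        perm_p, perm_z = perm.pvalue, perm.z
    else:
        perm_p, perm_z = 1.0, 0.0
    return {"border_status_counts": counts,
            "n_wt_robust_strong": sum(1 for b in wt_borders
                                      if b.strength == "strong"),
            "deg_association": {"pvalue": perm_p, "z": perm_z,
                                "n_deg": int(len(deg_regions))}}
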