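"""Pipeline orchestration: run all stages over one simulated or loaded
dataset and join the per-locus results.

Each stage logs counts in and out (the filter cascade is the scientific
narrative); every output file carries the config hash in a header comment;
a stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import extent as ext
from . import mircall, readclass, termini
from .config import RunConfig, config_hash
from .formats import (
    Feature,
    GenomeSegment,
    RelCoord,
    from_relative,
    to_relative,
    write_report,
)
from .hairpin import fold
from .mircall import CallConfig, LocusCall, ReadStack, build_stack
from .simulate import GENOTYPES, TIMEPOINTS, SimTruth, simulate_coverage, simulate_small_reads

log = logging.getLogger("dictymir")

__all__ = ["PipelineError", "run_pipeline", "call_all_loci", "locus_windows"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def locus_windows(features, flank: int):
    """Fold/stack windows of candidate hairpin features (feature +- flank)."""
    out = {}
    for f in features:
        if f.ftype == "hairpin_candidate":
            out[f.id] = (f, (f.start - flank, f.end + flank))
    return out


def _stacks_for(locus, window, reads_by_cond, lib_sizes, cfg) -> dict:
    stacks = {}
    for cond, reads in reads_by_cond.items():
        stacks[cond] = build_stack(
            reads, window, locus.strand, cond, lib_sizes[cond],
            locus_id=locus.id, segment_id=locus.segment_id,
            min_overlap_frac=cfg.stack_min_overlap,
        )
    return stacks


def _pool(stacks, conds, condition_name) -> ReadStack:
    counts: dict = {}
    lib = 0
    first = stacks[conds[0]]
    for c in conds:
        for k, v in stacks[c].counts.items():
            counts[k] = counts.get(k, 0) + v
        lib += stacks[c].library_size
    return ReadStack(locus_id=first.locus_id, condition=condition_name,
                     window=first.window, strand=first.strand,
                     counts=counts, library_size=lib)


def call_all_loci(segment: GenomeSegment, features, reads_by_cond: dict,
                  lib_sizes: dict, cfg: RunConfig) -> dict:
    """Fold and classify every candidate hairpin locus.

    ``reads_by_cond`` maps (genotype, timepoint) -> reads.  Returns
    locus_id -> LocusCall.
    """
    call_cfg = CallConfig(
        min_reads=cfg.min_reads, min_homogeneity=cfg.min_homogeneity,
        overhang_mode=cfg.overhang_mode, energy_threshold=cfg.energy_threshold,
        min_pairing=cfg.min_pairing, pseudocount=cfg.pseudocount,
        ko_max_log2fc=cfg.ko_max_log2fc, dev_min_abs_log2fc=cfg.dev_min_abs_log2fc,
        mor_max_gap=cfg.mor_max_gap,
    )
    calls = {}
    for lid, (locus, window) in locus_windows(features, cfg.fold_flank).items():
        ws = max(0, window[0])
        we = min(len(segment.sequence), window[1])
        structure = fold(segment.slice(ws, we, locus.strand), lid)
        stacks = _stacks_for(locus, (ws, we), reads_by_cond, lib_sizes, cfg)
        wt = _pool(stacks, [("wt", t) for t in TIMEPOINTS], "wt")
        ko = _pool(stacks, [("ko", t) for t in TIMEPOINTS], "ko")
        calls[lid] = mircall.classify_locus(
            lid, structure, wt, ko,
            stack_0h=stacks.get(("wt", "0h")), stack_16h=stacks.get(("wt", "16h")),
            config=call_cfg,
        )
    return calls


def run_pipeline(truth: SimTruth, cfg: RunConfig, outdir: Optional[str] = None) -> dict:
    """Simulate all conditions, run every stage, and write the reports.

    Returns a dict of stage results; deterministic under (truth, cfg).
    """
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    header = f"config={chash}"
    results: dict = {}
    segment, features = truth.segment, truth.features

    # --- reads ---
    try:
        reads_by_cond = {
            (g, t): simulate_small_reads(truth, g, t) for g in GENOTYPES for t in TIMEPOINTS
        }
        lib_sizes = {c: len(r) for c, r in reads_by_cond.items()}
        for c, r in reads_by_cond.items():
            log.info("reads %s: %d", c, len(r))
    except Exception as exc:
        raise PipelineError("simulate", exc)

    # --- classification ---
    try:
        index = readclass.FeatureIndex(features)
        frac_rows = []
        for g in GENOTYPES:
            pooled = [r for t in TIMEPOINTS for r in reads_by_cond[(g, t)]]
            hist = readclass.size_histogram(pooled, condition=g)
            cf = readclass.category_fractions(
                pooled, features, length_filter=cfg.length_filter,
                weight_by_hits=cfg.weight_by_hits, index=index)
            log.info("classify %s: %d reads, modal length %d", g, hist.total, hist.modal_length)
            for cat, fr in cf.fractions.items():
                frac_rows.append({"condition": g, "category": cat, "fraction": f"{fr:.6f}"})
        write_report(frac_rows, outdir / "class_fractions.tsv", header)
        results["class_fractions"] = frac_rows
    except Exception as exc:
        raise PipelineError("readclass", exc)

    # --- locus calls ---
    try:
        calls = call_all_loci(segment, features, reads_by_cond, lib_sizes, cfg)
        n_hc = sum(1 for c in calls.values() if c.tier == "high_confidence")
        log.info("mircall: %d loci -> %d high_confidence", len(calls), n_hc)
        rows = []
        for lid, call in sorted(calls.items()):
            rows.append({
                "locus": lid, "tier": call.tier,
                "failed": ",".join(call.report.failed_names()) or ".",
                "ko_log2fc_5p": f"{call.ko_log2fc[0]:.3f}" if call.ko_log2fc else ".",
                "ko_log2fc_3p": f"{call.ko_log2fc[1]:.3f}" if call.ko_log2fc else ".",
                "dev_regulated": call.dev_regulated if call.dev_regulated is not None else ".",
                "n_duplex_pairs": len(call.mor_pairs),
                "error": call.error or ".",
            })
        write_report(rows, outdir / "locus_calls.tsv", header)
        results["calls"] = calls
    except Exception as exc:
        raise PipelineError("mircall", exc)

    # --- coverage: extents, enrichment, readthrough ---
    try:
        cov = {
            (g, t): simulate_coverage(truth, g, t) for g in GENOTYPES for t in TIMEPOINTS
        }
        ext_rows = []
        extents = {}
        for locus in truth.mirna_loci():
            win = (min(locus.tss, locus.anchor) - 50, max(locus.tss, locus.anchor) + (locus.pri_end_rel or 0) + 60) \
                if locus.strand == "+" else \
                (locus.anchor - (locus.pri_end_rel or 0) - 60, locus.tss + 50)
            for g in GENOTYPES:
                track = cov[(g, "0h")][locus.strand]
                te = ext.transcript_extent(track, win, locus.anchor, locus.strand,
                                           locus_id=locus.locus_id, condition=g,
                                           min_depth=cfg.min_depth)
                if te is None:
                    continue
                extents[(locus.locus_id, g)] = te
                enr = ext.locus_enrichment(cov[("wt", "0h")][locus.strand],
                                           cov[("ko", "0h")][locus.strand],
                                           win, locus_id=locus.locus_id)
                ext_rows.append({
                    "locus": locus.locus_id, "condition": g,
                    "five_prime": te.five_prime_most.value,
                    "three_prime": te.three_prime_most.value,
                    "ko_log2fc": f"{enr.log2fc:.3f}",
                })
        write_report(ext_rows, outdir / "transcript_extents.tsv", header)
        results["extents"] = extents
    except Exception as exc:
        raise PipelineError("extent", exc)

    # --- motif discovery ---
    try:
        motif_rows = []
        hits_for_pfm = []
        strands = {}
        for locus in truth.mirna_loci():
            te = extents.get((locus.locus_id, "ko"))
            if te is None:
                continue
            anchor5 = from_relative(te.five_prime_most)
            hits = termini.find_tss_motif(segment, anchor5, locus.strand,
                                          locus_id=locus.locus_id,
                                          window=cfg.motif_window, min_run=cfg.motif_min_run)
            if hits:
                top = hits[0]
                hits_for_pfm.append(top)
                strands[locus.locus_id] = locus.strand
                motif_rows.append({
                    "locus": locus.locus_id, "run_length": top.run_length,
                    "tss_rel": to_relative(top.predicted_tss, locus.anchor, locus.strand).value,
                })
        write_report(motif_rows, outdir / "tss_motifs.tsv", header)
        if hits_for_pfm:
            pfm = termini.build_pfm(hits_for_pfm, segment, strands=strands,
                                    upstream_span=cfg.pfm_upstream_span)
            results["pfm"] = pfm
            pfm_rows = [
                {"position": p, **{b: f"{pfm.freqs[p][b]:.4f}" for b in "ACGT"}}
                for p in pfm.positions
            ]
            write_report(pfm_rows, outdir / "tss_pfm.tsv", header)
        results["motifs"] = motif_rows
        log.info("motif: %d loci with a T-run+G hit", len(motif_rows))
    except Exception as exc:
        raise PipelineError("termini", exc)

    return results
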