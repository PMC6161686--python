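#!/usr/bin/env python
"""Promoter motif discovery: T-homopolymer run immediately upstream of a G.

Finding on the default scenario: all 20 miRNA loci yield a motif hit within
140 nt of the 5'-most covered position; the model loci recover their 21-T
and 26-T runs exactly, and the position frequency matrix is T-dominated
immediately upstream of the anchoring G.
"""

import sys
from pathlib import Path

from dictymir.formats import to_relative, write_report
from dictymir.simulate import SimScenario, simulate_genome
from dictymir.termini import build_pfm, find_tss_motif

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = SimScenario(seed=seed)
    segment, _, truth = simulate_genome(scenario)

    rows, hits, strands = [], [], {}
    for locus in truth.mirna_loci():
        found = find_tss_motif(segment, locus.tss, locus.strand, locus_id=locus.locus_id)
        if not found:
            continue
        top = found[0]
        hits.append(top)
        strands[locus.locus_id] = locus.strand
        rows.append({
            "locus": locus.locus_id, "run_length": top.run_length,
            "tss_rel": to_relative(top.predicted_tss, locus.anchor, locus.strand).value,
        })
    print(f"motif hits at {len(rows)}/{len(truth.mirna_loci())} loci; "
          f"run lengths {sorted(r['run_length'] for r in rows)}")
    for r in rows[:2]:
        print(f"  {r['locus']}: {r['run_length']} consecutive Ts, TSS at {r['tss_rel']}")

    pfm = build_pfm(hits, segment, strands=strands)
    pfm_rows = [{"position": p, **{b: f"{pfm.freqs[p][b]:.4f}" for b in "ACGT"}}
                for p in pfm.positions]
    t_mean = sum(pfm.freqs[-k]["T"] for k in range(1, 9)) / 8
    print(f"PFM over {pfm.n_loci} loci: G frequency {pfm.freqs[1]['G']:.2f} at +1, "
          f"mean T frequency {t_mean:.2f} at -8..-1")

    write_report(rows, OUT / "tss_motifs.tsv")
    write_report(pfm_rows, OUT / "tss_pfm.tsv")
    print(f"wrote {OUT/'tss_motifs.tsv'} and tss_pfm.tsv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
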