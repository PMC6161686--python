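# Methods

`dictymir` curates small-RNA loci and dissects miRNA biogenesis in the
style of a Dicer-like-knockout study of an AT-rich amoebal genome: it
classifies small-RNA read populations, calls high-confidence miRNA loci
from read stacks on folded hairpins, maps primary-transcript extents and
readthrough, detects untemplated oligo(A) tails, and discovers the
T-run + G promoter motif.  Every step is exercised against a seeded
synthetic-data generator with planted ground truth.

## Coordinate conventions

Internally everything is 0-based, half-open, on named segments.  The
reporting convention of the field — a signed, zero-free coordinate where +1
is the first nucleotide of mir-5p and upstream positions are negative —
exists only at the boundary (`to_relative`, `from_relative`,
`span_length`).  Because the axis skips 0, an inclusive span that straddles
the origin is `|a| + b` rather than `b − a + 1`; the worked example is a
primary transcript mapped from −281 to +388, i.e. 669 nt.  Reads and
coverage on the − strand are flipped into locus-forward orientation at
stack-building time so that all downstream logic is strand-free.

## The high-confidence criteria

A candidate locus is a `hairpin_candidate` feature; its analysis window is
the feature ± 20 nt (configurable flank).  The window is folded, reads
overlapping it by ≥ 75% of their templated span are stacked, and the reads
are assigned to the arm (5′ or 3′ of the single apical loop) containing at
least half of their span.  The duplex is the pair of modal (5′-start,
length) reads; ties break to the smaller start, then the longer read.  The
criteria, with defaults:

| criterion | quantity | default threshold |
|---|---|---|
| i   | reads on each arm | ≥ 10 |
| ii  | duplex 3′ overhangs | both = 2 (strict); 0–4 (relaxed) |
| iii | 5′-end homogeneity per arm | ≥ 0.5 |
| iv  | folding energy density | < −0.5 pseudo-kcal/mol/nt (internal), < −0.2 (external) |
| v   | duplex pairing fraction | ≥ 0.60 |
| KO  | knockout log2 fold change per arm (cpm, pseudocount 1) | ≤ −2 |

`high_confidence` requires all six with the strict overhang; `candidate`
tolerates a read-support failure (abundant siRNA backgrounds occlude rare
arms) or an overhang that passes only the relaxed mode; everything else is
rejected, always with the full per-criterion report attached.
"Clearly down-regulated in the knockout" is quantified as log2fc ≤ −2
because the planted (and observed) depletion is near-abolition; −2 is
conservative yet robust to the pseudocount.  Developmental regulation
(|log2fc| ≥ 1 between timepoints on the dominant arm) is a flag, not a
gate.

Homogeneity is measured among reads starting within ±5 nt of the modal
start rather than over the whole arm.  This measures the precision of the
modal product itself: an immediately adjacent offset-RNA pair (a second
duplex ~22 nt away on the same arm) does not count against it, while
overlapping alternative 5′ ends — the signature of imprecise processing —
still do.  This mirrors treating each adjacent duplex pair as its own
miRNA while still rejecting loci whose pairs overlap.

Offset (moR-style) pairs are found by masking reads within ±2 nt of the
primary modal starts, re-calling arms on the residue, and accepting the
secondary duplex only if both its arms clear the read-support and
homogeneity bars and each secondary arm lies within 3 nt of (without
overlapping) the primary arm.  The base-proximal pair is labelled "-1",
the loop-proximal "-2".

### Overhang geometry

For a duplex with mir-5p = [a, a+L) and mir-3p = [b, b+L) in hairpin
coordinates, the two RNase-III-signature overhangs are

    overhang_arm3 = (b + L − 1) − partner(a)
    overhang_arm5 = (a + L − 1) − partner(b)

If the referenced terminus is unpaired, the nearest paired position within
3 nt inward is used with a register correction; an unresolvable terminus
makes criterion ii fail rather than raising.

## The folding model

The internal folder is a deterministic weighted base-pair maximisation
(Nussinov-style dynamic program): pair pseudo-energies G-C = −2,
A-U = −1, G-U = −1, minimum hairpin loop 3 nt, ties broken by pairing the
5′-most position that any optimal structure pairs, with the 3′-most
admissible partner.  It is verified against an independent exhaustive
recursion on short random sequences (score and structural legality).  It
is *not* a thermodynamic nearest-neighbour model, so the classical
−0.2 kcal/mol/nt density threshold is only applied to externally supplied
structures (three-line text files: sequence, dot-bracket, `energy=`);
for the internal pseudo-energies the default is recalibrated to −0.5 per
nt, configurable.  Windows are capped at 500 nt (O(n³) dynamic program).

## Read classification

Reads are assigned to the single highest-priority annotation class among
features they overlap by at least half their length; mRNA (and exon/intron)
hits split by strand into sense/antisense; no qualifying feature means
intergenic.  The priority order — structured ncRNAs, then repeats, then
mRNA — is a design choice (the field reports no canonical order):
structured ncRNAs are unambiguous annotations, and repeats-before-mRNA
keeps the dominant retrotransposon class intact where repeats overlap gene
models.  Candidate hairpins are deliberately *not* a class, so miRNA reads
land in "intergenic", as they do in the field's genome-wide summaries.
Multimappers count once at their reported placement by default; 1/hits
fractional weighting is available.

## Transcript extents, enrichment, readthrough

Extents come from per-base coverage depth (5′-most and 3′-most positions
with depth ≥ `min_depth`, default 1) rather than from individual read
ends; discrete 3′-end observations (RACE-clone style) have a separate end
census whose dominant end breaks ties 3′-most.  Keeping the two apart
separates sequencing-depth artifacts from biology.  Knockout enrichment is
a cpm log2 fold change with pseudocount 1 over the locus window.
Readthrough walks coverage from the hairpin 3′ edge toward a downstream
gene; a zero-coverage run is tolerated only if ≤ 50 nt long **and** ≥ 80%
A on the locus strand — A-homopolymer tracts defeat both sequencing and
poly(A) selection, so a covered transcript can legitimately appear
interrupted there.  Both knobs are configuration; the tolerance is an
operationalisation of a qualitative observation, so it is deliberately
permissive and monotone in `max_gap`.

## Tails and the promoter motif

Tail calling uses maximal templated extension from the read's anchored 5′
end; the unmatched 3′ suffix is the tail, and `is_oligoA` requires a
non-empty all-A suffix of ≤ 10 nt.  When the templated end lies in an A
tract contiguous with an all-A suffix the true cleavage point is
undecidable; the call reports a `[tail_len_min, tail_len_max]` range (the
suffix length plus the number of contiguous templated terminal A's) and,
by convention, the last templated A as the templated 3′ end.

The motif search scans a 140-nt window upstream of the 5′-most covered
position (inclusive) for maximal T-homopolymer runs of ≥ 8 nt immediately
followed by a G; the G is the predicted transcription start.  The minimum
run length is a default chosen below the reported run lengths (21 and 26)
since no minimum is established; hits rank by run length, then proximity
to the anchor — an invented deterministic rule standing in for
experimental TSS mapping.  The position frequency matrix aligns hit
windows at the G (+1 column, G frequency 1 by construction) over 30
upstream positions; it is exactly the mean of the per-locus one-hot
matrices.

## The synthetic-data generator

The generator *is* the study conditions; its defaults are fixed once:

* genome 50 kb, background ~78% AT, with T-runs ≥ 7 and A-runs ≥ 13 in
  background sequence broken so no spurious promoter motifs or coverage
  gaps arise;
* 20 miRNA loci (2 with adjacent offset pairs, 1 reading through into a
  downstream gene across a planted 30-nt A-run), 10 decoys, 5 siRNA repeat
  loci from a dispersed family, plus structured ncRNA, mRNA and
  complex-repeat features; ~30% of generic loci on the − strand;
* the first locus reproduces the worked example exactly: TSS 281 nt
  upstream of the mir-5p (21-T run), primary 3′ end at +388,
  3′-intermediates at +243/+248 with three templated A's before the +248
  cut; the readthrough locus has its TSS at −116 behind a 26-T run;
* read counts are negative binomial (gamma-Poisson, dispersion 0.1) with
  one expression latent per (locus, timepoint) shared across arms, duplex
  pairs and genotypes — so arm ratios are set by the planted means, the
  knockout contrast by the 50× depletion factor, and unaffected loci
  differ between genotypes by Poisson sampling only;
* arm means (pooled wild type): 55 (5p) / 38 (3p), doubled at offset-pair
  loci whose secondary pairs get 45/35 — the primary pair must own the
  modal read of each arm; read lengths 20–23 peaked at 21; 5′ ends modal
  with probability equal to the locus's planted homogeneity (drawn
  0.70–0.95), otherwise jittered ±1–3 nt; knockout homogeneity halved;
* background small RNAs come from discrete intergenic source regions (the
  spacers between planted blocks), not a genome-wide carpet — real
  intergenic small RNAs cluster at source loci, and a uniform carpet at
  desk scale would bury every arm in off-locus reads at densities no real
  34-Mb genome produces;
* coverage is noiseless by design (planted depth 5, ×8 in the knockout,
  zero over A-run gaps) so extent recovery is exact at `min_depth` 1;
* planted hairpins are palindromic {G,A}-against-reverse-complement stems
  (base GC fraction 0.75, G-C forced at the stem boundaries) between
  homopolymer flanks (A left, T right; C for the inert decoy variants).
  Under the pair-maximisation model every alternative pairing either
  crosses a G-C-anchored stem (strict loss) or nests outside it without
  touching the register, so the planted geometry is the unique optimum —
  the generator and the caller are provably self-consistent.

Each decoy violates exactly one criterion: too few 3p reads (counts
clipped ≤ 9, precise reads so nothing else fails); 5′ homogeneity 0.40;
6-nt overhangs (fails even the relaxed mode, so the failure is a clean
rejection); an A-U-only outer stem whose energy density stays above the
cut-off while the duplex remains fully paired; a duplex that is mostly a
long internal loop (pairing ~0.38) between an outer stem anchoring the
overhang-relevant termini and a deep loop-ward stem restoring the energy
criterion.  Non-read-support decoy arm counts are clipped ≥ 14 pooled so
the single violation is a generator contract, not a sampling accident.

### What the generator does not emulate

Sequencing errors, adapters and quality scores; genuine mapping ambiguity
(alignments are true placements; the naive matcher path is exercised by
reconstructing read sequences from the genome); thermodynamic folding
(planted stems are designed for the internal model); biological 5′-end
isomiR structure beyond symmetric jitter; coverage noise.  Passing tests
therefore demonstrate the correctness and self-consistency of the
pipeline's logic under controlled statistics, not performance on real
libraries — in particular the real study's genome-wide percentages depend
on a 34-Mb genome and its full annotation and are not reproduced here.

## Problem sizes

The default scenario (50-kb genome, ~110 k reads per library, four
libraries, 30 folded candidate windows) runs the whole pipeline in well
under a minute on one core; the test suite holds one such simulation in a
session fixture and reuses it.  These sizes were chosen as the smallest at
which every planted effect (50× depletion, 8× enrichment, class-fraction
stability) is statistically unambiguous.

## Known limitations

* The internal energy scale is a pseudo-energy; absolute thresholds are
  only comparable within a backend.
* The readthrough gap tolerance can in principle bridge an unrelated
  A-rich gap between two adjacent transcription units; it is reported with
  the tolerated gaps so a user can audit every bridge.
* Multi-segment genomes are supported by the formats layer but the
  simulator plants everything on a single segment.
* The criteria engine evaluates candidate windows it is given; de novo
  hairpin discovery is out of scope by design.
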