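# Methods

`uceforge` implements the hybrid recipe for designing ultraconserved-element
(UCE) target-enrichment probe sets from a panel of genome and/or
transcriptome assemblies, together with the in-silico capture protocol used
to evaluate such sets. This note documents the model, the parameters that
matter, the numerical choices, and what the synthetic test panels do and do
not establish.

## The procedure

**Discovery.** Error-free reads (default 100 bp at 50 bp stride, i.e. 2x
tiling) are simulated from every non-reference assembly and mapped back to a
designated reference. A read counts only if it aligns full-length at
identity >= 1 - `max_divergence` (default 0.05) to a *unique* location;
multi-mapping reads are discarded as a cheap orthology guard. A reference
position supported by at least `ceil(occupancy_fraction x n_taxa)` taxa
(the reference supports itself; defaults 0.90 for genome panels, 0.75 for
transcriptome panels) seeds a candidate conserved interval. Candidates are
merged when separated by strictly less than 100 bp, then filtered: repeat
content (soft-masked fraction) above 25% or length below 160 bp drops a
locus. Locus ids `uce-<N>` are assigned in (contig, start) order.

**Design.** Each locus receives `probes_per_locus` = 2 probes of 120 bp at a
stride of `probe_length / tiling_density` = 40 bp, placed symmetrically so
both cover the locus midpoint (starts mid-100 and mid-60, clamped into the
locus). Probes with GC outside [0.30, 0.70] or more than 25% repeat-masked
positions are dropped individually; a locus whose probes all fail is
reported as undesignable. The reference-only *temporary* set is self-screened
for redundancy at 50% identity / 50% coverage; loci recovered by it in at
least `min_species_for_final` = 15 assemblies (at identity 0.50 / coverage
0.83) become *final* loci; the *master* set re-designs probes from every
assembly's own copy of each final locus (located by matching the reference
locus sequence; minus-strand copies are reverse-complemented first), pools
them, and self-screens again. Subsets restrict the master set to chosen
source taxa; two independently built sets (genome-based and
transcriptome-based) merge by cross-screening at 50% identity with the
first set's probes winning ties.

**Capture.** Probes are matched to an assembly at the capture thresholds
(identity 0.50 by default, 0.75 for genome-derived probes against genomes;
coverage 0.83); per locus, hits collapse to maximal intervals; each interval
plus the flank (0-400 bp) is sliced out, clipped at contig ends, and
reverse-complemented for minus-strand hits so output is probe-oriented.
Slices are re-matched to the probes at identity 0.80 / probe coverage 0.67.
A slice matching probes of more than one locus is removed; a locus matched
by more than one slice in an assembly is removed for that taxon; matches
within one locus's own overlapping probe cohort are intentional and never
count as conflicts. Per-taxon efficiency is captured loci divided by the
set's distinct target loci; panels aggregate into a boolean loci x taxa
occupancy matrix (loci below a 3-taxon floor removed), a pairwise
shared-locus matrix S = O^T O, and strict-majority occupancy sublists
(> 50%, > 75% of taxa).

## Alignment engine

Every identity/coverage decision runs through one local matcher. Candidate
regions come from exact 12-mer seeds on both strands (2-bit k-mer codes;
windows containing N are unindexed); queries of >= 200 bp require two seeds
per diagonal cluster before a window is opened, since a lone shared 12-mer
between unrelated sequences is noise at that length. Each window is resolved
with an optimal Smith-Waterman alignment (Biopython's C `PairwiseAligner`);
matched spans are hard-masked and the window re-searched so tandem copies
are each reported. Contigs of <= 3 kb skip seeding entirely and are searched
exhaustively, which makes the matcher *exactly* optimal on small targets —
the property the test suite verifies against an independent full-DP oracle.

Scoring is pinned at match +1, mismatch -1, gap open -5, gap extend -2
(a gap of length L costs 5 + 2(L-1)). The gap costs are deliberately harsh,
in the spirit of LASTZ's defaults. With soft gap costs (e.g. open -2,
extend -1) the optimal local alignment between two *unrelated* 120-mers
routinely stretches past 50% identity at 50% coverage by absorbing cheap
gaps, which would make a 50/50 redundancy screen collapse unrelated loci;
under the pinned scheme 0 of 2000 random probe pairs qualify. Identity
counts gap columns as non-matching columns; query coverage is the aligned
query span over the query length; in the symmetric pair screen coverage is
taken against the shorter sequence.

Seeding bounds sensitivity: a qualifying alignment with no exact shared
12-mer cannot be found. At the divergences the panels model (<= 15%) the
probability that a 120 bp true match lacks a 12-mer seed is negligible; for
real data at 50% identity the matcher, like any seeded aligner, undercalls.

**Redundancy screen semantics.** The 50/50 screen builds a similarity graph
(edge = best local alignment in either orientation meets both thresholds)
and keeps one probe per connected component, chosen by source-taxon priority
then lexicographic id. Probes sharing *both* locus id and source taxon are
never linked: the two tiled probes of one locus overlap by 80/120 bp by
construction, and a literal screen would collapse every locus to a single
probe, defeating the tiling design. Cross-locus and cross-taxon links are
honoured, with two visible consequences that are properties of the method,
not artifacts: (i) near-identical cross-taxon copies of a locus chain into
one or two representatives, so master sets shrink far below
taxa x 2 x loci; (ii) occasionally two unrelated loci link through a
tail-probability alignment (pairs that share a seed k-mer are precisely the
enriched tail of the random-score distribution), costing the master set a
few percent of its loci — the screen trades those for a guarantee that no
retained pair is mutually similar.

## Synthetic panels

`generate_panel` plants `n_loci` cores (uniform 300-600 bp) separated by
spacers (uniform 600-900 bp) in a random ancestral genome; ~30% of spacers
carry one soft-masked tandem-repeat tract (motif 2-6 bp, 60-180 bp).
Evolution is substitution-only (uniform choice among the three alternative
bases) on a star phylogeny: taxon 1 is the reference and sits at the
ancestor, other taxa draw a core rate from 1-3% and evolve background at
15%, so pairwise core divergence to the reference equals the taxon's own
rate. Optional per-(taxon, locus) dropout replaces a core with random
sequence; transcriptome views export an expressed subset of cores (default
85%) with 50 bp of native flank, as exact genome substrings. Everything is
driven by one `numpy` generator per call, so identical seed and parameters
reproduce byte-identical FASTA.

Spacer lengths are set above the largest flank the capture experiments use
(400 bp) so that flank sweeps cannot make neighbouring loci collide except
where discovery itself splits a core; core divergence sits well below the
5% mapping ceiling and background divergence well above it (pairwise ~26%),
which is what makes zero false discovery an expectation rather than a hope.

What the panels do **not** model: indels (coordinates stay exact by
construction; an indel-bearing panel would exercise the gapped paths of the
matcher more heavily), paralogy beyond exact tandem duplication fixtures,
assembly gaps/errors, rate heterogeneity within a partition, GC bias, and
realistic tree shape. Green tests therefore establish that the pipeline's
logic — thresholds, filters, conflict rules, matrices, determinism — is
correct, not that any particular efficiency will be attained on real
assemblies.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; 1-based appears only in
  human-readable report text.
- "Merged at distances less than 100 bp" is strict: a gap of exactly 100 bp
  stays split. Likewise the repeat filter drops strictly more than 25%.
- N bases: excluded from both numerator and denominator of GC; counted as
  unmasked by the repeat fraction (N is ambiguity, not repeat); probes
  containing N are not emitted; k-mers containing N are not indexed.
- The occupancy count uses `ceil(fraction x total taxa)` and can be
  overridden with an explicit integer (`occupancy_min_taxa`) for panels
  whose published thresholds don't reduce to a clean fraction.
- Read mapping verifies candidates gap-free first (substitution-only
  placements are exact); candidates falling within 0.05 of the identity
  ceiling are re-scored with a full local alignment so small indels do not
  silently lose coverage ("gapped rescue").
- Master-set loci are located in each assembly by aligning the full
  reference locus sequence (best qualifying hit at the master thresholds)
  rather than the temporary probes: the longer query defines the interval,
  and probe design then proceeds on the assembly's own sequence.
- Mean-efficiency exclusions (taxa with degenerate assemblies) are a config
  list and are flagged in the per-taxon summary rather than dropped.
- Dedupe determinism: representative = (source-taxon priority, probe id);
  merged sets prefer the first set on ties. No stage uses randomness, so
  byte-identical outputs under a fixed seed are a hard invariant, not a
  statistical one.

## Problem sizes used in the checks

The standard discovery panel is 20 taxa x 200 loci (~240 kb per genome);
the mixed-set (GP/TP/MP) experiment uses 10 taxa x 30 loci with 12% dropout
and 85% expression, sizes at which every stage's behaviour is exercised and
the all-pairs dissimilarity audit can run against the brute-force DP oracle.
Counts from these panels (probes per set, loci retained, efficiencies) are
printed by the run reports and recomputed by `scripts/acceptance.py`; they
characterise the method's behaviour under the stated panel conditions.
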